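"""Brownian-dynamics point-load simulator for bead-spring lamin meshworks.

Protocol (mirroring the in-silico AFM pushing experiment):

1. ``relax``: thermal annealing of the discretized meshwork adhered to the
   substrate plane, followed by energy minimization;
2. ``select_push_site``: a random non-junction bead on a filament near the
   middle of the meshwork (to limit free-edge effects);
3. ``push``: the selected bead is displacement-clamped and driven at constant
   speed normal to the meshwork plane while every other bead undergoes
   overdamped Langevin dynamics at 300 K; the restoring force on the driver
   is recorded against its displacement, bonds stretched beyond the rupture
   distance r_b break permanently, and the force-extension (FE) curve with
   plateau -> stiffening -> failure-drop structure is returned.

The integrator is overdamped (Brownian) dynamics,
x += F dt/gamma + sqrt(2 kT dt/gamma) xi, appropriate for the quasi-static,
heavily damped loading regime; the loading speed is validated by the
quasi-static property (halving it leaves the measured strength unchanged
within tolerance) rather than by a mapping to wall-clock speed.

Internal units: Angstrom, kcal/mol, gamma = 1 (time unit = gamma A^2 /
(kcal/mol)).  Public inputs/outputs use nm and nN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .forcefield import ForceFieldParams, DEFAULT_PARAMS, KBOLTZ_KCALMOL, force_to_nN
from .forcefield import _energy_table
from .meshgen import BeadModel

logger = logging.getLogger("laminmesh")

__all__ = [
    "SimulationConfig",
    "FECurve",
    "Trajectory",
    "relax",
    "select_push_site",
    "push",
    "force_clamp",
    "segment_strain_distribution",
    "strength_toughness",
]

_NM = 10.0  # A per nm


@dataclass
class SimulationConfig:
    """Parameters of the relaxation and pushing protocol.

    Times are in the internal unit gamma*A^2/(kcal/mol); the loading speed is
    expressed as integration steps per nm of driver displacement, which is
    the only loading-rate quantity with observable consequences in the
    overdamped quasi-static regime.
    """

    temperature: float = 300.0          # K
    gamma: float = 1.0                  # friction, internal units
    dt: float = 0.02                    # stable for the stiffest branch (~33 kcal/mol/A^2)
    steps_per_nm: int = 2000            # loading speed (quasi-static at default)
    max_displacement: float = 25.0      # nm
    seed: int = 0
    anneal: list = field(default_factory=lambda: [(600.0, 1000), (300.0, 2000)])
    substrate: bool = True
    smooth_window_nm: float = 0.1       # force low-pass window (driver displacement)
    record_stride_nm: float = 1.0       # trajectory frame spacing
    neighbor_skin: float = 6.0          # A added to the nonbond cutoff
    chunk_steps: int = 250
    early_stop: bool = True             # stop once the load has collapsed after failure
    early_stop_force_nN: float = 0.05
    min_gtol: float = 5e-3              # minimizer projected-gradient tolerance
    params: ForceFieldParams = field(default_factory=ForceFieldParams)

    @property
    def kT(self) -> float:
        return KBOLTZ_KCALMOL * self.temperature


@dataclass
class FECurve:
    """Force-extension record: ordered (deformation nm, force nN) samples."""

    d: np.ndarray
    f: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if len(self.d) != len(self.f):
            raise ValueError("d and f must have equal length")
        if len(self.d) > 1 and np.any(np.diff(self.d) < -1e-9):
            raise ValueError("deformation must be non-decreasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("non-finite force values")

    def __len__(self):
        return len(self.d)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"d_nm": self.d, "F_nN": self.f}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "FECurve":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(d=df["d_nm"].to_numpy(), f=df["F_nN"].to_numpy(), meta=meta)


@dataclass
class Trajectory:
    """Sampled bead positions plus the per-step driver record."""

    times: np.ndarray            # internal units, frame times
    frames: np.ndarray           # (n_frames, n_beads, 3) nm
    frame_d: np.ndarray          # driver displacement at each frame, nm
    bond_lengths: np.ndarray     # (n_frames, n_bonds) nm
    broken_events: list          # (bond index, step) in breaking order
    driver_d: np.ndarray         # per-step displacement, nm
    driver_f: np.ndarray         # per-step raw force, nN
    work_nNnm: float = 0.0       # work done by the driver
    potential_start: float = 0.0  # kcal/mol
    potential_end: float = 0.0

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for t, fr in zip(self.times, self.frames):
                fh.write(f"{len(fr)}\ntime={t}\n")
                for x, y, z in fr:
                    fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")

    def write_events_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.broken_events, columns=["bond", "step"]).to_csv(
            path, index=False)


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _tensile_f(r, pp):
    if r < pp[6]:
        br = pp[0] * (r - pp[5])
    elif r < pp[7]:
        br = pp[11] + pp[1] * (r - pp[6])
    elif r < pp[8]:
        d = r - pp[7]
        br = pp[12] + (pp[2] + (pp[3] + pp[4] * d) * d) * d
    else:
        br = pp[13]
    x = (r - pp[9]) / pp[9] * pp[10]
    if x < -30.0:
        s = 1.0
    elif x > 500.0:
        s = 0.0
    else:
        s = 1.0 / (np.exp(x) + 1.0)
    return br * s


@njit(cache=True)
def _accumulate_forces(pos, F, bonds, broken, angles, pairs, pp, use_substrate,
                       break_now, allow_break):
    """Fill F with -grad(E); flag bonds beyond rb in break_now when allowed."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    # bonds
    for b in range(bonds.shape[0]):
        if broken[b]:
            continue
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            continue
        if allow_break and r > pp[9]:
            break_now[b] = True
            continue
        f = _tensile_f(r, pp) / r
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
    # angles (theta0 = pp[15], stiffness pp[14])
    for t in range(angles.shape[0]):
        i, j, k = angles[t, 0], angles[t, 1], angles[t, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb_ = np.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-9 or rb_ < 1e-9:
            continue
        c = (ax * bx + ay * by + az * bz) / (ra * rb_)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = pp[14] * (th - pp[15]) / s
        # dcos/dri = (b_hat - c*a_hat)/ra ; dcos/drk = (a_hat - c*b_hat)/rb
        fix = coef * (bx / rb_ - c * ax / ra) / ra
        fiy = coef * (by / rb_ - c * ay / ra) / ra
        fiz = coef * (bz / rb_ - c * az / ra) / ra
        fkx = coef * (ax / ra - c * bx / rb_) / rb_
        fky = coef * (ay / ra - c * by / rb_) / rb_
        fkz = coef * (az / ra - c * bz / rb_) / rb_
        F[i, 0] += fix
        F[i, 1] += fiy
        F[i, 2] += fiz
        F[k, 0] += fkx
        F[k, 1] += fky
        F[k, 2] += fkz
        F[j, 0] -= fix + fkx
        F[j, 1] -= fiy + fky
        F[j, 2] -= fiz + fkz
    # non-bonded cosine repulsion
    A = pp[16]
    rc = pp[17]
    for q in range(pairs.shape[0]):
        i, j = pairs[q, 0], pairs[q, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rc or r < 1e-9:
            continue
        f = A * np.pi / rc * np.sin(np.pi * r / rc) / r
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz
    # substrate 9-3 wall
    if use_substrate:
        eps = pp[18]
        zeq = pp[19]
        zcut = pp[20]
        zfloor = 0.05 * zeq
        for i in range(n):
            z = pos[i, 2]
            if z >= zcut:
                continue
            if z < zfloor:
                z = zfloor
            sr = zeq / z
            s3 = sr * sr * sr
            s9 = s3 * s3 * s3
            F[i, 2] += 4.5 * eps * (s9 - s3) / z


@njit(cache=True)
def _potential_energy(pos, bonds, broken, angles, pairs, pp, use_substrate,
                      tab_r0, tab_dr, tab_e):
    e = 0.0
    for b in range(bonds.shape[0]):
        if broken[b]:
            continue
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < pp[6]:
            e += 0.5 * pp[0] * (r - pp[5]) * (r - pp[5])
        else:
            u = (r - tab_r0) / tab_dr
            idx = int(u)
            if idx >= tab_e.shape[0] - 1:
                e += tab_e[tab_e.shape[0] - 1]
            else:
                w = u - idx
                e += tab_e[idx] * (1.0 - w) + tab_e[idx + 1] * w
    for t in range(angles.shape[0]):
        i, j, k = angles[t, 0], angles[t, 1], angles[t, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb_ = np.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-9 or rb_ < 1e-9:
            continue
        c = (ax * bx + ay * by + az * bz) / (ra * rb_)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        e += 0.5 * pp[14] * (th - pp[15]) * (th - pp[15])
    A = pp[16]
    rc = pp[17]
    for q in range(pairs.shape[0]):
        i, j = pairs[q, 0], pairs[q, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rc:
            e += A * (1.0 + np.cos(np.pi * r / rc))
    if use_substrate:
        eps = pp[18]
        zeq = pp[19]
        zcut = pp[20]
        sc = zeq / zcut
        shift = eps * (0.5 * sc**9 - 1.5 * sc**3)
        zfloor = 0.05 * zeq
        for i in range(pos.shape[0]):
            z = pos[i, 2]
            if z >= zcut:
                continue
            if z < zfloor:
                z = zfloor
            sr = zeq / z
            s3 = sr * sr * sr
            s9 = s3 * s3 * s3
            e += eps * (0.5 * s9 - 1.5 * s3) - shift
    return e


@njit(cache=True)
def _dynamics_chunk(pos, mobile, bonds, broken, angles, pairs, pp,
                    use_substrate, dt, gamma, kT, nsteps, driver, vz_step,
                    f_rec, rec_off, noise, break_step, step0, allow_break):
    """Integrate nsteps of overdamped Langevin dynamics.

    The driver bead (if >= 0) moves vz_step in z per step; f_rec records the
    reaction force (kcal/mol/A, +z resisting the motion) before each move.
    noise is a pre-drawn (nsteps, n, 3) standard-normal block (empty at T=0).
    Bonds beyond rb break permanently when allow_break.
    """
    n = pos.shape[0]
    F = np.empty((n, 3))
    amp = np.sqrt(2.0 * kT * dt / gamma)
    mob = dt / gamma
    bnow = np.zeros(broken.shape[0], dtype=np.bool_)
    use_noise = kT > 0.0 and noise.shape[0] >= nsteps
    for t in range(nsteps):
        if allow_break:
            for b in range(broken.shape[0]):
                bnow[b] = False
        _accumulate_forces(pos, F, bonds, broken, angles, pairs, pp,
                           use_substrate, bnow, allow_break)
        if allow_break:
            for b in range(broken.shape[0]):
                if bnow[b]:
                    broken[b] = True
                    break_step[b] = step0 + t
        if driver >= 0:
            f_rec[rec_off + t] = -F[driver, 2]
            pos[driver, 2] += vz_step
        if use_noise:
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] += F[i, 0] * mob + amp * noise[t, i, 0]
                    pos[i, 1] += F[i, 1] * mob + amp * noise[t, i, 1]
                    pos[i, 2] += F[i, 2] * mob + amp * noise[t, i, 2]
        else:
            for i in range(n):
                if mobile[i]:
                    pos[i, 0] += F[i, 0] * mob
                    pos[i, 1] += F[i, 1] * mob
                    pos[i, 2] += F[i, 2] * mob
    return 0


# --------------------------------------------------------------------------
# neighbor lists
# --------------------------------------------------------------------------

def _exclusion_keys(model: BeadModel) -> np.ndarray:
    """Sorted encoded (i<j) pairs within 2 bonds of each other."""
    n = model.n_beads
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in model.bonds:
        adj[i].append(int(j))
        adj[j].append(int(i))
    keys = set()
    for i in range(n):
        first = adj[i]
        second = {w for v in first for w in adj[v]}
        for j in set(first) | second:
            if j != i:
                a, b = (i, j) if i < j else (j, i)
                keys.add(a * n + b)
    return np.array(sorted(keys), dtype=np.int64)


def _nonbond_pairs(pos_A: np.ndarray, cutoff: float, excl: np.ndarray,
                   n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2), dtype=np.int64)
    tree = cKDTree(pos_A)
    pairs = tree.query_pairs(cutoff, output_type="ndarray").astype(np.int64)
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    keys = pairs[:, 0] * n + pairs[:, 1]
    idx = np.searchsorted(excl, keys)
    idx = np.clip(idx, 0, len(excl) - 1) if len(excl) else idx
    mask = np.ones(len(pairs), dtype=bool)
    if len(excl):
        mask = excl[idx] != keys
    return pairs[mask]


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------

def _arrays(model: BeadModel):
    pos = model.positions * _NM  # nm -> A
    bonds = np.ascontiguousarray(model.bonds)
    angles = np.ascontiguousarray(model.triplets)
    broken = model.broken.copy()
    return np.ascontiguousarray(pos), bonds, angles, broken


def relax(model: BeadModel, config: SimulationConfig | None = None,
          pinned=None) -> BeadModel:
    """Thermal annealing followed by energy minimization on the substrate.

    Returns a new BeadModel at a local potential-energy minimum; raises if
    the minimizer does not reach the gradient tolerance or any bond remains
    stretched beyond r1 (incomplete relaxation).
    """
    cfg = config or SimulationConfig()
    pp = cfg.params.as_array()
    pos, bonds, angles, broken = _arrays(model)
    n = len(pos)
    if n == 0:
        return model
    mobile = np.ones(n, dtype=bool)
    if pinned is not None:
        mobile[np.asarray(pinned, dtype=int)] = False
    excl = _exclusion_keys(model)
    cutoff = cfg.params.rc_nb + cfg.neighbor_skin
    rng = np.random.default_rng(cfg.seed)
    f_rec = np.zeros(1)
    break_step = np.full(len(bonds), -1, dtype=np.int64)

    for temp, steps in cfg.anneal:
        kT = KBOLTZ_KCALMOL * float(temp)
        done = 0
        while done < steps:
            take = min(cfg.chunk_steps, steps - done)
            pairs = _nonbond_pairs(pos, cutoff, excl, n)
            noise = (rng.standard_normal((take, n, 3)) if kT > 0
                     else np.zeros((0, 1, 3)))
            _dynamics_chunk(pos, mobile, bonds, broken, angles, pairs, pp,
                            cfg.substrate, cfg.dt, cfg.gamma, kT, take, -1,
                            0.0, f_rec, 0, noise, break_step, 0, False)
            done += take
            if not np.isfinite(pos).all():
                raise FloatingPointError("instability during annealing")

    # minimization (nonbond pairs refreshed between rounds)
    rt, et = _energy_table(cfg.params)
    tab_r0, tab_dr = rt[0], rt[1] - rt[0]
    free = np.flatnonzero(mobile)

    for _ in range(4):
        pairs = _nonbond_pairs(pos, cutoff, excl, n)

        dummy = np.zeros(len(bonds), dtype=bool)

        def fun(x, pos=pos, pairs=pairs, dummy=dummy):
            p = pos.copy()
            p[free] = x.reshape(-1, 3)
            F = np.empty_like(p)
            _accumulate_forces(p, F, bonds, broken, angles, pairs, pp,
                               cfg.substrate, dummy, False)
            e = _potential_energy(p, bonds, broken, angles, pairs, pp,
                                  cfg.substrate, tab_r0, tab_dr, et)
            return e, -F[free].ravel()

        res = minimize(fun, pos[free].ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "gtol": cfg.min_gtol,
                                "ftol": 1e-12})
        pos[free] = res.x.reshape(-1, 3)

    grad_inf = float(np.abs(res.jac).max()) if len(free) else 0.0
    # residual threshold ~0.15 nN per bead, far below the nN force scale
    if grad_inf > 2.0:
        raise RuntimeError(
            f"relaxation did not converge: max |grad| = {grad_inf:.3g} kcal/mol/A")
    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    blen = np.linalg.norm(d, axis=1)
    if len(blen) and blen[~broken].max() > cfg.params.r1:
        raise RuntimeError("relaxation left a bond stretched beyond r1")
    out = replace(model)
    out.positions = pos / _NM
    out.broken = broken
    return out


def select_push_site(model: BeadModel, seed=None,
                     central_fraction: float = 0.5) -> int:
    """A non-junction bead on a filament whose midpoint is central.

    The central region is the axis-aligned box of side ``central_fraction``
    times the meshwork extent, centered on the meshwork centroid (x, y).
    """
    if model.n_beads == 0:
        raise ValueError("empty model")
    xy = model.positions[:, :2]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    c = 0.5 * (lo + hi)
    half = 0.5 * central_fraction * (hi - lo)
    rng = np.random.default_rng(seed)
    candidates = []
    for chain in model.edge_beads:
        if len(chain) < 3:
            continue  # no interior bead
        mid = model.positions[chain, :2].mean(axis=0)
        if np.all(np.abs(mid - c) <= np.maximum(half, 1e-9)):
            candidates.append(chain)
    if not candidates:
        raise ValueError("no filament with interior beads in the central region")
    chain = candidates[rng.integers(len(candidates))]
    interior = chain[1:-1]
    # push at the middle of the chosen filament (transverse point load)
    return int(interior[len(interior) // 2])


def push(model: BeadModel, bead: int, config: SimulationConfig | None = None,
         pinned=None, return_trajectory: bool = True):
    """Constant-velocity displacement clamp on one bead, normal to the plane.

    Returns (FECurve, Trajectory).  The FE force is the reaction force on the
    driver, low-pass filtered over ``smooth_window_nm`` of displacement; the
    raw per-step record is kept in the trajectory.
    """
    cfg = config or SimulationConfig()
    pp = cfg.params.as_array()
    pos, bonds, angles, broken = _arrays(model)
    n = len(pos)
    if n == 0 or bead < 0 or bead >= n:
        raise ValueError("invalid driver bead")
    mobile = np.ones(n, dtype=bool)
    mobile[bead] = False
    if pinned is not None:
        mobile[np.asarray(pinned, dtype=int)] = False
    excl = _exclusion_keys(model)
    cutoff = cfg.params.rc_nb + cfg.neighbor_skin
    rng = np.random.default_rng(cfg.seed)
    kT = cfg.kT

    total_steps = int(round(cfg.max_displacement * cfg.steps_per_nm))
    vz_step = _NM / cfg.steps_per_nm if cfg.steps_per_nm > 0 else 0.0  # A/step
    driver_bonds = np.flatnonzero((bonds[:, 0] == bead) | (bonds[:, 1] == bead))
    f_rec = np.zeros(max(total_steps, 1))
    break_step = np.full(len(bonds), -1, dtype=np.int64)

    rt, et = _energy_table(cfg.params)
    pairs0 = _nonbond_pairs(pos, cutoff, excl, n)
    e_start = _potential_energy(pos, bonds, broken, angles, pairs0, pp,
                                cfg.substrate, rt[0], rt[1] - rt[0], et)

    rec_stride = max(1, int(round(cfg.record_stride_nm * cfg.steps_per_nm)))
    frames, ftimes, framed, framelens = [], [], [], []

    def snapshot(step):
        frames.append(pos.copy() / _NM)
        ftimes.append(step * cfg.dt)
        framed.append(step * vz_step / _NM)
        d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
        framelens.append(np.linalg.norm(d, axis=1) / _NM)

    snapshot(0)
    done = 0
    while done < total_steps:
        take = min(cfg.chunk_steps, total_steps - done)
        pairs = _nonbond_pairs(pos, cutoff, excl, n)
        noise = (rng.standard_normal((take, n, 3)) if kT > 0
                 else np.zeros((0, 1, 3)))
        _dynamics_chunk(pos, mobile, bonds, broken, angles, pairs, pp,
                        cfg.substrate, cfg.dt, cfg.gamma, kT, take, bead,
                        vz_step, f_rec, done, noise, break_step, done, True)
        done += take
        if not np.isfinite(pos).all():
            raise FloatingPointError(f"instability at step {done}")
        if done // rec_stride > (done - take) // rec_stride or done == total_steps:
            snapshot(done)
        if cfg.early_stop and len(driver_bonds) and broken[driver_bonds].all():
            # the pushed filament has parted on both sides of the driver:
            # the record past this point is contact with other filaments
            f_rec = f_rec[:done]
            total_steps = done
            break
        if cfg.early_stop and broken.any():
            w = max(1, int(0.5 * cfg.steps_per_nm))
            recent = f_rec[max(0, done - w):done]
            if len(recent) and force_to_nN(np.abs(recent).max()) < cfg.early_stop_force_nN:
                f_rec = f_rec[:done]
                total_steps = done
                break

    pairs = _nonbond_pairs(pos, cutoff, excl, n)
    e_end = _potential_energy(pos, bonds, broken, angles, pairs, pp,
                              cfg.substrate, rt[0], rt[1] - rt[0], et)

    d_nm = (np.arange(total_steps) + 1) * (vz_step / _NM)
    f_nN = force_to_nN(f_rec[:total_steps])
    # low-pass: moving average over the smoothing window
    w = max(1, int(round(cfg.smooth_window_nm * cfg.steps_per_nm)))
    if total_steps > 0 and w > 1:
        from scipy.ndimage import uniform_filter1d
        f_s = uniform_filter1d(f_nN, size=w, mode="nearest")
    else:
        f_s = f_nN
    # decimate to ~10 samples per smoothing window
    stride = max(1, w // 10)
    curve = FECurve(d=d_nm[::stride], f=f_s[::stride],
                    meta={"steps_per_nm": cfg.steps_per_nm, "seed": cfg.seed,
                          "bead": bead, "temperature": cfg.temperature})
    events = sorted(
        [(int(b), int(break_step[b])) for b in np.flatnonzero(break_step >= 0)],
        key=lambda e: e[1])
    work = float(np.sum(f_rec[:total_steps]) * vz_step)  # kcal/mol
    traj = Trajectory(
        times=np.asarray(ftimes), frames=np.asarray(frames),
        frame_d=np.asarray(framed), bond_lengths=np.asarray(framelens),
        broken_events=events,
        driver_d=d_nm, driver_f=f_nN,
        work_nNnm=force_to_nN(work) * 0.1,  # kcal/mol -> nN*nm (0.1 nm per A)
        potential_start=float(e_start), potential_end=float(e_end),
    )
    model.broken = broken
    model.positions = pos / _NM
    return curve, traj


def force_clamp(model: BeadModel, bead: int, force_nN: float,
                duration_steps: int, config: SimulationConfig | None = None,
                record_stride: int = 50):
    """Constant-force protocol: apply a fixed +z load to one bead.

    Records (time, driver height nm, applied force nN); failure shows up as
    discrete upward height steps.  Included as an in-silico mirror of the
    experimental force-clamp assay.
    """
    import pandas as pd
    cfg = config or SimulationConfig()
    pp = cfg.params.as_array().copy()
    pos, bonds, angles, broken = _arrays(model)
    n = len(pos)
    mobile = np.ones(n, dtype=bool)
    excl = _exclusion_keys(model)
    cutoff = cfg.params.rc_nb + cfg.neighbor_skin
    rng = np.random.default_rng(cfg.seed)
    f_app = force_nN / (force_to_nN(1.0))  # nN -> kcal/mol/A
    rows = []
    break_step = np.full(len(bonds), -1, dtype=np.int64)
    f_rec = np.zeros(1)
    done = 0
    stride = max(1, min(record_stride, cfg.chunk_steps))
    while done < duration_steps:
        take = min(stride, duration_steps - done)
        pairs = _nonbond_pairs(pos, cutoff, excl, n)
        # constant force enters as an extra per-step drift on the driver
        noise = (rng.standard_normal((take, n, 3)) if cfg.kT > 0
                 else np.zeros((0, 1, 3)))
        _dynamics_chunk(pos, mobile, bonds, broken, angles, pairs, pp,
                        cfg.substrate, cfg.dt, cfg.gamma, cfg.kT, take, -1,
                        0.0, f_rec, 0, noise, break_step, done, True)
        pos[bead, 2] += f_app * cfg.dt / cfg.gamma * take
        done += take
        rows.append((done * cfg.dt, pos[bead, 2] / _NM, force_nN))
    return pd.DataFrame(rows, columns=["t_s", "z_nm", "F_nN"])


# --------------------------------------------------------------------------
# observables
# --------------------------------------------------------------------------

def segment_strain_distribution(traj: Trajectory, at_displacement: float,
                                rest_length: float = 1.0, bins: int = 40,
                                range_=(-0.5, 3.0)):
    """Normalized histogram of per-bond strain at a given driver displacement.

    strain = (r - r0)/r0 over unbroken bonds in the trajectory frame closest
    to (and at least reaching) the requested displacement.
    """
    if len(traj.frame_d) == 0 or at_displacement > traj.frame_d[-1] + 1e-9:
        raise ValueError("displacement not reached in trajectory")
    idx = int(np.argmin(np.abs(traj.frame_d - at_displacement)))
    lengths = traj.bond_lengths[idx]
    strains = (lengths - rest_length) / rest_length
    hist, edges = np.histogram(strains, bins=bins, range=range_, density=True)
    return hist, edges


def strength_toughness(curve: FECurve) -> tuple[float, float]:
    """Strength = max force (nN); toughness = area under F(d) (nN*nm)."""
    if len(curve) == 0:
        raise ValueError("empty FE curve")
    strength = float(np.max(curve.f))
    if len(curve) < 2:
        raise ValueError("need >= 2 samples for toughness")
    order = np.argsort(curve.d, kind="stable")
    toughness = float(np.trapezoid(curve.f[order], curve.d[order]))
    return strength, toughness
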