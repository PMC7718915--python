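"""Experiment orchestration and synthetic fixtures.

Drives the topology sweep (regenerate a meshwork at each exponent lambda,
relax, push a central filament, measure strength and toughness, repeat over
replicates, and contrast the extreme exponents with a Welch t-test) and
generates the synthetic records used to validate the analysis code against
known ground truth: FE curves with plateau -> stiffening -> drop morphology,
force-clamp staircases, and jittered polyline skeletons of known graphs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import meshgen, simulator
from .meshgen import MeshGraph, MeshGeometry
from .simulator import FECurve, SimulationConfig
from .topology import FilamentSegmentSet

logger = logging.getLogger("laminmesh")

__all__ = [
    "MeshConfig",
    "SweepResult",
    "generate_mesh",
    "run_topology_sweep",
    "make_synthetic_fecurve",
    "make_synthetic_clamp_trace",
    "make_synthetic_segments",
    "planar_mesh",
    "DESK_PROFILE",
    "FULL_PROFILE",
]


@dataclass
class MeshConfig:
    """Parameters of one meshwork generation run."""

    n_nodes: int = 500
    m_seed: int = 2
    rewire_iters: int = 1_000_000
    coord_iters: int = 600_000
    k_min: int = 3
    k_max: int = 17
    L_mean: float = 12.0
    L_sd: float = 3.0


def generate_mesh(lambda_target: float, cfg: MeshConfig, seed) -> MeshGeometry:
    """Seed graph -> degree rewiring -> placement -> length relaxation."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = ss.spawn(4)

    def sub(s):
        return int(s.generate_state(1)[0] % (2**31 - 1))

    g = meshgen.build_seed_network(cfg.n_nodes, cfg.m_seed, seed=sub(s1))
    g = meshgen.rewire_to_power_law(g, lambda_target, n_iter=cfg.rewire_iters,
                                    k_min=cfg.k_min, k_max=cfg.k_max,
                                    seed=sub(s2))
    geom = meshgen.place_nodes(g, seed=sub(s3))
    return meshgen.relax_edge_lengths(geom, L_mean=cfg.L_mean, L_sd=cfg.L_sd,
                                      n_iter=cfg.coord_iters, seed=sub(s4))


# --------------------------------------------------------------------------
# profiles: problem sizes for a single-workstation run vs the full study
# --------------------------------------------------------------------------

DESK_PROFILE = {
    "mesh": MeshConfig(n_nodes=48, rewire_iters=150_000, coord_iters=120_000),
    "sim": SimulationConfig(steps_per_nm=500, dt=0.03, max_displacement=140.0,
                            anneal=[(600.0, 600), (300.0, 900)]),
    "n_reps": 20,
}

FULL_PROFILE = {
    "mesh": MeshConfig(n_nodes=500, rewire_iters=1_000_000, coord_iters=600_000),
    "sim": SimulationConfig(steps_per_nm=2000, dt=0.02, max_displacement=150.0),
    "n_reps": 100,
}


@dataclass
class SweepResult:
    """Per-lambda strength/toughness replicates and the extreme contrast."""

    lambdas: list
    strength: dict           # lambda -> list of nN
    toughness: dict          # lambda -> list of nN*nm
    failures: dict           # lambda -> count of failed replicates
    t_statistic: float | None = None
    p_value: float | None = None
    contrast: tuple | None = None   # (lambda_low, lambda_high)

    def summary(self) -> pd.DataFrame:
        rows = []
        for lam in self.lambdas:
            s = np.asarray(self.strength[lam])
            t = np.asarray(self.toughness[lam])
            rows.append({
                "lambda": lam, "n": len(s),
                "strength_mean_nN": s.mean() if len(s) else np.nan,
                "strength_sd_nN": s.std() if len(s) else np.nan,
                "toughness_mean_nNnm": t.mean() if len(t) else np.nan,
                "toughness_sd_nNnm": t.std() if len(t) else np.nan,
                "failed": self.failures[lam],
            })
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        d = {
            "lambdas": list(self.lambdas),
            "strength": {str(k): list(map(float, v)) for k, v in self.strength.items()},
            "toughness": {str(k): list(map(float, v)) for k, v in self.toughness.items()},
            "failures": {str(k): int(v) for k, v in self.failures.items()},
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "contrast": self.contrast,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def run_topology_sweep(lambdas, n_reps: int = 100,
                       mesh_config: MeshConfig | None = None,
                       sim_config: SimulationConfig | None = None,
                       seed=0) -> SweepResult:
    """Pushing experiment replicated over freshly generated meshworks.

    For each lambda and replicate: regenerate the meshwork (fresh seed
    stream), relax it on the substrate, pick a random central filament, push
    it to failure, and record strength (max FE force) and toughness (area
    under the FE curve).  Replicate failures (non-convergence, instability)
    are logged and excluded.  When both extreme lambdas have >= 2 successful
    replicates, a Welch t-test contrasts them.
    """
    lambdas = sorted(lambdas)
    if len(lambdas) < 2:
        raise ValueError("need >= 2 lambda values for a contrast")
    mesh_cfg = mesh_config or MeshConfig()
    sim_cfg = sim_config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    strength = {lam: [] for lam in lambdas}
    toughness = {lam: [] for lam in lambdas}
    failures = {lam: 0 for lam in lambdas}
    for lam in lambdas:
        for rep in range(n_reps):
            rep_ss, = ss.spawn(1)
            rep_seed = int(rep_ss.generate_state(1)[0] % (2**31 - 1))
            try:
                geom = generate_mesh(lam, mesh_cfg, rep_seed)
                model = meshgen.discretize(geom)
                cfg = SimulationConfig(**{**asdict_sim(sim_cfg), "seed": rep_seed})
                model = simulator.relax(model, cfg)
                site = simulator.select_push_site(model, seed=rep_seed)
                curve, _ = simulator.push(model, site, cfg)
                curve.meta["lambda"] = lam
                s, t = simulator.strength_toughness(curve)
            except Exception as exc:  # noqa: BLE001 - replicate fault isolation
                logger.warning("replicate lambda=%s rep=%d failed: %s",
                               lam, rep, exc)
                failures[lam] += 1
                continue
            strength[lam].append(s)
            toughness[lam].append(t)
    out = SweepResult(lambdas=lambdas, strength=strength, toughness=toughness,
                      failures=failures)
    lo, hi = lambdas[0], lambdas[-1]
    if len(toughness[lo]) >= 2 and len(toughness[hi]) >= 2 and n_reps > 1:
        t_stat, p = stats.ttest_ind(toughness[hi], toughness[lo],
                                    equal_var=False)
        out.t_statistic = float(t_stat)
        out.p_value = float(p)
        out.contrast = (lo, hi)
    return out


def asdict_sim(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["params"] = cfg.params  # keep the dataclass, not a dict
    return d


# --------------------------------------------------------------------------
# synthetic fixtures (known ground truth for the analysis code)
# --------------------------------------------------------------------------

def make_synthetic_fecurve(plateau_force: float = 0.30,
                           plateau_span: float = 54.0,
                           high_slope: float = 0.30,
                           peak_force: float = 2.4,
                           peak_d: float = 91.0,
                           drop_step: float = 4.3,
                           noise_sd: float = 0.0,
                           dx: float = 0.05,
                           seed=None) -> FECurve:
    """Piecewise FE curve: soft rise -> plateau -> linear stiffening -> drop.

    Parameter defaults follow the population means of pooled AFM pushing
    records (plateau 0.30 nN over ~54 nm, final stiffness 0.30 nN/nm, failure
    2.4 nN at 91 nm, step unit 4.3 nm).  The geometry must close: the
    stiffening ramp needs (peak_force - plateau_force)/high_slope nm, so
    peak_d must exceed plateau_span + ramp span.
    """
    for v in (plateau_force, plateau_span, high_slope, peak_force, peak_d,
              drop_step):
        if v <= 0:
            raise ValueError("parameters must be positive")
    ramp = (peak_force - plateau_force) / high_slope
    rise = peak_d - plateau_span - ramp
    if rise <= 0:
        raise ValueError("inconsistent geometry: peak_d <= plateau span + ramp")
    d = np.arange(0.0, peak_d + drop_step + 5.0, dx)
    f = np.empty_like(d)
    # linear entropic rise to the plateau force (slope ~ the soft stiffness)
    m = d < rise
    f[m] = plateau_force * d[m] / rise
    m = (d >= rise) & (d < rise + plateau_span)
    f[m] = plateau_force
    m = (d >= rise + plateau_span) & (d < peak_d)
    f[m] = plateau_force + high_slope * (d[m] - rise - plateau_span)
    m = d >= peak_d
    f[m] = np.maximum(peak_force - (peak_force / drop_step) * (d[m] - peak_d), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=len(f))
    return FECurve(d=d, f=f, meta={
        "synthetic": True, "plateau_force": plateau_force,
        "plateau_span": plateau_span, "high_slope": high_slope,
        "peak_force": peak_force, "peak_d": peak_d, "drop_step": drop_step,
        "noise_sd": noise_sd, "seed": seed,
    })


def make_synthetic_clamp_trace(steps, noise_sd: float = 0.0,
                               F_load: float = 1.5, dt: float = 0.01,
                               lead_in: float = 1.0, seed=None) -> pd.DataFrame:
    """Staircase height trace under a constant force channel.

    ``steps`` is a list of (size_nm, dwell_s) pairs; the trace starts with a
    ``lead_in`` dwell at height 0 and jumps by each step size after the
    preceding dwell.  Gaussian noise is added to both channels.
    """
    for s, w in steps:
        if s <= 0 or w <= 0:
            raise ValueError("step sizes and dwells must be positive")
    t_total = lead_in + sum(w for _, w in steps) + lead_in
    t = np.arange(0.0, t_total, dt)
    z = np.zeros_like(t)
    level = 0.0
    t_edge = lead_in
    for size, dwell in steps:
        level += size
        z[t >= t_edge] = level
        t_edge += dwell
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=len(z))
        fch = F_load + rng.normal(0.0, noise_sd * 0.05, size=len(z))
    else:
        fch = np.full_like(z, F_load)
    return pd.DataFrame({"t_s": t, "z_nm": z, "F_nN": fch})


def planar_mesh(rows: int = 5, cols: int = 6, spacing: float = 45.0,
                perturb: float = 5.0, seed=None) -> MeshGeometry:
    """Planar ground-truth meshwork for skeleton round-trip fixtures.

    A triangular lattice with small random node perturbations: straight
    edges meet only at shared endpoints and at angles of roughly 60 degrees,
    so the polyline skeleton of this geometry has no spurious crossovers and
    its junction graph is recoverable exactly.  Nodes of degree < 3 (lattice
    corners) are dropped so every ground-truth vertex is a true junction.
    """
    rng = np.random.default_rng(seed)
    coords = []
    index = {}
    for r in range(rows):
        for c in range(cols):
            index[(r, c)] = len(coords)
            coords.append([(c + 0.5 * (r % 2)) * spacing,
                           r * spacing * np.sqrt(3) / 2])
    coords = np.asarray(coords, dtype=float)
    coords += rng.uniform(-perturb, perturb, size=coords.shape)
    edges = set()
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0), (1, 1 if r % 2 else -1)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                edges.add((min(i, j), max(i, j)))
    # drop low-degree fringe nodes so the truth has only real junctions
    g = MeshGraph(n_nodes=len(coords), edges=np.array(sorted(edges)))
    while True:
        deg = g.degrees()
        keep = np.flatnonzero(deg >= 3)
        if len(keep) == g.n_nodes:
            break
        relabel = -np.ones(g.n_nodes, dtype=int)
        relabel[keep] = np.arange(len(keep))
        mask = np.isin(g.edges, keep).all(axis=1)
        g = MeshGraph(n_nodes=len(keep), edges=relabel[g.edges[mask]])
        coords = coords[keep]
    lo = coords.min(axis=0) - 2 * perturb
    coords = coords - lo
    box = tuple(coords.max(axis=0) + 2 * perturb)
    return MeshGeometry(graph=g, coords=coords, box=box)


def make_synthetic_segments(geom: MeshGeometry, jitter_sd: float = 0.0,
                            spacing: float = 1.0, z0: float = 0.0,
                            seed=None) -> FilamentSegmentSet:
    """Polyline skeleton of a meshwork geometry with optional jitter.

    Each edge becomes a polyline sampled at ~``spacing`` nm whose end points
    coincide exactly at shared junctions before jitter; Gaussian jitter of
    ``jitter_sd`` nm (smooth along the polyline, as skeleton-tracing noise
    is) emulates rendered tomogram skeletons.
    """
    from scipy.ndimage import uniform_filter1d
    rng = np.random.default_rng(seed)
    pls = []
    c = geom.coords
    for i, j in geom.graph.edges:
        L = float(np.linalg.norm(c[j] - c[i]))
        npts = max(2, int(round(L / spacing)) + 1)
        t = np.linspace(0.0, 1.0, npts)[:, None]
        xy = (1 - t) * c[i] + t * c[j]
        pl = np.column_stack([xy, np.full(npts, z0)])
        if jitter_sd > 0:
            noise = rng.normal(0.0, 1.0, size=pl.shape)
            if npts >= 5:
                noise = uniform_filter1d(noise, size=5, axis=0, mode="nearest")
                noise /= max(noise.std(), 1e-9)
            pl = pl + jitter_sd * noise
        pls.append(pl)
    return FilamentSegmentSet(polylines=pls, label="synthetic")


def provenance_record(config: dict, seed, path=None) -> dict:
    """Machine-readable record of a run: config, seed, package version."""
    from . import __version__
    rec = {"config": config, "seed": seed, "version": __version__}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2, default=str)
    return rec
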