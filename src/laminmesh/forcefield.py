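"""Mesoscopic bead-spring force field for lamin filaments.

The total energy of a filament meshwork is

    E = E_T + E_B + E_nonbond,

where the tensile term sums a nonlinear piecewise bond force over bonded bead
pairs, the bending term sums a harmonic angle potential over consecutive bead
triplets, and the non-bonded term is a soft cosine repulsion that keeps
different filaments from interpenetrating.  The bond force

    F_T(r) = [exp((r - r_b)/r_b * Xi) + 1]^-1 *
             { k1 (r - r0)                                        r <  r1
             { R1 + k2 (r - r1)                                   r <  r2
             { R2 + k3_1 (r - r2) + k3_2 (r - r2)^2
                  + k3_3 (r - r2)^3                               r <  r3
             { R3                                                 r >= r3

encodes, in order, the elastic regime, the plateau of alpha-helix coiled-coil
unfolding, the stiffening alpha->beta transition, and a force cap before
rupture; the Fermi-Dirac prefactor drives the force smoothly to zero around
the breaking distance r_b.  All bonded-term constants were parameterized from
steered all-atom simulations of lamin tetramers and are taken here as given.

A fixed plane substrate (the nuclear membrane) attracts every bead through an
integrated van der Waals (9-3) wall with a prescribed surface energy,
equilibrium height and cutoff.

Internal units: kcal mol^-1, Angstrom, radians.  Conversions to pN/nN are
provided for comparison with AFM data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ForceFieldParams",
    "fermi_smoothing",
    "tensile_force",
    "tensile_energy",
    "bending_energy",
    "nonbond_energy",
    "substrate_energy",
    "force_to_pN",
    "force_to_nN",
    "KCAL_PER_MOL_J",
    "KBOLTZ_KCALMOL",
]

#: 1 kcal mol^-1 in joules (per molecule).
KCAL_PER_MOL_J = 4184.0 / 6.02214076e23
#: Boltzmann constant in kcal mol^-1 K^-1.
KBOLTZ_KCALMOL = 0.0019872043
#: 1 kcal mol^-1 A^-1 expressed in piconewtons.
_PN_PER_KCALMOL_A = 4184.0 / 6.02214076e23 / 1.0e-10 * 1.0e12  # = 69.477


def _substrate_eps_kcalmol(surface_energy_mJ_m2: float, bead_area_nm2: float = 1.0) -> float:
    """Per-bead adhesion well depth from an areal surface energy.

    Beads tile a filament at 1 nm spacing, so each bead is assigned 1 nm^2 of
    contact area; 20 mJ m^-2 * 1 nm^2 = 2e-20 J = 2.879 kcal mol^-1.
    """
    e_j = surface_energy_mJ_m2 * 1e-3 * bead_area_nm2 * 1e-18
    return e_j / KCAL_PER_MOL_J


@dataclass
class ForceFieldParams:
    """All constants of the mesoscopic force field, in declared units.

    Bonded/non-bonded lengths are in Angstrom, energies in kcal mol^-1;
    the substrate heights are stored in Angstrom (converted from the nm
    values they are usually quoted in).
    """

    # tensile law, kcal mol^-1 A^-n and Angstrom
    k1: float = 0.7975
    k2: float = 0.162
    k3_1: float = 1.022
    k3_2: float = 0.365
    k3_3: float = 0.116
    r0: float = 10.0
    r1: float = 15.0
    r2: float = 19.0
    r3: float = 27.6
    rb: float = 36.0
    Xi: float = 300.0
    R1: float = 3.988
    R2: float = 4.635
    R3: float = 113.936
    # bending
    kB_bend: float = 34.32          # kcal mol^-1 rad^-2
    theta0: float = math.pi         # straight filament
    # non-bonded cosine repulsion
    A_nb: float = 4.0               # kcal mol^-1
    rc_nb: float = 10.0             # A
    # substrate (plane wall)
    surface_energy: float = 20.0    # mJ m^-2
    z_eq: float = 15.0              # A  (1.5 nm)
    z_cut: float = 40.0             # A  (4.0 nm)

    @property
    def eps_substrate(self) -> float:
        """Per-bead substrate well depth, kcal mol^-1 (2.879 at defaults)."""
        return _substrate_eps_kcalmol(self.surface_energy)

    def validate(self) -> None:
        if not (self.r0 < self.r1 < self.r2 < self.r3 < self.rb):
            raise ValueError("require r0 < r1 < r2 < r3 < rb")
        if self.z_eq <= 0 or self.z_cut <= self.z_eq:
            raise ValueError("require 0 < z_eq < z_cut")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "ForceFieldParams":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        p = cls(**d)
        p.validate()
        return p

    def as_array(self) -> np.ndarray:
        """Flat parameter vector consumed by the numba kernels."""
        return np.array(
            [self.k1, self.k2, self.k3_1, self.k3_2, self.k3_3,
             self.r0, self.r1, self.r2, self.r3, self.rb, self.Xi,
             self.R1, self.R2, self.R3, self.kB_bend, self.theta0,
             self.A_nb, self.rc_nb, self.eps_substrate, self.z_eq, self.z_cut],
            dtype=np.float64,
        )


DEFAULT_PARAMS = ForceFieldParams()


def fermi_smoothing(r, params: ForceFieldParams = DEFAULT_PARAMS):
    """Fermi-Dirac prefactor [exp((r - rb)/rb * Xi) + 1]^-1.

    Equals 1/2 exactly at r = rb and decreases strictly with r; Xi sets how
    abruptly the bond force is extinguished around the breaking distance.
    """
    r = np.asarray(r, dtype=float)
    x = (r - params.rb) / params.rb * params.Xi
    # avoid overflow far beyond rb
    out = np.where(x > 500.0, 0.0, 1.0 / (np.exp(np.minimum(x, 500.0)) + 1.0))
    return out if out.ndim else float(out)


def _tensile_branch(r, p: ForceFieldParams):
    r = np.asarray(r, dtype=float)
    dr2 = r - p.r2
    conds = [r < p.r1, r < p.r2, r < p.r3]
    vals = [
        p.k1 * (r - p.r0),
        p.R1 + p.k2 * (r - p.r1),
        p.R2 + p.k3_1 * dr2 + p.k3_2 * dr2**2 + p.k3_3 * dr2**3,
    ]
    return np.select(conds, vals, default=p.R3)


def tensile_force(r, params: ForceFieldParams = DEFAULT_PARAMS):
    """Bond tension F_T(r) in kcal mol^-1 A^-1 (positive = restoring).

    Piecewise branch value times the Fermi smoothing factor.  Continuous at
    r1 and r2 by the printed continuity constants R1, R2; at r3 within the
    rounding of the printed constants.
    """
    r = np.asarray(r, dtype=float)
    out = _tensile_branch(r, params) * fermi_smoothing(r, params)
    return out if out.ndim else float(out)


_ENERGY_TABLE_CACHE: dict = {}


def _energy_table(p: ForceFieldParams):
    key = tuple(p.as_array())
    tab = _ENERGY_TABLE_CACHE.get(key)
    if tab is None:
        r = np.linspace(p.r0, p.rb * 1.4, 6001)
        e = cumulative_trapezoid(tensile_force(r, p), r, initial=0.0)
        tab = (r, e)
        _ENERGY_TABLE_CACHE[key] = tab
    return tab


def tensile_energy(r, params: ForceFieldParams = DEFAULT_PARAMS):
    """Bond strain energy: quadrature of the tensile force from r0 to r.

    Zero at r0; analytic harmonic 0.5*k1*(r-r0)^2 below r1 (where the
    smoothing factor is 1 to machine precision), dense tabulated trapezoid
    quadrature above, flat beyond the table end where the force has vanished.
    """
    p = params
    r = np.asarray(r, dtype=float)
    rt, et = _energy_table(p)
    out = np.where(
        r < p.r1,
        0.5 * p.k1 * (r - p.r0) ** 2,
        np.interp(r, rt, et),
    )
    return out if out.ndim else float(out)


def bending_energy(theta, params: ForceFieldParams = DEFAULT_PARAMS):
    """Harmonic angle energy 0.5*kB*(theta-theta0)^2 and its derivative.

    Returns (energy kcal mol^-1, dE/dtheta kcal mol^-1 rad^-1).
    """
    theta = np.asarray(theta, dtype=float)
    d = theta - params.theta0
    e = 0.5 * params.kB_bend * d**2
    g = params.kB_bend * d
    if e.ndim == 0:
        return float(e), float(g)
    return e, g


def nonbond_energy(r, params: ForceFieldParams = DEFAULT_PARAMS):
    """Soft cosine repulsion A*[1 + cos(pi r / rc)] for r < rc, else 0."""
    p = params
    r = np.asarray(r, dtype=float)
    out = np.where(r < p.rc_nb, p.A_nb * (1.0 + np.cos(np.pi * r / p.rc_nb)), 0.0)
    return out if out.ndim else float(out)


def substrate_energy(z, params: ForceFieldParams = DEFAULT_PARAMS, shifted: bool = True):
    """Plane-wall 9-3 adhesion energy per bead, kcal mol^-1.

    U(z) = eps * [ (1/2)(z_eq/z)^9 - (3/2)(z_eq/z)^3 ], which has its minimum
    -eps at z_eq with zero slope.  Truncated at z_cut and (by default) shifted
    so the energy is continuous and zero there.  z below a small floor is
    evaluated at the floor (finite repulsion cap).
    """
    p = params
    eps = p.eps_substrate
    z = np.asarray(z, dtype=float)
    zf = np.maximum(z, 0.05 * p.z_eq)
    s = p.z_eq / zf
    u = eps * (0.5 * s**9 - 1.5 * s**3)
    if shifted:
        sc = p.z_eq / p.z_cut
        u = u - eps * (0.5 * sc**9 - 1.5 * sc**3)
    u = np.where(z >= p.z_cut, 0.0, u)
    return u if u.ndim else float(u)


def force_to_pN(f):
    """Convert kcal mol^-1 A^-1 to pN (factor 69.477)."""
    out = np.asarray(f, dtype=float) * _PN_PER_KCALMOL_A
    return out if out.ndim else float(out)


def force_to_nN(f):
    """Convert kcal mol^-1 A^-1 to nN."""
    out = np.asarray(f, dtype=float) * (_PN_PER_KCALMOL_A * 1e-3)
    return out if out.ndim else float(out)
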