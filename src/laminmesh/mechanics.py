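"""Feature extraction from force-extension curves and force-clamp traces.

AFM-style analysis of filament pushing records: plateau force/stiffness/
extent in the low-force regime, stiffness of the strain-stiffening rise
(linear fit gated at R^2 >= 0.93), failure force and deformation at the
final peak, step units at force drops, hysteresis energy between approach
and retract, toughness density, chord engineering strain, and staircase
step/lifetime analysis of constant-force (clamp) traces.

Units: forces nN, distances nm, energies J externally; nN*nm = 1e-18 J.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter, find_peaks
from scipy.stats import linregress

from .simulator import FECurve

logger = logging.getLogger("laminmesh")

__all__ = [
    "MechanicalFeatures",
    "EnergyMeasures",
    "ClampAnalysis",
    "extract_features",
    "loading_rate",
    "hysteresis_energy",
    "toughness_density",
    "engineering_strain",
    "energy_in_bond_units",
    "clamp_step_analysis",
]

NNNM_TO_J = 1e-18  # 1 nN*nm in joules
R2_GATE = 0.93     # minimum goodness of fit for a reported stiffness


@dataclass
class MechanicalFeatures:
    """Observables of a single FE curve (AFM conventions)."""

    plateau_force: float | None = None       # F_low, nN
    plateau_stiffness: float | None = None   # kappa_low, nN/nm
    plateau_r2: float | None = None
    plateau_span: float | None = None        # d_low, nm (extent of the plateau)
    high_stiffness: float | None = None      # kappa_high, nN/nm
    high_r2: float | None = None
    failure_force: float | None = None       # F_high, nN
    failure_deformation: float | None = None  # d_high, nm (position of final peak)
    deformation: float | None = None         # inflection -> first peak distance, nm
    step_units: list = field(default_factory=list)  # nm, per force drop
    flags: list = field(default_factory=list)

    def stiffnesses_gated(self) -> bool:
        """True when every reported stiffness carries R^2 >= the gate."""
        ok = True
        if self.high_stiffness is not None:
            ok &= (self.high_r2 or 0.0) >= R2_GATE
        return ok


@dataclass
class EnergyMeasures:
    hysteresis_energy_J: float
    toughness_density_MJ_m3: float | None = None
    bond_equivalents: float | None = None


@dataclass
class ClampAnalysis:
    """Discrete failure steps of a constant-force trace."""

    step_sizes: np.ndarray       # nm
    lifetimes: np.ndarray        # time units between consecutive events
    F_load: float                # nN
    levels: np.ndarray = None    # fitted piecewise-constant heights


# --------------------------------------------------------------------------
# FE feature extraction
# --------------------------------------------------------------------------

def _smooth(f: np.ndarray, window: int) -> np.ndarray:
    window = min(window, len(f) - (1 - len(f) % 2))
    if window < 5:
        return f.copy()
    if window % 2 == 0:
        window -= 1
    return savgol_filter(f, window, 3)


def extract_features(curve: FECurve, peak_prominence: float = 0.2,
                     plateau_slope_fraction: float = 0.2,
                     min_plateau_span: float = 10.0) -> MechanicalFeatures:
    """Extract the standard FE observables from a pushing curve.

    Definitions follow AFM practice: failure force = final (global) force
    peak; high stiffness = slope of the linear steep rise before that peak
    (fit rejected if R^2 < 0.93); step unit = distance from a peak to the end
    of the following force drop; plateau = the longest region before the
    stiffening rise whose local slope stays below ``plateau_slope_fraction``
    of the high stiffness, at least ``min_plateau_span`` long; deformation =
    distance from the curvature inflection before the first peak to that
    peak.
    """
    out = MechanicalFeatures()
    if len(curve) < 50:
        raise ValueError("need >= 50 samples")
    d, f = curve.d, curve.f
    if np.allclose(f, 0.0, atol=1e-12):
        out.flags.append("no signal")
        return out
    dx = float(np.median(np.diff(d)))
    win = max(5, int(round(2.0 / dx)) | 1)  # ~2 nm smoothing window
    fs = _smooth(f, win)

    # peaks located on the smoothed curve; height/position read from the raw
    # record in a +-1 nm window so smoothing does not round off the maximum
    peaks, props = find_peaks(fs, prominence=peak_prominence)
    half = max(1, int(round(1.0 / dx)))
    if len(peaks):
        p_final = peaks[np.argmax(fs[peaks])]
        lo, hi = max(0, p_final - half), min(len(f), p_final + half + 1)
        p_raw = lo + int(np.argmax(f[lo:hi]))
        out.failure_force = float(f[p_raw])
        out.failure_deformation = float(d[p_raw])
    else:
        p_final = len(d) - 1
        out.flags.append("no peak")

    # high stiffness: linear fit to the steep contiguous rise below the peak
    if len(peaks):
        seg = np.flatnonzero((fs[:p_final + 1] >= 0.45 * fs[p_final])
                             & (fs[:p_final + 1] <= 0.95 * fs[p_final]))
        if len(seg) >= 5:
            brk = np.flatnonzero(np.diff(seg) > 1)
            start = seg[brk[-1] + 1] if len(brk) else seg[0]
            seg = np.arange(start, seg[-1] + 1)
    else:
        seg = np.arange(len(d))  # monotone ramp: single stiffness
    if len(seg) >= 5:
        res = linregress(d[seg], f[seg])
        out.high_r2 = float(res.rvalue**2)
        if res.rvalue**2 >= R2_GATE:
            out.high_stiffness = float(res.slope)
        else:
            out.flags.append("high-stiffness fit rejected (R^2 < 0.93)")

    # plateau: the dominant force level before the final peak.  The level is
    # the mode of the smoothed force histogram; its extent is bounded by the
    # intersections of the entropic-rise line and the stiffening line with
    # that level, which is insensitive to noise and to smoothing width.
    sigma = float(np.std(f - fs))           # noise estimate from the residual
    sigma_s = sigma / max(np.sqrt(win), 1)
    if len(peaks):
        pre = fs[:p_final]
        fmax = fs[p_final]
        cand = pre[(pre > 0.05 * fmax) & (pre < 0.8 * fmax)]
        found = False
        if len(cand) >= 10:
            bw = max(0.02 * fmax, 2.0 * sigma_s)
            hist, edges_ = np.histogram(cand, bins=max(5, int(0.8 * fmax / bw)))
            k = int(np.argmax(hist))
            inbin = cand[(cand >= edges_[k]) & (cand < edges_[k + 1])]
            P0 = float(np.median(inbin)) if len(inbin) else \
                0.5 * (edges_[k] + edges_[k + 1])
            tol = max(0.04 * abs(P0), 3.0 * sigma_s)
            at = np.abs(pre - P0) <= tol
            # longest run at the level, bridging noise gaps < 2 nm
            runs = []
            i = 0
            while i < len(at):
                if at[i]:
                    j = i
                    while j + 1 < len(at) and at[j + 1]:
                        j += 1
                    runs.append([i, j])
                    i = j + 1
                else:
                    i += 1
            merged = []
            for r in runs:
                if merged and d[r[0]] - d[merged[-1][1]] < 2.0:
                    merged[-1][1] = r[1]
                else:
                    merged.append(r)
            best = (0.0, -1, -1)
            for i, j in merged:
                if d[j] - d[i] > best[0]:
                    best = (d[j] - d[i], i, j)
            if best[1] >= 0 and best[0] >= min_plateau_span:
                i0, i1 = best[1], best[2]
                P = float(np.median(f[i0:i1 + 1]))
                res = linregress(d[i0:i1 + 1], f[i0:i1 + 1])
                out.plateau_force = P
                out.plateau_stiffness = float(res.slope)
                out.plateau_r2 = float(res.rvalue**2)
                # yield point: stiffening line reaches the plateau level
                d_yield = None
                if out.high_stiffness:
                    resh = linregress(d[seg], f[seg])
                    d_yield = (P - resh.intercept) / resh.slope
                if d_yield is None or not (d[i1] - 5 <= d_yield <= d[p_final]):
                    d_yield = d[i1]
                # plateau onset: entropic-rise line reaches the level
                rise = np.flatnonzero((fs[:i0] >= 0.2 * P) & (fs[:i0] <= 0.8 * P))
                d_start = d[i0]
                if len(rise) >= 5:
                    resr = linregress(d[rise], f[rise])
                    if resr.slope > 0:
                        cross = (P - resr.intercept) / resr.slope
                        if d[0] <= cross <= d[i0] + 5:
                            d_start = cross
                out.plateau_span = float(d_yield - d_start)
                found = True
        if not found:
            out.flags.append("no plateau")

    # step units: intersection of the falling flank with the post-drop
    # baseline, measured from the raw peak (robust to smoothing width)
    for pi, p in enumerate(peaks):
        prom = props["prominences"][pi]
        stop = peaks[pi + 1] if pi + 1 < len(peaks) else len(fs)
        if stop <= p + 1:
            continue
        fall_end = p + int(np.argmin(fs[p:stop]))
        base = fs[fall_end]
        amp = fs[p] - base
        if amp < 0.5 * prom:
            continue
        flank = np.flatnonzero((fs[p:fall_end + 1] <= base + 0.8 * amp)
                               & (fs[p:fall_end + 1] >= base + 0.2 * amp)) + p
        if len(flank) >= 2:
            res = linregress(d[flank], fs[flank])
            if res.slope < 0:
                d_base = (base - res.intercept) / res.slope
                lo = max(0, p - half)
                p_raw = lo + int(np.argmax(f[lo:min(len(f), p + half + 1)]))
                out.step_units.append(float(d_base - d[p_raw]))

    # deformation: inflection (min of 2nd derivative) before the first peak
    if len(peaks):
        p0 = peaks[0]
        if p0 > 5:
            curv = np.gradient(np.gradient(fs[:p0 + 1], d[:p0 + 1]), d[:p0 + 1])
            infl = int(np.argmin(curv[: max(1, p0 - 2)]))
            out.deformation = float(d[p0] - d[infl])
    return out


def loading_rate(stiffness: float, speed: float) -> float:
    """Loading rate = measured stiffness (nN/nm) x pushing speed (nm/s)."""
    if stiffness < 0 or speed < 0:
        raise ValueError("inputs must be non-negative")
    return stiffness * speed


# --------------------------------------------------------------------------
# energies and derived quantities
# --------------------------------------------------------------------------

def hysteresis_energy(approach: FECurve, retract: FECurve) -> float:
    """Energy dissipated between approach and retract, in joules.

    Integrates F_approach - F_retract over the overlapping deformation range
    (retract resampled onto the approach grid).  Warns (via the return of a
    negative contribution flag in the log) when the retract curve lies above
    the approach curve anywhere.
    """
    lo = max(approach.d.min(), retract.d.min())
    hi = min(approach.d.max(), retract.d.max())
    if hi <= lo:
        raise ValueError("approach and retract ranges do not overlap")
    m = (approach.d >= lo) & (approach.d <= hi)
    dgrid = approach.d[m]
    fa = approach.f[m]
    order = np.argsort(retract.d, kind="stable")
    fr = np.interp(dgrid, retract.d[order], retract.f[order])
    diff = fa - fr
    if np.any(diff < -1e-9):
        logger.warning("retract force exceeds approach force over part of "
                       "the range; negative hysteresis contribution")
    return float(np.trapezoid(diff, dgrid)) * NNNM_TO_J


def toughness_density(E: float, r: float, L: float) -> float:
    """Tensile toughness E / (pi r^2 L) in MJ m^-3 (E in J; r, L in nm)."""
    if r <= 0 or L <= 0 or E < 0:
        raise ValueError("need E >= 0 and positive r, L")
    volume_m3 = math.pi * r * r * L * 1e-27
    return E / volume_m3 / 1e6


def engineering_strain(L: float, d: float) -> float:
    """Chord strain (percent) of a filament of length L deflected by d.

    The filament is taken as two straight chords from its anchored ends to
    the pushed midpoint: strain = (2*sqrt((L/2)^2 + d^2) - L)/L * 100.
    """
    if L <= 0 or d < 0:
        raise ValueError("need L > 0 and d >= 0")
    stretched = 2.0 * math.sqrt((L / 2.0) ** 2 + d * d)
    return (stretched - L) / L * 100.0


def energy_in_bond_units(E: float, e_bond: float = 5.8e-19) -> float:
    """Energy expressed as a count of C-C covalent bond energies."""
    if E < 0 or e_bond <= 0:
        raise ValueError("need E >= 0 and e_bond > 0")
    return E / e_bond


# --------------------------------------------------------------------------
# force clamp
# --------------------------------------------------------------------------

def _binary_segmentation(y: np.ndarray, min_size: int, min_step: float):
    """Recursive change-point splits on a piecewise-constant signal."""
    cps: list[int] = []

    def split(lo, hi):
        n = hi - lo
        if n < 2 * min_size:
            return
        seg = y[lo:hi]
        csum = np.cumsum(seg)
        total = csum[-1]
        ks = np.arange(min_size, n - min_size + 1)
        mean_l = csum[ks - 1] / ks
        mean_r = (total - csum[ks - 1]) / (n - ks)
        gain = np.abs(mean_l - mean_r)
        k = int(ks[np.argmax(gain)])
        if gain.max() < min_step:
            return
        cps.append(lo + k)
        split(lo, lo + k)
        split(lo + k, hi)

    split(0, len(y))
    return sorted(cps)


def clamp_step_analysis(trace, F_load: float | None = None,
                        force_tol: float = 0.1, min_step: float = 0.5,
                        min_dwell_samples: int = 5) -> ClampAnalysis:
    """Detect discrete failure steps in a constant-force trace.

    ``trace`` is a DataFrame-like with columns t_s, z_nm, F_nN.  The force
    channel must be constant within ``force_tol`` (nN), else the record is
    not a clamp trace and an error is raised.  Steps are found by binary
    change-point segmentation of the height channel with a minimum step of
    0.5 nm (below the smallest reported step class); lifetimes are the dwell
    times between consecutive events.
    """
    t = np.asarray(trace["t_s"], dtype=float)
    z = np.asarray(trace["z_nm"], dtype=float)
    fch = np.asarray(trace["F_nN"], dtype=float)
    if len(t) < 2 * min_dwell_samples:
        raise ValueError("trace too short")
    f0 = float(np.median(fch))
    if np.max(np.abs(fch - f0)) > force_tol:
        raise ValueError("not a clamp trace: force channel drifts beyond tolerance")
    if F_load is None:
        F_load = f0
    cps = _binary_segmentation(z, min_dwell_samples, min_step)
    bounds = [0] + cps + [len(z)]
    levels = np.array([np.mean(z[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])
    steps = np.diff(levels)
    keep = np.abs(steps) >= min_step
    step_sizes = np.abs(steps[keep])
    event_times = np.array([t[c] for c, k in zip(cps, keep) if k])
    if len(event_times):
        lifetimes = np.diff(np.concatenate([[t[0]], event_times]))
    else:
        lifetimes = np.zeros(0)
    return ClampAnalysis(step_sizes=step_sizes, lifetimes=lifetimes,
                         F_load=float(F_load), levels=levels)
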