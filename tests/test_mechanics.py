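"""AFM-style feature extraction, energies, and clamp-trace analysis."""

import numpy as np
import pytest

from laminmesh import mechanics, workbench
from laminmesh.mechanics import (extract_features, loading_rate,
                                 hysteresis_energy, toughness_density,
                                 engineering_strain, energy_in_bond_units,
                                 clamp_step_analysis)
from laminmesh.simulator import FECurve

TRUE = dict(plateau_force=0.30, plateau_span=54.0, high_slope=0.30,
            peak_force=2.4, peak_d=91.0, drop_step=4.3)


class TestExtractFeatures:
    def test_noise_free_round_trip_within_2pct(self):
        feats = extract_features(workbench.make_synthetic_fecurve(**TRUE))
        assert feats.plateau_force == pytest.approx(TRUE["plateau_force"], rel=0.02)
        assert feats.plateau_span == pytest.approx(TRUE["plateau_span"], rel=0.02)
        assert feats.high_stiffness == pytest.approx(TRUE["high_slope"], rel=0.02)
        assert feats.failure_force == pytest.approx(TRUE["peak_force"], rel=0.02)
        assert feats.failure_deformation == pytest.approx(TRUE["peak_d"], rel=0.02)
        assert feats.step_units[-1] == pytest.approx(TRUE["drop_step"], rel=0.02)
        assert feats.high_r2 >= 0.93 and feats.stiffnesses_gated()

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_recovery_within_10pct(self, seed):
        curve = workbench.make_synthetic_fecurve(noise_sd=0.05, seed=seed, **TRUE)
        feats = extract_features(curve)
        assert feats.plateau_force == pytest.approx(TRUE["plateau_force"], rel=0.10)
        assert feats.plateau_span == pytest.approx(TRUE["plateau_span"], rel=0.10)
        assert feats.high_stiffness == pytest.approx(TRUE["high_slope"], rel=0.10)
        assert feats.failure_force == pytest.approx(TRUE["peak_force"], rel=0.10)
        assert feats.failure_deformation == pytest.approx(TRUE["peak_d"], rel=0.10)
        assert feats.step_units[-1] == pytest.approx(TRUE["drop_step"], rel=0.10)

    def test_linear_ramp_single_stiffness_no_peak_no_plateau(self):
        c = FECurve(d=np.linspace(0, 50, 600), f=np.linspace(0, 5, 600))
        feats = extract_features(c)
        assert "no peak" in feats.flags
        assert feats.failure_force is None
        assert feats.plateau_force is None
        assert feats.high_stiffness == pytest.approx(0.1, rel=1e-6)

    def test_flat_curve_flagged_no_signal(self):
        c = FECurve(d=np.linspace(0, 50, 600), f=np.zeros(600))
        feats = extract_features(c)
        assert feats.flags == ["no signal"]
        assert feats.failure_force is None

    def test_too_short_curve_raises(self):
        with pytest.raises(ValueError):
            extract_features(FECurve(d=np.arange(10.0), f=np.arange(10.0)))


class TestLoadingRate:
    def test_product(self):
        assert loading_rate(0.30, 1000.0) == pytest.approx(300.0)
        assert loading_rate(0.0078, 100.0) == pytest.approx(0.78)
        assert loading_rate(0.5, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            loading_rate(-1.0, 1.0)


class TestHysteresis:
    def test_identical_curves_zero(self):
        d = np.linspace(0, 20, 200)
        c = FECurve(d=d, f=np.sin(d / 3) + 1)
        assert hysteresis_energy(c, c) == pytest.approx(0.0, abs=1e-24)

    def test_rectangle_energy_scale(self):
        # 1 nN over 10 nm against a zero retract: 10 nN nm = 1e-17 J
        d = np.linspace(0, 10, 500)
        approach = FECurve(d=d, f=np.ones_like(d))
        retract = FECurve(d=d, f=np.zeros_like(d))
        assert hysteresis_energy(approach, retract) == pytest.approx(1e-17, rel=1e-3)

    def test_resampling_invariance(self):
        d1 = np.linspace(0, 30, 400)
        d2 = np.linspace(0, 30, 2500)
        fa = lambda d: 0.1 * d
        fr = lambda d: 0.05 * d
        e1 = hysteresis_energy(FECurve(d=d1, f=fa(d1)), FECurve(d=d1, f=fr(d1)))
        e2 = hysteresis_energy(FECurve(d=d2, f=fa(d2)), FECurve(d=d2, f=fr(d2)))
        assert e1 == pytest.approx(e2, rel=0.01)

    def test_retract_above_approach_flagged(self, caplog):
        import logging
        d = np.linspace(0, 10, 200)
        approach = FECurve(d=d, f=np.full_like(d, 0.5))
        retract = FECurve(d=d, f=np.full_like(d, 1.0))
        with caplog.at_level(logging.WARNING, logger="laminmesh"):
            e = hysteresis_energy(approach, retract)
        assert e < 0
        assert any("negative hysteresis" in r.message for r in caplog.records)

    def test_non_overlapping_ranges_raise(self):
        a = FECurve(d=np.linspace(0, 5, 60), f=np.ones(60))
        b = FECurve(d=np.linspace(10, 15, 60), f=np.ones(60))
        with pytest.raises(ValueError):
            hysteresis_energy(a, b)


class TestDerivedQuantities:
    def test_toughness_density_worked_example(self):
        # 1e-16 J in a filament of radius 2 nm, length 54 nm (V = 679 nm^3)
        t = toughness_density(1e-16, 2.0, 54.0)
        assert t == pytest.approx(147.0, rel=0.005)

    def test_toughness_density_linearity_and_zero(self):
        assert toughness_density(0.0, 2.0, 54.0) == 0.0
        assert toughness_density(2e-16, 2.0, 54.0) == pytest.approx(
            2 * toughness_density(1e-16, 2.0, 54.0))

    def test_engineering_strain_chord(self):
        assert engineering_strain(54.0, 0.0) == 0.0
        assert engineering_strain(54.0, 91.0) == pytest.approx(251.5, abs=0.1)
        assert engineering_strain(54.0, 54.0) == pytest.approx(123.6, abs=0.1)

    def test_bond_unit_count(self):
        assert energy_in_bond_units(1e-16) == pytest.approx(172.4, abs=0.1)
        assert energy_in_bond_units(5.8e-19) == pytest.approx(1.0)
        assert energy_in_bond_units(0.0) == 0.0


class TestClampAnalysis:
    def test_noise_free_round_trip(self):
        steps = [(1.3, 2.0), (4.0, 3.0), (4.0, 1.5)]
        trace = workbench.make_synthetic_clamp_trace(steps, noise_sd=0.0)
        res = clamp_step_analysis(trace)
        assert np.allclose(res.step_sizes, [1.3, 4.0, 4.0], rtol=0.02)
        # dwell times: lead-in, then the configured dwells
        assert np.allclose(res.lifetimes, [1.0, 2.0, 3.0], rtol=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_recovery_within_10pct(self, seed):
        steps = [(1.3, 2.0), (4.0, 3.0), (4.0, 1.5)]
        trace = workbench.make_synthetic_clamp_trace(steps, noise_sd=0.1,
                                                     seed=seed)
        res = clamp_step_analysis(trace)
        assert len(res.step_sizes) == 3
        assert np.allclose(res.step_sizes, [1.3, 4.0, 4.0], rtol=0.10)

    def test_single_step(self):
        trace = workbench.make_synthetic_clamp_trace([(8.0, 2.0)],
                                                     noise_sd=0.05, seed=1)
        res = clamp_step_analysis(trace)
        assert len(res.step_sizes) == 1
        assert res.step_sizes[0] == pytest.approx(8.0, rel=0.10)

    def test_flat_trace_no_events(self):
        trace = workbench.make_synthetic_clamp_trace([(1.0, 1.0)], noise_sd=0.0)
        trace["z_nm"] = 0.0  # remove the step entirely
        res = clamp_step_analysis(trace)
        assert len(res.step_sizes) == 0

    def test_drifting_force_rejected(self):
        trace = workbench.make_synthetic_clamp_trace([(2.0, 1.0)], noise_sd=0.0)
        trace["F_nN"] = np.linspace(0.5, 3.0, len(trace))
        with pytest.raises(ValueError, match="not a clamp trace"):
            clamp_step_analysis(trace)
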