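"""Relaxation and point-load pushing of bead-spring meshworks."""

import numpy as np
import pytest

from laminmesh import meshgen, simulator
from laminmesh.forcefield import tensile_force, force_to_nN
from laminmesh.meshgen import BeadModel
from laminmesh.simulator import (SimulationConfig, FECurve, relax,
                                 select_push_site, push, strength_toughness,
                                 segment_strain_distribution)


def _free_filament(n=3, z=5.0):
    x = np.arange(n) - (n - 1) / 2
    pos = np.column_stack([x, np.zeros(n), np.full(n, z)])
    chain = np.arange(n)
    return BeadModel(
        positions=pos,
        bonds=np.column_stack([chain[:-1], chain[1:]]),
        rest_length=1.0,
        triplets=np.zeros((0, 3)),
        node_map=np.array([0, n - 1]),
        edge_beads=[chain],
    )


def _straight_filament_on_substrate(n=13):
    x = np.arange(n, dtype=float)
    pos = np.column_stack([x, np.zeros(n), np.full(n, 1.5)])
    chain = np.arange(n)
    return BeadModel(
        positions=pos,
        bonds=np.column_stack([chain[:-1], chain[1:]]),
        rest_length=1.0,
        triplets=np.column_stack([chain[:-2], chain[1:-1], chain[2:]]),
        node_map=np.array([0, n - 1]),
        edge_beads=[chain],
    )


class TestRelax:
    def test_single_filament_bond_lengths(self):
        bm = _straight_filament_on_substrate()
        cfg = SimulationConfig(seed=1, anneal=[(300.0, 300)])
        out = relax(bm, cfg)
        d = np.linalg.norm(np.diff(out.positions, axis=0), axis=1)
        assert np.all(np.abs(d - 1.0) < 0.05)
        # beads adhered near the substrate equilibrium height
        assert np.all(np.abs(out.positions[:, 2] - 1.5) < 0.3)

    def test_energy_descends(self):
        bm = _straight_filament_on_substrate()
        bm.positions[:, 2] += 0.8  # start off-equilibrium
        cfg = SimulationConfig(seed=1, temperature=0.0, anneal=[])
        from laminmesh.simulator import _potential_energy, _arrays, _nonbond_pairs, _exclusion_keys
        from laminmesh.forcefield import _energy_table
        pos, bonds, angles, broken = _arrays(bm)
        rt, et = _energy_table(cfg.params)
        e0 = _potential_energy(pos, bonds, broken, angles,
                               np.zeros((0, 2), dtype=np.int64),
                               cfg.params.as_array(), True, rt[0],
                               rt[1] - rt[0], et)
        out = relax(bm, cfg)
        pos1 = out.positions * 10.0
        e1 = _potential_energy(np.ascontiguousarray(pos1), bonds, broken,
                               angles, np.zeros((0, 2), dtype=np.int64),
                               cfg.params.as_array(), True, rt[0],
                               rt[1] - rt[0], et)
        assert e1 <= e0

    def test_deterministic(self):
        cfg = SimulationConfig(seed=9, anneal=[(300.0, 200)])
        a = relax(_straight_filament_on_substrate(), cfg)
        b = relax(_straight_filament_on_substrate(), cfg)
        assert np.array_equal(a.positions, b.positions)


class TestSelectPushSite:
    def test_single_centered_edge_gives_middle_bead(self):
        bm = _straight_filament_on_substrate(n=13)
        assert select_push_site(bm, seed=0) == 6

    def test_deterministic(self, small_bead_model):
        assert select_push_site(small_bead_model, seed=3) == \
            select_push_site(small_bead_model, seed=3)

    def test_no_central_filament_raises(self):
        # two edges hugging opposite borders; nothing near the middle
        pos = np.array([[0, 0, 1.5], [0, 50, 1.5], [0, 100, 1.5],
                        [100, 0, 1.5], [100, 50, 1.5], [100, 100, 1.5]],
                       dtype=float)
        bm = BeadModel(
            positions=pos,
            bonds=np.array([[0, 1], [1, 2], [3, 4], [4, 5]]),
            rest_length=1.0, triplets=np.zeros((0, 3)),
            node_map=np.array([0, 2, 3, 5]),
            edge_beads=[np.array([0, 1, 2]), np.array([3, 4, 5])],
        )
        with pytest.raises(ValueError):
            select_push_site(bm, seed=0, central_fraction=0.3)

    def test_empty_model_raises(self):
        bm = BeadModel(positions=np.zeros((0, 3)), bonds=np.zeros((0, 2)),
                       rest_length=1.0, triplets=np.zeros((0, 3)),
                       node_map=np.zeros(0, dtype=int), edge_beads=[])
        with pytest.raises(ValueError):
            select_push_site(bm, seed=0)


class TestPush:
    def test_three_bead_closed_form(self):
        # middle bead of a pinned two-bond filament pushed transversely:
        # driver force = 2 F_T(r) sin(alpha) with r, alpha from geometry
        bm = _free_filament(3)
        cfg = SimulationConfig(temperature=0.0, substrate=False,
                               steps_per_nm=2000, max_displacement=2.5, seed=1)
        curve, traj = push(bm, 1, cfg, pinned=[0, 2])
        d = curve.d
        r_A = np.sqrt(10.0**2 + (10 * d) ** 2)
        pred = force_to_nN(2 * tensile_force(r_A) * (10 * d) / r_A)
        sel = d > 0.3
        rel = np.abs(curve.f[sel] - pred[sel]) / np.maximum(pred[sel], 1e-9)
        assert rel.max() < 0.05

    def test_zero_displacement_empty_curve(self):
        bm = _free_filament(3)
        cfg = SimulationConfig(temperature=0.0, substrate=False,
                               max_displacement=0.0, seed=1)
        curve, traj = push(bm, 1, cfg, pinned=[0, 2])
        assert len(curve) == 0
        assert len(traj.broken_events) == 0

    def test_bond_breaking_monotone_and_permanent(self):
        bm = _free_filament(3)
        cfg = SimulationConfig(temperature=0.0, substrate=False,
                               steps_per_nm=400, max_displacement=8.0, seed=1,
                               early_stop=False)
        curve, traj = push(bm, 1, cfg, pinned=[0, 2])
        assert len(traj.broken_events) == 2  # both bonds part
        steps = [s for _, s in traj.broken_events]
        assert steps == sorted(steps)
        assert bm.broken.all()

    def test_seeded_reproducibility(self):
        def run():
            bm = _straight_filament_on_substrate()
            cfg = SimulationConfig(seed=5, steps_per_nm=300,
                                   max_displacement=3.0,
                                   anneal=[(300.0, 100)])
            bm = relax(bm, cfg)
            return push(bm, 6, cfg)
        c1, t1 = run()
        c2, t2 = run()
        assert np.array_equal(c1.f, c2.f)
        assert np.array_equal(t1.frames, t2.frames)

    def test_work_bounds_potential_gain_at_zero_temperature(self):
        bm = _free_filament(5)
        cfg = SimulationConfig(temperature=0.0, substrate=False,
                               steps_per_nm=1000, max_displacement=2.0, seed=1)
        curve, traj = push(bm, 2, cfg, pinned=[0, 4])
        gain = (traj.potential_end - traj.potential_start) * 0.0069477  # nN nm
        assert traj.work_nNnm >= gain - 1e-6


class TestForceClamp:
    def test_constant_load_lifts_driver(self):
        bm = _straight_filament_on_substrate()
        cfg = SimulationConfig(seed=3, anneal=[(300.0, 100)])
        bm = relax(bm, cfg)
        trace = simulator.force_clamp(bm, 6, force_nN=0.5,
                                      duration_steps=2000, config=cfg)
        assert list(trace.columns) == ["t_s", "z_nm", "F_nN"]
        assert trace["t_s"].is_monotonic_increasing
        assert trace["z_nm"].iloc[-1] > trace["z_nm"].iloc[0]


class TestStrainDistribution:
    def test_relaxed_state_concentrated_near_zero(self):
        bm = _straight_filament_on_substrate()
        cfg = SimulationConfig(seed=2, steps_per_nm=300, max_displacement=2.0,
                               anneal=[(300.0, 200)])
        bm = relax(bm, cfg)
        curve, traj = push(bm, 6, cfg)
        hist, edges = segment_strain_distribution(traj, 0.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean_strain = np.sum(hist * centers * np.diff(edges))
        assert abs(mean_strain) < 0.1

    def test_histogram_normalized(self):
        bm = _straight_filament_on_substrate()
        cfg = SimulationConfig(seed=2, steps_per_nm=300, max_displacement=2.0,
                               anneal=[(300.0, 100)])
        bm = relax(bm, cfg)
        _, traj = push(bm, 6, cfg)
        hist, edges = segment_strain_distribution(traj, 2.0)
        assert np.sum(hist * np.diff(edges)) == pytest.approx(1.0)

    def test_unreached_displacement_raises(self):
        bm = _straight_filament_on_substrate()
        cfg = SimulationConfig(seed=2, steps_per_nm=200, max_displacement=1.0,
                               anneal=[])
        _, traj = push(bm, 6, cfg)
        with pytest.raises(ValueError):
            segment_strain_distribution(traj, 50.0)


class TestStrengthToughness:
    def test_triangle_curve(self):
        d = np.linspace(0, 20, 201)
        f = np.where(d <= 10, 0.2 * d, 2 - 0.2 * (d - 10))
        s, t = strength_toughness(FECurve(d=d, f=f))
        assert s == pytest.approx(2.0, rel=1e-6)
        assert t == pytest.approx(20.0, rel=1e-3)

    def test_zero_curve(self):
        c = FECurve(d=np.linspace(0, 5, 50), f=np.zeros(50))
        assert strength_toughness(c) == (0.0, 0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            strength_toughness(FECurve(d=[], f=[]))
        with pytest.raises(ValueError):
            strength_toughness(FECurve(d=[1.0], f=[1.0]))

    def test_area_invariant_to_sample_shuffle(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.random(200)) * 30
        f = np.abs(np.sin(d / 5))
        s1, t1 = strength_toughness(FECurve(d=d, f=f))
        perm = rng.permutation(200)
        # re-sorted internally by deformation
        c2 = FECurve.__new__(FECurve)
        c2.d, c2.f, c2.meta = d[perm], f[perm], {}
        s2, t2 = strength_toughness(c2)
        assert s1 == s2
        assert t1 == pytest.approx(t2, rel=1e-9)
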