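import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ddssa.model import Reaction, SpeciesRef, build_network
from ddssa.particles import (CM2_TO_UM2, ArrivalRecord, ParticleSimConfig,
                             ParticleWorld, SphericalGeometry, _resolve_moves,
                             apply_boundaries, brownian_step, find_pairs,
                             init_positions, react_pairs, run_particle_sim)

A_C, A_N = SpeciesRef("A", "c"), SpeciesRef("A", "n")


class TestBrownianStep:
    def test_zero_diffusion_leaves_positions(self, rng):
        pos = rng.normal(size=(50, 3))
        out = brownian_step(pos, 0.0, 1e-3, rng)
        np.testing.assert_array_equal(out, pos)

    def test_negative_diffusion_rejected(self, rng):
        with pytest.raises(ValueError):
            brownian_step(np.zeros((1, 3)), -1e-7, 1e-3, rng)

    def test_msd_matches_nominal_diffusion(self, rng):
        # cube truncation is variance-calibrated: MSD after n steps = 6 D n dt
        D, dt, n_steps = 1e-7, 1e-3, 10
        pos = np.zeros((20_000, 3))
        for _ in range(n_steps):
            pos = brownian_step(pos, D, dt, rng)
        msd = np.mean(np.sum(pos**2, axis=1))
        expected = 6.0 * D * CM2_TO_UM2 * n_steps * dt
        assert msd == pytest.approx(expected, rel=0.02)

    def test_steps_confined_to_cube(self, rng):
        D, dt = 1e-7, 1e-3
        sigma = np.sqrt(2 * D * CM2_TO_UM2 * dt)
        pos = brownian_step(np.zeros((5000, 3)), D, dt, rng)
        assert np.abs(pos).max() <= 3.0 * sigma + 1e-12

    def test_seeded_reproducibility(self):
        a = brownian_step(np.zeros((10, 3)), 1e-7, 1e-3, np.random.default_rng(5))
        b = brownian_step(np.zeros((10, 3)), 1e-7, 1e-3, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestBoundaries:
    def setup_method(self):
        self.geom = SphericalGeometry()

    def test_full_permeability_always_crosses(self, rng):
        pos = np.array([4.3, 0.0, 0.0])
        proposed = np.array([4.2, 0.0, 0.0])  # into the nucleus
        new, comp, crossed = apply_boundaries(pos, proposed, A_C, self.geom, rng)
        assert crossed and comp == "n"
        np.testing.assert_array_equal(new, proposed)

    def test_zero_permeability_never_crosses(self, rng):
        geom = SphericalGeometry(permeability={(A_C, "nuclear"): 0.0})
        old = np.tile([4.32, 0.0, 0.0], (2000, 1))
        proposed = np.tile([4.2, 0.0, 0.0], (2000, 1))
        _, crossed = _resolve_moves(old, proposed, A_C, geom, rng,
                                    sigma=0.05, can_cross_nuclear=True)
        assert not crossed.any()

    def test_crossing_fraction_matches_permeability(self, rng):
        # 10^4 crossing attempts at permeability 0.5: binomial proportion
        geom = SphericalGeometry(permeability={(A_C, "nuclear"): 0.5})
        n = 10_000
        old = np.tile([4.32, 0.0, 0.0], (n, 1))
        proposed = np.tile([4.2, 0.0, 0.0], (n, 1))
        _, crossed = _resolve_moves(old, proposed, A_C, geom, rng,
                                    sigma=0.05, can_cross_nuclear=True)
        frac = crossed.mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_outer_membrane_reflects(self, rng):
        old = np.tile([7.7, 0.0, 0.0], (100, 1))
        proposed = np.tile([7.9, 0.0, 0.0], (100, 1))  # outside the cell
        new, crossed = _resolve_moves(old, proposed, A_C, self.geom, rng,
                                      sigma=0.05, can_cross_nuclear=False)
        assert not crossed.any()
        radii = np.linalg.norm(new, axis=1)
        assert np.all(radii <= self.geom.cell_radius)
        assert np.all(radii >= self.geom.nucleus_radius)


class TestFindPairs:
    def test_single_particle_no_pairs(self):
        assert find_pairs(np.zeros((1, 3)), 0.1) == []

    def test_exact_cutoff_distance_included(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
        assert find_pairs(pos, 0.1) == [(0, 1)]

    def test_bin_size_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            find_pairs(np.zeros((2, 3)), 0.1, bin_size=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 400), st.floats(0.05, 1.0), st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, n, cutoff, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-2, 2, size=(n, 3))
        got = set(find_pairs(pos, cutoff))
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        want = {(i, j) for i in range(n) for j in range(i + 1, n)
                if d[i, j] <= cutoff}
        assert got == want

    def test_cross_species_pairs_match_brute_force(self, rng):
        a = rng.uniform(-1, 1, size=(150, 3))
        b = rng.uniform(-1, 1, size=(100, 3))
        got = set(find_pairs(a, 0.3, positions_b=b))
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        want = {(i, j) for i in range(150) for j in range(100) if d[i, j] <= 0.3}
        assert got == want


class TestReactPairs:
    def test_zero_probability_never_reacts(self, rng):
        pairs = [(0, 1), (2, 3)]
        for _ in range(50):
            assert react_pairs(pairs, 0.0, rng) == []

    def test_one_reaction_per_particle(self, rng):
        # particle 0 appears in two candidate pairs; only one may fire
        for _ in range(200):
            hits = react_pairs([(0, 1), (0, 2)], 1.0, rng)
            assert len(hits) == 1

    def test_geometric_waiting_time(self, rng):
        # immobile pair, p = 0.5: steps-to-reaction is geometric, mean 2
        reps, steps = 10_000, []
        for _ in range(reps):
            k = 1
            while not react_pairs([(0, 1)], 0.5, rng):
                k += 1
            steps.append(k)
        steps = np.array(steps)
        se = steps.std(ddof=1) / np.sqrt(reps)
        assert abs(steps.mean() - 2.0) <= 3 * se


class TestInitPositions:
    def setup_method(self):
        self.geom = SphericalGeometry()

    def test_uniform_cytosol_radial_density(self, rng):
        pos = init_positions(("uniform", "c"), self.geom, 20_000, rng)
        r = np.linalg.norm(pos, axis=1)
        assert r.min() > self.geom.nucleus_radius
        assert r.max() < self.geom.cell_radius
        # uniform in volume <=> r^3 uniform on [r_n^3, r_c^3]
        u = (r**3 - self.geom.nucleus_radius**3) / (
            self.geom.cell_radius**3 - self.geom.nucleus_radius**3)
        counts, _ = np.histogram(u, bins=20, range=(0, 1))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_cluster_containment(self, rng):
        pos = init_positions(("cluster", 7.0, 0.5), self.geom, 5000, rng)
        d = np.linalg.norm(pos - np.array([7.0, 0.0, 0.0]), axis=1)
        assert d.max() <= 0.5

    def test_cluster_overlapping_membrane_rejected(self, rng):
        with pytest.raises(ValueError, match="overlaps"):
            init_positions(("cluster", 4.4, 0.5), self.geom, 10, rng)

    def test_zero_count_empty(self, rng):
        assert init_positions(("uniform", "n"), self.geom, 0, rng).shape == (0, 3)

    def test_membrane_placement_on_surface(self, rng):
        pos = init_positions(("membrane",), self.geom, 1000, rng)
        np.testing.assert_allclose(np.linalg.norm(pos, axis=1),
                                   self.geom.cell_radius, rtol=1e-12)


class TestRunParticleSim:
    def _world(self, rng, n=50):
        geom = SphericalGeometry()
        return ParticleWorld.build(geom, {A_C: ("cluster", 7.0, 0.5)},
                                   {A_C: n, A_N: 0}, rng)

    def _net(self):
        return build_network(
            [A_C, A_N],
            [Reaction((A_C,), (A_N,), kind="delayed", delay_source="tau1")])

    def test_frozen_world_constant_trajectory(self, rng):
        world = self._world(rng)
        cfg = ParticleSimConfig(diffusion={A_C: 0.0})
        traj, _ = run_particle_sim(world, self._net(), cfg, t_end=0.05, rng=rng)
        assert np.all(traj.column(A_C) == 50)

    def test_translocation_events_recorded(self, rng):
        world = self._world(rng)
        cfg = ParticleSimConfig(diffusion={A_C: 1e-7})
        traj, recs = run_particle_sim(world, self._net(), cfg, t_end=10.0,
                                      record=["A_c->A_n"], rng=rng)
        rec = recs["A_c->A_n"]
        assert rec.n_initial == 50
        assert rec.n_events > 0
        assert np.all(np.diff(rec.event_times) >= 0)
        assert rec.event_positions.shape == (rec.n_events, 3)
        # arrival positions sit on the nuclear side of the membrane
        assert np.linalg.norm(rec.event_positions, axis=1).max() < 4.29
        # cumulative nuclear count is the mirror of the event record
        a_n = traj.column(A_N)
        assert a_n[-1] == rec.n_events
        assert np.all(np.diff(a_n) >= 0)

    def test_particle_number_conserved_without_reactions(self, rng):
        world = self._world(rng)
        net = build_network([A_C], [])
        cfg = ParticleSimConfig(diffusion={A_C: 1e-7})
        traj, _ = run_particle_sim(world, net, cfg, t_end=0.5, rng=rng)
        assert np.all(traj.column(A_C) == 50)

    def test_seeded_runs_bit_reproducible(self):
        def one(seed):
            rng = np.random.default_rng(seed)
            world = self._world(rng)
            cfg = ParticleSimConfig(diffusion={A_C: 1e-7})
            traj, _ = run_particle_sim(world, self._net(), cfg, t_end=2.0, rng=rng)
            return traj
        a, b = one(7), one(7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_horizon_rejected(self, rng):
        with pytest.raises(ValueError):
            run_particle_sim(self._world(rng), self._net(),
                             ParticleSimConfig(), t_end=0.0, rng=rng)


def test_arrival_record_validation():
    with pytest.raises(ValueError, match="horizon"):
        ArrivalRecord(np.array([5.0]), n_initial=10, horizon=1.0)
    rec = ArrivalRecord(np.array([3.0, 1.0]), n_initial=4, horizon=5.0)
    np.testing.assert_array_equal(rec.event_times, [1.0, 3.0])
    assert rec.arrival_fraction == 0.5


def test_geometry_validation():
    with pytest.raises(ValueError):
        SphericalGeometry(cell_radius=3.0, nucleus_radius=4.0)
    with pytest.raises(ValueError):
        SphericalGeometry(permeability={(A_C, "nuclear"): 1.5})
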