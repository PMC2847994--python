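import math

import numpy as np
import pytest

from ddssa.delays import DelayDistribution, DelayWindowRule
from ddssa.engine import (DSSAEngine, EngineConfig, apply_window_rules,
                          propensity, run_ensemble, run_m1, run_m3, run_ssa)
from ddssa.model import Reaction, SpeciesRef, build_network, resample_trajectory

A, B, C = SpeciesRef("A"), SpeciesRef("B"), SpeciesRef("C")
A_C, A_N, B_C = SpeciesRef("A", "c"), SpeciesRef("A", "n"), SpeciesRef("B", "c")


def exp_dist(rate, t_max_factor=15.0, n=2000):
    t = np.linspace(0.0, t_max_factor / rate, n)
    F = 1.0 - np.exp(-rate * t)
    return DelayDistribution(t, F / F[-1])


class TestPropensity:
    def test_zero_count_zero_propensity(self):
        r = Reaction((A,), (B,), rate_k=2.0)
        assert propensity(r, {A: 0}) == 0.0

    def test_unary_mass_action(self):
        r = Reaction((A,), (B,), rate_k=0.1)
        assert propensity(r, {A: 1000}) == pytest.approx(100.0)

    def test_dimerization_combinatorics(self):
        r = Reaction((A, A), (B,), rate_k=1.0)
        assert propensity(r, {A: 2}) == pytest.approx(1.0)  # 2*1/2
        assert propensity(r, {A: 5}) == pytest.approx(10.0)

    def test_binary_distinct_species(self):
        r = Reaction((A, B), (C,), rate_k=0.5)
        assert propensity(r, {A: 4, B: 3}) == pytest.approx(6.0)

    def test_delayed_channel_uses_scale_and_free_pool(self):
        r = Reaction((A,), (B,), kind="delayed", delay_source="d")
        assert propensity(r, {A: 3}, k_delayed_scale=100.0) == 300.0
        # explicit (tuned) rate takes precedence
        r2 = Reaction((A,), (B,), rate_k=0.015, kind="delayed", delay_source="d")
        assert propensity(r2, {A: 3}, k_delayed_scale=100.0) == pytest.approx(0.045)

    def test_m2_counts_in_transit_for_immediate_channels(self):
        r = Reaction((A,), (B,), rate_k=1.0)
        assert propensity(r, {A: 2}, in_transit={A: 5}) == pytest.approx(7.0)

    def test_negative_counts_rejected(self):
        r = Reaction((A,), (B,), rate_k=1.0)
        with pytest.raises(ValueError, match="negative"):
            propensity(r, {A: -1})


class TestWindowRules:
    def test_no_rules_unrestricted(self):
        assert apply_window_rules([], "ch", 0.5) is None

    def test_expired_rule_ignored(self):
        rule = DelayWindowRule(0.0, 1.0, 0.0, 0.5, channel="ch")
        assert apply_window_rules([rule], "ch", 2.0) is None
        assert apply_window_rules([rule], "ch", 0.5) is rule

    def test_other_channel_ignored(self):
        rule = DelayWindowRule(0.0, 1.0, 0.0, 0.5, channel="other")
        assert apply_window_rules([rule], "ch", 0.5) is None

    def test_overlapping_rules_rejected(self):
        rules = [DelayWindowRule(0.0, 2.0, 0.0, 0.5, channel="ch"),
                 DelayWindowRule(1.0, 3.0, 0.5, 1.0, channel="ch")]
        with pytest.raises(ValueError, match="overlapping"):
            apply_window_rules(rules, "ch", 1.5)


class TestDssaCore:
    def test_single_molecule_degenerate_delay_completes_at_tau(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        cfg = EngineConfig(mode="m1", t_end=10.0, k_delayed_scale=1e6, seed=1)
        traj = run_m1(net, {A: 1, B: 0},
                      cfg, delay_map={"d": DelayDistribution.degenerate(3.0)})
        t_product = traj.times[np.argmax(traj.column(B) > 0)]
        assert t_product == pytest.approx(3.0, abs=1e-5)

    def test_pure_decay_matches_analytic_mean(self):
        net = build_network([A, B], [Reaction((A,), (B,), rate_k=0.1)])
        grid = np.linspace(0, 10, 21)
        cfg = EngineConfig(mode="ssa", t_end=10.0, seed=2)
        mean, _ = run_ensemble(net, {A: 1000, B: 0}, cfg, runs=50, grid=grid)
        expected = 1000 * math.exp(-1.0)
        se = math.sqrt(1000 * math.exp(-1) * (1 - math.exp(-1)) / 50)
        assert abs(mean.column(A)[-1] - expected) <= 3 * se

    def test_degenerate_delay_path_identical_to_constant_dssa(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        m1 = run_m1(net, {A: 30, B: 0},
                    EngineConfig(mode="m1", t_end=20.0, seed=3),
                    delay_map={"d": DelayDistribution.degenerate(2.5)})
        const = run_m1(net, {A: 30, B: 0},
                       EngineConfig(mode="const", t_end=20.0, seed=3),
                       delay_map={"d": 2.5})
        np.testing.assert_array_equal(m1.times, const.times)
        np.testing.assert_array_equal(m1.values, const.values)

    def test_zero_delay_reduces_to_instant_conversion(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        cfg = EngineConfig(mode="m1", t_end=1.0, seed=4)
        traj = run_m1(net, {A: 50, B: 0}, cfg,
                      delay_map={"d": DelayDistribution.degenerate(0.0)})
        assert traj.column(B)[-1] == 50

    def test_ssa_mode_rejects_delayed_channels(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        with pytest.raises(ValueError, match="SSA mode"):
            DSSAEngine(net, {A: 1}, EngineConfig(mode="ssa", t_end=1.0),
                       {"d": DelayDistribution.degenerate(1.0)})

    def test_unknown_delay_reference_rejected(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="nope")])
        cfg = EngineConfig(mode="m1", t_end=1.0, seed=1)
        with pytest.raises(KeyError, match="nope"):
            run_m1(net, {A: 1, B: 0}, cfg, delay_map={})

    def test_in_transit_molecules_remain_observable(self):
        # while a translocation is pending, the molecule is still physically
        # present: observable counts must not dip
        net = build_network([A_C, A_N], [
            Reaction((A_C,), (A_N,), kind="delayed", delay_source="d")])
        cfg = EngineConfig(mode="m1", t_end=10.0, seed=5)
        traj = run_m1(net, {A_C: 20, A_N: 0}, cfg,
                      delay_map={"d": DelayDistribution.degenerate(5.0)})
        totals = traj.values.sum(axis=1)
        np.testing.assert_array_equal(totals, 20)


class TestM2:
    def _race_net(self):
        return build_network([A_C, A_N, B_C], [
            Reaction((A_C,), (A_N,), kind="delayed", delay_source="d"),
            Reaction((A_C,), (B_C,), rate_k=0.1)])

    def test_race_fraction_matches_exponential_survival(self):
        n0, k, tau = 4000, 0.1, 3.0
        cfg = EngineConfig(mode="m1", t_end=30.0, enable_M2=True, seed=6)
        traj = run_m1(self._race_net(), {A_C: n0, A_N: 0, B_C: 0}, cfg,
                      delay_map={"d": DelayDistribution.degenerate(tau)})
        expected = math.exp(-k * tau)
        frac = traj.column(A_N)[-1] / n0
        assert abs(frac - expected) <= 3 * math.sqrt(expected * (1 - expected) / n0)

    def test_disabling_m2_suppresses_the_competing_reaction(self):
        # without poaching, the high-rate delayed channel commits everything
        # instantly and the decay never fires: measurably different from M2
        n0 = 2000
        cfg = EngineConfig(mode="m1", t_end=30.0, enable_M2=False, seed=7)
        traj = run_m1(self._race_net(), {A_C: n0, A_N: 0, B_C: 0}, cfg,
                      delay_map={"d": DelayDistribution.degenerate(3.0)})
        assert traj.column(A_N)[-1] == n0
        assert traj.column(B_C)[-1] == 0

    def test_m2_restricted_to_unary_delayed_channels(self):
        net = build_network([A, B, C], [
            Reaction((A, B), (C,), kind="delayed", delay_source="d")])
        with pytest.raises(ValueError, match="unary"):
            DSSAEngine(net, {A: 1, B: 1},
                       EngineConfig(mode="m1", t_end=1.0, enable_M2=True),
                       {"d": DelayDistribution.degenerate(1.0)})

    def test_m2_in_m3_mode_rejected(self):
        with pytest.raises(ValueError, match="M2"):
            EngineConfig(mode="m3", enable_M2=True)


class TestM3:
    def _competing_net(self):
        return build_network([A, B, C], [
            Reaction((A,), (B,), kind="delayed", delay_source="d1"),
            Reaction((A,), (C,), kind="delayed", delay_source="d2")])

    def test_symmetric_distributions_split_evenly(self):
        dm = {"d1": exp_dist(1.0), "d2": exp_dist(1.0)}
        grid = np.linspace(0, 30, 31)
        cfg = EngineConfig(mode="m3", t_end=30.0, seed=8)
        mean, _ = run_ensemble(self._competing_net(), {A: 1000}, cfg,
                               runs=20, grid=grid, delay_map=dm)
        se = math.sqrt(1000 * 0.25 / 20)
        assert abs(mean.column(B)[-1] - 500.0) <= 3 * se

    def test_single_channel_degenerate_delay_all_products_at_tau(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        cfg = EngineConfig(mode="m3", t_end=10.0, seed=9)
        traj = run_m3(net, {A: 25, B: 0}, cfg,
                      delay_map={"d": DelayDistribution.degenerate(4.0)})
        out = resample_trajectory(traj, np.array([3.999, 4.0]))
        np.testing.assert_array_equal(out.column(B), [0.0, 25.0])

    def test_mixed_network_rejected(self):
        net = build_network([A, B, C], [
            Reaction((A,), (B,), kind="delayed", delay_source="d"),
            Reaction((A,), (C,), rate_k=1.0)])
        with pytest.raises(ValueError, match="every channel"):
            DSSAEngine(net, {A: 1}, EngineConfig(mode="m3", t_end=1.0),
                       {"d": DelayDistribution.degenerate(1.0)})

    def test_piecewise_distributions_switch_at_interval_bounds(self):
        # an early window with a short degenerate delay, a late window with a
        # long one: completions must reflect the distribution active at
        # selection time
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        piecewise = [((0.0, 1e-2), DelayDistribution.degenerate(1.0)),
                     ((1e-2, np.inf), DelayDistribution.degenerate(50.0))]
        cfg = EngineConfig(mode="m3", t_end=200.0, seed=21)
        traj = run_m3(net, {A: 40, B: 0}, cfg, delay_map={"d": piecewise})
        # all molecules are selected in the first rounds at t ~ 0
        completions = traj.times[np.diff(traj.column(B), prepend=0) > 0]
        assert np.allclose(completions, 1.0)

    def test_window_rule_limits_delays_during_interval(self):
        # draws during [0, 1) restricted below the median: with all molecules
        # selected at t=0, every completion lands at or below the median
        d = exp_dist(1.0)
        rule = DelayWindowRule(0.0, 1.0, 0.0, 0.5, channel="A->B")
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        cfg = EngineConfig(mode="m3", t_end=30.0, seed=10,
                           window_rules=[rule])
        traj = run_m3(net, {A: 200, B: 0}, cfg, delay_map={"d": d})
        completion_times = traj.times[np.diff(traj.column(B), prepend=0) > 0]
        assert completion_times.max() <= d.median + 1e-9


class TestConservation:
    def test_mass_constant_through_pending_queue(self):
        net = build_network([A_C, A_N, B_C], [
            Reaction((A_C,), (A_N,), kind="delayed", delay_source="d"),
            Reaction((A_C,), (B_C,), rate_k=0.05)])
        weights = {A_C: 1.0, A_N: 1.0, B_C: 1.0}
        eng = DSSAEngine(net, {A_C: 300, A_N: 0, B_C: 0},
                         EngineConfig(mode="m1", t_end=50.0, enable_M2=True,
                                      seed=11),
                         {"d": exp_dist(0.5)})
        assert eng.mass(weights) == 300
        for _ in range(5000):
            if not eng.dssa_step():
                break
            assert eng.mass(weights) == 300  # exact integers at every event

    def test_m3_mass_constant(self):
        net = build_network([A, B, C], [
            Reaction((A,), (B,), kind="delayed", delay_source="d1"),
            Reaction((A,), (C,), kind="delayed", delay_source="d2")])
        eng = DSSAEngine(net, {A: 200}, EngineConfig(mode="m3", t_end=50.0,
                                                     seed=12),
                         {"d1": exp_dist(1.0), "d2": exp_dist(0.3)})
        w = {A: 1.0, B: 1.0, C: 1.0}
        for _ in range(2000):
            if not eng.m3_round():
                break
            assert eng.mass(w) == 200

    def test_seeded_paths_identical(self):
        net = build_network([A, B], [
            Reaction((A,), (B,), kind="delayed", delay_source="d")])
        dm = {"d": exp_dist(1.0)}
        t1 = run_m1(net, {A: 100, B: 0},
                    EngineConfig(mode="m1", t_end=20.0, seed=13), dm)
        t2 = run_m1(net, {A: 100, B: 0},
                    EngineConfig(mode="m1", t_end=20.0, seed=13), dm)
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_k_delayed_scale_insensitivity(self):
        # waiting times are negligible against delays, so doubling the high
        # rate must not move the mean trajectory beyond the Monte-Carlo band
        net = build_network([A_C, A_N], [
            Reaction((A_C,), (A_N,), kind="delayed", delay_source="d")])
        dm = {"d": exp_dist(0.5)}
        grid = np.linspace(0, 20, 41)
        means = []
        for scale in (1e4, 2e4):
            cfg = EngineConfig(mode="m1", t_end=20.0, seed=14,
                               k_delayed_scale=scale)
            mean, _ = run_ensemble(net, {A_C: 400, A_N: 0}, cfg, runs=10,
                                   grid=grid, delay_map=dm)
            means.append(mean.column(A_N))
        F = means[0] / 400
        band = 3 * np.sqrt(np.maximum(400 * F * (1 - F), 1e-9) * 2 / 10) + 1
        assert np.all(np.abs(means[0] - means[1]) <= band)
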