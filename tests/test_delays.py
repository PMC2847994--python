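import numpy as np
import pytest
from scipy import stats

from ddssa.delays import (DelayDistribution, DelayWindowRule,
                          Diffusion1DProblem, cdf_from_ssa_mean, empirical_cdf,
                          random_walk_1d, sample_delay, solve_arrival_pde,
                          truncate)
from ddssa.model import SpeciesRef, Trajectory
from ddssa.particles import ArrivalRecord


def exp_distribution(rate=1.0, t_max=15.0, n=3000):
    t = np.linspace(0.0, t_max, n)
    F = 1.0 - np.exp(-rate * t)
    return DelayDistribution(t, F / F[-1])


class TestEmpiricalCdf:
    def test_degenerate_all_events_at_one_time(self):
        rec = ArrivalRecord(np.full(10, 5.0), n_initial=10, horizon=10.0)
        d = empirical_cdf(rec)
        assert d.cdf(4.999) == 0.0
        assert d.cdf(5.0) == 1.0
        assert d.arrival_mass == 1.0

    def test_hand_counted_quartiles(self):
        rec = ArrivalRecord(np.array([1.0, 2.0, 3.0, 4.0]), 4, horizon=5.0)
        d = empirical_cdf(rec)
        assert d.cdf(2.5) == pytest.approx(0.5)
        assert d.arrival_mass == 1.0

    def test_partial_arrival_mass_bookkeeping(self):
        rec = ArrivalRecord(np.arange(1.0, 6.0), n_initial=10, horizon=10.0)
        d = empirical_cdf(rec)
        assert d.arrival_mass == pytest.approx(0.5)
        assert d.F[-1] == 1.0  # conditional CDF still proper

    def test_empty_record_rejected(self):
        rec = ArrivalRecord(np.array([]), n_initial=5, horizon=1.0)
        with pytest.raises(ValueError):
            empirical_cdf(rec)


class TestSampling:
    def test_u_zero_gives_smallest_support(self):
        d = exp_distribution()
        assert d.quantile(0.0) == d.t_grid[0]

    def test_exponential_sample_mean(self, rng):
        d = exp_distribution(rate=1.0)
        x = sample_delay(d, rng, size=100_000)
        assert abs(x.mean() - 1.0) <= 3.0 / np.sqrt(100_000) + 0.01

    def test_window_restricts_to_lower_quantiles(self, rng):
        d = exp_distribution()
        w = DelayWindowRule(0.0, 1.0, 0.0, 0.5)
        x = sample_delay(d, rng, window=w, now=0.5, size=2000)
        assert np.max(x) <= d.median + 1e-9

    def test_expired_window_ignored(self, rng):
        d = exp_distribution()
        w = DelayWindowRule(0.0, 1.0, 0.0, 0.1)
        x = sample_delay(d, rng, window=w, now=2.0, size=2000)
        assert np.max(x) > d.median  # unrestricted draws reach the tail

    def test_glivenko_cantelli(self, rng):
        ref = exp_distribution()
        n = 10_000
        samples = sample_delay(ref, rng, size=n)
        emp = empirical_cdf(ArrivalRecord(samples, n, horizon=np.inf))
        grid = np.sort(samples)
        sup = np.max(np.abs(emp.cdf(grid) - ref.cdf(grid)))
        assert sup <= 1.63 / np.sqrt(n)


class TestTruncate:
    def test_identity_at_one(self):
        d = exp_distribution()
        assert truncate(d, 1.0) is d

    def test_hand_renormalization(self):
        rec = ArrivalRecord(np.array([1.0, 2.0, 3.0, 4.0]), 4, horizon=5.0)
        d = truncate(empirical_cdf(rec), 0.5)
        np.testing.assert_allclose(d.t_grid, [1.0, 2.0])
        np.testing.assert_allclose(d.F, [0.5, 1.0])

    def test_degenerate_unchanged(self):
        d = DelayDistribution.degenerate(7.0)
        out = truncate(d, 0.3)
        assert out.quantile(0.99) == 7.0

    def test_invalid_u_max_rejected(self):
        with pytest.raises(ValueError):
            truncate(exp_distribution(), 0.0)

    def test_truncate_equals_window_sampling(self, rng):
        # conditioning on F <= u_max == restricting the uniform to [0, u_max)
        d = exp_distribution()
        a = sample_delay(truncate(d, 0.5), rng, size=4000)
        w = DelayWindowRule(0.0, 1e9, 0.0, 0.5)
        b = sample_delay(d, rng, window=w, now=0.0, size=4000)
        assert stats.ks_2samp(a, b).pvalue > 0.01


class TestArrivalPde:
    def test_conservation_and_completeness(self):
        prob = Diffusion1DProblem(D=0.5, L=1.0, x0=0.5, dx=0.005, dt_pde=0.002)
        d = solve_arrival_pde(prob, t_end=8.0)
        assert d.source["conservation_gap"] < 1e-9
        assert d.source["absorbed_mass"] >= 0.999  # certain absorption in 1D
        assert np.all(np.diff(d.F) >= -1e-12)

    def test_frozen_particle_rejected(self):
        prob = Diffusion1DProblem(D=0.0, L=1.0, x0=0.5)
        with pytest.raises(RuntimeError, match="no probability absorbed"):
            solve_arrival_pde(prob, t_end=1.0)

    def test_no_absorbing_boundary_rejected(self):
        prob = Diffusion1DProblem(D=0.5, L=1.0, x0=0.5,
                                  bc_left="reflecting", bc_right="reflecting")
        with pytest.raises(ValueError, match="absorbing"):
            solve_arrival_pde(prob, t_end=1.0)

    def test_pdf_matches_eigenfunction_series(self):
        # absorbing at 0, reflecting at L: phi_n = sin(lam_n x),
        # lam_n = (n + 1/2) pi / L; dP/dt = sum c_n D lam_n exp(-D lam_n^2 t)
        D, L, x0 = 0.5, 1.0, 0.5
        prob = Diffusion1DProblem(D=D, L=L, x0=x0, dx=0.002, dt_pde=5e-4)
        d = solve_arrival_pde(prob, t_end=3.0)
        t = d.t_grid[d.t_grid >= 0.05]
        n = np.arange(200)[:, None]
        lam = (n + 0.5) * np.pi / L
        series = np.sum((2.0 / L) * np.sin(lam * x0) * D * lam
                        * np.exp(-D * lam**2 * t[None, :]), axis=0)
        pdf = d.pdf[d.t_grid >= 0.05] * d.source["absorbed_mass"]
        assert np.max(np.abs(pdf - series)) < 1e-3

    def test_x0_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            Diffusion1DProblem(D=0.5, L=1.0, x0=2.0)


class TestRandomWalk:
    def test_first_step_capture_possible(self):
        rec = random_walk_1d(200, step_size=0.1, L=1.0, x0=0.1, rng_or_seed=3)
        assert rec.event_times.min() == 1.0  # one step (dt defaults to 1)

    def test_all_walkers_absorbed(self):
        rec = random_walk_1d(500, step_size=0.05, L=1.0, x0=0.5, rng_or_seed=4)
        assert rec.n_events == 500

    def test_mean_first_passage_time(self):
        D = 0.5
        rec = random_walk_1d(4000, step_size=0.01, L=1.0, x0=0.4,
                             rng_or_seed=5, D=D)
        analytic = 0.4 * (2 * 1.0 - 0.4) / (2 * D)
        se = rec.event_times.std(ddof=1) / np.sqrt(rec.n_events)
        assert abs(rec.event_times.mean() - analytic) <= 3 * se

    def test_agrees_with_pde_and_refines(self):
        # the walk CDF approaches the PDE CDF; a finer step stays within the
        # sampling band and does not degrade
        D, L, x0, n = 0.5, 1.0, 0.5, 4000
        pde = solve_arrival_pde(
            Diffusion1DProblem(D=D, L=L, x0=x0, dx=0.004, dt_pde=0.001), 8.0)
        ks = {}
        for step in (0.02, 0.01):
            rec = random_walk_1d(n, step, L, x0, rng_or_seed=6, D=D)
            emp = empirical_cdf(rec)
            grid = np.sort(rec.event_times)
            ks[step] = np.max(np.abs(emp.cdf(grid) - pde.cdf(grid)))
        assert ks[0.01] <= 1.63 / np.sqrt(n)
        assert ks[0.01] <= ks[0.02] + 0.01

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            random_walk_1d(10, step_size=0.0, L=1.0, x0=0.5, rng_or_seed=1)
        with pytest.raises(ValueError):
            random_walk_1d(10, step_size=0.1, L=1.0, x0=1.5, rng_or_seed=1)


class TestCdfFromSsaMean:
    def _decay_traj(self, k=1.0, n0=1000.0):
        t = np.linspace(0.0, 12.0, 600)
        a = SpeciesRef("A")
        return Trajectory(t, (a,), (n0 * np.exp(-k * t))[:, None],
                          kind="linear"), a

    def test_exponential_decay_median(self):
        traj, a = self._decay_traj()
        d = cdf_from_ssa_mean(traj, a)
        assert d.cdf(np.log(2.0)) == pytest.approx(0.5, abs=0.01)

    def test_constant_time_course_rejected(self):
        t = np.linspace(0, 1, 10)
        a = SpeciesRef("A")
        traj = Trajectory(t, (a,), np.full((10, 1), 3.0), kind="linear")
        with pytest.raises(ValueError, match="constant"):
            cdf_from_ssa_mean(traj, a)

    def test_accumulating_product_normalized(self):
        t = np.linspace(0.0, 5.0, 100)
        b = SpeciesRef("B")
        traj = Trajectory(t, (b,), (200 * (1 - np.exp(-t)))[:, None],
                          kind="linear")
        d = cdf_from_ssa_mean(traj, b)
        assert d.F[-1] == 1.0
        assert d.cdf(1.0) == pytest.approx((1 - np.exp(-1)) / (1 - np.exp(-5)),
                                           abs=0.01)


def test_distribution_csv_roundtrip(tmp_path):
    d = exp_distribution()
    path = tmp_path / "dist.csv"
    d.to_csv(path)
    back = DelayDistribution.from_csv(path)
    np.testing.assert_array_equal(back.t_grid, d.t_grid)
    np.testing.assert_array_equal(back.F, d.F)


def test_distribution_validation():
    with pytest.raises(ValueError):
        DelayDistribution(np.array([0.0, 1.0]), np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        DelayDistribution(np.array([0.0, 1.0]), np.array([0.2, 0.8]))
    with pytest.raises(ValueError):
        DelayDistribution(np.array([-1.0, 1.0]), np.array([0.2, 1.0]))
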