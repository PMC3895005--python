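import numpy as np
import pytest
from scipy.stats import skew

from conftest import (
    TEMPERATURE,
    build_synthetic_archive,
    harmonic_exact_delta_f,
)
from ionpull import (
    HarmonicPotential,
    LangevinParams,
    PullingSchedule,
    assemble_work_distribution,
    backward_schedule,
    convergence_trace,
    delta_delta_f,
    jarzynski_delta_f,
    mean_force_delta_f,
    quasi_equilibrium_delta_f,
    run_stepwise_pulling,
    selectivity_ratio,
)
from ionpull.errors import ConfigurationError, GridMismatchError
from ionpull.free_energy import FreeEnergyProfile, WorkTrajectorySet
from ionpull.units import kbt


def _gaussian_work_set(mu, sigma, n, seed):
    rng = np.random.default_rng(seed)
    w = rng.normal(mu, sigma, size=n)
    return WorkTrajectorySet(
        lambdas=[0.0, 1.0],
        works=np.column_stack([np.zeros(n), w]),
        weights=np.ones(n),
        mode="monte_carlo",
    )


class TestAssembly:
    def test_degenerate_single_positions(self):
        # each step has all samples at one z: a single deterministic W
        arc = build_synthetic_archive(
            [np.full(5, 0.2), np.full(5, 1.3), np.full(5, 2.1)]
        )
        ws = assemble_work_distribution(arc, mode="exhaustive")
        expected_w1 = arc.step_work_samples(0)[0]
        expected_w2 = expected_w1 + arc.step_work_samples(1)[0]
        assert np.allclose(ws.works.min(axis=0), ws.works.max(axis=0))
        assert ws.works[0, 1] == pytest.approx(expected_w1)
        assert ws.works[0, 2] == pytest.approx(expected_w2)

    def test_exhaustive_enumerates_product(self):
        rng = np.random.default_rng(0)
        arc = build_synthetic_archive([rng.normal(i, 0.3, 10) for i in range(3)])
        ws = assemble_work_distribution(arc, mode="exhaustive")
        assert ws.n_trajectories == 100  # 10 x 10 (last step unused)
        # oracle: brute-force mean over all combos
        w0 = arc.step_work_samples(0)
        w1 = arc.step_work_samples(1)
        brute = np.add.outer(w0, w1).ravel()
        assert ws.mean_works()[2] == pytest.approx(brute.mean(), rel=1e-12)

    def test_monte_carlo_matches_exhaustive_mean(self):
        rng = np.random.default_rng(1)
        arc = build_synthetic_archive([rng.normal(i, 0.3, 10) for i in range(3)])
        ex = assemble_work_distribution(arc, mode="exhaustive")
        mc = assemble_work_distribution(arc, mode="monte_carlo", n_draws=100_000, seed=2)
        sd = ex.works[:, 2].std()
        se = sd / np.sqrt(mc.n_trajectories)
        assert abs(mc.mean_works()[2] - ex.mean_works()[2]) < 3 * se

    def test_exhaustive_cap(self):
        arc = build_synthetic_archive([np.random.default_rng(0).normal(0, 1, 5000)] * 4)
        with pytest.raises(ConfigurationError, match="monte_carlo"):
            assemble_work_distribution(arc, mode="exhaustive")

    def test_unknown_mode(self):
        arc = build_synthetic_archive([np.zeros(3) + 0.1, np.ones(3)])
        with pytest.raises(ConfigurationError):
            assemble_work_distribution(arc, mode="magic")

    def test_harmonic_works_nearly_gaussian(self, harmonic_archive):
        ws = assemble_work_distribution(
            harmonic_archive, mode="monte_carlo", n_draws=100_000, seed=4
        )
        assert abs(skew(ws.works[:, 2])) < 0.2


class TestJarzynski:
    def test_delta_distribution(self):
        n = 50
        ws = WorkTrajectorySet(
            lambdas=[0.0, 1.0],
            works=np.column_stack([np.zeros(n), np.full(n, 1.7)]),
            weights=np.ones(n),
            mode="monte_carlo",
        )
        prof = jarzynski_delta_f(ws, TEMPERATURE, n_boot=0)
        assert prof.delta_f[1] == pytest.approx(1.7, abs=1e-12)

    def test_gaussian_closed_form(self):
        # dF = mu - sigma^2 / (2 kBT)
        ws = _gaussian_work_set(1.0, 0.5, 200_000, seed=11)
        prof = jarzynski_delta_f(ws, TEMPERATURE, n_boot=0)
        expected = 1.0 - 0.25 / (2 * kbt(TEMPERATURE))
        assert prof.delta_f[1] == pytest.approx(expected, abs=0.01)

    def test_jensen_inequality(self):
        ws = _gaussian_work_set(0.3, 1.0, 5000, seed=3)
        prof = jarzynski_delta_f(ws, TEMPERATURE, n_boot=0)
        assert np.all(prof.delta_f <= ws.mean_works() + 1e-9)

    def test_reference_point_exactly_zero(self):
        ws = _gaussian_work_set(1.0, 0.5, 100, seed=0)
        prof = jarzynski_delta_f(ws, TEMPERATURE, n_boot=10, seed=1)
        assert prof.delta_f[0] == 0.0

    def test_bootstrap_se_positive_and_seeded(self):
        ws = _gaussian_work_set(1.0, 0.5, 2000, seed=5)
        p1 = jarzynski_delta_f(ws, TEMPERATURE, n_boot=50, seed=9)
        p2 = jarzynski_delta_f(ws, TEMPERATURE, n_boot=50, seed=9)
        assert p1.se[1] > 0
        assert np.array_equal(p1.se, p2.se)


class TestHarmonicOracle:
    """Parameter-recovery against the analytic coupled-harmonic profile."""

    def test_jarzynski_recovers_quadratic(self, harmonic_archive):
        ws = assemble_work_distribution(
            harmonic_archive, mode="monte_carlo", n_draws=100_000, seed=3
        )
        prof = jarzynski_delta_f(ws, TEMPERATURE, n_boot=0)
        assert prof.delta_f[2] == pytest.approx(harmonic_exact_delta_f(2.0), abs=0.1)

    def test_quasi_equilibrium_recovers_quadratic(self, harmonic_archive):
        prof = quasi_equilibrium_delta_f(harmonic_archive, TEMPERATURE, n_boot=0)
        assert prof.delta_f[2] == pytest.approx(harmonic_exact_delta_f(2.0), abs=0.1)

    def test_estimators_agree_in_long_relaxation_limit(self, harmonic_archive):
        ws = assemble_work_distribution(
            harmonic_archive, mode="monte_carlo", n_draws=100_000, seed=3
        )
        jz = jarzynski_delta_f(ws, TEMPERATURE, n_boot=100, seed=5)
        qe = quasi_equilibrium_delta_f(harmonic_archive, TEMPERATURE, n_boot=100, seed=5)
        pooled = np.sqrt(jz.se[2] ** 2 + qe.se[2] ** 2)
        assert abs(jz.delta_f[2] - qe.delta_f[2]) <= 2 * max(pooled, 1e-3)

    def test_mean_force_variant_on_fine_ladder(self):
        # left Riemann sum: O(delta_lambda) error, so use a fine ladder
        pot = HarmonicPotential(0.6)
        sched = PullingSchedule(
            delta_lambda=0.25, n_steps=9, tau1=0.2, tau2=4.0, k=0.6
        )
        params = LangevinParams(
            temperature=TEMPERATURE, diffusion_coefficient=40.0, timestep=5e-4,
            seed=21, sample_interval=5e-4,
        )
        arc = run_stepwise_pulling(pot, sched, params)
        prof = mean_force_delta_f(arc)
        # bound: |left sum - integral| <= slope_max * dl / 2 * lambda + noise
        assert prof.delta_f[-1] == pytest.approx(
            harmonic_exact_delta_f(2.0), abs=0.15
        )

    def test_state_function_forward_backward(self, harmonic_archive):
        params = harmonic_archive.params
        sched_b = backward_schedule(harmonic_archive.schedule)
        arc_b = run_stepwise_pulling(HarmonicPotential(0.6), sched_b, params)
        qe_f = quasi_equilibrium_delta_f(harmonic_archive, TEMPERATURE, n_boot=100)
        qe_b = quasi_equilibrium_delta_f(arc_b, TEMPERATURE, n_boot=100)
        pooled = np.sqrt(qe_f.se[-1] ** 2 + qe_b.se[-1] ** 2)
        assert abs(qe_f.delta_f[-1] + qe_b.delta_f[-1]) <= 2 * pooled

    def test_quasi_equilibrium_zero_delta_lambda(self):
        arc = build_synthetic_archive(
            [np.array([0.0, 0.3, -0.2]), np.array([0.1, 0.2, 0.0])],
            delta_lambda=0.0,
        )
        prof = quasi_equilibrium_delta_f(arc, TEMPERATURE, n_boot=0)
        assert np.all(prof.delta_f == 0.0)


class TestDeltaDeltaF:
    def _profile(self, values):
        v = np.asarray(values, dtype=float)
        return FreeEnergyProfile(
            lambdas=np.arange(v.size, dtype=float),
            delta_f=v,
            se=np.zeros(v.size),
            estimator="jarzynski",
        )

    def test_identical_profiles(self):
        p = self._profile([0.0, 1.0, 2.5])
        d = delta_delta_f(p, p)
        assert np.all(d.values == 0.0)

    def test_constant_shift(self):
        a = self._profile([0.0, 1.0, 2.5])
        b = self._profile([0.0, 2.0, 3.5])
        d = delta_delta_f(a, b)
        assert np.allclose(d.values[1:], 1.0)

    def test_peak_reported(self):
        a = self._profile([0.0, 3.0, 1.0])
        b = self._profile([0.0, 0.5, 0.5])
        d = delta_delta_f(a, b)
        assert d.peak_lambda == 1.0
        assert d.peak_value == pytest.approx(2.5)

    def test_grid_mismatch(self):
        a = self._profile([0.0, 1.0])
        b = self._profile([0.0, 1.0, 2.0])
        with pytest.raises(GridMismatchError):
            delta_delta_f(a, b)


class TestSelectivityRatio:
    def test_printed_value(self):
        assert selectivity_ratio(3.7, 310.0) == pytest.approx(405.9, abs=0.5)

    def test_zero_barrier(self):
        assert selectivity_ratio(0.0, 310.0) == 1.0

    def test_unit_exponent(self):
        assert selectivity_ratio(kbt(310.0), 310.0) == pytest.approx(np.e, rel=1e-12)


class TestConvergenceTrace:
    def test_approaches_analytic(self, harmonic_archive):
        exact = harmonic_exact_delta_f(2.0)
        trace = convergence_trace(
            harmonic_archive, 2.0, [0.5, 2.0, 5.0], TEMPERATURE, seed=6
        )
        assert abs(trace.values[-1] - exact) < abs(trace.values[0] - exact)
        assert trace.converged is not None

    def test_single_point_no_flag(self, harmonic_archive):
        trace = convergence_trace(harmonic_archive, 2.0, [5.0], TEMPERATURE)
        assert trace.values.size == 1
        assert trace.converged is None

    def test_identical_archives_zero_ddf(self, harmonic_archive):
        trace = convergence_trace(
            harmonic_archive,
            2.0,
            [1.0, 5.0],
            TEMPERATURE,
            archive_b=harmonic_archive,
            seed=8,
        )
        assert np.all(trace.values == 0.0)

    def test_tau_beyond_recorded_rejected(self, harmonic_archive):
        with pytest.raises(ConfigurationError):
            convergence_trace(harmonic_archive, 2.0, [50.0], TEMPERATURE)

    def test_lambda_off_grid_rejected(self, harmonic_archive):
        with pytest.raises(GridMismatchError):
            convergence_trace(harmonic_archive, 11.0, [1.0], TEMPERATURE)
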