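import numpy as np
import pytest

from conftest import build_synthetic_archive
from ionpull import (
    detailed_balance_overlap,
    fit_position_mixture,
    negative_force_fraction,
    partition_forces,
    pool_positions,
    probability_ratio,
    transition_probability,
)
from ionpull.errors import ConfigurationError, EmptyDataError
from ionpull.protocol import Histogram
from ionpull.states import (
    ForceSegment,
    fit_gaussian_mixture_1d,
    reverse_transition_probability,
)
from ionpull.toysim import SPECIES_FIXTURES


def _gauss_hist(mean, sd, lo=-8.0, hi=9.0, bw=0.005):
    from scipy.stats import norm

    edges = np.arange(lo, hi + bw / 2, bw)
    c = 0.5 * (edges[:-1] + edges[1:])
    d = norm.pdf(c, mean, sd)
    d = d / (d.sum() * bw)
    return Histogram(edges=edges, density=d)


class TestPooling:
    def test_single_step_archive_matches_g(self):
        rng = np.random.default_rng(0)
        z = rng.normal(1.0, 0.3, 500)
        arc = build_synthetic_archive([z, z])
        pooled = pool_positions(arc)
        assert pooled.total == 1000
        g = arc.steps[0].g()
        # pooled counts over the first step's support reproduce g up to scale
        assert pooled.bin_width == g.bin_width

    def test_counts_additive_across_archives(self):
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(0, 1, 300), rng.normal(0, 1, 400)
        a = build_synthetic_archive([z1, z1])
        b = build_synthetic_archive([z2, z2])
        assert (
            pool_positions(a).total + pool_positions(b).total
            == build_synthetic_archive([z1, z1]).n_steps * 300 + 2 * 400
        )

    def test_k_like_modes_near_wells(self, species_archives):
        pooled = pool_positions(species_archives["K_like"])
        modes = pooled.modes(min_prominence_fraction=0.05)
        for center, _, _ in SPECIES_FIXTURES["K_like"]:
            assert np.min(np.abs(modes - center)) < 0.3

    def test_na_like_dominant_mode_near_deep_well(self, species_archives):
        pooled = pool_positions(species_archives["Na_like"])
        modes = pooled.modes(min_prominence_fraction=0.05)
        assert np.min(np.abs(modes - 5.5)) < 0.3


class TestMixture:
    def test_two_gaussian_recovery(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(7.1, 0.3, 2500), rng.normal(10.4, 0.3, 2500)]
        )
        comps = fit_position_mixture(x, max_components=4, seed=0)
        assert len(comps) == 2
        assert comps[0].mean == pytest.approx(7.1, abs=0.1)
        assert comps[1].mean == pytest.approx(10.4, abs=0.1)
        assert sum(c.weight for c in comps) == pytest.approx(1.0, abs=1e-9)

    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 5000)
        comps = fit_position_mixture(x, max_components=3, seed=0)
        assert len(comps) == 1

    def test_components_sorted_by_mean(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(m, 0.2, 1000) for m in (3.0, -1.0, 1.0)])
        comps = fit_position_mixture(x, max_components=3, seed=1)
        means = [c.mean for c in comps]
        assert means == sorted(means)
        assert [c.component_id for c in comps] == list(range(len(comps)))

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
        _, _, trace = fit_gaussian_mixture_1d(x, 2, seed=0)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_zero_variance_gives_floored_single_component(self):
        comps = fit_position_mixture(np.full(100, 2.5), max_components=2)
        assert len(comps) == 1
        assert comps[0].sd > 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_position_mixture(np.arange(15.0), max_components=2)


class TestForcePartition:
    def test_samples_at_bias_center_give_zero_force(self):
        # every sample exactly at lambda: f = k (lambda - z) = 0
        arc = build_synthetic_archive(
            [np.full(50, 0.0), np.full(50, 1.0), np.full(50, 2.0)]
        )
        comps = fit_position_mixture(
            np.concatenate([s.z for s in arc.steps]), max_components=1
        )
        segs = partition_forces(arc, comps)
        assert all(np.all(s.forces == 0.0) for s in segs)

    def test_uniform_offset_gives_constant_force(self):
        arc = build_synthetic_archive(
            [np.full(50, -1.0), np.full(50, 0.0), np.full(50, 1.0)], k=0.6
        )
        comps = fit_position_mixture(
            np.concatenate([s.z for s in arc.steps]), max_components=1
        )
        segs = partition_forces(arc, comps)
        for s in segs:
            assert np.allclose(s.forces, 0.6)

    def test_forces_recomputable_from_samples(self, species_archives):
        arc = species_archives["K_like"]
        zs = np.concatenate([s.z for s in arc.steps])
        comps = fit_position_mixture(zs[::50], max_components=4, seed=0)
        segs = partition_forces(arc, comps)
        k = arc.schedule.k
        for seg in segs:
            lo, hi = seg.metadata["ci"]
            # every force value corresponds to some (lambda, z in CI) pair
            zmin = min(s.lambda_i - seg.forces.max() / k for s in arc.steps)
            assert seg.n > 0
            assert lo <= seg.mean_z <= hi

    def test_entry_region_forces_broader_than_outer(self, species_archives):
        arc = species_archives["Na_like"]
        zs = np.concatenate([s.z for s in arc.steps])
        comps = fit_position_mixture(zs[::20], max_components=8, seed=0)
        segs = partition_forces(arc, comps)
        entry = [s.sd_f for s in segs if 5.0 < s.mean_z < 12.0]
        outer = [s.sd_f for s in segs if s.mean_z > 12.0]
        assert entry and outer
        assert max(entry) > max(outer)


def _seg(forces, dispersion, mean_z, cid=0):
    return ForceSegment(
        component_id=cid, mean_z=mean_z, forces=np.asarray(forces, float),
        dispersion=dispersion,
    )


class TestTransitionProbability:
    def test_small_small_forward_one_reverse_zero(self):
        a = _seg([1.0, 1.1], "small", 1.0)
        b = _seg([0.5, 0.6], "small", 2.0, cid=1)
        assert transition_probability(a, b) == 1.0
        assert reverse_transition_probability(a, b) == 0.0

    def test_small_small_forward_zero(self):
        a = _seg([0.1, 0.2], "small", 1.0)
        b = _seg([0.5, 0.6], "small", 2.0, cid=1)
        assert transition_probability(a, b) == 0.0
        assert reverse_transition_probability(a, b) == 1.0

    def test_large_small_fraction_against_mean(self):
        # 386 of 1300 large-SD observations >= the small segment's mean (0)
        f = np.concatenate([np.full(386, 1.0), np.full(914, -1.0)])
        a = _seg(f, "large", 1.0)
        b = _seg([0.0, 0.0], "small", 2.0, cid=1)
        assert transition_probability(a, b) == pytest.approx(386 / 1300)

    def test_small_large_focuses_on_large(self):
        a = _seg([0.5, 0.5], "small", 1.0)
        b = _seg([0.0, 1.0, 2.0, 0.2], "large", 2.0, cid=1)
        # fraction of large segment <= 0.5
        assert transition_probability(a, b) == pytest.approx(0.5)

    def test_large_large_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        fi = rng.normal(0.5, 1.0, 150)
        fj = rng.normal(0.2, 1.0, 180)
        a = _seg(fi, "large", 1.0)
        b = _seg(fj, "large", 2.0, cid=1)
        p1 = sum((x >= y) for x in fi for y in fj) / (fi.size * fj.size)
        p2 = sum((y <= x) for x in fi for y in fj) / (fi.size * fj.size)
        assert transition_probability(a, b) == pytest.approx(p1 * p2, abs=1e-12)

    def test_large_large_symmetric_identical_quarter(self):
        rng = np.random.default_rng(8)
        half = rng.normal(1.0, 0.5, 100)
        f = np.concatenate([half, -half])  # symmetric about 0, 200 values
        a = _seg(f, "large", 1.0)
        b = _seg(f.copy(), "large", 2.0, cid=1)
        # exact pairwise fraction is 1/2 + ties/(2 n) -> ~0.25
        assert transition_probability(a, b) == pytest.approx(0.25, abs=0.01)

    def test_order_enforced(self):
        a = _seg([1.0, 1.0], "small", 3.0)
        b = _seg([0.5, 0.5], "small", 2.0, cid=1)
        with pytest.raises(ConfigurationError):
            transition_probability(a, b)

    def test_empty_segment_rejected(self):
        a = _seg([], "small", 1.0)
        b = _seg([0.5], "small", 2.0, cid=1)
        with pytest.raises(EmptyDataError):
            transition_probability(a, b)


class TestNegativeForceFraction:
    def test_printed_example(self):
        f = np.concatenate([np.full(386, -0.5), np.full(914, 0.5)])
        frac = negative_force_fraction(_seg(f, "large", 7.0))
        assert frac == pytest.approx(386 / 1300)
        assert round(frac, 1) == 0.3

    def test_all_positive(self):
        assert negative_force_fraction(_seg([0.1, 0.2], "small", 1.0)) == 0.0

    def test_all_negative(self):
        assert negative_force_fraction(_seg([-0.1, -0.2], "small", 1.0)) == 1.0


class TestProbabilityRatio:
    def test_printed_example(self):
        assert probability_ratio(0.3, 0.02) == pytest.approx(15.0)

    def test_identity(self):
        assert probability_ratio(0.4, 0.4) == 1.0

    def test_zero_numerator(self):
        assert probability_ratio(0.0, 0.2) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ConfigurationError):
            probability_ratio(0.3, 0.0)


class TestOverlap:
    def test_identical_distributions(self):
        g = _gauss_hist(0.0, 1.0)
        rep = detailed_balance_overlap(g, g)
        assert rep.overlap == pytest.approx(1.0, abs=1e-9)
        assert rep.forward_weight == pytest.approx(rep.backward_weight)

    def test_disjoint_supports(self):
        e1 = np.linspace(0.0, 1.0, 11)
        e2 = np.linspace(5.0, 6.0, 11)
        g1 = Histogram(edges=e1, density=np.full(10, 1.0))
        g2 = Histogram(edges=e2, density=np.full(10, 1.0))
        rep = detailed_balance_overlap(g1, g2)
        assert rep.overlap == 0.0
        assert rep.below_floor

    def test_unit_gaussians_one_sd_apart(self):
        from scipy.stats import norm

        g1 = _gauss_hist(0.0, 1.0)
        g2 = _gauss_hist(1.0, 1.0)
        rep = detailed_balance_overlap(g1, g2)
        assert rep.overlap == pytest.approx(2 * norm.cdf(-0.5), abs=1e-3)

    def test_symmetry(self):
        g1 = _gauss_hist(0.0, 1.0)
        g2 = _gauss_hist(1.5, 0.7)
        assert detailed_balance_overlap(g1, g2).overlap == pytest.approx(
            detailed_balance_overlap(g2, g1).overlap, abs=1e-9
        )

    def test_rebin_invariance(self):
        g1a = _gauss_hist(0.0, 1.0, bw=0.005)
        g2a = _gauss_hist(1.0, 1.0, bw=0.005)
        g1b = _gauss_hist(0.0, 1.0, bw=0.01)
        g2b = _gauss_hist(1.0, 1.0, bw=0.01)
        assert detailed_balance_overlap(g1a, g2a).overlap == pytest.approx(
            detailed_balance_overlap(g1b, g2b).overlap, abs=1e-3
        )

    def test_bounded_in_unit_interval(self, harmonic_archive):
        for a, b in zip(harmonic_archive.steps[:-1], harmonic_archive.steps[1:]):
            rep = detailed_balance_overlap(a.g(), b.g())
            assert 0.0 <= rep.overlap <= 1.0
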