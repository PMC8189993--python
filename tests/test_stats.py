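"""Welch from summaries, circular two-sample tests, size-ratio null models."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import chelamorph as cm
from chelamorph.stats import _watson_u2


def _raw_with_moments(mean, sd, n, seed):
    """Raw data whose sample mean/sd equal the targets exactly."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestWelch:
    def test_identical_summaries_are_null(self):
        r = cm.welch_from_summary(10, 2, 20, 10, 2, 20)
        assert r.t == 0 and r.p == pytest.approx(1.0)

    def test_published_size_contrast(self):
        """The two bulb-mite cultures differ only in scale."""
        r = cm.welch_from_summary(304.24, 17.56, 20, 287.59, 30.97, 20)
        assert r.p == pytest.approx(0.045, abs=0.0005)

    def test_published_pest_velocity_ratio_contrast(self, species, metadata):
        pests = set(metadata[metadata.pest].species_code)
        vr = species.set_index("species_code").VR_mean
        a = vr[vr.index.isin(pests)]
        b = vr[~vr.index.isin(pests)]
        assert len(a) == 9 and len(b) == 38
        r = cm.welch_from_summary(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        assert r.p == pytest.approx(0.1024, abs=0.005)

    def test_summary_equals_raw_data_oracle(self):
        a = _raw_with_moments(12.0, 3.0, 15, 1)
        b = _raw_with_moments(10.5, 2.0, 12, 2)
        oracle = sps.ttest_ind(a, b, equal_var=False)
        r = cm.welch_from_summary(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        assert r.t == pytest.approx(oracle.statistic, rel=1e-9)
        assert r.p == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_sign_flips_under_group_swap(self):
        r1 = cm.welch_from_summary(12, 3, 15, 10, 2, 12)
        r2 = cm.welch_from_summary(10, 2, 12, 12, 3, 15)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cm.welch_from_summary(1, 0, 10, 2, 0, 10)
        with pytest.raises(ValueError):
            cm.welch_from_summary(1, 1, 1, 2, 1, 10)


class TestWatson:
    def test_identical_multisets_are_null(self):
        a = [10.0, 80.0, 200.0, 355.0, 30.0]
        r = cm.watson_two_sample(a, list(a), mode="randomization",
                                 n_permutations=199, seed=0)
        assert r.p_randomization > 0.5

    def test_antipodal_clusters_are_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 5, 10) % 360
        b = rng.normal(180, 5, 10) % 360
        r = cm.watson_two_sample(a, b, mode="randomization",
                                 n_permutations=999, seed=0)
        assert r.p_randomization <= 0.01

    def test_symmetry_in_the_two_samples(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 360, 8)
        b = rng.uniform(0, 360, 9)
        ra = cm.watson_two_sample(a, b).p_asymptotic
        rb = cm.watson_two_sample(b, a).p_asymptotic
        assert ra == pytest.approx(rb, rel=1e-9)

    def test_randomization_matches_exhaustive_permutation(self):
        """Independent oracle: enumerate all label assignments on a tiny
        instance and compare the exact permutation p-value."""
        a = np.radians([10.0, 40.0, 95.0, 330.0])
        b = np.radians([150.0, 180.0, 200.0, 260.0])
        pooled = np.concatenate([a, b])
        obs = _watson_u2(a, b)
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            if _watson_u2(pooled[mask], pooled[~mask]) >= obs - 1e-12:
                count += 1
            total += 1
        exact = count / total
        r = cm.watson_two_sample(np.degrees(a), np.degrees(b),
                                 mode="randomization", n_permutations=1999,
                                 seed=3)
        assert abs(r.p_randomization - exact) < 0.05

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            cm.watson_two_sample([1.0, 2.0], [3.0, 4.0, 5.0, 6.0])


class TestMardiaWatsonWheeler:
    def test_identical_samples_are_null(self):
        a = [10.0, 100.0, 190.0, 280.0]
        r = cm.mardia_watson_wheeler(a, list(a), mode="both",
                                     n_permutations=199, seed=0)
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_asymptotic == pytest.approx(1.0, abs=1e-6)

    def test_antipodal_clusters_have_small_asymptotic_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 4, 12) % 360
        b = rng.normal(180, 4, 12) % 360
        r = cm.mardia_watson_wheeler(a, b)
        assert r.p_asymptotic < 0.01

    def test_asymptotic_and_randomization_agree_at_moderate_n(self):
        rng = np.random.default_rng(5)
        a = np.degrees(rng.vonmises(0.0, 1.0, 25)) % 360
        b = np.degrees(rng.vonmises(0.6, 1.0, 25)) % 360
        r = cm.mardia_watson_wheeler(a, b, mode="both", n_permutations=999,
                                     seed=6)
        assert abs(r.p_asymptotic - r.p_randomization) < 0.05


class TestSizeRatio:
    def test_constant_ratio_community_has_zero_variance_ratio(self):
        r = cm.size_ratio_null_test([100.0, 130.0, 169.0], iterations=50,
                                    seed=0)
        assert r.variance_ratio == pytest.approx(0.0, abs=1e-12)
        assert r.minimum_ratio == pytest.approx(1.3)

    def test_ties_give_unit_minimum_ratio_and_zero_difference(self):
        r = cm.size_ratio_null_test([100.0, 100.0, 120.0], iterations=50,
                                    seed=0)
        assert r.minimum_ratio == 1.0
        assert r.minimum_difference == 0.0

    def test_bulb_mite_community_adjacent_ratios(self, species):
        """The sizes of the third biome's three taxa give the frozen
        adjacent ratios (direct arithmetic on the packaged means)."""
        sizes = sorted(species.set_index("species_code")
                       .loc[["T6", "R2", "R1"], "IL_mean"])
        ratios = [sizes[1] / sizes[0], sizes[2] / sizes[1]]
        assert ratios[0] == pytest.approx(1.3580, abs=1e-4)
        assert ratios[1] == pytest.approx(1.0579, abs=1e-4)
        r = cm.size_ratio_null_test(sizes, iterations=200, seed=0)
        assert set(r.p_values) == {"variance_ratio", "variance_difference",
                                   "minimum_ratio", "minimum_difference"}

    def test_scale_invariance_of_ratio_metrics(self):
        sizes = [100.0, 123.0, 177.0, 240.0]
        r1 = cm.size_ratio_null_test(sizes, iterations=10, seed=0)
        r2 = cm.size_ratio_null_test([3.7 * s for s in sizes], iterations=10,
                                     seed=0)
        assert r2.variance_ratio == pytest.approx(r1.variance_ratio, rel=1e-9)
        assert r2.minimum_ratio == pytest.approx(r1.minimum_ratio, rel=1e-9)
        assert r2.minimum_difference == pytest.approx(
            3.7 * r1.minimum_difference, rel=1e-9)
        assert r2.variance_difference == pytest.approx(
            3.7 ** 2 * r1.variance_difference, rel=1e-9)

    def test_p_values_calibrated_under_the_null(self):
        """Sizes drawn from the null give approximately Uniform(0,1)
        p-values (lower-tail, endpoints fixed)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(120):
            sizes = np.concatenate([[100.0, 300.0],
                                    rng.uniform(100.0, 300.0, 4)])
            r = cm.size_ratio_null_test(sizes, iterations=99,
                                        seed=int(rng.integers(2**31)))
            ps.append(r.p_values["variance_ratio"])
        assert 0.35 < np.mean(ps) < 0.65
        assert sps.kstest(ps, "uniform").pvalue > 0.005

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            cm.size_ratio_null_test([100.0, 120.0])
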