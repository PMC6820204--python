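import itertools

import numpy as np
import pytest
import scipy.stats

from hgalpha.stats import exact_signed_rank, fdr_correct, \
    interaction_contrast, distance_decay_fit, r_equivalent, \
    signed_rank_null_counts, trial_label_permutation


def brute_force_p(diffs: np.ndarray) -> float:
    """Independent oracle: enumerate every sign assignment explicitly."""
    d = diffs[diffs != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = d.size
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        if w_plus <= w_obs + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / 2 ** n)


class TestExactSignedRank:
    def test_full_null_cdf_matches_enumeration_at_n8(self):
        # every possible sign pattern of magnitudes 1..8
        mags = np.arange(1.0, 9.0)
        for signs in itertools.product([1, -1], repeat=8):
            d = mags * np.array(signs)
            res = exact_signed_rank(d)
            assert res.p_value == pytest.approx(brute_force_p(d), abs=1e-12)

    def test_tied_magnitudes_use_average_ranks(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, 3.0, -0.5])
        res = exact_signed_rank(d)
        assert res.p_value == pytest.approx(brute_force_p(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_scipy_exact_method(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(9)
        ours = exact_signed_rank(d)
        ref = scipy.stats.wilcoxon(d, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero difference"):
            res = exact_signed_rank(np.array([0.0, 1.0, 2.0, -3.0, 4.0]))
        assert res.n == 4

    def test_minimum_p_at_n2(self):
        res = exact_signed_rank(np.array([1.0, 2.0]))
        assert res.p_value >= 0.5

    def test_statistic_bounds(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(8)
        res = exact_signed_rank(d)
        assert 0 <= res.statistic <= 8 * 9 / 2
        assert 0 < res.p_value <= 1

    def test_null_counts_sum_to_two_power_n(self):
        counts, denom = signed_rank_null_counts(np.arange(1.0, 9.0))
        assert denom == 256 and sum(counts) == 256


class TestREquivalent:
    def test_p_of_one_gives_zero_effect(self):
        assert r_equivalent(1.0, 8) == 0.0

    def test_monotone_in_p(self):
        rs = [r_equivalent(p, 8) for p in (0.5, 0.1, 0.01, 0.001)]
        assert all(a < b for a, b in zip(rs, rs[1:]))

    def test_printed_effect_size_for_w0_at_n8(self):
        assert r_equivalent(0.0078125, 8) == pytest.approx(0.812, abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_equivalent(0.0, 8)
        with pytest.raises(ValueError):
            r_equivalent(0.5, 2)


class TestFdr:
    def test_benjamini_hochberg_step_up(self):
        # p_(4) = 0.05 <= 4q/4, so step-up rejects everything below it too
        mask = fdr_correct(np.array([0.004, 0.02, 0.03, 0.05]), q=0.05)
        assert list(mask) == [True, True, True, True]
        # raising the largest p above its threshold stops the cascade there
        mask = fdr_correct(np.array([0.004, 0.02, 0.03, 0.06]), q=0.05)
        assert list(mask) == [True, True, True, False]

    def test_uniformly_small_p_all_pass(self):
        assert fdr_correct(np.full(10, 0.01), q=0.05).all()

    def test_single_p_reduces_to_plain_threshold(self):
        assert fdr_correct(np.array([0.04]), q=0.05)[0]
        assert not fdr_correct(np.array([0.06]), q=0.05)[0]

    def test_empty_input(self):
        assert fdr_correct(np.array([])).size == 0

    def test_false_discovery_proportion_controlled_under_null(self):
        rng = np.random.default_rng(0)
        fdp = [fdr_correct(rng.uniform(size=100), q=0.05).mean()
               for _ in range(200)]
        assert np.mean(fdp) <= 0.05 + 0.01


class TestPermutation:
    def test_separated_groups_reach_minimum_p(self):
        a = np.arange(10.0)
        b = np.arange(10.0) + 100.0
        assert trial_label_permutation(a, b, n_perm=1000, seed=1) == \
            pytest.approx(1 / 1001)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        p1 = trial_label_permutation(a, b, n_perm=300, seed=5)
        p2 = trial_label_permutation(a, b, n_perm=300, seed=5)
        assert p1 == p2

    def test_constant_data_degenerates_to_one(self):
        with pytest.warns(UserWarning, match="constant"):
            assert trial_label_permutation(np.ones(6), np.ones(6)) == 1.0

    def test_type_one_error_controlled_on_exchangeable_data(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 300
        for s in range(n_sim):
            a = rng.standard_normal(10)
            b = rng.standard_normal(10)
            p = trial_label_permutation(a, b, n_perm=199, seed=s)
            rejections += p <= 0.05
        assert rejections / n_sim <= 0.085

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            trial_label_permutation(np.ones(3), np.ones(8))


class TestDistanceDecay:
    def test_noiseless_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 40, 30)
        hemi = np.repeat([0, 1, 2], 10)
        alpha = -8.0 + 0.21 * d
        fits, _ = distance_decay_fit(d, hemi, alpha)
        for f in fits:
            assert f["slope"] == pytest.approx(0.21, abs=1e-9)

    def test_constant_alpha_gives_null_group_test(self):
        d = np.tile(np.arange(5.0), 4)
        hemi = np.repeat(np.arange(4), 5)
        with pytest.warns(UserWarning):
            _, group = distance_decay_fit(d, hemi, np.full(20, -3.0))
        assert group.p_value == 1.0

    def test_consistent_positive_slopes_reach_exact_minimum_p(self):
        rng = np.random.default_rng(1)
        rows_d, rows_h, rows_a = [], [], []
        for h in range(8):
            d = rng.uniform(0, 40, 12)
            rows_d.append(d)
            rows_h.append(np.full(12, h))
            rows_a.append(-10 + 0.2 * d + 0.3 * rng.standard_normal(12))
        fits, group = distance_decay_fit(np.concatenate(rows_d),
                                         np.concatenate(rows_h),
                                         np.concatenate(rows_a))
        assert len(fits) == 8
        assert group.statistic == 0.0
        assert group.p_value == pytest.approx(2 / 256)

    def test_small_hemispheres_excluded_with_warning(self):
        d = np.array([1.0, 2.0, 0.5, 1.5, 2.5])
        hemi = np.array([0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="excluded"):
            fits, _ = distance_decay_fit(d, hemi, d * 0.1)
        assert [f["hemisphere"] for f in fits] == [1]


class TestInteractionContrast:
    def test_identical_conditions_are_degenerate(self):
        cm = np.tile(np.array([[1.0, 1.0], [2.0, 2.0]]), (8, 1, 1))
        with pytest.warns(UserWarning):
            res = interaction_contrast(cm)
        assert res.p_value == 1.0

    def test_w7_configuration_matches_enumeration(self):
        # contrasts with |d| ranks {3, 4} opposing the majority: W = 7
        contrasts = np.array([-1, -2, 3, 4, -5, -6, -7, -8], float)
        cm = np.zeros((8, 2, 2))
        cm[:, 1, 0] = contrasts  # alHG clear - vocoded carries the contrast
        res = interaction_contrast(cm)
        assert res.statistic == 7.0
        assert res.p_value == pytest.approx(38 / 256)

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            interaction_contrast(np.zeros((8, 3, 2)))
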