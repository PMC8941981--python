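"""Median-difference max/min-statistic permutation test."""

import itertools

import numpy as np
import pytest

from betarec.permtest import median_diff_map, permutation_test


def exhaustive_oracle(pre, post, alpha, scheme):
    """Independent enumeration of the reference distribution."""
    n_pre, n_post = pre.shape[0], post.shape[0]
    pooled = np.concatenate([pre, post], axis=0)
    maxima, minima = [], []
    if scheme == "pooled":
        for comb in itertools.combinations(range(n_pre + n_post), n_pre):
            rest = [i for i in range(n_pre + n_post) if i not in comb]
            d = np.median(pooled[rest], axis=0) - np.median(pooled[list(comb)], axis=0)
            maxima.append(d.max())
            minima.append(d.min())
    else:
        for swap in itertools.product([False, True], repeat=n_pre):
            g_pre = np.array(
                [post[i] if s else pre[i] for i, s in enumerate(swap)]
            )
            g_post = np.array(
                [pre[i] if s else post[i] for i, s in enumerate(swap)]
            )
            d = np.median(g_post, axis=0) - np.median(g_pre, axis=0)
            maxima.append(d.max())
            minima.append(d.min())
    upper = np.percentile(maxima, 100 * (1 - alpha / 2))
    lower = np.percentile(minima, 100 * (alpha / 2))
    return upper, lower


class TestMedianDiffMap:
    def test_identical_stacks_zero(self, rng):
        stack = rng.normal(size=(5, 3, 4))
        assert np.allclose(median_diff_map(stack, stack), 0)

    def test_constant_offset(self):
        pre = np.full((4, 2, 3), 1.0)
        post = np.full((4, 2, 3), 3.0)
        assert np.allclose(median_diff_map(pre, post), 2.0)

    def test_three_trial_toy_against_sort_oracle(self, rng):
        pre = rng.normal(size=(3, 2, 2))
        post = rng.normal(size=(3, 2, 2))
        got = median_diff_map(pre, post)
        for i in range(2):
            for j in range(2):
                med_post = sorted(post[:, i, j])[1]
                med_pre = sorted(pre[:, i, j])[1]
                assert got[i, j] == pytest.approx(med_post - med_pre)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            median_diff_map(rng.normal(size=(3, 2, 2)), rng.normal(size=(3, 2, 3)))


class TestPermutationTest:
    @pytest.mark.parametrize("scheme", ["pooled", "paired"])
    def test_exhaustive_matches_independent_enumeration(self, rng, scheme):
        pre = rng.normal(size=(4, 2, 3))
        post = rng.normal(size=(4, 2, 3)) + 0.5
        out = permutation_test(
            pre, post, alpha=0.2, scheme=scheme, exhaustive=True, rng=0
        )
        upper, lower = exhaustive_oracle(pre, post, 0.2, scheme)
        assert out.upper_threshold == pytest.approx(upper)
        assert out.lower_threshold == pytest.approx(lower)
        assert out.n_perm == (70 if scheme == "pooled" else 16)

    def test_observed_map_untouched_by_machinery(self, rng):
        pre = rng.normal(size=(6, 3, 4))
        post = rng.normal(size=(6, 3, 4))
        out = permutation_test(pre, post, n_perm=200, rng=1)
        assert np.array_equal(out.observed, median_diff_map(pre, post))

    def test_mask_consistent_with_thresholds(self, rng):
        pre = rng.normal(size=(8, 4, 5))
        post = rng.normal(size=(8, 4, 5)) + 1.0
        out = permutation_test(pre, post, n_perm=300, rng=2)
        expected = (out.observed > out.upper_threshold) | (
            out.observed < out.lower_threshold
        )
        assert np.array_equal(out.sig_mask, expected)

    def test_thresholds_monotone_in_alpha(self, rng):
        pre = rng.normal(size=(10, 3, 3))
        post = rng.normal(size=(10, 3, 3))
        gen = np.random.default_rng(3)
        tight = permutation_test(pre, post, n_perm=500, alpha=0.01, rng=gen)
        gen = np.random.default_rng(3)
        loose = permutation_test(pre, post, n_perm=500, alpha=0.20, rng=gen)
        assert tight.upper_threshold >= loose.upper_threshold
        assert tight.lower_threshold <= loose.lower_threshold

    def test_seed_determinism(self, rng):
        pre = rng.normal(size=(6, 2, 2))
        post = rng.normal(size=(6, 2, 2))
        a = permutation_test(pre, post, n_perm=200, rng=7)
        b = permutation_test(pre, post, n_perm=200, rng=7)
        assert a.upper_threshold == b.upper_threshold
        assert np.array_equal(a.sig_mask, b.sig_mask)

    def test_strong_effect_detected_within_support(self, rng):
        pre = rng.normal(size=(15, 4, 6))
        post = rng.normal(size=(15, 4, 6))
        post[:, 1, 2:4] += 5.0  # localized injected effect
        out = permutation_test(pre, post, n_perm=500, rng=4)
        assert out.sig_mask[1, 2:4].all()
        assert not out.sig_mask[0].any() and not out.sig_mask[2:].any()

    def test_matrixwise_variant_shapes(self, rng):
        pre = rng.normal(size=(5, 3, 4))
        post = rng.normal(size=(5, 3, 4))
        out = permutation_test(pre, post, n_perm=150, matrixwise=True, rng=5)
        assert out.upper_threshold.shape == (3, 4)
        assert out.lower_threshold.shape == (3, 4)
        assert np.all(out.lower_threshold <= out.upper_threshold)

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(
                rng.normal(size=(1, 2, 2)), rng.normal(size=(5, 2, 2)), rng=0
            )

    def test_paired_requires_equal_counts(self, rng):
        with pytest.raises(ValueError, match="paired"):
            permutation_test(
                rng.normal(size=(4, 2, 2)),
                rng.normal(size=(5, 2, 2)),
                scheme="paired",
                rng=0,
            )
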