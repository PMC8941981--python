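"""Median-difference max/min-statistic permutation test on spectrograms.

Tests whether post-sample spectral power differs from pre-sample power at
any frequency-time cell while controlling the family-wise error rate.  The
test statistic per cell is the median power over post segments minus the
median over pre segments.  The reference distribution is built by
relabelling segments: on each permutation the global maximum and minimum of
the permuted median-difference map are recorded, and the upper/lower
significance thresholds are the (1 - alpha/2) percentile of the maxima and
the (alpha/2) percentile of the minima.  Comparing every observed cell to
these two scalar thresholds bounds the probability of any false positive
at alpha under exchangeability (max-statistic control).

A ``matrixwise`` variant retains per-cell running maxima/minima instead of
global scalars, for comparison with a literal per-cell reading of the
procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["PermutationOutcome", "median_diff_map", "permutation_test"]


@dataclass
class PermutationOutcome:
    """Result of the permutation test on a frequency x time grid."""

    observed: np.ndarray  # median-difference map
    upper_threshold: float | np.ndarray
    lower_threshold: float | np.ndarray
    sig_mask: np.ndarray  # boolean
    n_perm: int
    alpha: float
    scheme: str
    seed: int | None = None

    @property
    def any_significant(self) -> bool:
        return bool(self.sig_mask.any())


def median_diff_map(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Per-cell median over post trials minus median over pre trials."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 3 or post.ndim != 3 or pre.shape[1:] != post.shape[1:]:
        raise ValueError(
            f"need (n_trials, n_freqs, n_times) stacks on a common grid, "
            f"got {pre.shape} and {post.shape}"
        )
    if pre.shape[0] < 1 or post.shape[0] < 1:
        raise ValueError("need at least one trial per condition")
    return np.median(post, axis=0) - np.median(pre, axis=0)


def permutation_test(
    pre: np.ndarray,
    post: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    scheme: str = "pooled",
    rng: np.random.Generator | int | None = None,
    matrixwise: bool = False,
    exhaustive: bool = False,
) -> PermutationOutcome:
    """Two-tailed max/min-statistic permutation test at level ``alpha``.

    ``scheme="pooled"`` shuffles all 2N segments into two pseudo-conditions
    of N; ``scheme="paired"`` independently swaps the pre/post segments
    within each trial (requires equal trial counts).  Thresholds use linear
    interpolation on the sorted permutation extrema.

    With ``exhaustive=True`` every distinct relabelling is visited exactly
    once (feasible only for small trial counts); ``n_perm`` and ``rng`` are
    then ignored and the reference distribution is the complete one.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 3 or post.ndim != 3 or pre.shape[1:] != post.shape[1:]:
        raise ValueError(f"incompatible stacks {pre.shape} and {post.shape}")
    n_pre, n_post = pre.shape[0], post.shape[0]
    if n_pre < 2 or n_post < 2:
        raise ValueError(f"need >= 2 trials per condition, got {n_pre}/{n_post}")
    if n_perm < 100 and not exhaustive:
        raise ValueError("n_perm must be >= 100")
    if scheme not in ("pooled", "paired"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "paired" and n_pre != n_post:
        raise ValueError("paired scheme requires equal pre/post trial counts")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    observed = median_diff_map(pre, post)
    grid_shape = observed.shape
    pooled = np.concatenate([pre, post], axis=0).reshape(n_pre + n_post, -1)

    n_tot = n_pre + n_post

    if exhaustive:
        if scheme == "pooled":
            all_idx = np.arange(n_tot)
            splits = [
                (np.array(s), np.setdiff1d(all_idx, s))
                for s in itertools.combinations(range(n_tot), n_pre)
            ]
        else:
            splits = [
                np.array(s, dtype=bool)
                for s in itertools.product((False, True), repeat=n_pre)
            ]
        n_perm = len(splits)

    if matrixwise:
        maxima = np.full((n_perm,) + grid_shape, np.nan)
        minima = np.full((n_perm,) + grid_shape, np.nan)
    else:
        maxima = np.empty(n_perm)
        minima = np.empty(n_perm)

    for p in range(n_perm):
        if scheme == "pooled":
            if exhaustive:
                pre_idx, post_idx = splits[p]
            else:
                idx = rng.permutation(n_tot)
                pre_idx, post_idx = idx[:n_pre], idx[n_pre:]
            g_pre, g_post = pooled[pre_idx], pooled[post_idx]
        else:
            swap = splits[p] if exhaustive else rng.random(n_pre) < 0.5
            g_pre = np.where(swap[:, None], pooled[n_pre:], pooled[:n_pre])
            g_post = np.where(swap[:, None], pooled[:n_pre], pooled[n_pre:])
        diff = np.median(g_post, axis=0) - np.median(g_pre, axis=0)
        if matrixwise:
            maxima[p] = diff.reshape(grid_shape)
            minima[p] = diff.reshape(grid_shape)
        else:
            maxima[p] = diff.max()
            minima[p] = diff.min()

    upper = np.percentile(maxima, 100.0 * (1 - alpha / 2), axis=0)
    lower = np.percentile(minima, 100.0 * (alpha / 2), axis=0)
    sig_mask = (observed > upper) | (observed < lower)
    return PermutationOutcome(
        observed=observed,
        upper_threshold=upper if matrixwise else float(upper),
        lower_threshold=lower if matrixwise else float(lower),
        sig_mask=sig_mask,
        n_perm=n_perm,
        alpha=alpha,
        scheme=scheme,
        seed=seed,
    )
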