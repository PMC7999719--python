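"""Resampling machinery shared by every analysis stage.

Three primitives: a simple percentile bootstrap of a two-group mean
difference with Bonferroni adjustment, a moving block bootstrap for
temporally correlated binned series (overlapping blocks, uniform start
positions, overhang truncated), and Benjamini-Hochberg FDR adjustment.
All bootstraps are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .events import BinnedActivity


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap mean-difference result.

    ``significant`` is True when the Bonferroni-adjusted (1 - alpha)
    percentile interval excludes 0.  ``degenerate`` flags a group of
    size one (the CI carries no resampling information).
    """

    estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    alpha: float
    alpha_adjusted: float
    significant: bool
    degenerate: bool = False

    def flipped(self) -> "BootstrapResult":
        """The same result for the negated statistic (B-A -> A-B)."""
        return BootstrapResult(
            estimate=-self.estimate,
            ci_low=-self.ci_high,
            ci_high=-self.ci_low,
            n_replicates=self.n_replicates,
            alpha=self.alpha,
            alpha_adjusted=self.alpha_adjusted,
            significant=self.significant,
            degenerate=self.degenerate,
        )


def _percentile_result(
    diffs: np.ndarray,
    estimate: float,
    alpha: float,
    n_comparisons: int,
    degenerate: bool,
) -> BootstrapResult:
    alpha_adj = alpha / n_comparisons
    lo, hi = np.quantile(diffs, [alpha_adj / 2.0, 1.0 - alpha_adj / 2.0])
    return BootstrapResult(
        estimate=float(estimate),
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=int(diffs.size),
        alpha=float(alpha),
        alpha_adjusted=float(alpha_adj),
        significant=bool(lo > 0 or hi < 0),
        degenerate=degenerate,
    )


def bootstrap_mean_diff(
    group_a,
    group_b,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    seed=0,
) -> BootstrapResult:
    """Percentile bootstrap of ``mean(A) - mean(B)``.

    Each replicate resamples both groups independently with replacement
    at their original sizes.  The CI is the percentile interval at the
    Bonferroni-adjusted level ``alpha / n_comparisons``.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_replicates < 1000:
        raise ValueError("n_replicates must be >= 1000")
    rng = np.random.default_rng(seed)
    means_a = a[rng.integers(0, a.size, size=(n_replicates, a.size))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, size=(n_replicates, b.size))].mean(axis=1)
    return _percentile_result(
        means_a - means_b,
        estimate=float(a.mean() - b.mean()),
        alpha=alpha,
        n_comparisons=n_comparisons,
        degenerate=(a.size == 1 or b.size == 1),
    )


def block_bootstrap_means(x: np.ndarray, block_bins: int, n_replicates: int, rng) -> np.ndarray:
    """Replicate means of a moving-block-bootstrap rebuild of ``x``.

    Each replicate concatenates ``ceil(n / L)`` uniformly drawn,
    overlapping, contiguous blocks of ``L`` bins and truncates the
    overhang to the original length ``n``; its mean is returned.  The
    mean of the truncated concatenation equals the (k-1) full block
    sums plus the partial sum of the final block divided by ``n``,
    which is computed here exactly from prefix sums.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    L = int(block_bins)
    if L < 1:
        raise ValueError("block length must be at least one bin")
    if L > n:
        raise ValueError("block longer than series")
    k = math.ceil(n / L)
    r = n - (k - 1) * L  # length of the truncated final block, in 1..L
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n_starts = n - L + 1
    full_sums = csum[L:] - csum[:-L]  # block sums for starts 0..n-L
    part_sums = csum[r : r + n_starts] - csum[:n_starts]
    starts = rng.integers(0, n_starts, size=(n_replicates, k))
    if k > 1:
        totals = full_sums[starts[:, :-1]].sum(axis=1) + part_sums[starts[:, -1]]
    else:
        totals = part_sums[starts[:, 0]]
    return totals / n


def moving_block_bootstrap_diff(
    series_a,
    series_b,
    block_length: float,
    n_replicates: int = 10000,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    seed=0,
) -> BootstrapResult:
    """Moving block bootstrap of the difference of two series' means.

    ``block_length`` is in seconds when the inputs are
    :class:`~abnremap.events.BinnedActivity` (converted to whole bins),
    or directly in bins for plain arrays.  The two series are resampled
    independently from separate RNG streams derived from ``seed``.
    """
    if isinstance(series_a, BinnedActivity) and isinstance(series_b, BinnedActivity):
        if series_a.bin_width != series_b.bin_width:
            raise ValueError("series must share a bin width")
        L = max(1, int(round(block_length / series_a.bin_width)))
        a, b = series_a.values, series_b.values
    else:
        a = np.asarray(series_a, dtype=float).ravel()
        b = np.asarray(series_b, dtype=float).ravel()
        L = max(1, int(round(block_length)))
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    means_a = block_bootstrap_means(a, L, n_replicates, rng_a)
    means_b = block_bootstrap_means(b, L, n_replicates, rng_b)
    return _percentile_result(
        means_a - means_b,
        estimate=float(np.mean(a) - np.mean(b)),
        alpha=alpha,
        n_comparisons=n_comparisons,
        degenerate=False,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
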