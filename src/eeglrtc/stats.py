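"""Uncertainty and paired-comparison statistics for scaling exponents.

A moving-block bootstrap resamples contiguous blocks of the windowed
embedding rows (preserving short-range temporal dependence) to attach 95%
confidence intervals to DFA exponents, and paired comparisons between two
per-subject alpha vectors report the paired t-test, Bonferroni-corrected p,
Wilcoxon signed-rank p, and paired Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import dfa as _dfa
from .embedding import Embedding

__all__ = [
    "BootstrapResult",
    "ComparisonReport",
    "block_length",
    "moving_block_bootstrap_alpha",
    "paired_comparison",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Moving-block bootstrap summary of a DFA exponent."""

    alpha_mean: float
    ci_low: float
    ci_high: float
    n_resamples: int
    block_length: int
    seed: int
    approach: str
    alphas: np.ndarray


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two alpha vectors."""

    t_stat: float
    p_value: float
    p_bonferroni: float
    wilcoxon_p: float
    cohens_d: float
    n_pairs: int
    correction_factor: int
    degenerate: bool = False


def block_length(n: int) -> int:
    """Bootstrap block length: max(2, round(sqrt(n)))."""
    if n < 2:
        raise ValueError("need at least two windows")
    return max(2, int(np.round(np.sqrt(n))))


def _resample_rows(data: np.ndarray, L: int, rng: np.random.Generator) -> np.ndarray:
    """Concatenate uniformly drawn contiguous blocks of length L, truncate to n."""
    n = data.shape[0]
    n_blocks = int(np.ceil(n / L))
    starts = rng.integers(0, n - L + 1, size=n_blocks)
    rows = np.concatenate([np.arange(s, s + L) for s in starts])[:n]
    return data[rows]


def moving_block_bootstrap_alpha(
    data: Embedding | np.ndarray,
    approach: str = "mean",
    n_resamples: int = 1000,
    seed: int = 0,
    order: int = 1,
    max_retries: int = 10,
) -> BootstrapResult:
    """Moving-block bootstrap CI for the DFA exponent of an embedding.

    Rows of the embedding (or a 1-D series) are resampled in contiguous
    blocks of length max(2, round(sqrt(n))) drawn with replacement from all
    start positions; the chosen DFA approach is recomputed on each resample.
    The interval is the 2.5/97.5 percentile of the resampled exponents. A
    resample on which DFA fails (e.g. an exactly-zero fluctuation) is
    redrawn, up to `max_retries` times each.
    """
    if approach not in ("norm", "mean"):
        raise ValueError("approach must be 'norm' or 'mean'")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    arr = data.coords if isinstance(data, Embedding) else np.asarray(data, dtype=float)
    series_2d = arr[:, None] if arr.ndim == 1 else arr
    n = series_2d.shape[0]
    if n < 16:
        raise ValueError("underlying series must have length >= 16")
    L = block_length(n)
    rng = np.random.default_rng(seed)
    run = _dfa.norm_based_dfa if approach == "norm" else _dfa.mean_based_dfa
    alphas = np.empty(n_resamples)
    for b in range(n_resamples):
        for attempt in range(max_retries + 1):
            sample = _resample_rows(series_2d, L, rng)
            try:
                alphas[b] = run(sample, order=order).alpha
                break
            except ValueError:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"resample {b} failed DFA {max_retries + 1} times"
                    )
    lo, hi = np.percentile(alphas, [2.5, 97.5])
    return BootstrapResult(
        alpha_mean=float(alphas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        block_length=L,
        seed=seed,
        approach=approach,
        alphas=alphas,
    )


def paired_comparison(
    a: np.ndarray,
    b: np.ndarray,
    correction_factor: int = 4,
    zero_method: str = "wilcox",
) -> ComparisonReport:
    """Paired t-test, Bonferroni correction, Wilcoxon, and paired Cohen's d.

    Cohen's d for paired data is mean(a - b) / sd(a - b) with the n-1
    denominator. The Bonferroni-corrected p is min(1, factor * p). Zero
    differences are handled by the classical Wilcoxon convention (discarded)
    unless `zero_method` selects another scipy policy. If every difference
    is zero the statistics are degenerate and reported as t=0, p=1, d=0 with
    the `degenerate` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D sequences of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.all(diff == 0):
        return ComparisonReport(
            t_stat=0.0,
            p_value=1.0,
            p_bonferroni=1.0,
            wilcoxon_p=1.0,
            cohens_d=0.0,
            n_pairs=n,
            correction_factor=correction_factor,
            degenerate=True,
        )
    t_stat, p_value = sps.ttest_rel(a, b)
    cohens_d = diff.mean() / diff.std(ddof=1)
    wilcoxon_p = float(sps.wilcoxon(a, b, zero_method=zero_method).pvalue)
    return ComparisonReport(
        t_stat=float(t_stat),
        p_value=float(p_value),
        p_bonferroni=float(min(1.0, correction_factor * p_value)),
        wilcoxon_p=wilcoxon_p,
        cohens_d=float(cohens_d),
        n_pairs=n,
        correction_factor=correction_factor,
    )
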