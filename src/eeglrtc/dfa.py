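"""Detrended fluctuation analysis on low-dimensional embeddings.

DFA estimates a scaling exponent alpha from the slope of log RMS fluctuation
versus log scale of the mean-removed cumulative sum of a series, detrended
segment by segment with a least-squares polynomial (order 1 by default,
DFA-1). alpha = 0.5 marks uncorrelated noise; 0.5 < alpha < 1 marks
persistent long-range temporal correlations; alpha > 1 leaves the power-law
regime.

Two ways of applying DFA to an n x d embedding are provided: the norm-based
approach collapses the embedding to the per-row Euclidean norm and runs DFA
once, while the mean-based approach runs DFA on each embedding dimension
separately and averages the per-dimension exponents (and fit R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import Embedding

__all__ = [
    "DFAResult",
    "norm_collapse",
    "dfa_profile",
    "fluctuation_at_scale",
    "fit_power_law",
    "dfa_alpha",
    "mean_based_dfa",
    "norm_based_dfa",
]

# design matrices are reused heavily across scales and bootstrap resamples
_DESIGN_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _design(p: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    key = (p, order)
    if key not in _DESIGN_CACHE:
        t = np.arange(p, dtype=float)
        X = np.vander(t, order + 1)
        _DESIGN_CACHE[key] = (X, np.linalg.pinv(X))
        if len(_DESIGN_CACHE) > 8192:
            _DESIGN_CACHE.clear()
    return _DESIGN_CACHE[key]


@dataclass(frozen=True)
class DFAResult:
    """Scaling exponent with its supporting fit.

    scales and fluctuations hold the F(p) curve; alpha and r_squared come
    from the OLS fit of log10 F on log10 p. `approach` is "norm" or "mean";
    per_dimension_alphas is filled only by the mean-based approach.
    `short_series` flags fits on fewer than four scales.
    """

    alpha: float
    r_squared: float
    scales: np.ndarray
    fluctuations: np.ndarray
    approach: str
    detrend_order: int
    per_dimension_alphas: np.ndarray | None = None
    per_dimension_r_squared: np.ndarray | None = None
    short_series: bool = False


def _coords(Y: Embedding | np.ndarray) -> np.ndarray:
    arr = Y.coords if isinstance(Y, Embedding) else np.asarray(Y, dtype=float)
    return np.atleast_2d(arr.T).T if arr.ndim == 1 else arr


def norm_collapse(Y: Embedding | np.ndarray) -> np.ndarray:
    """Collapse an n x d embedding to the per-row Euclidean norm."""
    return np.linalg.norm(_coords(Y), axis=1)


def dfa_profile(y: np.ndarray) -> np.ndarray:
    """Mean-removed cumulative sum Z(k) = sum_{i<=k} (y_i - mean(y))."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("profile needs a 1-D series of length >= 2")
    return np.cumsum(y - y.mean())


def fluctuation_at_scale(Z: np.ndarray, p: int, order: int = 1) -> float:
    """RMS fluctuation of the profile at scale p.

    The profile is split into floor(n/p) non-overlapping segments from the
    start (the trailing remainder is excluded at this scale); a degree-`order`
    polynomial is fit per segment by least squares and the RMS of the
    residuals over the covered samples is returned.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.size
    if not 4 <= p <= n // 4:
        raise ValueError(f"scale p={p} outside [4, n/4] for n={n}")
    m = n // p
    segments = Z[: m * p].reshape(m, p)
    X, pinv = _design(p, order)
    beta = segments @ pinv.T
    resid = segments - beta @ X.T
    return float(np.sqrt(np.mean(resid**2)))


def fit_power_law(scales: np.ndarray, fluctuations: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of the OLS line of log10 F on log10 p."""
    logp = np.log10(np.asarray(scales, dtype=float))
    logf = np.log10(np.asarray(fluctuations, dtype=float))
    slope, intercept = np.polyfit(logp, logf, 1)
    fitted = slope * logp + intercept
    ss_res = np.sum((logf - fitted) ** 2)
    ss_tot = np.sum((logf - logf.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def dfa_alpha(y: np.ndarray, order: int = 1, approach: str = "norm") -> DFAResult:
    """DFA of a 1-D series over all integer scales in [4, floor(n/4)].

    The full integer scale grid is used (at n ~ 90 only 19 scales exist, so
    no log-spacing is applied). Requires at least two scales (n >= 20) for
    the log-log fit; fits on fewer than four scales are flagged via
    `short_series`.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 16:
        raise ValueError(f"series of length {n} too short for DFA (need >= 16)")
    p_max = n // 4
    scales = np.arange(4, p_max + 1)
    if scales.size < 2:
        raise ValueError(
            f"series of length {n} yields {scales.size} scale(s) in [4, {p_max}]; "
            "at least two are needed to fit a slope"
        )
    Z = dfa_profile(y)
    F = np.empty(scales.size)
    for i, p in enumerate(scales):
        F[i] = fluctuation_at_scale(Z, int(p), order)
        if F[i] == 0.0:
            raise ValueError(f"zero fluctuation at scale p={p}; log F undefined")
    alpha, r2 = fit_power_law(scales, F)
    return DFAResult(
        alpha=alpha,
        r_squared=r2,
        scales=scales,
        fluctuations=F,
        approach=approach,
        detrend_order=order,
        short_series=scales.size < 4,
    )


def norm_based_dfa(Y: Embedding | np.ndarray, order: int = 1) -> DFAResult:
    """DFA of the Euclidean-norm collapse of the embedding."""
    return dfa_alpha(norm_collapse(Y), order=order, approach="norm")


def mean_based_dfa(Y: Embedding | np.ndarray, order: int = 1) -> DFAResult:
    """Per-dimension DFA with averaged exponents.

    alpha and r_squared are the arithmetic means of the per-dimension values;
    the reported fluctuation curve is the across-dimension mean of the
    per-dimension F(p) (for plotting/reporting only — the exponent is the
    mean of slopes, not the slope of the mean).
    """
    C = _coords(Y)
    results = [dfa_alpha(C[:, j], order=order) for j in range(C.shape[1])]
    alphas = np.array([r.alpha for r in results])
    r2s = np.array([r.r_squared for r in results])
    F = np.mean([r.fluctuations for r in results], axis=0)
    return DFAResult(
        alpha=float(alphas.mean()),
        r_squared=float(r2s.mean()),
        scales=results[0].scales,
        fluctuations=F,
        approach="mean",
        detrend_order=order,
        per_dimension_alphas=alphas,
        per_dimension_r_squared=r2s,
        short_series=results[0].short_series,
    )
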