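"""Ensemble p-value statistics and FDR thresholding rules.

Two combination rules turn m per-method p-values at each (CpG, cell type)
into one ensemble p-value:

* ``avepv`` (probit averaging, an unweighted Stouffer combination on the
  p-value scale): Phi(mean_i Phi^{-1}(p_i)), with Phi the standard normal CDF.
* ``minpv`` (minimum p-value through its null distribution): the Beta(1, m)
  CDF of min_i p_i, i.e. 1 - (1 - min_i p_i)^m, the order-statistic
  correction for taking the best of m looks.

Under independent uniform nulls ``minpv`` is exactly uniform, while
``avepv`` is conservative: the mean of m probits is N(0, 1/m), so the
statistic concentrates toward 1/2 (an equal-weight probit average, not a
Stouffer combination, which would rescale by sqrt(m)).  Neither rule
corrects for inter-method correlation.  Benjamini-Hochberg adjustment handles
p-value-based thresholding; posterior-probability methods are thresholded by
the Bayesian FDR rule (reject the longest prefix of candidates, sorted by
1 - posterior, whose running mean stays at or below the target level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AggregatedResult",
    "avepv",
    "minpv",
    "aggregate",
    "bh_adjust",
    "bayesian_fdr_threshold",
]

# probit boundary guard: p in {0, 1} maps to +-inf otherwise
_P_FLOOR = 1e-15


def _subset_slab(cube, subset):
    """Extract the (p, K, m) slab for the chosen method subset."""
    idx = cube.subset_index(subset)
    return cube.p[:, :, idx], [cube.method_labels[i] for i in idx]


@dataclass
class AggregatedResult:
    """Ensemble p-values for one method subset."""

    avepv: np.ndarray
    minpv: np.ndarray
    m: int
    method_subset: list[str]


def avepv(cube, subset: list[str] | None = None) -> np.ndarray:
    """Probit-average ensemble p-value, per (CpG, cell type).

    Inputs are clipped into [1e-15, 1 - 1e-15] before the probit so boundary
    p-values stay finite; the statistic is strictly increasing in every
    input and idempotent on identical inputs.
    """
    slab, _ = _subset_slab(cube, subset)
    z = stats.norm.ppf(np.clip(slab, _P_FLOOR, 1.0 - _P_FLOOR))
    return stats.norm.cdf(z.mean(axis=2))


def minpv(cube, subset: list[str] | None = None) -> np.ndarray:
    """Beta(1, m) CDF of the per-(CpG, cell type) minimum p-value.

    Equals 1 - (1 - min_i p_i)^m; with m = 1 this is the identity, so a
    singleton subset returns the raw p-values.
    """
    slab, labels = _subset_slab(cube, subset)
    m = len(labels)
    return stats.beta.cdf(slab.min(axis=2), 1, m)


def aggregate(cube, subset: list[str] | None = None) -> AggregatedResult:
    """Compute both ensemble statistics for one method subset."""
    slab, labels = _subset_slab(cube, subset)
    return AggregatedResult(
        avepv=avepv(cube, subset),
        minpv=minpv(cube, subset),
        m=len(labels),
        method_subset=labels,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        return arr.copy()
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def bayesian_fdr_threshold(
    posteriors: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-probability rejection at a target Bayesian FDR.

    With q_j = 1 - posterior_j (the local posterior error probability),
    candidates are sorted by ascending q and the largest prefix whose running
    mean of q is at most ``alpha`` is rejected; the running mean estimates
    the FDR incurred by rejecting that prefix.  Ties (notably posterior = 1,
    q = 0) are broken stably in original order.

    Returns ``(reject, path)``: a boolean vector in the original order and
    the running-mean path over the sorted candidates.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    post = np.asarray(posteriors, dtype=float).ravel()
    if post.size == 0:
        raise ValueError("posteriors must be non-empty")
    if np.any(post < 0) or np.any(post > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    q = 1.0 - post
    order = np.argsort(q, kind="stable")
    path = np.cumsum(q[order]) / np.arange(1, q.size + 1)
    passing = np.flatnonzero(path <= alpha)
    reject = np.zeros(q.size, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject, path
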