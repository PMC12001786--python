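"""Synthetic pure-cell reference panels and array-style preprocessing.

A reference panel summarises purified-cell methylation pools as per-CpG,
per-cell-type beta-value means ``mu`` and variances ``var``, plus a per-CpG
pooled variance across a designated subset of cell types.  Simulated bulk
mixtures draw cell-type profiles from these summaries, so the panel is the
single source of the noise scale (and therefore of the planted effect size,
which is a signal-to-noise multiple of the pooled SD).

The preprocessing helpers mirror the standard methylation-array QC chain:
beta-value clipping away from {0, 1}, detection-p masking, sequential
sample/probe call-rate filtering, and a homogeneity-of-variance check used to
justify a common per-CpG variance across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ReferencePanel",
    "synthesize_reference",
    "clip_beta",
    "apply_call_rate_filters",
    "pooled_variance",
    "levene_common_variance_test",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ReferencePanel:
    """Per-CpG, per-cell-type beta-value means and variances.

    Attributes
    ----------
    cpg_ids : list of str, length p
    cell_types : list of str, length K
    mu : (p, K) array of beta-value means, strictly inside (0, 1)
    var : (p, K) array of per-cell-type variances, strictly positive
    pooled_var : (p,) array of pooled variances over ``pooling_cell_types``
    pooling_cell_types : cell types entering the pooled variance
    pure_samples : optional dict cell_type -> (p, n_k) matrix of the simulated
        pure replicates the summaries were computed from (kept only on request)
    """

    cpg_ids: list[str]
    cell_types: list[str]
    mu: np.ndarray
    var: np.ndarray
    pooled_var: np.ndarray
    pooling_cell_types: list[str] = field(default_factory=list)
    pure_samples: dict[str, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.pooled_var = np.asarray(self.pooled_var, dtype=float)
        p, k = len(self.cpg_ids), len(self.cell_types)
        if self.mu.shape != (p, k):
            raise ValueError(f"mu has shape {self.mu.shape}, expected {(p, k)}")
        if self.var.shape != (p, k):
            raise ValueError(f"var has shape {self.var.shape}, expected {(p, k)}")
        if self.pooled_var.shape != (p,):
            raise ValueError(
                f"pooled_var has shape {self.pooled_var.shape}, expected {(p,)}"
            )
        if np.any(self.mu <= 0.0) or np.any(self.mu >= 1.0):
            raise ValueError("all means must lie strictly inside (0, 1)")
        if np.any(self.var <= 0.0):
            raise ValueError("all variances must be strictly positive")
        if np.any(self.pooled_var <= 0.0):
            raise ValueError("all pooled variances must be strictly positive")
        if not self.pooling_cell_types:
            self.pooling_cell_types = list(self.cell_types)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    @property
    def pooled_sd(self) -> np.ndarray:
        return np.sqrt(self.pooled_var)


def synthesize_reference(
    p: int,
    cell_types: list[str],
    mean_hyper: tuple[float, float] = (0.1, 0.9),
    sd_hyper: tuple[float, float] = (0.01, 0.05),
    pure_samples_per_type: int = 20,
    seed: int | np.random.Generator = 0,
    pooling_cell_types: list[str] | None = None,
    keep_pure_samples: bool = False,
) -> ReferencePanel:
    """Synthesize a pure-cell reference panel.

    Per-CpG means mu_ck are drawn uniformly within ``mean_hyper``
    (independently per cell type); a per-CpG generating SD is drawn uniformly
    within ``sd_hyper`` and shared across cell types.  For each cell type,
    ``pure_samples_per_type`` pure replicates are simulated as Gaussian draws
    around mu_ck; the panel's ``var`` holds the empirical per-cell-type
    variances of those replicates and ``pooled_var`` the sample-size-weighted
    pooled variance over ``pooling_cell_types`` (default: all).

    Deterministic given ``seed``.
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("cell_types must be unique")
    m_lo, m_hi = mean_hyper
    s_lo, s_hi = sd_hyper
    if not (0.0 < m_lo <= m_hi < 1.0):
        raise ValueError("mean_hyper must be an interval inside (0, 1)")
    if not (0.0 < s_lo <= s_hi < 0.5):
        raise ValueError("sd_hyper must be an interval inside (0, 0.5)")
    if pure_samples_per_type < 2:
        raise ValueError("need at least 2 pure replicates per cell type")
    pooling = list(pooling_cell_types) if pooling_cell_types else list(cell_types)
    unknown = set(pooling) - set(cell_types)
    if unknown:
        raise ValueError(f"unknown pooling cell types: {sorted(unknown)}")

    rng = _as_rng(seed)
    k = len(cell_types)
    mu = rng.uniform(m_lo, m_hi, size=(p, k))
    gen_sd = rng.uniform(s_lo, s_hi, size=p)

    var = np.empty((p, k))
    pure: dict[str, np.ndarray] = {}
    for j, ct in enumerate(cell_types):
        draws = rng.normal(
            loc=mu[:, j][:, None],
            scale=gen_sd[:, None],
            size=(p, pure_samples_per_type),
        )
        var[:, j] = draws.var(axis=1, ddof=1)
        pure[ct] = draws

    # sample-size-weighted pooled variance over the designated subset
    n_g = pure_samples_per_type
    pool_idx = [cell_types.index(ct) for ct in pooling]
    w = n_g - 1
    pooled = (var[:, pool_idx] * w).sum(axis=1) / (w * len(pool_idx))

    return ReferencePanel(
        cpg_ids=[f"cpg{i:06d}" for i in range(p)],
        cell_types=list(cell_types),
        mu=mu,
        var=var,
        pooled_var=pooled,
        pooling_cell_types=pooling,
        pure_samples=pure if keep_pure_samples else None,
        meta={
            "mean_hyper": list(mean_hyper),
            "sd_hyper": list(sd_hyper),
            "pure_samples_per_type": pure_samples_per_type,
            "generating_sd": gen_sd,
        },
    )


def clip_beta(values: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Clip beta values into [epsilon, 1 - epsilon].

    Replaces 0 with epsilon and 1 with 1 - epsilon; interior values are
    unchanged.  Keeps downstream logit/probit transforms finite.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError("beta values must lie in [0, 1]")
    return np.clip(arr, epsilon, 1.0 - epsilon)


def apply_call_rate_filters(
    values: np.ndarray,
    detection_p: np.ndarray | None = None,
    detection_threshold: float = 1e-16,
    sample_rate: float = 0.95,
    probe_rate: float = 0.90,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detection-p masking followed by sequential call-rate filtering.

    ``values`` is probes x samples.  Entries whose detection p-value exceeds
    ``detection_threshold`` are set to missing.  Samples with a call rate
    below ``sample_rate`` are removed first; probes with a call rate below
    ``probe_rate`` (computed over the surviving samples) are removed second.

    Returns ``(filtered, kept_probe_idx, kept_sample_idx)``.
    """
    x = np.asarray(values, dtype=float).copy()
    if x.ndim != 2:
        raise ValueError("values must be a 2-D probes x samples matrix")
    if not (0.0 < sample_rate <= 1.0) or not (0.0 < probe_rate <= 1.0):
        raise ValueError("call-rate thresholds must lie in (0, 1]")
    if detection_p is not None:
        dp = np.asarray(detection_p, dtype=float)
        if dp.shape != x.shape:
            raise ValueError(
                f"detection_p shape {dp.shape} does not match values {x.shape}"
            )
        x[dp > detection_threshold] = np.nan

    observed = ~np.isnan(x)
    sample_cr = observed.mean(axis=0)
    kept_samples = np.flatnonzero(sample_cr >= sample_rate)
    x = x[:, kept_samples]
    if x.shape[1] == 0:
        return x, np.array([], dtype=int), kept_samples
    probe_cr = (~np.isnan(x)).mean(axis=1)
    kept_probes = np.flatnonzero(probe_cr >= probe_rate)
    return x[kept_probes, :], kept_probes, kept_samples


def pooled_variance(group_values: list[np.ndarray]) -> float:
    """Sample-size-weighted pooled variance over groups.

    Returns sum_g (n_g - 1) s2_g / sum_g (n_g - 1), each s2_g the unbiased
    within-group variance.  Every group must contribute at least two
    observations.
    """
    if len(group_values) < 2:
        raise ValueError("need at least two groups")
    num = 0.0
    den = 0.0
    for g in group_values:
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size < 2:
            raise ValueError("every group needs at least 2 observations")
        num += (arr.size - 1) * arr.var(ddof=1)
        den += arr.size - 1
    return num / den


def levene_common_variance_test(
    group_values: list[np.ndarray], centering: str = "mean"
) -> tuple[float, float]:
    """Homogeneity-of-variance test across groups.

    One-way ANOVA F statistic on absolute deviations from each group's centre
    (mean for classical Levene, median for the Brown-Forsythe variant), with
    (K-1, N-K) degrees of freedom.  A non-significant result supports using a
    common per-CpG variance across cell types.
    """
    if centering not in ("mean", "median"):
        raise ValueError("centering must be 'mean' or 'median'")
    if len(group_values) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in group_values]
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 observations")
    centre = np.mean if centering == "mean" else np.median
    devs = np.concatenate([np.abs(g - centre(g)) for g in groups])
    if np.all(devs == 0.0):
        raise ValueError("degenerate groups: all deviations are zero")
    if np.allclose(devs, devs[0]):
        # every deviation equals one common constant: no between-group spread
        return 0.0, 1.0
    stat, pval = stats.levene(
        *groups, center=centering if centering == "mean" else "median"
    )
    if np.isnan(stat):
        raise ValueError("test statistic undefined for the given groups")
    return float(stat), float(pval)
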