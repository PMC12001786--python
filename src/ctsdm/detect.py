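"""Linear interaction-model detection of cell-type-specific effects.

The native detector regresses each CpG's bulk beta values on the cell-type
fractions and on phenotype-by-fraction interaction terms,

    X_c ~ f_1 + ... + f_K + f_1*y + ... + f_K*y (+ covariates, no intercept),

so the interaction coefficient gamma_k is the case-control methylation shift
within cell type k (the CellDMC/TOAST model class).  Because the fractions
sum to one, an intercept would be collinear with the fraction block; the
no-intercept parameterisation keeps every gamma_k directly interpretable.
Per-cell-type two-sided t tests use df = n - 2K - q; general linear
hypotheses on the same fit are available as single-contrast F tests.

The module also normalises external methods' outputs (p-value tables or
posterior-probability tables) into a common CpG x cell-type x method p-value
cube for downstream ensemble combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .aggregate import bh_adjust
from .simulate import SimulatedDataset

__all__ = [
    "DetectionResult",
    "PValueCube",
    "fit_interaction_model",
    "contrast_test",
    "assemble_cube",
    "perturb_fractions",
    "detect_dataset",
]


@dataclass
class DetectionResult:
    """Per-CpG, per-cell-type interaction-model inference.

    ``estimates``/``std_errors``/``statistics``/``p_values``/``adjusted_p``
    are (p, K) matrices for the interaction coefficients gamma_k.  The full
    fit (all 2K + q coefficients, the inverse Gram matrix and the residual
    variances) is retained so arbitrary contrasts can be tested afterwards.
    """

    estimates: np.ndarray
    std_errors: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    adjusted_p: np.ndarray
    df: int
    cell_types: list[str]
    cpg_ids: list[str]
    coef_full: np.ndarray = field(repr=False, default=None)
    xtx_inv: np.ndarray = field(repr=False, default=None)
    sigma2: np.ndarray = field(repr=False, default=None)
    design_columns: list[str] = field(default_factory=list)


@dataclass
class PValueCube:
    """CpG x cell-type x method p-values on a common scale.

    Posterior-probability sources are stored as 1 - posterior so that small
    values mean strong evidence for every method.
    """

    p: np.ndarray  # (p, K, m)
    method_labels: list[str]
    source_kinds: list[str]
    cpg_ids: list[str] | None = None
    cell_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 3:
            raise ValueError("p must be a (p, K, m) array")
        if self.p.shape[2] != len(self.method_labels):
            raise ValueError("method_labels length must match the third axis")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("cube entries must lie in [0, 1]")

    @property
    def n_methods(self) -> int:
        return self.p.shape[2]

    def subset_index(self, subset: list[str] | None) -> list[int]:
        if subset is None:
            return list(range(self.n_methods))
        if not subset:
            raise ValueError("method subset must be non-empty")
        idx = []
        for label in subset:
            if label not in self.method_labels:
                raise ValueError(f"unknown method label {label!r}")
            idx.append(self.method_labels.index(label))
        return idx


def _build_design(
    phenotype: np.ndarray,
    fractions: np.ndarray,
    covariates: np.ndarray | None,
    cell_types: list[str],
) -> tuple[np.ndarray, list[str]]:
    y = phenotype[:, None].astype(float)
    cols = [fractions, fractions * y]
    names = [f"f[{ct}]" for ct in cell_types] + [f"f[{ct}]:y" for ct in cell_types]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != fractions.shape[0]:
            cov = cov.T
        cols.append(cov)
        names += [f"cov{j}" for j in range(cov.shape[1])]
    return np.column_stack(cols), names


def fit_interaction_model(
    bulk: np.ndarray,
    phenotype: np.ndarray,
    fractions: np.ndarray,
    covariates: np.ndarray | None = None,
    cell_types: list[str] | None = None,
    cpg_ids: list[str] | None = None,
    adjust: str = "per_cell_type",
    alpha: float = 0.05,
) -> DetectionResult:
    """OLS fit of the no-intercept interaction model at every CpG.

    ``bulk`` is (p, n); the design matrix [f, f*y, covariates] is shared by
    all CpGs, so a single Gram inverse serves the whole array.  Two-sided
    t tests of gamma_k = 0 use df = n - 2K - q; BH adjustment is applied
    within each cell type (``adjust='global'`` pools all cells instead).
    """
    bulk = np.asarray(bulk, dtype=float)
    y = np.asarray(phenotype).ravel()
    f = np.asarray(fractions, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary, cases coded 1")
    n = y.size
    p, k = bulk.shape[0], f.shape[1]
    if bulk.shape[1] != n or f.shape[0] != n:
        raise ValueError("bulk columns, phenotype and fraction rows must align")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("fraction rows must sum to 1")
    if cell_types is None:
        cell_types = [f"cell{j}" for j in range(k)]
    if cpg_ids is None:
        cpg_ids = [f"cpg{i:06d}" for i in range(p)]
    if adjust not in ("per_cell_type", "global"):
        raise ValueError("adjust must be 'per_cell_type' or 'global'")

    design, names = _build_design(y, f, covariates, cell_types)
    d = design.shape[1]
    if n <= d:
        raise ValueError(f"need n > {d} samples for {d} coefficients, got {n}")
    # rank check with the offending column named
    _, r = np.linalg.qr(design)
    rdiag = np.abs(np.diag(r))
    bad = np.flatnonzero(rdiag < 1e-10 * max(rdiag.max(), 1.0))
    if bad.size:
        raise ValueError(
            f"rank-deficient design; offending column(s): {[names[j] for j in bad]}"
        )

    xtx_inv = np.linalg.inv(design.T @ design)
    coef = bulk @ design @ xtx_inv.T  # (p, d)
    resid = bulk - coef @ design.T
    df = n - d
    sigma2 = (resid**2).sum(axis=1) / df
    se_full = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])

    sl = slice(k, 2 * k)  # interaction block
    est = coef[:, sl]
    se = se_full[:, sl]
    tstat = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    if adjust == "per_cell_type":
        padj = np.column_stack([bh_adjust(pvals[:, j]) for j in range(k)])
    else:
        padj = bh_adjust(pvals.ravel()).reshape(pvals.shape)

    return DetectionResult(
        estimates=est,
        std_errors=se,
        statistics=tstat,
        p_values=pvals,
        adjusted_p=padj,
        df=df,
        cell_types=list(cell_types),
        cpg_ids=list(cpg_ids),
        coef_full=coef,
        xtx_inv=xtx_inv,
        sigma2=sigma2,
        design_columns=names,
    )


def contrast_test(
    result: DetectionResult, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """F test of a single linear combination c'beta = 0 at every CpG.

    For a unit contrast selecting one interaction coefficient, F = t^2 and
    the p-value equals the two-sided t p-value exactly.
    """
    c = np.asarray(contrast, dtype=float).ravel()
    d = result.coef_full.shape[1]
    if c.size != d:
        raise ValueError(f"contrast must have length {d}, got {c.size}")
    if np.all(c == 0.0):
        raise ValueError("contrast must be non-zero")
    est = result.coef_full @ c
    var = result.sigma2 * float(c @ result.xtx_inv @ c)
    fstat = np.divide(est**2, var, out=np.zeros_like(est), where=var > 0)
    pval = stats.f.sf(fstat, 1, result.df)
    return fstat, pval


def assemble_cube(
    tables: list[np.ndarray],
    source_kinds: list[str],
    method_labels: list[str],
    cpg_ids: list[str] | None = None,
    cell_types: list[str] | None = None,
) -> PValueCube:
    """Stack per-method (p, K) tables into a common p-value cube.

    Posterior-probability tables are converted entrywise to 1 - posterior.
    Values breaching [0, 1] by at most 1e-12 (floating-point dust) are
    clipped; larger breaches raise.
    """
    if not (len(tables) == len(source_kinds) == len(method_labels)):
        raise ValueError("tables, source_kinds and method_labels must align")
    if len(set(method_labels)) != len(method_labels):
        raise ValueError("method labels must be unique")
    shapes = {np.asarray(t).shape for t in tables}
    if len(shapes) != 1:
        raise ValueError(f"tables are not conformable: shapes {sorted(shapes)}")
    layers = []
    for tab, kind in zip(tables, source_kinds):
        arr = np.asarray(tab, dtype=float)
        if kind == "posterior":
            arr = 1.0 - arr
        elif kind != "p-value":
            raise ValueError("source kind must be 'p-value' or 'posterior'")
        if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError("table values outside [0, 1] beyond tolerance")
        layers.append(np.clip(arr, 0.0, 1.0))
    return PValueCube(
        p=np.stack(layers, axis=2),
        method_labels=list(method_labels),
        source_kinds=list(source_kinds),
        cpg_ids=cpg_ids,
        cell_types=cell_types,
    )


def perturb_fractions(
    fractions: np.ndarray,
    noise_scale: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Add bounded uniform noise to a fraction matrix and renormalise.

    Emulates imperfectly estimated cell proportions.  ``noise_scale`` is the
    half-width of the additive U(-noise_scale, noise_scale) perturbation;
    zero returns the input unchanged.  Rows are floored at zero and rescaled
    to sum to one.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    f = np.asarray(fractions, dtype=float)
    if noise_scale == 0:
        return f.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = np.maximum(f + rng.uniform(-noise_scale, noise_scale, size=f.shape), 0.0)
    sums = noisy.sum(axis=1, keepdims=True)
    zero_rows = (sums == 0).ravel()
    noisy[zero_rows] = 1.0 / f.shape[1]  # fully destroyed row: fall back to uniform
    sums[sums == 0] = 1.0
    return noisy / sums


def detect_dataset(
    dataset: SimulatedDataset, covariates: np.ndarray | None = None, **kwargs
) -> DetectionResult:
    """Run the native detector on a simulated cohort with its true fractions."""
    return fit_interaction_model(
        dataset.bulk,
        dataset.phenotype,
        dataset.fractions,
        covariates=covariates,
        cell_types=dataset.cell_types,
        cpg_ids=dataset.cpg_ids,
        **kwargs,
    )
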