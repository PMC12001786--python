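"""Replicated benchmarking: confusion metrics, AUROC, type-I error.

Each simulated replicate yields, per method and cell type, calls at a fixed
FDR level against the planted truth.  Metrics follow the usual conventions:
empirical FDR is defined as 0 when nothing is rejected, F1 as 0 when the
method neither rejects nor should have, and sensitivity/AUROC are undefined
(NaN / omitted) for cell types with no planted effects.  Empirical FDR
across the affected cell types is pooled on confusion counts, not averaged
over per-cell-type ratios.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .aggregate import bh_adjust
from .reference import ReferencePanel
from .simulate import SimulationDesign, simulate_dataset

__all__ = [
    "confusion_metrics",
    "auroc",
    "type1_error",
    "pooled_fdr",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    empirical_fdr: float
    for_rate: float
    f1: float


def confusion_metrics(calls: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and derived rates for one call vector.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    empirical FDR = FP/(TP+FP) with 0 when nothing is rejected;
    FOR = FN/(FN+TN) with 0 when everything is rejected;
    F1 = 2TP/(2TP+FP+FN) with 0 when the denominator is 0.
    """
    c = np.asarray(calls, dtype=bool).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    if c.size != t.size:
        raise ValueError(f"calls length {c.size} != truth length {t.size}")
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    fn = int(np.sum(~c & t))
    tn = int(np.sum(~c & ~t))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    fdr = fp / max(tp + fp, 1)
    for_rate = fn / max(fn + tn, 1)
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, fdr, for_rate, f1)


def auroc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC; larger score = more significant.

    Ties count half; both classes must be present.
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    if s.size != t.size:
        raise ValueError("scores and truth must have equal length")
    if t.all() or not t.any():
        raise ValueError("AUROC needs both classes present in truth")
    return float(roc_auc_score(t, s))


def type1_error(p_values: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of (unadjusted) null p-values below alpha."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.mean(p < alpha))


def pooled_fdr(
    calls: np.ndarray, truth: np.ndarray, columns: list[int] | None = None
) -> float:
    """False discovery proportion pooling TP/FP counts over cell types.

    ``calls`` and ``truth`` are (p, K); ``columns`` selects the cell types
    to pool (default: all).  Returns 0 when nothing is rejected.
    """
    c = np.asarray(calls, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if c.shape != t.shape:
        raise ValueError("calls and truth must have the same shape")
    if columns is not None:
        c, t = c[:, columns], t[:, columns]
    tp = int(np.sum(c & t))
    fp = int(np.sum(c & ~t))
    return fp / max(tp + fp, 1)


def run_benchmark(
    designs: list[SimulationDesign],
    panel: ReferencePanel,
    methods: dict,
    alpha: float = 0.05,
    base_seed: int = 0,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Simulate, detect, threshold and score over replicated settings.

    ``methods`` maps a label to a callable ``dataset -> (p, K) p-value
    matrix``.  Per replicate the p-values are BH-adjusted within each cell
    type and called at ``alpha``; all metrics are recorded per cell type,
    plus a ``pooled(affected)`` row holding the empirical FDR pooled on
    confusion counts over the cell types with planted effects.  Replicate r
    of every design uses seed ``base_seed + r``.
    """
    if not designs or not methods:
        raise ValueError("need at least one design and one method")
    rows = []
    for design in designs:
        reps = n_replicates if n_replicates is not None else design.n_replicates
        affected = [
            j for j, ct in enumerate(design.cell_types) if design.effects.get(ct, 0) > 0
        ]
        for r in range(reps):
            t0 = time.perf_counter()
            ds = simulate_dataset(design, panel, base_seed + r)
            sim_s = time.perf_counter() - t0
            for label, method in methods.items():
                t0 = time.perf_counter()
                pmat = np.asarray(method(ds), dtype=float)
                fit_s = time.perf_counter() - t0
                k = len(design.cell_types)
                if pmat.shape != (ds.n_cpgs, k):
                    raise ValueError(
                        f"method {label!r} returned shape {pmat.shape}, "
                        f"expected {(ds.n_cpgs, k)}"
                    )
                padj = np.column_stack([bh_adjust(pmat[:, j]) for j in range(k)])
                calls = padj <= alpha
                truth = ds.truth.truth
                for j, ct in enumerate(design.cell_types):
                    cm = confusion_metrics(calls[:, j], truth[:, j])
                    has_both = truth[:, j].any() and not truth[:, j].all()
                    rows.append(
                        {
                            "method": label,
                            "cell_type": ct,
                            "replicate": r,
                            "snr": design.snr,
                            "n": design.n,
                            "sensitivity": cm.sensitivity,
                            "specificity": cm.specificity,
                            "empirical_fdr": cm.empirical_fdr,
                            "f1": cm.f1,
                            "for_rate": cm.for_rate,
                            "auroc": auroc(1.0 - pmat[:, j], truth[:, j])
                            if has_both
                            else float("nan"),
                            "type1_error": type1_error(pmat[:, j], alpha)
                            if not truth[:, j].any()
                            else float("nan"),
                            "tp": cm.tp,
                            "fp": cm.fp,
                            "tn": cm.tn,
                            "fn": cm.fn,
                            "sim_seconds": sim_s,
                            "fit_seconds": fit_s,
                        }
                    )
                if affected:
                    rows.append(
                        {
                            "method": label,
                            "cell_type": "pooled(affected)",
                            "replicate": r,
                            "snr": design.snr,
                            "n": design.n,
                            "empirical_fdr": pooled_fdr(calls, truth, affected),
                            "sim_seconds": sim_s,
                            "fit_seconds": fit_s,
                        }
                    )
    return pd.DataFrame(rows)


def summarize_benchmark(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of every metric over replicates, per setting."""
    value_cols = [
        c
        for c in (
            "sensitivity",
            "specificity",
            "empirical_fdr",
            "f1",
            "for_rate",
            "auroc",
            "type1_error",
        )
        if c in metrics.columns
    ]
    grouped = metrics.groupby(["method", "cell_type", "snr", "n"], sort=False)
    out = grouped[value_cols].agg(["mean", "median"])
    out.columns = [f"{m}_{stat}" for m, stat in out.columns]
    return out.reset_index()
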