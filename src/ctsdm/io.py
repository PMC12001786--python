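"""Table readers/writers and on-disk layouts.

Canonical dialect: tab-separated text with a header row of sample (column)
identifiers and a first column of CpG (row) identifiers; CSV is accepted on
read.  Panels serialise as a directory of TSVs plus a JSON manifest; datasets
as bulk/phenotype/fractions/truth TSVs plus a manifest recording the seed and
design, sufficient to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionResult, PValueCube
from .reference import ReferencePanel
from .simulate import EffectMap, SimulatedDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_panel",
    "load_panel",
    "save_dataset",
    "load_dataset",
    "write_detection",
    "read_cube_long",
    "write_cube_long",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix with row identifiers in the first column.

    Returns ``(values, row_ids, col_ids)``.  Duplicate identifiers and empty
    files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )
    if df.shape[0] == 0:
        raise ValueError(f"empty matrix in {path}")
    for axis, ids in (("row", df.index), ("column", df.columns)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {axis} identifier {dup[0]!r} in {path}")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [
        str(c) for c in df.columns
    ]


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
) -> None:
    """Write a matrix at full float precision (round-trips bit-exactly)."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def save_panel(panel: ReferencePanel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(out / "mu.tsv", panel.mu, panel.cpg_ids, panel.cell_types)
    write_matrix(out / "var.tsv", panel.var, panel.cpg_ids, panel.cell_types)
    write_matrix(
        out / "pooled_var.tsv",
        panel.pooled_var[:, None],
        panel.cpg_ids,
        ["pooled_var"],
    )
    manifest = {
        "cell_types": panel.cell_types,
        "pooling_cell_types": panel.pooling_cell_types,
        "n_cpgs": panel.n_cpgs,
        "meta": {k: v for k, v in panel.meta.items() if not isinstance(v, np.ndarray)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_panel(in_dir: str | Path) -> ReferencePanel:
    src = Path(in_dir)
    mu, cpg_ids, cell_types = read_matrix(src / "mu.tsv")
    var, _, _ = read_matrix(src / "var.tsv")
    pooled, _, _ = read_matrix(src / "pooled_var.tsv")
    manifest = json.loads((src / "manifest.json").read_text())
    return ReferencePanel(
        cpg_ids=cpg_ids,
        cell_types=cell_types,
        mu=mu,
        var=var,
        pooled_var=pooled[:, 0],
        pooling_cell_types=manifest.get("pooling_cell_types", cell_types),
        meta=manifest.get("meta", {}),
    )


def save_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(out / "bulk.tsv", dataset.bulk, dataset.cpg_ids, dataset.sample_ids)
    write_matrix(
        out / "phenotype.tsv",
        dataset.phenotype[:, None].astype(float),
        dataset.sample_ids,
        ["phenotype"],
    )
    write_matrix(
        out / "fractions.tsv", dataset.fractions, dataset.sample_ids, dataset.cell_types
    )
    write_matrix(
        out / "truth.tsv",
        dataset.truth.truth.astype(float),
        dataset.cpg_ids,
        dataset.cell_types,
    )
    if dataset.truth.effect_size is not None:
        write_matrix(
            out / "effect_size.tsv",
            np.column_stack([dataset.truth.effect_size, dataset.truth.sign]),
            dataset.cpg_ids,
            ["effect_size", "sign"],
        )
    (out / "manifest.json").write_text(json.dumps(dataset.meta, indent=2, default=str))


def load_dataset(in_dir: str | Path) -> SimulatedDataset:
    src = Path(in_dir)
    bulk, cpg_ids, sample_ids = read_matrix(src / "bulk.tsv")
    pheno, _, _ = read_matrix(src / "phenotype.tsv")
    fractions, _, cell_types = read_matrix(src / "fractions.tsv")
    truth_path = src / "truth.tsv"
    if truth_path.exists():
        truth_vals, _, _ = read_matrix(truth_path)
        truth = EffectMap(truth=truth_vals.astype(bool))
        es_path = src / "effect_size.tsv"
        if es_path.exists():
            es, _, _ = read_matrix(es_path)
            truth.effect_size = es[:, 0]
            truth.sign = es[:, 1]
    else:
        truth = EffectMap(truth=np.zeros((len(cpg_ids), len(cell_types)), dtype=bool))
    meta_path = src / "manifest.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SimulatedDataset(
        bulk=bulk,
        phenotype=pheno[:, 0].astype(int),
        fractions=fractions,
        truth=truth,
        cpg_ids=cpg_ids,
        cell_types=cell_types,
        sample_ids=sample_ids,
        meta=meta,
    )


def write_detection(result: DetectionResult, path: str | Path) -> None:
    """Long-format TSV: CpG, cell_type, estimate, se, t, p, p_adj."""
    p, k = result.p_values.shape
    df = pd.DataFrame(
        {
            "CpG": np.repeat(result.cpg_ids, k),
            "cell_type": np.tile(result.cell_types, p),
            "estimate": result.estimates.ravel(),
            "se": result.std_errors.ravel(),
            "t": result.statistics.ravel(),
            "p": result.p_values.ravel(),
            "p_adj": result.adjusted_p.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_cube_long(cube: PValueCube, path: str | Path) -> None:
    """One long table with a method column (stacked p-value cube)."""
    p, k, m = cube.p.shape
    cpgs = cube.cpg_ids or [f"cpg{i:06d}" for i in range(p)]
    cts = cube.cell_types or [f"cell{j}" for j in range(k)]
    df = pd.DataFrame(
        {
            "CpG": np.repeat(cpgs, k * m),
            "cell_type": np.tile(np.repeat(cts, m), p),
            "method": np.tile(cube.method_labels, p * k),
            "p": cube.p.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cube_long(path: str | Path) -> PValueCube:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"CpG", "cell_type", "method", "p"}
    if not required.issubset(df.columns):
        raise ValueError(f"cube table must have columns {sorted(required)}")
    cpgs = list(dict.fromkeys(df["CpG"]))
    cts = list(dict.fromkeys(df["cell_type"]))
    methods = list(dict.fromkeys(df["method"]))
    cube = np.full((len(cpgs), len(cts), len(methods)), np.nan)
    ci = {c: i for i, c in enumerate(cpgs)}
    ki = {c: i for i, c in enumerate(cts)}
    mi = {c: i for i, c in enumerate(methods)}
    cube[
        df["CpG"].map(ci).to_numpy(),
        df["cell_type"].map(ki).to_numpy(),
        df["method"].map(mi).to_numpy(),
    ] = df["p"].to_numpy()
    if np.isnan(cube).any():
        raise ValueError("cube table is not a complete CpG x cell_type x method grid")
    return PValueCube(
        p=cube,
        method_labels=[str(m) for m in methods],
        source_kinds=["p-value"] * len(methods),
        cpg_ids=[str(c) for c in cpgs],
        cell_types=[str(c) for c in cts],
    )
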