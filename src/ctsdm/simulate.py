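"""In-silico bulk methylation mixtures with planted cell-type-specific effects.

A bulk sample is a convex combination of cell-type-specific beta-value
profiles: X_c = sum_k f_k * X_ck, with per-sample fractions f drawn uniformly
within per-cell-type bounds and renormalised to sum to one.  Case samples
receive a mean shift s_c = SNR * sigma_c at the planted (CpG, cell type)
pairs, where sigma_c is the panel's pooled per-CpG SD, so the effect size is
expressed in noise units.

Two array designs are bundled as presets: a five-cell-type layout with
epithelial/fibroblast/immune fractions and 500 planted CpGs each in
epithelial, CD4T and monocyte cells, and a six-cell-type blood layout with
1,000-CpG effect sets and an optional 500-CpG set shared between CD4T and
CD8T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reference import ReferencePanel

__all__ = [
    "SimulationDesign",
    "EffectMap",
    "SimulatedDataset",
    "draw_fractions",
    "assign_effects",
    "effect_size",
    "simulate_cell_profiles",
    "mix",
    "simulate_dataset",
    "replicates",
    "preset_design",
    "PRESET_NAMES",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulation setting.

    ``fraction_bounds`` maps each cell type to its uniform interval
    [lo_k, hi_k]; raw draws are renormalised row-wise.  ``effects`` gives the
    number of planted differential CpGs per cell type; ``shared_effects``
    lists ((cell_type_a, cell_type_b), count) sets planted in both members.
    ``snr`` scales the pooled per-CpG SD into the planted mean shift.
    """

    cell_types: tuple[str, ...]
    fraction_bounds: dict[str, tuple[float, float]]
    n: int
    snr: float
    effects: dict[str, int] = field(default_factory=dict)
    shared_effects: tuple[tuple[tuple[str, str], int], ...] = ()
    case_fraction: float = 0.5
    effect_sign: int | str = 1
    clip_output: bool = True
    epsilon: float = 1e-6
    n_replicates: int = 50
    p: int | None = None

    def __post_init__(self) -> None:
        if not self.cell_types:
            raise ValueError("cell_types must be non-empty")
        if set(self.fraction_bounds) != set(self.cell_types):
            raise ValueError("fraction_bounds must cover exactly the cell types")
        for ct, (lo, hi) in self.fraction_bounds.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"invalid fraction bounds for {ct}: [{lo}, {hi}]")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        unknown = set(self.effects) - set(self.cell_types)
        if unknown:
            raise ValueError(f"effects name unknown cell types: {sorted(unknown)}")
        for ct, cnt in self.effects.items():
            if cnt < 0:
                raise ValueError(f"negative effect count for {ct}")
        for (a, b), cnt in self.shared_effects:
            if a not in self.cell_types or b not in self.cell_types:
                raise ValueError(f"shared set names unknown cell type: ({a}, {b})")
            if cnt < 0 or cnt > self.effects.get(a, 0) or cnt > self.effects.get(b, 0):
                raise ValueError(
                    "shared count must not exceed either member's effect count"
                )
        if self.effect_sign not in (1, -1, "random"):
            raise ValueError("effect_sign must be +1, -1 or 'random'")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def effect_counts(self) -> np.ndarray:
        return np.array([self.effects.get(ct, 0) for ct in self.cell_types])


@dataclass
class EffectMap:
    """Planted truth: which (CpG, cell type) pairs carry a case-control shift.

    ``truth`` is a (p, K) boolean matrix; ``effect_size`` the per-CpG shift
    magnitude s_c (filled once a panel's pooled SD is known); ``sign`` the
    per-CpG shift direction, shared across cell types for CpGs planted in
    more than one cell type.
    """

    truth: np.ndarray
    effect_size: np.ndarray | None = None
    sign: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.truth.ndim != 2:
            raise ValueError("truth must be a (p, K) matrix")
        if self.sign is None:
            self.sign = np.ones(self.truth.shape[0])

    @property
    def column_counts(self) -> np.ndarray:
        return self.truth.sum(axis=0)

    @property
    def any_effect(self) -> np.ndarray:
        return self.truth.any(axis=1)


@dataclass
class SimulatedDataset:
    """One simulated bulk cohort: mixtures, phenotype, fractions and truth."""

    bulk: np.ndarray  # (p, n)
    phenotype: np.ndarray  # (n,) 0/1, cases = 1
    fractions: np.ndarray  # (n, K)
    truth: EffectMap
    cpg_ids: list[str]
    cell_types: list[str]
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_cpgs(self) -> int:
        return self.bulk.shape[0]

    @property
    def n_samples(self) -> int:
        return self.bulk.shape[1]


def draw_fractions(
    design: SimulationDesign, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw an (n, K) fraction matrix.

    Raw draws are uniform within each cell type's interval; each row is then
    divided by its sum, preserving relative abundances while enforcing the
    sum-to-one constraint of a composition.
    """
    rng = _as_rng(seed)
    lo = np.array([design.fraction_bounds[ct][0] for ct in design.cell_types])
    hi = np.array([design.fraction_bounds[ct][1] for ct in design.cell_types])
    raw = rng.uniform(lo, hi, size=(n, design.n_cell_types))
    sums = raw.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("a raw fraction row summed to zero; widen the bounds")
    return raw / sums


def assign_effects(
    design: SimulationDesign, p: int, seed: int | np.random.Generator
) -> EffectMap:
    """Choose which CpGs carry effects in which cell types.

    Shared sets are drawn first and marked in both members; the remaining
    per-cell-type quota is filled with CpGs exclusive to that cell type, so
    column sums match the design exactly and non-shared CpGs are
    non-overlapping across cell types.
    """
    rng = _as_rng(seed)
    counts = {ct: design.effects.get(ct, 0) for ct in design.cell_types}
    shared_used = {ct: 0 for ct in design.cell_types}
    for (a, b), cnt in design.shared_effects:
        shared_used[a] += cnt
        shared_used[b] += cnt
    for ct in design.cell_types:
        if shared_used[ct] > counts[ct]:
            raise ValueError(f"shared sets exceed the effect count of {ct}")
    n_unique = sum(cnt for _, cnt in design.shared_effects) + sum(
        counts[ct] - shared_used[ct] for ct in design.cell_types
    )
    if n_unique > p:
        raise ValueError(f"design needs {n_unique} distinct CpGs but p={p}")

    order = rng.permutation(p)
    truth = np.zeros((p, design.n_cell_types), dtype=bool)
    col = {ct: j for j, ct in enumerate(design.cell_types)}
    cursor = 0
    for (a, b), cnt in design.shared_effects:
        idx = order[cursor : cursor + cnt]
        truth[idx, col[a]] = True
        truth[idx, col[b]] = True
        cursor += cnt
    for ct in design.cell_types:
        extra = counts[ct] - shared_used[ct]
        idx = order[cursor : cursor + extra]
        truth[idx, col[ct]] = True
        cursor += extra

    if design.effect_sign == "random":
        sign = rng.choice([-1.0, 1.0], size=p)
    else:
        sign = np.full(p, float(design.effect_sign))
    return EffectMap(truth=truth, sign=sign)


def effect_size(snr: float, pooled_sd: np.ndarray) -> np.ndarray:
    """Planted mean shift s_c = snr * pooled SD, elementwise."""
    if snr < 0:
        raise ValueError("snr must be non-negative")
    sd = np.asarray(pooled_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("pooled_sd must be strictly positive")
    return snr * sd


def simulate_cell_profiles(
    panel: ReferencePanel,
    truth: EffectMap,
    phenotype: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw per-cell-type profiles, shape (p, K, n).

    Every (CpG, cell type, sample) value is Gaussian with mean mu_ck and the
    panel's pooled variance sigma2_c; case samples additionally receive the
    shift sign_c * s_c at planted (c, k) pairs.
    """
    rng = _as_rng(seed)
    y = np.asarray(phenotype)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    p, k = panel.mu.shape
    if truth.truth.shape != (p, k):
        raise ValueError(
            f"truth shape {truth.truth.shape} does not match panel {(p, k)}"
        )
    if truth.effect_size is None:
        raise ValueError("EffectMap.effect_size must be set before simulation")
    n = y.size
    sd = np.sqrt(panel.pooled_var)
    profiles = rng.normal(size=(p, k, n)) * sd[:, None, None] + panel.mu[:, :, None]
    shift = truth.truth * (truth.sign * truth.effect_size)[:, None]  # (p, K)
    profiles[:, :, y == 1] += shift[:, :, None]
    return profiles


def mix(profiles: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Fraction-weighted sum over cell types: bulk (p, n)."""
    profiles = np.asarray(profiles, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if profiles.ndim != 3 or fractions.ndim != 2:
        raise ValueError("profiles must be (p, K, n) and fractions (n, K)")
    p, k, n = profiles.shape
    if fractions.shape != (n, k):
        raise ValueError(
            f"fractions shape {fractions.shape} does not match profiles {(n, k)}"
        )
    if not np.allclose(fractions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("fraction rows must sum to 1 within 1e-9")
    return np.einsum("pkn,nk->pn", profiles, fractions)


def simulate_dataset(
    design: SimulationDesign,
    panel: ReferencePanel,
    seed: int | np.random.Generator,
) -> SimulatedDataset:
    """Generate one complete cohort under a design and a reference panel.

    Composes fraction drawing, effect assignment, profile simulation and
    mixing on a single random stream, so the result is bitwise reproducible
    given (design, panel, seed).  Cases come first in sample order; exactly
    round(case_fraction * n) of them.
    """
    if design.p is not None and design.p != panel.n_cpgs:
        raise ValueError(
            f"design expects p={design.p} CpGs but panel has {panel.n_cpgs}"
        )
    if list(design.cell_types) != list(panel.cell_types):
        raise ValueError("design and panel cell types must match (same order)")
    rng = _as_rng(seed)
    n = design.n
    n_cases = int(round(design.case_fraction * n))
    y = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n - n_cases, dtype=int)])

    fractions = draw_fractions(design, n, rng)
    truth = assign_effects(design, panel.n_cpgs, rng)
    truth.effect_size = effect_size(design.snr, panel.pooled_sd)
    profiles = simulate_cell_profiles(panel, truth, y, rng)
    bulk = mix(profiles, fractions)
    if design.clip_output:
        bulk = np.clip(bulk, design.epsilon, 1.0 - design.epsilon)
    return SimulatedDataset(
        bulk=bulk,
        phenotype=y,
        fractions=fractions,
        truth=truth,
        cpg_ids=list(panel.cpg_ids),
        cell_types=list(panel.cell_types),
        sample_ids=[f"s{i:04d}" for i in range(n)],
        meta={
            "seed": seed if isinstance(seed, int) else None,
            "snr": design.snr,
            "n": n,
            "clip_output": design.clip_output,
            "epsilon": design.epsilon,
        },
    )


def replicates(
    design: SimulationDesign, panel: ReferencePanel, base_seed: int
):
    """Yield ``design.n_replicates`` datasets; replicate r uses base_seed + r."""
    for r in range(design.n_replicates):
        yield simulate_dataset(design, panel, base_seed + r)


_450K_BOUNDS = {
    "Epithelial": (0.3, 0.4),
    "Fibroblast": (0.35, 0.45),
    "CD4T": (0.1, 0.2),
    "Monocyte": (0.0, 0.1),
    "B-cell": (0.0, 0.1),
}
_EPIC_BOUNDS = {
    "Neutrophil": (0.4, 0.6),
    "CD4T": (0.2, 0.3),
    "CD8T": (0.05, 0.15),
    "Monocyte": (0.0, 0.1),
    "B-cell": (0.0, 0.1),
    "NK": (0.0, 0.1),
}

PRESET_NAMES = ("450k", "epic-1a", "epic-1b", "epic-2a", "epic-2b")


def preset_design(
    name: str,
    snr: float = 11.0,
    n: int = 100,
    p: int | None = None,
    n_replicates: int = 50,
    scale: float = 1.0,
) -> SimulationDesign:
    """Bundled study designs.

    ``450k``: five cell types, 10,000 CpGs, 500 planted CpGs each in
    epithelial, CD4T and monocyte cells.  ``epic-1a/1b/2a/2b``: six blood cell
    types, 20,000 CpGs, 1,000-CpG effect sets (1a: neutrophil/CD4T/CD8T/
    monocyte; 2a: CD4T/CD8T/monocyte), the 'b' variants sharing 500 CpGs
    between CD4T and CD8T.  ``scale`` shrinks p and the effect counts
    proportionally for desk-scale runs.
    """
    if name == "450k":
        cts = tuple(_450K_BOUNDS)
        bounds = dict(_450K_BOUNDS)
        default_p = 10_000
        effects = {"Epithelial": 500, "CD4T": 500, "Monocyte": 500}
        shared: tuple = ()
    elif name in ("epic-1a", "epic-1b", "epic-2a", "epic-2b"):
        cts = tuple(_EPIC_BOUNDS)
        bounds = dict(_EPIC_BOUNDS)
        default_p = 20_000
        if name.startswith("epic-1"):
            effects = {"Neutrophil": 1000, "CD4T": 1000, "CD8T": 1000, "Monocyte": 1000}
        else:
            effects = {"CD4T": 1000, "CD8T": 1000, "Monocyte": 1000}
        shared = ((("CD4T", "CD8T"), 500),) if name.endswith("b") else ()
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    if scale <= 0 or scale > 1:
        raise ValueError("scale must lie in (0, 1]")
    if scale != 1.0:
        effects = {ct: int(round(c * scale)) for ct, c in effects.items()}
        shared = tuple(((a, b), int(round(c * scale))) for (a, b), c in shared)
        default_p = int(round(default_p * scale))
    return SimulationDesign(
        cell_types=cts,
        fraction_bounds=bounds,
        n=n,
        snr=snr,
        effects=effects,
        shared_effects=shared,
        n_replicates=n_replicates,
        p=p if p is not None else default_p,
    )


def with_overrides(design: SimulationDesign, **kwargs) -> SimulationDesign:
    """Return a copy of ``design`` with the given fields replaced."""
    return replace(design, **kwargs)


def design_from_file(path) -> SimulationDesign:
    """Load a SimulationDesign from a YAML or JSON config file.

    Keys mirror the dataclass fields; unknown keys are rejected so typos
    surface instead of silently falling back to defaults.
    """
    import dataclasses
    from pathlib import Path

    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"design config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationDesign)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown design keys in {path}: {sorted(unknown)}")
    if "cell_types" in raw:
        raw["cell_types"] = tuple(raw["cell_types"])
    if "fraction_bounds" in raw:
        raw["fraction_bounds"] = {
            ct: tuple(b) for ct, b in raw["fraction_bounds"].items()
        }
    if "shared_effects" in raw:
        raw["shared_effects"] = tuple(
            (tuple(pair), int(cnt)) for pair, cnt in raw["shared_effects"]
        )
    return SimulationDesign(**raw)
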