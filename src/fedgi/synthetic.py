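"""Synthetic multi-center case/control cohorts with planted gene signal.

Count coordinates are Poisson draws:

    count[sample, class c, gene g] ~ Poisson(
        base_rate[c, g] * batch_factor[c] * effect_size**(case and g in signal)
    )

which supports planted multiplicative case signal on chosen genes,
center-wide multiplicative batch effects on class counts, skewed label
ratios, and an optional label-confounded batch pathology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .encoding import (
    DEFAULT_VOCABULARY,
    AnnotatedVariant,
    CohortDataset,
    GenePanel,
    VariantClassVocabulary,
)

__all__ = [
    "PanelSpec",
    "CenterSpec",
    "generate_panel",
    "default_base_rates",
    "generate_center_cohort",
    "counts_to_variants",
    "write_annovar_tsv",
    "split_random",
    "split_stratified",
]


@dataclass(frozen=True)
class PanelSpec:
    """Panel size plus the score-generating distributions.

    Intolerance scores are Normal(loc, scale) (signed intolerance-style scores);
    publication weights are Gamma(shape, scale) (non-negative, skewed).
    """

    n_genes: int = 50
    intolerance_loc: float = 0.0
    intolerance_scale: float = 1.0
    pubweight_shape: float = 1.5
    pubweight_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def generate_panel(spec: PanelSpec, seed: int) -> GenePanel:
    rng = np.random.default_rng(seed)
    genes = tuple(f"GENE{i:04d}" for i in range(spec.n_genes))
    intol = rng.normal(spec.intolerance_loc, spec.intolerance_scale, spec.n_genes)
    pw = rng.gamma(spec.pubweight_shape, spec.pubweight_scale, spec.n_genes)
    return GenePanel(genes, intol, pw)


def default_base_rates(
    n_genes: int, n_classes: int = len(DEFAULT_VOCABULARY.classes), seed: int = 0
) -> np.ndarray:
    """Per-(class, gene) Poisson rates, Gamma(2, 0.5)-distributed (mean 1)."""
    rng = np.random.default_rng(seed)
    return rng.gamma(2.0, 0.5, size=(n_classes, n_genes))


@dataclass(frozen=True)
class CenterSpec:
    """Generative description of one center's cohort."""

    center_id: str
    n_cases: int
    n_controls: int
    signal_genes: tuple[int, ...] = ()
    effect_size: float = 1.0
    batch_factor: np.ndarray | None = None  # per-class multiplier, len n_classes
    base_rates: np.ndarray | None = None  # (n_classes, n_genes); shared across centers
    confound_with_label: bool = False  # apply batch_factor to cases only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one sample")
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        object.__setattr__(self, "signal_genes", tuple(self.signal_genes))


def _rates_for(
    spec: CenterSpec, panel: GenePanel, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    base = (
        spec.base_rates
        if spec.base_rates is not None
        else default_base_rates(len(panel), n_classes, seed=spec.seed)
    )
    base = np.asarray(base, dtype=float)
    if base.shape != (n_classes, len(panel)):
        raise ValueError(f"base_rates must have shape ({n_classes}, {len(panel)})")
    if np.any(base < 0):
        raise ValueError("rates must be non-negative")
    bf = (
        np.ones(n_classes)
        if spec.batch_factor is None
        else np.asarray(spec.batch_factor, dtype=float)
    )
    if bf.shape != (n_classes,):
        raise ValueError(f"batch_factor must have length {n_classes}")
    return base, bf


def generate_center_cohort(
    spec: CenterSpec,
    panel: GenePanel,
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
    rng: np.random.Generator | None = None,
) -> CohortDataset:
    """Draw one center's cohort; cases first, then controls."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_classes = len(vocabulary)
    base, bf = _rates_for(spec, panel, n_classes)

    case_rates = base.copy()
    if spec.signal_genes:
        case_rates[:, list(spec.signal_genes)] *= spec.effect_size
    control_rates = base.copy()
    if spec.confound_with_label:
        case_rates = case_rates * bf[:, None]
    else:
        case_rates = case_rates * bf[:, None]
        control_rates = control_rates * bf[:, None]

    n = spec.n_cases + spec.n_controls
    tensor = np.zeros((n, n_classes + 2, len(panel)))
    labels = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    for i in range(n):
        rates = case_rates if labels[i] == 1 else control_rates
        tensor[i, :n_classes, :] = rng.poisson(rates)
    tensor[:, n_classes, :] = panel.intolerance
    tensor[:, n_classes + 1, :] = panel.publication_weight
    sample_ids = tuple(f"{spec.center_id}_S{i:04d}" for i in range(n))
    return CohortDataset(
        tensor=tensor,
        labels=labels,
        sample_ids=sample_ids,
        center_id=spec.center_id,
        panel=panel,
        vocabulary=vocabulary,
    )


def counts_to_variants(
    cohort: CohortDataset,
) -> list[list[AnnotatedVariant]]:
    """Materialize synthetic annotated-variant records realizing the counts.

    Re-encoding the returned lists against the same panel reproduces the
    cohort's count coordinates exactly, exercising the full annotation ->
    tensor path.
    """
    vocab = cohort.vocabulary
    n_classes = len(vocab)
    out: list[list[AnnotatedVariant]] = []
    for i in range(cohort.n_samples):
        records: list[AnnotatedVariant] = []
        counts = cohort.tensor[i, :n_classes, :].astype(int)
        for g, gene in enumerate(cohort.panel.genes):
            pos = 1000 * (g + 1)
            for c, vclass in enumerate(vocab.classes):
                for k in range(counts[c, g]):
                    records.append(
                        AnnotatedVariant("chr1", pos + c * 50 + k + 1, "A", "T", gene, vclass)
                    )
        out.append(records)
    return out


def write_annovar_tsv(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write records in the Annovar variant-function TSV dialect."""
    with open(path, "w") as fh:
        for v in variants:
            fh.write(
                f"{v.variant_class}\t{v.gene}\t{v.chrom}\t{v.pos}\t{v.pos}\t{v.ref}\t{v.alt}\n"
            )


def _fold_datasets(
    dataset: CohortDataset, fold_indices: list[np.ndarray]
) -> list[CohortDataset]:
    return [
        dataset.subset(idx, center_id=f"{dataset.center_id}_fold{k}")
        for k, idx in enumerate(fold_indices)
    ]


def split_random(dataset: CohortDataset, n_folds: int, seed: int) -> list[CohortDataset]:
    """Disjoint, exhaustive random partition into n_folds sub-cohorts."""
    if n_folds > dataset.n_samples:
        raise ValueError("n_folds cannot exceed the number of samples")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test for _, test in kf.split(np.zeros(dataset.n_samples))]
    return _fold_datasets(dataset, folds)


def split_stratified(dataset: CohortDataset, n_folds: int, seed: int) -> list[CohortDataset]:
    """Partition preserving the case/control ratio per fold (within 1 case)."""
    if n_folds > dataset.n_samples:
        raise ValueError("n_folds cannot exceed the number of samples")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        test for _, test in skf.split(np.zeros(dataset.n_samples), dataset.labels)
    ]
    return _fold_datasets(dataset, folds)
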