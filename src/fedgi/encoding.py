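"""Gene-centric feature encoding of annotated exome variants.

Each sample's variant list is condensed, per panel gene, into a histogram of
functional-annotation classes plus two gene-level scores (an intolerance
score and a disease publication weight), yielding one fixed-length feature
vector per gene and a ``(n_classes + 2, n_genes)`` matrix per sample.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_VARIANT_CLASSES",
    "VariantClassVocabulary",
    "AnnotatedVariant",
    "GenePanel",
    "EncodingReport",
    "CohortDataset",
    "read_annovar_table",
    "read_vcf_with_mapping",
    "build_gene_histogram",
    "encode_sample",
    "encode_cohort",
]

#: Canonical functional-annotation classes, in fixed histogram order.
DEFAULT_VARIANT_CLASSES: tuple[str, ...] = (
    "exonic",
    "UTR3",
    "UTR5",
    "ncRNA exonic",
    "ncRNA intronic",
    "upstream",
    "downstream",
    "intronic",
    "splicing",
)


@dataclass(frozen=True)
class VariantClassVocabulary:
    """Ordered set of variant-class names; the order defines histogram coordinates."""

    classes: tuple[str, ...] = DEFAULT_VARIANT_CLASSES

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("variant class names must be unique")
        if not self.classes:
            raise ValueError("vocabulary must be non-empty")
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.classes)}
        )

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]


DEFAULT_VOCABULARY = VariantClassVocabulary()


@dataclass(frozen=True)
class AnnotatedVariant:
    """One functionally annotated variant assigned to a single gene.

    Positions are 1-based (VCF convention).  A variant annotated to several
    genes is represented by one record per gene.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene list with per-gene intolerance and publication-weight scores.

    The gene order is fixed and defines the column order of every encoded
    tensor produced against this panel.
    """

    genes: tuple[str, ...]
    intolerance: np.ndarray
    publication_weight: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene symbols must be unique")
        intol = np.asarray(self.intolerance, dtype=float)
        pw = np.asarray(self.publication_weight, dtype=float)
        if intol.shape != (len(self.genes),) or pw.shape != (len(self.genes),):
            raise ValueError("score arrays must be 1-D with one entry per gene")
        if np.any(pw < 0):
            raise ValueError("publication weights must be non-negative")
        n_missing = int(np.isnan(intol).sum() + np.isnan(pw).sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} missing panel scores imputed to 0", stacklevel=2
            )
            intol = np.nan_to_num(intol)
            pw = np.nan_to_num(pw)
        object.__setattr__(self, "intolerance", intol)
        object.__setattr__(self, "publication_weight", pw)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        return self._index[gene]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenePanel":
        """Read ``gene<TAB>intolerance<TAB>publication_weight`` (header optional)."""
        genes: list[str] = []
        intol: list[float] = []
        pw: list[float] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                if lineno == 1 and not _is_number(parts[1]):
                    continue  # header
                genes.append(parts[0])
                intol.append(float(parts[1]) if parts[1] != "" else np.nan)
                pw.append(float(parts[2]) if parts[2] != "" else np.nan)
        return cls(tuple(genes), np.array(intol), np.array(pw))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tintolerance_score\tpublication_weight\n")
            for g, a, b in zip(self.genes, self.intolerance, self.publication_weight):
                fh.write(f"{g}\t{a:.17g}\t{b:.17g}\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


@dataclass
class EncodingReport:
    """Counters for records that fall outside the vocabulary or the panel."""

    unknown_class_counts: Counter = field(default_factory=Counter)
    off_panel_count: int = 0
    n_records: int = 0

    @property
    def n_unknown(self) -> int:
        return sum(self.unknown_class_counts.values())


def read_annovar_table(
    path: str | Path,
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
    report: EncodingReport | None = None,
) -> list[AnnotatedVariant]:
    """Parse one sample's Annovar-style variant-function table.

    Expected tab-separated columns: class, gene(s), chrom, start, end, ref,
    alt.  A record annotated to k ``;``-separated genes fans out to k
    variants.  Records whose class is not in ``vocabulary`` yield no variants
    but are tallied in ``report.unknown_class_counts``.
    """
    if report is None:
        report = EncodingReport()
    variants: list[AnnotatedVariant] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        warnings.warn(f"{path}: empty annotation table", stacklevel=2)
        return variants
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ValueError(
                f"{path}:{lineno}: malformed line, expected >=7 tab-separated "
                f"fields, got {len(parts)}"
            )
        vclass, gene_field, chrom, start, _end, ref, alt = parts[:7]
        report.n_records += 1
        if vclass not in vocabulary:
            report.unknown_class_counts[vclass] += 1
            continue
        try:
            pos = int(start)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer position {start!r}") from exc
        for gene in gene_field.split(";"):
            gene = gene.strip()
            if gene:
                variants.append(
                    AnnotatedVariant(chrom, pos, ref, alt, gene, vclass)
                )
    return variants


def read_vcf_with_mapping(
    path: str | Path,
    mapping: dict[tuple[str, int, str, str], tuple[str, str]],
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
    report: EncodingReport | None = None,
) -> list[AnnotatedVariant]:
    """Read a plain VCF and annotate via a (chrom, pos, ref, alt) -> (gene, class) map.

    Records absent from the mapping or mapping to an out-of-vocabulary class
    are tallied, not silently dropped.  Genotype zygosity is ignored: each
    VCF record contributes one count.
    """
    if report is None:
        report = EncodingReport()
    variants: list[AnnotatedVariant] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            chrom, pos_s, _id, ref, alt = parts[:5]
            pos = int(pos_s)
            report.n_records += 1
            key = (chrom, pos, ref, alt)
            if key not in mapping:
                report.unknown_class_counts["<unmapped>"] += 1
                continue
            gene, vclass = mapping[key]
            if vclass not in vocabulary:
                report.unknown_class_counts[vclass] += 1
                continue
            variants.append(AnnotatedVariant(chrom, pos, ref, alt, gene, vclass))
    return variants


def build_gene_histogram(
    variants: Iterable[AnnotatedVariant],
    gene: str,
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
) -> np.ndarray:
    """Count one sample's variants on ``gene`` per vocabulary class."""
    counts = np.zeros(len(vocabulary), dtype=np.int64)
    for v in variants:
        if v.gene == gene and v.variant_class in vocabulary:
            counts[vocabulary.index(v.variant_class)] += 1
    return counts


def encode_sample(
    variants: Iterable[AnnotatedVariant],
    panel: GenePanel,
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
    report: EncodingReport | None = None,
) -> np.ndarray:
    """Encode one sample as a ``(len(vocabulary) + 2, len(panel))`` matrix.

    Column g is the feature vector of panel gene g: the class histogram
    followed by the gene's intolerance score and publication weight.  Score
    rows are set from the panel regardless of observed variants.  Variants on
    genes outside the panel are ignored and counted in ``report``.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    n_classes = len(vocabulary)
    mat = np.zeros((n_classes + 2, len(panel)), dtype=float)
    for v in variants:
        if v.gene not in panel:
            if report is not None:
                report.off_panel_count += 1
            continue
        if v.variant_class not in vocabulary:
            if report is not None:
                report.unknown_class_counts[v.variant_class] += 1
            continue
        mat[vocabulary.index(v.variant_class), panel.index(v.gene)] += 1
    mat[n_classes, :] = panel.intolerance
    mat[n_classes + 1, :] = panel.publication_weight
    return mat


@dataclass
class CohortDataset:
    """An encoded cohort: feature tensor, labels, and identifying metadata.

    ``tensor`` has shape ``(N, n_classes + 2, n_genes)``; ``labels`` are
    binary with 1 = case.
    """

    tensor: np.ndarray
    labels: np.ndarray
    sample_ids: tuple[str, ...]
    center_id: str
    panel: GenePanel
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be 3-D (N, features, genes)")
        n, d, g = self.tensor.shape
        if d != len(self.vocabulary) + 2:
            raise ValueError(
                f"feature dimension {d} != vocabulary size + 2 = "
                f"{len(self.vocabulary) + 2}"
            )
        if g != len(self.panel):
            raise ValueError(f"gene dimension {g} != panel size {len(self.panel)}")
        if self.labels.shape != (n,) or len(self.sample_ids) != n:
            raise ValueError("labels and sample_ids must have one entry per sample")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0 = control, 1 = case)")
        self.labels = self.labels.astype(np.int64)
        self.sample_ids = tuple(self.sample_ids)
        counts = self.tensor[:, : len(self.vocabulary), :]
        if np.any(counts < 0):
            raise ValueError("count coordinates must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_genes(self) -> int:
        return self.tensor.shape[2]

    def subset(self, indices: Sequence[int], center_id: str | None = None) -> "CohortDataset":
        idx = np.asarray(indices, dtype=int)
        return CohortDataset(
            tensor=self.tensor[idx],
            labels=self.labels[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            center_id=self.center_id if center_id is None else center_id,
            panel=self.panel,
            vocabulary=self.vocabulary,
        )

    def save(self, path: str | Path) -> None:
        """Write the cohort to an ``.npz`` container with embedded metadata."""
        meta = {
            "center_id": self.center_id,
            "sample_ids": list(self.sample_ids),
            "vocabulary": list(self.vocabulary.classes),
            "genes": list(self.panel.genes),
            "intolerance": self.panel.intolerance.tolist(),
            "publication_weight": self.panel.publication_weight.tolist(),
        }
        np.savez_compressed(
            path,
            tensor=self.tensor,
            labels=self.labels,
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CohortDataset":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            panel = GenePanel(
                tuple(meta["genes"]),
                np.array(meta["intolerance"]),
                np.array(meta["publication_weight"]),
            )
            return cls(
                tensor=data["tensor"],
                labels=data["labels"],
                sample_ids=tuple(meta["sample_ids"]),
                center_id=meta["center_id"],
                panel=panel,
                vocabulary=VariantClassVocabulary(tuple(meta["vocabulary"])),
            )


def concat_cohorts(cohorts: Sequence[CohortDataset], center_id: str = "pooled") -> CohortDataset:
    """Stack cohorts that share a panel and vocabulary into one dataset."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    first = cohorts[0]
    for c in cohorts[1:]:
        if c.panel.genes != first.panel.genes:
            raise ValueError("cohorts must share the same gene panel")
        if c.vocabulary.classes != first.vocabulary.classes:
            raise ValueError("cohorts must share the same vocabulary")
    return CohortDataset(
        tensor=np.concatenate([c.tensor for c in cohorts], axis=0),
        labels=np.concatenate([c.labels for c in cohorts]),
        sample_ids=tuple(s for c in cohorts for s in c.sample_ids),
        center_id=center_id,
        panel=first.panel,
        vocabulary=first.vocabulary,
    )


def encode_cohort(
    variant_lists: Sequence[Iterable[AnnotatedVariant]],
    labels: Sequence[int],
    panel: GenePanel,
    vocabulary: VariantClassVocabulary = DEFAULT_VOCABULARY,
    sample_ids: Sequence[str] | None = None,
    center_id: str = "",
    report: EncodingReport | None = None,
) -> CohortDataset:
    """Encode per-sample variant lists into a stacked cohort tensor."""
    if len(variant_lists) != len(labels):
        raise ValueError("one label per variant list required")
    if sample_ids is None:
        sample_ids = tuple(f"S{i:04d}" for i in range(len(labels)))
    mats = [
        encode_sample(vl, panel, vocabulary, report=report) for vl in variant_lists
    ]
    tensor = (
        np.stack(mats, axis=0)
        if mats
        else np.zeros((0, len(vocabulary) + 2, len(panel)))
    )
    return CohortDataset(
        tensor=tensor,
        labels=np.asarray(labels),
        sample_ids=tuple(sample_ids),
        center_id=center_id,
        panel=panel,
        vocabulary=vocabulary,
    )
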