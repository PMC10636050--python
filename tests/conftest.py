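import numpy as np
import pytest

from fedgi.encoding import (
    AnnotatedVariant,
    CohortDataset,
    GenePanel,
    VariantClassVocabulary,
)


@pytest.fixture
def vocab():
    return VariantClassVocabulary()


@pytest.fixture
def small_panel():
    return GenePanel(
        genes=("NOD2", "IL23R", "ATG16L1"),
        intolerance=np.array([-1.5, 0.3, 0.8]),
        publication_weight=np.array([120.0, 45.0, 30.0]),
    )


@pytest.fixture
def toy_variants():
    """Five variants: 2 exonic + 1 splicing on NOD2, 1 intronic on IL23R, 1 off-panel."""
    return [
        AnnotatedVariant("16", 50745926, "C", "T", "NOD2", "exonic"),
        AnnotatedVariant("16", 50745930, "G", "A", "NOD2", "exonic"),
        AnnotatedVariant("16", 50746000, "A", "G", "NOD2", "splicing"),
        AnnotatedVariant("1", 67705958, "G", "A", "IL23R", "intronic"),
        AnnotatedVariant("2", 1000, "T", "C", "OFFPANEL1", "exonic"),
    ]


def make_cohort(
    n: int = 20,
    n_genes: int = 4,
    seed: int = 0,
    separable: bool = False,
    labels: np.ndarray | None = None,
    center_id: str = "test",
) -> CohortDataset:
    """Small random cohort; ``separable`` plants an obvious case signal."""
    rng = np.random.default_rng(seed)
    panel = GenePanel(
        genes=tuple(f"G{i}" for i in range(n_genes)),
        intolerance=rng.normal(size=n_genes),
        publication_weight=rng.gamma(2.0, 1.0, size=n_genes),
    )
    if labels is None:
        labels = (np.arange(n) % 2 == 0).astype(int)
    tensor = np.zeros((n, 11, n_genes))
    tensor[:, :9, :] = rng.poisson(1.0, size=(n, 9, n_genes))
    if separable:
        tensor[labels == 1, 0, 0] += 8  # strong exonic burden on gene 0 for cases
    tensor[:, 9, :] = panel.intolerance
    tensor[:, 10, :] = panel.publication_weight
    return CohortDataset(
        tensor=tensor,
        labels=np.asarray(labels),
        sample_ids=tuple(f"{center_id}_S{i}" for i in range(n)),
        center_id=center_id,
        panel=panel,
    )


@pytest.fixture
def separable_cohort():
    return make_cohort(n=20, separable=True, seed=3)
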