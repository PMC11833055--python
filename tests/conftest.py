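import numpy as np
import pandas as pd
import pytest

from transcord import SharedGeneMatrix, StudyProfile


def random_profile(rng: np.random.Generator, label: str, genes) -> StudyProfile:
    """A study profile with Gaussian log2FCs and uniform p-values."""
    genes = list(genes)
    data = pd.DataFrame(
        {
            "log2fc": rng.normal(0.0, 2.0, size=len(genes)),
            "p_value": rng.uniform(0.0, 1.0, size=len(genes)),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return StudyProfile(label, data)


def random_shared_matrix(
    rng: np.random.Generator, n_genes: int, labels
) -> SharedGeneMatrix:
    genes = [f"g{i:04d}" for i in range(n_genes)]
    fc = pd.DataFrame(
        rng.normal(0.0, 2.0, size=(n_genes, len(labels))),
        index=pd.Index(genes, name="gene_id"),
        columns=list(labels),
    )
    return SharedGeneMatrix(fc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
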