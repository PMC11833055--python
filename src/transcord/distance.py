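"""The cross-model transcriptome distance S and model similarity ranking.

For two studies a, b sharing n genes, the distance is the L1 norm of the
difference of their log2 fold-change vectors:

    S(a, b) = sum over shared genes g of |FC_a(g) - FC_b(g)|

with FC the log2 fold change.  Smaller S means the two models perturb the
shared transcriptome more similarly.  S is a true metric on fold-change
vectors (non-negative, zero iff identical, symmetric, triangle
inequality), so ranking candidate models by their S to a reference model
is well-posed.

All shared genes contribute — there is no significance filtering or
winsorizing before the sum — so S reflects the full shared profile, not
only the extreme genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import SharedGeneMatrix

__all__ = [
    "DistanceResult",
    "DistanceMatrix",
    "l1_fc_distance",
    "distance_matrix",
    "rank_by_similarity",
    "gene_contributions",
]


@dataclass(frozen=True)
class DistanceResult:
    """S distance between one study pair over their shared genes."""

    study_a: str
    study_b: str
    s_value: float
    n_genes: int

    @property
    def per_gene(self) -> float:
        """Mean |Δlog2FC| per shared gene — comparable across matrices of
        different size, unlike the raw sum."""
        return self.s_value / self.n_genes


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise S values with zero diagonal."""

    values: pd.DataFrame = field(repr=False)
    n_genes: int = 0

    @property
    def labels(self) -> list[str]:
        return list(self.values.columns)

    def s(self, a: str, b: str) -> float:
        for lab in (a, b):
            if lab not in self.values.columns:
                raise KeyError(f"unknown study label {lab!r}; have {self.labels}")
        return float(self.values.loc[a, b])


def l1_fc_distance(matrix: SharedGeneMatrix, a: str, b: str) -> DistanceResult:
    """Compute S(a, b) = Σ|fc[g, a] − fc[g, b]| over the shared genes."""
    if matrix.n_genes == 0:
        raise ValueError("distance undefined on an empty shared-gene matrix")
    delta = matrix.column(a) - matrix.column(b)
    return DistanceResult(a, b, float(np.abs(delta).sum()), matrix.n_genes)


def distance_matrix(matrix: SharedGeneMatrix) -> DistanceMatrix:
    """All pairwise S values for the studies in a shared-gene matrix."""
    labels = matrix.studies
    if len(labels) < 2:
        raise ValueError("need at least two studies for a distance matrix")
    vals = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            s = l1_fc_distance(matrix, a, b).s_value
            vals.loc[a, b] = s
            vals.loc[b, a] = s
    return DistanceMatrix(vals, matrix.n_genes)


def rank_by_similarity(dm: DistanceMatrix, reference: str) -> list[tuple[str, float]]:
    """Non-reference studies ordered by ascending S to the reference.

    The nearest model (smallest S) comes first; ties break
    lexicographically on the label.
    """
    if reference not in dm.labels:
        raise KeyError(f"unknown reference label {reference!r}; have {dm.labels}")
    others = [lab for lab in dm.labels if lab != reference]
    return sorted(
        ((lab, dm.s(lab, reference)) for lab in others),
        key=lambda t: (t[1], t[0]),
    )


def gene_contributions(
    matrix: SharedGeneMatrix, a: str, b: str, top_k: int
) -> list[tuple[str, float]]:
    """The top_k genes contributing most |Δlog2FC| to S(a, b).

    Ties break lexicographically; the contributions over *all* genes sum
    to S(a, b), so this decomposes the distance gene by gene.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    delta = np.abs(matrix.column(a) - matrix.column(b))
    order = sorted(zip(matrix.genes, delta), key=lambda t: (-t[1], t[0]))
    return [(g, float(d)) for g, d in order[:top_k]]
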