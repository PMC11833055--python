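"""DEG classification, three-way set partitioning, and heatmap gene selection.

A gene is called differentially expressed when its raw p-value falls below
the significance threshold *and* its linear fold change (2**log2fc) lies
strictly outside the [fc_down, fc_up] band.  The default band is the
widely used 1.5-fold rule; the heatmap selection uses a stricter 2-fold
band.  All inequalities are strict, so genes sitting exactly on a
threshold are not called.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .profiles import GeneEffect, SharedGeneMatrix, StudyProfile

__all__ = [
    "Direction",
    "DegCriteria",
    "DegCall",
    "VennPartition",
    "classify_gene",
    "deg_set",
    "venn_partition",
    "select_heatmap_genes",
]


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class DegCriteria:
    """Significance thresholds on raw p-value and linear fold change.

    ``fc_down`` defaults to ``1/fc_up`` (0.6667 for the default 1.5-fold
    band), which is symmetric in log space.  Pass ``fc_down=0.667``
    explicitly to reproduce a rounded down-regulation bound; on real data
    the difference can move genes whose fold change lies between 0.6667
    and 0.667.
    """

    p_threshold: float = 0.05
    fc_up: float = 1.5
    fc_down: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError(f"p_threshold must lie in (0, 1], got {self.p_threshold}")
        if not self.fc_up > 1.0:
            raise ValueError(f"fc_up must exceed 1, got {self.fc_up}")
        if self.fc_down is None:
            object.__setattr__(self, "fc_down", 1.0 / self.fc_up)
        if not (0.0 < self.fc_down < 1.0):
            raise ValueError(f"fc_down must lie in (0, 1), got {self.fc_down}")


#: The 2-fold band used to pick genes for the cross-model heatmap.
HEATMAP_CRITERIA = DegCriteria(p_threshold=0.05, fc_up=2.0, fc_down=0.5)


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    direction: Direction


def classify_gene(effect: GeneEffect, criteria: DegCriteria = DegCriteria()) -> DegCall:
    """Classify one gene as up, down, or not significant.

    Up iff p < p_threshold and 2**log2fc > fc_up; down iff p < p_threshold
    and 2**log2fc < fc_down; otherwise not significant.  Strictly.
    """
    effect = GeneEffect(*effect).validate()
    fc = 2.0 ** effect.log2fc
    if effect.p_value < criteria.p_threshold:
        if fc > criteria.fc_up:
            return DegCall(effect.gene_id, Direction.UP)
        if fc < criteria.fc_down:
            return DegCall(effect.gene_id, Direction.DOWN)
    return DegCall(effect.gene_id, Direction.NOT_SIGNIFICANT)


def deg_set(profile: StudyProfile, criteria: DegCriteria = DegCriteria()) -> set[str]:
    """The set of gene ids called differentially expressed in a profile."""
    return {
        e.gene_id
        for e in profile.effects()
        if classify_gene(e, criteria).direction is not Direction.NOT_SIGNIFICANT
    }


@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint regions of a three-set overlap.

    Region keys: ``a_only``, ``b_only``, ``c_only``, ``ab``, ``ac``,
    ``bc``, ``abc``.  Pairwise keys exclude the triple: ``ab`` holds genes
    in A and B but not C.
    """

    regions: Mapping[str, frozenset[str]]

    _KEYS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")

    def __post_init__(self) -> None:
        if set(self.regions) != set(self._KEYS):
            raise ValueError(f"regions must have keys {self._KEYS}")

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in self._KEYS}

    def set_total(self, which: str) -> int:
        """Reconstruct an input set's cardinality from its covering regions."""
        cover = {
            "a": ("a_only", "ab", "ac", "abc"),
            "b": ("b_only", "ab", "bc", "abc"),
            "c": ("c_only", "ac", "bc", "abc"),
        }[which]
        return sum(len(self.regions[k]) for k in cover)


def venn_partition(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> VennPartition:
    """Partition three gene sets into the 7 disjoint Venn regions."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return VennPartition(
        {
            "abc": frozenset(abc),
            "ab": frozenset((a & b) - abc),
            "ac": frozenset((a & c) - abc),
            "bc": frozenset((b & c) - abc),
            "a_only": frozenset(a - b - c),
            "b_only": frozenset(b - a - c),
            "c_only": frozenset(c - a - b),
        }
    )


def select_heatmap_genes(
    matrix: SharedGeneMatrix,
    profiles: Sequence[StudyProfile],
    criteria: DegCriteria = HEATMAP_CRITERIA,
) -> list[str]:
    """Genes common to every study and strongly differential in at least one.

    Restricts to ``matrix.genes`` (the genes detected in all studies) and
    keeps those classified up or down under ``criteria`` (by default the
    2-fold band with p < 0.05) in one or more of the supplied profiles.
    Returned in lexicographic order.
    """
    by_label = {p.label: p for p in profiles}
    missing = [s for s in matrix.studies if s not in by_label]
    if missing:
        raise ValueError(f"no profile supplied for matrix studies: {missing}")
    selected = []
    for gene in matrix.genes:
        for study in matrix.studies:
            call = classify_gene(by_label[study].effect(gene), criteria)
            if call.direction is not Direction.NOT_SIGNIFICANT:
                selected.append(gene)
                break
    return selected
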