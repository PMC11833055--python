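"""Per-study differential-expression tables and the shared-gene matrix.

A *study profile* is one model's gene-level differential-expression result
set: for every gene, a log2 fold change (treated vs. control) and a raw
p-value.  Profiles from several studies are harmonised onto the exact
intersection of their gene sets, yielding a shared-gene log2FC matrix on
which the cross-model distance statistic is computed.

Gene matching is exact, case-sensitive string equality: the intended use
case compares mouse studies reporting the same gene symbols, so no
ortholog or alias mapping is attempted.  A gene missing (or with a missing
value) in any study is excluded from the shared matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneEffect",
    "StudyProfile",
    "SharedGeneMatrix",
    "ProfileFormatError",
    "ProfileValidationError",
    "EmptyIntersectionError",
    "read_profile",
    "write_profile",
    "intersect_profiles",
]


class ProfileFormatError(ValueError):
    """A DEG table is structurally malformed (e.g. a required column is absent)."""


class ProfileValidationError(ValueError):
    """A DEG table violates a content invariant (e.g. duplicate gene ids)."""


class EmptyIntersectionError(ValueError):
    """No gene is shared by every profile; the distance statistic is undefined."""


class GeneEffect(NamedTuple):
    """One gene's differential-expression result in one study."""

    gene_id: str
    log2fc: float
    p_value: float

    def validate(self) -> "GeneEffect":
        if not self.gene_id:
            raise ProfileValidationError("gene_id must be a non-empty string")
        if not np.isfinite(self.log2fc):
            raise ProfileValidationError(
                f"log2fc for gene {self.gene_id!r} must be finite, got {self.log2fc}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ProfileValidationError(
                f"p_value for gene {self.gene_id!r} must lie in [0, 1], got {self.p_value}"
            )
        return self


@dataclass(frozen=True)
class StudyProfile:
    """A labelled collection of per-gene effects with unique gene ids.

    ``data`` is a DataFrame indexed by ``gene_id`` with float columns
    ``log2fc`` and ``p_value``; rows are kept in lexicographic gene order.
    """

    label: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.label:
            raise ProfileValidationError("profile label must be non-empty")
        df = self.data
        missing = {"log2fc", "p_value"} - set(df.columns)
        if missing:
            raise ProfileFormatError(f"profile data lacks columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ProfileValidationError(
                f"duplicate gene_id {dup!r} in profile {self.label!r}"
            )
        if not df.index.is_monotonic_increasing:
            object.__setattr__(self, "data", df.sort_index())

    @classmethod
    def from_effects(cls, label: str, effects: Iterable[GeneEffect]) -> "StudyProfile":
        effects = [GeneEffect(*e).validate() for e in effects]
        df = pd.DataFrame(
            {
                "log2fc": [e.log2fc for e in effects],
                "p_value": [e.p_value for e in effects],
            },
            index=pd.Index([e.gene_id for e in effects], name="gene_id"),
            dtype=float,
        )
        return cls(label, df)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def effects(self) -> list[GeneEffect]:
        return [
            GeneEffect(g, float(r.log2fc), float(r.p_value))
            for g, r in self.data.iterrows()
        ]

    def effect(self, gene_id: str) -> GeneEffect:
        row = self.data.loc[gene_id]
        return GeneEffect(gene_id, float(row["log2fc"]), float(row["p_value"]))

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


@dataclass(frozen=True)
class SharedGeneMatrix:
    """log2 fold changes over the genes common to every study.

    ``fc`` is genes × studies; the row index is the exact intersection of
    the source profiles' gene sets in lexicographic order, and columns
    follow the order in which the profiles were supplied.
    """

    fc: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.fc
        if df.index.has_duplicates:
            raise ProfileValidationError("duplicate gene ids in shared matrix")
        if df.columns.has_duplicates:
            raise ProfileValidationError("duplicate study labels in shared matrix")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ProfileValidationError("shared matrix contains non-finite log2fc")
        if not df.index.is_monotonic_increasing:
            object.__setattr__(self, "fc", df.sort_index())

    @property
    def genes(self) -> list[str]:
        return list(self.fc.index)

    @property
    def studies(self) -> list[str]:
        return list(self.fc.columns)

    @property
    def n_genes(self) -> int:
        return len(self.fc)

    def column(self, label: str) -> np.ndarray:
        if label not in self.fc.columns:
            raise KeyError(f"unknown study label {label!r}; have {self.studies}")
        return self.fc[label].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.fc.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SharedGeneMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(float))


def read_profile(
    path: str | Path,
    label: str,
    *,
    sep: str = "\t",
    gene_col: str = "gene_id",
    fc_col: str = "log2fc",
    p_col: str = "pvalue",
) -> StudyProfile:
    """Read a delimited DEG table into a :class:`StudyProfile`.

    The table must carry a header naming a gene column, a log2 fold-change
    column and a p-value column (names remappable).  Rows whose log2fc or
    p-value is missing or non-finite are dropped and counted in a warning
    log entry.  A duplicate gene id raises :class:`ProfileValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (gene_col, fc_col, p_col) if c not in df.columns]
    if missing:
        raise ProfileFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    df = df[[gene_col, fc_col, p_col]].rename(
        columns={gene_col: "gene_id", fc_col: "log2fc", p_col: "p_value"}
    )
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    keep = np.isfinite(df["log2fc"]) & np.isfinite(df["p_value"])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) with missing/non-finite log2fc or p-value",
            path,
            n_dropped,
        )
    df = df.loc[keep]
    bad_p = df.loc[(df["p_value"] < 0) | (df["p_value"] > 1), "gene_id"]
    if len(bad_p):
        raise ProfileValidationError(
            f"{path}: p-value outside [0, 1] for gene {bad_p.iloc[0]!r}"
        )
    dup = df.loc[df["gene_id"].duplicated(), "gene_id"]
    if len(dup):
        raise ProfileValidationError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    data = df.set_index("gene_id").astype(float)
    return StudyProfile(label, data)


def write_profile(profile: StudyProfile, path: str | Path, *, sep: str = "\t") -> None:
    """Write a profile as a delimited DEG table (columns gene_id, log2fc, pvalue)."""
    out = profile.data.rename(columns={"p_value": "pvalue"})
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)


def intersect_profiles(profiles: Sequence[StudyProfile]) -> SharedGeneMatrix:
    """Align profiles on the exact intersection of their gene sets.

    Column order follows the input order; rows are the shared genes in
    lexicographic order.  An empty intersection raises
    :class:`EmptyIntersectionError` because the downstream distance is
    undefined on zero genes.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to intersect")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ProfileValidationError(f"profile labels must be distinct, got {labels}")
    shared: set[str] = set(profiles[0].genes)
    for p in profiles[1:]:
        shared &= set(p.genes)
    if not shared:
        raise EmptyIntersectionError(
            f"no gene is shared by all {len(profiles)} profiles; distance undefined"
        )
    genes = sorted(shared)
    fc = pd.DataFrame(
        {p.label: p.data.loc[genes, "log2fc"].to_numpy(dtype=float) for p in profiles},
        index=pd.Index(genes, name="gene_id"),
    )
    return SharedGeneMatrix(fc)
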