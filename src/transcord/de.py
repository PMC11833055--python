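"""Minimal two-group differential-expression engine for count matrices.

Turns a gene × sample count matrix plus a two-group design into a
:class:`~transcord.profiles.StudyProfile`: per-gene log2 fold change from
pseudocounted CPM group means, and a per-gene p-value from a two-sided
Welch t-test on log2(CPM + pseudocount).

This is intentionally not a reimplementation of negative-binomial
shrinkage estimators (DESeq2-style): the engine exists to supply a
calibrated, dependency-light significance source for synthetic counts,
and real studies are expected to enter the pipeline as precomputed DEG
tables.  The pseudocount (default 0.5) is the main small-count bias knob:
it bounds fold changes for genes with zeros and stabilises the log
transform's variance at low expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import StudyProfile

__all__ = [
    "CountMatrix",
    "GroupDesign",
    "cpm_normalize",
    "estimate_log2fc",
    "welch_de",
    "build_profile",
    "bh_adjust",
]

CONTROL = "control"
TREATED = "treated"


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer counts, genes × samples, unique gene ids."""

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        arr = df.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", df.round().astype(np.int64))

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment with exactly two groups of >= 2 samples."""

    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != {CONTROL, TREATED}:
            raise ValueError(
                f"design must use exactly the groups {{{CONTROL!r}, {TREATED!r}}}, got {sorted(labels)}"
            )
        for g in (CONTROL, TREATED):
            n = sum(1 for v in self.groups.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} sample(s); need at least 2")

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["sample"].astype(str), df["group"].astype(str))))


def cpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Counts-per-million: scale each sample's column to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return cm.counts / totals * 1e6


def _group_cpm(
    cm: CountMatrix, design: GroupDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    unassigned = set(cm.samples) - set(design.groups)
    if unassigned:
        raise ValueError(f"samples not assigned to a group: {sorted(unassigned)}")
    cpm = cpm_normalize(cm)
    return cpm[design.samples_in(TREATED)], cpm[design.samples_in(CONTROL)]


def estimate_log2fc(
    cm: CountMatrix, design: GroupDesign, pseudocount: float = 0.5
) -> pd.Series:
    """Per-gene log2((mean treated CPM + pc) / (mean control CPM + pc))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    treated, control = _group_cpm(cm, design)
    return pd.Series(
        np.log2((treated.mean(axis=1) + pseudocount) / (control.mean(axis=1) + pseudocount)),
        index=cm.counts.index,
        name="log2fc",
    )


def welch_de(
    cm: CountMatrix, design: GroupDesign, pseudocount: float = 0.5
) -> pd.Series:
    """Two-sided Welch t-test on log2(CPM + pc), per gene.

    Degenerate genes with zero variance in both groups get p = 1 when the
    group means are equal (no evidence at all) and p = 0 when they differ
    (a noiseless shift).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    treated, control = _group_cpm(cm, design)
    x = np.log2(treated.to_numpy(dtype=float) + pseudocount)
    y = np.log2(control.to_numpy(dtype=float) + pseudocount)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; their
        # p-values are overwritten by the degenerate rules below
        warnings.filterwarnings("ignore", message=".*Precision loss occurred.*")
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    means_equal = x.mean(axis=1) == y.mean(axis=1)
    p[degenerate & means_equal] = 1.0
    p[degenerate & ~means_equal] = 0.0
    return pd.Series(p, index=cm.counts.index, name="p_value")


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjusted p-values (optional; raw p is the default
    input to DEG calling)."""
    from scipy.stats import false_discovery_control

    return pd.Series(false_discovery_control(p.to_numpy()), index=p.index, name="p_adj")


def build_profile(
    cm: CountMatrix,
    design: GroupDesign,
    label: str,
    pseudocount: float = 0.5,
    adjust: bool = False,
) -> StudyProfile:
    """Run the engine and package the result as a StudyProfile.

    Gene order in the profile is lexicographic regardless of the count
    matrix's row order.  With ``adjust=True`` the p-values are
    BH-adjusted before entering the profile.
    """
    lfc = estimate_log2fc(cm, design, pseudocount)
    p = welch_de(cm, design, pseudocount)
    if adjust:
        p = bh_adjust(p)
    data = pd.DataFrame({"log2fc": lfc, "p_value": p}).sort_index()
    data.index.name = "gene_id"
    return StudyProfile(label, data)
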