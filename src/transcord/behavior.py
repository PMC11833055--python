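"""Rodent behavioral index formulas from raw event inputs.

Implements the standard scoring formulas for three assays:

* novel object recognition — recognition index = TN/(TN+TF) x 100%, with
  TN and TF the times spent exploring the novel and familiar object;
* Y-maze — spontaneous alternation % = alternations/(entries - 2) x 100%,
  an alternation being entry into three different arms in turn;
* elevated plus maze — open-arm entry % and open-arm time %.

All indices are on the 0-100 percent scale and are invariant under a
uniform rescaling of the time unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ExplorationTimes",
    "ArmEntrySequence",
    "EpmCounts",
    "UndefinedIndexError",
    "recognition_index",
    "count_alternations",
    "spontaneous_alternation_pct",
    "open_arm_entry_pct",
    "open_arm_time_pct",
]


class UndefinedIndexError(ValueError):
    """The index's denominator is zero; the score is undefined."""


@dataclass(frozen=True)
class ExplorationTimes:
    """Seconds spent exploring the novel (tn) and familiar (tf) object."""

    tn: float
    tf: float

    def __post_init__(self) -> None:
        if self.tn < 0 or self.tf < 0:
            raise ValueError("exploration times must be non-negative")


@dataclass(frozen=True)
class ArmEntrySequence:
    """Ordered arm-entry events in a three-arm maze."""

    entries: tuple[str, ...]
    alphabet: frozenset[str] = frozenset({"A", "B", "C"})

    def __init__(
        self, entries: Sequence[str], alphabet: Sequence[str] = ("A", "B", "C")
    ) -> None:
        alphabet = frozenset(alphabet)
        if len(alphabet) != 3:
            raise ValueError(f"a Y-maze has 3 arms, got alphabet {sorted(alphabet)}")
        bad = [e for e in entries if e not in alphabet]
        if bad:
            raise ValueError(f"arm label(s) {bad} not in alphabet {sorted(alphabet)}")
        object.__setattr__(self, "entries", tuple(entries))
        object.__setattr__(self, "alphabet", alphabet)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EpmCounts:
    """Elevated-plus-maze event counts and arm times (seconds)."""

    open_entries: int
    closed_entries: int
    open_time: float = 0.0
    total_time: float = 0.0

    def __post_init__(self) -> None:
        if self.open_entries < 0 or self.closed_entries < 0:
            raise ValueError("entry counts must be non-negative")
        if not (0.0 <= self.open_time <= self.total_time or self.total_time == 0):
            raise ValueError("need 0 <= open_time <= total_time")


def recognition_index(t: ExplorationTimes) -> float:
    """Novel-object preference: 100 * TN / (TN + TF).

    50 means no preference; above 50 means the animal preferred the novel
    object, the signature of intact recognition memory.
    """
    total = t.tn + t.tf
    if total == 0:
        raise UndefinedIndexError("no exploration time recorded (TN + TF = 0)")
    return 100.0 * t.tn / total


def count_alternations(seq: ArmEntrySequence) -> int:
    """Number of spontaneous alternations in an arm-entry sequence.

    An alternation is a run of three consecutive entries into three
    different arms.  Windows overlap: in A,B,C,A,B,C every one of the 4
    length-3 windows alternates.  Overlapping counting is what makes the
    conventional (entries - 2) denominator attainable at 100%.
    """
    e = seq.entries
    return sum(1 for i in range(len(e) - 2) if len({e[i], e[i + 1], e[i + 2]}) == 3)


def spontaneous_alternation_pct(seq: ArmEntrySequence) -> float:
    """Y-maze working-memory score: 100 * alternations / (entries - 2)."""
    if len(seq) < 3:
        raise UndefinedIndexError(
            f"need at least 3 arm entries for the alternation index, got {len(seq)}"
        )
    return 100.0 * count_alternations(seq) / (len(seq) - 2)


def open_arm_entry_pct(e: EpmCounts) -> float:
    """Percent of arm entries into the open arms (anxiety-related)."""
    total = e.open_entries + e.closed_entries
    if total == 0:
        raise UndefinedIndexError("no arm entries recorded")
    return 100.0 * e.open_entries / total


def open_arm_time_pct(e: EpmCounts) -> float:
    """Percent of session time spent in the open arms."""
    if e.total_time == 0:
        raise UndefinedIndexError("total_time is zero")
    return 100.0 * e.open_time / e.total_time
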