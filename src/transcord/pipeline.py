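"""End-to-end convenience: simulate a panel, run DE, and rank the models."""

from __future__ import annotations

from dataclasses import dataclass, field

from .de import build_profile
from .distance import DistanceMatrix, distance_matrix, rank_by_similarity
from .profiles import StudyProfile, intersect_profiles
from .simulate import EffectTruth, SimConfig, simulate_panel

__all__ = ["PanelResult", "run_panel"]


@dataclass(frozen=True)
class PanelResult:
    """Everything the end-to-end run produced, ground truth included."""

    profiles: dict[str, StudyProfile] = field(repr=False)
    distances: DistanceMatrix
    ranking: list[tuple[str, float]]
    truth: EffectTruth = field(repr=False)


def run_panel(config: SimConfig) -> PanelResult:
    """Simulate every study, estimate effects, and rank models by S distance.

    Runs the full chain: NB count simulation per study, the two-group DE
    engine, shared-gene intersection, the pairwise L1 fold-change
    distance matrix, and ascending-distance ranking of the comparison
    models against the reference.
    """
    studies, truth = simulate_panel(config)
    profiles = [
        build_profile(cm, design, label) for label, (cm, design) in studies.items()
    ]
    matrix = intersect_profiles(profiles)
    dm = distance_matrix(matrix)
    ranking = rank_by_similarity(dm, config.reference)
    return PanelResult(
        profiles={p.label: p for p in profiles},
        distances=dm,
        ranking=ranking,
        truth=truth,
    )
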