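"""DEG calling thresholds, Venn partitioning, heatmap gene selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transcord import (
    HEATMAP_CRITERIA,
    DegCriteria,
    Direction,
    GeneEffect,
    classify_gene,
    deg_set,
    intersect_profiles,
    select_heatmap_genes,
    venn_partition,
)

from conftest import random_profile


def brute_force_direction(log2fc, p, crit):
    """Independent re-statement of the calling rule, scalar arithmetic only."""
    fc = math.pow(2.0, log2fc)
    if p < crit.p_threshold and fc > crit.fc_up:
        return Direction.UP
    if p < crit.p_threshold and fc < crit.fc_down:
        return Direction.DOWN
    return Direction.NOT_SIGNIFICANT


@pytest.mark.parametrize(
    "log2fc,p,expected",
    [
        (1.0, 0.01, Direction.UP),  # FC 2.0 > 1.5, significant
        (1.0, 0.20, Direction.NOT_SIGNIFICANT),  # p fails
        (math.log2(1.5), 0.01, Direction.NOT_SIGNIFICANT),  # exactly on fc_up
        (-1.0, 0.01, Direction.DOWN),  # FC 0.5 < 2/3
        (-0.5, 0.01, Direction.NOT_SIGNIFICANT),  # FC ~0.707 inside band
        (2.0, 0.05, Direction.NOT_SIGNIFICANT),  # exactly on p threshold
    ],
)
def test_classify_gene_default_criteria(log2fc, p, expected):
    assert classify_gene(GeneEffect("g", log2fc, p)).direction is expected


def test_exact_fc_down_boundary_excluded():
    crit = DegCriteria()
    assert crit.fc_down == pytest.approx(2.0 / 3.0)
    eff = GeneEffect("g", math.log2(crit.fc_down), 0.01)
    assert classify_gene(eff, crit).direction is Direction.NOT_SIGNIFICANT


def test_literal_rounded_down_bound():
    """fc_down=0.667 sits above 2/3, so a gene between the two bounds flips."""
    crit = DegCriteria(fc_down=0.667)
    between = GeneEffect("g", math.log2(0.6668), 0.01)  # 2/3 < FC < 0.667
    assert classify_gene(between, crit).direction is Direction.DOWN
    assert classify_gene(between, DegCriteria()).direction is Direction.NOT_SIGNIFICANT


def test_invalid_criteria_rejected():
    for kwargs in ({"p_threshold": 0.0}, {"fc_up": 1.0}, {"fc_down": 1.2}):
        with pytest.raises(ValueError):
            DegCriteria(**kwargs)


def test_deg_set_matches_brute_force_filter(rng):
    prof = random_profile(rng, "A", [f"g{i:03d}" for i in range(200)])
    crit = DegCriteria()
    expected = set()
    for e in prof.effects():
        if brute_force_direction(e.log2fc, e.p_value, crit) is not Direction.NOT_SIGNIFICANT:
            expected.add(e.gene_id)
    assert deg_set(prof, crit) == expected
    assert expected  # the random panel must actually exercise both branches
    assert len(expected) < 200


def test_deg_set_monotone_under_threshold_tightening(rng):
    """Lowering p or widening the FC band can only shrink the DEG set."""
    prof = random_profile(rng, "A", [f"g{i:03d}" for i in range(300)])
    loose = deg_set(prof, DegCriteria(p_threshold=0.05, fc_up=1.5))
    assert deg_set(prof, DegCriteria(p_threshold=0.01, fc_up=1.5)) <= loose
    assert deg_set(prof, DegCriteria(p_threshold=0.05, fc_up=2.0)) <= loose


def brute_force_venn(a, b, c):
    """Per-element membership enumeration over the union."""
    regions = {k: set() for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")}
    for g in a | b | c:
        key = "".join(lab for lab, s in zip("abc", (a, b, c)) if g in s)
        regions[{"a": "a_only", "b": "b_only", "c": "c_only"}.get(key, key)].add(g)
    return regions


def test_venn_example():
    part = venn_partition({"1", "2", "3"}, {"2", "3", "4"}, {"3"})
    assert part.counts == {
        "a_only": 1, "b_only": 1, "c_only": 0, "ab": 1, "ac": 0, "bc": 0, "abc": 1,
    }
    assert part.regions["abc"] == {"3"}
    assert part.regions["ab"] == {"2"}


@pytest.mark.parametrize(
    "a,b,c",
    [
        ({"x"}, {"y"}, {"z"}),  # pairwise disjoint
        ({"x", "y"}, {"x", "y"}, {"x", "y"}),  # identical
        (set(), set(), set()),  # empty allowed
    ],
)
def test_venn_degenerate_configurations(a, b, c):
    part = venn_partition(a, b, c)
    assert {k: set(v) for k, v in part.regions.items()} == brute_force_venn(a, b, c)


@settings(deadline=None, derandomize=True, max_examples=80)
@given(
    a=st.sets(st.integers(0, 30).map(str), max_size=15),
    b=st.sets(st.integers(0, 30).map(str), max_size=15),
    c=st.sets(st.integers(0, 30).map(str), max_size=15),
)
def test_venn_partition_properties(a, b, c):
    """Regions are disjoint, cover the union, reconstruct each set's size,
    and permute consistently under relabeling."""
    part = venn_partition(a, b, c)
    regions = list(part.regions.values())
    union = set().union(*regions)
    assert union == a | b | c
    assert sum(len(r) for r in regions) == len(union)  # disjointness
    assert part.set_total("a") == len(a)
    assert part.set_total("b") == len(b)
    assert part.set_total("c") == len(c)
    swapped = venn_partition(b, a, c)
    assert swapped.regions["a_only"] == part.regions["b_only"]
    assert swapped.regions["ab"] == part.regions["ab"]
    assert swapped.regions["ac"] == part.regions["bc"]
    assert swapped.regions["abc"] == part.regions["abc"]


def test_heatmap_selection_single_gene_cases():
    import transcord as tc

    strong = tc.StudyProfile.from_effects("A", [("g1", 1.5, 0.01), ("g2", 0.1, 0.9)])
    quiet = tc.StudyProfile.from_effects("B", [("g1", 0.0, 0.9), ("g2", 0.0, 0.9)])
    m = intersect_profiles([strong, quiet])
    # g1: FC ~2.83 > 2 in one model -> selected; g2: ns everywhere -> dropped
    assert select_heatmap_genes(m, [strong, quiet]) == ["g1"]


def test_heatmap_selection_requires_all_profiles():
    import transcord as tc

    a = tc.StudyProfile.from_effects("A", [("g1", 1.5, 0.01)])
    b = tc.StudyProfile.from_effects("B", [("g1", 0.0, 0.9)])
    m = intersect_profiles([a, b])
    with pytest.raises(ValueError, match="B"):
        select_heatmap_genes(m, [a])


def test_heatmap_selection_matches_brute_force(rng):
    genes = [f"g{i:03d}" for i in range(300)]
    profs = [random_profile(rng, lab, genes) for lab in ("CS", "HU", "FL")]
    m = intersect_profiles(profs)
    selected = select_heatmap_genes(m, profs)
    expected = []
    for g in sorted(genes):
        hit = False
        for p in profs:
            e = p.effect(g)
            if brute_force_direction(e.log2fc, e.p_value, HEATMAP_CRITERIA) is not Direction.NOT_SIGNIFICANT:
                hit = True
        if hit:
            expected.append(g)
    assert selected == expected
    assert set(selected) <= set(m.genes)
    assert 0 < len(selected) < len(genes)
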