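"""HOR assembly: unit normalization, rotation merging, scoring, naming, projection."""

import pytest

from centrohor.decompose import Block
from centrohor.hors import (
    annotate_monomer_sequence,
    hor_coverage,
    merge_to_hors,
    normalize_unit,
    project_annotation,
    score_and_rank,
    select_threshold,
)
from centrohor.htrm import run_htrm


@pytest.mark.parametrize(
    "unit,expected",
    [
        ((4, 1, 2, 3), (1, 2, 3, 4)),
        ((3, 4, 1, 2), (1, 2, 3, 4)),
        ((2, 3, 4, 1), (1, 2, 3, 4)),
        ((1, 2, 3, 4), (1, 2, 3, 4)),
        ((2, 1, 2, 1), (1, 2, 1, 2)),
    ],
)
def test_normalize_unit_rotations(unit, expected):
    assert normalize_unit(unit) == expected


def test_all_rotations_map_to_same_canonical_form():
    unit = (5, 1, 4, 2, 3)
    forms = {normalize_unit(unit[i:] + unit[:i]) for i in range(5)}
    assert len(forms) == 1


def annotate(seq, threshold=0.94, monomers=None):
    return annotate_monomer_sequence(
        seq, threshold=threshold, monomer_count=monomers or max(seq)
    )


def test_rotated_trs_merge_into_one_hor():
    # two runs of the same HOR in different phases, separated by a spacer
    seq = [1, 2, 3, 4] * 3 + [9] + [3, 4, 1, 2] * 3
    layer = run_htrm(seq)
    hors = merge_to_hors(layer, seq)
    assert len(hors) == 1
    h = hors[0]
    assert h.canonical_pattern == (1, 2, 3, 4)
    assert h.rn == 6 and h.hor_len == 24


def test_different_units_stay_separate():
    seq = [1, 2] * 3 + [9] + [1, 3] * 3
    hors = merge_to_hors(run_htrm(seq), seq)
    assert sorted(h.canonical_pattern for h in hors) == [(1, 2), (1, 3)]


def test_nested_variants_share_one_hor_across_copy_numbers():
    # 1-2-3-4 units where the (2-3) span is amplified x2, x3 or x1 (literal)
    seq = (
        [1, 2, 3, 4]
        + [1, 2, 3, 2, 3, 4]
        + [1, 2, 3, 4]
        + [1, 2, 3, 2, 3, 2, 3, 4]
        + [1, 2, 3, 4]
    )
    ann = annotate(seq)
    assert len(ann.hors) == 1
    h = ann.hors[0]
    assert h.canonical_pattern == (1, 2, 3, 4)
    assert len(h.instances) == 5
    patterns = [i.pattern for i in h.instances]
    assert patterns.count("1_2_3_4") == 3
    assert "1_(2_3)x2_4" in patterns and "1_(2_3)x3_4" in patterns
    assert ann.coverage == 1.0


def test_coverage_fractions(make_blocks):
    seq = [1, 2] * 5 + [7, 8, 9] * 2 + [5, 6, 4, 3]
    ann = annotate(seq)
    covered = sum(h.hor_len for h in ann.hors)
    assert ann.coverage == pytest.approx(covered / len(seq))
    assert hor_coverage(ann.hors, len(seq)) == ann.coverage


def test_scoring_formula_and_naming():
    seq = [1, 2, 3, 4, 5] * 20
    ann = annotate(seq)
    h = ann.hors[0]
    assert (h.cr, h.pr, h.score) == (1.0, 1.0, 1.0)
    assert h.name == "R1L5"
    # direct substitution: m.len 100, HOR.len 50, unit 5, rn 10
    h.hor_len, h.rn, h.unit_len = 50, 10, 5
    (scored,) = score_and_rank([h], 100)
    assert (scored.cr, scored.pr, scored.score) == (0.5, 1.0, 0.5)


def test_ranking_orders_by_score_then_ties():
    seq = [1, 2] * 10 + [9] + [3, 4] * 4 + [8] + [5, 6, 7] * 3
    ann = annotate(seq)
    scores = [h.score for h in ann.hors]
    assert scores == sorted(scores, reverse=True)
    assert [h.rank for h in ann.hors] == list(range(1, len(ann.hors) + 1))
    assert all(h.name == f"R{h.rank}L{h.unit_len}" for h in ann.hors)


def test_score_invariant_under_id_relabeling():
    seq = [1, 2, 3, 1, 2, 3, 4, 4, 4]
    relabel = {1: 3, 2: 1, 3: 4, 4: 2}
    seq2 = [relabel[s] for s in seq]
    a1, a2 = annotate(seq), annotate(seq2)
    assert a1.coverage == a2.coverage
    assert sorted(h.score for h in a1.hors) == sorted(h.score for h in a2.hors)


def test_rotation_of_sequence_by_one_unit_keeps_canonical_patterns():
    seq = [1, 2, 3, 4, 5] * 12
    rot = seq[5:] + seq[:5]
    a1, a2 = annotate(seq), annotate(rot)
    assert {h.canonical_pattern for h in a1.hors} == {
        h.canonical_pattern for h in a2.hors
    }


def test_select_threshold_prefers_max_coverage_then_lowest():
    anns = [annotate([1, 2] * 4, threshold=t) for t in (0.94, 0.945, 0.95)]
    anns[0].coverage, anns[1].coverage, anns[2].coverage = 0.6, 0.9, 0.7
    assert select_threshold(anns).threshold == 0.945
    anns[0].coverage = anns[1].coverage = anns[2].coverage = 0.5
    assert select_threshold(anns).threshold == 0.94
    assert select_threshold([anns[2]]).threshold == 0.95


def test_projection_maps_monomer_spans_to_genomic_intervals(make_blocks):
    blocks = make_blocks(["A" * 171 for _ in range(24)])
    seq = list(range(1, 13)) * 2  # one 12-monomer unit, two instances
    ann = annotate(seq)
    intervals = project_annotation(ann, blocks)
    assert len(intervals) == 2
    assert intervals[0][:2] == (0, 12 * 171)
    assert intervals[1][:2] == (12 * 171, 24 * 171)
    assert intervals[0][3] == "_".join(map(str, range(1, 13)))
    ann.hors = []
    assert project_annotation(ann, blocks) == []
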