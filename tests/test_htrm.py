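"""Hierarchical tandem repeat mining: detection oracle, region checking, compression."""

import numpy as np
import pytest

from centrohor.htrm import (
    TandemRepeat,
    TandemRun,
    compress,
    detect_tandem,
    reduce_span,
    region_check,
    run_htrm,
)


def brute_force_runs(seq, k):
    """Enumerate every (start, repeats) triple and keep the maximal ones.

    A triple is kept iff repeats >= 2, the region is periodic with unit
    length k, the periodicity does not extend one symbol to the left
    (leftmost phase) and no further full unit follows on the right.
    """
    n = len(seq)
    out = []
    for s in range(n):
        unit = tuple(seq[s : s + k])
        if len(unit) < k:
            break
        r = 1
        while tuple(seq[s + r * k : s + (r + 1) * k]) == unit:
            r += 1
        if r < 2:
            continue
        if s > 0 and s - 1 + k < n and seq[s - 1] == seq[s - 1 + k]:
            continue  # extendable to the left: not leftmost
        out.append(TandemRun(start=s, unit=unit, repeats=r))
    return out


def test_detection_examples():
    assert detect_tandem([2, 3, 2, 3, 2, 3], 2) == [
        TandemRun(start=0, unit=(2, 3), repeats=3)
    ]
    assert detect_tandem([1, 2, 3], 1) == []


def test_detection_matches_brute_force_on_random_sequences(rng):
    for _ in range(300):
        n = int(rng.integers(2, 31))
        alphabet = int(rng.integers(1, 6))
        seq = rng.integers(1, alphabet + 1, size=n).tolist()
        for k in range(1, 6):
            assert detect_tandem(seq, k) == brute_force_runs(seq, k), (seq, k)


def run_check(seq, runs, layer):
    ostart = list(range(len(seq)))
    oend = [i + 1 for i in range(len(seq))]
    return region_check(runs, layer, seq, ostart, oend)


def test_region_check_disjoint_run_is_saved():
    seq = [1, 1, 2, 3, 4]
    layer, accepted, updated = run_check(seq, detect_tandem(seq, 1), [])
    assert updated and len(layer) == 1
    assert (layer[0].start, layer[0].end, layer[0].unit) == (0, 2, (1,))


def test_region_check_covered_new_run_is_discarded():
    old = TandemRepeat(unit=(1, 2), repeats=3, start=0, end=6, boundaries=(0, 2, 4, 6))
    seq = [1, 2, 1, 2, 1, 2]
    new = [TandemRun(start=2, unit=(1, 2), repeats=2)]
    layer, _, updated = run_check(seq, new, [old])
    assert not updated and layer == [old]


def test_region_check_covering_run_absorbs_old_as_children():
    old1 = TandemRepeat(unit=(2,), repeats=2, start=1, end=3, boundaries=(1, 2, 3))
    old2 = TandemRepeat(unit=(4,), repeats=2, start=6, end=8, boundaries=(6, 7, 8))
    # working sequence after both compressions, spanning [0, 10) originally
    seq = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
    ostart = [0, 1, 3, 4, 5, 5, 6, 8, 9, 9]
    # original:  1 2 2 3 4 | 1 2 4 4 5 -> not literal; only spans matter here
    ostart = [0, 1, 3, 4, 5, 5, 6, 8, 9, 9]
    oend = [1, 3, 4, 5, 5, 6, 8, 9, 10, 10]
    # construct a consistent toy projection: ten working symbols over [0, 10)
    ostart = list(range(10))
    oend = [i + 1 for i in range(10)]
    new = [TandemRun(start=0, unit=(1, 2, 3, 4, 5), repeats=2)]
    layer, accepted, updated = region_check(new, [old1, old2], seq, ostart, oend)
    assert updated and len(layer) == 1
    tr = layer[0]
    assert (tr.start, tr.end, tr.repeats) == (0, 10, 2)
    assert tr.children == [old1, old2]


def test_region_check_fully_contained_old_becomes_child():
    old = TandemRepeat(unit=(9,), repeats=2, start=0, end=2, boundaries=(0, 1, 2))
    seq = [9, 8, 9, 8, 9, 8, 9, 8]
    new = [TandemRun(start=0, unit=(9, 8), repeats=4)]
    layer, _, updated = run_check(seq, new, [old])
    assert updated and len(layer) == 1
    assert layer[0].unit == (9, 8) and layer[0].children == [old]


def test_region_check_partial_overlap_trims_whole_units():
    # old extends past the right end of the new run: last unit trimmed off
    old = TandemRepeat(unit=(7,), repeats=2, start=6, end=10, boundaries=(6, 8, 10))
    seq = [9, 8, 9, 8, 9, 8, 9, 8]
    new = [TandemRun(start=0, unit=(9, 8), repeats=4)]
    layer, _, updated = run_check(seq, new, [old])
    assert updated
    kept = [tr for tr in layer if tr.unit == (9, 8)]
    assert len(kept) == 1 and (kept[0].start, kept[0].end, kept[0].repeats) == (0, 6, 3)
    assert old in layer  # old survives a partial overlap


def test_region_check_partial_overlap_dropping_below_two_repeats_discards():
    old = TandemRepeat(unit=(7,), repeats=2, start=3, end=7, boundaries=(3, 5, 7))
    seq = [9, 8, 9, 8, 5, 5, 5, 5]
    new = [TandemRun(start=0, unit=(9, 8), repeats=2)]
    layer, _, updated = run_check(seq, new, [old])
    assert not updated and layer == [old]


def test_region_check_trims_conflicts_among_new_runs():
    seq = [2, 3, 2, 3, 2, 3, 2]  # (2,3)x3 at 0 and (3,2)x3 at 1 overlap
    runs = detect_tandem(seq, 2)
    layer, _, _ = run_check(seq, runs, [])
    assert len(layer) == 1
    assert (layer[0].start, layer[0].unit, layer[0].repeats) == (0, (2, 3), 3)


def test_compress_keeps_one_unit_copy_and_spans():
    seq = [1, 2, 1, 2, 3]
    ostart = list(range(5))
    oend = [i + 1 for i in range(5)]
    new_seq, new_os, new_oe = compress(seq, ostart, oend, [(0, 2, 2)])
    assert new_seq == [1, 2, 3]
    assert new_os == [0, 1, 4]
    assert new_oe == [1, 4, 5]


def test_compress_without_regions_is_identity():
    seq = [1, 2, 3]
    out = compress(seq, [0, 1, 2], [1, 2, 3], [])
    assert out == ([1, 2, 3], [0, 1, 2], [1, 2, 3])


def test_run_htrm_simple_layers():
    layer = run_htrm([1, 1, 2, 3, 2, 3]).trs
    assert [(tr.unit, tr.repeats, tr.start, tr.end) for tr in layer] == [
        ((1,), 2, 0, 2),
        ((2, 3), 2, 2, 6),
    ]
    assert run_htrm([1, 2, 3, 4]).trs == ()


def test_run_htrm_nested_unit_collapses_to_full_pattern():
    # 1-2-3-4-5-(6-7-8-9)x2-10-11, three tandem copies (39 symbols)
    unit = [1, 2, 3, 4, 5, 6, 7, 8, 9, 6, 7, 8, 9, 10, 11]
    seq = unit * 3
    layer = run_htrm(seq).trs
    assert len(layer) == 1
    top = layer[0]
    assert top.unit == (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
    assert top.repeats == 3
    assert (top.start, top.end) == (0, 45)
    assert len(top.children) == 3
    for child in top.children:
        assert child.unit == (6, 7, 8, 9) and child.repeats == 2
    # every instance reduces (nested repeats to one copy) to the unit
    for t in range(top.repeats):
        a, b = top.instance_span(t)
        assert reduce_span(a, b, top.instance_children(t), seq) == top.unit


def assert_layer_sound(layer, seq):
    """Disjoint spans; every cleanly nested instance reduces to its unit.

    A nested repeat may sit out of phase with the enclosing repeat, in
    which case its span straddles an instance boundary; the expand-once
    reduction is only defined for instances whose children nest cleanly.
    """
    spans = sorted((tr.start, tr.end) for tr in layer)
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        assert b0 <= a1

    def check(tr):
        assert tr.repeats >= 2
        assert tr.boundaries[0] == tr.start and tr.boundaries[-1] == tr.end
        assert list(tr.boundaries) == sorted(set(tr.boundaries))
        for t in range(tr.repeats):
            a, b = tr.instance_span(t)
            straddle = any(
                c.start < a < c.end or c.start < b < c.end for c in tr.children
            )
            if not straddle:
                assert reduce_span(a, b, tr.instance_children(t), seq) == tr.unit
        for c in tr.children:
            check(c)

    for tr in layer:
        check(tr)


def test_run_htrm_top_layer_is_disjoint_and_lossless(rng):
    for _ in range(100):
        n = int(rng.integers(4, 40))
        seq = rng.integers(1, int(rng.integers(2, 5)) + 1, size=n).tolist()
        assert_layer_sound(run_htrm(seq, max_unit_len=6).trs, seq)


def test_run_htrm_rejects_empty():
    with pytest.raises(ValueError):
        run_htrm([])
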