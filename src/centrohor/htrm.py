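"""Hierarchical tandem repeat mining (HTRM) over a monomer-ID sequence.

Local tandem amplifications inside a higher-order repeat unit (local-nested
HORs) break the plain periodicity of the monomer sequence, so a single-pass
tandem-repeat finder cannot see the outer repeat.  HTRM works bottom-up:

1. *detect*: find all maximal tandem runs of the current unit length
   (starting at 1) in the working sequence;
2. *region check*: reconcile the new runs with the *top layer*, the set of
   non-overlapping accepted repeats of maximal coverage (in original
   monomer coordinates) -- disjoint runs are saved, runs covered by an old
   repeat are discarded, runs covering old repeats replace them (the old
   repeats become their children), partial overlaps are trimmed to whole
   units;
3. *update*: every newly saved run is compressed in the working sequence to
   a single copy of its unit, and detection restarts at unit length 1; if
   nothing was saved, the unit length is increased by one.

Compression-to-one-copy is what makes nesting transparent: a unit such as
1-2-3-(4-5)x3 collapses to 1-2-3-4-5, so the surrounding canonical units
and the nested one line up into one long run whose unit is the canonical
HOR unit.  The repeat counts and spans of everything that was compressed
survive in the top layer as children with original-coordinate projections.

The loop terminates because every compression strictly shortens the
working sequence and the unit length is bounded (default 40).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

__all__ = [
    "TandemRun",
    "TandemRepeat",
    "TopLayer",
    "detect_tandem",
    "region_check",
    "compress",
    "run_htrm",
]


@dataclass(frozen=True)
class TandemRun:
    """A maximal tandem run in *working-sequence* coordinates.

    The region [start, start + repeats * len(unit)) repeats ``unit``
    ``repeats`` (>= 2) times.  A run is reported at its leftmost phase and
    is maximal: the periodicity extends neither one symbol to the left nor
    one full unit to the right.
    """

    start: int
    unit: tuple[int, ...]
    repeats: int

    @property
    def end(self) -> int:
        return self.start + self.repeats * len(self.unit)


@dataclass
class TandemRepeat:
    """An accepted tandem repeat, projected to original monomer coordinates.

    ``unit`` is the repeat unit with any nested amplification reduced to a
    single copy (the "expand-once" monomer pattern); per-instance nested
    repeats are the ``children`` whose spans fall inside the instance.
    ``boundaries`` has ``repeats + 1`` entries delimiting the instances.
    """

    unit: tuple[int, ...]
    repeats: int
    start: int
    end: int
    boundaries: tuple[int, ...]
    children: list["TandemRepeat"] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start

    def instance_span(self, t: int) -> tuple[int, int]:
        return self.boundaries[t], self.boundaries[t + 1]

    def instance_children(self, t: int) -> list["TandemRepeat"]:
        a, b = self.instance_span(t)
        return [c for c in self.children if a <= c.start and c.end <= b]

    def to_dict(self) -> dict:
        return {
            "unit": list(self.unit),
            "repeats": self.repeats,
            "start": self.start,
            "end": self.end,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass(frozen=True)
class TopLayer:
    """Non-overlapping accepted tandem repeats, sorted by start."""

    trs: tuple[TandemRepeat, ...]

    def coverage(self, m_len: int) -> float:
        return sum(tr.span for tr in self.trs) / m_len if m_len else 0.0

    def to_dict(self) -> dict:
        return {"trs": [tr.to_dict() for tr in self.trs]}


def detect_tandem(seq: Sequence[int], unit_len: int) -> list[TandemRun]:
    """All maximal tandem runs of ``unit_len`` in ``seq``, left to right.

    Each maximal periodic region contributes one run anchored at its
    leftmost position with ``floor(region_length / unit_len)`` repeats.
    """
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    n = len(seq)
    k = unit_len
    out: list[TandemRun] = []
    i = 0
    limit = n - k
    while i < limit:
        if seq[i] == seq[i + k]:
            j = i
            while j < limit and seq[j] == seq[j + k]:
                j += 1
            r = (j + k - i) // k
            if r >= 2:
                out.append(TandemRun(start=i, unit=tuple(seq[i : i + k]), repeats=r))
            i = j + 1
        else:
            i += 1
    return out


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def region_check(
    new_runs: list[TandemRun],
    layer: list[TandemRepeat],
    seq: Sequence[int],
    ostart: Sequence[int],
    oend: Sequence[int],
) -> tuple[list[TandemRepeat], list[tuple[int, int, int]], bool]:
    """Reconcile newly detected runs with the top layer.

    Returns ``(new_layer, accepted_working_regions, updated)`` where each
    accepted working region is ``(w_start, unit_len, repeats)`` ready for
    compression.  The four-way rule against old repeats (disjoint / new
    covers old / old covers new / partial) is applied in original
    coordinates; overlaps among the new runs themselves keep the leftmost
    run and trim later ones to whole units.
    """
    new_layer = list(layer)
    accepted: list[tuple[int, int, int]] = []
    out_trs: list[TandemRepeat] = []
    updated = False
    last_end_w = -1

    for run in new_runs:
        k = len(run.unit)
        s_w, r = run.start, run.repeats
        # conflicts among same-length new runs: leftmost wins, trim whole units
        if s_w < last_end_w:
            shift = ceil((last_end_w - s_w) / k)
            s_w += shift * k
            r -= shift
            if r < 2:
                continue

        def ospan(ws: int, reps: int) -> tuple[int, int]:
            return ostart[ws], oend[ws + reps * k - 1]

        o_s, o_e = ospan(s_w, r)
        olds = [tr for tr in new_layer if _overlaps(tr.start, tr.end, o_s, o_e)]
        if any(tr.start <= o_s and o_e <= tr.end for tr in olds):
            continue  # covered by an old repeat: discard
        partial = [
            tr for tr in olds if not (o_s <= tr.start and tr.end <= o_e)
        ]
        if partial:
            # trim whole units off either flank until no partial overlap remains
            while r >= 2:
                a, b = ostart[s_w], oend[s_w + k - 1]
                if any(_overlaps(tr.start, tr.end, a, b) for tr in partial):
                    s_w += k
                    r -= 1
                    continue
                a, b = ostart[s_w + (r - 1) * k], oend[s_w + r * k - 1]
                if any(_overlaps(tr.start, tr.end, a, b) for tr in partial):
                    r -= 1
                    continue
                break
            if r < 2:
                continue
            o_s, o_e = ospan(s_w, r)
            olds = [tr for tr in new_layer if _overlaps(tr.start, tr.end, o_s, o_e)]
            if any(not (o_s <= tr.start and tr.end <= o_e) for tr in olds):
                continue  # defensive: trimming could not isolate the run
        children = sorted(
            (tr for tr in olds if o_s <= tr.start and tr.end <= o_e),
            key=lambda tr: tr.start,
        )
        for tr in children:
            new_layer.remove(tr)
        bounds = tuple(ostart[s_w + t * k] for t in range(r)) + (o_e,)
        tr_new = TandemRepeat(
            unit=tuple(seq[s_w : s_w + k]),
            repeats=r,
            start=o_s,
            end=o_e,
            boundaries=bounds,
            children=children,
        )
        new_layer.append(tr_new)
        out_trs.append(tr_new)
        accepted.append((s_w, k, r))
        last_end_w = s_w + r * k
        updated = True

    new_layer.sort(key=lambda tr: tr.start)
    return new_layer, accepted, updated


def compress(
    seq: list[int],
    ostart: list[int],
    oend: list[int],
    accepted: list[tuple[int, int, int]],
) -> tuple[list[int], list[int], list[int]]:
    """Replace each accepted region by one copy of its unit.

    The surviving copy keeps per-symbol original spans except that the last
    symbol absorbs the span of the removed copies, so projections of later,
    larger repeats stay contiguous and lossless.
    """
    for (s1, k1, r1), (s2, _, _) in zip(accepted, accepted[1:]):
        if s2 < s1 + k1 * r1:
            raise RuntimeError("accepted regions overlap")
    new_seq: list[int] = []
    new_os: list[int] = []
    new_oe: list[int] = []
    pos = 0
    for s_w, k, r in accepted:
        new_seq.extend(seq[pos:s_w])
        new_os.extend(ostart[pos:s_w])
        new_oe.extend(oend[pos:s_w])
        new_seq.extend(seq[s_w : s_w + k])
        new_os.extend(ostart[s_w : s_w + k])
        new_oe.extend(oend[s_w : s_w + k - 1])
        new_oe.append(oend[s_w + r * k - 1])
        pos = s_w + r * k
    new_seq.extend(seq[pos:])
    new_os.extend(ostart[pos:])
    new_oe.extend(oend[pos:])
    return new_seq, new_os, new_oe


def run_htrm(seq: Sequence[int], max_unit_len: int = 40) -> TopLayer:
    """Full bottom-up mining loop; returns the final top layer.

    Unit length starts at 1 and resets to 1 after every successful
    compression; it increases by one when a pass saves nothing, and the
    loop ends once it exceeds ``max_unit_len``.
    """
    if len(seq) == 0:
        raise ValueError("empty monomer sequence")
    work = list(seq)
    ostart = list(range(len(seq)))
    oend = [i + 1 for i in range(len(seq))]
    layer: list[TandemRepeat] = []
    k = 1
    while k <= max_unit_len:
        if 2 * k > len(work):
            break
        runs = detect_tandem(work, k)
        layer, accepted, updated = region_check(runs, layer, work, ostart, oend)
        if updated:
            work, ostart, oend = compress(work, ostart, oend, accepted)
            k = 1
        else:
            k += 1
    return TopLayer(trs=tuple(sorted(layer, key=lambda tr: tr.start)))


def reduce_span(
    a: int,
    b: int,
    children: list[TandemRepeat],
    orig: Sequence[int],
) -> tuple[int, ...]:
    """Project original symbols in [a, b) with each nested repeat reduced to one unit copy.

    Applying this to a repeat instance reproduces the repeat's ``unit``
    (the expand-once monomer pattern); used for round-trip checks and
    pattern rendering.
    """
    out: list[int] = []
    pos = a
    for c in sorted(children, key=lambda tr: tr.start):
        if c.start < pos or c.end > b:
            continue
        out.extend(orig[pos : c.start])
        inner = [g for g in c.children if c.start <= g.start and g.end <= c.boundaries[1]]
        out.extend(reduce_span(c.start, c.boundaries[1], inner, orig))
        pos = c.end
    out.extend(orig[pos:b])
    return tuple(out)


def render_span(
    a: int,
    b: int,
    children: list[TandemRepeat],
    orig: Sequence[int],
) -> str:
    """Human-readable expanded pattern for [a, b), e.g. ``1_2_(3_4)x3_5``."""
    parts: list[str] = []
    pos = a
    for c in sorted(children, key=lambda tr: tr.start):
        if c.start < pos or c.end > b:
            continue
        parts.extend(str(s) for s in orig[pos : c.start])
        inner = [g for g in c.children if c.start <= g.start and g.end <= c.boundaries[1]]
        parts.append(f"({render_span(c.start, c.boundaries[1], inner, orig)})x{c.repeats}")
        pos = c.end
    parts.extend(str(s) for s in orig[pos:b])
    return "_".join(parts)
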