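"""Higher-order repeat (HOR) assembly, threshold selection, scoring and naming.

Tandem repeats from the top layer whose units are rotations of one another
(4-1-2-3, 3-4-1-2, ... of 1-2-3-4) describe the same HOR read in different
phases, so they are merged under the lexicographically smallest rotation of
the unit.  Because nested amplifications were compressed to one unit copy
during mining, pattern variants that differ only in nested copy number
(1-2-(3-4)xn-5 for any n, including the literal n = 1 unit) share the same
canonical unit and merge automatically.

Each merged HOR is scored by ``HORscore = cr * pr`` with
``cr = HOR.len / m.len`` (fraction of the monomer sequence covered) and
``pr = HOR.rn / (HOR.len / HORunit.len)`` (ratio of actual to nominal
repeat count; < 1 signals local nesting / over-compression).  HORs are
ranked by descending score and named ``R{rank}L{HORunit.len}``.

The monomer-similarity threshold itself is chosen by re-annotating at each
threshold of the schedule and keeping the one with the largest total HOR
coverage (ties -> lowest threshold), which couples monomer inference to
HOR detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .decompose import Block
from .htrm import TandemRepeat, TopLayer, render_span, run_htrm

__all__ = [
    "HORInstance",
    "HOR",
    "Annotation",
    "normalize_unit",
    "merge_to_hors",
    "hor_coverage",
    "score_and_rank",
    "select_threshold",
    "annotate_monomer_sequence",
    "project_annotation",
]


def normalize_unit(unit: Sequence[int]) -> tuple[int, ...]:
    """Canonical rotation of a repeat unit: the lexicographically smallest one."""
    u = tuple(unit)
    if not u:
        raise ValueError("empty unit")
    return min(tuple(u[i:] + u[:i]) for i in range(len(u)))


@dataclass(frozen=True)
class HORInstance:
    """One HOR unit occurrence in monomer coordinates."""

    start: int
    end: int
    pattern: str
    nested: bool


@dataclass
class HOR:
    """A merged, scored higher-order repeat."""

    canonical_pattern: tuple[int, ...]
    trs: list[TandemRepeat]
    instances: list[HORInstance]
    hor_len: int          # covered length, in original monomer symbols
    rn: int               # total repeat count across merged TRs
    unit_len: int         # canonical unit length in monomer symbols
    first_start: int
    cr: float = 0.0
    pr: float = 0.0
    score: float = 0.0
    rank: int = 0
    name: str = ""


@dataclass
class Annotation:
    """Annotation of one monomer sequence at one similarity threshold."""

    threshold: float
    monomer_count: int
    monomer_sequence: tuple[int, ...]
    hors: list[HOR]
    coverage: float
    breakpoints: int


def merge_to_hors(top_layer: TopLayer, monomer_sequence: Sequence[int]) -> list[HOR]:
    """Group top-layer repeats by canonical unit rotation into HORs."""
    groups: dict[tuple[int, ...], list[TandemRepeat]] = {}
    for tr in top_layer.trs:
        groups.setdefault(normalize_unit(tr.unit), []).append(tr)
    hors = []
    for key, trs in groups.items():
        instances = []
        for tr in trs:
            for t in range(tr.repeats):
                a, b = tr.instance_span(t)
                kids = tr.instance_children(t)
                instances.append(
                    HORInstance(
                        start=a,
                        end=b,
                        pattern=render_span(a, b, kids, monomer_sequence),
                        nested=bool(kids),
                    )
                )
        instances.sort(key=lambda x: x.start)
        hors.append(
            HOR(
                canonical_pattern=key,
                trs=trs,
                instances=instances,
                hor_len=sum(tr.span for tr in trs),
                rn=sum(tr.repeats for tr in trs),
                unit_len=len(key),
                first_start=min(tr.start for tr in trs),
            )
        )
    return hors


def hor_coverage(hors: list[HOR], m_len: int) -> float:
    """Fraction of monomer symbols inside any HOR instance."""
    if m_len <= 0:
        raise ValueError("m_len must be positive")
    return sum(h.hor_len for h in hors) / m_len


def score_and_rank(hors: list[HOR], m_len: int) -> list[HOR]:
    """Compute cr, pr and HORscore; sort, rank and name the HORs.

    Ties are broken by larger covered length, then shorter unit, then first
    occurrence, so ranks are reproducible.
    """
    if m_len <= 0:
        raise ValueError("m_len must be positive")
    for h in hors:
        h.cr = h.hor_len / m_len
        h.pr = h.rn / (h.hor_len / h.unit_len)
        h.score = h.cr * h.pr
    hors = sorted(
        hors, key=lambda h: (-h.score, -h.hor_len, h.unit_len, h.first_start)
    )
    for rank, h in enumerate(hors, start=1):
        h.rank = rank
        h.name = f"R{rank}L{h.unit_len}"
    return hors


def _breakpoints(hors: list[HOR]) -> int:
    """Number of maximal annotated runs along the monomer sequence."""
    spans = sorted((i.start, i.end) for h in hors for i in h.instances)
    runs = 0
    cur_end = None
    for a, b in spans:
        if cur_end is None or a > cur_end:
            runs += 1
            cur_end = b
        else:
            cur_end = max(cur_end, b)
    return runs


def annotate_monomer_sequence(
    monomer_sequence: Sequence[int],
    threshold: float,
    monomer_count: int,
    max_unit_len: int = 40,
) -> Annotation:
    """Mine, merge, score and rank HORs for one monomer sequence."""
    layer = run_htrm(monomer_sequence, max_unit_len=max_unit_len)
    hors = merge_to_hors(layer, monomer_sequence)
    m_len = len(monomer_sequence)
    hors = score_and_rank(hors, m_len)
    return Annotation(
        threshold=threshold,
        monomer_count=monomer_count,
        monomer_sequence=tuple(monomer_sequence),
        hors=hors,
        coverage=hor_coverage(hors, m_len),
        breakpoints=_breakpoints(hors),
    )


def select_threshold(annotations: list[Annotation]) -> Annotation:
    """The annotation with the largest HOR coverage; ties -> lowest threshold."""
    if not annotations:
        raise ValueError("no sweep results")
    return max(annotations, key=lambda a: (a.coverage, -a.threshold))


def project_annotation(
    annotation: Annotation, blocks: list[Block]
) -> list[tuple[int, int, str, str]]:
    """Genomic (start, end, hor_name, pattern) per HOR instance, BED-style half-open."""
    out = []
    n = len(blocks)
    for h in annotation.hors:
        for inst in h.instances:
            if not (0 <= inst.start < inst.end <= n):
                raise RuntimeError("instance span outside the block list")
            out.append(
                (blocks[inst.start].start, blocks[inst.end - 1].end, h.name, inst.pattern)
            )
    out.sort(key=lambda x: (x[0], x[1]))
    return out
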