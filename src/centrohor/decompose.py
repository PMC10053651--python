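"""Decomposition of a satellite DNA array into monomer-sized blocks.

A centromeric satellite array is, to first approximation, a tandem
concatenation of diverged copies of a single monomer (~100-400 bp; 171 bp
for human alpha satellite).  Given one monomer template, the array is
segmented into consecutive, non-overlapping *blocks*, each the best local
match to the template, by a dynamic program that jointly chooses all block
boundaries to maximise the summed semi-global alignment score of the
template against every block (match +1, mismatch -1, indel -1).

The DP state is (template position, array position); starting a fresh
template copy at array position ``i`` is free and inherits the best score
of any segmentation of the prefix ``[0, i)``, so the recursion effectively
chains alignments end to end.  It runs in O(len(array) * len(template))
time and O(len(template)) memory per column (numba-compiled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["MonomerTemplate", "Block", "decompose", "DecompositionError"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# fraction of the template length below which a terminal block is trimmed
_MIN_TERMINAL_FRACTION = 0.6


class DecompositionError(ValueError):
    """Raised for unusable inputs (empty sequence, array shorter than half the template)."""


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes; soft-masked bases are uppercased, N stays N."""
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise DecompositionError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return np.array([_CODE[c] for c in s], dtype=np.uint8)


@dataclass(frozen=True)
class MonomerTemplate:
    """A monomer template sequence (upper-case A/C/G/T)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise DecompositionError("empty monomer template")
        if set(seq) - set("ACGT"):
            raise DecompositionError("template alphabet must be A/C/G/T")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Block:
    """One monomer instance: a half-open slice [start, end) of the input array."""

    index: int
    start: int
    end: int
    sequence: str

    @property
    def len(self) -> int:  # noqa: A003 - field name fixed by the data model
        return self.end - self.start


@njit(cache=True)
def _decompose_dp(seq, tmpl, match, mismatch, gap):  # pragma: no cover - numba
    L = seq.size
    P = tmpl.size
    NEG = -(1 << 40)
    best = np.empty(L + 1, dtype=np.int64)
    best_start = np.empty(L + 1, dtype=np.int64)
    prev = np.empty(P + 1, dtype=np.int64)
    prev_s = np.empty(P + 1, dtype=np.int64)
    cur = np.empty(P + 1, dtype=np.int64)
    cur_s = np.empty(P + 1, dtype=np.int64)

    best[0] = 0
    best_start[0] = 0
    prev[0] = 0
    prev_s[0] = 0
    for p in range(1, P + 1):
        prev[p] = prev[p - 1] - gap
        prev_s[p] = 0

    for i in range(1, L + 1):
        c = seq[i - 1]
        for p in range(1, P + 1):
            sub = match if (tmpl[p - 1] == c and c < 4) else -mismatch
            d = prev[p - 1] + sub
            h = prev[p] - gap
            if d >= h:
                cur[p] = d
                cur_s[p] = prev_s[p - 1]
            else:
                cur[p] = h
                cur_s[p] = prev_s[p]
        # template-deletion moves within the column (block body)
        for p in range(2, P + 1):
            v = cur[p - 1] - gap
            if v > cur[p]:
                cur[p] = v
                cur_s[p] = cur_s[p - 1]
        best[i] = cur[P]
        best_start[i] = cur_s[P]
        # a new block may start at i; allow leading template deletions
        cur[0] = best[i]
        cur_s[0] = i
        for p in range(1, P + 1):
            v = cur[p - 1] - gap
            if v > cur[p]:
                cur[p] = v
                cur_s[p] = cur_s[p - 1]
        prev, cur = cur, prev
        prev_s, cur_s = cur_s, prev_s

    return best, best_start


def decompose(
    sequence: str,
    template: MonomerTemplate,
    *,
    match: int = 1,
    mismatch: int = 1,
    gap: int = 1,
    trim_terminal: bool = True,
) -> list[Block]:
    """Tile ``sequence`` with monomer blocks best matching ``template``.

    Returns consecutive, non-overlapping blocks whose concatenation equals the
    decomposed region of the input.  Terminal blocks shorter than 60% of the
    template length are trimmed (alignment fragments).
    """
    if not sequence:
        raise DecompositionError("empty input sequence")
    if 2 * len(sequence) < len(template):
        raise DecompositionError("array too short: input is shorter than half the template")
    seq = _encode(sequence)
    tmpl = _encode(template.sequence)
    _, best_start = _decompose_dp(seq, tmpl, match, mismatch, gap)

    bounds = []
    i = len(sequence)
    while i > 0:
        j = int(best_start[i])
        if not 0 <= j < i:  # defensive; DP guarantees strict progress
            raise RuntimeError("decomposition traceback failed")
        bounds.append((j, i))
        i = j
    bounds.reverse()

    if trim_terminal and bounds:
        min_len = _MIN_TERMINAL_FRACTION * len(template)
        if bounds and (bounds[0][1] - bounds[0][0]) < min_len:
            bounds = bounds[1:]
        if bounds and (bounds[-1][1] - bounds[-1][0]) < min_len:
            bounds = bounds[:-1]

    norm = sequence.upper()
    return [
        Block(index=k, start=s, end=e, sequence=norm[s:e])
        for k, (s, e) in enumerate(bounds)
    ]
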