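"""Pairwise block similarity and identical-block merging.

Similarity between two blocks is ``1 - ed(b1, b2) / max(b1.len, b2.len)``
with ``ed`` the unit-cost Levenshtein distance (computed with edlib).
Identical blocks (similarity exactly 1 by string equality) are collapsed to
a single representative before the quadratic pairwise step; this changes
nothing downstream and is what makes large arrays tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .decompose import Block

__all__ = [
    "block_similarity",
    "similarity_matrix",
    "merge_identical",
    "MergedBlockSet",
]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (global alignment)."""
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def block_similarity(b1: Block, b2: Block) -> float:
    """Similarity in [0, 1]: 1 - ed / max(len1, len2)."""
    if not b1.sequence or not b2.sequence:
        raise ValueError("block sequences must be non-empty")
    return 1.0 - edit_distance(b1.sequence, b2.sequence) / max(b1.len, b2.len)


def similarity_matrix(blocks: list[Block]) -> np.ndarray:
    """Symmetric matrix of pairwise block similarities with unit diagonal."""
    if not blocks:
        raise ValueError("need at least one block")
    n = len(blocks)
    S = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = block_similarity(blocks[i], blocks[j])
    return S


@dataclass(frozen=True)
class MergedBlockSet:
    """Distinct-sequence representatives of a block list.

    ``member_map[i]`` is the representative index of original block ``i``;
    representatives are ordered by first occurrence along the array.
    """

    representatives: tuple[Block, ...]
    multiplicity: tuple[int, ...]
    member_map: tuple[int, ...]
    S_merged: np.ndarray

    @property
    def n_original(self) -> int:
        return len(self.member_map)

    def expand_matrix(self) -> np.ndarray:
        """Reconstruct the full (unmerged) similarity matrix."""
        idx = np.asarray(self.member_map)
        return self.S_merged[np.ix_(idx, idx)]


def merge_identical(blocks: list[Block]) -> MergedBlockSet:
    """Collapse blocks with identical sequences; representatives keep first-occurrence order."""
    if not blocks:
        raise ValueError("need at least one block")
    rep_of_seq: dict[str, int] = {}
    reps: list[Block] = []
    mult: list[int] = []
    member_map: list[int] = []
    for b in blocks:
        r = rep_of_seq.get(b.sequence)
        if r is None:
            r = len(reps)
            rep_of_seq[b.sequence] = r
            reps.append(b)
            mult.append(0)
        mult[r] += 1
        member_map.append(r)
    S = similarity_matrix(reps)
    return MergedBlockSet(
        representatives=tuple(reps),
        multiplicity=tuple(mult),
        member_map=tuple(member_map),
        S_merged=S,
    )
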