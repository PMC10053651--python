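"""Monomer inference by community detection on the block similarity graph.

For each similarity threshold in an ascending schedule, blocks whose
similarity exceeds the threshold are linked; Louvain communities of that
graph are the monomers.  The graph is built over merged representatives,
with multiplicities folded into edge weights (``m_i * m_j``) and self-loops
(``m * (m - 1) / 2``) so that modularity equals modularity on the unmerged
block graph.  Monomer IDs are 1..k in order of each community's first block
occurrence along the array, which makes labels stable and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .similarity import MergedBlockSet

__all__ = [
    "ThresholdSchedule",
    "MonomerAssignment",
    "build_block_graph",
    "detect_monomers",
    "to_monomer_sequence",
    "sweep_thresholds",
]


@dataclass(frozen=True)
class ThresholdSchedule:
    """Ascending similarity thresholds t_min, t_min + step, ... strictly below 1."""

    t_min: float = 0.94
    step: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 < self.t_min < 1.0:
            raise ValueError("t_min must be in (0, 1)")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def thresholds(self) -> tuple[float, ...]:
        out = []
        k = 0
        while True:
            t = self.t_min + k * self.step
            if t >= 1.0 - 1e-12:
                break
            out.append(round(t, 10))
            k += 1
        return tuple(out)


@dataclass(frozen=True)
class MonomerAssignment:
    """Monomer ID (1..monomer_count) per merged-block representative, at one threshold."""

    threshold: float
    community_of: tuple[int, ...]
    monomer_count: int


def build_block_graph(merged: MergedBlockSet, threshold: float) -> nx.Graph:
    """Graph over representatives with an edge iff similarity > threshold (strict).

    Edge weights carry block multiplicities so that Louvain on this graph is
    equivalent to Louvain on the graph of all original blocks (where every
    identical group forms an internal clique).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    S = merged.S_merged
    mult = merged.multiplicity
    n = len(mult)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        if mult[i] > 1:
            G.add_edge(i, i, weight=mult[i] * (mult[i] - 1) / 2.0)
        for j in range(i + 1, n):
            if S[i, j] > threshold:
                G.add_edge(i, j, weight=float(mult[i] * mult[j]))
    return G


def detect_monomers(
    G: nx.Graph, merged: MergedBlockSet, threshold: float, seed: int = 0
) -> MonomerAssignment:
    """Louvain communities of the block graph; one monomer per community."""
    comms = louvain_communities(G, weight="weight", resolution=1.0, seed=seed)
    # first original-block occurrence of each community orders the IDs
    first_pos = {}
    for c in comms:
        members = frozenset(c)
        first_pos[members] = min(
            i for i, r in enumerate(merged.member_map) if r in members
        )
    ordered = sorted(first_pos, key=first_pos.get)
    community_of = [0] * G.number_of_nodes()
    for mono_id, members in enumerate(ordered, start=1):
        for r in members:
            community_of[r] = mono_id
    return MonomerAssignment(
        threshold=threshold,
        community_of=tuple(community_of),
        monomer_count=len(ordered),
    )


def to_monomer_sequence(
    merged: MergedBlockSet, assignment: MonomerAssignment
) -> tuple[int, ...]:
    """Rewrite the original block list as a sequence of monomer IDs."""
    return tuple(assignment.community_of[r] for r in merged.member_map)


def sweep_thresholds(
    merged: MergedBlockSet,
    schedule: ThresholdSchedule = ThresholdSchedule(),
    seed: int = 0,
):
    """Yield one (assignment, monomer sequence) per ascending threshold.

    Lazy so that callers may stop the sweep early; for a fixed seed the
    full sweep is reproducible.
    """
    for t in schedule.thresholds:
        G = build_block_graph(merged, t)
        a = detect_monomers(G, merged, t, seed=seed)
        yield a, to_monomer_sequence(merged, a)
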