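"""RMSD similarity graph and overlapping clustering into motif classes.

Occurrences are vertices; an edge joins two occurrences whose motif-anchored
context RMSD is at most the threshold τ (default 2.5 Å, with 2.0 Å as the
stricter variant).  Clustering seeks dense classes of mutually similar
occurrences while letting a vertex belong to up to two classes — the case of
an occurrence close to two otherwise dissimilar groups.

The clusterer is a deterministic greedy heuristic behind a small interface:
grow a class from the unassigned vertex of highest weighted degree, admitting
neighbours while the class density stays above a floor and the average
similarity does not drop by more than a slack; once every vertex is covered,
grant one secondary membership to vertices adjacent to at least half of
another class.  Reported per class: density 2E/(V(V-1)) and average
similarity mean((τ - w)/τ) over internal edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx

from .errors import ValidationError

#: Experimentally chosen RMSD threshold (Å) for class membership.
DEFAULT_TAU = 2.5


@dataclass
class SimilarityGraph:
    """Undirected graph over occurrence ids, edges weighted by RMSD (Å)."""

    tau: float
    nx_graph: nx.Graph

    @property
    def vertices(self) -> list[str]:
        return sorted(self.nx_graph.nodes)

    def similarity(self, u: str, v: str) -> float:
        """Normalized similarity (τ - rmsd)/τ of an edge."""
        return (self.tau - self.nx_graph.edges[u, v]["weight"]) / self.tau


@dataclass
class MotifClass:
    """A set of occurrences with similar local 3D context."""

    id: int
    members: tuple[str, ...]
    density: float = 1.0
    avg_similarity: float = 1.0
    topological_representative: object = None
    sequence_representative: object = None

    def __len__(self) -> int:
        return len(self.members)


def similarity_graph(
    ids: Sequence[str], rmsd_fn: Callable[[str, str], float], tau: float = DEFAULT_TAU
) -> SimilarityGraph:
    """All-pairs RMSD evaluated once; edge iff RMSD ≤ τ."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    g = nx.Graph()
    g.add_nodes_from(ids)
    ids = list(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = rmsd_fn(ids[i], ids[j])
            if w <= tau:
                g.add_edge(ids[i], ids[j], weight=w)
    return SimilarityGraph(tau, g)


def _class_stats(sg: SimilarityGraph, members: set[str]) -> tuple[float, float]:
    n = len(members)
    if n < 2:
        return 1.0, 1.0
    sub = sg.nx_graph.subgraph(members)
    e = sub.number_of_edges()
    density = 2 * e / (n * (n - 1))
    avg = (
        sum((sg.tau - d["weight"]) / sg.tau for _, _, d in sub.edges(data=True)) / e
        if e
        else 0.0
    )
    return density, avg


def cluster(
    sg: SimilarityGraph,
    density_floor: float = 0.5,
    similarity_slack: float = 0.10,
    secondary_fraction: float = 0.5,
) -> list[MotifClass]:
    """Greedy overlapping clustering of the similarity graph.

    Deterministic: ties in vertex selection are broken by (weighted degree,
    degree, lexicographic id); candidate admission order is by best
    similarity to the class, then id.
    """
    g = sg.nx_graph
    unassigned = set(g.nodes)
    classes: list[set[str]] = []

    def weighted_degree(v: str) -> float:
        return sum((sg.tau - d["weight"]) / sg.tau for _, _, d in g.edges(v, data=True))

    while unassigned:
        seed = min(unassigned, key=lambda v: (-weighted_degree(v), -g.degree(v), v))
        members = {seed}
        density, avg = 1.0, 1.0
        while True:
            candidates = sorted(
                {
                    nb
                    for m in members
                    for nb in g.neighbors(m)
                    if nb not in members and nb in unassigned
                },
                key=lambda v: (-max(sg.similarity(v, m) for m in members if g.has_edge(v, m)), v),
            )
            admitted = False
            for cand in candidates:
                nd, na = _class_stats(sg, members | {cand})
                # a singleton has no internal edges yet: its first admission
                # sets the similarity baseline instead of being tested
                sim_ok = len(members) == 1 or na >= avg * (1.0 - similarity_slack)
                if nd >= density_floor and sim_ok:
                    members.add(cand)
                    density, avg = nd, na
                    admitted = True
                    break
            if not admitted:
                break
        classes.append(members)
        unassigned -= members

    # one secondary membership per vertex, when strongly adjacent to another class
    membership: dict[str, int] = {}
    for cls in classes:
        for v in cls:
            membership[v] = membership.get(v, 0) + 1
    for v in sorted(g.nodes):
        if membership.get(v, 0) >= 2:
            continue
        for cls in classes:
            if v in cls:
                continue
            links = sum(1 for m in cls if g.has_edge(v, m))
            nd, _na = _class_stats(sg, cls | {v})
            if links > 0 and links >= secondary_fraction * len(cls) and nd >= density_floor:
                cls.add(v)
                membership[v] = membership.get(v, 0) + 1
                break  # at most one secondary membership

    out = []
    for i, members in enumerate(classes):
        density, avg = _class_stats(sg, members)
        out.append(
            MotifClass(
                id=i,
                members=tuple(sorted(members)),
                density=density,
                avg_similarity=avg,
            )
        )
    return out


def assign_to_class(
    occ_id: str,
    cls: MotifClass,
    rmsd_fn: Callable[[str, str], float],
    tau: float = DEFAULT_TAU,
) -> bool:
    """True iff the occurrence is within τ of at least one member (inclusive)."""
    return any(rmsd_fn(occ_id, m) <= tau for m in cls.members)
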