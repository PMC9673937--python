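"""Context kinds, occurrence search, and PPV / TPR evaluation.

Four kinds of context are derived from a class's representatives:

* ``sequence`` — the two regular expressions only;
* ``all_interactions`` — the topological representative with the motif's
  non-canonical edges removed (removal usually splits it into a loop-side
  and a helix-side query graph; an extra inter-strand interaction keeps it
  in one piece, giving a single set of occurrences);
* ``sequence_all_interactions`` — the all-interactions graphs plus the
  regular expressions;
* ``sequence_canonical_short_range`` — the regular expressions plus the
  graphs reduced to their short-range canonical edges.

Searching a context in an RNA graph enumerates embeddings of each query
graph: backbone adjacency and order are preserved, vertex labels and edge
families must be equal, and a contracted query vertex of weight p may map to
any run of 1..k consecutive same-label nucleotides (weights are flexible,
mirroring the common-subgraph equivalence rule).  For the combined kinds,
the strand regex must additionally match the sequence window of length
2(k+1) centred on the embedded motif strand.

Per class and strand the positive predictive value is PPV = TP / Positives,
a hit counting as true only when its two motif-strand positions coincide
exactly with the corresponding strand of an annotated occurrence of that
class.  The global true positive rate is the fraction of annotated
occurrences whose both strands are recovered by one same class.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .classify import MotifClass
from .errors import ValidationError
from .graph import AminorOccurrence, Key, RnaGraph
from .nomenclature import mirror
from .represent import CommonSubgraph, SequenceRepresentative, edge_range

log = logging.getLogger(__name__)

KINDS = (
    "sequence",
    "all_interactions",
    "sequence_all_interactions",
    "sequence_canonical_short_range",
)

#: Template numbers whose strand belongs to each side.
SIDE_MOTIF = {"loop": (5, 6), "helix": (1, 2)}


@dataclass
class QueryGraph:
    """One connected piece of a topological context, ready for matching."""

    side: str  # "loop" | "helix" | "both"
    cs: CommonSubgraph
    k: int
    tuple_indices: tuple[int, ...]
    edges: tuple[tuple[int, int, str], ...]  # filtered common edges

    def motif_indices(self) -> set[int]:
        return {
            i for i in self.tuple_indices
            if self.cs.tuples[i].branch is None and self.cs.tuples[i].label.isdigit()
        }


@dataclass
class ClassContext:
    """A class's searchable context of one kind."""

    class_id: int
    kind: str
    k: int
    queries: tuple[QueryGraph, ...] = ()
    seqrep: SequenceRepresentative | None = None


@dataclass(frozen=True)
class StrandHit:
    """One predicted strand occurrence (positions are motif-strand keys)."""

    structure_id: str
    side: str  # "loop" | "helix" | "both"
    class_id: int
    loop_positions: tuple[Key, Key] | None = None
    helix_positions: tuple[Key, Key] | None = None

    def positions(self, side: str) -> tuple[Key, Key] | None:
        return self.loop_positions if side == "loop" else self.helix_positions


# ---------------------------------------------------------------------------
# Context construction
# ---------------------------------------------------------------------------

def _motif_tuple_index(cs: CommonSubgraph, no: int) -> int:
    return no - 1  # motif tuples are stored first, in template order


def build_context(cls: MotifClass, kind: str) -> ClassContext:
    """Derive the searchable context of ``kind`` from the class representatives."""
    if kind not in KINDS:
        raise ValidationError(f"unknown context kind {kind!r}")
    cs: CommonSubgraph | None = cls.topological_representative
    rep: SequenceRepresentative | None = cls.sequence_representative
    if cs is None or rep is None:
        raise ValidationError(f"class {cls.id}: representatives not computed")
    k = rep.k
    if kind == "sequence":
        return ClassContext(cls.id, kind, k, (), rep)

    tuples = cs.tuples
    motif_idx = set(range(6))

    def is_motif_noncanonical(i: int, j: int, fam: str) -> bool:
        return i in motif_idx and j in motif_idx and fam != "CAN"

    edges = [e for e in cs.edges if not is_motif_noncanonical(*e)]
    if kind == "sequence_canonical_short_range":
        edges = [
            (i, j, fam)
            for (i, j, fam) in edges
            if fam == "CAN" and edge_range(cs, i, j, fam) == "short"
        ]

    # connectivity: strand covalent links + remaining interaction edges
    conn = nx.Graph()
    conn.add_nodes_from(range(len(tuples)))
    for a, b in ((1, 2), (3, 4), (5, 6)):
        conn.add_edge(_motif_tuple_index(cs, a), _motif_tuple_index(cs, b))
    for i, t in enumerate(tuples):
        if t.branch is not None:
            conn.add_edge(i, _motif_tuple_index(cs, t.branch[0]))
    for i, j, _fam in edges:
        conn.add_edge(i, j)

    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(conn)):
        for i in comp:
            comp_of[i] = ci

    loop_comp = comp_of[_motif_tuple_index(cs, 5)]
    helix_comp = comp_of[_motif_tuple_index(cs, 1)]
    queries = []
    if loop_comp == helix_comp:
        idx = tuple(sorted(i for i, c in comp_of.items() if c == loop_comp))
        queries.append(
            QueryGraph("both", cs, k, idx, tuple(e for e in edges if e[0] in idx))
        )
    else:
        for side, comp in (("loop", loop_comp), ("helix", helix_comp)):
            idx = tuple(sorted(i for i, c in comp_of.items() if c == comp))
            queries.append(
                QueryGraph(side, cs, k, idx, tuple(e for e in edges if e[0] in idx))
            )
    seqrep = rep if kind in ("sequence_all_interactions", "sequence_canonical_short_range") else None
    return ClassContext(cls.id, kind, k, tuple(queries), seqrep)


# ---------------------------------------------------------------------------
# Sequence search
# ---------------------------------------------------------------------------

def _chain_window(g: RnaGraph, keys: Sequence[Key], start: int, length: int) -> str | None:
    if start < 0 or start + length > len(keys):
        return None
    return "".join(g.residue(k) for k in keys[start : start + length])


def search_sequences(
    ctx: ClassContext, graphs: Iterable[RnaGraph]
) -> list[StrandHit]:
    """All overlapping matches of the two regexes, each side separately."""
    rep = ctx.seqrep if ctx.seqrep is not None else None
    if rep is None:
        raise ValidationError("context kind has no sequence component")
    k = ctx.k
    hits = []
    for g in graphs:
        for chain in g.chains():
            keys = g.chain_keys(chain)
            seq = "".join(g.residue(kk) for kk in keys)
            for side in ("loop", "helix"):
                for start in rep.search_positions(seq, side):
                    i = start - 1  # 0-based window start
                    pair = (keys[i + k], keys[i + k + 1])
                    hits.append(
                        StrandHit(
                            g.structure_id, side, ctx.class_id,
                            loop_positions=pair if side == "loop" else None,
                            helix_positions=pair if side == "helix" else None,
                        )
                    )
    return sorted(set(hits), key=lambda h: (h.structure_id, h.side, h.loop_positions or (), h.helix_positions or ()))


# ---------------------------------------------------------------------------
# Graph search
# ---------------------------------------------------------------------------

def _strand_plan(q: QueryGraph, root: int) -> list[int]:
    """Tuple indices of the branch rooted at ``root``, motif-outwards."""
    items = [
        (q.cs.tuples[i].runs[0], i)
        for i in q.tuple_indices
        if q.cs.tuples[i].branch is not None and q.cs.tuples[i].branch[0] == root
    ]
    return [i for _, i in sorted(items)]


def _run_assignments(
    g: RnaGraph, q: QueryGraph, anchor: Key, root: int, step
) -> Iterable[dict[int, tuple[Key, ...]]]:
    """Enumerate images of one branch's runs, walking ``step`` from ``anchor``.

    Consecutive selected runs (member-0 run indices i, i+1) must be adjacent;
    a selection gap allows a spacer of 0..k arbitrary nucleotides.  Each run
    maps to 1..k consecutive nucleotides of its label.
    """
    plan = _strand_plan(q, root)
    k = q.k

    def rec(pi: int, cur: Key | None, prev_run: int, acc: dict):
        if pi == len(plan):
            yield dict(acc)
            return
        ti = plan[pi]
        t = q.cs.tuples[ti]
        gap_allowed = range(0, k + 1) if t.runs[0] != prev_run + 1 else (0,)
        for gap in gap_allowed:
            pos = cur
            ok = True
            for _ in range(gap):
                pos = step(pos) if pos is not None else None
                if pos is None:
                    ok = False
                    break
            if not ok:
                continue
            # consume 1..k vertices of the run's label
            run: list[Key] = []
            nxt = pos
            for _ln in range(k):
                nxt = step(nxt) if nxt is not None else None
                if nxt is None or g.label(nxt) != t.label:
                    break
                run.append(nxt)
                acc[ti] = tuple(run)
                yield from rec(pi + 1, nxt, t.runs[0], acc)
            acc.pop(ti, None)

    yield from rec(0, anchor, -1, {})


def _bot_candidates(
    g: RnaGraph, q: QueryGraph, ti: int, images: dict[int, tuple[Key, ...]]
) -> set[Key]:
    cands: set[Key] | None = None
    for (i, j, fam) in q.edges:
        if ti not in (i, j):
            continue
        other = j if i == ti else i
        if other not in images:
            continue
        # edge family is stated i→j; we scan arcs leaving the mapped end
        want = fam if other == i else mirror(fam)
        found = set()
        for u in images[other]:
            for v, arc in g.interactions_of(u):
                if arc.family == want:
                    found.add(v)
        cands = found if cands is None else (cands & found)
    if cands is None:
        cands = set(g.nucleotides)
    return cands


def _edges_satisfied(g: RnaGraph, q: QueryGraph, images: dict[int, tuple[Key, ...]]) -> bool:
    for (i, j, fam) in q.edges:
        if i not in images or j not in images:
            return False
        if not any(
            g.has_family(u, v, fam) for u in images[i] for v in images[j]
        ):
            return False
    return True


def _anchor_candidates(g: RnaGraph, q: QueryGraph, side_pair: tuple[int, int]):
    a, b = side_pair
    for u, v in g.covalent_arcs():
        yield {a - 1: (u,), b - 1: (v,)}


def _resolve_helix_partner(
    g: RnaGraph, q: QueryGraph, images: dict[int, tuple[Key, ...]]
) -> Iterable[dict[int, tuple[Key, ...]]]:
    """Map motif tuples 3,4 through the canonical pairs, when present."""
    mot = q.motif_indices()
    if 2 not in mot and 3 not in mot:  # tuples of template 3 and 4
        yield images
        return
    (v1,) = images[0]
    (v2,) = images[1]
    for v4, arc in g.interactions_of(v1):
        if arc.family != "CAN":
            continue
        v3 = g.cov_prev(v4)
        if v3 is None or not g.has_family(v2, v3, "CAN"):
            continue
        if len({v1, v2, v3, v4}) != 4:
            continue
        out = dict(images)
        out[2] = (v3,)
        out[3] = (v4,)
        yield out


def _window_matches(
    g: RnaGraph, rep: SequenceRepresentative, side: str, pair: tuple[Key, Key], k: int
) -> bool:
    chain = pair[0][0]
    keys = g.chain_keys(chain)
    i = keys.index(pair[0])
    win = _chain_window(g, keys, i - k, 2 * (k + 1))
    return win is not None and rep.matches(win, side)


def search_graph(ctx: ClassContext, g: RnaGraph) -> list[StrandHit]:
    """All embeddings of the context's query graphs into ``g``."""
    if not ctx.queries:
        raise ValidationError("context kind has no graph component")
    hits: set[StrandHit] = set()
    for q in ctx.queries:
        sides = ("loop", "helix") if q.side == "both" else (q.side,)
        # anchor each involved side on a covalent pair
        anchor_sets = [
            list(_anchor_candidates(g, q, SIDE_MOTIF[s])) for s in sides
        ]
        for combo in itertools.product(*anchor_sets):
            images: dict[int, tuple[Key, ...]] = {}
            used = set()
            clash = False
            for part in combo:
                for ti, im in part.items():
                    if im[0] in used:
                        clash = True
                    used.add(im[0])
                    images[ti] = im
            if clash:
                continue
            for with_partner in (
                _resolve_helix_partner(g, q, images)
                if "helix" in sides
                else (images,)
            ):
                _match_branches(g, q, sides, with_partner, hits, ctx)
    return sorted(
        hits,
        key=lambda h: (h.structure_id, h.side, h.loop_positions or (), h.helix_positions or ()),
    )


def _match_branches(g, q, sides, images, hits, ctx):
    branch_roots = [r for s in sides for r in SIDE_MOTIF[s]]
    gen_per_root = []
    for root in branch_roots:
        anchor = images[root - 1][0]
        step = g.cov_prev if root in (1, 5) else g.cov_next
        gen_per_root.append(list(_run_assignments(g, q, anchor, root, step)))
    bots = [
        i for i in q.tuple_indices
        if q.cs.tuples[i].label == "⊥"
    ]
    for combo in itertools.product(*gen_per_root):
        im = dict(images)
        used = {v for vs in images.values() for v in vs}
        ok = True
        for part in combo:
            for ti, run in part.items():
                if used & set(run):
                    ok = False
                    break
                used |= set(run)
                im[ti] = run
            if not ok:
                break
        if not ok:
            continue
        # every selected tuple of this query must be mapped
        needed = [
            i for i in q.tuple_indices
            if i not in im and q.cs.tuples[i].label != "⊥"
        ]
        if needed:
            continue
        for final in _assign_bots(g, q, bots, im, used):
            if not _edges_satisfied(g, q, final):
                continue
            if not _regex_ok(g, q, sides, final, ctx):
                continue
            loop_pos = (final[4][0], final[5][0]) if "loop" in sides else None
            helix_pos = (final[0][0], final[1][0]) if "helix" in sides else None
            hits.add(
                StrandHit(g.structure_id, q.side, ctx.class_id, loop_pos, helix_pos)
            )
            break  # one embedding per anchor/runs is enough for hit identity


def _assign_bots(g, q, bots, images, used):
    if not bots:
        yield images
        return
    ti, rest = bots[0], bots[1:]
    for cand in sorted(_bot_candidates(g, q, ti, images)):
        if cand in used:
            continue
        images[ti] = (cand,)
        yield from _assign_bots(g, q, rest, images, used | {cand})
    images.pop(ti, None)


def _regex_ok(g, q, sides, images, ctx) -> bool:
    if ctx.seqrep is None:
        return True
    for s in sides:
        a, b = SIDE_MOTIF[s]
        pair = (images[a - 1][0], images[b - 1][0])
        if not _window_matches(g, ctx.seqrep, s, pair, ctx.k):
            return False
    return True


def search_context(ctx: ClassContext, graphs: Iterable[RnaGraph]) -> list[StrandHit]:
    """Dispatch on kind: regex scan, graph embedding, or both combined."""
    if ctx.kind == "sequence":
        return search_sequences(ctx, graphs)
    hits: list[StrandHit] = []
    for g in graphs:
        hits.extend(search_graph(ctx, g))
    return hits


# ---------------------------------------------------------------------------
# PPV / TPR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPVResult:
    class_id: int
    side: str
    tp: int
    positives: int

    @property
    def value(self) -> float | None:
        return None if self.positives == 0 else self.tp / self.positives


@dataclass
class PredictionReport:
    kind: str
    rows: list[PPVResult] = field(default_factory=list)
    tpr: float | None = None
    found: int = 0
    total: int = 0

    def mean_ppv(self, side: str) -> float | None:
        vals = [r.value for r in self.rows if r.side == side and r.value is not None]
        return sum(vals) / len(vals) if vals else None


def _truth_strands(
    truth: Sequence[AminorOccurrence], assignment: Mapping[str, set[int]], cls_id: int
) -> tuple[set, set]:
    loops, helices = set(), set()
    for occ in truth:
        if cls_id in assignment.get(occ.id, set()):
            loops.add((occ.structure_id, occ.loop_strand))
            helices.add((occ.structure_id, occ.helix_strand_a))
    return loops, helices


def ppv(
    hits: Sequence[StrandHit],
    truth: Sequence[AminorOccurrence],
    assignment: Mapping[str, set[int]],
    cls_id: int,
    side: str,
) -> PPVResult:
    """PPV of one class on one strand side.

    ``assignment`` maps occurrence id → class ids (via ``assign_to_class``).
    Hits on A-minor strands of *other* classes count as false positives.
    For single-graph ("both") hits a true positive needs both strands of one
    same truth occurrence; callers report the same value for both sides.
    """
    loops, helices = _truth_strands(truth, assignment, cls_id)
    if side not in ("loop", "helix"):
        raise ValidationError(f"side must be loop or helix, got {side!r}")
    relevant = [h for h in hits if h.side in (side, "both")]
    tp = 0
    for h in relevant:
        if h.side == "both":
            both = any(
                h.structure_id == occ.structure_id
                and h.loop_positions == occ.loop_strand
                and h.helix_positions == occ.helix_strand_a
                for occ in truth
                if cls_id in assignment.get(occ.id, set())
            )
            tp += bool(both)
        else:
            pos = (h.structure_id, h.positions(side))
            tp += pos in (loops if side == "loop" else helices)
    return PPVResult(cls_id, side, tp, len(relevant))


def tpr(
    per_class_hits: Mapping[int, Sequence[StrandHit]],
    truth: Sequence[AminorOccurrence],
) -> tuple[float | None, int]:
    """Global TPR: an occurrence is found when both its strands are hit by
    one same class.  Returns (rate or None on empty truth, found count)."""
    if not truth:
        return None, 0
    found = 0
    for occ in truth:
        hit = False
        for cls_id, hits in per_class_hits.items():
            loop_ok = any(
                h.structure_id == occ.structure_id
                and h.loop_positions == occ.loop_strand
                for h in hits
                if h.side in ("loop", "both")
            )
            helix_ok = any(
                h.structure_id == occ.structure_id
                and h.helix_positions == occ.helix_strand_a
                for h in hits
                if h.side in ("helix", "both")
            )
            if loop_ok and helix_ok:
                hit = True
                break
        found += hit
    return found / len(truth), found


def evaluate(
    classes: Sequence[MotifClass],
    kind: str,
    graphs: Sequence[RnaGraph],
    truth: Sequence[AminorOccurrence],
    assignment: Mapping[str, set[int]],
    min_members: int = 3,
) -> PredictionReport:
    """Search one context kind for all classes in scope and score it.

    Only classes with at least ``min_members`` occurrences are considered.
    """
    report = PredictionReport(kind)
    per_class: dict[int, list[StrandHit]] = {}
    for cls in classes:
        if len(cls) < min_members:
            continue
        ctx = build_context(cls, kind)
        hits = search_context(ctx, graphs)
        per_class[cls.id] = hits
        single = any(h.side == "both" for h in hits) or (
            ctx.queries and ctx.queries[0].side == "both"
        )
        if single:
            r = ppv(hits, truth, assignment, cls.id, "loop")
            report.rows.append(r)
            report.rows.append(PPVResult(cls.id, "helix", r.tp, r.positives))
        else:
            for side in ("loop", "helix"):
                report.rows.append(ppv(hits, truth, assignment, cls.id, side))
    rate, found = tpr(per_class, truth)
    report.tpr, report.found, report.total = rate, found, len(truth)
    return report
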