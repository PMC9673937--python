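"""Structural context of an A-minor occurrence: branches and k-S-extensions.

A *branch* of length ``k`` from a motif vertex ``u`` follows the covalent
backbone away from the motif (never crossing another motif vertex) for at
most ``k`` steps; each branch vertex is labeled by its pairing state in the
whole molecule (``0`` unpaired, ``C`` canonical only, ``N`` non-canonical
only, ``M`` both), and the interaction partners of branch vertices are pulled
in as ``⊥`` vertices.  The *k-S-extension* is the union of the six motif
vertices and the branches grown from the vertices in ``S`` (a subset of the
cis Sugar/Sugar participants 1, 2, 5, 6), together with all interaction arcs
among the included vertices.

The *contracted* extension merges maximal runs of consecutive same-label
branch vertices into single weighted vertices, so that loops or helices
differing by one or two nucleotides look identical.  Motif vertices are never
contracted and keep their template numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

from .errors import ValidationError
from .graph import AminorOccurrence, Interaction, Key, RnaGraph
from .nomenclature import mirror

log = logging.getLogger(__name__)

#: Direction in which each template vertex's branch grows (the other covalent
#: neighbour is a motif vertex).
BRANCH_DIRECTION = {1: "5p", 2: "3p", 3: "5p", 4: "3p", 5: "5p", 6: "3p"}

#: Slot identifying a vertex of an extension: motif slots are ("m", n) with
#: template number n; branch slots are (root, direction, offset) with offset
#: counted 1..k away from the motif.
Slot = tuple


@dataclass(frozen=True)
class Branch:
    root: int  # template number
    direction: str  # "5p" | "3p"
    vk: tuple[Key, ...]  # ordered away from the motif
    labels: tuple[str, ...]  # pairing-state label per vk vertex
    vk_plus: frozenset[Key]  # interaction partners of vk, labeled ⊥


def branch(g: RnaGraph, occ: AminorOccurrence, u: int, k: int) -> Branch:
    """Branch of length ``k`` from template vertex ``u`` of ``occ``."""
    if u not in range(1, 7):
        raise ValidationError(f"template number {u} outside 1..6")
    if k < 1:
        raise ValidationError("branch/extension order k must be >= 1")
    motif = set(occ.positions)
    direction = BRANCH_DIRECTION[u]
    step = g.cov_prev if direction == "5p" else g.cov_next
    vk: list[Key] = []
    cur = occ[u]
    for _ in range(k):
        nxt = step(cur)
        if nxt is None or nxt in motif:
            break  # truncated at chain end / next motif vertex
        vk.append(nxt)
        cur = nxt
    labels = tuple(g.label(w) for w in vk)
    plus = frozenset(p for w in vk for p, _arc in g.interactions_of(w))
    return Branch(u, direction, tuple(vk), labels, plus)


@dataclass
class Extension:
    """A k-S-extension of one embedded A-minor occurrence."""

    graph: RnaGraph
    occurrence: AminorOccurrence
    k: int
    S: frozenset[int]
    branches: dict[int, Branch]

    # -- vertex sets ----------------------------------------------------

    def core_slots(self) -> list[tuple[Slot, Key]]:
        """(slot, key) for every non-⊥ vertex: motif 1..6 then branch slots.

        A vertex reachable through two branches keeps its first slot only
        (deduplicated by identity; logged).
        """
        out: list[tuple[Slot, Key]] = [(("m", n), self.occurrence[n]) for n in range(1, 7)]
        seen = set(self.occurrence.positions)
        for root in sorted(self.S):
            br = self.branches[root]
            for offset, key in enumerate(br.vk, start=1):
                if key in seen:
                    log.info("vertex %s reached by two branches; deduplicated", key)
                    continue
                out.append(((root, br.direction, offset), key))
                seen.add(key)
        return out

    def core_keys(self) -> set[Key]:
        return {key for _, key in self.core_slots()}

    def bot_keys(self) -> set[Key]:
        """⊥ vertices: interaction partners of branch vertices that are not
        themselves motif or branch vertices."""
        core = self.core_keys()
        return {p for br in self.branches.values() for p in br.vk_plus} - core

    def vertex_keys(self) -> set[Key]:
        return self.core_keys() | self.bot_keys()

    def n_core(self) -> int:
        return len(self.core_slots())

    # -- induced arcs ---------------------------------------------------

    def interaction_arcs(self) -> Iterator[tuple[Key, Key, Interaction]]:
        """Interaction arcs among included vertices.

        ⊥ vertices participate only through their arcs *into* the context
        (that is what they are: interaction partners of branch vertices), so
        arcs between two ⊥ vertices are excluded.
        """
        core = self.core_keys()
        verts = core | self.bot_keys()
        for u, v, arc in self.graph.interaction_arcs():
            if u in verts and v in verts and (u in core or v in core):
                yield u, v, arc

    # -- strand sequences -----------------------------------------------

    def strand_keys(self, strand: str) -> list[Key]:
        """Covalent path of one extended strand, 5'→3'.

        ``loop`` = branch(5) + nucleotides 5,6 + branch(6);
        ``helix`` = branch(1) + nucleotides 1,2 + branch(2).
        """
        if strand == "loop":
            a, b = 5, 6
        elif strand == "helix":
            a, b = 1, 2
        else:
            raise ValidationError(f"strand must be 'loop' or 'helix', got {strand!r}")
        left = self.branches.get(a)
        right = self.branches.get(b)
        keys = list(reversed(left.vk)) if left else []
        keys += [self.occurrence[a], self.occurrence[b]]
        keys += list(right.vk) if right else []
        return keys

    def strand_sequence(self, strand: str) -> str:
        """Nucleotide string of the strand, length 2(k+1) when branches are
        full, shorter when truncated at a chain end."""
        return "".join(self.graph.residue(key) for key in self.strand_keys(strand))


def extend(g: RnaGraph, occ: AminorOccurrence, S, k: int) -> Extension:
    """Build the k-S-extension of ``occ`` in ``g``."""
    S = frozenset(S)
    if not S or not S <= set(range(1, 7)):
        raise ValidationError(f"S must be a non-empty subset of 1..6, got {set(S)}")
    if k < 1:
        raise ValidationError("extension order k must be >= 1")
    for key in occ.positions:
        if key not in g:
            raise ValidationError(f"occurrence vertex {key} not in graph")
    branches = {u: branch(g, occ, u, k) for u in sorted(S)}
    return Extension(g, occ, k, S, branches)


# ---------------------------------------------------------------------------
# Contraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVertex:
    """Vertex of a contracted extension.

    ``kind`` is ``motif`` (template vertex, never contracted, weight 1),
    ``branch`` (a maximal run of same-label branch vertices, weight = run
    length) or ``bot`` (a ⊥ context partner, weight 1).
    """

    id: str
    kind: str  # "motif" | "branch" | "bot"
    label: str  # "0"|"C"|"N"|"M"|"⊥"|template number as string
    weight: int
    template_no: int | None = None
    root: int | None = None  # branch slot
    direction: str | None = None
    run_index: int | None = None  # 0-based along the branch, motif-outwards
    members: tuple[Key, ...] = ()
    residues: tuple[str, ...] = ()
    offsets: tuple[int, ...] = ()  # uncontracted branch offsets (1..k)


@dataclass
class ContractedExtension:
    """Weight-contracted k-S-extension."""

    k: int
    S: frozenset[int]
    vertices: dict[str, CVertex]
    branch_runs: dict[tuple[int, str], list[str]]  # ordered run ids per branch
    interactions: dict[tuple[str, str], frozenset[str]]  # directed, families
    #: (u, v, family) → "short"|"long" ("long" wins when multiplicity collapsed)
    ranges: dict[tuple[str, str, str], str] = field(default_factory=dict)
    source: Extension | None = field(default=None, repr=False, compare=False)

    def motif_id(self, n: int) -> str:
        return f"m{n}"

    def interaction_edges(self) -> list[tuple[str, str, str]]:
        """Undirected interaction edges (u, v, family-from-u), u < v."""
        out = []
        for (u, v), fams in sorted(self.interactions.items()):
            if u < v:
                out.extend((u, v, f) for f in sorted(fams))
        return out

    def strand_labels(self, root: int) -> list[str]:
        """Uncontracted label sequence of one branch (round-trip check)."""
        out: list[str] = []
        key = next(kd for kd in self.branch_runs if kd[0] == root)
        for cid in self.branch_runs[key]:
            cv = self.vertices[cid]
            out.extend([cv.label] * cv.weight)
        return out


def contract(e: Extension) -> ContractedExtension:
    """Merge maximal same-label runs within each branch.

    Runs never merge across motif vertices; ⊥ vertices are excluded from
    contraction and carry weight 1.  Interaction arcs are re-attached to the
    merged vertices with multiplicity collapsed; arcs that end up inside a
    single merged vertex are dropped.
    """
    vertices: dict[str, CVertex] = {}
    key_to_cid: dict[Key, str] = {}

    for n in range(1, 7):
        cid = f"m{n}"
        key = e.occurrence[n]
        vertices[cid] = CVertex(
            id=cid, kind="motif", label=str(n), weight=1, template_no=n,
            members=(key,), residues=(e.graph.residue(key),),
        )
        key_to_cid[key] = cid

    branch_runs: dict[tuple[int, str], list[str]] = {}
    core_slots = e.core_slots()
    by_branch: dict[tuple[int, str], list[tuple[int, Key]]] = {}
    for slot, key in core_slots:
        if slot[0] == "m":
            continue
        root, direction, offset = slot
        by_branch.setdefault((root, direction), []).append((offset, key))

    for (root, direction) in sorted(by_branch):
        items = sorted(by_branch[(root, direction)])
        runs: list[list[tuple[int, Key]]] = []
        for offset, key in items:
            lab = e.graph.label(key)
            if runs and e.graph.label(runs[-1][-1][1]) == lab:
                runs[-1].append((offset, key))
            else:
                runs.append([(offset, key)])
        ids = []
        for ri, run in enumerate(runs):
            cid = f"b{root}{direction}-{ri}"
            keys = tuple(k for _, k in run)
            vertices[cid] = CVertex(
                id=cid, kind="branch", label=e.graph.label(keys[0]),
                weight=len(keys), root=root, direction=direction, run_index=ri,
                members=keys, residues=tuple(e.graph.residue(k) for k in keys),
                offsets=tuple(o for o, _ in run),
            )
            for k in keys:
                key_to_cid[k] = cid
            ids.append(cid)
        branch_runs[(root, direction)] = ids
    for u in sorted(e.S):
        branch_runs.setdefault((u, e.branches[u].direction), [])

    for key in sorted(e.bot_keys()):
        cid = f"x{key[0]}:{key[1]}"
        vertices[cid] = CVertex(
            id=cid, kind="bot", label="⊥", weight=1,
            members=(key,), residues=(e.graph.residue(key),),
        )
        key_to_cid[key] = cid

    interactions: dict[tuple[str, str], set[str]] = {}
    ranges: dict[tuple[str, str, str], str] = {}
    for u, v, arc in e.interaction_arcs():
        cu, cv = key_to_cid[u], key_to_cid[v]
        if cu == cv:
            log.info("interaction inside contracted vertex %s dropped", cu)
            continue
        interactions.setdefault((cu, cv), set()).add(arc.family)
        prev = ranges.get((cu, cv, arc.family))
        rng = arc.range or "long"
        ranges[(cu, cv, arc.family)] = "long" if "long" in (prev, rng) else "short"

    return ContractedExtension(
        k=e.k, S=e.S, vertices=vertices,
        branch_runs=branch_runs,
        interactions={k: frozenset(v) for k, v in interactions.items()},
        ranges=ranges,
        source=e,
    )
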