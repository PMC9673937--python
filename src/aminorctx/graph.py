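"""RNA interaction graphs and the type I/II A-minor motif template.

An :class:`RnaGraph` is a directed labeled multigraph over the nucleotides of
one structure: covalent arcs follow the 5'→3' backbone, and every hydrogen-bond
interaction is stored as two opposite arcs whose Leontis–Westhof families
mirror each other (tSH one way, tHS the other).  Canonical pairs — cWW A-U,
G-C and the Wobble G-U — carry the special family ``CAN``.

The A-minor motif of type I/II is an assembly of two consecutive loop
nucleotides (numbered 5, 6; usually adenines, but either may be substituted)
docking into the minor groove of a helix formed by two consecutive canonical
pairs {1,4} and {2,3}; vertices 1, 2, 5, 6 are the cis Sugar/Sugar
participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

from .errors import ValidationError
from .nomenclature import FAMILIES, mirror

#: Vertex key inside a graph: (chain, 1-based sequence index).
Key = tuple[str, int]

RESIDUES = ("A", "C", "G", "U")


@dataclass(frozen=True, order=True)
class Nucleotide:
    """One nucleotide of one chain; ``seq_index`` is 1-based."""

    structure_id: str
    chain: str
    seq_index: int
    residue: str  # A, C, G, U or "other"

    @property
    def key(self) -> Key:
        return (self.chain, self.seq_index)

    def __str__(self) -> str:
        return f"{self.structure_id}/{self.chain}/{self.seq_index}{self.residue}"


@dataclass(frozen=True)
class Interaction:
    """A directed interaction arc with its family and range tag."""

    family: str
    range: str | None = None  # "short" | "long" | None (not yet computed)


class RnaGraph:
    """Directed labeled multigraph of one RNA structure (possibly multi-chain)."""

    def __init__(self, structure_id: str = "synthetic"):
        self.structure_id = structure_id
        self._nts: dict[Key, Nucleotide] = {}
        self._cov_next: dict[Key, Key] = {}  # 5'→3'
        self._cov_prev: dict[Key, Key] = {}
        self._arcs: dict[tuple[Key, Key], Interaction] = {}

    # -- construction -------------------------------------------------

    def add_nucleotide(self, chain: str, seq_index: int, residue: str) -> Nucleotide:
        key = (chain, seq_index)
        if key in self._nts:
            raise ValidationError(f"duplicate nucleotide {key}")
        residue = residue.upper().replace("T", "U")
        if residue not in RESIDUES:
            residue = "other"
        nt = Nucleotide(self.structure_id, chain, seq_index, residue)
        self._nts[key] = nt
        return nt

    def add_chain(self, chain: str, sequence: str, start: int = 1) -> None:
        """Add a whole chain with its covalent backbone."""
        prev: Key | None = None
        for offset, res in enumerate(sequence):
            nt = self.add_nucleotide(chain, start + offset, res)
            if prev is not None:
                self.add_covalent(prev, nt.key)
            prev = nt.key

    def add_covalent(self, u: Key, v: Key) -> None:
        self._require(u)
        self._require(v)
        if u in self._cov_next or v in self._cov_prev:
            raise ValidationError(f"covalent degree exceeded at {u}->{v}")
        if u[0] != v[0]:
            raise ValidationError(f"covalent arc across chains {u}->{v}")
        if v[1] <= u[1]:
            raise ValidationError(f"covalent arc {u}->{v} violates 5'->3' order")
        self._cov_next[u] = v
        self._cov_prev[v] = u

    def add_interaction(
        self, u: Key, v: Key, family: str, range: str | None = None
    ) -> None:
        """Store one interaction as two mirrored arcs (family given u→v)."""
        self._require(u)
        self._require(v)
        if family not in FAMILIES:
            raise ValidationError(f"unknown family {family!r} on {u}-{v}")
        if u == v:
            raise ValidationError(f"self-interaction at {u}")
        if range not in (None, "short", "long"):
            raise ValidationError(f"bad range tag {range!r}")
        self._arcs[(u, v)] = Interaction(family, range)
        self._arcs[(v, u)] = Interaction(mirror(family), range)

    def _require(self, key: Key) -> None:
        if key not in self._nts:
            raise ValidationError(f"unknown nucleotide {key}")

    # -- access --------------------------------------------------------

    def __contains__(self, key: Key) -> bool:
        return key in self._nts

    def __len__(self) -> int:
        return len(self._nts)

    def nucleotide(self, key: Key) -> Nucleotide:
        return self._nts[key]

    def residue(self, key: Key) -> str:
        return self._nts[key].residue

    @property
    def nucleotides(self) -> Mapping[Key, Nucleotide]:
        return self._nts

    def chains(self) -> list[str]:
        return sorted({c for c, _ in self._nts})

    def chain_keys(self, chain: str) -> list[Key]:
        """Keys of one chain in 5'→3' (seq_index) order."""
        return sorted(k for k in self._nts if k[0] == chain)

    def chain_sequence(self, chain: str) -> str:
        return "".join(self._nts[k].residue for k in self.chain_keys(chain))

    def cov_next(self, key: Key) -> Key | None:
        return self._cov_next.get(key)

    def cov_prev(self, key: Key) -> Key | None:
        return self._cov_prev.get(key)

    def covalent_arcs(self) -> Iterator[tuple[Key, Key]]:
        return iter(sorted(self._cov_next.items()))

    def interaction_arcs(self) -> Iterator[tuple[Key, Key, Interaction]]:
        for (u, v), arc in sorted(self._arcs.items()):
            yield u, v, arc

    def interactions_of(self, key: Key) -> list[tuple[Key, Interaction]]:
        """Outgoing interaction arcs of ``key`` (partner, arc)."""
        return [(v, arc) for (u, v), arc in sorted(self._arcs.items()) if u == key]

    def interaction(self, u: Key, v: Key) -> Interaction | None:
        return self._arcs.get((u, v))

    def has_family(self, u: Key, v: Key, family: str) -> bool:
        arc = self._arcs.get((u, v))
        return arc is not None and arc.family == family

    # -- labels ---------------------------------------------------------

    def label(self, key: Key) -> str:
        """Pairing-state label: 0 unpaired, C only canonical, N only
        non-canonical, M both.  Depends only on incident arc families."""
        fams = {arc.family for (u, _), arc in self._arcs.items() if u == key}
        if not fams:
            return "0"
        if fams == {"CAN"}:
            return "C"
        if "CAN" in fams:
            return "M"
        return "N"

    # -- secondary structure and range tags ------------------------------

    def nested_can_pairs(self) -> set[frozenset[Key]]:
        """Maximum non-crossing subset of CAN pairs (the nested secondary
        structure), computed by Nussinov-style dynamic programming over the
        chains laid out in sorted order."""
        order = sorted(self._nts)
        index = {k: i for i, k in enumerate(order)}
        pairs = {}
        for (u, v), arc in self._arcs.items():
            if arc.family == "CAN" and index[u] < index[v]:
                pairs[(index[u], index[v])] = (u, v)
        if not pairs:
            return set()
        n = len(order)
        partners: dict[int, list[int]] = {}
        for (i, q) in pairs:
            partners.setdefault(i, []).append(q)
        best = np.zeros((n + 1, n + 1), dtype=np.int32)
        # best[i][j] over half-open span [i, j)
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span
                b = best[i + 1, j]  # i unpaired
                for q in partners.get(i, ()):
                    if i + 1 <= q < j:
                        cand = 1 + best[i + 1, q] + best[q + 1, j]
                        if cand > b:
                            b = cand
                best[i, j] = b
        # traceback
        chosen: set[frozenset[Key]] = set()

        def trace(i: int, j: int) -> None:
            while i < j:
                if best[i, j] == best[i + 1, j]:
                    i += 1
                    continue
                for q in sorted(partners.get(i, ())):
                    if i + 1 <= q < j and best[i, j] == 1 + best[i + 1, q] + best[q + 1, j]:
                        u, v = pairs[(i, q)]
                        chosen.add(frozenset({u, v}))
                        trace(i + 1, q)
                        i = q + 1
                        break
                else:  # pragma: no cover - defensive
                    i += 1

        trace(0, n)
        return chosen

    def compute_ranges(self) -> None:
        """Fill missing range tags: an interaction is short-range iff both
        endpoints lie in the same secondary-structure element, i.e. their
        innermost enclosing nested CAN pair is the same.  Tags already present
        (e.g. read from input files) are kept."""
        order = sorted(self._nts)
        index = {k: i for i, k in enumerate(order)}
        nested = self.nested_can_pairs()
        spans = sorted(
            (min(index[u] for u in p), max(index[u] for u in p)) for p in nested
        )

        def innermost(i: int) -> tuple[int, int] | None:
            best_span = None
            for (a, b) in spans:
                if a < i < b and (best_span is None or b - a < best_span[1] - best_span[0]):
                    best_span = (a, b)
            return best_span

        enclosing = {k: innermost(index[k]) for k in order}
        for (u, v), arc in list(self._arcs.items()):
            if arc.range is not None:
                continue
            tag = "short" if enclosing[u] == enclosing[v] else "long"
            self._arcs[(u, v)] = Interaction(arc.family, tag)

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        for (u, v), arc in self._arcs.items():
            back = self._arcs.get((v, u))
            if back is None or back.family != mirror(arc.family):
                raise ValidationError(f"arc {u}->{v} lacks mirrored partner")
        for u, v in self._cov_next.items():
            if u[0] != v[0] or v[1] <= u[1]:
                raise ValidationError(f"covalent arc {u}->{v} out of order")
        for chain in self.chains():
            keys = self.chain_keys(chain)
            starts = [k for k in keys if k not in self._cov_prev]
            if len(keys) > 1 and len(starts) != 1:
                raise ValidationError(f"chain {chain} is not a single covalent path")
            if keys:
                walk = [starts[0] if starts else keys[0]]
                while (nxt := self._cov_next.get(walk[-1])) is not None:
                    walk.append(nxt)
                if walk != keys:
                    raise ValidationError(f"chain {chain} covalent path broken")


# ---------------------------------------------------------------------------
# Motif template and occurrences
# ---------------------------------------------------------------------------

#: Covalent arcs and canonical pairs every type I/II template has.
TEMPLATE_COVALENT = ((1, 2), (3, 4), (5, 6))
TEMPLATE_CAN = (frozenset({1, 4}), frozenset({2, 3}))


@dataclass(frozen=True)
class MotifTemplate:
    """Six-vertex type I/II A-minor template.

    ``noncanonical`` lists required non-canonical edges as
    (template_u, template_v, family), family read u→v.  By default the
    cis Sugar/Sugar contacts are {1,6} and {2,5} (vertices 1, 2, 5, 6 are
    the stated cSS participants); the edge set is overridable because
    instances vary.  ``residue_constraints`` restricts residues by template
    number; by default vertices 5 and 6 are unconstrained (either A may be
    replaced by another nucleotide).
    """

    noncanonical: tuple[tuple[int, int, str], ...] = ((6, 1, "cSS"), (5, 2, "cSS"))
    residue_constraints: Mapping[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v, fam) in self.noncanonical:
            if not ({u, v} <= set(range(1, 7))):
                raise ValidationError(f"template edge {u}-{v} outside 1..6")
            if fam not in FAMILIES or fam == "CAN":
                raise ValidationError(f"template edge {u}-{v} bad family {fam!r}")
            if not ({u, v} & {1, 2, 5, 6}):
                raise ValidationError(
                    f"non-canonical edge {u}-{v} must touch a cSS participant"
                )
        # connectivity over covalent + CAN + noncanonical edges
        gg = nx.Graph()
        gg.add_nodes_from(range(1, 7))
        gg.add_edges_from(TEMPLATE_COVALENT)
        gg.add_edges_from(tuple(p) for p in TEMPLATE_CAN)
        gg.add_edges_from((u, v) for u, v, _ in self.noncanonical)
        if not nx.is_connected(gg):
            raise ValidationError("template graph is not connected")

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifTemplate":
        nc = tuple(
            (int(e["u"]), int(e["v"]), str(e["family"]))
            for e in d.get("noncanonical", [])
        ) or cls.__dataclass_fields__["noncanonical"].default
        rc = {
            int(k): frozenset(v) for k, v in (d.get("residue_constraints") or {}).items()
        }
        return cls(noncanonical=nc, residue_constraints=rc)


@dataclass(frozen=True)
class AminorOccurrence:
    """Mapping of template numbers 1..6 onto nucleotides of one graph."""

    structure_id: str
    positions: tuple[Key, Key, Key, Key, Key, Key]  # template 1..6

    def __post_init__(self) -> None:
        if len(set(self.positions)) != 6:
            raise ValidationError("occurrence vertices must be distinct")

    def __getitem__(self, template_no: int) -> Key:
        return self.positions[template_no - 1]

    @property
    def loop_strand(self) -> tuple[Key, Key]:
        return (self[5], self[6])

    @property
    def helix_strand_a(self) -> tuple[Key, Key]:
        return (self[1], self[2])

    @property
    def helix_strand_b(self) -> tuple[Key, Key]:
        return (self[3], self[4])

    @property
    def id(self) -> str:
        return self.structure_id + "|" + ";".join(f"{c}:{i}" for c, i in self.positions)


def occurrence_satisfies(
    g: RnaGraph, t: MotifTemplate, positions: tuple[Key, ...]
) -> bool:
    """Does the induced subgraph at ``positions`` satisfy the template?"""
    if len(set(positions)) != 6:
        return False
    m = {i + 1: k for i, k in enumerate(positions)}
    for (a, b) in TEMPLATE_COVALENT:
        if g.cov_next(m[a]) != m[b]:
            return False
    for pair in TEMPLATE_CAN:
        a, b = sorted(pair)
        if not g.has_family(m[a], m[b], "CAN"):
            return False
    for (u, v, fam) in t.noncanonical:
        if not g.has_family(m[u], m[v], fam):
            return False
    for no, allowed in t.residue_constraints.items():
        if g.residue(m[no]) not in allowed:
            return False
    return True


def find_motif_occurrences(
    g: RnaGraph, t: MotifTemplate | None = None
) -> list[AminorOccurrence]:
    """All embeddings of the template into ``g``, deduplicated and sorted.

    Anchored backtracking: enumerate the helix pair (1,2) over covalent arcs,
    resolve (4,3) through the canonical pairs, then scan covalent pairs (5,6)
    against the template's non-canonical edge set.
    """
    t = t or MotifTemplate()
    found: set[tuple[Key, ...]] = set()
    cov = list(g.covalent_arcs())
    for v1, v2 in cov:
        v4s = [w for w, arc in g.interactions_of(v1) if arc.family == "CAN"]
        for v4 in v4s:
            v3 = g.cov_prev(v4)
            if v3 is None or not g.has_family(v2, v3, "CAN"):
                continue
            for v5, v6 in cov:
                pos = (v1, v2, v3, v4, v5, v6)
                if occurrence_satisfies(g, t, pos):
                    found.add(pos)
    return [AminorOccurrence(g.structure_id, p) for p in sorted(found)]
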