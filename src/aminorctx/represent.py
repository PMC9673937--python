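"""Class representatives: maximum common subgraph and per-strand regexes.

The *topological representative* of a class is the maximum common subgraph of
the contracted k-extensions of all its members.  Equivalent vertices must
share their label (0, C, N, M or ⊥) and belong to the same branch (vertices
with equal labels but different weights may be equivalent; order along the
strand is preserved); equivalent interaction edges must share their
Leontis–Westhof family; the six motif vertices and their edges are always
part of the common subgraph.  The objective maximizes the number of common
interaction (Ah) edges weighted by the weights of their incident vertices —
here Σ_edges (w(u)+w(v)) with w taken as the minimum over the mapped members.
Covalent edges constrain the mapping but contribute nothing.

The solver is exact: a branch-and-bound search over an association structure
whose elements are cross-member vertex-correspondence tuples; any consistent
set of tuples (injective per member, order-consistent per branch) is a common
subgraph, and size-n consistency reduces to pairwise consistency.  At the
instance sizes that arise for k = 3 this is fast.

The *sequence representative* is one position-wise character class per
strand, of length 2(k+1): a position is constrained to the union of the
members' residues when its nucleotide belongs to the common subgraph in every
member, and is the wildcard N otherwise.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Sequence

from .context import ContractedExtension
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tup:
    """One cross-member vertex correspondence (an association-graph vertex)."""

    ids: tuple[str, ...]  # one contracted-vertex id per member
    label: str
    branch: tuple[int, str] | None  # (root, direction); None for motif / ⊥
    runs: tuple[int, ...]  # run index per member (branch tuples only)
    weight: int  # min weight across members


@dataclass
class CommonSubgraph:
    """Maximum common subgraph of n contracted extensions."""

    members: tuple[ContractedExtension, ...]
    tuples: tuple[Tup, ...]  # motif tuples first, then mapped context tuples
    edges: tuple[tuple[int, int, str], ...]  # (tuple idx, tuple idx, family)
    objective: int

    def mapping(self, member_index: int) -> dict[int, str]:
        """Tuple index → contracted-vertex id in one member."""
        return {i: t.ids[member_index] for i, t in enumerate(self.tuples)}

    def n_interaction_edges(self) -> int:
        return len(self.edges)


def _compatible(t1: Tup, t2: Tup) -> bool:
    for a, b in zip(t1.ids, t2.ids):
        if a == b:
            return False  # injectivity per member
    if t1.branch is not None and t1.branch == t2.branch:
        signs = {(-1 if a < b else 1) for a, b in zip(t1.runs, t2.runs)}
        if len(signs) != 1:
            return False  # order along the strand not preserved
    return True


def _common_families(
    members: Sequence[ContractedExtension], t1: Tup, t2: Tup
) -> frozenset[str]:
    fams: frozenset[str] | None = None
    for m, a, b in zip(members, t1.ids, t2.ids):
        f = m.interactions.get((a, b), frozenset())
        fams = f if fams is None else (fams & f)
        if not fams:
            return frozenset()
    return fams or frozenset()


def _slot_key(m: ContractedExtension, cid: str):
    """Member-independent description of a non-⊥ vertex (for ⊥ profiles)."""
    cv = m.vertices[cid]
    if cv.kind == "motif":
        return ("m", cv.template_no)
    return ("b", cv.root, cv.direction, cv.run_index)


def _bot_classes(m: ContractedExtension) -> dict[frozenset, list[str]]:
    """⊥ vertices grouped by arc profile; profile-equal ⊥s are interchangeable.

    The profile records, per outgoing arc into a non-⊥ vertex, the target's
    slot and the arc family.  ⊥s with no arc into the context cannot occur
    (⊥ vertices are interaction partners by definition) and would contribute
    nothing; they are dropped.
    """
    classes: dict[frozenset, list[str]] = {}
    for cid in sorted(m.vertices):
        cv = m.vertices[cid]
        if cv.kind != "bot":
            continue
        profile = frozenset(
            (_slot_key(m, v), fam)
            for (u, v), fams in m.interactions.items()
            if u == cid and m.vertices[v].kind != "bot"
            for fam in fams
        )
        if profile:
            classes.setdefault(profile, []).append(cid)
    return classes


def _branch_candidates(members: Sequence[ContractedExtension]) -> list[Tup]:
    """Cross-products of label-equal runs, per branch."""
    out: list[Tup] = []
    slots = members[0].branch_runs.keys()
    for slot in sorted(slots):
        per_member = [
            [m.vertices[cid] for cid in m.branch_runs[slot]] for m in members
        ]
        for combo in itertools.product(*per_member):
            labels = {cv.label for cv in combo}
            if len(labels) != 1:
                continue
            out.append(
                Tup(
                    ids=tuple(cv.id for cv in combo),
                    label=combo[0].label,
                    branch=slot,
                    runs=tuple(cv.run_index for cv in combo),
                    weight=min(cv.weight for cv in combo),
                )
            )
    return sorted(set(out), key=lambda t: (t.branch, t.ids))


def _coarse(profile: frozenset) -> frozenset:
    # equivalent runs may sit at different run indices across members, so the
    # cross-member pre-filter compares branch-level profiles only
    return frozenset(
        ((slot[:3] if slot[0] == "b" else slot), fam) for slot, fam in profile
    )


def _bot_combos(
    per_member_classes: list[dict[frozenset, list[str]]]
) -> list[tuple[tuple[frozenset, ...], int]]:
    """Cross-member ⊥-class combinations with their capacities.

    ⊥s of one arc-profile class are interchangeable, so the search optimizes
    the *multiplicity* of each class combination (bounded by the smallest
    class) and concrete ⊥ ids are assigned only afterwards.
    """
    out = []

    def join(i: int, combo: list[frozenset], common: frozenset | None) -> None:
        # running-intersection join: prunes as soon as no potential common
        # edge survives, so the member count does not blow the product up
        if common is not None and not common:
            return
        if i == len(per_member_classes):
            cap = min(len(pc[p]) for pc, p in zip(per_member_classes, combo))
            out.append((tuple(combo), cap))
            return
        for prof in sorted(per_member_classes[i]):
            c = _coarse(prof)
            join(i + 1, combo + [prof], c if common is None else common & c)

    join(0, [], None)
    return out


def common_subgraph_class(members: Sequence[ContractedExtension]) -> CommonSubgraph:
    """Exact maximum common subgraph of ``members`` (n ≥ 1).

    Branch-and-bound over correspondence tuples, maximizing the weighted
    common-Ah-edge objective; ties broken toward the lexicographically
    smallest mapping.  The optimal mapping is then extended maximally with
    zero-contribution compatible tuples (objective-neutral, deterministic),
    so that regex coverage is well defined.
    """
    all_members = tuple(members)
    if not all_members:
        raise ValidationError("need at least one member")
    if len({(m.k, m.S) for m in all_members}) != 1:
        raise ValidationError("members must share the same k and S")

    # structurally identical members constrain nothing beyond one copy:
    # solve on the distinct set, then replicate the mapping (ids are
    # structural, so a duplicate member shares its twin's vertex ids)
    def signature(m: ContractedExtension):
        verts = tuple(
            (cid, cv.label, cv.weight, cv.kind, cv.root, cv.direction, cv.run_index)
            for cid, cv in sorted(m.vertices.items())
        )
        arcs = tuple((k, tuple(sorted(v))) for k, v in sorted(m.interactions.items()))
        return verts, arcs

    sig_index: dict = {}
    unique: list[ContractedExtension] = []
    member_to_unique: list[int] = []
    for m in all_members:
        s = signature(m)
        if s not in sig_index:
            sig_index[s] = len(unique)
            unique.append(m)
        member_to_unique.append(sig_index[s])
    members = tuple(unique)
    n = len(members)

    motif = [
        Tup(ids=(f"m{i}",) * n, label=str(i), branch=None, runs=(), weight=1)
        for i in range(1, 7)
    ]
    cands = _branch_candidates(members)
    per_member_classes = [_bot_classes(m) for m in members]
    combos = _bot_combos(per_member_classes)

    _contrib_cache: dict[tuple[Tup, Tup], int] = {}

    def contrib(t1: Tup, t2: Tup) -> int:
        key = (t1, t2) if t1.ids <= t2.ids else (t2, t1)
        if key not in _contrib_cache:
            _contrib_cache[key] = len(_common_families(members, key[0], key[1])) * (
                key[0].weight + key[1].weight
            )
        return _contrib_cache[key]

    def bot_gain(combo: tuple[frozenset, ...], t: Tup) -> int:
        """Common edges between one ⊥ of each class and a non-⊥ tuple."""
        fams: set[str] | None = None
        for m, prof, tid in zip(members, combo, t.ids):
            slot = _slot_key(m, tid)
            f = {fam for (s, fam) in prof if s == slot}
            fams = f if fams is None else fams & f
            if not fams:
                return 0
        return len(fams) * (1 + t.weight)

    def solve_bots(others: list[Tup]) -> tuple[int, list[tuple[tuple, int]]]:
        """Exact best ⊥ multiplicities given the chosen non-⊥ tuples."""
        gains = []
        for combo, cap in combos:
            g = sum(bot_gain(combo, t) for t in others)
            if g > 0:
                gains.append((g, combo, cap))
        gains.sort(key=lambda x: (-x[0], x[1]))
        suffix = [0] * (len(gains) + 1)
        for i in range(len(gains) - 1, -1, -1):
            suffix[i] = suffix[i + 1] + gains[i][0] * gains[i][2]
        best = [0, []]

        def rec(i: int, usage: dict, acc: int, mults: list) -> None:
            if acc > best[0]:
                best[0], best[1] = acc, list(mults)
            if i == len(gains) or acc + suffix[i] <= best[0]:
                return
            g, combo, cap = gains[i]
            avail = min(
                cap,
                *(
                    len(pc[p]) - usage.get((mi, p), 0)
                    for mi, (pc, p) in enumerate(zip(per_member_classes, combo))
                ),
            )
            for m in range(avail, -1, -1):
                for mi, p in enumerate(combo):
                    usage[(mi, p)] = usage.get((mi, p), 0) + m
                mults.append((combo, m))
                rec(i + 1, usage, acc + m * g, mults)
                mults.pop()
                for mi, p in enumerate(combo):
                    usage[(mi, p)] -= m
            return

        rec(0, {}, 0, [])
        return best[0], [(c, m) for c, m in best[1] if m > 0]

    # split branch candidates into edge-relevant (searched) and neutral
    bot_pot = {
        c.ids: sum(
            bot_gain(combo, c) * cap for combo, cap in combos
        )
        for c in cands
    }
    relevant: list[Tup] = []
    neutral: list[Tup] = []
    for c in cands:
        tot = (
            sum(contrib(c, m) for m in motif)
            + sum(contrib(c, o) for o in cands if o is not c)
            + bot_pot[c.ids]
        )
        (relevant if tot > 0 else neutral).append(c)

    base = sum(contrib(a, b) for a, b in itertools.combinations(motif, 2))

    def total_potential(c: Tup) -> int:
        return (
            sum(contrib(c, m) for m in motif)
            + sum(contrib(c, o) for o in relevant if o is not c)
            + bot_pot[c.ids]
        )

    relevant.sort(key=lambda c: (-total_potential(c), c.ids))
    suffix_pot = [0] * (len(relevant) + 1)
    for i in range(len(relevant) - 1, -1, -1):
        suffix_pot[i] = suffix_pot[i + 1] + total_potential(relevant[i])
    motif_bot_pot = sum(
        max(0, sum(bot_gain(combo, m) for m in motif)) * cap for combo, cap in combos
    )

    best_obj = -1
    best_sel: list[Tup] = []
    best_bots: list[tuple[tuple, int]] = []

    def dfs(i: int, chosen: list[Tup], gain: int, chosen_bpot: int) -> None:
        nonlocal best_obj, best_sel, best_bots
        if gain + suffix_pot[i] + motif_bot_pot + chosen_bpot < best_obj:
            return
        if i == len(relevant):
            bots_gain, mults = solve_bots(motif + chosen)
            total = gain + bots_gain
            key = sorted(t.ids for t in chosen)
            if total > best_obj or (
                total == best_obj and key < sorted(t.ids for t in best_sel)
            ):
                best_obj = total
                best_sel = list(chosen)
                best_bots = mults
            return
        c = relevant[i]
        if all(_compatible(c, t) for t in chosen):
            add = sum(contrib(c, t) for t in chosen) + sum(contrib(c, m) for m in motif)
            chosen.append(c)
            dfs(i + 1, chosen, gain + add, chosen_bpot + bot_pot[c.ids])
            chosen.pop()
        dfs(i + 1, chosen, gain, chosen_bpot)

    dfs(0, [], 0, 0)

    # materialize concrete ⊥ ids for the chosen class multiplicities
    bot_tuples: list[Tup] = []
    counters: dict[tuple[int, frozenset], int] = {}
    for combo, mult in sorted(best_bots, key=lambda x: str(x[0])):
        for _ in range(mult):
            ids = []
            for mi, p in enumerate(combo):
                j = counters.get((mi, p), 0)
                counters[(mi, p)] = j + 1
                ids.append(per_member_classes[mi][p][j])
            bot_tuples.append(
                Tup(ids=tuple(ids), label="⊥", branch=None, runs=(), weight=1)
            )

    # maximal extension with objective-neutral branch tuples
    selected = list(best_sel)
    for c in sorted(neutral, key=lambda t: t.ids):
        if all(_compatible(c, t) for t in selected):
            selected.append(c)
    selected += bot_tuples

    tuples = tuple(motif) + tuple(
        sorted(selected, key=lambda t: (t.branch is None, t.branch or (), t.runs, t.ids))
    )
    edges = []
    for i, j in itertools.combinations(range(len(tuples)), 2):
        for fam in sorted(_common_families(members, tuples[i], tuples[j])):
            edges.append((i, j, fam))
    objective = base + best_obj
    # re-expand to the original member list (duplicates share their twin's ids)
    expanded = tuple(
        Tup(
            ids=tuple(t.ids[ui] for ui in member_to_unique),
            label=t.label,
            branch=t.branch,
            runs=tuple(t.runs[ui] for ui in member_to_unique) if t.runs else (),
            weight=t.weight,
        )
        for t in tuples
    )
    return CommonSubgraph(all_members, expanded, tuple(edges), objective)


def mces_pair(a: ContractedExtension, b: ContractedExtension) -> CommonSubgraph:
    """Maximum common subgraph of two contracted extensions."""
    return common_subgraph_class((a, b))


def edge_range(cs: CommonSubgraph, i: int, j: int, family: str) -> str:
    """Range tag of a common edge: short iff short in every member."""
    t1, t2 = cs.tuples[i], cs.tuples[j]
    for m, a, b in zip(cs.members, t1.ids, t2.ids):
        if m.ranges.get((a, b, family), "long") == "long":
            return "long"
    return "short"


# ---------------------------------------------------------------------------
# Sequence representative
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRepresentative:
    """Per-strand position-wise character classes, length 2(k+1), 5'→3'."""

    k: int
    helix: tuple[frozenset[str] | None, ...]  # None = unconstrained (N)
    loop: tuple[frozenset[str] | None, ...]

    def _classes(self, strand: str) -> tuple[frozenset[str] | None, ...]:
        if strand not in ("helix", "loop"):
            raise ValidationError(f"strand must be 'helix' or 'loop', got {strand!r}")
        return self.helix if strand == "helix" else self.loop

    def pattern(self, strand: str) -> str:
        """Human-readable expression: A, [AG], N ..."""
        out = []
        for cls in self._classes(strand):
            if cls is None or len(cls) == 4:
                out.append("N")
            elif len(cls) == 1:
                out.append(next(iter(cls)))
            else:
                out.append("[" + "".join(sorted(cls)) + "]")
        return "".join(out)

    def regex(self, strand: str) -> re.Pattern:
        parts = []
        for cls in self._classes(strand):
            if cls is None or len(cls) == 4:
                parts.append("[ACGU]")
            else:
                parts.append("[" + "".join(sorted(cls)) + "]")
        return re.compile("".join(parts))

    def matches(self, sequence: str, strand: str) -> bool:
        return self.regex(strand).fullmatch(sequence.upper()) is not None

    def search_positions(self, sequence: str, strand: str) -> list[int]:
        """All (overlapping) 1-based match start positions in ``sequence``."""
        pat = re.compile("(?=" + self.regex(strand).pattern + ")")
        return [m.start() + 1 for m in pat.finditer(sequence.upper())]


#: (left template vertex, right template vertex) per strand, 5'→3'.
STRAND_ROOTS = {"helix": (1, 2), "loop": (5, 6)}


def _member_pattern(
    cs: CommonSubgraph, member_index: int, strand: str, k: int
) -> list[str | None]:
    """One member's covered residues over the 2(k+1) strand positions.

    Branch offset o (1..k) maps to position k+1-o on the 5' side and
    k+2+o on the 3' side; a common contracted vertex of minimum weight p
    covers the first p uncontracted offsets of its run in each member.
    """
    left, right = STRAND_ROOTS[strand]
    m = cs.members[member_index]
    length = 2 * (k + 1)
    pat: list[str | None] = [None] * length
    for t in cs.tuples:
        cv = m.vertices[t.ids[member_index]]
        if cv.kind == "motif":
            no = cv.template_no
            if no == left:
                pat[k] = cv.residues[0]
            elif no == right:
                pat[k + 1] = cv.residues[0]
        elif cv.kind == "branch" and t.branch is not None and t.branch[0] in (left, right):
            for off, res in zip(cv.offsets[: t.weight], cv.residues[: t.weight]):
                pos = (k + 1 - off) if t.branch[0] == left else (k + 2 + off)
                pat[pos - 1] = res
    return pat


def sequence_representative(
    members: Sequence[ContractedExtension] | None = None,
    cs: CommonSubgraph | None = None,
    k: int | None = None,
) -> SequenceRepresentative:
    """Build the class's two expressions from its common subgraph.

    A position is covered iff it belongs to the common subgraph in *every*
    member; covered positions take the union of member residues, uncovered
    (including truncated) positions become N.
    """
    if cs is None:
        if not members:
            raise ValidationError("need members or a common subgraph")
        cs = common_subgraph_class(members)
    k = k if k is not None else cs.members[0].k
    strands = {}
    for strand in ("helix", "loop"):
        length = 2 * (k + 1)
        patterns = [
            _member_pattern(cs, i, strand, k) for i in range(len(cs.members))
        ]
        classes: list[frozenset[str] | None] = []
        for pos in range(length):
            col = [p[pos] for p in patterns]
            if any(c is None for c in col):
                if any(c is not None for c in col):
                    log.info("strand %s position %d N-padded (truncated member)", strand, pos + 1)
                classes.append(None)
            else:
                classes.append(frozenset(col))
        strands[strand] = tuple(classes)
    return SequenceRepresentative(k=k, helix=strands["helix"], loop=strands["loop"])
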