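"""Maximum common subgraph (MCES) and sequence representatives."""

import itertools

import numpy as np
import pytest

import aminorctx as amc
from aminorctx.context import ContractedExtension
from aminorctx.represent import (
    common_subgraph_class,
    mces_pair,
    sequence_representative,
)

from conftest import make_planted_graph


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every label/branch/order-consistent mapping
# ---------------------------------------------------------------------------

def _full_objective(m: ContractedExtension) -> int:
    total = 0
    for (u, v), fams in m.interactions.items():
        if u < v:
            total += len(fams) * (m.vertices[u].weight + m.vertices[v].weight)
    return total


def oracle_objective(members: list[ContractedExtension]) -> int:
    """Exhaustive search over all consistent cross-member mappings."""
    m0 = members[0]
    others = members[1:]
    cands0 = sorted(
        cid for cid, cv in m0.vertices.items() if cv.kind in ("branch", "bot")
    )

    def compatible(cv0, cv):
        if cv0.kind != cv.kind or cv0.label != cv.label:
            return False
        if cv0.kind == "branch":
            return (cv0.root, cv0.direction) == (cv.root, cv.direction)
        return True

    def objective(mapping):
        # mapping: member-0 id -> tuple of ids in `others`; motif implied
        rows = [{f"m{i}": f"m{i}" for i in range(1, 7)} for _ in members]
        for cid0, imgs in mapping.items():
            rows[0][cid0] = cid0
            for mi, img in enumerate(imgs, start=1):
                rows[mi][cid0] = img
        total = 0
        keys = sorted(rows[0])
        for a, b in itertools.combinations(keys, 2):
            fams = None
            for mm, row in zip(members, rows):
                f = mm.interactions.get((row[a], row[b]), frozenset())
                fams = f if fams is None else fams & f
                if not fams:
                    break
            if fams:
                wa = min(mm.vertices[row[a]].weight for mm, row in zip(members, rows))
                wb = min(mm.vertices[row[b]].weight for mm, row in zip(members, rows))
                total += len(fams) * (wa + wb)
        return total

    best = [0]

    def order_ok(mapping, cid0, imgs):
        cv0 = m0.vertices[cid0]
        if cv0.kind != "branch":
            return True
        for other_cid, other_imgs in mapping.items():
            cv0b = m0.vertices[other_cid]
            if cv0b.kind != "branch" or (cv0b.root, cv0b.direction) != (
                cv0.root,
                cv0.direction,
            ):
                continue
            s0 = np.sign(cv0.run_index - cv0b.run_index)
            for mi, mm in enumerate(others):
                s = np.sign(
                    mm.vertices[imgs[mi]].run_index
                    - mm.vertices[other_imgs[mi]].run_index
                )
                if s != s0:
                    return False
        return True

    def rec(i, mapping, used):
        if i == len(cands0):
            best[0] = max(best[0], objective(mapping))
            return
        cid0 = cands0[i]
        rec(i + 1, mapping, used)  # leave unmapped
        cv0 = m0.vertices[cid0]
        options = []
        for mi, mm in enumerate(others):
            opts = [
                cid
                for cid, cv in sorted(mm.vertices.items())
                if compatible(cv0, cv) and cid not in used[mi]
            ]
            options.append(opts)
        for imgs in itertools.product(*options):
            if not order_ok(mapping, cid0, imgs):
                continue
            mapping[cid0] = imgs
            for mi, img in enumerate(imgs):
                used[mi].add(img)
            rec(i + 1, mapping, used)
            for mi, img in enumerate(imgs):
                used[mi].remove(img)
            del mapping[cid0]

    rec(0, {}, [set() for _ in others])
    # motif-only mapping contributes too
    best[0] = max(best[0], objective({}))
    return best[0]


def small_contracted(rng, S=(5, 6), k=3, extras=3) -> ContractedExtension:
    g, occ = make_planted_graph(rng, n_extra_interactions=int(rng.integers(0, extras + 1)))
    return amc.contract(amc.extend(g, occ, S, k))


class TestMcesPair:
    def test_identity_is_whole_graph(self):
        rng = np.random.default_rng(1)
        a = small_contracted(rng, S=(1, 2, 5, 6))
        cs = mces_pair(a, a)
        assert cs.objective == _full_objective(a)

    def test_motif_only_when_nothing_else_common(self):
        g1, o1 = make_planted_graph(np.random.default_rng(2))
        g2, o2 = make_planted_graph(np.random.default_rng(3))
        # give every loop-branch vertex of the second graph an N label
        for p in (17, 18, 21, 22, 23):
            g2.add_interaction(("A", p), ("A", 35), "tHH")
        a = amc.contract(amc.extend(g1, o1, (5, 6), 3))
        b = amc.contract(amc.extend(g2, o2, (5, 6), 3))
        cs = mces_pair(a, b)
        # common part: the 4 motif interactions (2 CAN + 2 cSS), weights 1+1
        assert cs.objective == 8
        assert all(t.label == "⊥" or t.branch is None for t in cs.tuples[6:]) or len(cs.tuples) >= 6

    def test_objective_symmetric(self):
        rng = np.random.default_rng(4)
        a = small_contracted(rng)
        b = small_contracted(rng)
        assert mces_pair(a, b).objective == mces_pair(b, a).objective

    def test_mapped_tuples_share_label_and_branch(self):
        rng = np.random.default_rng(5)
        a = small_contracted(rng, S=(1, 2, 5, 6))
        b = small_contracted(rng, S=(1, 2, 5, 6))
        cs = mces_pair(a, b)
        for t in cs.tuples[6:]:
            cva = a.vertices[t.ids[0]]
            cvb = b.vertices[t.ids[1]]
            assert cva.label == cvb.label == t.label
            if t.branch is not None:
                assert (cva.root, cva.direction) == t.branch
                assert (cvb.root, cvb.direction) == t.branch

    @pytest.mark.parametrize("seed", range(80))
    def test_objective_equals_brute_force(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        S = (5, 6) if seed % 2 else (1, 5, 6)
        k = 2 if seed % 3 else 3
        a = small_contracted(rng, S=S, k=k)
        b = small_contracted(rng, S=S, k=k)
        assert mces_pair(a, b).objective == oracle_objective([a, b])


class TestClassSubgraph:
    def test_identical_members_give_full_graph(self):
        rng = np.random.default_rng(6)
        a = small_contracted(rng, S=(1, 2, 5, 6))
        cs = common_subgraph_class([a, a, a])
        assert cs.objective == _full_objective(a)

    def test_two_members_equal_pairwise(self):
        rng = np.random.default_rng(7)
        a = small_contracted(rng)
        b = small_contracted(rng)
        assert common_subgraph_class([a, b]).objective == mces_pair(a, b).objective

    def test_objective_non_increasing_in_members(self):
        rng = np.random.default_rng(8)
        a, b, c = (small_contracted(rng) for _ in range(3))
        assert common_subgraph_class([a, b]).objective >= common_subgraph_class(
            [a, b, c]
        ).objective

    @pytest.mark.parametrize("seed", range(30))
    def test_three_way_objective_equals_brute_force(self, seed):
        rng = np.random.default_rng(20_000 + seed)
        members = [small_contracted(rng, S=(5, 6), k=2, extras=2) for _ in range(3)]
        assert common_subgraph_class(members).objective == oracle_objective(members)


class TestSequenceRepresentative:
    def _members(self, seeds, mutate=None):
        out = []
        for s in seeds:
            g, occ = make_planted_graph(np.random.default_rng(s))
            if mutate:
                mutate(g, s)
            out.append(amc.contract(amc.extend(g, occ, (1, 2, 5, 6), 3)))
        return out

    def test_expressions_have_length_2k_plus_2(self):
        members = self._members([11, 12, 13])
        rep = sequence_representative(members)
        assert len(rep.helix) == 8 and len(rep.loop) == 8

    def test_position_classes_are_member_unions(self):
        members = self._members([11, 12, 13])
        rep = sequence_representative(members)
        # identical topology: every position covered; classes = residue unions
        for strand, (left, right) in (("helix", (1, 2)), ("loop", (5, 6))):
            seqs = [m.source.strand_sequence(strand) for m in members]
            for pos in range(8):
                want = frozenset(s[pos] for s in seqs)
                got = rep._classes(strand)[pos]
                assert got == want

    def test_uncovered_positions_are_n(self):
        def mutate(g, s):
            if s == 21:  # make one member's loop branch N-labeled: not common
                for p in (17, 18, 21, 22, 23):
                    g.add_interaction(("A", p), ("A", 35), "tHH")

        members = self._members([21, 22], mutate=mutate)
        rep = sequence_representative(members)
        pat = rep.pattern("loop")
        assert pat[:3] == "NNN" and pat[-3:] == "NNN"
        assert "N" not in pat[3:5]  # motif positions stay covered

    def test_every_member_matches_its_class_expressions(self, small_classification):
        cl = small_classification
        for c in cl.classes:
            rep = c.sequence_representative
            for m in c.members:
                e = cl.extensions[m]
                assert rep.matches(e.strand_sequence("loop"), "loop")
                assert rep.matches(e.strand_sequence("helix"), "helix")

    def test_two_residue_union_renders_bracket_class(self):
        def mutate(g, s):
            # rewrite the residue 3' of vertex 6 (loop strand position 6)
            res = {31: "A", 32: "G", 33: "A"}[s]
            key = ("A", 21)
            nt = g.nucleotides[key]
            g._nts[key] = amc.Nucleotide(nt.structure_id, nt.chain, nt.seq_index, res)

        members = self._members([31, 32, 33], mutate=mutate)
        rep = sequence_representative(members)
        assert rep._classes("loop")[5] == frozenset({"A", "G"})
        assert rep.pattern("loop")[5] == "[" or "[AG]" in rep.pattern("loop")
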