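"""Context kinds, sequence/graph search, PPV and TPR."""

import itertools

import numpy as np
import pytest

import aminorctx as amc
from aminorctx.classify import MotifClass
from aminorctx.predict import (
    SIDE_MOTIF,
    ClassContext,
    StrandHit,
    build_context,
    ppv,
    search_context,
    search_graph,
    search_sequences,
    tpr,
)
from aminorctx.represent import common_subgraph_class, sequence_representative

from conftest import make_planted_graph


def make_class(graph_occ_pairs, k=2, S=(1, 2, 5, 6)) -> MotifClass:
    members = [
        amc.contract(amc.extend(g, occ, S, k)) for g, occ in graph_occ_pairs
    ]
    cs = common_subgraph_class(members)
    cls = MotifClass(0, tuple(f"m{i}" for i in range(len(members))))
    cls.topological_representative = cs
    cls.sequence_representative = sequence_representative(cs=cs, k=k)
    return cls


# ---------------------------------------------------------------------------
# Brute-force embedding oracle: enumerate, then validate
# ---------------------------------------------------------------------------

def oracle_hits(ctx: ClassContext, g: amc.RnaGraph) -> set:
    hits = set()
    cov = list(g.covalent_arcs())
    for q in ctx.queries:
        sides = ("loop", "helix") if q.side == "both" else (q.side,)
        k = q.k
        plans = {}
        for side in sides:
            for root in SIDE_MOTIF[side]:
                plans[root] = [
                    i
                    for i in q.tuple_indices
                    if q.cs.tuples[i].branch is not None
                    and q.cs.tuples[i].branch[0] == root
                ]
                plans[root].sort(key=lambda i: q.cs.tuples[i].runs[0])
        bot_idx = [i for i in q.tuple_indices if q.cs.tuples[i].label == "⊥"]
        needs_partner = any(
            q.cs.tuples[i].branch is None and q.cs.tuples[i].label in ("3", "4")
            for i in q.tuple_indices
        )

        anchor_space = [cov] * len(sides)
        partner_space = cov if (needs_partner and "helix" in sides) else [None]
        for anchors in itertools.product(*anchor_space):
            for partner in partner_space:
                base = {}
                for side, (u, v) in zip(sides, anchors):
                    a, b = SIDE_MOTIF[side]
                    base[a - 1] = (u,)
                    base[b - 1] = (v,)
                if partner is not None:
                    base[2] = (partner[0],)
                    base[3] = (partner[1],)
                for im in _oracle_branches(g, q, sides, plans, base, k):
                    if not _oracle_nonbot_edges_ok(g, q, im):
                        continue
                    for fin in _oracle_bots(g, q, bot_idx, im):
                        if not _oracle_valid(g, q, fin, ctx, sides):
                            continue
                        loop_pos = (fin[4][0], fin[5][0]) if "loop" in sides else None
                        helix_pos = (fin[0][0], fin[1][0]) if "helix" in sides else None
                        hits.add((g.structure_id, q.side, loop_pos, helix_pos))
    return hits


def _walk(g, start, step, n):
    out, cur = [], start
    for _ in range(n):
        cur = step(cur) if cur is not None else None
        if cur is None:
            return None
        out.append(cur)
    return out


def _oracle_branches(g, q, sides, plans, base, k):
    roots = [r for s in sides for r in SIDE_MOTIF[s]]
    specs = []  # (root, tuple indices)
    for root in roots:
        specs.append((root, plans[root]))
    choice_space = []
    for root, plan in specs:
        per_run = []
        prev_run = -1
        for ti in plan:
            t = q.cs.tuples[ti]
            gaps = range(0, k + 1) if t.runs[0] != prev_run + 1 else (0,)
            per_run.append([(gap, ln) for gap in gaps for ln in range(1, k + 1)])
            prev_run = t.runs[0]
        choice_space.append(list(itertools.product(*per_run)))
    for combo in itertools.product(*choice_space):
        images = dict(base)
        ok = True
        for (root, plan), choices in zip(specs, combo):
            anchor = images[root - 1][0]
            step = g.cov_prev if root in (1, 5) else g.cov_next
            cur = anchor
            for ti, (gap, ln) in zip(plan, choices):
                spacer = _walk(g, cur, step, gap)
                if spacer is None:
                    ok = False
                    break
                cur = spacer[-1] if spacer else cur
                run = _walk(g, cur, step, ln)
                if run is None:
                    ok = False
                    break
                t = q.cs.tuples[ti]
                if any(g.label(x) != t.label for x in run):
                    ok = False
                    break
                images[ti] = tuple(run)
                cur = run[-1]
            if not ok:
                break
        if ok:
            vals = [x for v in images.values() for x in v]
            if len(vals) == len(set(vals)):
                yield images


def _oracle_nonbot_edges_ok(g, q, images):
    for (i, j, fam) in q.edges:
        if i not in images or j not in images:
            continue  # involves a ⊥ not yet assigned
        if not any(g.has_family(u, v, fam) for u in images[i] for v in images[j]):
            return False
    return True


def _oracle_bots(g, q, bot_idx, images):
    used = {x for v in images.values() for x in v}
    domains = []
    for ti in bot_idx:
        # domain prefilter: the vertex must carry every family this ⊥ needs
        need = {fam for (i, j, fam) in q.edges if i == ti} | {
            amc.nomenclature.mirror(fam) for (i, j, fam) in q.edges if j == ti
        }
        domain = []
        for key in sorted(g.nucleotides):
            if key in used:
                continue
            fams = {arc.family for _p, arc in g.interactions_of(key)}
            if need <= fams:
                domain.append(key)
        domains.append(domain)
    for combo in itertools.product(*domains):
        if len(set(combo)) != len(combo) or set(combo) & used:
            continue
        out = dict(images)
        for ti, key in zip(bot_idx, combo):
            out[ti] = (key,)
        yield out


def _oracle_valid(g, q, images, ctx, sides):
    for i in q.tuple_indices:
        if i not in images:
            return False
    for (i, j, fam) in q.edges:
        if not any(
            g.has_family(u, v, fam) for u in images[i] for v in images[j]
        ):
            return False
    if ctx.seqrep is not None:
        for s in sides:
            a, b = SIDE_MOTIF[s]
            pair = (images[a - 1][0], images[b - 1][0])
            chain = pair[0][0]
            keys = g.chain_keys(chain)
            i = keys.index(pair[0])
            if i - ctx.k < 0 or i - ctx.k + 2 * (ctx.k + 1) > len(keys):
                return False
            win = "".join(
                g.residue(kk) for kk in keys[i - ctx.k : i - ctx.k + 2 * (ctx.k + 1)]
            )
            if not ctx.seqrep.matches(win, s):
                return False
    return True


def impl_hits(ctx, g):
    return {
        (h.structure_id, h.side, h.loop_positions, h.helix_positions)
        for h in search_graph(ctx, g)
    }


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestBuildContext:
    def test_sequence_kind_has_regexes_only(self, small_classification):
        cls = small_classification.classes[0]
        ctx = build_context(cls, "sequence")
        assert ctx.queries == () and ctx.seqrep is not None

    def test_all_interactions_splits_into_two_graphs(self, small_classification):
        cls = small_classification.classes[0]
        ctx = build_context(cls, "all_interactions")
        assert {q.side for q in ctx.queries} == {"loop", "helix"}
        assert ctx.seqrep is None

    def test_inter_strand_interaction_keeps_single_graph(self):
        def build(seed):
            g, occ = make_planted_graph(np.random.default_rng(seed))
            # extra loop-helix interaction beyond the motif itself
            g.add_interaction(("A", 18), ("A", 13), "tWH")
            return g, occ

        cls = make_class([build(1), build(1)], k=3)
        ctx = build_context(cls, "all_interactions")
        assert len(ctx.queries) == 1 and ctx.queries[0].side == "both"

    def test_short_range_kind_keeps_only_short_can_edges(self, small_classification):
        cls = small_classification.classes[0]
        ctx = build_context(cls, "sequence_canonical_short_range")
        for q in ctx.queries:
            for (i, j, fam) in q.edges:
                assert fam == "CAN"
        assert ctx.seqrep is not None

    def test_missing_representative_is_error(self):
        with pytest.raises(amc.errors.ValidationError):
            build_context(MotifClass(0, ("x",)), "sequence")


class TestSearchSequences:
    def _ctx(self, classes_loop, classes_helix, k=3):
        rep = amc.SequenceRepresentative(k=k, helix=classes_helix, loop=classes_loop)
        return ClassContext(0, "sequence", k, (), rep)

    def _graph(self, seq):
        g = amc.RnaGraph("G")
        g.add_chain("A", seq)
        return g

    def test_all_wildcards_slide_over_sequence(self):
        ctx = self._ctx((None,) * 8, (None,) * 8)
        hits = search_sequences(ctx, [self._graph("ACGUACGUAC")])
        loop_hits = [h for h in hits if h.side == "loop"]
        assert len(loop_hits) == 3  # window starts 1..3

    def test_unique_planted_word_hits_once(self):
        classes = tuple(frozenset(c) for c in "GGGGCCCC")
        ctx = self._ctx(classes, (None,) * 8)
        hits = search_sequences(ctx, [self._graph("AUAUGGGGCCCCAUAU")])
        loop_hits = [h for h in hits if h.side == "loop"]
        assert len(loop_hits) == 1
        assert loop_hits[0].loop_positions == (("A", 8), ("A", 9))

    def test_character_class_matches_both_variants(self):
        classes = tuple(
            frozenset(c) if c != "R" else frozenset("AG") for c in "UUURUUUU"
        )
        ctx = self._ctx(classes, (None,) * 8)
        for base in "AG":
            g = self._graph(f"UUU{base}UUUU")
            assert any(h.side == "loop" for h in search_sequences(ctx, [g]))
        assert not [
            h
            for h in search_sequences(ctx, [self._graph("UUUCUUUU")])
            if h.side == "loop"
        ]

    def test_overlapping_matches_reported(self):
        classes = tuple(frozenset("A") for _ in range(8))
        ctx = self._ctx(classes, (None,) * 8)
        hits = [h for h in search_sequences(ctx, [self._graph("A" * 12)]) if h.side == "loop"]
        assert len(hits) == 5


class TestSearchGraph:
    def test_planted_context_found_at_planted_location(self, small_classification, small_dataset):
        cl = small_classification
        cls = cl.classes[0]
        ctx = build_context(cls, "sequence_all_interactions")
        member = cl.occurrences[cls.members[0]]
        g = small_dataset.graphs[member.structure_id]
        hits = search_graph(ctx, g)
        loop_hits = {h.loop_positions for h in hits if h.side == "loop"}
        assert member.loop_strand in loop_hits

    def test_regex_exclusion_gives_zero_hits(self, small_classification, small_dataset):
        cl = small_classification
        cls = cl.classes[0]
        ctx = build_context(cls, "sequence_all_interactions")
        impossible = amc.SequenceRepresentative(
            k=3,
            helix=ctx.seqrep.helix,
            loop=tuple(frozenset("U") for _ in range(8)),
        )
        ctx2 = ClassContext(cls.id, ctx.kind, ctx.k, ctx.queries, impossible)
        member = cl.occurrences[cls.members[0]]
        g = small_dataset.graphs[member.structure_id]
        # GNRA loop windows are not all-U: every loop hit disappears
        assert not [h for h in search_graph(ctx2, g) if h.side == "loop"]

    @pytest.mark.parametrize("seed", range(25))
    def test_hits_equal_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(30_000 + seed)
        pair = [
            make_planted_graph(rng, n_extra_interactions=2) for _ in range(2)
        ]
        cls = make_class(pair, k=2)
        target, _ = make_planted_graph(rng, n_extra_interactions=3)
        kind = "all_interactions" if seed % 2 else "sequence_all_interactions"
        ctx = build_context(cls, kind)
        assert impl_hits(ctx, target) == oracle_hits(ctx, target)

    @pytest.mark.parametrize("seed", range(5))
    def test_self_recovery_on_member_graph(self, seed):
        rng = np.random.default_rng(31_000 + seed)
        pair = [make_planted_graph(rng, n_extra_interactions=2) for _ in range(2)]
        cls = make_class(pair, k=2)
        ctx = build_context(cls, "all_interactions")
        g, occ = pair[0]
        hits = search_graph(ctx, g)
        assert occ.loop_strand in {h.loop_positions for h in hits if h.side == "loop"}
        assert occ.helix_strand_a in {
            h.helix_positions for h in hits if h.side == "helix"
        }


class TestNesting:
    def test_combined_hits_subset_of_each_component(self, small_classification, small_dataset):
        cl = small_classification
        graphs = [small_dataset.graphs[s] for s in sorted(small_dataset.graphs)]
        for cls in cl.classes:
            both = search_context(build_context(cls, "sequence_all_interactions"), graphs)
            seq = search_context(build_context(cls, "sequence"), graphs)
            topo = search_context(build_context(cls, "all_interactions"), graphs)

            def keyset(hits, side):
                return {
                    (h.structure_id, h.positions(side))
                    for h in hits
                    if h.side in (side, "both")
                }

            for side in ("loop", "helix"):
                assert keyset(both, side) <= keyset(seq, side)
                assert keyset(both, side) <= keyset(topo, side)


def fake_occ(i, sid="S"):
    base = 10 * i
    return amc.AminorOccurrence(
        sid,
        tuple(("A", base + j) for j in range(1, 7)),
    )


class TestPpvArithmetic:
    def test_three_of_four_hits(self):
        truth = [fake_occ(1)]
        assignment = {truth[0].id: {0}}
        hits = [
            StrandHit("S", "loop", 0, loop_positions=truth[0].loop_strand),
            StrandHit("S", "loop", 0, loop_positions=(("A", 901), ("A", 902))),
            StrandHit("S", "loop", 0, loop_positions=(("A", 903), ("A", 904))),
            StrandHit("S", "loop", 0, loop_positions=(("A", 905), ("A", 906))),
        ]
        r = ppv(hits, truth, assignment, 0, "loop")
        assert (r.tp, r.positives, r.value) == (1, 4, 0.25)

    def test_all_hits_true(self):
        truth = [fake_occ(1), fake_occ(2)]
        assignment = {o.id: {0} for o in truth}
        hits = [
            StrandHit("S", "helix", 0, helix_positions=o.helix_strand_a) for o in truth
        ]
        assert ppv(hits, truth, assignment, 0, "helix").value == 1.0

    def test_no_hits_gives_null(self):
        r = ppv([], [fake_occ(1)], {}, 0, "loop")
        assert r.value is None and r.positives == 0

    def test_other_class_occurrence_counts_false_positive(self):
        o1, o2 = fake_occ(1), fake_occ(2)
        assignment = {o1.id: {0}, o2.id: {1}}
        hits = [
            StrandHit("S", "loop", 0, loop_positions=o1.loop_strand),
            StrandHit("S", "loop", 0, loop_positions=o2.loop_strand),
        ]
        r = ppv(hits, [o1, o2], assignment, 0, "loop")
        assert (r.tp, r.positives) == (1, 2)

    def test_single_graph_hit_needs_both_strands(self):
        o = fake_occ(1)
        assignment = {o.id: {0}}
        good = StrandHit("S", "both", 0, o.loop_strand, o.helix_strand_a)
        bad = StrandHit("S", "both", 0, o.loop_strand, (("A", 901), ("A", 902)))
        r = ppv([good, bad], [o], assignment, 0, "loop")
        assert (r.tp, r.positives) == (1, 2)


class TestTpr:
    def _hits_for(self, occs, cls_id=0):
        hits = []
        for o in occs:
            hits.append(StrandHit(o.structure_id, "loop", cls_id, loop_positions=o.loop_strand))
            hits.append(
                StrandHit(o.structure_id, "helix", cls_id, helix_positions=o.helix_strand_a)
            )
        return hits

    def test_table_arithmetic_76_of_87(self):
        truth = [fake_occ(i, f"S{i}") for i in range(87)]
        rate, found = tpr({0: self._hits_for(truth[:76])}, truth)
        assert found == 76
        assert rate == pytest.approx(76 / 87)
        assert f"{rate:.2f}" == "0.87"

    def test_table_arithmetic_368_of_374(self):
        truth = [fake_occ(i, f"S{i}") for i in range(374)]
        rate, found = tpr({0: self._hits_for(truth[:368])}, truth)
        assert found == 368
        assert f"{rate:.2f}" == "0.98"

    def test_both_strands_must_come_from_same_class(self):
        o = fake_occ(1)
        hits = {
            0: [StrandHit("S", "loop", 0, loop_positions=o.loop_strand)],
            1: [StrandHit("S", "helix", 1, helix_positions=o.helix_strand_a)],
        }
        rate, found = tpr(hits, [o])
        assert found == 0

    def test_empty_truth_is_null(self):
        assert tpr({}, []) == (None, 0)


class TestDecoys:
    def test_sequence_ppv_drops_with_decoys_tpr_stays(
        self, small_dataset, decoy_dataset
    ):
        from aminorctx.pipeline import classify_occurrences, predict_all_kinds

        base = classify_occurrences(
            small_dataset.graphs, small_dataset.coords, small_dataset.truth
        )
        clean = predict_all_kinds(
            base, small_dataset.graphs, small_dataset.truth, kinds=("sequence",)
        )["sequence"]
        noisy_cl = classify_occurrences(
            decoy_dataset.graphs, decoy_dataset.coords, decoy_dataset.truth
        )
        noisy = predict_all_kinds(
            noisy_cl, decoy_dataset.graphs, decoy_dataset.truth, kinds=("sequence",)
        )["sequence"]
        for side in ("loop", "helix"):
            assert noisy.mean_ppv(side) < clean.mean_ppv(side)
        assert noisy.tpr == 1.0
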