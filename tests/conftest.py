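"""Shared fixtures: tiny planted-motif graphs and randomized instances.

Everything is generated programmatically and seeded; no stored data files.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import aminorctx as amc
from aminorctx.graph import RnaGraph, occurrence_satisfies
from aminorctx.nomenclature import LW_FAMILIES

NONCAN_FAMILIES = sorted(LW_FAMILIES - {"cWW"})


def make_planted_graph(
    rng: np.random.Generator | None = None,
    n_extra_interactions: int = 0,
    chain_len: int = 40,
) -> tuple[RnaGraph, amc.AminorOccurrence]:
    """One chain with a planted A-minor template plus optional random arcs.

    Layout (1-based): helix strand a = 8..15 with motif 1,2 at 11,12;
    partner strand built by CAN pairs 24..31 (3,4 at 27,28); loop strand
    5,6 at 19,20.  Extra random non-canonical arcs perturb labels and ⊥s.
    """
    rng = rng or np.random.default_rng(0)
    g = RnaGraph("T")
    seq = "".join(rng.choice(list("ACGU"), size=chain_len))
    g.add_chain("A", seq)
    for j in range(8):
        g.add_interaction(("A", 8 + j), ("A", 31 - j), "CAN")
    v1, v2 = ("A", 11), ("A", 12)
    v4, v3 = ("A", 28), ("A", 27)
    v5, v6 = ("A", 19), ("A", 20)
    g.add_interaction(v6, v1, "cSS")
    g.add_interaction(v5, v2, "cSS")
    for _ in range(n_extra_interactions):
        for _attempt in range(30):
            i = int(rng.integers(1, chain_len + 1))
            j = int(rng.integers(1, chain_len + 1))
            if abs(i - j) < 2:
                continue
            if g.interaction(("A", i), ("A", j)) is not None:
                continue
            fam = str(rng.choice(NONCAN_FAMILIES))
            g.add_interaction(("A", i), ("A", j), fam)
            break
    g.compute_ranges()
    g.validate()
    occ = amc.AminorOccurrence("T", (v1, v2, v3, v4, v5, v6))
    assert occurrence_satisfies(g, amc.MotifTemplate(), occ.positions)
    return g, occ


def brute_force_occurrences(g: RnaGraph, t: amc.MotifTemplate) -> set[tuple]:
    """Independent occurrence search: try every assignment of three covalent
    arcs to the template's (1,2), (3,4), (5,6) pairs."""
    arcs = list(g.covalent_arcs())
    found = set()
    for (a1, a2), (a3, a4), (a5, a6) in itertools.product(arcs, repeat=3):
        pos = (a1, a2, a3, a4, a5, a6)
        if occurrence_satisfies(g, t, pos):
            found.add(pos)
    return found


@pytest.fixture(scope="session")
def small_dataset() -> amc.Dataset:
    """3 archetypes x 4 molecules, low noise, no decoys."""
    spec = amc.FixtureSpec(
        seed=7,
        archetypes=(("gnra_dock", 4), ("arich_loop", 4), ("plain_loop", 4)),
        sigma=0.25,
    )
    return amc.generate(spec)


@pytest.fixture(scope="session")
def decoy_dataset() -> amc.Dataset:
    spec = amc.FixtureSpec(
        seed=7,
        archetypes=(("gnra_dock", 4), ("arich_loop", 4), ("plain_loop", 4)),
        sigma=0.25,
        decoy_slots=5,
    )
    return amc.plant_decoys(amc.generate(spec))


@pytest.fixture(scope="session")
def small_classification(small_dataset) -> "amc.Classification":
    from aminorctx.pipeline import classify_occurrences

    return classify_occurrences(
        small_dataset.graphs, small_dataset.coords, small_dataset.truth
    )


def random_contracted_pairs(seed: int, count: int, n_members: int = 2):
    """Random same-(k,S) contracted extensions for MCES oracle checks."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        members = []
        k = 3
        S = (1, 2, 5, 6)
        for _m in range(n_members):
            g, occ = make_planted_graph(
                rng, n_extra_interactions=int(rng.integers(0, 5))
            )
            e = amc.extend(g, occ, S, k)
            members.append(amc.contract(e))
        out.append(tuple(members))
    return out
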