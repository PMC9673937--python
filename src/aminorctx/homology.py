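"""Dedicated homology detection between A-minor occurrences.

Two occurrences from homologous molecules are called homologous when the
global alignments of the sequence windows around their three motif strands
(strand ± 30 nt, truncated at chain ends) all score at least 50, and the
motif-anchored context RMSD is at most 2 Å.  Occurrences are then grouped
single-link: homology groups are the connected components of the graph with
one edge per homologous pair.

Alignment scoring follows EMBOSS Needle's nucleotide defaults: EDNAFULL
match +5 / mismatch -4, affine gaps with opening penalty 10 and extension
penalty 0.5 (the opening penalty covers the first gap position), end gaps
free.  The scorer is a hand-rolled Gotoh dynamic program; the test suite
cross-checks it against Bio.Align.PairwiseAligner.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .graph import AminorOccurrence, RnaGraph

log = logging.getLogger(__name__)

#: Default operating-point thresholds.
SCORE_THRESHOLD = 50.0
RMSD_THRESHOLD = 2.0
FLANK = 30

MATCH, MISMATCH = 5.0, -4.0
GAP_OPEN, GAP_EXTEND = 10.0, 0.5


def flank_windows(
    occ: AminorOccurrence, g: RnaGraph, flank: int = FLANK
) -> tuple[str, str, str]:
    """Sequence windows around the three motif strands.

    Returns (loop 5-6, helix 1-2, helix 3-4) windows: each strand plus
    ``flank`` nucleotides on each side along its chain, truncated at chain
    ends.  Full-length windows have 2·flank + 2 = 62 nt.
    """
    out = []
    for a, b in ((5, 6), (1, 2), (3, 4)):
        (chain, i), (_, j) = occ[a], occ[b]
        lo, hi = min(i, j), max(i, j)
        keys = [
            (chain, p)
            for p in range(lo - flank, hi + flank + 1)
            if (chain, p) in g
        ]
        out.append("".join(g.residue(k) for k in keys))
    return tuple(out)


def nw_score(s1: str, s2: str) -> float:
    """Global alignment score, affine gaps, end gaps not penalized (Gotoh)."""
    if not s1 or not s2:
        log.info("nw_score on empty sequence -> 0")
        return 0.0
    a, b = s1.upper(), s2.upper()
    n, m = len(a), len(b)
    neg = -np.inf
    # M: a[i-1] aligned to b[j-1]; X: gap in b (a consumed); Y: gap in a
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading end gaps free
    Y[0, 1:] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            open_x = max(M[i - 1, j], Y[i - 1, j]) - GAP_OPEN
            X[i, j] = max(open_x, X[i - 1, j] - GAP_EXTEND)
            open_y = max(M[i, j - 1], X[i, j - 1]) - GAP_OPEN
            Y[i, j] = max(open_y, Y[i, j - 1] - GAP_EXTEND)
    # trailing end gaps free: best over last row/column
    best = max(M[n, m], X[n, m], Y[n, m])
    for i in range(n + 1):
        best = max(best, M[i, m], X[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j], Y[n, j])
    return float(best)


@dataclass(frozen=True)
class HomologyVerdict:
    pair: tuple[str, str]  # occurrence ids
    scores: tuple[float, ...]  # one per strand window
    rmsd: float
    homologous: bool


def are_homologous(
    o1: AminorOccurrence,
    o2: AminorOccurrence,
    g1: RnaGraph,
    g2: RnaGraph,
    rmsd: float,
    score_threshold: float = SCORE_THRESHOLD,
    rmsd_threshold: float = RMSD_THRESHOLD,
    families: Mapping[str, str] | None = None,
    require: str = "all",
) -> HomologyVerdict | None:
    """Verdict for one pair; ``rmsd`` is the 3–1,2,5,6-extension context RMSD.

    Only pairs from homologous molecules are eligible: when ``families``
    (structure_id → molecule family) is given, pairs from different families
    or with missing metadata are skipped (None returned, logged).
    ``require`` is "all" (all three alignment scores over threshold) or
    "loop_best_helix" (loop window plus the better helix window).
    """
    if families is not None:
        f1 = families.get(o1.structure_id)
        f2 = families.get(o2.structure_id)
        if f1 is None or f2 is None:
            log.info("pair (%s, %s) skipped: missing family metadata", o1.id, o2.id)
            return None
        if f1 != f2:
            return None
    w1 = flank_windows(o1, g1)
    w2 = flank_windows(o2, g2)
    scores = tuple(nw_score(a, b) for a, b in zip(w1, w2))
    if require == "all":
        seq_ok = all(s >= score_threshold for s in scores)
    elif require == "loop_best_helix":
        seq_ok = scores[0] >= score_threshold and max(scores[1:]) >= score_threshold
    else:
        raise ValueError(f"unknown require mode {require!r}")
    return HomologyVerdict(
        pair=(o1.id, o2.id),
        scores=scores,
        rmsd=rmsd,
        homologous=seq_ok and rmsd <= rmsd_threshold,
    )


@dataclass(frozen=True)
class HomologyGroup:
    id: int
    members: tuple[str, ...]


def homology_groups(
    verdicts: Sequence[HomologyVerdict], ids: Sequence[str] | None = None
) -> list[HomologyGroup]:
    """Single-link grouping: connected components of the homology graph."""
    g = nx.Graph()
    if ids is not None:
        g.add_nodes_from(ids)
    for v in verdicts:
        g.add_nodes_from(v.pair)
        if v.homologous:
            g.add_edge(*v.pair)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [HomologyGroup(i, tuple(c)) for i, c in enumerate(comps)]
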