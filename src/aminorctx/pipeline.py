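"""End-to-end convenience layer: occurrences → classes → representatives →
prediction report.  Thin orchestration over the per-stage modules; every
step is also available separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .classify import DEFAULT_TAU, MotifClass, assign_to_class, cluster, similarity_graph
from .context import ContractedExtension, Extension, contract, extend
from .errors import ValidationError
from .geometry import LocalStructure, local_structure, rmsd_context
from .graph import AminorOccurrence, RnaGraph
from .io import CoordinateSet
from .predict import PredictionReport, evaluate
from .represent import common_subgraph_class, sequence_representative


@dataclass
class Classification:
    """Classes of embedded occurrences plus everything used to build them."""

    k: int
    S: frozenset[int]
    tau: float
    occurrences: dict[str, AminorOccurrence]
    extensions: dict[str, Extension]
    contracted: dict[str, ContractedExtension]
    structures: dict[str, LocalStructure]
    classes: list[MotifClass] = field(default_factory=list)
    _rmsd_cache: dict[frozenset, float] = field(default_factory=dict)

    def rmsd(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if a == b:
            return 0.0
        if key not in self._rmsd_cache:
            self._rmsd_cache[key] = rmsd_context(self.structures[a], self.structures[b])
        return self._rmsd_cache[key]

    def assignment(self) -> dict[str, set[int]]:
        """Occurrence id → ids of classes it belongs to (RMSD ≤ τ to ≥1 member)."""
        out: dict[str, set[int]] = {}
        for oid in self.occurrences:
            out[oid] = {
                c.id for c in self.classes if assign_to_class(oid, c, self.rmsd, self.tau)
            }
        return out


def classify_occurrences(
    graphs: Mapping[str, RnaGraph],
    coords: Mapping[str, CoordinateSet],
    occurrences: Sequence[AminorOccurrence],
    k: int = 3,
    S: Iterable[int] = (1, 2, 5, 6),
    tau: float = DEFAULT_TAU,
    with_representatives: bool = True,
) -> Classification:
    """Extend, embed, compare and cluster a set of occurrences."""
    S = frozenset(S)
    exts, cexts, structs, occs = {}, {}, {}, {}
    for occ in occurrences:
        if occ.structure_id not in graphs:
            raise ValidationError(f"no graph for structure {occ.structure_id}")
        e = extend(graphs[occ.structure_id], occ, S, k)
        occs[occ.id] = occ
        exts[occ.id] = e
        cexts[occ.id] = contract(e)
        structs[occ.id] = local_structure(e, coords[occ.structure_id])
    cl = Classification(k, S, tau, occs, exts, cexts, structs)
    sg = similarity_graph(sorted(occs), cl.rmsd, tau)
    cl.classes = cluster(sg)
    if with_representatives:
        for c in cl.classes:
            members = [cexts[m] for m in c.members]
            cs = common_subgraph_class(members)
            c.topological_representative = cs
            c.sequence_representative = sequence_representative(cs=cs, k=k)
    return cl


def predict_all_kinds(
    cl: Classification,
    graphs: Mapping[str, RnaGraph],
    truth: Sequence[AminorOccurrence],
    kinds: Sequence[str] = (
        "sequence",
        "all_interactions",
        "sequence_canonical_short_range",
        "sequence_all_interactions",
    ),
    min_members: int = 3,
) -> dict[str, PredictionReport]:
    """Search every context kind and score PPV per class/strand plus TPR."""
    assignment = cl.assignment()
    glist = [graphs[s] for s in sorted(graphs)]
    return {
        kind: evaluate(cl.classes, kind, glist, truth, assignment, min_members)
        for kind in kinds
    }
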