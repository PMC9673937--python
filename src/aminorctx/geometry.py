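"""Motif-anchored superposition and RMSD between local 3D structures.

Each nucleotide of a k-S-extension (⊥ vertices excluded) is represented by
its C3' atom.  To compare two occurrences, the six motif nucleotides are
superposed slot-for-slot by a least-squares rigid transform (Kabsch); that
transform is then frozen and the RMSD is computed over all slot-corresponding
points of the two local structures.  Fitting on the motif only makes the
measure symmetric in its two arguments; both directions are computed and
checked to agree to 1e-9 Å, and their mean is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .context import Extension, Slot
from .errors import GeometryError
from .io import CoordinateSet

log = logging.getLogger(__name__)

MOTIF_SLOTS = tuple(("m", n) for n in range(1, 7))


@dataclass(frozen=True)
class LocalStructure:
    """Ordered C3' point set of one extension (slots → points, Å)."""

    slots: tuple[Slot, ...]
    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if len(self.slots) != len(self.points):
            raise GeometryError("slot/point length mismatch")
        if len(set(self.slots)) != len(self.slots):
            raise GeometryError("duplicate slots")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.slots)

    def point(self, slot: Slot) -> np.ndarray:
        return self.points[self.slots.index(slot)]

    def subset(self, slots) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.slots)}
        return self.points[[index[s] for s in slots]]

    def transformed(self, t: "RigidTransform") -> "LocalStructure":
        return LocalStructure(self.slots, t.apply(self.points))


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R @ x + t with R orthonormal, det(R) = +1."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    @staticmethod
    def random(rng: np.random.Generator, scale: float = 10.0) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=rng).as_matrix()
        return RigidTransform(rot, rng.normal(scale=scale, size=3))


def local_structure(e: Extension, coords: CoordinateSet) -> LocalStructure:
    """One C3' point per non-⊥ vertex of the extension, slotted."""
    slots, pts, missing = [], [], []
    for slot, key in e.core_slots():
        if key not in coords:
            missing.append(key)
            continue
        slots.append(slot)
        pts.append(coords[key])
    if missing:
        raise GeometryError(f"missing C3' coordinates for vertices: {missing}")
    return LocalStructure(tuple(slots), np.asarray(pts, dtype=float))


def kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set ``q`` onto ``p``."""
    if p.shape != q.shape or p.shape[1] != 3:
        raise GeometryError("point sets must be (n, 3) and congruent")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9:  # rank < 2: collinear/degenerate point set
        raise GeometryError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, pc - r @ qc)


def superpose_motif(a: LocalStructure, b: LocalStructure) -> RigidTransform:
    """Kabsch transform mapping b's six motif points onto a's,
    correspondence by template number."""
    for s in MOTIF_SLOTS:
        if s not in a.slots or s not in b.slots:
            raise GeometryError(f"motif slot {s} missing")
    return kabsch(a.subset(MOTIF_SLOTS), b.subset(MOTIF_SLOTS))


def _rmsd(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def _directional(a: LocalStructure, b: LocalStructure) -> tuple[float, int]:
    common = [s for s in a.slots if s in set(b.slots)]
    if len(common) == len(MOTIF_SLOTS):
        log.info("no common branch slots beyond the motif; RMSD over motif only")
    t = superpose_motif(a, b)
    return _rmsd(a.subset(common), t.apply(b.subset(common))), len(common)


def rmsd_context(a: LocalStructure, b: LocalStructure) -> float:
    """Motif-anchored RMSD (Å) between two local 3D structures.

    Computed over the intersection of slots; with unequal branch lengths the
    denominator is the number of compared pairs.  Pairs sharing fewer than
    12 points are flagged in the log.
    """
    fwd, n = _directional(a, b)
    rev, _ = _directional(b, a)
    if abs(fwd - rev) > 1e-9:
        raise GeometryError(
            f"directional RMSDs disagree ({fwd:.12f} vs {rev:.12f})"
        )
    if n < 12:
        log.info("context RMSD compared over only %d points", n)
    return 0.5 * (fwd + rev)


def rmsd_matrix(structures: list[LocalStructure]) -> np.ndarray:
    """Dense symmetric all-pairs context RMSD matrix."""
    n = len(structures)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = rmsd_context(structures[i], structures[j])
    return m
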