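"""Seeded generator of synthetic RNA molecules with planted A-minor motifs.

Each molecule is a single chain carrying (i) a receptor helix H1 whose
central consecutive canonical pairs host the motif's helix side (vertices
1, 2, 3, 4), and (ii) a donor element whose loop contributes the two
consecutive docking nucleotides (5, 6), joined to the helix by the two cis
Sugar/Sugar arcs of the type I/II template.  Three archetypes emulate the
loop contexts most often seen around real A-minors:

* ``gnra_dock`` — a GNRA tetraloop hairpin docking into the helix;
* ``arich_loop`` — an A-rich internal loop (with tSH and tWH arcs across
  the loop, as in the A-rich motif);
* ``plain_loop`` — an unstructured internal loop.

Toy C3' coordinates are built per archetype from idealized A-form helix
constants (rise 2.81 Å, twist 32.7°, C3' radius 9.4 Å) with loops on bulged
arcs; every molecule is a rigid motion of its archetype layout plus i.i.d.
Gaussian coordinate noise σ (default 0.3 Å, the sub-Å scale of coordinate
uncertainty in good crystal structures).  All comparisons downstream are
superposition-based, so only the internal geometry matters.  By
construction — and asserted at generation time — occurrences of one
archetype lie within 2.5 Å context RMSD of each other while distinct
archetypes are separated by more than 2.5 Å.

Sequence decoys (strands matching a class's loop expression but carrying no
interaction topology) can be planted into the unpaired linker of each
molecule without touching the truth annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .context import extend
from .errors import ValidationError
from .geometry import local_structure, rmsd_context
from .graph import AminorOccurrence, MotifTemplate, RnaGraph, find_motif_occurrences
from .io import (
    CoordinateSet,
    write_coords_csv,
    write_fasta,
    write_graphs_json,
    write_occurrence_list,
)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# idealized A-form constants for C3' placement
RISE = 2.81  # Å per step
TWIST = np.deg2rad(32.7)
RADIUS = 9.4  # Å
PAIR_PHASE = np.deg2rad(152.0)  # angular offset of the paired strand

ARCHETYPES = ("gnra_dock", "arich_loop", "plain_loop")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible description of one synthetic dataset."""

    seed: int = 0
    archetypes: tuple[tuple[str, int], ...] = (
        ("gnra_dock", 10),
        ("arich_loop", 10),
        ("plain_loop", 10),
    )
    sigma: float = 0.3  # coordinate noise, Å
    decoy_slots: int = 0  # decoy payload slots per molecule

    @property
    def n_molecules(self) -> int:
        return sum(n for _, n in self.archetypes)


@dataclass
class Dataset:
    """In-memory synthetic dataset; writable as plain-text files."""

    spec: FixtureSpec
    graphs: dict[str, RnaGraph]
    coords: dict[str, CoordinateSet]
    truth: list[AminorOccurrence]
    archetype_of: dict[str, str]  # occurrence id -> archetype
    #: structure id -> (start, stop, side) 1-based inclusive decoy payload spans
    decoy_regions: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        out = {}
        for sid, g in sorted(self.graphs.items()):
            for chain in g.chains():
                out[f"{sid}|{chain}"] = g.chain_sequence(chain)
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_graphs_json([self.graphs[s] for s in sorted(self.graphs)], outdir / "graphs.json")
        write_fasta(self.sequences(), outdir / "sequences.fa")
        (outdir / "coords").mkdir(exist_ok=True)
        for sid in sorted(self.coords):
            write_coords_csv(self.coords[sid], outdir / "coords" / f"{sid}.csv")
        write_occurrence_list(self.truth, outdir / "truth.csv", labels=self.archetype_of)


# ---------------------------------------------------------------------------
# Per-archetype sequence design (positions are segment-local)
# ---------------------------------------------------------------------------

#: H1 strand (8 nt; motif vertices 1,2 at local offsets 3,4),
#: donor stem strand (5 nt), loop strand holding vertices 5,6 and partners.
_DESIGN = {
    "gnra_dock": dict(
        h1="GCGAAGUC", stem2="GGCAC", loop1="GAAA", loop2=None, stem3=None, contact="tWW"
    ),
    "arich_loop": dict(
        h1="CAGGACAG", stem2="CCGUG", loop1="GAAAU", loop2="UCA", stem3="GCAG", contact="tHH"
    ),
    "plain_loop": dict(
        h1="UGCACUGG", stem2="GAGCC", loop1="UCACUU", loop2="AGU", stem3="GGAC", contact="tSW"
    ),
}
#: index of motif vertex 5 within loop1 (vertex 6 follows it)
_V5_AT = {"gnra_dock": 2, "arich_loop": 2, "plain_loop": 2}

#: rigid placement (rotation axis, angle deg, translation) of the donor stem
_DONOR_FRAME = {
    "gnra_dock": ((0.0, 1.0, 0.0), 75.0, (22.0, 4.0, -6.0)),
    "arich_loop": ((1.0, 0.0, 0.0), -60.0, (-5.0, 24.0, 3.0)),
    "plain_loop": ((1.0, 1.0, 0.0), 120.0, (14.0, -20.0, 8.0)),
}
#: bulge vector (Å) shaping the donor loop arc
_BULGE = {
    "gnra_dock": (6.0, -8.0, 3.0),
    "arich_loop": (-9.0, 2.0, 7.0),
    "plain_loop": (4.0, 9.0, -6.0),
}


def _rotation(axis, deg) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * np.deg2rad(deg)).as_matrix()


def _helix_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """C3' points of an n-step A-form stem: (strand1 5'→3', strand2 5'→3')."""
    j = np.arange(n)
    s1 = np.stack(
        [RADIUS * np.cos(j * TWIST), RADIUS * np.sin(j * TWIST), RISE * j], axis=1
    )
    partner = np.stack(
        [
            RADIUS * np.cos(j * TWIST + PAIR_PHASE),
            RADIUS * np.sin(j * TWIST + PAIR_PHASE),
            RISE * j + 1.4,
        ],
        axis=1,
    )
    return s1, partner[::-1]  # strand2 runs antiparallel


def _arc(a: np.ndarray, b: np.ndarray, n: int, bulge: np.ndarray, jitter: np.ndarray) -> np.ndarray:
    """n points on a quadratic arc from a to b bulged by ``bulge``."""
    t = (np.arange(1, n + 1) / (n + 1))[:, None]
    mid = (a + b) / 2 + bulge
    pts = (1 - t) ** 2 * a + 2 * t * (1 - t) * mid + t**2 * b
    return pts + jitter


@dataclass
class _Layout:
    """Sequence, pairings, extra arcs and base coordinates of one archetype."""

    sequence: str
    can_pairs: list[tuple[int, int]]
    noncan: list[tuple[int, int, str]]  # (i, j, family) 1-based positions
    motif: tuple[int, int, int, int, int, int]  # chain positions of vertices 1..6
    coords: np.ndarray  # (len, 3) base C3' layout
    linker: tuple[int, int]  # 1-based inclusive span available for decoys


def _build_layout(archetype: str, decoy_slots: int) -> _Layout:
    d = _DESIGN[archetype]
    arng = np.random.default_rng(
        np.random.SeedSequence([0xA1109, ARCHETYPES.index(archetype)])
    )
    h1, stem2, loop1 = d["h1"], d["stem2"], d["loop1"]
    loop2, stem3 = d["loop2"], d["stem3"]

    segs: list[tuple[str, str]] = [("tail5", "GAU"), ("h1s1", h1), ("t1", "UUCGCU"),
                                   ("h1s2", _revcomp(h1))]
    # each decoy slot holds a loop payload and a helix payload (8 nt each)
    linker = "CA" + "".join(
        "AA" + _random_seq(arng, 8) + "AA" + _random_seq(arng, 8)
        for _ in range(decoy_slots)
    ) + "GU"
    segs.append(("linker", linker))
    segs.append(("s2a", stem2))
    segs.append(("loop1", loop1))
    if stem3 is not None:  # internal loop: loop1 / stem3 hairpin / loop2
        segs.append(("s3a", stem3))
        segs.append(("t3", "UUCG"))
        segs.append(("s3b", _revcomp(stem3)))
        segs.append(("loop2", loop2))
    segs.append(("s2b", _revcomp(stem2)))
    segs.append(("tail3", "ACG"))

    starts: dict[str, int] = {}
    pos = 1
    for name, seq in segs:
        starts[name] = pos
        pos += len(seq)
    sequence = "".join(seq for _, seq in segs)
    n = len(sequence)

    def span(name: str) -> range:
        seq = dict(segs)[name]
        return range(starts[name], starts[name] + len(seq))

    can_pairs: list[tuple[int, int]] = []
    for j in range(len(h1)):
        can_pairs.append((starts["h1s1"] + j, starts["h1s2"] + len(h1) - 1 - j))
    for j in range(len(stem2)):
        can_pairs.append((starts["s2a"] + j, starts["s2b"] + len(stem2) - 1 - j))
    if stem3 is not None:
        for j in range(len(stem3)):
            can_pairs.append((starts["s3a"] + j, starts["s3b"] + len(stem3) - 1 - j))

    v1 = starts["h1s1"] + 3
    v2 = v1 + 1
    v4 = starts["h1s2"] + len(h1) - 4  # partner of v1
    v3 = v4 - 1  # partner of v2
    v5 = starts["loop1"] + _V5_AT[archetype]
    v6 = v5 + 1
    noncan = [(v6, v1, "cSS"), (v5, v2, "cSS")]
    # archetype-specific tertiary contact off the helix strand (makes the
    # helix-side context position-specific: the contacted branch vertex is
    # labeled M, its partner in the hairpin T1 becomes a ⊥ context vertex)
    noncan.append((starts["h1s1"] + 6, starts["t1"] + 1, d["contact"]))
    if archetype == "arich_loop":
        noncan.append((starts["loop1"] + 1, starts["loop2"] + 1, "tSH"))
        noncan.append((starts["loop1"] + 4, starts["loop2"], "tWH"))

    # ---- base coordinates -------------------------------------------
    coords = np.zeros((n + 1, 3))  # 1-based
    s1_pts, s2_pts = _helix_coords(len(h1))
    for j, p in zip(span("h1s1"), s1_pts):
        coords[j] = p
    for j, p in zip(span("h1s2"), s2_pts):
        coords[j] = p

    rot = _rotation(*_DONOR_FRAME[archetype][:2])
    tr = np.asarray(_DONOR_FRAME[archetype][2])
    d1, d2 = _helix_coords(len(stem2))
    for j, p in zip(span("s2a"), d1):
        coords[j] = p @ rot.T + tr
    for j, p in zip(span("s2b"), d2):
        coords[j] = p @ rot.T + tr
    if stem3 is not None:
        t1, t2 = _helix_coords(len(stem3))
        shift = tr + rot @ np.array([2.0, 3.0, RISE * (len(stem2) + len(loop1) - 2)])
        bend = _rotation((0, 0, 1), 25.0)
        for j, p in zip(span("s3a"), t1):
            coords[j] = p @ (rot @ bend).T + shift
        for j, p in zip(span("s3b"), t2):
            coords[j] = p @ (rot @ bend).T + shift

    bulge = np.asarray(_BULGE[archetype])

    def fill_arc(name: str, a_pos: int, b_pos: int, bulge_vec) -> None:
        m = len(dict(segs)[name])
        jit = arng.normal(scale=0.6, size=(m, 3))
        pts = _arc(coords[a_pos], coords[b_pos], m, np.asarray(bulge_vec), jit)
        for j, p in zip(span(name), pts):
            coords[j] = p

    fill_arc("t1", starts["t1"] - 1, starts["h1s2"], (10.0, 3.0, 5.0))
    fill_arc("linker", starts["linker"] - 1, starts["s2a"], (-12.0, -10.0, 6.0))
    if stem3 is None:
        fill_arc("loop1", starts["loop1"] - 1, starts["s2b"], bulge)
    else:
        fill_arc("loop1", starts["loop1"] - 1, starts["s3a"], bulge)
        fill_arc("t3", starts["t3"] - 1, starts["s3b"], (5.0, 5.0, 5.0))
        fill_arc("loop2", starts["loop2"] - 1, starts["s2b"], -0.6 * bulge)
    # tails extrapolate away from their neighbours
    for j in reversed(span("tail5")):
        nxt = coords[j + 1]
        ref = coords[j + 2]
        coords[j] = nxt + (nxt - ref) + arng.normal(scale=0.4, size=3)
    for j in span("tail3"):
        prv = coords[j - 1]
        ref = coords[j - 2]
        coords[j] = prv + (prv - ref) + arng.normal(scale=0.4, size=3)

    lk = span("linker")
    return _Layout(
        sequence=sequence,
        can_pairs=can_pairs,
        noncan=noncan,
        motif=(v1, v2, v3, v4, v5, v6),
        coords=coords[1:],
        linker=(lk.start, lk.stop - 1),
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _molecule(
    sid: str, archetype: str, layout: _Layout, rng: np.random.Generator, sigma: float
) -> tuple[RnaGraph, CoordinateSet, AminorOccurrence]:
    g = RnaGraph(sid)
    g.add_chain("A", layout.sequence)
    for i, j in layout.can_pairs:
        g.add_interaction(("A", i), ("A", j), "CAN")
    for i, j, fam in layout.noncan:
        g.add_interaction(("A", i), ("A", j), fam)
    g.compute_ranges()
    g.validate()

    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    tr = rng.normal(scale=30.0, size=3)
    pts = layout.coords @ rot.T + tr + rng.normal(scale=sigma, size=layout.coords.shape)
    cs = CoordinateSet(sid)
    for i in range(len(layout.sequence)):
        cs.points[("A", i + 1)] = pts[i]

    occ = AminorOccurrence(sid, tuple(("A", p) for p in layout.motif))
    return g, cs, occ


def generate(spec: FixtureSpec, validate: bool = True) -> Dataset:
    """Build the dataset described by ``spec`` (same spec → identical data)."""
    for name, count in spec.archetypes:
        if name not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {name!r}")
        if count < 0:
            raise ValidationError("archetype counts must be >= 0")
    graphs: dict[str, RnaGraph] = {}
    coords: dict[str, CoordinateSet] = {}
    truth: list[AminorOccurrence] = []
    arch_of: dict[str, str] = {}
    decoy_regions: dict[str, list[tuple[int, int]]] = {}

    for ai, (archetype, count) in enumerate(spec.archetypes):
        layout = _build_layout(archetype, spec.decoy_slots)
        for mi in range(count):
            sid = f"{archetype[:4].upper()}{mi:03d}"
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, ai, mi])
            )
            g, cs, occ = _molecule(sid, archetype, layout, rng, spec.sigma)
            graphs[sid] = g
            coords[sid] = cs
            truth.append(occ)
            arch_of[occ.id] = archetype
            start, _stop = layout.linker
            regions = []
            for s in range(spec.decoy_slots):
                base = start + 2 + 20 * s
                regions.append((base + 2, base + 9, "loop"))
                regions.append((base + 12, base + 19, "helix"))
            decoy_regions[sid] = regions

    ds = Dataset(spec, graphs, coords, truth, arch_of, decoy_regions)
    if validate:
        _validate_dataset(ds)
    return ds


def _validate_dataset(ds: Dataset) -> None:
    """Construction guarantees: planted occurrences are exactly what template
    search finds, and archetypes are RMSD-separated around the 2.5 Å threshold."""
    template = MotifTemplate()
    planted = {occ.id for occ in ds.truth}
    for sid, g in ds.graphs.items():
        hits = {o.id for o in find_motif_occurrences(g, template)}
        want = {oid for oid in planted if oid.startswith(sid + "|")}
        if hits != want:
            raise ValidationError(
                f"{sid}: template search found {hits}, planted {want}"
            )
    structures = {}
    for occ in ds.truth:
        e = extend(ds.graphs[occ.structure_id], occ, {1, 2, 5, 6}, 3)
        structures[occ.id] = local_structure(e, ds.coords[occ.structure_id])
    ids = sorted(structures)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = rmsd_context(structures[ids[i]], structures[ids[j]])
            same = ds.archetype_of[ids[i]] == ds.archetype_of[ids[j]]
            if same and r >= 2.5:
                raise ValidationError(
                    f"intra-archetype RMSD {r:.2f} Å >= 2.5 ({ids[i]}, {ids[j]})"
                )
            if not same and r <= 2.5:
                raise ValidationError(
                    f"inter-archetype RMSD {r:.2f} Å <= 2.5 ({ids[i]}, {ids[j]})"
                )


def plant_decoys(ds: Dataset, spec: FixtureSpec | None = None) -> Dataset:
    """Fill each molecule's decoy slots with its own strand 8-mers.

    Each slot receives the molecule's loop-strand window and helix-strand
    window — strings matching the molecule's class expressions but carrying
    no interaction topology.  Graph residues are rewritten in place of the
    linker payloads; truth annotations and coordinates are untouched.  With
    zero slots the dataset is returned unchanged.
    """
    spec = spec or ds.spec
    if spec.decoy_slots == 0:
        return ds
    new_graphs: dict[str, RnaGraph] = {}
    occ_by_sid = {occ.structure_id: occ for occ in ds.truth}
    for sid, g in ds.graphs.items():
        occ = occ_by_sid[sid]
        e = extend(g, occ, {1, 2, 5, 6}, 3)
        payload = {s: e.strand_sequence(s) for s in ("loop", "helix")}
        strand_keys = set(e.strand_keys("loop")) | set(e.strand_keys("helix"))
        ng = RnaGraph(sid)
        seq = list(g.chain_sequence("A"))
        for (start, stop, side) in ds.decoy_regions[sid]:
            if any(("A", p) in strand_keys for p in range(start, stop + 1)):
                raise ValidationError(f"{sid}: decoy region overlaps a truth strand")
            seq[start - 1 : stop] = list(payload[side])
        ng.add_chain("A", "".join(seq))
        for u, v, arc in g.interaction_arcs():
            if u <= v:
                ng.add_interaction(u, v, arc.family, arc.range)
        ng.validate()
        new_graphs[sid] = ng
    return Dataset(
        ds.spec, new_graphs, ds.coords, ds.truth, ds.archetype_of, ds.decoy_regions
    )
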