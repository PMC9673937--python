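"""Readers and writers for graphs, coordinates, sequences and occurrence lists.

Formats
-------
* FR3D-style interaction table: TSV with columns ``unit_id_1  unit_id_2
  family``; a unit id is ``structure|model|chain|residue|number`` (e.g.
  ``1ABC|1|A|G|42``).  The covalent backbone comes from a companion FASTA of
  chain sequences (record ids ``structure|chain`` or plain chain names).
* Graph JSON: this package's lossless dialect, schema ``rnagraph-v1``.
* Coordinates: PDB/mmCIF (via gemmi, first model / first altloc, C3' atoms)
  or a fixture CSV ``chain,seq_index,x,y,z``.
* Occurrence CSV: ``structure_id,chain,pos1..pos6``; a position may override
  its chain as ``B:15``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

from .errors import ParseError, SchemaError, ValidationError
from .graph import AminorOccurrence, Key, MotifTemplate, RnaGraph, occurrence_satisfies
from .nomenclature import LW_FAMILIES, normalize_family

SCHEMA = "rnagraph-v1"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Record id → sequence (uppercased, T→U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


# ---------------------------------------------------------------------------
# FR3D-style interaction table
# ---------------------------------------------------------------------------

def _parse_unit_id(token: str, lineno: int) -> tuple[str, str, str, int]:
    parts = token.split("|")
    if len(parts) != 5:
        raise ParseError(
            f"line {lineno}: malformed unit id {token!r} "
            "(expected structure|model|chain|residue|number)"
        )
    structure, _model, chain, residue, number = parts
    try:
        pos = int(number)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer position in {token!r}") from None
    return structure, chain, residue, pos


def read_interaction_table(
    path: str | Path,
    fasta_path: str | Path,
    structure_id: str | None = None,
) -> RnaGraph:
    """Build a graph from a pairwise annotation table plus chain sequences.

    Interactions are given one-directional; the mirrored arcs are synthesized.
    cWW rows between canonical/Wobble partners become CAN.  Rows whose two
    units belong to different structures (intermolecular) are dropped.
    An optional fourth column gives the range tag (short/long).
    """
    seqs = read_fasta(fasta_path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected 3+ columns, got {len(parts)}")
            u = _parse_unit_id(parts[0], lineno)
            v = _parse_unit_id(parts[1], lineno)
            family = parts[2]
            rng = parts[3] if len(parts) > 3 and parts[3] in ("short", "long") else None
            if family not in LW_FAMILIES and family != "CAN":
                raise ValidationError(
                    f"line {lineno}: family {family!r} outside the 13-symbol set"
                )
            rows.append((u, v, family, rng, lineno))

    if structure_id is None:
        sids = {u[0] for u, v, *_ in rows} | {v[0] for u, v, *_ in rows}
        structure_id = sorted(sids)[0] if sids else "structure"

    g = RnaGraph(structure_id)
    for rec_id, seq in seqs.items():
        chain = rec_id.split("|")[-1]
        g.add_chain(chain, seq)

    for u, v, family, rng, lineno in rows:
        if u[0] != v[0]:
            continue  # intermolecular pair: dropped
        if u[0] != structure_id:
            continue
        for (_, chain, res, pos) in (u, v):
            if (chain, pos) not in g:
                raise ParseError(
                    f"line {lineno}: unit {chain}|{res}|{pos} not covered by FASTA"
                )
            have = g.residue((chain, pos))
            if have not in ("other",) and res.upper().replace("T", "U") != have:
                raise ValidationError(
                    f"line {lineno}: residue mismatch at {chain}:{pos} "
                    f"(table {res}, sequence {have})"
                )
        fam = normalize_family(family, u[2], v[2])
        g.add_interaction((u[1], u[3]), (v[1], v[3]), fam, rng)

    g.compute_ranges()
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Graph JSON
# ---------------------------------------------------------------------------

def graph_to_dict(g: RnaGraph) -> dict:
    seen = set()
    interactions = []
    for u, v, arc in g.interaction_arcs():
        if frozenset({u, v}) in seen:
            continue
        seen.add(frozenset({u, v}))
        interactions.append(
            {
                "nt1": list(u),
                "nt2": list(v),
                "family": arc.family,
                "range": arc.range,
            }
        )
    return {
        "schema": SCHEMA,
        "structure_id": g.structure_id,
        "nucleotides": [
            {"chain": c, "index": i, "residue": g.residue((c, i))}
            for (c, i) in sorted(g.nucleotides)
        ],
        "covalent": [[list(u), list(v)] for u, v in g.covalent_arcs()],
        "interactions": interactions,
    }


def write_graph_json(g: RnaGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(g), fh, indent=1, sort_keys=True)
        fh.write("\n")


def graph_from_dict(doc: dict, pointer: str = "") -> RnaGraph:
    def fail(ptr: str, msg: str) -> None:
        raise SchemaError(f"{pointer}{ptr}: {msg}")

    if not isinstance(doc, dict):
        fail("", "document is not an object")
    if doc.get("schema") != SCHEMA:
        fail("/schema", f"expected {SCHEMA!r}, got {doc.get('schema')!r}")
    for fld in ("structure_id", "nucleotides", "covalent", "interactions"):
        if fld not in doc:
            fail(f"/{fld}", "missing required field")
    g = RnaGraph(doc["structure_id"])
    for i, nt in enumerate(doc["nucleotides"]):
        try:
            g.add_nucleotide(nt["chain"], int(nt["index"]), nt["residue"])
        except (KeyError, TypeError, ValidationError) as exc:
            fail(f"/nucleotides/{i}", str(exc))
    if len(g) > 1 and not doc["covalent"]:
        fail("/covalent", "graph has nucleotides but no covalent arcs")
    for i, (u, v) in enumerate(doc["covalent"]):
        try:
            g.add_covalent((u[0], int(u[1])), (v[0], int(v[1])))
        except (IndexError, TypeError, ValidationError) as exc:
            fail(f"/covalent/{i}", str(exc))
    for i, rec in enumerate(doc["interactions"]):
        try:
            u, v = rec["nt1"], rec["nt2"]
            g.add_interaction(
                (u[0], int(u[1])), (v[0], int(v[1])), rec["family"], rec.get("range")
            )
        except (KeyError, IndexError, TypeError, ValidationError) as exc:
            fail(f"/interactions/{i}", str(exc))
    try:
        g.validate()
    except ValidationError as exc:
        fail("", str(exc))
    return g


def read_graph_json(path: str | Path) -> RnaGraph:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from None
    return graph_from_dict(doc)


def read_graphs_json(path: str | Path) -> list[RnaGraph]:
    """A file holding either one graph object or a list of graph objects."""
    with open(path) as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        return [graph_from_dict(d, pointer=f"/{i}") for i, d in enumerate(doc)]
    return [graph_from_dict(doc)]


def write_graphs_json(graphs: list[RnaGraph], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([graph_to_dict(g) for g in graphs], fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

@dataclass
class CoordinateSet:
    """C3' coordinates of one structure, keyed like the graph vertices."""

    structure_id: str
    points: dict[Key, np.ndarray] = field(default_factory=dict)
    missing: list[Key] = field(default_factory=list)  # residues lacking a C3'

    def __getitem__(self, key: Key) -> np.ndarray:
        return self.points[key]

    def __contains__(self, key: Key) -> bool:
        return key in self.points


def read_c3_coordinates(path: str | Path, structure_id: str | None = None) -> CoordinateSet:
    """C3' coordinates from PDB/mmCIF (first model, first altloc) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_coords_csv(path, structure_id)
    return _read_coords_structure(path, structure_id)


def _read_coords_csv(path: Path, structure_id: str | None) -> CoordinateSet:
    cs = CoordinateSet(structure_id or path.stem)
    with open(path) as fh:
        reader = csv.DictReader(fh)
        need = {"chain", "seq_index", "x", "y", "z"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ParseError(f"{path}: coordinate CSV needs columns {sorted(need)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = (row["chain"], int(row["seq_index"]))
                pt = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
            except (ValueError, TypeError):
                raise ParseError(f"{path} line {i}: malformed coordinate row") from None
            if not np.all(np.isfinite(pt)):
                raise ParseError(f"{path} line {i}: non-finite coordinates")
            cs.points[key] = pt
    return cs


def _read_coords_structure(path: Path, structure_id: str | None) -> CoordinateSet:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: unreadable structure file ({exc})") from None
    cs = CoordinateSet(structure_id or st.name or path.stem)
    model = st[0]  # first model only
    for chain in model:
        for residue in chain:
            key = (chain.name, residue.seqid.num)
            if key in cs.points:
                continue  # first occurrence (altloc/insertion) wins
            atom = None
            for a in residue:
                if a.name == "C3'" and (atom is None or a.altloc in ("", "A")):
                    atom = a
                    if a.altloc in ("", "A"):
                        break
            if atom is None:
                cs.missing.append(key)
                continue
            cs.points[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return cs


def write_coords_csv(cs: CoordinateSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "seq_index", "x", "y", "z"])
        for (c, i) in sorted(cs.points):
            x, y, z = cs.points[(c, i)]
            w.writerow([c, i, f"{x:.4f}", f"{y:.4f}", f"{z:.4f}"])


# ---------------------------------------------------------------------------
# Occurrence lists
# ---------------------------------------------------------------------------

OCC_HEADER = ["structure_id", "chain", "pos1", "pos2", "pos3", "pos4", "pos5", "pos6"]


def read_occurrence_list(
    path: str | Path,
    graphs: Mapping[str, RnaGraph],
    template: MotifTemplate | None = None,
    validate: bool = True,
) -> list[AminorOccurrence]:
    """Occurrence CSV validated against graphs and the motif template.

    Extra columns (e.g. an archetype label) are ignored.  With
    ``validate=True`` every row must induce a subgraph satisfying the motif
    template in its structure's graph.
    """
    template = template or MotifTemplate()
    out: list[AminorOccurrence] = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        if not set(OCC_HEADER) <= set(reader.fieldnames):
            raise ParseError(f"{path}: occurrence CSV needs columns {OCC_HEADER}")
        for i, row in enumerate(reader, start=2):
            sid = row["structure_id"]
            chain = row["chain"]
            positions = []
            for col in OCC_HEADER[2:]:
                tok = row[col]
                if ":" in tok:
                    c, p = tok.split(":", 1)
                    positions.append((c, int(p)))
                else:
                    positions.append((chain, int(tok)))
            if sid not in graphs:
                raise ValidationError(f"{path} line {i}: unknown structure {sid!r}")
            g = graphs[sid]
            for key in positions:
                if key not in g:
                    raise ValidationError(
                        f"{path} line {i}: nucleotide {key} absent from {sid}"
                    )
            pos6 = tuple(positions)
            if validate and not occurrence_satisfies(g, template, pos6):
                raise ValidationError(
                    f"{path} line {i}: positions do not satisfy the motif template"
                )
            out.append(AminorOccurrence(sid, pos6))
    return out


def write_occurrence_list(
    occs: list[AminorOccurrence],
    path: str | Path,
    labels: Mapping[str, str] | None = None,
) -> None:
    """Write occurrences; ``labels`` maps occurrence id → archetype tag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = list(OCC_HEADER) + (["label"] if labels else [])
        w.writerow(header)
        for occ in occs:
            chain = occ[1][0]
            row = [occ.structure_id, chain]
            for no in range(1, 7):
                c, p = occ[no]
                row.append(str(p) if c == chain else f"{c}:{p}")
            if labels:
                row.append(labels.get(occ.id, ""))
            w.writerow(row)
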