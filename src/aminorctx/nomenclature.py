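"""Leontis–Westhof base-pair nomenclature and the CAN family.

Base pairs are classified by the two interacting edges (Watson-Crick ``W``,
Hoogsteen ``H``, Sugar ``S``) and the glycosidic-bond orientation (``c``\\ is
or ``t``\\ rans), giving twelve families (cWW, tWW, cWH, ...).  Canonical
Watson-Crick pairs (cWW A-U / G-C) and the Wobble G-U pair are treated as
secondary structure and carry the special family ``CAN`` instead of cWW.
"""

from __future__ import annotations

#: The twelve Leontis–Westhof families plus the canonical marker.
LW_FAMILIES: frozenset[str] = frozenset(
    {
        "cWW", "tWW",
        "cWH", "tWH", "cHW", "tHW",
        "cWS", "tWS", "cSW", "tSW",
        "cHH", "tHH",
        "cHS", "tHS", "cSH", "tSH",
        "cSS", "tSS",
    }
)

FAMILIES: frozenset[str] = LW_FAMILIES | {"CAN"}

#: Canonical Watson-Crick and Wobble residue pairs (unordered).
_CANONICAL_PAIRS = {
    frozenset({"A", "U"}),
    frozenset({"G", "C"}),
    frozenset({"G", "U"}),  # Wobble, treated as secondary structure
}


def mirror(family: str) -> str:
    """Family of the reverse arc: swap the two edge letters, keep c/t.

    ``mirror("tSH") == "tHS"``; ``CAN`` and the symmetric families
    (cWW, tWW, cHH, tHH, cSS, tSS) are their own mirrors.
    """
    if family == "CAN":
        return "CAN"
    if family not in LW_FAMILIES:
        raise ValueError(f"unknown Leontis-Westhof family: {family!r}")
    return family[0] + family[2] + family[1]


def is_canonical_cww(res1: str, res2: str) -> bool:
    """True if a cWW pair between these residues is canonical (incl. Wobble)."""
    return frozenset({res1.upper(), res2.upper()}) in _CANONICAL_PAIRS


def normalize_family(family: str, res1: str, res2: str) -> str:
    """Map annotation families onto the graph model's family set.

    cWW pairs between canonical (or Wobble) partners become ``CAN``;
    everything else is kept as annotated.
    """
    if family == "CAN":
        return "CAN"
    if family not in LW_FAMILIES:
        raise ValueError(f"unknown Leontis-Westhof family: {family!r}")
    if family == "cWW" and is_canonical_cww(res1, res2):
        return "CAN"
    return family
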