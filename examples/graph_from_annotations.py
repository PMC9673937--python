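"""Build an RNA graph from an FR3D-style annotation table and find motifs.

Writes a minimal annotation table plus chain FASTA to a temporary directory,
parses them into the interaction-graph model (canonical cWW/Wobble pairs
become the CAN family; every interaction is stored as two mirrored arcs),
and searches for type I/II A-minor template embeddings.
"""

import tempfile
from pathlib import Path

import aminorctx as amc

rows = """\
1XYZ|1|A|G|4	1XYZ|1|A|C|13	cWW
1XYZ|1|A|C|5	1XYZ|1|A|G|12	cWW
1XYZ|1|A|A|20	1XYZ|1|A|G|4	cSS
1XYZ|1|A|A|19	1XYZ|1|A|C|5	cSS
"""
#            ^ helix pairs {4,13} and {5,12}; loop adenines 19-20 dock via cSS

with tempfile.TemporaryDirectory() as tmp:
    tab = Path(tmp) / "annotations.tsv"
    tab.write_text(rows)
    fa = Path(tmp) / "chains.fa"
    fa.write_text(">1XYZ|A\nGGAGCAAUUUUGCGAUGUAACU\n")
    g = amc.read_interaction_table(tab, fa)

print(f"structure {g.structure_id}: {len(g)} nucleotides")
print("arc 4->13:", g.interaction(("A", 4), ("A", 13)).family)   # CAN
print("arc 20->4:", g.interaction(("A", 20), ("A", 4)).family)   # cSS
print("arc 4->20:", g.interaction(("A", 4), ("A", 20)).family)   # mirrored cSS

occurrences = amc.find_motif_occurrences(g)
for occ in occurrences:
    print("A-minor occurrence:", occ.id)
    print("  loop strand:", occ.loop_strand, " helix strand:", occ.helix_strand_a)
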