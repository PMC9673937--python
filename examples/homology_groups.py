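"""Group A-minor occurrences into homology groups.

Two occurrences are homologous when the global alignments of the three
+-30 nt windows around their motif strands all score at least 50 (EDNAFULL,
affine gaps 10/0.5, free end gaps) and their context RMSD is at most 2 Å;
groups are single-link connected components.  Here molecules of one
archetype share their design sequence, so each archetype collapses into one
group.
"""

import aminorctx as amc
from aminorctx.pipeline import classify_occurrences

spec = amc.FixtureSpec(
    seed=3, archetypes=(("gnra_dock", 3), ("arich_loop", 3), ("plain_loop", 3))
)
dataset = amc.generate(spec)
cl = classify_occurrences(
    dataset.graphs, dataset.coords, dataset.truth, with_representatives=False
)

ids = sorted(cl.occurrences)
verdicts = []
for i, a in enumerate(ids):
    for b in ids[i + 1 :]:
        oa, ob = cl.occurrences[a], cl.occurrences[b]
        v = amc.are_homologous(
            oa, ob,
            dataset.graphs[oa.structure_id], dataset.graphs[ob.structure_id],
            rmsd=cl.rmsd(a, b),
        )
        verdicts.append(v)

groups = amc.homology_groups(verdicts, ids)
print(f"{len(groups)} homology groups from {len(ids)} occurrences")
for g in groups:
    archetypes = sorted({dataset.archetype_of[m] for m in g.members})
    print(f"group {g.id}: {len(g.members)} members ({', '.join(archetypes)})")
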