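# Methods

This note documents the models, algorithms, parameters and design choices
behind `aminorctx`, and what the synthetic study conditions do and do not
show about real structures.

## Graph model

A structure is a directed labeled multigraph over nucleotides: covalent arcs
follow the 5'→3' backbone (each vertex has at most one predecessor and one
successor), and every hydrogen-bond interaction is stored as two opposite
arcs whose Leontis–Westhof families mirror each other (`tSH` ⇄ `tHS`;
symmetric families and `CAN` are self-mirrored). Canonical cWW A-U/G-C pairs
and the Wobble G-U pair carry the family `CAN` and are treated as secondary
structure. Stacking and base-phosphate contacts are outside the model.

A vertex's pairing-state label depends only on the multiset of its incident
interaction families in the whole molecule: `0` (none), `C` (only CAN),
`N` (only non-CAN), `M` (both).

**Short vs long range.** The literature colors interactions as intra- vs
inter-element without a formal definition, so the package fixes one: the
nested secondary structure is the maximum non-crossing subset of CAN pairs
(Nussinov-style dynamic program over the given pairs), and an interaction is
*short-range* iff both endpoints have the same innermost enclosing nested
pair. Helix stacks, hairpin-loop and internal-loop contacts come out short;
tertiary contacts between distinct elements come out long. Range tags read
from input files take precedence over the computed ones.

**Motif template.** The type I/II template fixes covalent arcs 1→2, 3→4,
5→6 and canonical pairs {1,4}, {2,3}; its non-canonical edge set defaults to
cis Sugar/Sugar contacts {1,6} and {2,5} (vertices 1, 2, 5, 6 are the cSS
participants) but is configurable, because instances in the wild vary and
the exact default edge multiset is a modelling choice, not ground truth.
Residues are unconstrained by default (either adenine may be substituted).
Occurrence search is an anchored backtracking over covalent pairs and is
checked against blind enumeration in the tests.

## Extensions and contraction

A branch of length `k` walks the backbone away from a motif vertex, never
crossing another motif vertex and truncating silently at chain ends. Each of
the template vertices has exactly one free direction (the other neighbour is
a motif vertex), recorded as the branch direction. Interaction partners of
branch vertices join as `⊥` vertices; they carry no branch membership, are
excluded from coordinates, sequences and contraction, and participate only
through their arcs *into* the context — arcs between two `⊥` vertices are
deliberately excluded from the model, since neither endpoint belongs to the
context proper. A vertex reachable through two branches keeps its first slot
only (deduplicated by identity and logged).

Contraction merges maximal runs of same-label consecutive branch vertices
into weighted vertices (weight = run length, between 1 and `k`); motif
vertices keep their template numbers and are never contracted; runs never
merge across motif vertices. Arc multiplicity onto a merged vertex is
collapsed; an arc that ends up inside one merged vertex is dropped and
logged. When multiplicity collapse mixes range tags, `long` wins (the
conservative choice for the short-range-only context).

Strand sequences read the covalent path of one extended strand 5'→3'
(loop = branch(5)+5,6+branch(6); helix = branch(1)+1,2+branch(2)); full
branches give length `2(k+1)`.

## Geometry

Local 3D structures hold one C3' point per non-`⊥` vertex. The rigid
transform is fit by Kabsch SVD on the six motif points only (degenerate
configurations with singular-value rank < 2 raise an error), then frozen;
the context RMSD runs over the intersection of slots, with the number of
compared pairs in the denominator. Fitting on the motif only makes the
measure symmetric; both directions are computed, must agree to 1e-9 Å, and
their mean is reported. Pairs sharing fewer than 12 points are logged.
Optimality is cross-checked in the tests against an independent quaternion
(Horn) superposition.

## Clustering

The similarity graph has an edge whenever RMSD ≤ τ; τ defaults to 2.5 Å
with 2.0 Å supported as the stricter variant. The clusterer is a
deterministic greedy heuristic behind a small interface (the published
objective — density and average similarity with up to two memberships per
vertex — is a contract, not a fully specified algorithm):

1. grow a class from the unassigned vertex of highest weighted degree
   (ties: degree, then lexicographic id), admitting the unassigned neighbour
   with the best similarity to the class while density `2E/(V(V−1))` stays
   ≥ 0.5 (configurable) and average similarity `mean((τ−w)/τ)` does not drop
   by more than 10% (a singleton's first admission sets the baseline);
2. after coverage, grant at most one secondary membership per vertex when it
   is adjacent to at least half of another class and the class's density
   floor survives.

Coverage, the ≤ 2 membership bound, and connectedness of multi-member
classes hold by construction and are property-tested. Assignment of new
occurrences to existing classes uses the inclusive rule RMSD ≤ τ to at
least one member.

## Maximum common subgraph

The topological representative is the exact maximum common subgraph of all
members' contracted extensions. Equivalent vertices share label and branch
(weights may differ; order along the strand must be preserved; offsets are
otherwise free); equivalent edges share their family; the motif is always
included. The objective sums, over common interaction edges, the weights of
the incident vertices, each weight taken as the minimum across the mapped
members (the conservative shared mass); covalent edges constrain but score
zero.

The solver is a branch-and-bound over an association structure of
cross-member correspondence tuples; pairwise consistency (injectivity per
member, sign-consistent run order per branch) implies n-way consistency, so
size-n cliques reduce to pairwise checks. Three reductions keep it fast at
the sizes `k = 3` produces, none affecting exactness:

* structurally identical members are collapsed to one representative before
  solving (their vertex ids coincide, so the mapping replicates);
* `⊥` vertices are grouped into interchangeability classes by arc profile,
  and the search optimizes class-combination *multiplicities* under capacity
  constraints, materializing concrete ids afterwards;
* vertices that cannot carry any common interaction edge are excluded from
  the search and appended greedily afterwards — they are objective-neutral,
  and appending keeps the mapping maximal so that sequence coverage is
  well defined.

Ties between equal-objective optima break toward the lexicographically
smallest mapping. Correctness is established against brute-force enumeration
on 200+ randomized instances (pairwise and 3-way).

The sequence representative constrains a position iff its nucleotide belongs
to the common subgraph in *every* member: a common contracted vertex of
minimum weight `p` covers the first `p` uncontracted offsets of its run in
each member (deterministic; offsets count motif-outwards), truncated members
contribute `N` at missing positions, and covered positions take the union of
member residues. Expressions are rendered 5'→3' with `N` for unconstrained
positions.

## Context kinds and search

From the representatives, four searchable contexts are derived per class:
sequence (regexes only); all-interactions (the topological representative
with the motif's non-canonical edges removed — usually splitting into a
loop-side and a helix-side query, a single query when an extra inter-strand
interaction survives); their combination; and the variant keeping only
short-range CAN edges (short iff short in every member).

Graph search embeds a query into an *uncontracted* target: anchors are
covalent pairs for each motif strand (helix partners resolved through the
canonical pairs), a contracted query vertex of weight `p` maps to any run of
1..k consecutive same-label target vertices (weight-flexible, mirroring the
equivalence rule; a bounded mode was considered and rejected as stricter
than the matching semantics elsewhere), selection gaps along a branch allow
spacers of up to `k` arbitrary vertices, `⊥` vertices map to any target
vertex with the required family arcs, and every query edge must be realized
between the image sets. For the combined kinds the strand expression must
additionally match the chain window of length `2(k+1)` centred on the
embedded motif strand — defined on the chain window rather than the
embedded-run sequence so that combined hits are exactly a subset of
sequence-only hits (the nesting property). Hit identity is the pair of
motif-strand positions; truth coincidence is exact.

PPV is computed per class and strand; hits on A-minor strands of other
classes are false positives; single-query classes need both strands of one
occurrence for a true positive and report one value for both sides. TPR
counts occurrences recovered on both strands by one same class. Reporting
covers classes with ≥ 3 members.

## Homology

Windows are each motif strand ± 30 nt (truncated at chain ends; full
windows span 62 nt). Scoring is a hand-rolled Gotoh global alignment with
EDNAFULL match/mismatch (+5/−4), affine gaps (open 10 covering the first
gap position, extend 0.5), and free end gaps; the test suite cross-checks it
against Biopython's `PairwiseAligner` configured identically. A pair is
homologous when all three window scores are ≥ 50 (a `loop_best_helix` mode
relaxes this to the loop window plus the better helix window, since with
three alignments "both scores" admits either reading) and the
3-{1,2,5,6}-extension RMSD is ≤ 2 Å; pairs from different molecule families,
or with missing family metadata, are skipped and logged. Groups are
single-link connected components.

## Synthetic study conditions

The generator builds single-chain molecules around a fixed skeleton —
receptor helix H1 (8 pairs, motif pairs central), a 6-nt hairpin, an
unpaired linker with optional decoy slots, and a donor element that differs
by archetype:

* `gnra_dock`: 5-pair stem closed by a GNRA tetraloop; vertices 5,6 are the
  two loop adenines;
* `arich_loop`: internal loop with an A-rich strand carrying tSH and tWH
  arcs across the loop;
* `plain_loop`: internal loop with no extra interactions.

Each archetype also carries one tertiary contact off the helix strand
(distinct family per archetype), making the helix-side context
position-specific the way real helices carry tertiary anchors. Coordinates
use idealized A-form constants for C3' placement (rise 2.81 Å, twist 32.7°,
radius 9.4 Å) with loops on bulged arcs; each molecule is a random rigid
motion of its archetype layout plus i.i.d. Gaussian noise of σ = 0.3 Å — the
sub-Å scale of coordinate uncertainty in well-resolved crystal structures.
Generation asserts the construction guarantees: template search returns
exactly the planted occurrences, intra-archetype context RMSD < 2.5 Å,
inter-archetype > 2.5 Å. One RNG stream per molecule is derived from
(seed, archetype index, molecule index), so datasets are byte-stable and
unaffected by count changes elsewhere.

Decoy slots plant the molecule's own loop- and helix-strand 8-mers into the
unpaired linker: they match the class expressions but carry no topology,
so they degrade sequence-only PPV while leaving topology-aware kinds and
the truth annotations untouched.

**What passing on these fixtures shows — and does not.** The fixtures have
clean labels, complete coordinates, unambiguous archetypes, and noise far
below the class threshold; they validate the machinery (definitions,
exactness of the combinatorial searches, orderings between context kinds),
not performance on real structures, where annotation errors, missing
residues, homology structure and borderline RMSDs dominate. Absolute PPV
values on synthetic data are not comparable to values on structure-database
scans.

## Numerical and interface choices

* Positions are 1-based and inclusive everywhere; coordinates use the first
  model and first altloc, keyed by (chain, author residue number).
* Intermolecular interaction rows (across structure ids) are dropped at
  load; occurrences are intramolecular.
* `k = 1` is the minimum extension order; `k = 0` is rejected.
* The RMSD matrix CSV prints 3 decimals; JSON round-trips are lossless.
* Deterministic tie-breaks are used everywhere randomness is not explicit;
  the only RNG in the package is the generator's, always seeded.

## Known limitations

* The clusterer realizes the published objective by a replaceable greedy
  heuristic; it is not a bit-exact reimplementation of any particular
  overlapping-clustering code.
* No stacking or base-phosphate edges; no base-pair annotation from raw
  coordinates (an external annotator's output is the expected input).
* The exact MCES solver is exponential in the worst case; it is exact and
  fast at `k = 3` context sizes but not intended for large general graphs.
* Sequence search is binary (match/no match); no probabilistic sequence
  models or hit ranking.
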