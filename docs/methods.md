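# Methods

## The dating model

The receptor's three architecture variants are treated as states of a
single irreversible character on a rooted, time-calibrated species tree.
Variant 1 (EGF + EGF_CA1 + EGF_CA2) is the ancestral state; variants 2 and
3 each arise by exon deletion and are never reverted (no orthologue regains
a lost domain). Tips carry *state sets* — a species whose predicted
transcripts include both V1 and V2 has the set {V1, V2} — and a tip whose
set contains V1 is *V1-compatible*: its genome still encodes the ancestral
exon structure, so no deletion can be inferred on its lineage.

Under irreversibility the ancestral labelling is forced:

* any node with a V1-compatible descendant tip must be V1 (a derived
  ancestor could never yield that descendant);
* a maximal clade whose tips are all derived takes its tips' unique derived
  variant;
* the root is V1 by assumption, even if every sampled tip is derived.

Every edge from a V1 node to a derived node is an emergence event. The
reported age is the **parent** node's age — the earliest divergence from an
ancestor shared with a variant-1 lineage. The deletion itself happened
somewhere on that edge, so the report is an upper bound, and output
documents it as such; the parent node's 95% CI travels with the event.

A derived-only clade mixing V2 and V3 has no defensible resolution:
resolving it by parsimony would require chaining one deletion onto the
other (V2→V3 means regaining EGF_CA2), which the biology forbids. Such
clades raise `AmbiguousDerivedClade` rather than guessing. They do not
occur in the shipped data; the exhaustive 5-tip test characterises exactly
when the refusal triggers.

Gene origin is bracketed from a presence matrix: the crown age (MRCA of all
gene-bearing tips; 0 for a single tip) is the establishment estimate, the
stem age is that node's parent age. On the shipped fixtures the receptor is
absent in the lamprey and present in all 59 bony vertebrates, giving crown
435 mya (the bony-vertebrate radiation) and stem 550 mya (the outgroup
attachment, the age of the first vertebrates).

## The timetree fixture

`data/vertebrate_timetree.nwk` is a 59-tip, fully binary (58 internal nodes)
ultrametric tree in the annotation Newick dialect
(`[&age=A,ci={lo,hi}]` before the branch length). The seven
emergence-relevant node ages and their CIs are the published calibrations:
Afrotheria 101 (96–105), Primates 82 (76–89), sloth 66 (60–72),
Laurasiatheria 62 (58–66), zebra finch 38 (16–43), platypus 177 (163–191),
turkey 37 (28–39) mya; the root sits at 435 mya. All other ages are
interpolated placeholders satisfying monotonicity and are flagged
non-authoritative in the file. Tip state sets follow the timetree account:
28 V1-only species, 20 V2-only, 2 V3-only (platypus, turkey), 8 dual
V1+V2, and the duck with all three. The two amphibians are encoded as dual
V1+V2: encoding them V2-only would imply an eighth emergence event far
older than the Afrotherian one, contradicting the account that Afrotheria
were the earliest V2-only vertebrates; treating them as still
V1-compatible keeps the event set consistent, and they count among the
eight dual species.

`data/s1_architectures_synthetic.tsv` is a synthetic stand-in for the
per-orthologue architecture table (the original is not publicly
deposited). It lists one protein per predicted transcript variant per
species with schematic 1-based coordinates, constructed to match every
published census count (10/12 primates V2-only; 8 dual species of which
exactly one bony fish; elephant shark V2 but excluded from the tree).

## Alignment and distances

Pairwise alignment is a three-state Gotoh dynamic programme maximising the
BLOSUM62 sum minus `open + (k−1)·extend` per length-`k` gap, with defaults
open = 10, extend = 1 (Clustal-like; the original analysis delegated to
Clustal Omega without reporting parameters, so these are package defaults,
not reproductions). Terminal gaps are penalised — orthologues are compared
full length. Traceback prefers diagonal over up (gap in the second
sequence) over left, making alignments bit-reproducible; scores are checked
against exhaustive path enumeration (lengths ≤ 6) and against Biopython's
`PairwiseAligner` on longer pairs. Because co-optimal alignments depend on
argument orientation, `distance_matrix` aligns each pair in canonical
(id-sorted) order so the p-distance — 1 − identities / non-double-gap
columns, with no multiple-hit correction — is a function of the pair alone.

The progressive MSA builds an NJ guide tree from p-distances and merges
profiles in post-order by profile–profile affine alignment, scoring column
pairs as the mean BLOSUM62 value over non-gap residue pairs ("once a gap,
always a gap"). It makes no claim of matching Clustal column-for-column;
tests pin the invariants (rows ungap to inputs, bounded column count) and
optimality on tiny cases where the progressive order is exact.

## Conservation scoring

Each column scores the number of the ten Taylor physico-chemical classes
(`data/taylor_properties.tsv`; charged = positive ∪ negative) whose
membership is homogeneous — all entries in, or all out. Gaps and X carry
the empty property set, so a gapped column can never reach the sentinel 11
reserved for gap-free single-residue columns; scores otherwise run 0–10.
This emulates the AMAS-style conservation annotation drawn under published
alignments; the exact variant used originally is unstated, so the property
table is configurable and only the semantics above are promised. Projection
onto a reference row drops reference-gapped columns and renumbers by
residue. Domain rankings use mean projected score (ties to the more
N-terminal start); hotspots are runs in the top decile (configurable).

## Neighbor joining

Canonical Saitou–Nei: Q-matrix ties break to the lowest index pair in the
current working order, the final three lineages join at an unresolved
trifurcation, and negative branch lengths (possible off additive input) are
clamped to zero with a log entry. On additive matrices the tests require
exact topology (RF = 0) and path lengths within 1e−9 for n ≤ 12.

## Synthetic data

`simulate` provides the study-condition generators. Defaults: 59 tips;
pure-birth rate 0.01/lineage/mya (expected root age ≈ ln 59/0.01 ≈ 410 mya,
near the bony-vertebrate radiation; a richer diversification model would
add nothing the pipeline consumes); V2-loss rate 0.001 and V3-loss rate
0.0003 events/branch/mya, which over the ≈5,000 mya of expected total
branch length yield a handful of emergence events per replicate with V2
outnumbering V3, as observed. Loss events are competing exponentials per
branch; the first arrival wins and fixes the whole subtree (no regain, no
second loss), so tip states are single-derived as in the real data.
Sequences evolve by per-site Poisson substitution with region-specific
rates (defaults mimic the conserved EGF_CA1/GAIN-N/7TM hotspots at
0.05–0.10 substitutions/site/100 mya against 0.4–0.6 elsewhere), uniform
replacement over the 19 alternatives; the root-to-tip difference therefore
follows the 20-state Jukes–Cantor-style curve (19/20)(1 − e^(−20rt/19)),
which the tests check at 10,000 sites. The simulator produces no indels and
uses no empirical substitution matrix; passing parameter-recovery tests
therefore demonstrates sensitivity to rate heterogeneity, not robustness to
alignment error on real data. All generators are bit-deterministic under a
fixed seed via salted seed sequences.

## Problem sizes and numerical choices

Tests run simulations at 20–30 tips and 10–520 residues with 50 seeded
replicates per recovery property — sizes chosen so each property is
exercised end-to-end while the whole suite stays interactive. Exhaustive
oracles cap at 5 tips (all labellings), length 6 (all alignment paths) and
column size 4 (all property patterns). Ages are compared exactly where the
model promises exactness (event ages are existing node ages, never
interpolated) and at 1e−9 elsewhere. Protein coordinates are 1-based
inclusive throughout; the gap character is `-` and `.` is rejected;
unknown domain tokens require an explicit `OTHER:` prefix so vocabulary
typos cannot silently reach the classifier.

## Known limitations

* Emergence ages are upper bounds tied to the input calibration; the model
  neither re-estimates divergence times nor places the deletion within the
  edge.
* Species sampling drives the bound: removing V1 lineages can only push an
  emergence age rootward (a monotonicity the tests check).
* The progressive aligner is a baseline, not a Clustal/consistency-grade
  MSA engine.
* Statistics apply no multiple-testing correction, mirroring the original
  analysis; the report footer says so.
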