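# Methods

## The problem

Dinoflagellate light-harvesting complex (LHC) genes are encoded as
polyproteins: one gene model carries several ~120-residue, three-helix
antenna-protein units that are cleaved apart post-translationally. Families
of this kind expand by two mechanisms that leave different genomic
footprints: **intragenic** duplication (a unit copied in tandem within its
locus) and **intergenic** duplication (a unit or a whole locus copied to a
separate locus). This package implements the full cataloguing procedure —
unit detection, phylogenetic classification into subfamilies, phylogroups
and subgroups, duplication-mode calling, fusion-locus detection and
cleavage-motif association — together with a forward simulator used to
validate every step by parameter recovery.

## The simulator

`simfamily` runs a discrete-generation forward process started from two
founder units ("R-like" and "F-like" subfamilies) differing at an exact
fraction `founder_divergence` of sites (default 0.4 — deep enough that
subfamily anchoring is unambiguous, shallow enough that one profile detects
both). Per generation, Poisson-distributed numbers of five event kinds act
on the genome:

| event | default rate/gen | action |
|---|---|---|
| intragenic duplication | 0.3 | copy a uniform unit adjacent to its template |
| intergenic duplication | 0.3 | copy a unit — or, with probability 0.5, its whole locus — to a new locus |
| fusion | 0.05 | append a copy of a unit to a pure opposite-subfamily locus |
| conversion | 0 | overwrite a unit's sequence with a uniform paralog's |
| loss | 0.05 | delete a unit (guarded: a subfamily never goes extinct) |

After the events of each generation, every site of every unit mutates
independently with probability `subst_per_site_per_generation` (default
3×10⁻⁴) to a uniformly chosen different residue. The defaults are the
conditions used throughout the recovery experiments; all are configurable.
A drawn event may realize nothing (fusion with no pure opposite-subfamily
target; loss blocked by the extinction guard): the truth log counts drawn
attempts (`draws`, the quantity whose mean obeys the Poisson law) separately
from realized per-unit events (`events`, the quantity that satisfies
unit-count conservation).

**Lineage bookkeeping.** Each unit carries a true subgroup label: intragenic
copies and whole-locus copies inherit it, a dispersed single-unit copy
founds a new subgroup (a dispersed copy is the seed of an independently
evolving lineage), and conversion relabels the converted unit to its donor's
subfamily and subgroup (sequence content defines type) while the unit's own
event history is retained.

**Rendering.** Units are joined by a fixed 8-residue linker (`GSGSGSGS`);
at junctions whose downstream unit belongs to the motif subgroup, the
linker's first four residues are the cleavage motif (`SPLR`). By default
the motif subgroup resolves at render time to the largest surviving F
subgroup — the motif marks the most expanded lineage, and a fixed label
could denote a lineage that went extinct during the run. Output is 60-column
protein FASTA, a GFF3 locus map (1-based inclusive on disk, converted once
to 0-based half-open in memory), the pristine founder sequences (used
downstream as subfamily anchors and as the profile seed), and the truth log
as TSV.

What the simulator deliberately does **not** model: codon-level evolution,
indels within units, rate heterogeneity or a substitution matrix (uniform
replacement among the 19 alternatives — recovery tests need divergence
levels, not realism), and population-level processes (every change fixes
instantly). Passing recovery tests therefore certify the machinery under
clean fixed-length, indel-free units; real gene models add boundary noise,
splice variants and length variation that only the external-data mode
exercises.

## Unit detection

`unitscan` builds a fixed-length position weight matrix from a gapless seed
alignment: score(pos, r) = log₂(((count+1)/(N+20)) / 0.05) — pseudocount 1,
uniform background. The profile is slid over every start offset; candidates
are accepted greedily in descending score order (ties to the smaller start),
skipping overlaps, and kept when scoring at least `min_score` (default half
the consensus self-score). A fixed-length PWM rather than a profile HMM is
the stated fidelity boundary of this stand-in: simulated units are
fixed-length, and downstream analysis needs presence and identity, not
indel-aware boundaries. Same-locus identical duplicates are then collapsed
(keeping the smallest start) — this removes alternative-splice echoes in
real data while retaining cross-locus identical sequences, which are
exactly the intergenic signal. Junction-motif hits are exact string matches
classified against the unit spans: fully inside a unit, intersecting an
inter-span gap (junction), or in a terminal flank.

## Alignment and tree

`msa` implements affine-gap global alignment (Gotoh; a length-k gap costs
open + (k−1)·extend, defaults −10/−1, BLOSUM62) with a fixed traceback
preference (diagonal, then gap-in-second, then gap-in-first), and
progressive alignment over a UPGMA guide tree built on the k-mer multiset
distance d = 1 − shared/max(len), k = 3. Profile–profile columns score as
the mean pairwise substitution score of their non-gap residues. Columns
with a gap fraction above 0.5 (configurable) are trimmed, with an index map
back to original coordinates. De-gapping any output row must reproduce its
input exactly; this is asserted on every call.

`phylo` computes p-distances with pairwise deletion (optionally
Poisson-corrected, d = −ln(1−p), p capped at 0.95), canonical Saitou–Nei
neighbor joining with a deterministic lexicographic tie-break on the Q
criterion, and bootstrap supports: columns resampled with replacement,
NJ rebuilt per replicate, support = the fraction of replicates containing
the same bipartition, attached as internal-node labels in [0, 1]. Negative
NJ branch-length estimates are clamped to zero with the deficit moved to
the sister edge. Bootstrap proportions stand in for SH-like local supports
— both live on [0, 1] and the classification thresholds (0.9 / 0.8) are
applied unchanged; this, and NJ in place of maximum likelihood, are the
main fidelity compromises, acceptable because classification consumes only
topology and supports.

## Classification

`archclass` anchors every leaf to a subfamily by its nearest reference
sequence in patristic distance (exact tie → `other`). Phylogroups are the
maximal supported clades (≥ 0.9) whose members share one subfamily, read
with the opposite subfamily's anchor as the orientation leaf; subgroups are
the maximal supported clades (≥ 0.8) properly nested in a group. Labels are
ordinal by descending size, so "F1" is the largest F group by construction
— correspondence with any particular published group of the same name is
nominal. Units outside any group get `<subfamily>0`; subgroup 0 means no
affiliation, and single-member groups are flagged (`*` in reports) to keep
singleton lineages distinct from unplaced units.

Duplication mode: each unit's nearest homolog by percent identity on the
trimmed alignment (patristic distance optional); candidates within 1e-9 of
the minimum count as tied. Ties confined to the unit's own locus →
intragenic; confined to other loci → intergenic; present on both sides →
**ambiguous**, an explicit abstention — an exact two-sided tie carries no
deciding signal. A locus is a fusion locus iff it carries units of both
subfamilies. The motif association is a 2×2 table (locus carries a junction
motif × locus contains the focal clade) with a two-sided Fisher exact p
computed by hypergeometric enumeration (all tables with the observed
margins whose point probability is at most the observed one, relative slack
1e-12); degenerate margins give p = 1 with a warning. The pipeline's focal
clade is the largest detected F subgroup (falling back to the largest F
group when no subgroup resolves) — the finest detected proxy for the most
expanded lineage.

## Recovery experiments and their truth definitions

`validate` runs simulate → render → scan → align → classify and scores the
result against the truth log (20 replicates at the default conditions):

* **Unit recovery**: scanned spans matched to true spans by overlap;
  recall and boundary error are reported.
* **Duplication-mode truth** is the most recent duplication event
  (intragenic, intergenic or fusion — the latter expected intergenic) each
  unit participated in, *as template or copy*. The creating event alone is
  not recoverable even in principle: a unit later copied away by the
  opposite mode has its nearest homolog redefined by that later event, and
  at the default substitution depth (~2 substitutions per unit lineage over
  the whole run) recent duplicates are exactly identical, so no distance
  rule can separate them. Accuracy is therefore scored over committed
  (non-ambiguous) calls, with the committed fraction (~0.74 at defaults)
  reported alongside. Mode classification here runs on the uncollapsed
  scanned units: the simulator emits no splice variants, so same-locus
  identical copies are genuine tandem duplicates, not redundancy.
* **Fusion truth**: loci whose surviving units span both subfamilies in
  the truth log, compared against detection from tree-anchored subfamily
  labels (precision and recall).
* **Conversion stress**: raising the conversion rate (0 → 0.3 → 0.9)
  strictly degrades mode accuracy — conversion rewrites sequences without
  redefining duplication relationships.

Measured at the defaults: mode accuracy 0.92 (pooled over 20 replicates),
fusion precision and recall 1.0, unit recall 1.0.

## Numerical and design choices

* One global seed per pipeline run; each stage derives a sub-seed from a
  hash of (seed, stage name), so adding a stage never shifts another
  stage's randomness.
* Coordinates are 0-based half-open everywhere in memory; conversion to
  GFF3's 1-based inclusive convention happens at exactly one read/write
  point.
* Supports are proportions, never percentages; Newick branch lengths are
  written at 6 decimals; TSV floats at 6 decimals (round-trip exact).
* Problem sizes in the test and acceptance runs (20 recovery replicates,
  100 random trees, 200 event-count replicates, 40-generation golden
  pipeline run with 100 bootstrap replicates) keep the full suite in the
  tens of seconds while leaving every statistical check well-powered.
* The external benchmark mode (`pipeline.compare_to_reference`) reports
  per-quantity diffs against published counts for runs on real gene
  models; it asserts nothing, since tool substitutions (PWM scan for
  profile HMM search, NJ+bootstrap for ML+SH-like supports) change counts
  in ways the package does not promise to reproduce.

## Known limitations

* The motif-association test's power at simulation scale depends on the
  motif lineage resolving as a supported clade; in shallow or heavily
  dispersed runs the focal clade can miss the motif lineage and the test
  honestly returns p ≈ 1.
* Bootstrap support for very young clades (zero internal divergence) is
  essentially arbitrary; subgroup recovery is therefore qualitative at the
  default substitution depth.
* Percent-identity distances quantize at 1/(alignment columns); tie
  handling at finer resolution would require per-site weighting that the
  data do not support.
* No attempt is made to reconstruct historical scenarios (orderings of
  specific duplication chains); the package detects patterns.
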