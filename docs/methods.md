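# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic communities do and do not emulate, and
the design decisions taken where more than one reasonable choice existed.

## Sequence model and coordinates

All sequences live in fixed alignment coordinates over `{A, C, G, T, -}`;
a dataset is rectangular. Column coordinates are 0-based and half-open
throughout. Lower-case residues and `.` gaps are normalised on read, so a
write/read round trip is the identity. An optional Stockholm reader
derives the match-column mask from the `#=GC RF` reference annotation
(non-`.`/`~` columns are match columns), and `drop_insert_columns`
projects an alignment onto that mask, emulating the match-only output of
a covariance-model aligner. Running such an aligner is out of scope; a
deliberately logic-free adapter hook exists for drivers that want to
shell out.

## Quality control

* **Length filter**: a sequence is kept iff its ungapped length is at
  least 1200 bases. The threshold is on gene length, not alignment
  columns, and the boundary is strict: 1199 is discarded, 1200 kept.
* **Internal window**: clustering identities are computed over a
  contiguous 900-column window. "The internal stretch covered by all
  sequences" is operationalised deterministically as the window
  maximising the minimum per-sequence non-gap count, ties broken toward
  the smallest start column; a fixed start may be configured instead.
  On gap-free data every window ties and the selector returns column 0.
* **Gap filter**: more than 40 gap characters inside the window discards
  the sequence; exactly 40 is kept. All gaps falling in the window are
  counted, terminal or internal — the distinction is not recoverable
  from the alignment alone. Both filters partition their input and
  commute.

## Pairwise identity and clustering

Identity between two aligned sequences over the window is

    100 * (columns with identical residues) / (columns where at least
    one sequence has a residue)

Dual-gap columns are excluded from numerator and denominator; residue
versus gap counts as a mismatch. A sequence that is all-gap inside the
window has undefined identity and is rejected.

Greedy centroid clustering visits sequences by decreasing ungapped
length (ties: ascending id) and joins each to the first existing
centroid — in centroid creation order — with identity at or above the
threshold, else founds a new cluster. This is deterministic by
construction; the scan-order subtleties of accelerated heuristic tools
are not reproduced, and a naive restatement of the same rule serves as a
test oracle. The two-level scheme clusters all sequences at 97%, then
the 97% centroids at 85%; each OTU is linked to exactly one 85% cluster.
85% clusters whose total underlying sequence count is 1 are removed and
their OTUs flagged unplaced (a `singleton_unit="otu"` switch counts
OTUs instead of sequences).

Novelty is decided by a joint 97% re-clustering of pipeline plus
reference sequences. Precedence is genome_backed > mg_and_silva >
mg_only: an OTU with a genome-derived member is genome-backed
regardless of reference matches; otherwise it is mg_and_silva iff its
representative (optionally: any member) lands in a joint cluster with a
reference sequence. Reference-only joint clusters are discarded and
counted, mirroring the exclusion of database-only clusters from census
statistics.

## Chimera screening

For each query, candidate parents are pre-selected from the clean
training set (genome-derived sequences) by shared k-mer count (k=8) of
the ungapped window sequences — globally and additionally per
half-window, because a chimera matches its two parents on opposite
sides and a global ranking can be dominated by one of them. Candidate
pairs are scored by scanning breakpoints every `stride` (default 10)
columns, including the degenerate pure-parent models at the window
edges, so the model identity never falls below the best single parent.
With

    divergence = id(query, best two-parent model) - id(query, best single parent)

the verdict is *chimeric* iff divergence >= 2.0 percentage points and
the query matches each parent at >= 90% on that parent's side. All
thresholds are configurable. The screen presumes, as reference-based
chimera detection generally does, that the parents' lineages are
represented in the training database; with only ~90%-identical
relatives available the side-identity requirement is intentionally
conservative.

Chimeric sequences still participate in clustering (screening happens
at the representative level, as in the census workflow), and planted
chimeras demonstrably distort the 85% level by founding bridge
clusters — one reason chimeras inflate richness estimates. Flagged
representatives are excluded from tree building.

## Phylogeny

The internal engine is distance-based: p-distances over the window are
corrected with the Jukes–Cantor formula `d = -(3/4) ln(1 - (4/3) p)`,
with p capped at 0.70 (warning at the formal saturation point 0.75),
and fed to an in-package neighbor-joining implementation. Negative NJ
branch lengths are clamped to zero with the deficit moved to the
sibling branch, preserving the joined pair's path length. NJ is
consistent on additive distances (tested against exhaustive bipartition
enumeration for small trees and against an independent NJ
implementation on noisy matrices). Likelihood-based inference is out of
scope; an adapter slot exists because downstream stages only need
Newick trees with branch lengths.

Bootstrap replicates resample window columns with replacement.
Majority-rule consensus keeps bipartitions present in a strict majority
of replicates (supports therefore lie in (50, 100]); strict-majority
splits are pairwise compatible, so the consensus tree is built by
nesting canonical split sides.

**Rogue removal.** Per round, every remaining leaf is scored by what
its pruning does to the consensus, compared against the unpruned
majority splits *restricted to the same leaf subset* (splits that
merge after restriction keep the highest count — a split that existed
only as a leaf-shifted variant of another is not lost resolution).
The primary criterion is the change in the number of majority splits;
ties are broken by the change in their total support, which must
exceed `min_support_gain = 0.5` (in summed replicate fractions) to
count. The support term is needed because a uniformly wandering leaf
typically depresses every support without dissolving any single
majority split — a pure resolved-count criterion never fires on
exactly the instability it is meant to catch — while the floor keeps
ordinary bootstrap noise (measured well below 0.2 per leaf on stable
data) from triggering mass pruning. All positive-improvement leaves
are pruned each round; the procedure stops when a round identifies
fewer than five rogues (configurable; those remain in place), when
pruning would leave fewer than four leaves, or after `max_rounds`.

Rooting places the root on the stem of the smallest clade containing
the outgroup; a non-monophyletic outgroup falls back to the edge with
the highest outgroup Jaccard purity, with a warning. Without an
outgroup the pipeline midpoint-roots — unrooted trees leave the
lineage containing the NJ trifurcation without a clade of its own,
which starves phylum assignment. Long pendant branches (default: more
than 10x the median) can be flagged as likely contaminants; flags are
advisory.

**Phylum assignment** treats internal edges with bootstrap support
below 50 as collapsed (unresolved). Each unlabeled leaf walks toward
the root to the smallest supported clade containing at least one
labeled leaf and receives that phylum iff all labeled leaves in the
clade agree; mixed clades, or reaching the root, leave it unassigned.
In the pipeline, a leaf inherits a label when the sequences it
represents (its OTU's, or its cluster's, members) carry a unanimous
known taxonomy — genome-derived taxonomy annotates whole OTUs, not
just the representative that happened to be chosen.

## Census statistics

* **PD**: the sum of all branch lengths. Per phylum, trees are built
  independently from the representatives of previously known OTUs (not
  mg_only) and from all representatives;
  `increase = 100 * (PD_all - PD_known) / PD_known`. Phyla with fewer
  than 5 known OTUs are skipped — the baseline is too thin to be
  meaningful.
* **Richness**: per-phylum OTU counts, split by novelty category, plus
  85%-cluster counts (a cluster counts toward its centroid OTU's
  phylum).
* **Environment tally**: an OTU adds at most one count to each
  environment in which at least one member was observed; empty labels
  tally as `unknown`; configured environments (e.g. `engineered`) can
  be dropped.
* **Primer mismatch**: the primer (reverse primers as their reverse
  complement) is aligned semi-globally to each ungapped gene under unit
  edit costs; among minimal-edit alignments the one with the smallest
  weighted score is taken — a deterministic tie-break. The weighted
  score sums 0.4 per mismatch outside the 3' window (last 5 primer
  bases in the primer's own orientation), 1.0 per mismatch inside, 1.0
  per gap outside and 3.0 per gap inside; IUPAC-degenerate positions
  match their set at no cost, which is provably equivalent to the best
  concrete primer variant for any fixed alignment. Weights and window
  are configurable. Per 85% cluster, the mean and population SD (a
  sample-SD switch exists) of member scores are reported per primer; a
  cluster is predicted missed iff either primer's mean is strictly
  greater than 1, and the reported `mismatch_score` is the maximum of
  the two means. A sequence shorter than the primer has no site and
  scores infinite.

## Synthetic communities

The generator emulates the census inputs at desk scale. A global
ancestor is uniform over `{A,C,G,T}` at 1534 match columns; phylum
roots diverge from it by `between_phylum_divergence` (default 0.20
substitutions/site). Within a phylum, OTU ancestors are leaves of a
random bifurcating tree built by sequential random joins with
increasing heights; heights are scaled so the mean leaf-to-leaf path
equals `2 x between_otu_divergence` (default 0.05 per lineage), with a
deliberately narrow height spread (0.3 relative) so *all* between-OTU
identities stay inside the band the thresholds assume (~89-92% at the
defaults: below the 97% OTU threshold, above the 85% cluster
threshold). OTU members diverge `within_otu_divergence` (default
0.0025, i.e. ~99.5% identity) from their ancestor under a Jukes–Cantor
kernel: independent sites, uniform rates, equal frequencies — the
simplest model with a closed-form identity expectation usable as a
test oracle. No indels are simulated in match coordinates, so
alignment bookkeeping is exact.

Artifacts are planted on top, as fractions of the total output, with
mutually exclusive flags:

* **Chimeras** (default 5%): two parents from distinct phyla — drawn
  from genome-source sequences when possible, so the screening stage's
  training-set assumption holds — joined at a breakpoint uniform in
  the middle third of the internal window (columns [300, 600)), where
  both segments are visible to a window-restricted screen.
* **Truncated sequences** (5%): extra OTU members with leading columns
  masked until the ungapped length falls in [800, 1200) — caught by
  the length filter.
* **Gap-riddled sequences** (5%): extra members with 45 gaps planted in
  the columns common to every possible 900-column window, so the
  >40-gap rule fires for any window the selector returns.
* **Rogue lineages** (optional): isolated sequences evolved straight
  from the global ancestor, with no phylum membership.

Primer-binding sites for the 515f/806r pair are spliced into every
sequence at V4-like coordinates (515 and 787), overriding point
mutations there — primer regions are conserved in real SSU genes,
which is what makes universal primers possible. One third of phyla (by
default) get three 3'-window mismatches planted in the forward site,
so primer-miss prediction has planted truth; the margin (a per-member
score of ~3 versus the >1 threshold) is robust to alignment slack.

Sources are structured by lineage: a third of OTUs (configurable via
`mg_only_otu_fraction`) have all-metagenome members — full-length gene
censuses find a large share of lineages only in metagenomes, and
database representation follows lineages, not individual sequences —
while the rest draw sources per sequence from `source_mix` (default
metagenome/genome/reference_db = 60/20/20). Environments are assigned
per OTU with a 20% per-sequence chance of a second environment, to
exercise the max-one-per-environment tally. Everything is driven by one seeded
generator: a fixed seed reproduces the dataset bit-identically.

What the generator does **not** emulate: rRNA secondary structure and
rate heterogeneity across sites, indels and intervening sequences,
abundance structure and sequencing error, taxonomy-dependent chimera
rates, and real primer-site diversity. Passing recovery tests
therefore demonstrates the pipeline's internal correctness and
threshold behavior under controlled divergences — not performance on
real surveys, where identity bands are broader and reference coverage
is far sparser.

## Problem sizes and determinism

The shipped tests and the reproduction script run communities of up to
~500 sequences with 30-50 bootstrap replicates — sizes chosen so every
stage (including 20-seed simulation sweeps) runs comfortably on a
laptop core while still exercising multi-phylum, multi-cluster
structure. All stochastic steps (simulation, bootstrap) take explicit
seeds; identical seeds give identical outputs, including Newick
strings.

## Known limitations

* Identity is computed on the given fixed alignment; misalignment is
  invisible to the pipeline.
* The greedy clustering reproduces the stated scan rule, not the
  internals of any specific accelerated implementation; cluster
  boundaries for borderline pairs can differ from such tools.
* The chimera screen's transparency costs sensitivity for parents
  poorly represented in the training set, and chimeric sequences still
  shape 97%/85% cluster boundaries before their representatives are
  flagged.
* NJ trees are point estimates under a homogeneous substitution model;
  deep, saturated divergences (p capped at 0.70) compress.
* Rogue pruning on all-positive leaves per round can be aggressive on
  very noisy replicate sets even with the support-gain floor; the
  per-round log records every improvement score for audit.
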