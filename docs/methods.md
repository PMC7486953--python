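# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `repeatscape`. It describes what the code does and why;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The estimation problem

At sequencing coverage far below 1×, single-copy sequence is essentially
never sampled twice, while a repeat family with hundreds or thousands of
genomic copies is sampled by many reads that overlap across copies. Two
consequences drive the whole pipeline:

1. a graph whose nodes are reads and whose edges are confirmed overlaps
   decomposes, at the right similarity thresholds, into connected groups
   that approximate repeat families;
2. the fraction of reads belonging to such groups estimates the genomic
   fraction occupied by repeats.

All downstream quantities — total repeat content, per-family abundances in
Mb, cross-species comparisons, ancestral reconstructions, divergence
landscapes — are built on these two facts.

## Read clustering

**Candidate pairing.** All-vs-all alignment is quadratic and unnecessary.
Reads are indexed by canonical k-mers (k = 15 by default; a k-mer and its
reverse complement map to one key, so strand is free); pairs sharing ≥ 3
canonical k-mers become candidates. k-mers containing N are skipped — N
never matches. k-mers occurring in more than 2,000 reads are ignored for
pairing (guard against low-complexity sequence); at desk scale this cap is
never reached.

**Overlap confirmation.** For each candidate pair the shared k-mer positions
vote on relative orientation and diagonal offset (majority orientation,
modal offset, deterministic tie-breaks). The overlap implied by the offset
is aligned with edlib (global alignment of the two overlap substrings); an
edge requires overlap ≥ `min_overlap` (default 0.55 of the shorter read)
and identity ≥ `min_identity` (default 0.90). These two defaults define the
similarity regime of the whole pipeline: reads from repeat copies within
~10% pairwise divergence connect; anything older fragments. Both are
config-exposed; lowering `min_identity` can only add edges, so the largest
cluster is monotone in this parameter (property-tested).

**Partitioning.** Clusters are connected components with ≥
`min_cluster_size` members (default 10; the desk-scale benchmarks use 4–5
because their subsets are hundreds, not hundreds of thousands, of reads).
Components are ranked by size, ties broken by smallest member read id, so
cluster numbering is deterministic. Community-detection refinement was
considered and rejected for v1: connected components are the simplest
contract consistent with painted-graph analysis, and the benchmarks show
they recover planted partitions exactly in the error-free regime (adjusted
Rand index 1.0, computed against truth restricted to reads with repeat
provenance; reads whose midpoint falls in background but that straddle a
repeat boundary are truth-labeling artifacts, not clustering errors).

**Consensus.** Member reads are laid out by breadth-first propagation of the
stored pairwise offsets/orientations from the highest-degree read; each
column takes the majority base (ties to the alphabetically first).
Zero-coverage columns split contigs; contigs shorter than 55 bases are
dropped unless nothing longer exists. For tandem satellites the layout
spans an arbitrary window/rotation of the unit — consumers of consensi
(cluster matching, divergence) are written to tolerate rotation.

## Iterative repeat-content estimation

Each iteration draws `subset_size` reads from the pool without replacement,
clusters them, and records p_i = clustered/subset. Consensus contigs
accumulate into a library across iterations; everything not assigned to a
cluster (the unclustered remainder of the subset plus the undrawn pool) is
queried against the library, and q_i = matched/queried. Matched and
clustered reads are removed; the estimator is the cumulative removed
fraction of the original pool after the last iteration.

Two design choices deserve note:

- *The query targets all unassigned reads*, not only the undrawn pool.
  At study scale the subset is a negligible fraction of the pool and the
  distinction is invisible; at desk scale the pool can shrink below the
  subset size, and querying only the undrawn remainder would starve the
  query step entirely.
- *The consensus library accumulates across iterations.* The query step is
  known to be imperfect in one pass (each iteration tends to rediscover the
  same families); keeping earlier consensi lets later iterations recover
  stragglers of families discovered earlier.

A read matches the library when it aligns within a contig at ≥ 0.90
identity over ≥ 55 bases; reads straddling a repeat boundary are probed
with prefix/suffix windows of the minimum hit length, approximating a local
alignment. The estimator is in [0,1], non-decreasing across iterations, and
stabilizes quickly (the running estimate after iteration 2 is within 0.05
of the final value on benchmark simulations). Recovery: mean error within
±0.05 of planted fractions {0.2, 0.5, 0.8} on 100 kb genomes at 0.3×
(4 replicates per fraction; at ~300 reads per genome, single-replicate
binomial noise alone has σ ≈ 0.023, so replicate averaging is part of the
benchmark design).

## Cross-run comparison and pool-and-paint

**Pooled subsampling.** Comparing clusters discovered independently per
sample is unreliable (cluster boundaries drift between runs), so samples
are compared inside joint runs: every sample contributes an equal number of
reads (optionally per platform, mirroring a 25%/75% long/short design),
replicate draws are disjoint, and insufficiency errors name the offending
sample. Desk-scale defaults are 1,000 reads per sample and 5 replicates;
study-scale values (100,000 and 20) remain valid configuration and their
arithmetic (12 samples × 100,000 = 1,200,000 pooled reads per replicate) is
checked in the tests.

**Reciprocal best hits.** Clusters from two runs are matched by contig
similarity: the score of a contig pair is the identity of the shorter
aligned (either strand) within the longer, with 100-base end-window probes
rescuing partially overlapping contigs (tandem-array consensi are arbitrary
rotations; full-infix alignment alone punishes them). A pair is reciprocal
iff each cluster is the other's best hit above a 0.75 score floor (random
DNA aligns near 0.6); ties break by score then by cluster rank. Top-keep
clusters without a reciprocal partner are flagged and excluded, never
silently matched. On disjoint halves of an 18-family benchmark the top 15
clusters match 1:1 to the same truth families; occasional flag-and-exclude
events (a family split by one run) are the documented failure mode.

**Painting and assortativity.** Joint-cluster graphs are node-labeled by
species; the aggregation statistic is the observed fraction of edges
joining same-species reads, standardized by its permutation null (default
999 relabelings; benchmarks use 199), with a one-sided permutation p-value
including the identity permutation. Single-species clusters are reported as
undefined rather than scored. The pre/post-split benchmark simulates a
satellite amplifying either on both terminal branches (young, species-
private cohorts; cross-species orthologs beyond the edge threshold) or on
the ancestral branch of a slowly evolving family (copies similar within and
across species). The divergence rates differ between the two scenarios by
construction — a young private expansion is low-divergence within species,
while a family shared before the split can only appear as one mixed cluster
if its copies stayed similar across species. Discrimination: AUC > 0.9
(observed ≈ 0.99) over 25 + 25 replicates.

## Comparative statistics

- Pearson tests use the exact relation t = r√(n−2)/√(1−r²) and a two-sided
  p computed directly from the regularized incomplete beta,
  P = I_{df/(df+t²)}(df/2, 1/2); the test suite verifies agreement with
  numeric integration of the t density to 1e-6 for df 1–30. |r| = 1 is
  flagged and reported with the limiting p of 0 rather than an error.
- Abundance in Mb per haploid genome = proportion × C-value (pg) × 978
  (the standard picogram-to-megabase conversion). Male/female columns
  (naming convention `<species>_<sex>`, configurable regex) are averaged
  per species before phylogenetic analysis.
- PCA is an eigen-decomposition of the item correlation matrix
  (variance-standardized items: every cluster weighs equally; eigenvalues
  sum to the item count, so eigenvalues above unity mark components that
  explain more than any single cluster). Loading signs are fixed by making
  each vector's largest-magnitude element positive.
- Genome-size calibration is ordinary least squares of published C-values
  on flow-cytometry signal intensity, reporting adjusted R² =
  1 − (1−R²)(n−1)/(n−2) and predictions at new signal values.

## Ancestral state reconstruction

Per-cluster abundance (Mb) is modeled as Brownian motion on a fixed rooted
tree with branch lengths used as given (the mitochondrial tree is not
ultrametric; no transformation is applied). σ² is estimated by REML via
phylogenetically independent contrasts — the downpass combines children by
inverse branch-length weighting, emitting one standardized contrast per
combination (n−1 in total, polytomies handled by sequential pairwise
combination), and σ²_REML is the mean squared contrast. Ancestral states
are BLUPs: an up-pass sends each node the inverse-variance combination of
all adjacent subtrees, which is independent of σ². The whole reconstruction
is O(n) and is verified against an O(n³) oracle — explicit shared-path
covariance matrices, matrix inversion, GLS mean and conditional
expectations — to 1e-8 on random six-tip trees (observed agreement ~1e-15).
States are invariant to uniform branch-length rescaling; σ² scales
inversely. σ²_REML is unbiased within Monte-Carlo error over 1,000
simulations on the six-species topology.

Branch changes are child-minus-parent state differences in Mb, listed in
post-order; along any root-to-tip path they telescope to tip minus root.
The planted-jump benchmark adds a deterministic shift of 5σ√v on one branch
of the study tree over BM noise; the jump branch has the largest |Δ| in
≥ 90% of 200 simulations when planted on a terminal branch (observed ≈
0.98–1.0 on the *variegatus* branch). Jumps on the short internal branches
of this tree are smeared across adjacent branches by the GLS smoothing —
basal species are paraphyletic here, so a clade-wide shift has no single
clean branch attribution. This is a property of the estimator, not a bug,
and is the reason the benchmark plants on a terminal branch.

## Divergence landscapes

Each read is aligned (either strand) within its cluster's consensus
contig(s) with edlib; divergence is 100 × mismatched/aligned columns, indel
columns excluded from both numerator and denominator by default (a flag
counts them as mismatches). A read is skipped — and counted as skipped,
never dropped — when no alignment exists within an edit-distance floor of
0.35 × read length (random sequence sits near 0.5) or when fewer than half
its bases are aligned. Histograms use 1% bins over 0–30% with an explicit
overflow count, so bin mass + overflow = scored reads always.

Two metric caveats, both tested: the optimal alignment may represent an end
mismatch as an indel (equal edit cost), so the default indel-excluding
metric runs a few tenths of a percent below a per-site counting oracle; the
indel-inclusive variant equals the edit distance exactly and matches the
Jukes–Cantor expectation 3/4(1 − e^(−4rv/3)) on simulated reads.

## The synthetic-data generator

The generator is the package's study stand-in: six species on a ladder tree
(basal *parallelus*, then *variegatus*, then sister pairs
*rufus*/*biguttulus* and *sibiricus*/*scalaris*; branch lengths are
plausible mitochondrial substitutions/site chosen once), genomes dominated
by repeats of six classes, a satellite expansion on the lineage to the two
largest genomes, two read platforms ("short" 150 bp at 0.23× and
"long-short" 300 bp at a desk-scale 0.06×), male and female read draws per
species, and flow-cytometry-style C-values (8.4–14.0 pg; *rufus* and
*variegatus* values are plausible fill-ins consistent with
*sibiricus*/*scalaris* being the two largest).

Model choices:

- **Substitution model** Jukes–Cantor, applied exactly per site
  (P(change) = 3/4(1 − e^(−4rv/3)), changed sites uniform over the other
  three bases). Indels are not simulated — divergence is reported in
  percent mismatches only.
- **Copy-number dynamics.** A family originates at a tree node with
  identical ancestral copies; along each branch the copy count is
  multiplied by a per-branch fold change applied at the branch midpoint
  (new copies share the first half-branch with their template and
  accumulate private mutations over the second half), then all copies
  mutate independently. Post-split expansions therefore produce young,
  species-private cohorts; pre-split expansions produce cohorts shared by
  all descendants — the contrast the pool-and-paint analysis detects.
- **Placement.** Satellite copies form one tandem array; all other classes
  are dispersed uniformly among background segments. Truth intervals tile
  the genome exactly (0-based half-open). An optional `min_gap` forces
  background spacers of at least one read length between repeat blocks,
  making families unbridgeable by read chains ("well-separated"); the
  default 0 lets repeats abut, as real repeats do.
- **Reads** are uniform single-end draws from both strands with i.i.d.
  substitution errors (default 0.5%, a post-filtering short-read rate) and
  constant quality on output; truth provenance comes from the midpoint
  interval. No adapters, duplicates, quality profiles, or B-chromosome
  polymorphism are modeled.

What the simulations do *not* establish: performance on real reads with
indels and quality artifacts, annotation accuracy (class labels beyond a
naive tandem-periodicity flag are out of scope), behavior of satellite
consensus building under concerted evolution, or absolute numbers at full
sequencing scale (per-species repeat contents, empirical correlations),
which would require the real read sets. Benchmarks at desk scale (genomes of
20 kb–1 Mb, hundreds to thousands of reads) validate the estimators'
contracts, not their behavior at hundreds of millions of reads.

## Problem sizes and determinism

Default benchmark sizes — 100–150 kb genomes, 0.3–0.7× coverage, subsets of
hundreds of reads, 199–999 permutations, 200 BM simulations — were chosen
so the full test suite runs in well under a minute while keeping every
statistic's sampling error far from its acceptance margin. Every stochastic
operation takes an explicit seed; pipeline stages derive their streams
deterministically from one global seed plus the stage name, and a rerun
with the same configuration is byte-identical (tested).
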