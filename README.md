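# repeatscape

Comparative repeatome profiling from low-coverage sequencing reads.

Species with very large genomes — gomphocerine grasshoppers reach 8–14 pg of
DNA per haploid genome — are effectively unassemblable, yet most of that DNA
is repetitive. `repeatscape` implements the desk-scale analytical chain for
characterizing such repeatomes *without* an assembly: because a repeat family
with hundreds of genomic copies is sampled by many reads even at ≪1×
coverage, reads can be clustered by sequence overlap into family-level
groups, and relative group sizes estimate genomic proportions.

The package is aimed at researchers studying repeat-driven genome-size
evolution who want a transparent, testable re-implementation of this
pipeline with a built-in synthetic-data generator: every stage can be run
against simulated genomes whose repeat content, divergence ages, and
phylogenetic history are known exactly.

## What it computes

- **Graph-based read clustering** (`repeatscape.cluster`): candidate read
  pairs by shared canonical k-mers (strand-aware), overlap confirmation by
  alignment (edge iff overlap ≥ 55% of the shorter read at ≥ 90% identity),
  connected components as repeat clusters, greedy layout consensus contigs,
  and cluster proportions.
- **Iterative repeat-content estimation** (`repeatscape.enrich`): the
  discover–query–filter loop. Per iteration *i*, a subset of the read pool
  is clustered de novo (fraction *pᵢ* assigned), the unassigned remainder is
  queried against the accumulated consensus library (fraction *qᵢ*
  matched), and both are removed. Total repeat content is estimated as
  Σ(*p*+*q*) — the cumulative removed fraction of the original pool after
  the last iteration.
- **Cross-run comparison and pool-and-paint** (`repeatscape.compare`):
  equal-proportion pooled subsampling across samples (disjoint replicate
  draws), reciprocal-best-hit matching of cluster consensi across runs, and
  species-painted cluster graphs with a permutation z-statistic for
  within-species aggregation (the quantitative form of "does repeat
  diversification pre- or post-date the species split?").
- **Comparative statistics** (`repeatscape.stats`): abundance matrices in
  read proportions and in Mb per haploid genome (Mb = proportion × pg × 978),
  Pearson tests with exact *t* = *r*√(n−2)/√(1−*r*²) and two-sided *p* via
  the regularized incomplete beta, PCA on variance-standardized items, and
  the least-squares flow-cytometry calibration of genome size on signal
  intensity.
- **Ancestral reconstruction** (`repeatscape.asr`): REML Brownian-motion
  reconstruction of per-cluster abundance (Mb) on a fixed rooted tree —
  σ² from phylogenetically independent contrasts, node states by a
  linear-time message-passing BLUP (verified against explicit GLS) — and
  per-branch abundance changes.
- **Divergence landscapes** (`repeatscape.divergence`): percent divergence
  of each read to its cluster consensus, per-cluster/per-class means, and
  1%-bin histograms as a proxy for repeat age distributions.
- **Synthetic data** (`repeatscape.simulate`): species genomes with planted
  repeat families (six classes, tandem satellites, dispersed mobile
  elements), Jukes–Cantor divergence along a species tree with
  branch-specific copy-number expansions, and uniform low-coverage reads
  with sequencing error — all with recorded truth.

## Worked example

```python
import repeatscape as rs

# six-species study: genomes, 12 read sets (2 sexes x 2 platforms), truth
study = rs.simulate_study(seed=1)
reads = study.readsets["scalaris_f"]

graph = rs.build_similarity_graph(reads)
clusters = rs.cluster_graph(graph, min_cluster_size=10)
props = rs.cluster_proportions(clusters, len(reads))
print(len(reads), "reads ->", len(clusters), "clusters;",
      "top cluster proportion %.3f" % props[1])

trace, enriched = rs.run_enrichment(
    reads, rs.EnrichmentConfig(subset_size=len(reads) // 2, n_iterations=5,
                               min_cluster_size=4), seed=1)
print("repeat content estimate: %.2f (truth %.2f)"
      % (trace.estimate, study.genomes["scalaris"].repeat_fraction))
```

prints

```
418 reads -> 6 clusters; top cluster proportion 0.275
repeat content estimate: 0.72 (truth 0.81)
```

The 418 reads are a 0.23× + 0.06× draw from the simulated *scalaris* genome;
the clusters recover the largest planted families (the top one is the
expanded satellite, 27.5% of reads). At this very small per-sample read
count the estimator underestimates the true repeat fraction of 0.81 — the
dedicated recovery benchmark (100 kb genomes at 0.3×,
`repeatscape.benchmarks.estimator_recovery`) shows mean absolute error
below 0.05 across planted fractions 0.2–0.8.

A full run of every stage (simulation → enrichment → pooled joint clustering
→ RBH matching → painting → statistics → ancestral reconstruction →
divergence landscape) writes TSV/FASTA/GraphML outputs plus a manifest:

```bash
repeatscape run-all --seed 3 --outdir demo_run
```

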