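"""End-to-end orchestration and the default simulated study.

The default scenario emulates a six-species gomphocerine grasshopper study:
a ladder phylogeny with two terminal sister pairs, genomes dominated by
repeats of six classes, a satellite expansion on the lineage leading to the
two largest-genome species, male and female read sets per species at low
coverage on two platform types, and flow-cytometry-style genome sizes in pg.
Genome lengths are desk-scale (hundreds of kb rather than Gb); all relative
quantities - repeat fractions, class mix, expansion fold changes, coverage -
are kept at study-like values.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from ._util import derive_seed
from .asr import Phylogeny, abundance_asr_pipeline, branch_changes
from .cluster import (Read, build_consensus, build_similarity_graph,
                      cluster_graph, cluster_proportions, label_satellite_like)
from .compare import paint_graph, pooled_subsample, reciprocal_best_match, \
    species_assortativity
from .divergence import landscape
from .enrich import EnrichmentConfig, run_enrichment
from .simulate import (RepeatFamilySpec, build_genome, evolve_family,
                       sample_reads)
from .stats import abundance_matrix, average_sex_columns, pca_standardized, \
    pearson_test

#: Six-species topology: parallelus basal, then variegatus, then the two
#: terminal sister pairs (rufus,biguttulus) and (sibiricus,scalaris).
#: Branch lengths are plausible mitochondrial substitutions/site.
GOMPHOCERINE_NEWICK = (
    "(parallelus:0.110,(variegatus:0.095,((rufus:0.042,biguttulus:0.045)"
    "rufbig:0.028,(sibiricus:0.038,scalaris:0.040)sibsca:0.030)"
    "derived:0.025)inner:0.015)root;"
)

#: Haploid genome sizes (pg) used by the demo sample sheet; scalaris and
#: sibiricus carry the two largest genomes.
DEFAULT_GENOME_SIZES_PG = {
    "parallelus": 9.73,
    "variegatus": 9.9,
    "rufus": 9.0,
    "biguttulus": 8.4,
    "sibiricus": 10.43,
    "scalaris": 13.98,
}

SPECIES = list(DEFAULT_GENOME_SIZES_PG)


def default_family_specs() -> list[RepeatFamilySpec]:
    """Planted repeat families approximating the study-like class mix.

    Class shares of the repeatome are roughly: DNA transposons and LINEs the
    largest, then helitrons and LTR elements, satellites variable with an
    expansion on the sibiricus/scalaris lineage, SINEs minor. Divergence
    rates give read-to-consensus divergence peaking around 4-6% at the tips.
    """
    return [
        RepeatFamilySpec("sat1", "satellite", 170, 60,
                         branch_multipliers={"sibsca": 3.0, "scalaris": 2.0,
                                             "sibiricus": 1.4},
                         divergence_rate=0.45),
        RepeatFamilySpec("hel1", "helitron", 800, 35, divergence_rate=0.55),
        RepeatFamilySpec("hel2", "helitron", 600, 20,
                         branch_multipliers={"rufbig": 1.8},
                         divergence_rate=0.5),
        RepeatFamilySpec("line1", "LINE", 600, 55, divergence_rate=0.5),
        RepeatFamilySpec("ltr1", "LTR", 700, 30, divergence_rate=0.35),
        RepeatFamilySpec("sine1", "SINE", 120, 40, divergence_rate=0.6),
        RepeatFamilySpec("dna1", "DNA_transposon", 500, 48,
                         divergence_rate=0.55),
        RepeatFamilySpec("dna2", "DNA_transposon", 400, 30,
                         divergence_rate=0.5),
    ]


@dataclass
class StudyData:
    tree: Phylogeny
    genomes: dict[str, "object"]  # species -> SpeciesGenome
    readsets: dict[str, list[Read]]  # sample -> reads (both platforms pooled)
    sample_sheet: pd.DataFrame
    family_specs: list[RepeatFamilySpec]


def simulate_study(seed: int = 0,
                   background_length: int = 45_000,
                   family_specs: list[RepeatFamilySpec] | None = None,
                   newick: str = GOMPHOCERINE_NEWICK,
                   genome_sizes_pg: dict[str, float] | None = None,
                   coverage_short: float = 0.23, read_length_short: int = 150,
                   coverage_long: float = 0.06, read_length_long: int = 300,
                   error_rate: float = 0.005,
                   sexes: tuple[str, ...] = ("f", "m")) -> StudyData:
    """Simulate the default study: genomes plus per-sample read sets.

    Each species gets one genome; each sex is an independent read draw from
    that genome on both platforms ("short" HiSeq-like 150 bp at 0.23x and
    "long-short" merged MiSeq-like 300 bp at a desk-scale 0.06x).
    """
    tree = Phylogeny.from_newick(newick)
    specs = family_specs if family_specs is not None else default_family_specs()
    sizes = genome_sizes_pg or DEFAULT_GENOME_SIZES_PG

    per_species_copies: dict[str, list[tuple[RepeatFamilySpec, list[str]]]] = {
        t: [] for t in tree.tips}
    for spec in specs:
        copies = evolve_family(tree, spec, seed=derive_seed(seed, "evolve"))
        for sp in tree.tips:
            per_species_copies[sp].append((spec, copies[sp]))

    genomes = {}
    readsets: dict[str, list[Read]] = {}
    sheet_rows = []
    for sp in tree.tips:
        genome = build_genome(sp, per_species_copies[sp], background_length,
                              seed=derive_seed(seed, f"bg:{sp}"))
        genomes[sp] = genome
        for sex in sexes:
            sample = f"{sp}_{sex}"
            reads: list[Read] = []
            for platform, cov, rlen in (("short", coverage_short, read_length_short),
                                        ("long-short", coverage_long,
                                         read_length_long)):
                rs = sample_reads(genome, cov, rlen, error_rate,
                                  seed=derive_seed(seed, f"{sample}:{platform}"),
                                  platform=platform, sample_id=sample)
                reads.extend(rs.reads)
            readsets[sample] = reads
            sheet_rows.append({
                "sample_id": sample, "species": sp, "sex": sex,
                "genome_size_pg": sizes[sp],
                "n_reads": len(reads),
                "truth_repeat_fraction": genome.repeat_fraction,
            })
    return StudyData(tree=tree, genomes=genomes, readsets=readsets,
                     sample_sheet=pd.DataFrame(sheet_rows),
                     family_specs=specs)


def graded_family_study(seed: int = 0, n_families: int = 18,
                        background_length: int = 130_000,
                        coverage: float = 0.7, read_length: int = 100,
                        error_rate: float = 0.005,
                        divergence_rate: float = 0.35,
                        min_gap: int | None = None):
    """One-genome benchmark with many families of graded abundance.

    Families span all six classes with target genomic footprints declining
    from ~14 kb, so cluster ranks are informative but close enough to permute
    between subsample runs - the regime that reciprocal best-hit matching
    across runs must handle. ``min_gap`` (default: one read length) keeps
    families separated by unbridgeable background. Returns ``(reads, genome)``.
    """
    tree = Phylogeny.from_newick("(focal:0.08,other:0.08)root;")
    classes = list(
        ("satellite", "helitron", "LINE", "LTR", "SINE", "DNA_transposon"))
    rng = np.random.default_rng(derive_seed(seed, "graded"))
    specs = []
    for i in range(n_families):
        unit = int(rng.integers(150, 400))
        target_bases = 16_000 - 600 * i
        specs.append(RepeatFamilySpec(
            f"fam{i:02d}", classes[i % 6], unit,
            max(4, int(round(target_bases / unit))),
            divergence_rate=divergence_rate))
    families = []
    for spec in specs:
        copies = evolve_family(tree, spec, seed=derive_seed(seed, "evolve"))
        families.append((spec, copies["focal"]))
    genome = build_genome("focal", families, background_length,
                          seed=derive_seed(seed, "genome"),
                          min_gap=read_length if min_gap is None else min_gap)
    reads = sample_reads(genome, coverage, read_length, error_rate,
                         seed=derive_seed(seed, "reads")).reads
    return reads, genome


#: Two focal species plus outgroup, used by the expansion-timing benchmark.
EXPANSION_NEWICK = "((A:0.05,B:0.05)ab:0.06,C:0.11)root;"


def expansion_contrast_study(post_split: bool, seed: int = 0,
                             multiplier: float = 8.0,
                             ancestral_copies: int = 6,
                             background_length: int = 22_000,
                             coverage: float = 0.45, read_length: int = 100,
                             error_rate: float = 0.005):
    """Satellite expansion either after or before a species split.

    Post-split: the family amplifies independently on both terminal branches
    at a high substitution rate, so each species carries a young, private,
    low-divergence cohort while orthologous copies across species sit beyond
    the clustering identity threshold - reads aggregate by species in the
    cluster graph. Pre-split: the amplification happens on the ancestral
    branch of a slowly evolving family, so copies remain similar within and
    across species and the painted graph mixes. Returns the pooled reads of
    the two focal species (sample ids ``A`` and ``B``).
    """
    tree = Phylogeny.from_newick(EXPANSION_NEWICK)
    if post_split:
        mults, rate = {"A": multiplier, "B": multiplier}, 1.1
    else:
        mults, rate = {"ab": multiplier}, 0.35
    spec = RepeatFamilySpec("satX", "satellite", 170, ancestral_copies,
                            branch_multipliers=mults, divergence_rate=rate)
    copies = evolve_family(tree, spec, seed=derive_seed(seed, "evolve"))
    reads = []
    for sp in ("A", "B"):
        genome = build_genome(sp, [(spec, copies[sp])], background_length,
                              seed=derive_seed(seed, f"genome:{sp}"))
        rs = sample_reads(genome, coverage, read_length, error_rate,
                          seed=derive_seed(seed, f"reads:{sp}"), sample_id=sp)
        reads.extend(rs.reads)
    return reads


def planted_fraction_study(repeat_fraction: float, genome_length: int = 100_000,
                           coverage: float = 0.3, read_length: int = 100,
                           error_rate: float = 0.005, seed: int = 0,
                           divergence_rate: float = 0.4):
    """One-genome benchmark with a controlled total repeat fraction.

    Splits ``repeat_fraction x genome_length`` of repeat sequence over one
    satellite and two dispersed families (copy divergence ~4% at default
    rate), fills the rest with single-copy background, and samples uniform
    low-coverage reads. Returns ``(reads, genome)``; the recomputed truth
    fraction is ``genome.repeat_fraction``.
    """
    tree = Phylogeny.from_newick("(focal:0.1,other:0.1)root;")
    repeat_bases = repeat_fraction * genome_length
    background = int(round(genome_length - repeat_bases))
    sat_bases = repeat_bases * 0.4
    fam_bases = repeat_bases * 0.3
    specs = [
        RepeatFamilySpec("satA", "satellite", 170,
                         max(1, int(round(sat_bases / 170))),
                         divergence_rate=divergence_rate),
        RepeatFamilySpec("famB", "LINE", 300,
                         max(1, int(round(fam_bases / 300))),
                         divergence_rate=divergence_rate),
        RepeatFamilySpec("famC", "DNA_transposon", 250,
                         max(1, int(round(fam_bases / 250))),
                         divergence_rate=divergence_rate),
    ]
    families = []
    for spec in specs:
        copies = evolve_family(tree, spec, seed=derive_seed(seed, "evolve"))
        families.append((spec, copies["focal"]))
    genome = build_genome("focal", families, background,
                          seed=derive_seed(seed, "genome"))
    reads = sample_reads(genome, coverage, read_length, error_rate,
                         seed=derive_seed(seed, "reads")).reads
    return reads, genome


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable).

    Every stochastic stage receives a seed derived deterministically from
    ``seed`` and the stage name, so a rerun with the same config is
    byte-identical.
    """

    seed: int = 0
    outdir: str = "repeatscape_run"
    background_length: int = 45_000
    error_rate: float = 0.005
    subset_size: int = 600
    n_iterations: int = 3
    min_cluster_size: int = 10
    per_sample: int = 300
    replicates: int = 2
    top_n_search: int = 50
    top_n_keep: int = 15
    top_k: int = 15
    n_permutations: int = 199
    mb_scaling: bool = True
    genome_sizes_pg: dict = field(default_factory=lambda: dict(DEFAULT_GENOME_SIZES_PG))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = rio.load_config(path) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> enrich -> pool -> joint cluster -> match -> paint ->
    stats -> ASR -> landscape, writing TSV/FASTA/GraphML outputs and a manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        study = simulate_study(seed=derive_seed(config.seed, "simulate"),
                               background_length=config.background_length,
                               error_rate=config.error_rate,
                               genome_sizes_pg=config.genome_sizes_pg)
        if config.mb_scaling:
            missing = [s for s in study.sample_sheet["species"].unique()
                       if s not in config.genome_sizes_pg]
            if missing:
                raise ValueError(f"missing genome size for species: {missing}")
        study.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t",
                                  index=False)
        for sp, genome in study.genomes.items():
            rio.write_genome(out / f"genome_{sp}.fasta",
                             out / f"truth_{sp}.tsv", genome)
        all_reads = [r for reads in study.readsets.values() for r in reads]
        rio.write_fastq(out / "reads.fastq", all_reads)
        rio.write_truth_table(out / "read_truth.tsv", all_reads)

        stage = "enrich"
        enriched: dict[str, list[Read]] = {}
        traces = {}
        for sample, reads in study.readsets.items():
            econf = EnrichmentConfig(
                subset_size=min(config.subset_size, max(1, len(reads) // 2)),
                n_iterations=config.n_iterations,
                min_cluster_size=config.min_cluster_size)
            trace, enr = run_enrichment(
                reads, econf, seed=derive_seed(config.seed, f"enrich:{sample}"))
            enriched[sample] = enr
            traces[sample] = trace
        pd.DataFrame([
            {"sample": s, "iteration": rec.i, "p": rec.p, "q": rec.q,
             "pool_remaining": rec.pool_remaining,
             "estimate": rec.removed_cum / traces[s].n_initial}
            for s, tr in traces.items() for rec in tr.iterations
        ]).to_csv(out / "enrichment_trace.tsv", sep="\t", index=False)

        stage = "pool-paint"
        per_sample = min(config.per_sample,
                         min(len(v) for v in enriched.values())
                         // config.replicates)
        pools = pooled_subsample(enriched, per_sample, config.replicates,
                                 seed=derive_seed(config.seed, "pool"))
        runs = []
        for pool in pools:
            graph = build_similarity_graph(pool.reads)
            clusters = cluster_graph(graph, config.min_cluster_size)
            by_id = {r.read_id: r for r in pool.reads}
            for c in clusters:
                c.consensus = build_consensus(c, by_id, graph)
                c.class_label = ("satellite-like"
                                 if any(label_satellite_like(x) == "satellite-like"
                                        for x in c.consensus) else "unknown")
            cluster_proportions(clusters, len(pool.reads))
            runs.append((pool, graph, clusters, by_id))

        pool0, graph0, clusters0, by_id0 = runs[0]
        rio.write_clusters_tsv(out / "joint_clusters.tsv", clusters0)
        rio.write_consensus_fasta(out / "joint_consensus.fasta", clusters0)
        if len(runs) > 1:
            table = reciprocal_best_match(clusters0, runs[1][2],
                                          config.top_n_search,
                                          config.top_n_keep)
            table.pairs.to_csv(out / "cluster_matches.tsv", sep="\t",
                               index=False)
        labels = {r.read_id: r.sample_id.rsplit("_", 1)[0]
                  for r in pool0.reads}
        painted = paint_graph(clusters0, graph0, labels)
        assort_rows = []
        for pg in painted:
            for n in pg.graph.nodes:
                pg.graph.nodes[n].pop("sample_id", None)
            if len(pg.composition) >= 2 and pg.graph.number_of_edges() >= 1:
                res = species_assortativity(
                    pg, config.n_permutations,
                    seed=derive_seed(config.seed, f"assort:{pg.cluster_id}"))
                assort_rows.append({"cluster_id": pg.cluster_id,
                                    "statistic": res.statistic,
                                    "p_value": res.p_value,
                                    "same_species_edge_fraction": res.observed})
        pd.DataFrame(assort_rows).to_csv(out / "assortativity.tsv", sep="\t",
                                         index=False)
        if painted:
            rio.write_graphml(out / "painted_cluster1.graphml",
                              painted[0].graph)

        stage = "stats"
        totals = {s: per_sample for s in enriched}
        matrix = abundance_matrix(clusters0, totals, top_k=config.top_k)
        matrix.to_csv(out / "abundance_matrix.tsv", sep="\t")
        sex_rows = []
        by_species = average_sex_columns(matrix)
        for sp in sorted({c.rsplit("_", 1)[0] for c in matrix.columns}):
            cols = [c for c in matrix.columns if c.rsplit("_", 1)[0] == sp]
            if len(cols) == 2 and matrix[cols[0]].std() > 0:
                res = pearson_test(matrix[cols[0]], matrix[cols[1]])
                sex_rows.append({"species": sp, "r": res.r, "t": res.t,
                                 "df": res.df, "p": res.p})
        pd.DataFrame(sex_rows).to_csv(out / "sex_correlations.tsv", sep="\t",
                                      index=False)
        if matrix.shape[0] >= 2:
            pca = pca_standardized(matrix.T)
            pd.DataFrame({
                "component": np.arange(1, len(pca.eigenvalues) + 1),
                "eigenvalue": pca.eigenvalues,
                "variance_fraction": pca.variance_fractions,
            }).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)

        stage = "asr"
        sizes_by_sample = {
            row.sample_id: config.genome_sizes_pg[row.species]
            for row in study.sample_sheet.itertuples()
        }
        if config.mb_scaling and matrix.shape[0] >= 1:
            results = abundance_asr_pipeline(matrix, study.tree,
                                             sizes_by_sample,
                                             average_sexes=True)
            chg = pd.concat([
                branch_changes(res, study.tree).assign(cluster_id=cid)
                for cid, res in results.items()
            ])
            chg.to_csv(out / "branch_changes.tsv", sep="\t", index=False)

        stage = "landscape"
        profile = landscape(clusters0, by_id0)
        profile.histogram.to_csv(out / "divergence_histogram.tsv", sep="\t",
                                 index=False)
        profile.class_means.to_csv(out / "divergence_class_means.tsv",
                                   sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    rio.write_manifest(out / "manifest.json", {
        "config": config.to_dict(),
        "seed": config.seed,
        "runtime_s": round(time.time() - t0, 2),
        "stages": ["simulate", "enrich", "pool-paint", "stats", "asr",
                   "landscape"],
    })
    rio.save_config(out / "config.yaml", config.to_dict())
    return out
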