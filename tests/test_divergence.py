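"""Divergence landscapes: read-to-consensus divergence and histograms."""

import numpy as np
import pytest

from repeatscape._util import random_dna, revcomp
from repeatscape.cluster import Read, RepeatCluster
from repeatscape.divergence import landscape, read_divergence


def _mutate(seq, n_mut, rng):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
    return "".join(s)


class TestReadDivergence:
    def test_exact_substring_scores_zero(self, rng):
        cons = random_dna(rng, 400)
        assert read_divergence(cons[50:150], cons) == 0.0
        assert read_divergence(revcomp(cons[50:150]), cons) == 0.0

    def test_mismatch_arithmetic(self, rng):
        cons = random_dna(rng, 400)
        read = _mutate(cons[100:200], 5, rng)
        assert read_divergence(read, cons) == pytest.approx(5.0)

    def test_unalignable_read_skipped(self, rng):
        assert read_divergence(random_dna(rng, 100),
                               random_dna(rng, 400),
                               min_aligned_fraction=0.9) is None

    def test_jukes_cantor_simulated_divergence_recovered(self, rng):
        # reads at JC distance 0.05: observed divergence should match the
        # multiple-hit-corrected expectation 3/4(1 - exp(-4*0.05/3)) = 4.84%,
        # cross-checked by direct per-site counting
        cons = random_dna(rng, 2000)
        p_diff = 0.75 * (1 - np.exp(-4 * 0.05 / 3))
        observed, exact, counted = [], [], []
        for i in range(1000):
            start = int(rng.integers(0, 1900))
            template = cons[start:start + 100]
            mask = rng.random(100) < p_diff
            read = "".join(
                ("ACGT"[("ACGT".index(b) + int(rng.integers(1, 4))) % 4]
                 if m else b) for b, m in zip(template, mask))
            observed.append(read_divergence(read, cons))
            exact.append(read_divergence(read, cons, include_indels=True))
            counted.append(100 * np.mean(
                [a != b for a, b in zip(read, template)]))
        # indel-inclusive numerator equals the edit distance: exact match to
        # per-site counting on substitution-only data
        assert np.mean(exact) == pytest.approx(np.mean(counted), abs=0.05)
        assert np.mean(exact) == pytest.approx(100 * p_diff, abs=0.35)
        # default metric drops alignment-end columns that edlib may render
        # as indels; small downward bias, bounded
        assert np.mean(observed) == pytest.approx(np.mean(counted), abs=0.5)


class TestLandscape:
    def _cluster_with(self, reads, cluster_id=1, consensus=None, label="LINE"):
        c = RepeatCluster(cluster_id, [r.read_id for r in reads],
                          class_label=label)
        c.consensus = consensus or []
        return c

    def test_zero_divergence_family_masses_first_bin(self, rng):
        cons = random_dna(rng, 500)
        reads = [Read(f"r|short|{i}", "r", "short", cons[i * 30:i * 30 + 100])
                 for i in range(10)]
        cluster = self._cluster_with(reads, consensus=[cons])
        profile = landscape([cluster], reads)
        assert profile.histogram["count"].iloc[0] == 10
        assert profile.histogram["count"].iloc[1:].sum() == 0

    def test_histogram_mass_conservation(self, rng):
        cons = random_dna(rng, 500)
        reads = [Read(f"r|short|{i}", "r", "short",
                      _mutate(cons[i * 20:i * 20 + 100],
                              int(rng.integers(0, 12)), rng))
                 for i in range(15)]
        reads.append(Read("r|short|99", "r", "short", random_dna(rng, 100)))
        cluster = self._cluster_with(reads, consensus=[cons])
        profile = landscape([cluster], reads)
        assert (profile.histogram["count"].sum() + profile.n_overflow
                == profile.n_scored)
        assert profile.n_scored + profile.n_skipped == len(reads)
        assert profile.n_skipped >= 1  # the random read cannot align

    def test_two_families_give_bimodal_histogram(self, rng):
        reads, clusters = [], []
        for cid, n_mut in ((1, 2), (2, 10)):
            cons = random_dna(rng, 500)
            fam = [Read(f"f{cid}|short|{i}", "s", "short",
                        _mutate(cons[i * 25:i * 25 + 100], n_mut, rng))
                   for i in range(12)]
            reads += fam
            clusters.append(self._cluster_with(fam, cid, [cons]))
        profile = landscape(clusters, reads, include_indels=True)
        counts = profile.histogram["count"].to_numpy()
        # all mass in two separated modes (alignment column-count wobble can
        # shift a 10%-read to 10/101 = 9.9, i.e. the adjacent bin)
        assert counts[2] == 12  # 2% family entirely in bin [2,3)
        assert counts[9] + counts[10] == 12  # 10% family at its mode
        assert counts[3:9].sum() == 0 and counts[11:].sum() == 0

    def test_class_mean_ordering_follows_simulated_ages(self, rng):
        # planted "young LTR, old SINE" configuration must come back in the
        # per-class means
        from repeatscape._util import derive_seed
        from repeatscape.asr import Phylogeny
        from repeatscape.cluster import (build_consensus,
                                         build_similarity_graph,
                                         cluster_graph)
        from repeatscape.simulate import (RepeatFamilySpec, build_genome,
                                          evolve_family, sample_reads)

        tree = Phylogeny.from_newick("(focal:0.1,other:0.1)root;")
        specs = [
            RepeatFamilySpec("ltr_young", "LTR", 400, 40,
                             divergence_rate=0.15),
            RepeatFamilySpec("sine_old", "SINE", 200, 80,
                             divergence_rate=0.7),
        ]
        fams = [(s, evolve_family(tree, s, seed=derive_seed(11, s.family_id))
                 ["focal"]) for s in specs]
        genome = build_genome("focal", fams, 30_000, seed=11, min_gap=100)
        reads = sample_reads(genome, 0.6, 100, 0.0, seed=11).reads
        graph = build_similarity_graph(reads)
        clusters = cluster_graph(graph, min_cluster_size=5)
        by_id = {r.read_id: r for r in reads}
        for c in clusters:
            c.consensus = build_consensus(c, by_id, graph)
            provs = [by_id[r].provenance for r in c.members]
            c.class_label = max(set(provs), key=provs.count)
        profile = landscape(clusters, by_id)
        means = profile.class_means.set_index("class_label")["mean_divergence"]
        assert means["ltr_young"] < means["sine_old"]

    def test_increasing_divergence_rate_increases_class_mean(self, rng):
        from repeatscape._util import derive_seed
        from repeatscape.asr import Phylogeny
        from repeatscape.cluster import (build_consensus,
                                         build_similarity_graph,
                                         cluster_graph)
        from repeatscape.simulate import (RepeatFamilySpec, build_genome,
                                          evolve_family, sample_reads)

        tree = Phylogeny.from_newick("(focal:0.1,other:0.1)root;")
        means = []
        for rate in (0.1, 0.4, 0.8):
            spec = RepeatFamilySpec("fam", "LINE", 400, 60,
                                    divergence_rate=rate)
            copies = evolve_family(tree, spec, seed=21)["focal"]
            genome = build_genome("focal", [(spec, copies)], 20_000, seed=21)
            reads = sample_reads(genome, 0.6, 100, 0.0, seed=21).reads
            graph = build_similarity_graph(reads)
            clusters = cluster_graph(graph, min_cluster_size=5)
            by_id = {r.read_id: r for r in reads}
            for c in clusters:
                c.consensus = build_consensus(c, by_id, graph)
            profile = landscape(clusters, by_id)
            means.append(profile.per_read["divergence"].mean())
        assert means[0] < means[1] < means[2]
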