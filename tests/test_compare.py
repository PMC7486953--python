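"""Pooled subsampling, reciprocal best-hit matching, and cluster painting."""

import numpy as np
import pytest

from repeatscape._util import random_dna
from repeatscape.cluster import (Read, RepeatCluster, build_consensus,
                                 build_similarity_graph, cluster_graph)
from repeatscape.compare import (paint_graph, pooled_subsample,
                                 reciprocal_best_match, species_assortativity,
                                 subsample_plan)


def _readset(sample, n, rng, length=100):
    return [Read(f"{sample}|short|{i}", sample, "short",
                 random_dna(rng, length)) for i in range(n)]


class TestPooledSubsample:
    def test_equal_counts_disjoint_and_exhaustive(self, rng):
        readsets = {"a": _readset("a", 20, rng), "b": _readset("b", 20, rng)}
        pools = pooled_subsample(readsets, per_sample=10, replicates=2, seed=1)
        seen = set()
        for pool in pools:
            per_sample = {}
            for r in pool.reads:
                per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
                assert r.read_id not in seen
                seen.add(r.read_id)
            assert per_sample == {"a": 10, "b": 10}
        assert len(seen) == 40  # exhaustive at these counts

    def test_insufficient_reads_error_names_sample(self, rng):
        readsets = {"small": _readset("small", 5, rng)}
        with pytest.raises(ValueError, match="small"):
            pooled_subsample(readsets, per_sample=4, replicates=2, seed=0)

    def test_platform_aware_draws(self, rng):
        reads = (_readset("s", 30, rng)
                 + [Read(f"s|long-short|{i}", "s", "long-short",
                         random_dna(rng, 200)) for i in range(10)])
        pools = pooled_subsample({"s": reads},
                                 per_sample={"short": 15, "long-short": 5},
                                 replicates=2, seed=3)
        for pool in pools:
            platforms = [r.platform for r in pool.reads]
            assert platforms.count("short") == 15
            assert platforms.count("long-short") == 5

    def test_plan_reproduces_study_scale_arithmetic(self):
        # 12 enriched readsets, 25,000 + 75,000 reads drawn per readset and
        # replicate -> 1,200,000 pooled reads per replicate
        available = {f"s{i:02d}": {"long-short": 3_000_000,
                                   "short": 9_000_000} for i in range(12)}
        plan = subsample_plan(available,
                              per_sample={"long-short": 25_000,
                                          "short": 75_000},
                              replicates=20)
        per_replicate = plan.groupby("replicate")["n_reads"].sum()
        assert (per_replicate == 1_200_000).all()
        assert len(per_replicate) == 20

    def test_plan_rejects_overdraw(self):
        with pytest.raises(ValueError, match="s00"):
            subsample_plan({"s00": 10_000}, per_sample=1_000, replicates=20)


class TestReciprocalBestMatch:
    def _clusters_from(self, reads, min_cluster_size=3):
        graph = build_similarity_graph(reads)
        clusters = cluster_graph(graph, min_cluster_size)
        by_id = {r.read_id: r for r in reads}
        for c in clusters:
            c.consensus = build_consensus(c, by_id, graph)
        return clusters

    def _family_reads(self, unit, sample, n, rng):
        # sequential overlapping windows: one well-connected cluster per unit
        out = []
        step = max(1, (len(unit) - 120) // max(1, n - 1))
        for i in range(n):
            start = min(i * step, len(unit) - 120)
            out.append(Read(f"{sample}|short|{i}", sample, "short",
                            unit[start:start + 120]))
        return out

    def test_self_match_is_identity(self, rng):
        units = [random_dna(rng, 500) for _ in range(3)]
        reads = []
        for j, u in enumerate(units):
            reads += self._family_reads(u, f"f{j}", 8, rng)
        clusters = self._clusters_from(reads)
        table = reciprocal_best_match(clusters, clusters, top_n_keep=3)
        assert table.matches == {c.cluster_id: c.cluster_id for c in clusters}

    def test_unrelated_clusters_have_no_match(self, rng):
        a = self._clusters_from(
            self._family_reads(random_dna(rng, 500), "a", 8, rng))
        b = self._clusters_from(
            self._family_reads(random_dna(rng, 500), "b", 8, rng))
        table = reciprocal_best_match(a, b, top_n_keep=1)
        assert table.matches == {}
        assert table.unmatched_top == [1]

    def test_matching_symmetric_in_arguments(self, rng):
        units = [random_dna(rng, 500) for _ in range(4)]
        reads_a, reads_b = [], []
        for j, u in enumerate(units):
            reads_a += self._family_reads(u, f"a{j}", 8, rng)
            reads_b += self._family_reads(u, f"b{j}", 8, rng)
        ca = self._clusters_from(reads_a)
        cb = self._clusters_from(reads_b)
        ab = reciprocal_best_match(ca, cb, top_n_keep=4).matches
        ba = reciprocal_best_match(cb, ca, top_n_keep=4).matches
        assert {v: k for k, v in ab.items()} == ba


class TestPaintAndAssortativity:
    def _painted(self, edges, labels):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from(edges)
        cluster = RepeatCluster(1, sorted(labels))
        return paint_graph([cluster], g, labels)[0]

    def test_single_species_composition(self, rng):
        labels = {f"r{i}": "spA" for i in range(4)}
        painted = self._painted([("r0", "r1"), ("r2", "r3")], labels)
        assert painted.composition == {"spA": 4}

    def test_unlabeled_read_rejected(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(["r0", "r1"])
        cluster = RepeatCluster(1, ["r0", "r1"])
        with pytest.raises(ValueError, match="unlabeled"):
            paint_graph([cluster], g, {"r0": "spA"})

    def test_single_species_assortativity_undefined(self):
        labels = {f"r{i}": "spA" for i in range(4)}
        painted = self._painted([("r0", "r1")], labels)
        with pytest.raises(ValueError, match="single-species"):
            species_assortativity(painted, 99, seed=0)

    def test_perfect_segregation_is_extreme(self):
        labels = {f"a{i}": "spA" for i in range(6)}
        labels.update({f"b{i}": "spB" for i in range(6)})
        edges = [(f"a{i}", f"a{j}") for i in range(6) for j in range(i + 1, 6)]
        edges += [(f"b{i}", f"b{j}") for i in range(6) for j in range(i + 1, 6)]
        painted = self._painted(edges, labels)
        res = species_assortativity(painted, n_permutations=999, seed=1)
        assert res.observed == 1.0
        assert res.statistic > 2.0
        assert res.p_value <= 5 / (999 + 1)

    def test_random_labels_center_on_null(self, rng):
        # statistic averaged over independent random labelings ~ 0
        import networkx as nx

        g = nx.gnm_random_graph(30, 60, seed=5)
        g = nx.relabel_nodes(g, {i: f"r{i}" for i in range(30)})
        stats = []
        for rep in range(60):
            labels = {n: ("spA" if rng.random() < 0.5 else "spB")
                      for n in g.nodes}
            if len(set(labels.values())) < 2:
                continue
            cluster = RepeatCluster(1, sorted(g.nodes))
            painted = paint_graph([cluster], g, labels)[0]
            res = species_assortativity(painted, 199, seed=rep)
            stats.append(res.statistic)
        assert abs(np.mean(stats)) < 0.2

    def test_statistic_invariant_to_node_order(self):
        labels = {f"r{i}": ("spA" if i % 2 else "spB") for i in range(8)}
        edges = [(f"r{i}", f"r{(i + 1) % 8}") for i in range(8)]
        a = species_assortativity(self._painted(edges, labels), 299, seed=4)
        b = species_assortativity(
            self._painted(list(reversed(edges)), labels), 299, seed=4)
        assert a.observed == b.observed
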