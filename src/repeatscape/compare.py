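"""Cross-sample pooling, cluster matching across runs, and cluster painting.

Comparing repeat clusters discovered independently in different samples is
unreliable, so samples are compared inside joint clustering runs: every
sample contributes an equal number of reads to a pooled readset (replicated
over disjoint draws), clusters from replicate runs are matched by reciprocal
best hits between their consensus contigs, and each joint cluster's graph is
"painted" by the species of origin of its reads. Aggregation of same-species
reads in the graph indicates repeat divergence after the species split;
dispersion indicates diversification that predates it. A permutation test on
the fraction of same-species edges quantifies the aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from ._util import revcomp
from .cluster import Read, RepeatCluster


@dataclass
class PooledSubsample:
    replicate_id: int
    draw_counts: dict[str, dict[str, int]]  # sample -> platform -> count
    reads: list[Read]


def subsample_plan(available: Mapping[str, Mapping[str, int] | int],
                   per_sample: Mapping[str, int] | int,
                   replicates: int) -> pd.DataFrame:
    """Validate a pooled-subsampling design and tabulate the draw counts.

    ``available`` gives per-sample read counts (optionally per platform);
    ``per_sample`` the number of reads drawn from each sample per replicate
    (optionally per platform). Raises if any sample cannot supply
    ``count x replicates`` reads without replacement. Returns one row per
    (replicate, sample, platform) with the pooled total per replicate
    recomputable as the column sum.
    """
    rows = []
    for sample, have in available.items():
        want = per_sample if isinstance(per_sample, Mapping) else {"all": per_sample}
        have_map = have if isinstance(have, Mapping) else {"all": have}
        for platform, count in want.items():
            n_have = (have_map.get(platform, 0) if platform != "all"
                      else sum(have_map.values()))
            if count * replicates > n_have:
                raise ValueError(
                    f"sample {sample!r} ({platform}): needs "
                    f"{count * replicates} reads, has {n_have}")
            for r in range(1, replicates + 1):
                rows.append({"replicate": r, "sample": sample,
                             "platform": platform, "n_reads": count})
    return pd.DataFrame(rows)


def pooled_subsample(enriched_readsets: Mapping[str, Sequence[Read]],
                     per_sample: Mapping[str, int] | int,
                     replicates: int, seed: int = 0) -> list[PooledSubsample]:
    """Equal-proportion pooled subsampling without replacement.

    Each of ``replicates`` pooled readsets receives exactly ``per_sample``
    reads from every sample (a map platform -> count draws per platform);
    draws are disjoint across replicates. Raises, naming the sample, when a
    readset is too small.
    """
    rng = np.random.default_rng(seed)
    pools: list[PooledSubsample] = [
        PooledSubsample(replicate_id=r + 1, draw_counts={}, reads=[])
        for r in range(replicates)
    ]
    for sample in sorted(enriched_readsets):
        reads = list(enriched_readsets[sample])
        groups: dict[str, list[Read]]
        if isinstance(per_sample, Mapping):
            groups = {}
            for rd in reads:
                groups.setdefault(rd.platform, []).append(rd)
            want = dict(per_sample)
        else:
            groups = {"all": reads}
            want = {"all": per_sample}
        for platform, count in want.items():
            group = groups.get(platform, [])
            if count * replicates > len(group):
                raise ValueError(
                    f"sample {sample!r} ({platform}): needs "
                    f"{count * replicates} reads, has {len(group)}")
            order = rng.permutation(len(group))
            for r in range(replicates):
                chunk = [group[j] for j in order[r * count:(r + 1) * count]]
                pools[r].reads.extend(chunk)
                pools[r].draw_counts.setdefault(sample, {})[platform] = count
    return pools


# ---------------------------------------------------------------------------
# Reciprocal best-hit matching of clusters across runs
# ---------------------------------------------------------------------------

@dataclass
class ClusterMatchTable:
    """Reciprocal best-hit matches between the clusters of two runs."""

    pairs: pd.DataFrame  # cluster_a, cluster_b, score_ab, score_ba, reciprocal
    matches: dict[int, int]  # reciprocal a -> b, restricted to top_n_keep
    unmatched_top: list[int]  # top_n_keep ranks of run a without a reciprocal hit


def _contig_score(x: str, y: str, window: int = 100) -> float:
    """Length-normalized similarity of two consensus contigs.

    Best identity over: the shorter contig aligned (either strand) within
    the longer, and end windows of the shorter aligned within the longer.
    The windows rescue pairs of contigs that cover partially overlapping
    stretches of the same repeat (common for tandem arrays, where contigs
    are arbitrary rotations of the unit).
    """
    s, l = (x, y) if len(x) <= len(y) else (y, x)
    queries = [s]
    if len(s) > window:
        queries += [s[:window], s[-window:]]
    best = 0.0
    for w in queries:
        for q in (w, revcomp(w)):
            dist = edlib.align(q, l, mode="HW", task="distance")["editDistance"]
            best = max(best, 1.0 - dist / len(w))
    return best


def cluster_pair_score(a: RepeatCluster, b: RepeatCluster) -> float:
    if not a.consensus or not b.consensus:
        return 0.0
    return max(_contig_score(ca, cb) for ca in a.consensus for cb in b.consensus)


def reciprocal_best_match(clusters_a: Sequence[RepeatCluster],
                          clusters_b: Sequence[RepeatCluster],
                          top_n_search: int = 50, top_n_keep: int = 15,
                          score_floor: float = 0.75) -> ClusterMatchTable:
    """Match clusters across two runs by reciprocal best consensus hits.

    All-vs-all contig similarity is computed among the ``top_n_search``
    highest-ranked clusters of each run; a pair is reciprocal iff each is the
    other's best hit with score >= ``score_floor`` (ties broken by higher
    score then lower cluster rank). Only the ``top_n_keep`` clusters of run a
    are retained in ``matches``; any of them without a reciprocal partner is
    flagged in ``unmatched_top`` and excluded.
    """
    ca = sorted(clusters_a, key=lambda c: c.cluster_id)[:top_n_search]
    cb = sorted(clusters_b, key=lambda c: c.cluster_id)[:top_n_search]
    if not ca or not cb:
        raise ValueError("both runs must provide clusters with consensi")

    scores = np.zeros((len(ca), len(cb)))
    for i, a in enumerate(ca):
        for j, b in enumerate(cb):
            scores[i, j] = cluster_pair_score(a, b)

    def best(row: np.ndarray) -> int | None:
        if row.max() < score_floor:
            return None
        return int(np.argmax(row))  # argmax takes the lowest rank on ties

    best_ab = {i: best(scores[i]) for i in range(len(ca))}
    best_ba = {j: best(scores[:, j]) for j in range(len(cb))}

    rows, matches, unmatched = [], {}, []
    for i, a in enumerate(ca):
        j = best_ab[i]
        reciprocal = j is not None and best_ba[j] == i
        rows.append({
            "cluster_a": a.cluster_id,
            "cluster_b": cb[j].cluster_id if j is not None else None,
            "score_ab": scores[i, j] if j is not None else 0.0,
            "score_ba": scores[i, j] if j is not None else 0.0,
            "reciprocal": bool(reciprocal),
        })
        if a.cluster_id <= top_n_keep:
            if reciprocal:
                matches[a.cluster_id] = cb[j].cluster_id
            else:
                unmatched.append(a.cluster_id)
    return ClusterMatchTable(pairs=pd.DataFrame(rows), matches=matches,
                             unmatched_top=unmatched)


# ---------------------------------------------------------------------------
# Pool-and-paint
# ---------------------------------------------------------------------------

@dataclass
class PaintedGraph:
    cluster_id: int
    graph: nx.Graph  # nodes carry a "species" attribute
    composition: dict[str, int]


@dataclass
class AssortativityResult:
    statistic: float  # permutation z-score of the same-species edge fraction
    p_value: float  # one-sided
    observed: float
    n_edges: int
    n_permutations: int


def paint_graph(clusters: Sequence[RepeatCluster], graph: nx.Graph,
                read_labels: Mapping[str, str]) -> list[PaintedGraph]:
    """Label each cluster's subgraph by species and tally its composition."""
    painted = []
    for c in clusters:
        missing = [rid for rid in c.members if rid not in read_labels]
        if missing:
            raise ValueError(f"unlabeled read(s) in cluster {c.cluster_id}: "
                             f"{missing[:3]}")
        sub = graph.subgraph(c.members).copy()
        comp: dict[str, int] = {}
        for rid in c.members:
            sp = read_labels[rid]
            sub.nodes[rid]["species"] = sp
            comp[sp] = comp.get(sp, 0) + 1
        painted.append(PaintedGraph(cluster_id=c.cluster_id, graph=sub,
                                    composition=comp))
    return painted


def species_assortativity(painted: PaintedGraph, n_permutations: int = 999,
                          seed: int = 0) -> AssortativityResult:
    """Permutation test for within-species aggregation in a painted graph.

    The statistic is the observed fraction of edges joining same-species
    reads, standardized by the mean and s.d. of that fraction under random
    relabeling of the nodes; the p-value is the one-sided permutation tail.
    A positive statistic means reads of the same species are more connected
    than expected - the signature of repeat amplification after the species
    split.
    """
    if len(painted.composition) < 2:
        raise ValueError(f"cluster {painted.cluster_id}: assortativity is "
                         "undefined for a single-species cluster")
    g = painted.graph
    if g.number_of_edges() < 1:
        raise ValueError(f"cluster {painted.cluster_id}: no edges")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    species = sorted({g.nodes[n]["species"] for n in nodes})
    sp_code = {s: i for i, s in enumerate(species)}
    labels = np.array([sp_code[g.nodes[n]["species"]] for n in nodes])
    u = np.array([index[a] for a, b in g.edges])
    v = np.array([index[b] for a, b in g.edges])

    observed = float(np.mean(labels[u] == labels[v]))
    rng = np.random.default_rng(seed)
    perm_vals = np.empty(n_permutations)
    for t in range(n_permutations):
        perm = rng.permutation(labels)
        perm_vals[t] = np.mean(perm[u] == perm[v])
    mu, sd = float(perm_vals.mean()), float(perm_vals.std())
    statistic = (observed - mu) / sd if sd > 0 else 0.0
    p = (1 + int(np.sum(perm_vals >= observed - 1e-12))) / (n_permutations + 1)
    return AssortativityResult(statistic=statistic, p_value=p,
                               observed=observed, n_edges=len(u),
                               n_permutations=n_permutations)
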