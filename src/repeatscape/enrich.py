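"""Iterative repeat discovery and total repeat-content estimation.

Implements the discover-query-filter loop used to enrich a low-coverage read
pool for repeats: each iteration draws a subset of the pool, clusters it de
novo (graph stage), records the fraction p_i of the subset assigned to
clusters, queries the remaining pool against the cluster consensus contigs
(fraction q_i matched), and removes both the clustered and the query-matched
reads from the pool before the next iteration. All removed reads accumulate
into a repeat-enriched readset.

The total repeat content of the genome is estimated as the cumulative
fraction of the original pool removed as repeat after the last iteration -
the sum of the per-iteration de novo and query yields, normalized by the
original pool size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from ._util import canonical_kmers, revcomp
from .cluster import (Read, build_consensus, build_similarity_graph,
                      cluster_graph)


@dataclass
class EnrichmentConfig:
    """Loop parameters; subset_size is deliberately desk-scale by default."""

    subset_size: int = 5000
    n_iterations: int = 5
    query_min_identity: float = 0.90
    query_min_hit_length: int = 55
    min_cluster_size: int = 10
    k: int = 15
    min_shared_kmers: int = 3
    min_overlap: float | int = 0.55
    min_identity: float = 0.90

    def __post_init__(self):
        if self.subset_size < 1 or self.n_iterations < 1:
            raise ValueError("subset_size and n_iterations must be >= 1")


@dataclass
class IterationRecord:
    i: int
    p: float  # fraction of the iteration's subset de novo assigned to clusters
    q: float  # fraction of the remaining pool matched by consensus query
    n_subset: int
    n_clustered: int
    n_pool_queried: int
    n_matched: int
    removed_cum: int  # total reads removed after this iteration
    pool_remaining: int


@dataclass
class EnrichmentTrace:
    n_initial: int
    iterations: list[IterationRecord] = field(default_factory=list)
    truncated: bool = False

    @property
    def estimate(self) -> float:
        return estimate_repeat_content(self)


def query_pool(pool_reads: Sequence[Read], consensi: Sequence[str],
               query_min_identity: float = 0.90,
               query_min_hit_length: int = 55,
               k: int = 15, min_shared_kmers: int = 2) -> set[str]:
    """Read ids from the pool with similarity to any consensus contig.

    A read matches iff it (or a contig, whichever is shorter) aligns within
    the other at identity >= ``query_min_identity`` over at least
    ``query_min_hit_length`` bases. A shared canonical k-mer prescreen keeps
    the alignment work proportional to the number of plausible hits.
    """
    if not consensi:
        raise ValueError("consensi must be non-empty")
    cons_kmers: set[str] = set()
    for c in consensi:
        for kmer, _, _ in canonical_kmers(c, k):
            cons_kmers.add(kmer)

    matched: set[str] = set()
    for read in pool_reads:
        shared = 0
        for kmer, _, _ in canonical_kmers(read.sequence, k):
            if kmer in cons_kmers:
                shared += 1
                if shared >= min_shared_kmers:
                    break
        if shared < min_shared_kmers:
            continue
        if _read_hits_any(read.sequence, consensi, query_min_identity,
                          query_min_hit_length):
            matched.add(read.read_id)
    return matched


def _read_hits_any(seq: str, consensi: Sequence[str], min_identity: float,
                   min_hit_length: int) -> bool:
    if len(seq) < min_hit_length:
        return False
    # local-alignment surrogate: try the full read plus prefix/suffix windows
    # of min_hit_length, so reads straddling a repeat boundary still hit
    windows = [seq]
    if len(seq) > min_hit_length:
        windows += [seq[:min_hit_length], seq[-min_hit_length:]]
    for cons in consensi:
        if len(cons) < min_hit_length:
            continue
        for w in windows:
            if len(w) > len(cons):
                continue
            max_ed = int((1.0 - min_identity) * len(w))
            for q in (w, revcomp(w)):
                if edlib.align(q, cons, mode="HW", task="distance",
                               k=max_ed)["editDistance"] != -1:
                    return True
        if len(seq) > len(cons):  # short consensus (bare satellite unit)
            max_ed = int((1.0 - min_identity) * len(cons))
            for q in (cons, revcomp(cons)):
                if edlib.align(q, seq, mode="HW", task="distance",
                               k=max_ed)["editDistance"] != -1:
                    return True
    return False


def run_enrichment(reads: Sequence[Read], config: EnrichmentConfig | None = None,
                   seed: int = 0) -> tuple[EnrichmentTrace, list[Read]]:
    """Run the discover-query-filter loop and return (trace, enriched reads).

    Each iteration draws ``subset_size`` reads without replacement from the
    pool, clusters them, queries the rest of the pool against the consensus
    contigs, and removes the clustered and matched reads. Unclustered subset
    reads return to the pool. The loop stops early (recording truncation)
    when the pool cannot fill a subset.
    """
    config = config or EnrichmentConfig()
    if len(reads) < config.subset_size:
        raise ValueError("pool smaller than subset_size for iteration 1")
    rng = np.random.default_rng(seed)
    pool: list[Read] = list(reads)
    n_initial = len(pool)
    trace = EnrichmentTrace(n_initial=n_initial)
    enriched: list[Read] = []
    library: list[str] = []  # consensus contigs accumulated over iterations

    for it in range(1, config.n_iterations + 1):
        if not pool:
            trace.truncated = True
            break
        n_sub = min(config.subset_size, len(pool))
        pick = rng.choice(len(pool), size=n_sub, replace=False)
        mask = np.zeros(len(pool), dtype=bool)
        mask[pick] = True
        subset = [pool[j] for j in np.flatnonzero(mask)]
        rest = [pool[j] for j in np.flatnonzero(~mask)]

        graph = build_similarity_graph(
            subset, k=config.k, min_shared_kmers=config.min_shared_kmers,
            min_overlap=config.min_overlap, min_identity=config.min_identity)
        clusters = cluster_graph(graph, min_cluster_size=config.min_cluster_size)
        by_id = {r.read_id: r for r in subset}
        clustered_ids = {rid for c in clusters for rid in c.members}
        p_i = len(clustered_ids) / n_sub

        library.extend(contig for c in clusters
                       for contig in build_consensus(c, by_id, graph))
        # the query targets everything not yet assigned to clusters: the
        # unclustered remainder of the subset plus the undrawn pool
        queryable = [r for r in subset if r.read_id not in clustered_ids] + rest
        if library and queryable:
            matched_ids = query_pool(queryable, library,
                                     config.query_min_identity,
                                     config.query_min_hit_length, k=config.k)
        else:
            matched_ids = set()
        q_i = len(matched_ids) / len(queryable) if queryable else 0.0

        enriched.extend(r for r in subset if r.read_id in clustered_ids)
        enriched.extend(r for r in queryable if r.read_id in matched_ids)
        pool = [r for r in queryable if r.read_id not in matched_ids]

        trace.iterations.append(IterationRecord(
            i=it, p=p_i, q=q_i, n_subset=n_sub,
            n_clustered=len(clustered_ids),
            n_pool_queried=len(queryable), n_matched=len(matched_ids),
            removed_cum=len(enriched), pool_remaining=len(pool)))
        if n_sub < config.subset_size:
            trace.truncated = True
            break
    return trace, enriched


def estimate_repeat_content(trace: EnrichmentTrace,
                            upto_iteration: int | None = None) -> float:
    """Total repeat content: cumulative removed fraction of the original pool.

    Evaluated after the last iteration by default; ``upto_iteration`` gives
    the running estimate after earlier iterations (used to check that the
    estimator stabilizes quickly).
    """
    if not trace.iterations:
        raise ValueError("trace has no iterations")
    records = trace.iterations
    if upto_iteration is not None:
        records = [r for r in records if r.i <= upto_iteration]
        if not records:
            raise ValueError(f"no iterations <= {upto_iteration}")
    return records[-1].removed_cum / trace.n_initial
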