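"""Graph-based de novo clustering of low-coverage reads into repeat families.

Single-copy sequence is essentially never sampled twice at coverage well below
1x, but a repeat family with hundreds of genomic copies is hit by many reads
that overlap across copies. Building a graph whose nodes are reads and whose
edges are confirmed sequence overlaps therefore groups reads by repeat family:
connected components of the graph approximate families, and component sizes
(as fractions of all reads) estimate genome proportions.

Candidate read pairs are found by shared canonical k-mers (strand-aware), then
confirmed by alignment of the k-mer-anchored overlap region; an edge requires
both a minimum overlap length and a minimum identity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np

from ._util import canonical_kmers, revcomp


@dataclass
class Read:
    """A sequencing read with its sample label and platform tag.

    ``provenance`` carries simulation truth (family id or ``"background"``)
    when the read comes from the synthetic-data generator; it is ``None`` for
    real data and is never consulted by any analysis operation.
    """

    read_id: str
    sample_id: str
    platform: str  # "short" (HiSeq-like) or "long-short" (merged MiSeq-like)
    sequence: str
    provenance: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has empty sequence")


@dataclass
class RepeatCluster:
    """A connected set of reads interpreted as one repeat family."""

    cluster_id: int  # 1-based rank by read count
    members: list[str]  # read ids, sorted
    consensus: list[str] = field(default_factory=list)
    proportion: float | None = None
    class_label: str = "unknown"

    @property
    def size(self) -> int:
        return len(self.members)


def _resolve_min_overlap(min_overlap: float | int, len_a: int, len_b: int) -> int:
    if isinstance(min_overlap, float) and min_overlap < 1:
        return max(1, int(np.ceil(min_overlap * min(len_a, len_b))))
    return int(min_overlap)


def build_similarity_graph(
    reads: Sequence[Read],
    k: int = 15,
    min_shared_kmers: int = 3,
    min_overlap: float | int = 0.55,
    min_identity: float = 0.90,
    max_kmer_bucket: int = 2000,
) -> nx.Graph:
    """Build the read-similarity graph.

    Pairs of reads sharing at least ``min_shared_kmers`` canonical k-mers are
    aligned over the overlap implied by the shared k-mer positions (majority
    orientation, modal diagonal). An edge is added iff the overlap spans at
    least ``min_overlap`` (a fraction of the shorter read when < 1, else
    bases) at identity >= ``min_identity``. k-mers containing N are skipped,
    so N never matches. k-mers occurring in more than ``max_kmer_bucket``
    reads are ignored for candidate generation (low-complexity guard).

    Edge attributes: ``overlap`` (bases), ``identity``, plus the relative
    placement (``a``, ``offset``, ``orient``) used for consensus layout.
    """
    graph = nx.Graph()
    for r in reads:
        if k >= len(r.sequence) + 1:
            raise ValueError(f"k={k} not smaller than read length of {r.read_id!r}")
        graph.add_node(r.read_id, sample_id=r.sample_id)
    if not reads:
        return graph

    kmer_maps: list[dict[str, tuple[int, bool]]] = []
    buckets: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        km: dict[str, tuple[int, bool]] = {}
        for kmer, pos, fwd in canonical_kmers(r.sequence, k):
            if kmer not in km:
                km[kmer] = (pos, fwd)
                buckets[kmer].append(i)
        kmer_maps.append(km)

    pair_counts: Counter[tuple[int, int]] = Counter()
    for members in buckets.values():
        if len(members) < 2 or len(members) > max_kmer_bucket:
            continue
        for i, j in combinations(members, 2):
            pair_counts[(i, j)] += 1

    for (i, j), n_shared in pair_counts.items():
        if n_shared < min_shared_kmers:
            continue
        edge = _confirm_pair(reads[i], reads[j], kmer_maps[i], kmer_maps[j],
                             k, min_overlap, min_identity)
        if edge is not None:
            graph.add_edge(reads[i].read_id, reads[j].read_id, **edge)
    return graph


def _confirm_pair(read_a: Read, read_b: Read,
                  km_a: Mapping[str, tuple[int, bool]],
                  km_b: Mapping[str, tuple[int, bool]],
                  k: int, min_overlap: float | int,
                  min_identity: float) -> dict | None:
    """Anchor the pair on shared k-mers and align the implied overlap."""
    seq_a, seq_b = read_a.sequence, read_b.sequence
    la, lb = len(seq_a), len(seq_b)
    votes: Counter[tuple[bool, int]] = Counter()
    for kmer in km_a.keys() & km_b.keys():
        pa, fa = km_a[kmer]
        pb, fb = km_b[kmer]
        if fa == fb:  # same strand
            votes[(True, pa - pb)] += 1
        else:  # b reverse-complemented relative to a
            votes[(False, pa - (lb - k - pb))] += 1
    if not votes:
        return None
    # majority orientation, then modal diagonal; deterministic tie-break
    (same, offset), _ = max(votes.items(), key=lambda kv: (kv[1], kv[0][0], -abs(kv[0][1])))

    b_oriented = seq_b if same else revcomp(seq_b)
    start = max(0, offset)
    end = min(la, offset + lb)
    overlap = end - start
    if overlap < _resolve_min_overlap(min_overlap, la, lb):
        return None
    sub_a = seq_a[start:end]
    sub_b = b_oriented[start - offset:end - offset]
    dist = edlib.align(sub_a, sub_b, mode="NW", task="distance")["editDistance"]
    identity = 1.0 - dist / overlap
    if identity < min_identity:
        return None
    return {
        "overlap": overlap,
        "identity": identity,
        "a": read_a.read_id,
        "offset": offset,
        "orient": 1 if same else -1,
    }


def cluster_graph(graph: nx.Graph, min_cluster_size: int = 10) -> list[RepeatCluster]:
    """Partition the similarity graph into repeat clusters.

    Clusters are connected components of size >= ``min_cluster_size``, ranked
    by non-increasing size with ties broken by smallest member read id.
    Smaller components and singletons count as unclustered
    (see :func:`unclustered_count`).
    """
    comps = [sorted(c) for c in nx.connected_components(graph)
             if len(c) >= min_cluster_size]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [RepeatCluster(cluster_id=i + 1, members=c)
            for i, c in enumerate(comps)]


def unclustered_count(graph: nx.Graph, clusters: Sequence[RepeatCluster]) -> int:
    return graph.number_of_nodes() - sum(c.size for c in clusters)


def build_consensus(cluster: RepeatCluster,
                    reads: Mapping[str, Read] | Sequence[Read],
                    graph: nx.Graph,
                    min_contig_length: int = 55) -> list[str]:
    """Greedy seed-and-extend consensus contig(s) for one cluster.

    Member reads are laid out by breadth-first propagation of the pairwise
    offsets/orientations stored on graph edges, starting from the
    highest-degree member; each layout column takes the majority base (ties
    to the alphabetically smallest). Zero-coverage columns split the layout
    into separate contigs; contigs shorter than ``min_contig_length`` are
    dropped unless nothing longer exists.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    by_id = {r.read_id: r for r in reads} if not isinstance(reads, Mapping) else reads
    members = cluster.members
    if len(members) == 1:
        return [by_id[members[0]].sequence]

    sub = graph.subgraph(members)
    seed = max(members, key=lambda n: (sub.degree(n), n))
    placement: dict[str, tuple[int, int]] = {seed: (0, 1)}  # id -> (offset, strand)
    queue = [seed]
    while queue:
        u = queue.pop()
        ou, su = placement[u]
        lu = len(by_id[u].sequence)
        for v in sub.neighbors(u):
            if v in placement:
                continue
            e = sub.edges[u, v]
            d, o = e["offset"], e["orient"]
            lv = len(by_id[v].sequence)
            if e["a"] == u:  # v placed relative to u's forward frame
                if su == 1:
                    placement[v] = (ou + d, o)
                else:
                    placement[v] = (ou + lu - d - lv, -o)
            else:  # u was the placed partner; solve for v (= the "a" side)
                if su == o:
                    placement[v] = (ou - d, 1)
                else:
                    placement[v] = (ou + d + lu - lv, -1)
            queue.append(v)

    lo = min(off for off, _ in placement.values())
    hi = max(off + len(by_id[rid].sequence) for rid, (off, _) in placement.items())
    counts = np.zeros((hi - lo, 4), dtype=np.int32)
    from ._util import encode

    for rid, (off, strand) in placement.items():
        seq = by_id[rid].sequence if strand == 1 else revcomp(by_id[rid].sequence)
        codes = encode(seq)
        valid = codes < 4
        pos = np.arange(len(codes))[valid] + (off - lo)
        counts[pos, codes[valid]] += 1

    covered = counts.sum(axis=1) > 0
    consensus_codes = counts.argmax(axis=1).astype(np.uint8)
    contigs: list[str] = []
    start = None
    for i, cov in enumerate(list(covered) + [False]):
        if cov and start is None:
            start = i
        elif not cov and start is not None:
            contigs.append("".join("ACGT"[c] for c in consensus_codes[start:i]))
            start = None
    kept = [c for c in contigs if len(c) >= min_contig_length]
    if not kept and contigs:
        kept = [max(contigs, key=len)]
    return kept


def cluster_proportions(clusters: Sequence[RepeatCluster],
                        total_reads: int) -> dict[int, float]:
    """Genome proportion of each cluster: member count / total reads analyzed."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    props = {c.cluster_id: c.size / total_reads for c in clusters}
    for c in clusters:
        c.proportion = props[c.cluster_id]
    return props


def label_satellite_like(contig: str, min_period: int = 5,
                         min_autocorrelation: float = 0.8) -> str:
    """Naive tandem-periodicity flag for a consensus contig.

    Returns ``"satellite-like"`` when some period p (min_period <= p <=
    len/2) matches the sequence against itself shifted by p at a fraction of
    positions >= ``min_autocorrelation``; otherwise ``"unknown"``. This is a
    deliberately minimal stand-in for homology-based annotation, which is out
    of scope; simulation truth labels are used wherever available.
    """
    n = len(contig)
    s = np.frombuffer(contig.encode(), dtype=np.uint8)
    for p in range(min_period, n // 2 + 1):
        frac = float(np.mean(s[:-p] == s[p:]))
        if frac >= min_autocorrelation:
            return "satellite-like"
    return "unknown"
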