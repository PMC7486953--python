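"""Divergence landscapes: percent divergence of reads from cluster consensi.

Each read is aligned to its cluster's consensus contig(s) and scored as the
percentage of mismatching aligned columns (indel columns excluded by
default). Because repeat copies decay by neutral substitution after
amplification, the distribution of read-to-consensus divergence is a proxy
for the age distribution of a family's copies: a recent expansion piles mass
near zero, an old family sits at higher divergence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._util import revcomp
from .cluster import Read, RepeatCluster

_CIG = re.compile(r"(\d+)([=XIDM])")


@dataclass
class DivergenceProfile:
    per_read: pd.DataFrame  # read_id, cluster_id, class_label, divergence
    cluster_means: pd.DataFrame  # cluster_id, class_label, mean_divergence, n_reads
    class_means: pd.DataFrame  # class_label, mean_divergence, n_reads
    histogram: pd.DataFrame  # bin_low, bin_high, count (1% bins, 0-30%)
    n_scored: int = 0
    n_skipped: int = 0
    n_overflow: int = 0  # reads scored above the last histogram bin

    def peak_bin(self) -> tuple[float, float]:
        i = int(self.histogram["count"].idxmax())
        row = self.histogram.loc[i]
        return float(row["bin_low"]), float(row["bin_high"])


def read_divergence(read: Read | str, consensus: str,
                    min_aligned_fraction: float = 0.5,
                    include_indels: bool = False,
                    max_edit_fraction: float = 0.35) -> float | None:
    """Percent divergence of one read from a consensus, or None if unalignable.

    The read is aligned (either strand) within the consensus; divergence is
    100 x mismatched / aligned columns. Indel columns are excluded from both
    numerator and denominator unless ``include_indels`` is set, in which case
    they count as mismatches. A read is skipped (None) when no alignment
    exists above the score floor - edit distance within ``max_edit_fraction``
    of the query length (random sequence sits near 50%) - or when fewer than
    ``min_aligned_fraction`` of its bases fall in aligned columns.
    """
    seq = read.sequence if isinstance(read, Read) else read
    best = None
    for q, c in _alignment_orientations(seq, consensus):
        res = edlib.align(q, c, mode="HW", task="path",
                          k=int(max_edit_fraction * len(q)))
        if res["editDistance"] == -1:
            continue
        if best is None or res["editDistance"] < best["editDistance"]:
            best = res
    if best is None:
        return None
    matches = mismatches = ins = dele = 0
    for count, op in _CIG.findall(best["cigar"]):
        n = int(count)
        if op == "=":
            matches += n
        elif op in "XM":
            mismatches += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
    aligned = matches + mismatches
    if aligned < min_aligned_fraction * len(seq):
        return None
    if include_indels:
        return 100.0 * (mismatches + ins + dele) / (aligned + ins + dele)
    if aligned == 0:
        return None
    return 100.0 * mismatches / aligned


def _alignment_orientations(seq: str, consensus: str):
    if len(seq) <= len(consensus):
        yield seq, consensus
        yield revcomp(seq), consensus
    else:  # short consensus (e.g. a bare satellite unit): anchor it in the read
        yield consensus, seq
        yield revcomp(consensus), seq


def landscape(clusters: Sequence[RepeatCluster],
              reads: Mapping[str, Read] | Sequence[Read],
              max_percent: float = 30.0,
              min_aligned_fraction: float = 0.5,
              include_indels: bool = False) -> DivergenceProfile:
    """Divergence profile over all clusters: per-read values, per-cluster and
    per-class means (read-weighted), and a pooled histogram in 1% bins.

    Reads scored above ``max_percent`` are tallied as overflow so histogram
    mass plus overflow always equals the number of scored reads; unalignable
    reads are counted as skipped, never silently dropped. Clusters without
    consensus contigs contribute only skips.
    """
    by_id = {r.read_id: r for r in reads} if not isinstance(reads, Mapping) else reads
    rows = []
    n_skipped = 0
    for c in clusters:
        for rid in c.members:
            read = by_id[rid]
            div = None
            if c.consensus:
                vals = [read_divergence(read, cons, min_aligned_fraction,
                                        include_indels)
                        for cons in c.consensus]
                vals = [v for v in vals if v is not None]
                div = min(vals) if vals else None
            if div is None:
                n_skipped += 1
            else:
                rows.append({"read_id": rid, "cluster_id": c.cluster_id,
                             "class_label": c.class_label, "divergence": div})
    per_read = pd.DataFrame(rows, columns=["read_id", "cluster_id",
                                           "class_label", "divergence"])

    if len(per_read):
        cluster_means = (per_read.groupby("cluster_id")
                         .agg(class_label=("class_label", "first"),
                              mean_divergence=("divergence", "mean"),
                              n_reads=("divergence", "size"))
                         .reset_index())
        class_means = (per_read.groupby("class_label")
                       .agg(mean_divergence=("divergence", "mean"),
                            n_reads=("divergence", "size"))
                       .reset_index())
    else:
        cluster_means = pd.DataFrame(columns=["cluster_id", "class_label",
                                              "mean_divergence", "n_reads"])
        class_means = pd.DataFrame(columns=["class_label", "mean_divergence",
                                            "n_reads"])

    edges = np.arange(0.0, max_percent + 1.0, 1.0)
    vals = per_read["divergence"].to_numpy(dtype=float) if len(per_read) else \
        np.empty(0)
    in_range = vals[vals < max_percent]
    counts, _ = np.histogram(in_range, bins=edges)
    histogram = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                              "count": counts})
    return DivergenceProfile(
        per_read=per_read, cluster_means=cluster_means,
        class_means=class_means, histogram=histogram,
        n_scored=int(len(per_read)), n_skipped=n_skipped,
        n_overflow=int(np.sum(vals >= max_percent)),
    )
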