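"""File formats shared by all stages.

Conventions: read names encode sample and platform as
``<sample>|<platform>|<serial>``; all coordinates are 0-based half-open;
truth tables, cluster assignments, match tables and abundance matrices are
TSV; graphs are GraphML; configuration is YAML with the seed recorded.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import Read, RepeatCluster
from .simulate import SpeciesGenome


def write_fasta(path, records: Mapping[str, str] | Sequence[tuple[str, str]]):
    items = records.items() if isinstance(records, Mapping) else records
    seqs = [SeqRecord(Seq(s), id=str(name), description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: Sequence[Read], quality: int = 35):
    """Write reads as FASTQ with a constant quality (no quality simulation)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n"
                     f"{chr(quality + 33) * len(r.sequence)}\n")


def read_fastq(path) -> list[Read]:
    """Read FASTQ; sample and platform are decoded from the read names."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        parts = rec.id.split("|")
        sample = parts[0] if len(parts) >= 3 else rec.id
        platform = parts[1] if len(parts) >= 3 else "short"
        reads.append(Read(read_id=rec.id, sample_id=sample, platform=platform,
                          sequence=str(rec.seq)))
    return reads


def write_truth_table(path, reads: Sequence[Read]):
    pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "sample": [r.sample_id for r in reads],
        "provenance": [r.provenance or "NA" for r in reads],
    }).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genome(path_fasta, path_truth, genome: SpeciesGenome):
    write_fasta(path_fasta, [(genome.species_id, genome.sequence)])
    pd.DataFrame(genome.truth_intervals,
                 columns=["start", "end", "label"]).to_csv(
        path_truth, sep="\t", index=False)


def write_clusters_tsv(path, clusters: Sequence[RepeatCluster]):
    rows = [{"read_id": rid, "cluster_id": c.cluster_id,
             "class_label": c.class_label}
            for c in clusters for rid in c.members]
    pd.DataFrame(rows, columns=["read_id", "cluster_id", "class_label"]).to_csv(
        path, sep="\t", index=False)


def write_consensus_fasta(path, clusters: Sequence[RepeatCluster]):
    records = []
    for c in clusters:
        for i, contig in enumerate(c.consensus):
            records.append((f"CL{c.cluster_id}_contig{i}", contig))
    write_fasta(path, records)


def write_graphml(path, graph: nx.Graph):
    nx.write_graphml(graph, str(path))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_manifest(path, manifest: dict):
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str) + "\n")
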