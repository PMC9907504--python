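"""Readers and writers for the on-disk dialects used across the pipeline.

FASTA via Biopython; coverage/taxonomy/presence-absence tables as TSV; gene
clusters as a JSON dialect mirroring antiSMASH-style region summaries:
{cluster_id, genome_id, class, is_reference, compound, genes: [{gene_id,
order_index, strand, role_annotation, domains, sequence}]}.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bgcnet import ClusterRecord, GeneRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_coverage",
    "write_coverage",
    "read_taxonomy",
    "write_taxonomy",
    "read_clusters_json",
    "write_clusters_json",
    "read_pa_matrix",
    "write_pa_matrix",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"contig_id", "mean_depth"}
    if not expected <= set(df.columns):
        raise ValueError(f"coverage TSV must have columns {sorted(expected)}")
    return df


def write_coverage(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"contig_id", "taxon", "rank", "bitscore", "evalue", "tier"}
    if not expected <= set(df.columns):
        raise ValueError(f"taxonomy TSV must have columns {sorted(expected)}")
    return df


def write_taxonomy(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _cluster_to_dict(c: ClusterRecord) -> dict:
    return {
        "cluster_id": c.cluster_id,
        "genome_id": c.genome_id,
        "class": c.bgc_class,
        "is_reference": c.is_reference,
        "compound": c.compound,
        "genes": [
            {
                "gene_id": g.gene_id,
                "order_index": g.order_index,
                "strand": g.strand,
                "role_annotation": g.role_annotation,
                "domains": list(g.domains),
                "sequence": g.sequence,
            }
            for g in c.genes
        ],
    }


def write_clusters_json(clusters: list[ClusterRecord], path) -> None:
    payload = [_cluster_to_dict(c) for c in clusters]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_clusters_json(path) -> list[ClusterRecord]:
    payload = json.loads(Path(path).read_text())
    out = []
    for d in payload:
        out.append(
            ClusterRecord(
                cluster_id=d["cluster_id"],
                genome_id=d["genome_id"],
                bgc_class=d.get("class", "Others"),
                is_reference=bool(d.get("is_reference", False)),
                compound=d.get("compound"),
                genes=[
                    GeneRecord(
                        gene_id=g["gene_id"],
                        order_index=int(g["order_index"]),
                        strand=g.get("strand", "+"),
                        role_annotation=g.get("role_annotation", ""),
                        domains=list(g.get("domains", [])),
                        sequence=g.get("sequence", ""),
                    )
                    for g in d.get("genes", [])
                ],
            )
        )
    return out


def read_pa_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_pa_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
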