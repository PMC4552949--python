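"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Bio.SeqIO (60-column wrapping), GFF3 reading through
gffutils, BED and the two documented tab-separated tables through pandas.

Table schemas
-------------
mapping table (TSV, PSL-convertible):
    transcript_id  chrom  strand  mapped_start  mapped_end  mapped_length
    identity_pct  coverage_in_mapping_pct  coverage_whole_pct  score
read-placement table (TSV, one file per developmental stage):
    read_id  stage  chrom  start  end
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, ProteinRecord

MAPPING_COLUMNS = [
    "transcript_id", "chrom", "strand", "mapped_start", "mapped_end",
    "mapped_length", "identity_pct", "coverage_in_mapping_pct",
    "coverage_whole_pct", "score",
]
READ_COLUMNS = ["read_id", "stage", "chrom", "start", "end"]


def require_file(path: str | os.PathLike, what: str = "input") -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"missing {what} file: {p}")
    return p


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    require_file(path, "FASTA")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_proteome(path: str | os.PathLike, species_id: str = "") -> list[ProteinRecord]:
    return [
        ProteinRecord(id=name, sequence=seq, species_id=species_id)
        for name, seq in read_fasta(path).items()
    ]


# ---------------------------------------------------------------- GFF3

def write_gff3(
    path: str | os.PathLike,
    genes: Iterable[GeneModel],
    contig_lengths: Mapping[str, int],
    source: str = "lsgscan",
) -> None:
    lines = ["##gff-version 3"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for gene in genes:
        start, end = gene.cds_span
        gid, tid = gene.gene_id, f"{gene.gene_id}.t1"
        common = f"{gene.chrom}\t{source}"
        lines.append(
            f"{common}\tgene\t{start + 1}\t{end}\t.\t{gene.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{common}\tmRNA\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        for i, (es, ee) in enumerate(gene.exons, 1):
            lines.append(
                f"{common}\texon\t{es + 1}\t{ee}\t.\t{gene.strand}\t.\t"
                f"ID={tid}.exon{i};Parent={tid}"
            )
            # exons are codon-aligned in generated worlds; phase 0 throughout
            lines.append(
                f"{common}\tCDS\t{es + 1}\t{ee}\t.\t{gene.strand}\t0\t"
                f"ID={tid}.cds;Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    require_file(path, "GFF3")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        protein_ids = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            protein_ids.append(f"{g.id}.p1")
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
        if not exons:  # bare gene line
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                exons=tuple(exons), protein_ids=tuple(protein_ids) or (f"{g.id}.p1",),
            )
        )
    return genes


# ---------------------------------------------------------------- BED

def write_bed(path: str | os.PathLike, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end", "name"])
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    require_file(path, "BED")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    return df


# ---------------------------------------------------------------- tables

def write_mapping_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.loc[:, MAPPING_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mapping_table(path: str | os.PathLike) -> pd.DataFrame:
    require_file(path, "mapping table")
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "chrom": str})


def write_read_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.loc[:, READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_read_table(path: str | os.PathLike) -> pd.DataFrame:
    require_file(path, "read-placement table")
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "stage": str, "chrom": str})
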