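"""Shared domain objects: proteins, gene models and planted ground truth.

Coordinates are 0-based half-open genomic intervals throughout the package;
GFF3 serialisation converts to 1-based inclusive at the file boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter amino-acid alphabet ('X' allowed)."""

    id: str
    sequence: str
    species_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon structure on a genome.

    ``exons`` are non-overlapping, sorted, half-open genomic intervals; the
    CDS span is the envelope of the exons (the generator plants no UTRs).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"gene {self.gene_id!r}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = end

    @property
    def cds_span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def span_length(self) -> int:
        start, end = self.cds_span
        return end - start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def spliced_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence in translation order (reverse-complemented
    for minus-strand genes)."""
    chrom_seq = genome[gene.chrom]
    if gene.exons[-1][1] > len(chrom_seq):
        raise ValueError(
            f"gene {gene.gene_id!r}: exon beyond end of {gene.chrom} "
            f"({gene.exons[-1][1]} > {len(chrom_seq)})"
        )
    parts = [chrom_seq[s:e] for s, e in gene.exons]
    cds = "".join(parts)
    return revcomp(cds) if gene.strand == "-" else cds


@dataclass
class OriginTruth:
    te_derived: bool = False
    dup_derived: bool = False
    retro_derived: bool = False
    chimeric: bool = False
    parent_id: str | None = None


@dataclass
class RetroLocusTruth:
    chrom: str
    start: int
    end: int
    parent_id: str
    kind: str  # "standalone" | "chimera"


@dataclass
class GroundTruth:
    """Planted labels for every generated gene, keyed by gene id."""

    labels: dict[str, str] = field(default_factory=dict)
    origins: dict[str, OriginTruth] = field(default_factory=dict)
    est_supported: dict[str, bool] = field(default_factory=dict)
    expressed: dict[str, dict[str, bool]] = field(default_factory=dict)
    retro_loci: list[RetroLocusTruth] = field(default_factory=list)

    def genes_with_label(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == label)
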