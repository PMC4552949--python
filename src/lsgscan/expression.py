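"""Transcript-mapping filters, EST expression calls, RPKM and stage profiles.

Transcript placements (BLAT-style) are first filtered on four inclusive
thresholds — mapping length >= 150 bp, identity >= 98%, coverage within the
mapping >= 97%, coverage of the whole transcript >= 75% — and transcripts
that then map to several loci with near-tied scores (runner-up within 2% of
the best, relative) are discarded as ambiguous. A gene is EST-supported when
the union of retained placements overlaps its span by strictly more than
100 bp.

Per-stage read counts become RPKM = reads per kilobase of gene span per
million mapped reads; a gene counts as expressed at a stage when its RPKM
exceeds a threshold (default 0, i.e. any read support — the natural reading
when planted-unexpressed genes receive no reads). A read is assigned to
every gene whose span it overlaps by at least 1 bp ("any" mode), or only to
unambiguously single-gene reads in "unique" mode.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import GeneModel

logger = logging.getLogger(__name__)

STAGES = (
    "1-cell", "2-cell", "4-cell", "28-cell", "early embryo", "late embryo",
    "L1", "L2", "L3", "L4", "L4 male",
    "young adult", "adult hermaphrodite", "adult male",
)

DEFAULT_MAPPING_FILTERS = dict(
    min_length=150, min_identity=98.0, min_cov_mapping=97.0, min_cov_whole=75.0
)


@dataclass(frozen=True)
class TranscriptMapping:
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    mapped_length: int
    identity_pct: float
    coverage_in_mapping_pct: float
    coverage_whole_pct: float
    score: float

    def __post_init__(self) -> None:
        for name in ("identity_pct", "coverage_in_mapping_pct", "coverage_whole_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.transcript_id!r}: {name}={v} outside [0, 100]")
        if self.mapped_length > self.end - self.start:
            raise ValueError(
                f"{self.transcript_id!r}: mapped_length exceeds the mapped interval"
            )


def mappings_from_table(df: pd.DataFrame) -> list[TranscriptMapping]:
    return [
        TranscriptMapping(
            transcript_id=str(r.transcript_id), chrom=str(r.chrom), strand=str(r.strand),
            start=int(r.mapped_start), end=int(r.mapped_end),
            mapped_length=int(r.mapped_length), identity_pct=float(r.identity_pct),
            coverage_in_mapping_pct=float(r.coverage_in_mapping_pct),
            coverage_whole_pct=float(r.coverage_whole_pct), score=float(r.score),
        )
        for r in df.itertuples()
    ]


def filter_mappings(
    mappings: Sequence[TranscriptMapping],
    min_length: int = 150,
    min_identity: float = 98.0,
    min_cov_mapping: float = 97.0,
    min_cov_whole: float = 75.0,
) -> list[TranscriptMapping]:
    """Keep placements meeting all four quality thresholds (all inclusive)."""
    kept = [
        m
        for m in mappings
        if m.mapped_length >= min_length
        and m.identity_pct >= min_identity
        and m.coverage_in_mapping_pct >= min_cov_mapping
        and m.coverage_whole_pct >= min_cov_whole
    ]
    logger.info("mapping filters: %d in, %d pass", len(mappings), len(kept))
    return kept


def resolve_ambiguous(
    mappings: Sequence[TranscriptMapping], rel_tol: float = 0.02
) -> list[TranscriptMapping]:
    """One best placement per transcript; multi-locus transcripts whose
    runner-up score is within ``rel_tol`` of the best (relative to the best)
    are discarded entirely."""
    by_transcript: dict[str, list[TranscriptMapping]] = {}
    for m in mappings:
        by_transcript.setdefault(m.transcript_id, []).append(m)
    kept = []
    for tid in sorted(by_transcript):
        group = sorted(by_transcript[tid], key=lambda m: -m.score)
        if len(group) == 1:
            kept.append(group[0])
            continue
        best, runner = group[0], group[1]
        if best.score <= 0 or (best.score - runner.score) / best.score < rel_tol:
            continue  # ambiguous placement
        kept.append(best)
    logger.info("ambiguity filter: %d transcripts in, %d retained",
                len(by_transcript), len(kept))
    return kept


def _overlap_bp(tree: IntervalTree, start: int, end: int) -> int:
    pieces = sorted(
        (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
    )
    total, cur_s, cur_e = 0, None, None
    for s, e in pieces:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def est_expressed(
    gene: GeneModel,
    retained: Sequence[TranscriptMapping],
    min_overlap_bp: int = 100,
) -> bool:
    """True iff the union of retained placements overlaps the gene span by
    strictly more than ``min_overlap_bp``."""
    tree = IntervalTree()
    for m in retained:
        if m.chrom == gene.chrom:
            tree.addi(m.start, m.end)
    if not tree:
        return False
    start, end = gene.cds_span
    return _overlap_bp(tree, start, end) > min_overlap_bp


def rpkm(read_count: int, gene_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of gene length per million mapped reads."""
    if gene_length_bp < 1:
        raise ValueError("gene length must be >= 1")
    if total_mapped_reads < 1:
        raise ValueError("library size must be >= 1")
    return read_count * 1e9 / (gene_length_bp * total_mapped_reads)


@dataclass
class StageLibrary:
    """Read placements of one developmental stage."""

    stage_name: str
    reads: pd.DataFrame  # columns read_id, chrom, start, end
    total_mapped_reads: int

    @classmethod
    def from_table(cls, df: pd.DataFrame, stage_name: str | None = None) -> "StageLibrary":
        name = stage_name or (str(df["stage"].iloc[0]) if len(df) else "unknown")
        return cls(stage_name=name, reads=df, total_mapped_reads=len(df))


def count_reads(
    genes: Sequence[GeneModel], library: StageLibrary, mode: str = "any"
) -> dict[str, int]:
    """Reads per gene: overlap of >= 1 bp with the gene span counts. In
    "unique" mode reads touching more than one gene are dropped."""
    if mode not in ("any", "unique"):
        raise ValueError("mode must be 'any' or 'unique'")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        s, e = g.cds_span
        trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
    counts = {g.gene_id: 0 for g in genes}
    for row in library.reads.itertuples():
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        hits = tree.overlap(int(row.start), int(row.end))
        if mode == "unique" and len(hits) > 1:
            continue
        for iv in hits:
            counts[iv.data] += 1
    return counts


def expression_matrix(
    genes: Sequence[GeneModel],
    libraries: Sequence[StageLibrary],
    mode: str = "any",
) -> pd.DataFrame:
    """Gene x stage table of read counts and RPKM (long format)."""
    rows = []
    for lib in libraries:
        counts = count_reads(genes, lib, mode=mode)
        total = max(lib.total_mapped_reads, 1)
        for g in genes:
            c = counts[g.gene_id]
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "stage": lib.stage_name,
                    "read_count": c,
                    "rpkm": rpkm(c, g.span_length, total),
                }
            )
    return pd.DataFrame(rows)


def stage_proportions(
    labels: pd.DataFrame,
    expression: pd.DataFrame,
    rpkm_threshold: float = 0.0,
    groups: Sequence[str] = ("SSG", "GSG", "EC"),
) -> pd.DataFrame:
    """Per-stage, per-group proportion of genes with RPKM above threshold."""
    label_of = dict(zip(labels["gene_id"], labels["label"]))
    expr = expression.assign(label=expression["gene_id"].map(label_of))
    rows = []
    for stage in expr["stage"].unique():
        at_stage = expr[expr["stage"] == stage]
        for group in groups:
            sub = at_stage[at_stage["label"] == group]
            if sub.empty:
                continue
            prop = float((sub["rpkm"] > rpkm_threshold).mean())
            rows.append({"stage": stage, "group": group, "proportion": prop,
                         "n": len(sub)})
    return pd.DataFrame(rows)


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic with a two-sided p.

    Degenerate zero-variance inputs are resolved by convention: identical
    constant samples give (0, 1); constant samples with different means give
    (inf with the sign of the difference, 0).
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean())) * float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def plot_stage_proportions(proportions: pd.DataFrame, path: str) -> None:
    """Grouped bar chart of expressed-gene proportions per stage (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = list(dict.fromkeys(proportions["stage"]))
    groups = list(dict.fromkeys(proportions["group"]))
    x = np.arange(len(stages))
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(max(8, len(stages) * 0.8), 4))
    for i, group in enumerate(groups):
        sub = proportions[proportions["group"] == group].set_index("stage")
        vals = [sub["proportion"].get(s, np.nan) for s in stages]
        ax.bar(x + i * width, vals, width, label=group)
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(stages, rotation=45, ha="right")
    ax.set_ylabel("proportion of genes with read support")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
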