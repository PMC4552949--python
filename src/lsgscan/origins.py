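"""Mechanism-of-formation calls from positional overlap with annotations.

A lineage-specific gene completely covered by transposable-element (TE)
annotation is called TE-derived (exaptation); one completely covered by
paralog positions is called duplication-derived. "Complete overlap" is read
literally as full containment of the gene's genomic span within the union
of annotation intervals (containment threshold 1.0), exposed as a
configurable fraction. Overlap is strand-ignorant — TE exaptation can be
antisense. Category totals use inclusion–exclusion (|TE ∪ DUP| =
TE + DUP − BOTH) and percentages are rounded half-up to two decimals.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel

TE_ONLY, DUP_ONLY, BOTH, NEITHER = "TE_only", "DUP_only", "BOTH", "NEITHER"


@dataclass
class AnnotationTrack:
    """Genomic intervals of one annotation kind (TE or paralog)."""

    kind: str
    trees: dict[str, IntervalTree]

    @classmethod
    def from_intervals(
        cls, kind: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "AnnotationTrack":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty annotation interval [{start},{end}) on {chrom}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        return cls(kind=kind, trees=trees)

    @classmethod
    def from_bed(cls, kind: str, bed: pd.DataFrame) -> "AnnotationTrack":
        return cls.from_intervals(
            kind, zip(bed["chrom"], bed["start"].astype(int), bed["end"].astype(int))
        )


def _union_coverage(tree: IntervalTree, start: int, end: int) -> int:
    hits = sorted(
        (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in hits:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def overlap_fraction(gene: GeneModel, track: AnnotationTrack) -> float:
    """Fraction of the gene span covered by the union of track intervals."""
    tree = track.trees.get(gene.chrom)
    if tree is None:
        return 0.0
    start, end = gene.cds_span
    return _union_coverage(tree, start, end) / (end - start)


@dataclass(frozen=True)
class OriginCall:
    gene_id: str
    te_derived: bool
    dup_derived: bool
    te_fraction: float
    dup_fraction: float

    @property
    def category(self) -> str:
        if self.te_derived and self.dup_derived:
            return BOTH
        if self.te_derived:
            return TE_ONLY
        if self.dup_derived:
            return DUP_ONLY
        return NEITHER


def call_origin(
    gene: GeneModel,
    te_track: AnnotationTrack,
    paralog_track: AnnotationTrack,
    containment_threshold: float = 1.0,
) -> OriginCall:
    if not (0.0 < containment_threshold <= 1.0):
        raise ValueError("containment threshold must be in (0, 1]")
    te_frac = overlap_fraction(gene, te_track)
    dup_frac = overlap_fraction(gene, paralog_track)
    eps = 1e-12  # guard float division against the exact-containment boundary
    return OriginCall(
        gene_id=gene.gene_id,
        te_derived=te_frac >= containment_threshold - eps,
        dup_derived=dup_frac >= containment_threshold - eps,
        te_fraction=te_frac,
        dup_fraction=dup_frac,
    )


def round_half_up_pct(count: int, total: int, digits: int = 2) -> float:
    """count/total as a percentage, rounded half-up to ``digits`` decimals."""
    if total <= 0:
        return 0.0
    q = Decimal(1).scaleb(-digits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_origins(
    calls: Sequence[OriginCall] | None,
    group_total: int,
    counts: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """Per-mechanism counts with percentages of the group total.

    Either pass per-gene ``calls`` or, for bookkeeping on externally counted
    data, the raw ``counts`` triple (TE, DUP, BOTH). The Total row is the
    union TE + DUP − BOTH by inclusion–exclusion.
    """
    if counts is None:
        if calls is None:
            raise ValueError("provide either calls or counts")
        te = sum(1 for c in calls if c.te_derived)
        dup = sum(1 for c in calls if c.dup_derived)
        both = sum(1 for c in calls if c.te_derived and c.dup_derived)
    else:
        te, dup, both = counts
    if both > min(te, dup):
        raise ValueError("BOTH count cannot exceed either single-mechanism count")
    union = te + dup - both
    if group_total < union:
        raise ValueError(f"group total {group_total} smaller than mechanism union {union}")
    rows = [
        ("Exaptation from TEs", te),
        ("Gene duplication", dup),
        ("Exaptation from TEs and gene duplication", both),
        ("Total", union),
    ]
    return pd.DataFrame(
        [
            {"mechanism": name, "count": n, "pct": round_half_up_pct(n, group_total)}
            for name, n in rows
        ]
    )


def origin_table_by_group(
    genes: Sequence[GeneModel],
    labels: pd.DataFrame,
    te_track: AnnotationTrack,
    paralog_track: AnnotationTrack,
    containment_threshold: float = 1.0,
    groups: Sequence[str] = ("SSG", "GSG"),
) -> tuple[pd.DataFrame, list[OriginCall]]:
    """Per-group mechanism table over the LSG groups, plus per-gene calls."""
    label_of = dict(zip(labels["gene_id"], labels["label"]))
    calls = [
        call_origin(g, te_track, paralog_track, containment_threshold)
        for g in genes
        if label_of.get(g.gene_id) in groups
    ]
    frames = []
    for group in groups:
        members = {g.gene_id for g in genes if label_of.get(g.gene_id) == group}
        sub = [c for c in calls if c.gene_id in members]
        tab = tabulate_origins(sub, group_total=len(members)) if members else pd.DataFrame()
        if not tab.empty:
            tab.insert(0, "group", group)
            frames.append(tab)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, calls
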