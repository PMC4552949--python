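"""Per-gene structural features and cross-group statistics.

Gene length is the genomic span of the gene (not the spliced length) and GC
content is computed on that full span including introns, in percent; both
choices are configurable. Group summaries report mean ± SE per metric
(sample SD with the n−1 denominator over sqrt(n)) together with the share of
genes with transcript support, and a one-way ANOVA tests each metric across
the SSG/GSG/EC groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LABELS
from .models import GeneModel, ProteinRecord

FEATURE_METRICS = ("gene_length_nt", "protein_length_aa", "exon_count", "gc_content_pct")


@dataclass(frozen=True)
class GeneFeatures:
    gene_id: str
    gene_length_nt: int
    protein_length_aa: int
    exon_count: int
    gc_content_pct: float


def gene_features(
    model: GeneModel,
    genome: Mapping[str, str],
    protein: ProteinRecord,
    gc_on_span: bool = True,
) -> GeneFeatures:
    """Length, exon count and GC% for one gene.

    ``gc_on_span=False`` restricts the GC computation to the spliced exons.
    """
    if model.chrom not in genome:
        raise KeyError(f"gene {model.gene_id!r}: chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom]
    start, end = model.cds_span
    if end > len(chrom_seq):
        raise ValueError(
            f"gene {model.gene_id!r}: exon beyond end of {model.chrom} "
            f"({end} > {len(chrom_seq)})"
        )
    if gc_on_span:
        region = chrom_seq[start:end]
    else:
        region = "".join(chrom_seq[s:e] for s, e in model.exons)
    region = region.upper()
    gc = region.count("G") + region.count("C")
    return GeneFeatures(
        gene_id=model.gene_id,
        gene_length_nt=end - start,
        protein_length_aa=protein.length_aa,
        exon_count=model.exon_count,
        gc_content_pct=100.0 * gc / len(region),
    )


def features_table(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    proteins: Mapping[str, ProteinRecord],
    gc_on_span: bool = True,
) -> pd.DataFrame:
    rows = []
    for m in models:
        prot = proteins[m.protein_ids[0]]
        f = gene_features(m, genome, prot, gc_on_span=gc_on_span)
        rows.append(vars(f))
    return pd.DataFrame(rows)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """F and p for k >= 2 groups of >= 2 observations each.

    F = (between-group SS / (k−1)) / (within-group SS / (N−k)); when every
    observation is identical the statistic is defined as 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def group_summary(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    est_supported: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Mean ± SE of every metric per LSG group, plus transcript support %.

    ``features`` carries one row per gene_id; ``labels`` maps gene_id to
    SSG/GSG/EC. Returns one row per group present, metric mean/SE columns,
    n, and transcript_support_pct (NaN when no support flags are given).
    """
    merged = features.merge(labels[["gene_id", "label"]], on="gene_id", how="inner")
    rows = []
    for label in LABELS:
        sub = merged[merged["label"] == label]
        if sub.empty:
            continue
        row: dict[str, object] = {"group": label, "n": len(sub)}
        for metric in FEATURE_METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
        if est_supported is not None:
            flags = [bool(est_supported.get(g, False)) for g in sub["gene_id"]]
            row["transcript_support_pct"] = 100.0 * sum(flags) / len(flags)
        else:
            row["transcript_support_pct"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def anova_by_metric(features: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of each structural metric across the label groups."""
    merged = features.merge(labels[["gene_id", "label"]], on="gene_id", how="inner")
    rows = []
    for metric in FEATURE_METRICS:
        groups = [
            merged.loc[merged["label"] == lab, metric].to_numpy(dtype=float)
            for lab in LABELS
            if (merged["label"] == lab).sum() >= 2
        ]
        if len(groups) < 2:
            continue
        f, p = one_way_anova(groups)
        rows.append({"metric": metric, "F": f, "p": p})
    return pd.DataFrame(rows)
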