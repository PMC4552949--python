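"""Hierarchical lineage-specificity screen: SSG / GSG / EC.

Every focal-species protein is searched against ordered clade panels
(congeners, other nematodes, invertebrates, vertebrates, and an outgroup
protein set standing in for UniProtKB). The label is defined by which
panels contain hits, so the screen is logically order-independent; panels
are nevertheless searched outermost-first with short-circuiting, because a
single hit in any non-genus panel already settles the gene as EC.

- no hit in any panel outside the focal species      -> SSG
- hits only inside the congener (same-genus) panels  -> GSG
- a hit in at least one non-genus panel              -> EC

When a gene has several isoforms the call is made at the gene level and is
conservative for specificity: the gene is EC if ANY isoform has a non-genus
hit, and SSG only if ALL isoforms are hit-free everywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import DEFAULT_EVALUE_CUTOFF, HitProvider, InternalAligner
from .models import ProteinRecord

logger = logging.getLogger(__name__)

SSG, GSG, EC = "SSG", "GSG", "EC"
LABELS = (SSG, GSG, EC)

CONGENER_PANEL = "congeners"
NON_GENUS_PANELS = ("other_nematodes", "invertebrates", "vertebrates", "outgroup_proteins")
PANEL_NAMES = (CONGENER_PANEL,) + NON_GENUS_PANELS


@dataclass(frozen=True)
class CladePanel:
    """One screening group: an ordered set of proteomes from one clade.

    ``rank`` encodes screening order (higher = evolutionarily more distant,
    searched first). The focal species must never appear inside a panel.
    """

    name: str
    proteomes: tuple[tuple[ProteinRecord, ...], ...]
    rank: int

    def __post_init__(self) -> None:
        if self.name not in PANEL_NAMES:
            raise ValueError(f"unknown panel name {self.name!r}; options: {PANEL_NAMES}")

    @property
    def all_proteins(self) -> list[ProteinRecord]:
        return [p for proteome in self.proteomes for p in proteome]

    @property
    def is_genus(self) -> bool:
        return self.name == CONGENER_PANEL


def _check_panels(panels: Sequence[CladePanel]) -> list[CladePanel]:
    if not panels:
        raise ValueError("no clade panels configured")
    names = [p.name for p in panels]
    if CONGENER_PANEL not in names:
        raise ValueError("panel set must include the congener panel")
    if not any(n in NON_GENUS_PANELS for n in names):
        raise ValueError("panel set must include at least one non-genus panel")
    return sorted(panels, key=lambda p: -p.rank)


def classify_gene(
    protein: ProteinRecord,
    panels: Sequence[CladePanel],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    provider: HitProvider | None = None,
) -> str:
    """Label a single protein as SSG, GSG or EC."""
    provider = provider or InternalAligner()
    congener_hit = False
    for panel in _check_panels(panels):
        if provider.has_hit(protein, panel.all_proteins, cutoff):
            if not panel.is_genus:
                return EC
            congener_hit = True
    return GSG if congener_hit else SSG


def classify_proteome(
    proteins: Sequence[ProteinRecord],
    panels: Sequence[CladePanel],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    provider: HitProvider | None = None,
    collect_evalues: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every protein; returns (label table, summary counts).

    The counts partition the proteome: |SSG| + |GSG| + |EC| = total.
    With ``collect_evalues`` the table gains one best-E column per panel
    (short-circuiting is disabled so every panel is searched).
    """
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")
    provider = provider or InternalAligner()
    ordered = _check_panels(panels)
    rows = []
    for protein in proteins:
        if collect_evalues:
            evals = {
                p.name: provider.best_evalue(protein, p.all_proteins, cutoff)
                for p in ordered
            }
            hit = {name: (e is not None and e <= cutoff) for name, e in evals.items()}
            if any(hit[p.name] for p in ordered if not p.is_genus):
                label = EC
            elif any(hit[p.name] for p in ordered if p.is_genus):
                label = GSG
            else:
                label = SSG
            row = {"protein_id": protein.id, "label": label}
            row.update({f"best_evalue_{n}": e for n, e in evals.items()})
        else:
            label = classify_gene(protein, ordered, cutoff, provider)
            row = {"protein_id": protein.id, "label": label}
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = {lab: 0 for lab in LABELS}
    if len(table):
        counts.update(table["label"].value_counts().to_dict())
    logger.info("classified %d proteins: %s", len(proteins), counts)
    return table, counts


def collapse_isoforms(
    label_table: pd.DataFrame, gene_to_proteins: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Gene-level labels from protein-level ones (EC dominates, then GSG)."""
    by_protein = dict(zip(label_table["protein_id"], label_table["label"]))
    rank = {EC: 2, GSG: 1, SSG: 0}
    rows = []
    for gene_id, prot_ids in gene_to_proteins.items():
        labs = [by_protein[p] for p in prot_ids if p in by_protein]
        if not labs:
            raise KeyError(f"gene {gene_id!r}: none of its proteins were classified")
        rows.append({"gene_id": gene_id, "label": max(labs, key=rank.__getitem__)})
    return pd.DataFrame(rows)
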