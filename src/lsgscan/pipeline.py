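"""End-to-end orchestration with config, logging and deterministic outputs.

Every numeric threshold of the analysis lives in :class:`PipelineConfig`,
one auditable place with the published defaults. A run writes labels.tsv,
table1.tsv, table2.tsv, origin_calls.tsv, retrogenes.tsv, retro_loci.bed,
chimeras.tsv, expression.tsv, proportions.tsv, ttests.tsv and a manifest
with the config hash and seed; identical inputs and config give identical
outputs. Reruns into the same directory resume from cached stage outputs
when (and only when) the config hash and seed match.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .characterize import anova_by_metric, features_table, group_summary
from .classify import CladePanel, classify_proteome, collapse_isoforms
from .expression import (
    StageLibrary, est_expressed, expression_matrix, filter_mappings,
    mappings_from_table, resolve_ambiguous, stage_proportions, two_sample_ttest,
)
from .homology import HitTableProvider, InternalAligner
from .models import ProteinRecord
from .origins import AnnotationTrack, origin_table_by_group
from .retrogenes import RetrogeneCall, call_chimeras, call_retrogenes
from .synthetic_data import SyntheticWorldConfig, generate_world

logger = logging.getLogger(__name__)

PANEL_RANKS = {
    "congeners": 1, "other_nematodes": 2, "invertebrates": 3,
    "vertebrates": 4, "outgroup_proteins": 5,
}


@dataclass
class PipelineConfig:
    """All tunable thresholds, at their published defaults."""

    homology_evalue: float = 1e-5
    translated_evalue: float = 1e-3
    length_class_bounds: tuple[int, int] = (30, 70)
    merge_gap_bp: int = 40
    min_merged_identity: float = 0.30
    min_merged_aa: int = 50
    spliced_min_score: float = 35.0
    min_introns: int = 2
    min_parent_coverage: float = 0.40
    chimera_min_overlap_bp: int = 50
    chimera_fp_overlap_bp: int = 90
    flank_bp: int = 10_000
    mapping_min_length: int = 150
    mapping_min_identity: float = 98.0
    mapping_min_cov_mapping: float = 97.0
    mapping_min_cov_whole: float = 75.0
    ambiguity_rel_tol: float = 0.02
    est_min_overlap_bp: int = 100
    rpkm_threshold: float = 0.0
    containment_threshold: float = 1.0
    intron_penalty: float = 50.0
    min_intron_len: int = 30
    gc_on_span: bool = True
    read_overlap_mode: str = "any"

    def validate(self) -> None:
        if not (0 < self.containment_threshold <= 1.0):
            raise ValueError("containment threshold must be in (0, 1]")
        if self.homology_evalue <= 0 or self.translated_evalue <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if not (0 < self.length_class_bounds[0] <= self.length_class_bounds[1]):
            raise ValueError("bad length-class bounds")
        if self.read_overlap_mode not in ("any", "unique"):
            raise ValueError("read_overlap_mode must be 'any' or 'unique'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_class_bounds"] = list(d["length_class_bounds"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "length_class_bounds" in data:
            data = dict(data, length_class_bounds=tuple(data["length_class_bounds"]))
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineInputs:
    proteome: Path
    panels_yaml: Path
    genome_fasta: Path
    gff3: Path
    te_bed: Path
    paralog_bed: Path
    mapping_table: Path
    read_tables: dict[str, Path]
    hit_table: Path | None = None
    external_mapping_table: Path | None = None

    def check(self) -> None:
        for name in ("proteome", "panels_yaml", "genome_fasta", "gff3",
                     "te_bed", "paralog_bed", "mapping_table"):
            lio.require_file(getattr(self, name), name.replace("_", " "))
        for stage, path in self.read_tables.items():
            lio.require_file(path, f"read table for stage {stage!r}")


def inputs_from_world_dir(world_dir: str | Path) -> PipelineInputs:
    """Standard file layout written by the synthetic generator."""
    root = Path(world_dir)
    read_tables = {}
    for p in sorted((root / "reads").glob("reads_*.tsv")):
        stage = p.stem[len("reads_"):].replace("_", " ")
        read_tables[stage] = p
    return PipelineInputs(
        proteome=root / "proteome.fasta",
        panels_yaml=root / "panels.yaml",
        genome_fasta=root / "genome.fasta",
        gff3=root / "genes.gff3",
        te_bed=root / "te.bed",
        paralog_bed=root / "paralogs.bed",
        mapping_table=root / "mappings.tsv",
        read_tables=read_tables,
    )


def load_panels(panels_yaml: str | Path) -> list[CladePanel]:
    """Build clade panels from a YAML mapping of panel name to FASTA paths.

    Entries tagged with the focal species (id prefix ``<focal>|``) are
    excluded — the outgroup protein set may legitimately contain them.
    """
    path = lio.require_file(panels_yaml, "panels config")
    spec = yaml.safe_load(path.read_text())
    focal = spec.get("focal_species", "")
    panels = []
    for name, files in spec["panels"].items():
        if name not in PANEL_RANKS:
            raise ValueError(f"unknown panel name {name!r} in {path}")
        proteomes = []
        for f in files:
            fpath = Path(f) if Path(f).is_absolute() else path.parent / f
            records = tuple(
                p for p in lio.read_proteome(fpath, species_id=name)
                if not (focal and p.id.startswith(focal + "|"))
            )
            proteomes.append(records)
        panels.append(
            CladePanel(name=name, proteomes=tuple(proteomes), rank=PANEL_RANKS[name])
        )
    return panels


def run_pipeline(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    inputs: PipelineInputs | None = None,
    synthetic_seed: int | None = None,
    world_config: SyntheticWorldConfig | None = None,
) -> dict:
    """Run every stage; returns a dict of result DataFrames and call lists."""
    config = config or PipelineConfig()
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    seed = synthetic_seed
    if inputs is None:
        if synthetic_seed is None and world_config is None:
            raise ValueError("provide input paths or request a synthetic world")
        wc = world_config or SyntheticWorldConfig()
        if synthetic_seed is not None:
            wc = dataclasses.replace(wc, seed=synthetic_seed)
        seed = wc.seed
        generate_world(wc, out / "world")
        inputs = inputs_from_world_dir(out / "world")
    inputs.check()

    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    resume_ok = False
    if manifest_path.is_file():
        try:
            old = json.loads(manifest_path.read_text())
            resume_ok = old.get("config_hash") == chash and old.get("seed") == seed
        except (json.JSONDecodeError, OSError):
            resume_ok = False

    def cached(path: Path) -> bool:
        return resume_ok and path.is_file()

    genome = lio.read_fasta(inputs.genome_fasta)
    genes = lio.read_gene_models(inputs.gff3)
    proteins = {
        p.id: p for p in lio.read_proteome(inputs.proteome, species_id="focal")
    }
    logger.info("loaded %d genes, %d proteins, %d contigs",
                len(genes), len(proteins), len(genome))

    # ---- classification --------------------------------------------------
    labels_path = out / "labels.tsv"
    if cached(labels_path):
        gene_labels = pd.read_csv(labels_path, sep="\t")
        logger.info("classification: resumed from %s", labels_path)
    else:
        panels = load_panels(inputs.panels_yaml)
        provider = (
            HitTableProvider(lio.require_file(inputs.hit_table, "hit table"))
            if inputs.hit_table
            else InternalAligner(config.length_class_bounds)
        )
        prot_list = [proteins[pid] for pid in sorted(proteins)]
        prot_table, counts = classify_proteome(
            prot_list, panels, cutoff=config.homology_evalue,
            provider=provider, collect_evalues=True,
        )
        gene_labels = collapse_isoforms(
            prot_table, {g.gene_id: g.protein_ids for g in genes}
        )
        evalue_cols = [c for c in prot_table.columns if c.startswith("best_evalue_")]
        first_protein = {g.gene_id: g.protein_ids[0] for g in genes}
        ev = prot_table.set_index("protein_id")[evalue_cols]
        for col in evalue_cols:
            gene_labels[col] = [
                ev.at[first_protein[g], col] for g in gene_labels["gene_id"]
            ]
        gene_labels.to_csv(labels_path, sep="\t", index=False)
        logger.info("classification: %s", counts)

    # ---- retrogene / chimera screen -------------------------------------
    retro_path = out / "retrogenes.tsv"
    chim_path = out / "chimeras.tsv"
    if cached(retro_path) and cached(chim_path):
        rdf = pd.read_csv(retro_path, sep="\t")
        retro_calls = [
            RetrogeneCall(
                chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                strand=str(r.strand), parent_gene_id=str(r.parent_gene_id),
                spliced_align_score=float(r.spliced_align_score),
                parent_introns_in_match=int(r.parent_introns_in_match),
                parent_alignment_coverage=float(r.parent_alignment_coverage),
                similarity=float(r.similarity), flank_bp=int(r.flank_bp),
            )
            for r in rdf.itertuples()
        ]
        chimera_df = pd.read_csv(chim_path, sep="\t")
        logger.info("retrogene screen: resumed (%d calls)", len(retro_calls))
    else:
        retro_calls = call_retrogenes(
            list(proteins.values()), genes, genome,
            evalue_cutoff=config.translated_evalue,
            merge_gap=config.merge_gap_bp,
            min_merged_identity=config.min_merged_identity,
            min_merged_aa=config.min_merged_aa,
            min_score=config.spliced_min_score,
            min_introns=config.min_introns,
            min_coverage=config.min_parent_coverage,
            flank_bp=config.flank_bp,
            min_intron_len=config.min_intron_len,
            intron_penalty=config.intron_penalty,
        )
        pd.DataFrame([dataclasses.asdict(c) for c in retro_calls]).to_csv(
            retro_path, sep="\t", index=False
        )
        lio.write_bed(
            out / "retro_loci.bed",
            [(c.chrom, c.start, c.end, f"retro_{c.parent_gene_id}")
             for c in retro_calls],
        )
        chimeras = call_chimeras(
            retro_calls, genes,
            min_overlap_bp=config.chimera_min_overlap_bp,
            fp_overlap_bp=config.chimera_fp_overlap_bp,
        )
        chimera_df = pd.DataFrame([dataclasses.asdict(c) for c in chimeras])
        chimera_df.to_csv(chim_path, sep="\t", index=False)

    # ---- origins ---------------------------------------------------------
    table2_path = out / "table2.tsv"
    calls_path = out / "origin_calls.tsv"
    if cached(table2_path) and cached(calls_path):
        table2 = pd.read_csv(table2_path, sep="\t")
        origin_calls_df = pd.read_csv(calls_path, sep="\t")
    else:
        te_track = AnnotationTrack.from_bed("TE", lio.read_bed(inputs.te_bed))
        par_track = AnnotationTrack.from_bed(
            "paralog", lio.read_bed(inputs.paralog_bed)
        )
        table2, origin_calls = origin_table_by_group(
            genes, gene_labels, te_track, par_track,
            containment_threshold=config.containment_threshold,
        )
        origin_calls_df = pd.DataFrame(
            [
                dict(gene_id=c.gene_id, te_derived=c.te_derived,
                     dup_derived=c.dup_derived, category=c.category,
                     te_fraction=c.te_fraction, dup_fraction=c.dup_fraction)
                for c in origin_calls
            ]
        )
        table2.to_csv(table2_path, sep="\t", index=False)
        origin_calls_df.to_csv(calls_path, sep="\t", index=False)

    # ---- expression ------------------------------------------------------
    expr_path = out / "expression.tsv"
    prop_path = out / "proportions.tsv"
    est_path = out / "est_support.tsv"
    if cached(expr_path) and cached(prop_path) and cached(est_path):
        expr = pd.read_csv(expr_path, sep="\t")
        proportions = pd.read_csv(prop_path, sep="\t")
        est_df = pd.read_csv(est_path, sep="\t")
        est_flags = dict(zip(est_df["gene_id"], est_df["est_supported"]))
    else:
        mapping_src = inputs.external_mapping_table or inputs.mapping_table
        mappings = mappings_from_table(lio.read_mapping_table(mapping_src))
        passing = filter_mappings(
            mappings,
            min_length=config.mapping_min_length,
            min_identity=config.mapping_min_identity,
            min_cov_mapping=config.mapping_min_cov_mapping,
            min_cov_whole=config.mapping_min_cov_whole,
        )
        retained = resolve_ambiguous(passing, rel_tol=config.ambiguity_rel_tol)
        est_flags = {
            g.gene_id: est_expressed(g, retained, config.est_min_overlap_bp)
            for g in genes
        }
        est_df = pd.DataFrame(
            [{"gene_id": g, "est_supported": v} for g, v in sorted(est_flags.items())]
        )
        est_df.to_csv(est_path, sep="\t", index=False)
        libraries = [
            StageLibrary.from_table(lio.read_read_table(path), stage_name=stage)
            for stage, path in inputs.read_tables.items()
        ]
        expr = expression_matrix(genes, libraries, mode=config.read_overlap_mode)
        expr.to_csv(expr_path, sep="\t", index=False)
        proportions = stage_proportions(
            gene_labels, expr, rpkm_threshold=config.rpkm_threshold
        )
        proportions.to_csv(prop_path, sep="\t", index=False)

    # pairwise group comparison of per-gene mean RPKM
    ttest_path = out / "ttests.tsv"
    if not cached(ttest_path):
        label_of = dict(zip(gene_labels["gene_id"], gene_labels["label"]))
        mean_rpkm = expr.groupby("gene_id")["rpkm"].mean()
        by_group = {
            lab: [mean_rpkm[g] for g in mean_rpkm.index if label_of.get(g) == lab]
            for lab in ("SSG", "GSG", "EC")
        }
        rows = []
        for a, b in itertools.combinations(("SSG", "GSG", "EC"), 2):
            if len(by_group[a]) >= 2 and len(by_group[b]) >= 2:
                t, p = two_sample_ttest(by_group[a], by_group[b])
                rows.append({"group_a": a, "group_b": b, "t": t, "p": p})
        pd.DataFrame(rows).to_csv(ttest_path, sep="\t", index=False)

    # ---- characterization ------------------------------------------------
    table1_path = out / "table1.tsv"
    anova_path = out / "anova.tsv"
    if cached(table1_path) and cached(anova_path):
        table1 = pd.read_csv(table1_path, sep="\t")
        anova = pd.read_csv(anova_path, sep="\t")
    else:
        prot_of = {
            g.gene_id: proteins[g.protein_ids[0]] for g in genes
        }
        feats = features_table(
            genes, genome, {g.protein_ids[0]: prot_of[g.gene_id] for g in genes},
            gc_on_span=config.gc_on_span,
        )
        table1 = group_summary(feats, gene_labels, est_supported=est_flags)
        anova = anova_by_metric(feats, gene_labels)
        table1.to_csv(table1_path, sep="\t", index=False)
        anova.to_csv(anova_path, sep="\t", index=False)

    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": config.to_dict(),
        "n_genes": len(genes),
        "n_proteins": len(proteins),
        "label_counts": gene_labels["label"].value_counts().to_dict(),
        "n_retrogene_calls": len(retro_calls),
        "n_chimera_calls": int(len(chimera_df)),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "labels": gene_labels,
        "table1": table1,
        "anova": anova,
        "table2": table2,
        "origin_calls": origin_calls_df,
        "retrogenes": retro_calls,
        "chimeras": chimera_df,
        "expression": expr,
        "proportions": proportions,
        "est_support": est_flags,
        "manifest": manifest,
        "outdir": out,
    }
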