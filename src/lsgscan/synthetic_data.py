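"""Miniature multi-species world generator with planted ground truth.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — clade-stratified homology, intron/exon gene
architecture, TE insertions, duplicate pairs, intronless retrocopies of
multi-exon parents, chimeric insertions, EST support and stage-varying read
coverage — on a single desk-scale contig, so that every downstream
classifier can be checked against known labels.

Planted structure, by downstream stage:

* classification: EC genes get mutated homologs in every clade panel (and
  the outgroup set), GSG genes only in congener panels, SSG genes nowhere
  outside the focal species. Per-clade amino-acid substitution rates are
  non-decreasing with clade distance so homology decays with divergence.
* origins: designated genes are fully contained in planted TE and/or
  paralog intervals; background TEs live strictly in intergenic gaps so no
  gene is covered by accident. Duplication-flagged genes are also sequence
  near-copies of a same-class sibling.
* retrogenes: intronless copies of multi-exon SSG parents (optionally
  diverged at the amino-acid level) placed elsewhere on the contig and
  annotated as single-exon genes; chimeric constructs place an unannotated
  retrocopy whose tail is shared, in frame, with a planted single-exon
  gene's CDS (overlap configurable, > 50 bp).
* expression: EST support and per-stage expression are planted at exact
  per-group counts; expressed genes receive Poisson-many (>= 1) reads at
  the stage's mean, unexpressed genes receive none, so RPKM > 0 is an exact
  oracle for the planted flag.

Sequences use a uniform random codon model (no codon-usage realism, no
indels, no read errors); background DNA is AT-rich (64% AT). The same seed
yields byte-identical output files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import io as lio
from .expression import STAGES
from .models import (
    GeneModel, GroundTruth, OriginTruth, ProteinRecord, RetroLocusTruth,
    revcomp, spliced_cds,
)

FOCAL_SPECIES = "celegans_sim"
CLADES = ("congeners", "other_nematodes", "invertebrates", "vertebrates")
_CLADE_PREFIX = {"congeners": "cong", "other_nematodes": "nema",
                 "invertebrates": "inv", "vertebrates": "vert"}

_BASES = np.array(list("ACGT"))
_BG_P = np.array([0.32, 0.18, 0.18, 0.32])  # AT-rich background
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in _NONSTOP_CODONS:
    _CODONS_BY_AA.setdefault(str(Seq(_c).translate()), []).append(_c)

DEFAULT_STAGE_PROFILE: dict[str, float] = {
    "1-cell": 8.0, "2-cell": 8.0, "4-cell": 8.0, "28-cell": 8.0,
    "early embryo": 10.0, "late embryo": 10.0,
    "L1": 12.0, "L2": 12.0, "L3": 12.0, "L4": 12.0, "L4 male": 12.0,
    "young adult": 10.0, "adult hermaphrodite": 10.0, "adult male": 10.0,
}


class ConfigurationError(ValueError):
    """A world configuration that contradicts itself."""


@dataclass
class SyntheticWorldConfig:
    seed: int = 0
    n_genes_per_class: tuple[int, int, int] = (12, 12, 12)  # SSG, GSG, EC
    n_species_per_clade: tuple[int, int, int, int] = (4, 4, 4, 4)
    te_density: float = 2.0  # TEs per 10 kb
    n_retrogenes: int = 4
    n_chimeras: int = 2
    #: per-clade amino-acid substitution probability (congener .. vertebrate)
    mutation_rates: tuple[float, float, float, float] = (0.05, 0.15, 0.25, 0.35)
    stage_expression_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROFILE)
    )
    gene_length_range: tuple[int, int] = (300, 900)  # spliced CDS, nt (SSG base)
    exon_count_range: tuple[int, int] = (1, 3)  # SSG base
    #: per-class scaling (SSG, GSG, EC): conserved genes are planted longer
    #: and more exonic than genus-specific ones than species-specific ones,
    #: echoing the structure observed in real lineage-specificity data
    class_size_factor: tuple[float, float, float] = (1.0, 1.7, 3.0)
    class_extra_exons: tuple[int, int, int] = (0, 1, 3)
    genome_size: int = 500_000
    intron_length_range: tuple[int, int] = (80, 400)
    intergenic_gap_range: tuple[int, int] = (200, 1200)
    #: planted expressed / EST-support prevalence per group (SSG, GSG, EC)
    expressed_prevalence: tuple[float, float, float] = (0.3204, 0.5869, 0.8097)
    est_support_prevalence: tuple[float, float, float] = (0.3204, 0.5869, 0.8097)
    n_te_origin: int = 3
    n_dup_origin: int = 3
    n_both_origin: int = 2
    retro_aa_divergence: float = 0.05
    dup_aa_divergence: float = 0.02
    chimera_overlap_bp: int = 75
    chimera_novel_bp: int = 225
    decoys_per_species: int = 5
    n_outgroup_decoys: int = 10
    read_length: int = 75
    include_decoy_transcripts: bool = True

    def validate(self) -> None:
        n_ssg, n_gsg, n_ec = self.n_genes_per_class
        if min(n_ssg, n_gsg, n_ec) < 0 or min(self.n_species_per_clade) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_retrogenes < 0 or self.n_chimeras < 0 or self.te_density < 0:
            raise ConfigurationError("counts must be non-negative")
        rates = self.mutation_rates
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ConfigurationError("mutation rates must lie in [0, 1]")
        if any(a > b for a, b in zip(rates, rates[1:])):
            raise ConfigurationError(
                "mutation rates must not decrease with clade distance"
            )
        needed_parents = self.n_retrogenes + self.n_chimeras
        if needed_parents > 0 and self.exon_count_range[1] < 3:
            raise ConfigurationError(
                "retrogenes/chimeras need parents with >= 3 exons but the exon "
                "count range excludes them"
            )
        if needed_parents > n_ssg:
            raise ConfigurationError(
                f"{needed_parents} retrogenes+chimeras requested but only "
                f"{n_ssg} SSG genes available as multi-exon parents"
            )
        for n in (self.n_te_origin, self.n_dup_origin, self.n_both_origin):
            if n < 0:
                raise ConfigurationError("origin counts must be non-negative")
        for label, count in (("SSG", n_ssg), ("GSG", n_gsg)):
            if self.n_te_origin + self.n_dup_origin + self.n_both_origin > count > 0:
                raise ConfigurationError(
                    f"origin-flagged gene count exceeds the {label} class size"
                )
        if self.chimera_overlap_bp % 3 or not (50 < self.chimera_overlap_bp):
            raise ConfigurationError(
                "chimera overlap must be a codon-aligned amount above 50 bp"
            )
        if not (0 < self.gene_length_range[0] <= self.gene_length_range[1]):
            raise ConfigurationError("bad gene length range")
        if not (1 <= self.exon_count_range[0] <= self.exon_count_range[1]):
            raise ConfigurationError("bad exon count range")
        if any(f <= 0 for f in self.class_size_factor) or any(
            e < 0 for e in self.class_extra_exons
        ):
            raise ConfigurationError("bad per-class size scaling")
        unknown = set(self.stage_expression_profile) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages in expression profile: {unknown}")


@dataclass
class SyntheticWorld:
    root: Path
    config: SyntheticWorldConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, ProteinRecord]
    truth: GroundTruth
    genome_fasta: Path
    gff3: Path
    proteome_fasta: Path
    panels_yaml: Path
    te_bed: Path
    paralog_bed: Path
    transcripts_fasta: Path
    mapping_table: Path
    read_tables: dict[str, Path]


# ------------------------------------------------------------ helpers

def _background(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.choice(4, size=n, p=_BG_P)])


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return [_NONSTOP_CODONS[i] for i in idx]


def _translate_codons(codons: list[str]) -> str:
    return str(Seq("".join(codons)).translate())


def mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Uniform random amino-acid replacement at the given per-site rate."""
    if rate <= 0.0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _AA20.replace(out[i], "") if out[i] in _AA20 else _AA20
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _encode(
    rng: np.random.Generator, aa: str,
    template_aa: str | None = None, template_codons: list[str] | None = None,
) -> list[str]:
    """Codons for an amino-acid sequence, reusing template codons at
    unchanged positions so nucleotide similarity tracks protein similarity."""
    codons = []
    for i, a in enumerate(aa):
        if (
            template_aa is not None
            and template_codons is not None
            and i < len(template_aa)
            and template_aa[i] == a
        ):
            codons.append(template_codons[i])
        else:
            opts = _CODONS_BY_AA[a]
            codons.append(opts[rng.integers(0, len(opts))])
    return codons


def _split_codons(rng: np.random.Generator, n_codons: int, k: int) -> list[int]:
    """Split n_codons into k exon lengths (in codons), each >= 20."""
    base = 20
    spare = n_codons - base * k
    if spare < 0:
        raise ConfigurationError(f"{n_codons} codons cannot fill {k} exons")
    extra = rng.multinomial(spare, np.full(k, 1.0 / k)) if k > 0 else []
    return [base + int(e) for e in extra]


@dataclass
class _GeneSpec:
    gene_id: str
    label: str
    strand: str
    exon_aa_lens: list[int]
    intron_lens: list[int]
    codons: list[str]
    aa: str
    origin: OriginTruth = field(default_factory=OriginTruth)

    @property
    def exon_nt_lens(self) -> list[int]:
        return [3 * n for n in self.exon_aa_lens]


def plant_retrogene(
    parent: GeneModel,
    genome: Mapping[str, str],
    mutation_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    spacer_bp: int = 200,
) -> tuple[tuple[str, int, int], dict[str, str]]:
    """Append an intronless copy of the parent's spliced CDS to its contig.

    The parent must have at least three exons so that any substantial match
    to the retrocopy spans at least two parental introns. With mutation
    rate 0 the inserted sequence is the spliced CDS verbatim; otherwise the
    copy is diverged at the amino-acid level and re-encoded.
    Returns the retro-locus interval and the updated genome.
    """
    if parent.exon_count < 3:
        raise ValueError(
            f"retrogene parent {parent.gene_id!r} needs >= 3 exons, "
            f"has {parent.exon_count}"
        )
    rng = rng or np.random.default_rng(0)
    cds = spliced_cds(parent, genome)
    if mutation_rate > 0.0:
        codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        aa = _translate_codons(codons)
        mutated = mutate_protein(rng, aa, mutation_rate)
        cds = "".join(_encode(rng, mutated, aa, codons))
    chrom_seq = genome[parent.chrom]
    start = len(chrom_seq) + spacer_bp
    new_genome = dict(genome)
    new_genome[parent.chrom] = chrom_seq + _background(rng, spacer_bp) + cds
    return (parent.chrom, start, start + len(cds)), new_genome


# ------------------------------------------------------------ generator

def _exact_count(prevalence: float, n: int) -> int:
    return int(prevalence * n + 0.5)


def generate_world(config: SyntheticWorldConfig, outdir: str | Path) -> SyntheticWorld:
    """Generate the full planted world and write every input file the
    pipeline consumes. Deterministic under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)

    n_ssg, n_gsg, n_ec = config.n_genes_per_class
    needed_parents = config.n_retrogenes + config.n_chimeras
    lo_len, hi_len = config.gene_length_range
    lo_k, hi_k = config.exon_count_range

    # --- class gene specs ------------------------------------------------
    specs: dict[str, _GeneSpec] = {}
    class_ids: dict[str, list[str]] = {"SSG": [], "GSG": [], "EC": []}
    for li, (label, count) in enumerate(
        (("SSG", n_ssg), ("GSG", n_gsg), ("EC", n_ec))
    ):
        factor = config.class_size_factor[li]
        lo_len_c, hi_len_c = int(lo_len * factor), int(hi_len * factor)
        lo_k_c = lo_k + config.class_extra_exons[li]
        hi_k_c = hi_k + config.class_extra_exons[li]
        for i in range(count):
            gid = f"{label.lower()}_{i:03d}"
            is_parent = label == "SSG" and i < needed_parents
            k = int(rng.integers(max(3, lo_k_c), max(3, hi_k_c) + 1)) if is_parent \
                else int(rng.integers(lo_k_c, hi_k_c + 1))
            n_codons = max(int(rng.integers(lo_len_c, hi_len_c + 1)) // 3, 20 * k, 60)
            exon_aa = _split_codons(rng, n_codons, k)
            introns = [
                int(rng.integers(*config.intron_length_range)) for _ in range(k - 1)
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            codons = _random_codons(rng, n_codons)
            specs[gid] = _GeneSpec(
                gene_id=gid, label=label, strand=strand,
                exon_aa_lens=exon_aa, intron_lens=introns,
                codons=codons, aa=_translate_codons(codons),
            )
            class_ids[label].append(gid)

    parents = class_ids["SSG"][:needed_parents]

    # --- origin flags (TE / duplication), SSG and GSG classes -----------
    for label in ("SSG", "GSG"):
        pool = [g for g in class_ids[label] if g not in parents]
        if not pool:
            continue
        perm = [pool[i] for i in rng.permutation(len(pool))]
        n_dup = min(config.n_dup_origin, len(perm))
        n_both = min(config.n_both_origin, max(0, len(perm) - n_dup))
        dup_ids = perm[:n_dup]
        both_ids = perm[n_dup : n_dup + n_both]
        rest = perm[n_dup + n_both :] + [g for g in class_ids[label] if g in parents]
        te_ids = rest[: config.n_te_origin]
        for gid in te_ids:
            specs[gid].origin.te_derived = True
        for gid in dup_ids + both_ids:
            specs[gid].origin.dup_derived = True
        for gid in both_ids:
            specs[gid].origin.te_derived = True
        # duplication-flagged genes become sequence near-copies of a sibling
        donors = [
            g for g in class_ids[label]
            if g not in dup_ids and g not in both_ids and g not in parents
        ]
        for gid in dup_ids + both_ids:
            if not donors:
                break
            donor = specs[donors[int(rng.integers(0, len(donors)))]]
            spec = specs[gid]
            aa = mutate_protein(rng, donor.aa, config.dup_aa_divergence)
            # DNA-level duplicates preserve the donor's intron/exon structure;
            # an intronless copy of a multi-exon gene would be a retrogene
            spec.exon_aa_lens = list(donor.exon_aa_lens)
            spec.intron_lens = [
                int(rng.integers(*config.intron_length_range))
                for _ in range(len(donor.exon_aa_lens) - 1)
            ]
            spec.codons = _encode(rng, aa, donor.aa, donor.codons)
            spec.aa = aa

    # --- retrogene and chimera constructs --------------------------------
    retro_specs: list[_GeneSpec] = []
    retro_parent: dict[str, str] = {}
    for i in range(config.n_retrogenes):
        parent = specs[parents[i]]
        aa = mutate_protein(rng, parent.aa, config.retro_aa_divergence)
        gid = f"retro_{i:02d}"
        retro_specs.append(
            _GeneSpec(
                gene_id=gid, label="SSG", strand="+",
                exon_aa_lens=[len(aa)], intron_lens=[],
                codons=_encode(rng, aa, parent.aa, parent.codons), aa=aa,
                origin=OriginTruth(retro_derived=True, parent_id=parent.gene_id),
            )
        )
        retro_parent[gid] = parent.gene_id

    chimera_constructs: list[tuple[_GeneSpec, list[str], str]] = []
    ov_codons = config.chimera_overlap_bp // 3
    novel_codons_n = config.chimera_novel_bp // 3
    for j in range(config.n_chimeras):
        parent = specs[parents[config.n_retrogenes + j]]
        retro_aa = mutate_protein(rng, parent.aa, config.retro_aa_divergence)
        retro_codons = _encode(rng, retro_aa, parent.aa, parent.codons)
        novel = _random_codons(rng, novel_codons_n)
        chim_codons = retro_codons[-ov_codons:] + novel
        gid = f"chim_{j:02d}"
        chimera_constructs.append(
            (
                _GeneSpec(
                    gene_id=gid, label="SSG", strand="+",
                    exon_aa_lens=[len(chim_codons)], intron_lens=[],
                    codons=chim_codons, aa=_translate_codons(chim_codons),
                    origin=OriginTruth(chimeric=True, parent_id=parent.gene_id),
                ),
                retro_codons,
                parent.gene_id,
            )
        )

    # --- assemble the contig ---------------------------------------------
    blocks: list[tuple[str, object]] = (
        [("gene", s) for s in specs.values()]
        + [("gene", s) for s in retro_specs]
        + [("chimera", c) for c in chimera_constructs]
    )
    order = rng.permutation(len(blocks)) if blocks else []
    parts: list[str] = []
    pos = 0
    gaps: list[tuple[int, int]] = []
    genes: list[GeneModel] = []
    truth = GroundTruth()
    chrom = "chrI"

    def _push_gap() -> None:
        nonlocal pos
        g = int(rng.integers(*config.intergenic_gap_range))
        parts.append(_background(rng, g))
        gaps.append((pos, pos + g))
        pos += g

    def _place_gene(spec: _GeneSpec) -> GeneModel:
        nonlocal pos
        cds = "".join(spec.codons)
        exon_nt = spec.exon_nt_lens
        if spec.strand == "+":
            chunks, off = [], 0
            for ln in exon_nt:
                chunks.append(cds[off : off + ln])
                off += ln
        else:
            rc = revcomp(cds)
            genomic_lens = exon_nt[::-1]
            chunks, off = [], 0
            for ln in genomic_lens:
                chunks.append(rc[off : off + ln])
                off += ln
            exon_nt = genomic_lens
        exons = []
        start = pos
        for i, chunk in enumerate(chunks):
            exons.append((pos, pos + len(chunk)))
            parts.append(chunk)
            pos += len(chunk)
            if i < len(chunks) - 1:
                intr = spec.intron_lens[i]
                parts.append(_background(rng, intr))
                pos += intr
        model = GeneModel(
            gene_id=spec.gene_id, chrom=chrom, strand=spec.strand,
            exons=tuple(exons), protein_ids=(f"{spec.gene_id}.p1",),
        )
        del start
        return model

    for bi in order:
        kind, payload = blocks[int(bi)]
        _push_gap()
        if kind == "gene":
            spec = payload  # type: ignore[assignment]
            model = _place_gene(spec)
            genes.append(model)
            truth.labels[spec.gene_id] = spec.label
            truth.origins[spec.gene_id] = spec.origin
            if spec.origin.retro_derived:
                s, e = model.cds_span
                truth.retro_loci.append(
                    RetroLocusTruth(chrom, s, e, spec.origin.parent_id, "standalone")
                )
        else:
            spec, retro_codons, parent_id = payload  # type: ignore[misc]
            retro_seq = "".join(retro_codons)
            retro_start = pos
            parts.append(retro_seq)
            pos += len(retro_seq)
            truth.retro_loci.append(
                RetroLocusTruth(chrom, retro_start, pos, parent_id, "chimera")
            )
            # chimeric gene: in-frame tail of the retrocopy + novel sequence
            novel_seq = "".join(spec.codons[ov_codons:])
            gene_start = pos - config.chimera_overlap_bp
            parts.append(novel_seq)
            pos += len(novel_seq)
            model = GeneModel(
                gene_id=spec.gene_id, chrom=chrom, strand="+",
                exons=((gene_start, pos),), protein_ids=(f"{spec.gene_id}.p1",),
            )
            genes.append(model)
            truth.labels[spec.gene_id] = spec.label
            truth.origins[spec.gene_id] = spec.origin
    _push_gap()
    if pos < config.genome_size:
        pad = config.genome_size - pos
        parts.append(_background(rng, pad))
        gaps.append((pos, pos + pad))
        pos += pad
    genome = {chrom: "".join(parts)}
    genome_len = len(genome[chrom])

    all_specs = {s.gene_id: s for s in specs.values()}
    for s in retro_specs:
        all_specs[s.gene_id] = s
    for s, _, _ in chimera_constructs:
        all_specs[s.gene_id] = s
    proteins = {
        f"{gid}.p1": ProteinRecord(f"{gid}.p1", s.aa, FOCAL_SPECIES)
        for gid, s in all_specs.items()
    }
    gene_by_id = {g.gene_id: g for g in genes}

    # --- annotation tracks ------------------------------------------------
    te_rows: list[tuple[str, int, int, str]] = []
    par_rows: list[tuple[str, int, int, str]] = []
    for gid in sorted(truth.origins):
        o = truth.origins[gid]
        if not (o.te_derived or o.dup_derived):
            continue
        s, e = gene_by_id[gid].cds_span
        if o.te_derived:
            te_rows.append(
                (chrom, max(0, s - int(rng.integers(10, 50))),
                 min(genome_len, e + int(rng.integers(10, 50))), f"TEp_{gid}")
            )
        if o.dup_derived:
            par_rows.append(
                (chrom, max(0, s - int(rng.integers(10, 50))),
                 min(genome_len, e + int(rng.integers(10, 50))), f"PAR_{gid}")
            )
    n_bg_te = int(round(config.te_density * genome_len / 10_000))
    big_gaps = [g for g in gaps if g[1] - g[0] >= 160]
    for t in range(n_bg_te):
        if not big_gaps:
            break
        gs, ge = big_gaps[int(rng.integers(0, len(big_gaps)))]
        max_len = min(800, ge - gs - 40)
        ln = int(rng.integers(100, max(101, max_len + 1)))
        off = int(rng.integers(gs + 20, max(gs + 21, ge - ln - 20)))
        te_rows.append((chrom, off, off + ln, f"TEbg_{t:03d}"))
    te_rows.sort(key=lambda r: (r[1], r[2]))
    par_rows.sort(key=lambda r: (r[1], r[2]))

    # --- clade panels -----------------------------------------------------
    panels_dir = root / "panels"
    panels_dir.mkdir(exist_ok=True)
    visibility = {"SSG": set(), "GSG": {"congeners"}, "EC": set(CLADES)}
    panel_files: dict[str, list[Path]] = {name: [] for name in CLADES}
    for clade, n_species, rate in zip(
        CLADES, config.n_species_per_clade, config.mutation_rates
    ):
        for si in range(n_species):
            species = f"{_CLADE_PREFIX[clade]}{si + 1}"
            records: list[tuple[str, str]] = []
            for gid in sorted(class_ids["SSG"] + class_ids["GSG"] + class_ids["EC"]):
                if clade in visibility[all_specs[gid].label]:
                    records.append(
                        (f"{species}|{gid}", mutate_protein(rng, all_specs[gid].aa, rate))
                    )
            for d in range(config.decoys_per_species):
                ln = int(rng.integers(80, 401))
                records.append(
                    (f"{species}|decoy{d}",
                     "".join(_AA20[i] for i in rng.integers(0, 20, ln)))
                )
            path = panels_dir / f"{species}.fasta"
            lio.write_fasta(path, records)
            panel_files[clade].append(path)
    # outgroup protein set: EC homologs + decoys + focal-tagged entries that
    # panel loading must exclude by species tag
    out_records: list[tuple[str, str]] = []
    vert_rate = config.mutation_rates[-1]
    for gid in sorted(class_ids["EC"]):
        out_records.append(
            (f"outgroup|{gid}", mutate_protein(rng, all_specs[gid].aa, vert_rate))
        )
    for d in range(config.n_outgroup_decoys):
        ln = int(rng.integers(80, 401))
        out_records.append(
            (f"outgroup|decoy{d}", "".join(_AA20[i] for i in rng.integers(0, 20, ln)))
        )
    for gid in sorted(all_specs)[: min(5, len(all_specs))]:
        out_records.append((f"{FOCAL_SPECIES}|{gid}", all_specs[gid].aa))
    outgroup_path = panels_dir / "outgroup.fasta"
    lio.write_fasta(outgroup_path, out_records)
    panel_files["outgroup_proteins"] = [outgroup_path]

    # --- transcripts: EST support planted at exact per-group counts ------
    tr_records: list[tuple[str, str]] = []
    map_rows: list[dict] = []
    for li, label in enumerate(("SSG", "GSG", "EC")):
        members = truth.genes_with_label(label)
        k = _exact_count(config.est_support_prevalence[li], len(members))
        chosen = (
            [members[i] for i in rng.choice(len(members), size=k, replace=False)]
            if k else []
        )
        for gid in members:
            truth.est_supported[gid] = gid in chosen
        for gid in sorted(chosen):
            g = gene_by_id[gid]
            seq = spliced_cds(g, genome)
            tid = f"tr_{gid}"
            tr_records.append((tid, seq))
            s, e = g.cds_span
            map_rows.append(
                dict(
                    transcript_id=tid, chrom=chrom, strand=g.strand,
                    mapped_start=s, mapped_end=e, mapped_length=len(seq),
                    identity_pct=100.0, coverage_in_mapping_pct=100.0,
                    coverage_whole_pct=100.0, score=float(len(seq)),
                )
            )
    if config.include_decoy_transcripts:
        decoy_gaps = [g for g in gaps if g[1] - g[0] >= 460]
        def _gap_pos(length: int) -> tuple[int, int]:
            gs, ge = decoy_gaps[int(rng.integers(0, len(decoy_gaps)))]
            off = int(rng.integers(gs + 10, max(gs + 11, ge - length - 10)))
            return off, off + length
        if decoy_gaps:
            cases = [
                ("decoy_short", 120, [dict(identity_pct=100.0, coverage_whole_pct=100.0,
                                           score=120.0)]),
                ("decoy_lowid", 400, [dict(identity_pct=95.0, coverage_whole_pct=100.0,
                                           score=380.0)]),
                ("decoy_lowcov", 400, [dict(identity_pct=100.0, coverage_whole_pct=60.0,
                                            score=400.0)]),
                ("decoy_ambig", 400, [dict(identity_pct=100.0, coverage_whole_pct=100.0,
                                           score=400.0),
                                      dict(identity_pct=99.0, coverage_whole_pct=100.0,
                                           score=396.0)]),
                ("decoy_multi", 400, [dict(identity_pct=100.0, coverage_whole_pct=100.0,
                                           score=400.0),
                                      dict(identity_pct=90.0, coverage_whole_pct=100.0,
                                           score=300.0)]),
            ]
            for tid, ln, placements in cases:
                tr_records.append((tid, _background(rng, ln)))
                for extra in placements:
                    s, e = _gap_pos(ln)
                    row = dict(
                        transcript_id=tid, chrom=chrom, strand="+",
                        mapped_start=s, mapped_end=e, mapped_length=ln,
                        identity_pct=100.0, coverage_in_mapping_pct=100.0,
                        coverage_whole_pct=100.0, score=float(ln),
                    )
                    row.update(extra)
                    map_rows.append(row)

    # --- per-stage read placements ---------------------------------------
    read_tables: dict[str, Path] = {}
    reads_dir = root / "reads"
    reads_dir.mkdir(exist_ok=True)
    stage_profile = config.stage_expression_profile
    for gid in truth.labels:
        truth.expressed[gid] = {}
    for stage in STAGES:
        if stage not in stage_profile:
            continue
        lam = stage_profile[stage]
        rows = []
        for li, label in enumerate(("SSG", "GSG", "EC")):
            members = truth.genes_with_label(label)
            k = _exact_count(config.expressed_prevalence[li], len(members))
            chosen = set(
                members[i] for i in rng.choice(len(members), size=k, replace=False)
            ) if k else set()
            for gid in members:
                truth.expressed[gid][stage] = gid in chosen
            for gid in sorted(chosen):
                s, e = gene_by_id[gid].cds_span
                n_reads = max(1, int(rng.poisson(lam)))
                span = e - s
                for r in range(n_reads):
                    if span > config.read_length:
                        rs = s + int(rng.integers(0, span - config.read_length + 1))
                        re_ = rs + config.read_length
                    else:
                        rs, re_ = s, e
                    rows.append(
                        dict(read_id=f"{gid}:{r}", stage=stage, chrom=chrom,
                             start=rs, end=re_)
                    )
        slug = stage.replace(" ", "_")
        path = reads_dir / f"reads_{slug}.tsv"
        lio.write_read_table(path, pd.DataFrame(rows, columns=lio.READ_COLUMNS))
        read_tables[stage] = path

    # --- write world files ------------------------------------------------
    genome_fasta = root / "genome.fasta"
    lio.write_fasta(genome_fasta, [(chrom, genome[chrom])])
    gff3 = root / "genes.gff3"
    genes_sorted = sorted(genes, key=lambda g: g.cds_span[0])
    lio.write_gff3(gff3, genes_sorted, {chrom: genome_len})
    proteome_fasta = root / "proteome.fasta"
    lio.write_fasta(
        proteome_fasta, [(pid, proteins[pid].sequence) for pid in sorted(proteins)]
    )
    te_bed = root / "te.bed"
    lio.write_bed(te_bed, te_rows)
    paralog_bed = root / "paralogs.bed"
    lio.write_bed(paralog_bed, par_rows)
    transcripts_fasta = root / "transcripts.fasta"
    lio.write_fasta(transcripts_fasta, tr_records)
    mapping_table = root / "mappings.tsv"
    lio.write_mapping_table(
        mapping_table, pd.DataFrame(map_rows, columns=lio.MAPPING_COLUMNS)
    )
    panels_yaml = root / "panels.yaml"
    panels_yaml.write_text(
        yaml.safe_dump(
            {
                "focal_species": FOCAL_SPECIES,
                "panels": {
                    name: [str(p.relative_to(root)) for p in paths]
                    for name, paths in panel_files.items()
                },
            },
            sort_keys=True,
        )
    )
    _write_truth(root, truth)

    return SyntheticWorld(
        root=root, config=config, genome=genome, genes=genes_sorted,
        proteins=proteins, truth=truth, genome_fasta=genome_fasta, gff3=gff3,
        proteome_fasta=proteome_fasta, panels_yaml=panels_yaml, te_bed=te_bed,
        paralog_bed=paralog_bed, transcripts_fasta=transcripts_fasta,
        mapping_table=mapping_table, read_tables=read_tables,
    )


def _write_truth(root: Path, truth: GroundTruth) -> None:
    rows = []
    for gid in sorted(truth.labels):
        o = truth.origins.get(gid, OriginTruth())
        rows.append(
            dict(
                gene_id=gid, label=truth.labels[gid],
                te_derived=o.te_derived, dup_derived=o.dup_derived,
                retro_derived=o.retro_derived, chimeric=o.chimeric,
                parent_id=o.parent_id or "",
                est_supported=truth.est_supported.get(gid, False),
            )
        )
    pd.DataFrame(rows).to_csv(root / "truth_genes.tsv", sep="\t", index=False)
    expr_rows = [
        dict(gene_id=gid, stage=stage, expressed=flag)
        for gid in sorted(truth.expressed)
        for stage, flag in truth.expressed[gid].items()
    ]
    pd.DataFrame(expr_rows).to_csv(root / "truth_expression.tsv", sep="\t", index=False)
    retro_rows = [dataclasses.asdict(r) for r in truth.retro_loci]
    pd.DataFrame(retro_rows).to_csv(root / "truth_retro_loci.tsv", sep="\t", index=False)
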