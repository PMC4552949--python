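"""Retroposition screen: translated genome matching, match merging, parental
assignment, intron-content verification and chimera calling.

The screen proxies the published tool chain at desk scale:

1. Every protein is matched against a six-frame translation of the genome
   with the local aligner (TBLASTN stand-in, E <= 1e-3); internal stop
   codons truncate a frame, so translations are split into open segments.
2. Adjacent same-frame-strand matches closer than 40 bp (strict, measured
   end-to-start) are merged transitively; merged loci must keep >30% amino-
   acid identity and span >50 aa.
3. Each merged locus is searched against the multi-exon proteins (parents
   must have >= 2 introns) and the closest match becomes the candidate
   parent; ties break by similarity, then parent CDS length, then id.
4. An intron-aware spliced alignment (GENEWISE proxy) aligns the parent's
   per-exon peptide blocks to the locus with 10 kb flanks: the score is the
   sum of matched block scores minus a per-intron penalty whenever the
   genomic gap between consecutive matched blocks exceeds a minimum intron
   length (30 nt). The score scale is raw substitution-matrix units, not
   GENEWISE bits; the acceptance threshold (35) is kept on this proxy scale
   and is configurable.
5. A call is accepted when score > 35, at least two parent introns fall in
   the matched part of the parent, and the alignment covers > 40% of the
   parent; the recruited locus is then re-aligned to its parent as a
   confirmation. Loci that coincide with the query's own gene or with the
   assigned parent's gene are self-matches and are dropped.
6. An annotated gene whose CDS overlaps a retro locus by > 50 bp is called
   chimeric; overlaps > 90 bp are flagged possible false positives (flagged,
   never removed). Genes whose CDS lies entirely inside the locus are the
   retrogene annotation itself, not chimeras, and the parent is excluded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .homology import (
    ScoringScheme, _aligner, evalue, scoring_scheme, select_matrix,
)
from .models import GeneModel, ProteinRecord, revcomp

logger = logging.getLogger(__name__)

DEFAULT_TRANSLATED_EVALUE = 1e-3
DEFAULT_MERGE_GAP = 40
DEFAULT_MIN_MERGED_IDENTITY = 0.30
DEFAULT_MIN_MERGED_AA = 50
DEFAULT_SPLICED_MIN_SCORE = 35.0
DEFAULT_MIN_INTRONS = 2
DEFAULT_MIN_COVERAGE = 0.40
DEFAULT_FLANK_BP = 10_000
DEFAULT_MIN_INTRON_LEN = 30
DEFAULT_INTRON_PENALTY = 50.0
DEFAULT_CHIMERA_MIN_OVERLAP = 50
DEFAULT_CHIMERA_FP_OVERLAP = 90


# ------------------------------------------------------------ translation

@dataclass(frozen=True)
class FrameSegment:
    """A stop-free stretch of one reading frame of one strand."""

    chrom: str
    strand: str
    frame: int
    aa_start: int  # offset (aa) within the full frame translation
    aa_seq: str
    chrom_length: int

    def genomic_interval(self, aa_from: int, aa_to: int) -> tuple[int, int]:
        """Genomic nt interval of aa range [aa_from, aa_to) within this segment."""
        lo = self.frame + 3 * (self.aa_start + aa_from)
        hi = self.frame + 3 * (self.aa_start + aa_to)
        if self.strand == "+":
            return lo, hi
        return self.chrom_length - hi, self.chrom_length - lo


def six_frame_segments(
    genome: Mapping[str, str], min_len_aa: int = 15
) -> list[FrameSegment]:
    """Stop-split six-frame translation of every contig."""
    segments: list[FrameSegment] = []
    for chrom, seq in genome.items():
        length = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                usable = s[frame : frame + 3 * ((length - frame) // 3)]
                if not usable:
                    continue
                aa = str(Seq(usable).translate())
                pos = 0
                for piece in aa.split("*"):
                    if len(piece) >= min_len_aa:
                        segments.append(
                            FrameSegment(chrom, strand, frame, pos, piece, length)
                        )
                    pos += len(piece) + 1
    return segments


@dataclass(frozen=True)
class GenomicMatch:
    protein_id: str
    chrom: str
    strand: str
    start: int
    end: int
    aa_identity_frac: float
    matched_aa_length: int
    score: float
    e_value: float

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def translated_match(
    protein: ProteinRecord,
    genome: Mapping[str, str] | None = None,
    evalue_cutoff: float = DEFAULT_TRANSLATED_EVALUE,
    segments: Sequence[FrameSegment] | None = None,
    scheme: ScoringScheme | None = None,
) -> list[GenomicMatch]:
    """Protein-to-genome matches via six-frame translation + local DP."""
    if segments is None:
        if genome is None:
            raise ValueError("provide a genome or precomputed frame segments")
        segments = six_frame_segments(genome)
    if scheme is None:
        scheme = scoring_scheme(select_matrix(protein.length_aa))
    aligner = _aligner(scheme.matrix_name)
    qseq = protein.sequence.upper()
    n_db = sum(len(s.aa_seq) for s in segments)
    if n_db == 0:
        return []
    matches: list[GenomicMatch] = []
    for seg in segments:
        score = aligner.score(qseq, seg.aa_seq)
        if score <= 0:
            continue
        e = evalue(score, len(qseq), n_db, scheme)
        if e > evalue_cutoff:
            continue
        aln = aligner.align(qseq, seg.aa_seq)[0]
        counts = aln.counts()
        tblocks = aln.aligned[1]
        t_from, t_to = int(tblocks[0][0]), int(tblocks[-1][1])
        g_start, g_end = seg.genomic_interval(t_from, t_to)
        matches.append(
            GenomicMatch(
                protein_id=protein.id, chrom=seg.chrom, strand=seg.strand,
                start=g_start, end=g_end,
                aa_identity_frac=counts.identities / aln.length if aln.length else 0.0,
                matched_aa_length=t_to - t_from,
                score=float(score), e_value=e,
            )
        )
    matches.sort(key=lambda m: (m.chrom, m.strand, m.start, m.end))
    return matches


# ------------------------------------------------------------ merge + filter

def merge_adjacent(
    matches: Sequence[GenomicMatch], max_gap: int = DEFAULT_MERGE_GAP
) -> list[GenomicMatch]:
    """Transitively merge same-protein/chrom/strand matches whose genomic
    gap (end-to-start) is strictly below ``max_gap``; overlapping matches
    always merge. Merged identity is the alignment-length-weighted mean and
    the merged aa length is the merged span in codons."""
    if not matches:
        return []
    keys = {(m.protein_id, m.chrom, m.strand) for m in matches}
    if len(keys) != 1:
        raise ValueError("merge_adjacent expects matches of one protein/chrom/strand")
    ordered = sorted(matches, key=lambda m: (m.start, m.end))
    merged: list[GenomicMatch] = []
    cur = ordered[0]
    cur_weight = cur.aa_identity_frac * cur.matched_aa_length
    cur_aa = cur.matched_aa_length
    for m in ordered[1:]:
        if m.start - cur.end < max_gap:
            cur_weight += m.aa_identity_frac * m.matched_aa_length
            cur_aa += m.matched_aa_length
            cur = replace(
                cur,
                end=max(cur.end, m.end),
                score=cur.score + m.score,
                e_value=min(cur.e_value, m.e_value),
            )
        else:
            merged.append(_finalize(cur, cur_weight, cur_aa))
            cur, cur_weight, cur_aa = m, m.aa_identity_frac * m.matched_aa_length, m.matched_aa_length
    merged.append(_finalize(cur, cur_weight, cur_aa))
    return merged


def _finalize(m: GenomicMatch, weight: float, aa: int) -> GenomicMatch:
    return replace(
        m,
        aa_identity_frac=weight / aa if aa else 0.0,
        matched_aa_length=(m.end - m.start) // 3,
    )


def filter_merged(
    merged: GenomicMatch,
    min_identity: float = DEFAULT_MIN_MERGED_IDENTITY,
    min_aa: int = DEFAULT_MIN_MERGED_AA,
) -> bool:
    """Keep merged loci with identity strictly above 30% and span strictly
    above 50 aa."""
    return merged.aa_identity_frac > min_identity and merged.matched_aa_length > min_aa


# ------------------------------------------------------------ parents

def assign_parent(
    merged: GenomicMatch,
    genome: Mapping[str, str],
    parents: Sequence[tuple[GeneModel, ProteinRecord]],
    evalue_cutoff: float = DEFAULT_TRANSLATED_EVALUE,
) -> tuple[GeneModel, ProteinRecord, float] | None:
    """Closest multi-exon protein to the merged locus, or None.

    Similarity is the identity fraction of the best local alignment between
    the locus translation and the candidate; candidates must reach E <=
    cutoff. Ties break deterministically: similarity, then parent CDS
    length, then lexicographic gene id.
    """
    if not parents:
        return None
    locus_seq = genome[merged.chrom][merged.start : merged.end]
    segs = six_frame_segments({merged.chrom: locus_seq}, min_len_aa=10)
    n_db = sum(len(s.aa_seq) for s in segs)
    if n_db == 0:
        return None
    best: tuple[float, int, str] | None = None
    best_entry = None
    for gene, protein in parents:
        scheme = scoring_scheme(select_matrix(protein.length_aa))
        aligner = _aligner(scheme.matrix_name)
        qseq = protein.sequence.upper()
        top_score, top_seg = 0.0, None
        for seg in segs:
            s = aligner.score(qseq, seg.aa_seq)
            if s > top_score:
                top_score, top_seg = s, seg
        if top_seg is None or evalue(top_score, len(qseq), n_db, scheme) > evalue_cutoff:
            continue
        aln = aligner.align(qseq, top_seg.aa_seq)[0]
        identity = aln.counts().identities / aln.length if aln.length else 0.0
        key = (identity, gene.spliced_length, gene.gene_id)
        # maximize identity, then CDS length; minimize id lexicographically
        if best is None or (key[0], key[1], _neg_str(key[2])) > (
            best[0], best[1], _neg_str(best[2])
        ):
            best = key
            best_entry = (gene, protein, identity)
    return best_entry


class _neg_str(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ------------------------------------------------------------ spliced check

@dataclass(frozen=True)
class VerifyResult:
    spliced_align_score: float
    introns_in_match: int
    coverage: float
    locus_introns: int


def _parent_blocks(parent: GeneModel, protein: ProteinRecord) -> list[tuple[int, int, str]]:
    """Per-exon peptide blocks of the parent, in translation order."""
    exon_lens = [e - s for s, e in parent.exons]
    if parent.strand == "-":
        exon_lens = exon_lens[::-1]
    seq = protein.sequence.upper()
    blocks = []
    cum_nt = 0
    prev_aa = 0
    for i, ln in enumerate(exon_lens):
        cum_nt += ln
        aa_end = min(len(seq), cum_nt // 3) if i < len(exon_lens) - 1 else len(seq)
        if aa_end > prev_aa:
            blocks.append((prev_aa, aa_end, seq[prev_aa:aa_end]))
        prev_aa = aa_end
    return blocks


def verify_intronless(
    retro_locus: tuple[str, int, int],
    genome: Mapping[str, str],
    parent: GeneModel,
    parent_protein: ProteinRecord,
    flank_bp: int = DEFAULT_FLANK_BP,
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    intron_penalty: float = DEFAULT_INTRON_PENALTY,
    block_min_score: float = 20.0,
) -> VerifyResult:
    """Spliced alignment of the parent's exon peptide blocks to the locus
    with flanks (GENEWISE proxy).

    Matched exon blocks are partitioned into runs that are contiguous at
    the locus (consecutive parent exons whose genomic gap is at most
    ``min_intron_len``); the best-scoring run is the reported alignment,
    since a retrocopy presents the parent's exons without intervening
    introns. Intron-like breaks between matched blocks each cost
    ``intron_penalty``. Paralogous loci — including the parent's own gene —
    therefore report at most one exon per run and introns_in_match = 0,
    which the downstream >= 2 introns rule rejects.

    Reports the penalised score of the best run, the number of parent
    introns inside the matched part of the parent (within that run), the
    fraction of the parent protein it covers, and the number of intron-like
    breaks among all matched blocks at the locus.
    """
    chrom, start, end = retro_locus
    contig = genome[chrom]
    w0 = max(0, start - flank_bp)
    w1 = min(len(contig), end + flank_bp)
    window = contig[w0:w1]
    segs = six_frame_segments({chrom: window}, min_len_aa=8)
    scheme = scoring_scheme(select_matrix(parent_protein.length_aa))
    aligner = _aligner(scheme.matrix_name)
    # every acceptable placement of every block: (q_range, g_interval, strand, score)
    Candidate = tuple[tuple[int, int], tuple[int, int], str, float]
    blocks = [b for b in _parent_blocks(parent, parent_protein) if len(b[2]) >= 4]
    candidates: list[list[Candidate]] = []
    for q_lo, _q_hi, pep in blocks:
        cands: list[Candidate] = []
        for seg in segs:
            s = aligner.score(pep, seg.aa_seq)
            if s < block_min_score:
                continue
            aln = aligner.align(pep, seg.aa_seq)[0]
            qb, tb = aln.aligned
            g_lo, g_hi = seg.genomic_interval(int(tb[0][0]), int(tb[-1][1]))
            cands.append(
                ((q_lo + int(qb[0][0]), q_lo + int(qb[-1][1])),
                 (w0 + g_lo, w0 + g_hi), seg.strand, float(s))
            )
        candidates.append(cands)
    if not any(candidates):
        return VerifyResult(0.0, 0, 0.0, 0)

    def _contiguous(a: Candidate, b: Candidate) -> bool:
        # b must follow a in translation order with at most an intron-free
        # gap; adjacent blocks of a real retrocopy abut, so genomic overlap
        # beyond one alignment-trimmed codon rules a pair out
        if a[2] != b[2]:
            return False
        gap = b[1][0] - a[1][1] if a[2] == "+" else a[1][0] - b[1][1]
        return -3 <= gap <= min_intron_len

    # best contiguous run of consecutive blocks (chain DP over candidates)
    best_run: tuple[float, int, int, int] | None = None  # score, first, last, cov_aa
    run_at: list[dict[int, tuple[float, int, int]]] = []  # per block: cand -> state
    for i, cands in enumerate(candidates):
        states: dict[int, tuple[float, int, int]] = {}
        for ci, cand in enumerate(cands):
            q_range, _, _, s = cand
            cov = q_range[1] - q_range[0]
            best_prev = None
            if i > 0:
                for pj, (ps, pfirst, pcov) in run_at[-1].items():
                    if _contiguous(candidates[i - 1][pj], cand):
                        if best_prev is None or ps > best_prev[0]:
                            best_prev = (ps, pfirst, pcov)
            if best_prev is not None:
                states[ci] = (best_prev[0] + s, best_prev[1], best_prev[2] + cov)
            else:
                states[ci] = (s, i, cov)
            score_i, first_i, cov_i = states[ci]
            if best_run is None or score_i > best_run[0]:
                best_run = (score_i, first_i, i, cov_i)
        run_at.append(states)
    assert best_run is not None
    run_score, first_block, last_block, cov_aa = best_run
    coverage = cov_aa / parent_protein.length_aa
    introns_in_match = last_block - first_block
    # each matched block that cannot be chained into the intronless run marks
    # an intron-like break at the locus; those carry the per-intron penalty
    n_matched_blocks = sum(1 for c in candidates if c)
    locus_introns = n_matched_blocks - (last_block - first_block + 1)
    score = run_score - intron_penalty * locus_introns
    return VerifyResult(score, introns_in_match, coverage, locus_introns)


# ------------------------------------------------------------ calls

@dataclass(frozen=True)
class RetrogeneCall:
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    spliced_align_score: float
    parent_introns_in_match: int
    parent_alignment_coverage: float
    similarity: float
    flank_bp: int = DEFAULT_FLANK_BP


@dataclass(frozen=True)
class ChimeraCall:
    gene_id: str
    retro_chrom: str
    retro_start: int
    retro_end: int
    cds_overlap_bp: int
    possible_false_positive: bool


def _reverify(
    call_locus: tuple[str, int, int],
    genome: Mapping[str, str],
    parent_protein: ProteinRecord,
    evalue_cutoff: float,
) -> bool:
    """Align the recruited locus back to the parent protein as confirmation."""
    chrom, start, end = call_locus
    locus_seq = genome[chrom][start:end]
    segs = six_frame_segments({chrom: locus_seq}, min_len_aa=10)
    n_db = sum(len(s.aa_seq) for s in segs)
    if n_db == 0:
        return False
    scheme = scoring_scheme(select_matrix(parent_protein.length_aa))
    aligner = _aligner(scheme.matrix_name)
    qseq = parent_protein.sequence.upper()
    top = max((aligner.score(qseq, seg.aa_seq) for seg in segs), default=0.0)
    return evalue(top, len(qseq), n_db, scheme) <= evalue_cutoff


def call_retrogenes(
    proteins: Sequence[ProteinRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    evalue_cutoff: float = DEFAULT_TRANSLATED_EVALUE,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_merged_identity: float = DEFAULT_MIN_MERGED_IDENTITY,
    min_merged_aa: int = DEFAULT_MIN_MERGED_AA,
    min_score: float = DEFAULT_SPLICED_MIN_SCORE,
    min_introns: int = DEFAULT_MIN_INTRONS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    flank_bp: int = DEFAULT_FLANK_BP,
    min_intron_len: int = DEFAULT_MIN_INTRON_LEN,
    intron_penalty: float = DEFAULT_INTRON_PENALTY,
    segments: Sequence[FrameSegment] | None = None,
) -> list[RetrogeneCall]:
    """Run the full screen over every protein; returns deduplicated calls."""
    if segments is None:
        segments = six_frame_segments(genome)
    gene_by_protein: dict[str, GeneModel] = {}
    for g in genes:
        for pid in g.protein_ids:
            gene_by_protein[pid] = g
    parents_pool = [
        (g, p)
        for g in sorted(genes, key=lambda g: g.gene_id)
        if g.intron_count >= 2
        for p in [next((q for q in proteins if q.id in g.protein_ids), None)]
        if p is not None
    ]
    accepted: list[RetrogeneCall] = []
    for protein in sorted(proteins, key=lambda p: p.id):
        own = gene_by_protein.get(protein.id)
        matches = translated_match(
            protein, evalue_cutoff=evalue_cutoff, segments=segments
        )
        if own is not None:
            s, e = own.cds_span
            matches = [m for m in matches if not m.overlaps(own.chrom, s, e)]
        by_group: dict[tuple[str, str], list[GenomicMatch]] = {}
        for m in matches:
            by_group.setdefault((m.chrom, m.strand), []).append(m)
        for group in by_group.values():
            for merged in merge_adjacent(group, max_gap=merge_gap):
                if not filter_merged(merged, min_merged_identity, min_merged_aa):
                    continue
                hit = assign_parent(merged, genome, parents_pool, evalue_cutoff)
                if hit is None:
                    continue
                parent_gene, parent_protein, similarity = hit
                ps, pe = parent_gene.cds_span
                if merged.overlaps(parent_gene.chrom, ps, pe):
                    continue  # the parent's own locus is not a retrocopy
                locus = (merged.chrom, merged.start, merged.end)
                vr = verify_intronless(
                    locus, genome, parent_gene, parent_protein,
                    flank_bp=flank_bp, min_intron_len=min_intron_len,
                    intron_penalty=intron_penalty,
                )
                if not (
                    vr.spliced_align_score > min_score
                    and vr.introns_in_match >= min_introns
                    and vr.coverage > min_coverage
                ):
                    continue
                if not _reverify(locus, genome, parent_protein, evalue_cutoff):
                    continue
                accepted.append(
                    RetrogeneCall(
                        chrom=merged.chrom, start=merged.start, end=merged.end,
                        strand=merged.strand, parent_gene_id=parent_gene.gene_id,
                        spliced_align_score=vr.spliced_align_score,
                        parent_introns_in_match=vr.introns_in_match,
                        parent_alignment_coverage=vr.coverage,
                        similarity=similarity, flank_bp=flank_bp,
                    )
                )
    # the same locus can be reached through several queries; keep the best
    accepted.sort(key=lambda c: (-c.spliced_align_score, c.chrom, c.start, c.end))
    unique: list[RetrogeneCall] = []
    for call in accepted:
        if not any(
            call.chrom == k.chrom and call.start < k.end and k.start < call.end
            for k in unique
        ):
            unique.append(call)
    unique.sort(key=lambda c: (c.chrom, c.start))
    logger.info("retrogene screen: %d accepted calls (%d before dedup)",
                len(unique), len(accepted))
    return unique


def call_chimeras(
    retro_calls: Sequence[RetrogeneCall],
    annotated_genes: Sequence[GeneModel],
    min_overlap_bp: int = DEFAULT_CHIMERA_MIN_OVERLAP,
    fp_overlap_bp: int = DEFAULT_CHIMERA_FP_OVERLAP,
) -> list[ChimeraCall]:
    """Annotated genes whose CDS overlaps a retro locus by > 50 bp.

    Overlap is measured on CDS (exon) intervals only. The parent gene of a
    call is excluded, as is any gene whose CDS lies essentially inside the
    locus (>= 95% contained — that gene is the retrogene annotation itself,
    modulo a few terminal residues the local alignment may trim).
    """
    out: list[ChimeraCall] = []
    for gene in sorted(annotated_genes, key=lambda g: g.gene_id):
        best: ChimeraCall | None = None
        for call in retro_calls:
            if call.chrom != gene.chrom or gene.gene_id == call.parent_gene_id:
                continue
            overlap = sum(
                max(0, min(e, call.end) - max(s, call.start)) for s, e in gene.exons
            )
            if overlap <= min_overlap_bp or overlap >= 0.95 * gene.spliced_length:
                continue
            if best is None or overlap > best.cds_overlap_bp:
                best = ChimeraCall(
                    gene_id=gene.gene_id, retro_chrom=call.chrom,
                    retro_start=call.start, retro_end=call.end,
                    cds_overlap_bp=overlap,
                    possible_false_positive=overlap > fp_overlap_bp,
                )
        if best is not None:
            out.append(best)
    return out
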