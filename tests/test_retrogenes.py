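"""Retroposition screen: matching, merging, parent assignment, intron
verification and chimera calls."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lsgscan import (
    GeneModel, GenomicMatch, ProteinRecord, call_chimeras, filter_merged,
    merge_adjacent, plant_retrogene, spliced_cds, translated_match,
    verify_intronless,
)
from lsgscan.retrogenes import RetrogeneCall
from lsgscan.synthetic_data import _random_codons, _translate_codons


def _match(start, end, identity=0.9, score=100.0, protein_id="p", strand="+"):
    return GenomicMatch(
        protein_id=protein_id, chrom="c", strand=strand, start=start, end=end,
        aa_identity_frac=identity, matched_aa_length=(end - start) // 3,
        score=score, e_value=1e-10,
    )


class TestMergeAdjacent:
    def test_gap_below_forty_merges(self):
        out = merge_adjacent([_match(100, 200), _match(230, 300)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 300)

    def test_gap_of_exactly_forty_does_not_merge(self):
        out = merge_adjacent([_match(100, 200), _match(240, 300)])
        assert len(out) == 2

    def test_overlapping_matches_always_merge(self):
        out = merge_adjacent([_match(100, 220), _match(160, 300)])
        assert len(out) == 1

    def test_transitive_chaining(self):
        # gaps 10, 35, 39: all below 40, single merged interval
        ms = [_match(0, 90), _match(100, 190), _match(225, 315), _match(354, 444)]
        out = merge_adjacent(ms)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 444)

    def test_idempotent_and_order_free(self):
        ms = [_match(0, 90), _match(100, 190), _match(400, 500)]
        once = merge_adjacent(ms)
        assert merge_adjacent(once) == once
        assert merge_adjacent(ms[::-1]) == once

    def test_weighted_identity(self):
        a = _match(0, 300, identity=1.0)      # 100 aa
        b = _match(310, 460, identity=0.4)    # 50 aa
        out = merge_adjacent([a, b])
        assert out[0].aa_identity_frac == pytest.approx((100 * 1.0 + 50 * 0.4) / 150)

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent([_match(0, 90), _match(100, 190, strand="-")])


class TestFilterMerged:
    @pytest.mark.parametrize(
        "identity,aa_len,kept",
        [(0.31, 51, True), (0.30, 200, False), (0.90, 50, False), (0.31, 50, False)],
    )
    def test_strict_boundaries(self, identity, aa_len, kept):
        m = dataclasses.replace(
            _match(0, aa_len * 3), aa_identity_frac=identity, matched_aa_length=aa_len
        )
        assert filter_merged(m) is kept


def _build_parent_world(n_exons=3, exon_aa=30, intron=120, seed=4):
    """A genome holding one multi-exon gene, returning (gene, protein, genome)."""
    rng = np.random.default_rng(seed)
    codons = _random_codons(rng, n_exons * exon_aa)
    aa = _translate_codons(codons)
    cds = "".join(codons)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    parts, exons, pos = [bg[:500]], [], 500
    off = 0
    for i in range(n_exons):
        chunk = cds[off : off + exon_aa * 3]
        off += exon_aa * 3
        exons.append((pos, pos + len(chunk)))
        parts.append(chunk)
        pos += len(chunk)
        if i < n_exons - 1:
            parts.append(bg[500 + i * intron : 500 + (i + 1) * intron])
            pos += intron
    parts.append(bg[1200:2000])
    genome = {"chr": "".join(parts)}
    gene = GeneModel(gene_id="parent", chrom="chr", strand="+",
                     exons=tuple(exons), protein_ids=("parent.p1",))
    return gene, ProteinRecord("parent.p1", aa), genome


class TestPlantRetrogene:
    def test_exact_splice_concatenation(self):
        gene, _, genome = _build_parent_world(n_exons=3, exon_aa=30)
        (chrom, s, e), new_genome = plant_retrogene(gene, genome)
        assert e - s == 270
        assert new_genome[chrom][s:e] == spliced_cds(gene, genome)

    def test_zero_mutation_identical(self):
        gene, _, genome = _build_parent_world()
        (chrom, s, e), g2 = plant_retrogene(gene, genome, mutation_rate=0.0)
        assert g2[chrom][s:e] == spliced_cds(gene, genome)

    def test_two_exon_parent_rejected(self):
        gene, _, genome = _build_parent_world(n_exons=2)
        with pytest.raises(ValueError, match="3 exons"):
            plant_retrogene(gene, genome)


class TestTranslatedMatch:
    def test_planted_exact_copy_found_at_coordinates(self):
        gene, protein, genome = _build_parent_world(exon_aa=40)
        (chrom, s, e), genome2 = plant_retrogene(gene, genome)
        matches = translated_match(protein, genome2)
        retro_hits = [m for m in matches if m.start >= s - 3 and m.end <= e + 3]
        assert retro_hits, "retrocopy locus not recovered"
        best = max(retro_hits, key=lambda m: m.score)
        assert abs(best.start - s) <= 3 and abs(best.end - e) <= 3
        assert best.aa_identity_frac == pytest.approx(1.0)

    def test_unrelated_protein_finds_nothing(self):
        _, _, genome = _build_parent_world()
        junk = ProteinRecord("junk", "WWWWWCCCCCWWWWWCCCCCWWWWWCCCCC")
        assert translated_match(junk, genome) == []


class TestVerifyIntronless:
    def test_exact_full_length_retrocopy(self):
        gene, protein, genome = _build_parent_world(n_exons=3, exon_aa=30)
        locus, genome2 = plant_retrogene(gene, genome)
        vr = verify_intronless(locus, genome2, gene, protein)
        assert vr.introns_in_match == 2
        assert vr.coverage == pytest.approx(1.0, abs=0.02)
        assert vr.spliced_align_score > 35

    def test_single_exon_coverage_rejected_later(self):
        gene, protein, genome = _build_parent_world(n_exons=3, exon_aa=30)
        # retrocopy of the first exon only
        rng = np.random.default_rng(9)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        first = spliced_cds(gene, genome)[:90]
        chrom_seq = genome["chr"]
        genome2 = {"chr": chrom_seq + spacer + first}
        locus = ("chr", len(chrom_seq) + 200, len(chrom_seq) + 290)
        vr = verify_intronless(locus, genome2, gene, protein)
        assert vr.introns_in_match == 0

    def test_parent_own_locus_is_not_intronless(self):
        """Aligning the parent to its own (intron-containing) locus must not
        look like a retrocopy: the best intronless chain is a single exon."""
        gene, protein, genome = _build_parent_world(n_exons=4, exon_aa=30)
        s, e = gene.cds_span
        vr = verify_intronless(("chr", s, e), genome, gene, protein, flank_bp=100)
        assert vr.introns_in_match == 0
        assert vr.locus_introns >= 2

    def test_partial_retrocopy_crossing_two_junctions(self):
        gene, protein, genome = _build_parent_world(n_exons=4, exon_aa=30)
        cds = spliced_cds(gene, genome)
        part = cds[150:360]  # 70 aa of 120 (~58%), spans junctions 2 and 3
        rng = np.random.default_rng(13)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        chrom_seq = genome["chr"]
        genome2 = {"chr": chrom_seq + spacer + part}
        locus = ("chr", len(chrom_seq) + 150, len(chrom_seq) + 150 + len(part))
        vr = verify_intronless(locus, genome2, gene, protein)
        assert vr.introns_in_match == 2
        assert 0.4 < vr.coverage < 0.7


class TestCallChimeras:
    def _retro(self, start, end, parent="parent"):
        return RetrogeneCall(chrom="c", start=start, end=end, strand="+",
                             parent_gene_id=parent, spliced_align_score=100.0,
                             parent_introns_in_match=2,
                             parent_alignment_coverage=1.0, similarity=0.95)

    def _gene(self, start, end, gene_id="g"):
        return GeneModel(gene_id=gene_id, chrom="c", strand="+",
                         exons=((start, end),), protein_ids=())

    @pytest.mark.parametrize(
        "overlap,called,flagged",
        [(60, True, False), (95, True, True), (50, False, False),
         (51, True, False), (90, True, False), (91, True, True)],
    )
    def test_overlap_boundaries(self, overlap, called, flagged):
        gene = self._gene(1000, 1600)
        retro = self._retro(1600 - overlap, 2400)
        calls = call_chimeras([retro], [gene])
        assert bool(calls) is called
        if called:
            assert calls[0].cds_overlap_bp == overlap
            assert calls[0].possible_false_positive is flagged

    def test_parent_gene_excluded(self):
        gene = self._gene(1000, 1600, gene_id="parent")
        calls = call_chimeras([self._retro(1500, 2400)], [gene])
        assert calls == []

    def test_retrogene_annotation_itself_excluded(self):
        gene = self._gene(1000, 1300)  # fully inside the locus
        calls = call_chimeras([self._retro(995, 1305)], [gene])
        assert calls == []


class TestZeroWorldScreen:
    def test_all_planted_retro_loci_recovered_no_false_calls(self, zero_world, zero_run):
        calls = zero_run["retrogenes"]
        truth = zero_world.truth.retro_loci
        assert len(calls) == len(truth)
        for t in truth:
            hit = [
                c for c in calls
                if c.chrom == t.chrom and abs(c.start - t.start) <= 3
                and abs(c.end - t.end) <= 3
            ]
            assert len(hit) == 1, f"locus {t} not uniquely recovered"
            assert hit[0].parent_gene_id == t.parent_id

    def test_accepted_calls_satisfy_all_thresholds(self, zero_run):
        for c in zero_run["retrogenes"]:
            assert c.spliced_align_score > 35
            assert c.parent_introns_in_match >= 2
            assert c.parent_alignment_coverage > 0.40

    def test_planted_chimeras_recovered(self, zero_world, zero_run):
        chim = zero_run["chimeras"]
        truth_chims = {
            g for g, o in zero_world.truth.origins.items() if o.chimeric
        }
        assert set(chim["gene_id"]) == truth_chims
        assert (chim["cds_overlap_bp"] == zero_world.config.chimera_overlap_bp).all()

    def test_chimeras_overlap_some_retro_locus(self, zero_run):
        loci = [(c.start, c.end) for c in zero_run["retrogenes"]]
        for row in zero_run["chimeras"].itertuples():
            assert any(s == row.retro_start and e == row.retro_end for s, e in loci)
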