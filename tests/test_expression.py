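"""Mapping filters, ambiguity resolution, EST calls, RPKM and stage profiles."""
from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lsgscan import (
    GeneModel, StageLibrary, TranscriptMapping, est_expressed, filter_mappings,
    resolve_ambiguous, rpkm, stage_proportions, two_sample_ttest,
)
from lsgscan.expression import count_reads


def _mapping(tid="t", length=200, identity=100.0, cov_map=100.0, cov_whole=100.0,
             score=200.0, start=0, end=None, chrom="c"):
    end = end if end is not None else start + length
    return TranscriptMapping(
        transcript_id=tid, chrom=chrom, strand="+", start=start, end=end,
        mapped_length=length, identity_pct=identity,
        coverage_in_mapping_pct=cov_map, coverage_whole_pct=cov_whole, score=score,
    )


def _gene(start, end, gene_id="g", chrom="c"):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand="+",
                     exons=((start, end),), protein_ids=())


class TestFilterMappings:
    def test_all_boundaries_inclusive(self):
        m = _mapping(length=150, identity=98.0, cov_map=97.0, cov_whole=75.0)
        assert filter_mappings([m]) == [m]

    @pytest.mark.parametrize(
        "kw",
        [dict(length=149, identity=99.0, cov_map=99.0, cov_whole=99.0),
         dict(length=200, identity=97.9),
         dict(length=200, cov_map=96.9),
         dict(length=200, cov_whole=74.9)],
    )
    def test_single_criterion_below_fails(self, kw):
        assert filter_mappings([_mapping(**kw)]) == []

    def test_idempotent_and_subset(self):
        ms = [_mapping(tid=f"t{i}", length=100 + 20 * i) for i in range(6)]
        once = filter_mappings(ms)
        assert filter_mappings(once) == once
        assert set(m.transcript_id for m in once) <= set(m.transcript_id for m in ms)


class TestResolveAmbiguous:
    def test_one_percent_difference_discarded(self):
        ms = [_mapping(score=100.0, start=0), _mapping(score=99.0, start=5000)]
        assert resolve_ambiguous(ms) == []

    def test_clear_best_kept(self):
        best = _mapping(score=100.0, start=0)
        ms = [best, _mapping(score=90.0, start=5000)]
        assert resolve_ambiguous(ms) == [best]

    def test_single_locus_kept(self):
        m = _mapping(score=100.0)
        assert resolve_ambiguous([m]) == [m]

    def test_exact_two_percent_is_unambiguous(self):
        # |100-98|/100 = 0.02, not < 0.02
        best = _mapping(score=100.0, start=0)
        ms = [best, _mapping(score=98.0, start=5000)]
        assert resolve_ambiguous(ms) == [best]


class TestEstExpressed:
    def test_boundary_strictly_greater_than_100(self):
        gene = _gene(0, 1000)
        assert est_expressed(gene, [_mapping(start=0, end=101, length=101)]) is True
        assert est_expressed(gene, [_mapping(start=0, end=100, length=100)]) is False

    def test_union_overlap_across_mappings(self):
        gene = _gene(0, 1000)
        ms = [_mapping(start=0, end=60, length=60),
              _mapping(start=60, end=120, length=60)]
        assert est_expressed(gene, ms) is True

    def test_wrong_chromosome(self):
        gene = _gene(0, 1000, chrom="other")
        assert est_expressed(gene, [_mapping(start=0, end=500, length=500)]) is False


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_reads(self):
        assert rpkm(0, 1000, 1_000_000) == 0.0

    def test_direct_arithmetic(self):
        assert rpkm(7, 1234, 2_500_000) == pytest.approx(7e9 / (1234 * 2.5e6))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 10_000), st.integers(100, 100_000), st.integers(1, 10**7))
    def test_linearity(self, reads, length, total):
        base = rpkm(reads, length, total)
        assert rpkm(2 * reads, length, total) == pytest.approx(2 * base)
        assert rpkm(reads, length, 2 * total) == pytest.approx(base / 2)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestReadCounting:
    def test_single_bp_overlap_counts(self):
        genes = [_gene(100, 200)]
        lib = StageLibrary("L1", pd.DataFrame(
            [{"read_id": "r1", "chrom": "c", "start": 50, "end": 101},
             {"read_id": "r2", "chrom": "c", "start": 200, "end": 260}]), 2)
        counts = count_reads(genes, lib)
        assert counts["g"] == 1  # r2 is half-open adjacent, no overlap

    def test_unique_mode_drops_multigene_reads(self):
        genes = [_gene(0, 200, "a"), _gene(150, 400, "b")]
        lib = StageLibrary("L1", pd.DataFrame(
            [{"read_id": "r", "chrom": "c", "start": 160, "end": 190}]), 1)
        assert count_reads(genes, lib, mode="any") == {"a": 1, "b": 1}
        assert count_reads(genes, lib, mode="unique") == {"a": 0, "b": 0}


class TestStageProportions:
    def _frame(self, rpkms):
        return pd.DataFrame(
            [{"gene_id": f"g{i}", "stage": "L1", "read_count": 0, "rpkm": v}
             for i, v in enumerate(rpkms)]
        )

    def _labels(self, n):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "label": ["SSG"] * n})

    def test_all_zero_gives_zero(self):
        props = stage_proportions(self._labels(4), self._frame([0.0] * 4))
        assert props.loc[0, "proportion"] == 0.0

    def test_all_covered_gives_one(self):
        props = stage_proportions(self._labels(4), self._frame([1.0, 2.0, 3.0, 4.0]))
        assert props.loc[0, "proportion"] == 1.0

    def test_fraction(self):
        props = stage_proportions(self._labels(10), self._frame([1.0] * 6 + [0.0] * 4))
        assert props.loc[0, "proportion"] == pytest.approx(0.6)


class TestTTest:
    def test_identical_samples(self):
        assert two_sample_ttest([1.0, 2, 3], [1.0, 2, 3]) == (0.0, 1.0)

    def test_shift_detected_at_large_n(self):
        a = [float(i % 7) for i in range(60)]
        b = [x + 5.0 for x in a]
        _, p = two_sample_ttest(a, b)
        assert p < 1e-6

    def test_matches_hand_computed_welch(self):
        a, b = [1.0, 2, 3, 4, 5], [2.0, 4, 6, 8, 10]
        va = sum((x - 3) ** 2 for x in a) / 4
        vb = sum((x - 6) ** 2 for x in b) / 4
        t_manual = (3 - 6) / math.sqrt(va / 5 + vb / 5)
        t, p = two_sample_ttest(a, b)
        assert t == pytest.approx(t_manual)
        assert 0 < p < 1

    def test_constant_samples_different_means(self):
        t, p = two_sample_ttest([2.0, 2.0], [1.0, 1.0])
        assert t == float("inf") and p == 0.0


class TestPlot:
    def test_bar_chart_smoke(self, tmp_path):
        from lsgscan.expression import plot_stage_proportions

        props = pd.DataFrame(
            [{"stage": s, "group": g, "proportion": 0.5, "n": 10}
             for s in ("L1", "L2") for g in ("SSG", "GSG")]
        )
        out = tmp_path / "fig.png"
        plot_stage_proportions(props, str(out))
        assert out.stat().st_size > 0


class TestZeroWorldExpression:
    def test_rpkm_positive_iff_planted_expressed(self, zero_world, zero_run):
        expr = zero_run["expression"].set_index(["gene_id", "stage"])
        for gid, stages in zero_world.truth.expressed.items():
            for stage, flag in stages.items():
                got = expr.at[(gid, stage), "rpkm"] > 0
                assert bool(got) == flag, (gid, stage)

    def test_proportions_match_planted_counts_exactly(self, zero_world, zero_run):
        truth = zero_world.truth
        props = zero_run["proportions"].set_index(["stage", "group"])
        for (stage, group), row in props.iterrows():
            members = truth.genes_with_label(group)
            planted = sum(truth.expressed[g][stage] for g in members)
            assert row["proportion"] == pytest.approx(planted / len(members))

    def test_est_support_matches_planted_flags(self, zero_world, zero_run):
        assert zero_run["est_support"] == zero_world.truth.est_supported

    def test_transcript_support_pct_matches_planted(self, zero_world, zero_run):
        t1 = zero_run["table1"].set_index("group")
        truth = zero_world.truth
        for group in ("SSG", "GSG", "EC"):
            members = truth.genes_with_label(group)
            planted_pct = 100.0 * sum(
                truth.est_supported[g] for g in members
            ) / len(members)
            assert t1.at[group, "transcript_support_pct"] == pytest.approx(planted_pct)

    def test_prevalence_ordering_echoes_planting(self, zero_run):
        """ECs are planted with higher expression prevalence than GSGs than
        SSGs; computed proportions preserve EC >= GSG >= SSG at every stage."""
        props = zero_run["proportions"].pivot(
            index="stage", columns="group", values="proportion"
        )
        assert (props["EC"] >= props["GSG"]).all()
        assert (props["GSG"] >= props["SSG"]).all()
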