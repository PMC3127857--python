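"""Capture oligo placement, panel design, enzyme ranking and summaries."""

import numpy as np
import pandas as pd
import pytest

from sgcseq import (
    CaptureOligo,
    DesignParams,
    GenomicInterval,
    ROI,
    SNPTrack,
    build_rois,
    design_panel,
    design_roi,
    design_summary,
    rank_enzymes,
)
from sgcseq.design import capture_totals, oligos_to_frame, summary_ratios
from sgcseq.reference import Fragment, digest_all

from conftest import random_dna


def make_roi(chrom, start, end, gene="G1", rid="G1.1", pad=50):
    return ROI(gene=gene, exon=GenomicInterval(chrom, start, end), pad=pad,
               interval=GenomicInterval(chrom, start, end), roi_id=rid)


def fragment(chrom, start, end, enzyme="MseI"):
    return Fragment(enzyme, GenomicInterval(chrom, start, end))


@pytest.fixture
def genome2k(rng):
    return {"c1": random_dna(rng, 2_000)}


def covered_positions(oligos, roi):
    """Oracle: explicit set of ROI positions covered by non-failed amplicons."""
    covered = set()
    for o in oligos:
        if o.design_failure:
            continue
        seg = o.amplicon.intersect(roi.interval)
        if seg:
            covered.update(range(seg.start, seg.end))
    return covered & set(range(roi.interval.start, roi.interval.end))


class TestDesignRoi:
    def test_roi_inside_small_fragment_one_oligo_no_flaps(self, genome2k):
        roi = make_roi("c1", 200, 300)
        oligos = design_roi(roi, [fragment("c1", 100, 600)], genome2k)
        assert len(oligos) == 1
        o = oligos[0]
        assert o.amplicon == GenomicInterval("c1", 100, 600)
        assert (o.flap5, o.flap3) == (0, 0)
        assert o.arm5.start == 100 and o.arm3.end == 600
        assert o.arm5_seq == genome2k["c1"][100:120]
        assert o.arm3_seq == genome2k["c1"][580:600]

    def test_oversize_fragment_cut_anchored_single_flap(self, genome2k):
        # fragment 1300 b > 800; the ROI is reachable within 800 of the 5'
        # cut end, so one arm anchors there and one flap remains
        roi = make_roi("c1", 500, 800)
        oligos = design_roi(roi, [fragment("c1", 0, 1300)], genome2k)
        assert len(oligos) == 1
        o = oligos[0]
        assert o.amplicon == GenomicInterval("c1", 0, 800)
        assert (o.flap5, o.flap3) == (0, 500)

    def test_oversize_fragment_both_anchors_when_neither_alone_suffices(self, genome2k):
        # under a strict sub-800 limit neither cut end alone reaches the
        # whole ROI: a 5'-anchored and a 3'-anchored amplicon jointly cover
        roi = make_roi("c1", 500, 800)
        params = DesignParams(max_amplicon=799)
        oligos = design_roi(roi, [fragment("c1", 0, 1300)], genome2k, params=params)
        assert len(oligos) == 2
        assert {o.amplicon for o in oligos} == {
            GenomicInterval("c1", 0, 799),
            GenomicInterval("c1", 501, 1300),
        }
        assert covered_positions(oligos, roi) == set(range(500, 800))
        for o in oligos:
            assert o.flap5 == 0 or o.flap3 == 0  # always cut-anchored

    def test_snp_in_arm_marks_design_failure(self, genome2k):
        roi = make_roi("c1", 200, 300)
        snps = SNPTrack([("c1", 105)])  # inside would-be arm [100,120)
        oligos = design_roi(roi, [fragment("c1", 100, 600)], genome2k, snps)
        assert len(oligos) == 1
        assert oligos[0].design_failure

    def test_roi_with_no_fragment_yields_empty(self, genome2k):
        roi = make_roi("c1", 1500, 1600)
        assert design_roi(roi, [fragment("c1", 0, 1000)], genome2k) == []

    def test_roi_spanning_cut_site_is_tiled(self, genome2k):
        roi = make_roi("c1", 300, 700)
        frags = [fragment("c1", 0, 500), fragment("c1", 500, 1100)]
        oligos = design_roi(roi, frags, genome2k)
        assert len(oligos) == 2
        assert covered_positions(oligos, roi) == set(range(300, 700))

    def test_long_roi_covered_only_within_reach_of_cut_ends(self, genome2k):
        # 1900-b target inside a 2000-b fragment: the middle [800,1200)
        # lies beyond max_amplicon reach of both cut ends and cannot be
        # captured by this enzyme
        roi = make_roi("c1", 50, 1950)
        oligos = design_roi(roi, [fragment("c1", 0, 2000)], genome2k)
        assert len(oligos) == 2
        expected = set(range(50, 800)) | set(range(1200, 1950))
        assert covered_positions(oligos, roi) == expected
        for o in oligos:
            assert len(o.amplicon) <= 800
            assert o.flap5 == 0 or o.flap3 == 0


class TestOligoInvariants:
    def test_panel_invariant_sweep(self, fixture_reference):
        """Every emitted oligo satisfies the structural design invariants."""
        genome = fixture_reference.genome
        rois = build_rois(fixture_reference.exons, genome)
        params = DesignParams()
        oligos, report = design_panel(
            rois, genome, ["Sau3AI", "MseI", "BfaI"], fixture_reference.snps, params
        )
        assert oligos, "fixture should produce designs"
        frags = {
            enz: digest_all(genome, enz) for enz in ("Sau3AI", "MseI", "BfaI")
        }
        snps = fixture_reference.snps
        for o in oligos:
            assert len(o.full_sequence) == 80
            assert len(o.arm5_seq) == len(o.arm3_seq) == 20
            assert len(o.amplicon) <= params.max_amplicon
            assert o.amplicon.contains(o.arm5) and o.amplicon.contains(o.arm3)
            # at least one arm boundary coincides with a fragment boundary
            # or the amplicon carries the corresponding flap
            chrom_frags = frags[o.enzyme][o.amplicon.chrom]
            boundaries = {f.interval.start for f in chrom_frags} | {
                f.interval.end for f in chrom_frags
            }
            assert o.amplicon.start in boundaries or o.amplicon.end in boundaries
            assert o.flap5 == 0 or o.flap3 == 0
            # arms lie within the amplicon's fragment
            host = [
                f for f in chrom_frags
                if f.interval.contains(o.arm5) and f.interval.contains(o.arm3)
            ]
            assert host, f"arms of {o.oligo_id} not inside one fragment"
            if not o.design_failure:
                assert not snps.overlaps(o.arm5)
                assert not snps.overlaps(o.arm3)

    def test_coverage_accounting_matches_position_set_oracle(self, fixture_reference):
        genome = fixture_reference.genome
        rois = build_rois(fixture_reference.exons, genome)
        oligos, report = design_panel(rois, genome, ["Sau3AI"], fixture_reference.snps)
        for roi in rois:
            mine = [o for o in oligos if roi.roi_id in o.roi_ids]
            assert report.per_roi_covered[roi.roi_id] == len(
                covered_positions(mine, roi)
            )

    def test_determinism_byte_identical_tables(self, fixture_reference):
        genome = fixture_reference.genome
        rois = build_rois(fixture_reference.exons, genome)
        a, _ = design_panel(rois, genome, ["Sau3AI", "MseI"], fixture_reference.snps)
        b, _ = design_panel(rois, genome, ["Sau3AI", "MseI"], fixture_reference.snps)
        assert oligos_to_frame(a).to_csv() == oligos_to_frame(b).to_csv()


class TestDesignPanel:
    def test_enzyme_with_no_sites_yields_zero_coverage(self):
        genome = {"c1": "ACGA" * 500}  # no TTAA
        rois = [make_roi("c1", 200, 300)]
        oligos, report = design_panel(rois, genome, ["MseI"])
        # the single uncut 2kb fragment exceeds max_amplicon and has no
        # internal cut to anchor tiles flush, but tiling still emits probes;
        # an enzyme with zero sites anywhere gives one whole-chromosome
        # fragment, so designs carry flaps on both sides
        assert all(o.flap5 > 0 or o.flap3 > 0 for o in oligos) or not oligos

    def test_empty_roi_list_rejected(self):
        with pytest.raises(ValueError):
            design_panel([], {"c1": "ACGT" * 100}, ["MseI"])

    def test_every_roi_in_own_fragment_gives_one_oligo_each(self):
        # plant TTAA fences so each ROI sits alone in a 240-b fragment
        seq = []
        for _ in range(5):
            seq.append("TTAA" + "ACG" * 80)
        seq.append("TTAA")
        genome = {"c1": "".join(seq)}
        rois = [make_roi("c1", 244 * i + 60, 244 * i + 180, rid=f"G1.{i + 1}")
                for i in range(5)]
        oligos, _ = design_panel(rois, genome, ["MseI"])
        per_roi = {}
        for o in oligos:
            for rid in o.roi_ids:
                per_roi[rid] = per_roi.get(rid, 0) + 1
        assert per_roi == {f"G1.{i + 1}": 1 for i in range(5)}


class TestRankEnzymes:
    def test_planted_sites_rank_first(self):
        # GATC fences every ~200 b, no TTAA anywhere; the ROI sits at the
        # genome's center, beyond MseI reach (whole genome = one fragment)
        block = "GATC" + "CCG" * 64 + "CC"
        genome = {"c1": block * 15}  # 2970 b
        rois = [make_roi("c1", 1400, 1500)]
        table = rank_enzymes(rois, genome, ["MseI", "Sau3AI"])
        assert table.iloc[0]["enzyme"] == "Sau3AI"
        assert table.iloc[0]["pct_roi_bases_covered"] == 100.0
        assert table.iloc[1]["pct_roi_bases_covered"] < 100.0

    def test_duplicated_enzyme_identical_rows(self, fixture_reference):
        genome = fixture_reference.genome
        rois = build_rois(fixture_reference.exons, genome)[:3]
        table = rank_enzymes(rois, genome, ["Sau3AI", "DpnII"])
        a, b = table.iloc[0], table.iloc[1]
        assert a["pct_roi_bases_covered"] == b["pct_roi_bases_covered"]
        assert a["pct_rois_fully_designable"] == b["pct_rois_fully_designable"]


class TestSummaries:
    @pytest.mark.parametrize(
        "genes,rois,oligos,expected",
        [
            (17_049, 157_624, 784_783, (9.25, 46, 5)),
            (1, 1, 1, (1.0, 1, 1)),
        ],
    )
    def test_summary_ratio_rounding(self, genes, rois, oligos, expected):
        assert summary_ratios(genes, rois, oligos) == expected

    def test_capture_totals_arithmetic(self):
        total, pct = capture_totals(47.554, 54.934, 48.141)
        assert total == 102.488
        assert pct == 98.8

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            summary_ratios(0, 10, 10)

    def test_design_summary_consistency(self, fixture_reference):
        genome = fixture_reference.genome
        rois = build_rois(fixture_reference.exons, genome)
        oligos, report = design_panel(rois, genome, ["Sau3AI"])
        assert report.covered_roi_bases <= report.roi_bases
        assert 0.0 <= report.pct_roi_bases_covered <= 100.0
        assert report.n_oligos == sum(report.per_enzyme_oligos.values())
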