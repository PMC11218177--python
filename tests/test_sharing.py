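"""Sharing classifier: coverage gate, three-rule classification, summaries,
CNV-gene and SV overlap channels."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multifoci as m
from multifoci.errors import InputDataError
from multifoci.records import Segment, SVBreakpoint
from multifoci.sharing import (
    FocusPair,
    classify_site,
    cnv_gene_overlap,
    coverage_gate,
    sharing_summary,
    sv_overlap,
)
from multifoci.synthetic import simulate_patient
from _oracles import sharing_oracle
from conftest import make_evidence, make_variant


class TestCoverageGate:
    @pytest.mark.parametrize(
        "t_depth,n_depth,expected",
        [
            ((20, 10), (20, 5), True),   # tumor 30, normal 25
            ((20, 10), (9, 0), False),   # normal below 10
            ((5, 4), (30, 0), False),    # tumor below 10
            ((10, 0), (10, 0), True),    # boundary inclusive on both sides
            ((9, 0), (9, 0), False),
        ],
    )
    def test_gate(self, t_depth, n_depth, expected):
        t = make_evidence(sample="T", ref_depth=t_depth[0], alt_depth=t_depth[1])
        n = make_evidence(sample="N", ref_depth=n_depth[0], alt_depth=n_depth[1])
        assert coverage_gate(t, n) is expected

    def test_mismatched_sites_rejected(self):
        t = make_evidence(sample="T")
        n = make_evidence(sample="N", pos=999)
        with pytest.raises(InputDataError):
            coverage_gate(t, n)


LOH_B = [Segment("chr1", 50, 200, 2, genotype="AA", status="neutral", loh=True)]


class TestClassifySite:
    """The three-rule truth table on hand-built sites."""

    @pytest.mark.parametrize(
        "partner_alt,partner_ref,pos,loh,expected",
        [
            (1, 39, 100, LOH_B, "shared"),      # a single partner alt read rescues
            (12, 28, 100, LOH_B, "shared"),
            (0, 40, 100, [], "unique"),          # reference bases only, no LOH
            (0, 40, 300, LOH_B, "unique"),       # outside the LOH interval
            (0, 40, 100, LOH_B, "excluded_loh"),  # alt-free inside partner LOH
            (1, 39, 100, LOH_B, "shared"),       # rule (i) precedes rule (iii)
            (0, 40, 51, LOH_B, "excluded_loh"),  # 0-based start boundary: pos 51 is inside
            (0, 40, 200, LOH_B, "excluded_loh"),  # end boundary inclusive in 1-based space
            (0, 40, 201, LOH_B, "unique"),
        ],
    )
    def test_truth_table(self, partner_alt, partner_ref, pos, loh, expected):
        v = make_variant(pos=pos)
        ev = make_evidence(sample="B", pos=pos, ref_depth=partner_ref, alt_depth=partner_alt, hq=False)
        assert classify_site(v, ev, loh) == expected

    def test_wrong_site_rejected(self):
        with pytest.raises(InputDataError):
            classify_site(make_variant(pos=1), make_evidence(pos=2), [])

    @settings(max_examples=200, derandomize=True)
    @given(alt0=st.integers(0, 5), extra=st.integers(0, 50), pos=st.integers(1, 400))
    def test_monotone_in_partner_alt_depth(self, alt0, extra, pos):
        """Adding partner alt reads never demotes a site away from shared."""
        v = make_variant(pos=pos)
        before = classify_site(v, make_evidence(pos=pos, ref_depth=40, alt_depth=alt0), LOH_B)
        after = classify_site(v, make_evidence(pos=pos, ref_depth=40, alt_depth=alt0 + extra), LOH_B)
        if before == "shared":
            assert after == "shared"
        if extra > 0 and before in ("unique", "excluded_loh"):
            assert after == "shared"


def _toy_pair(n=25, model="ME", target=0.4, seed=3):
    from multifoci.synthetic import PatientConfig

    cfg = PatientConfig(
        patient_id="TOY", origin_model=model, target_shared_snv_fraction=target,
        n_somatic_per_focus=n, seed=seed, germline_total=4, germline_immune=1,
        sv_count_per_focus=5, planted_drivers=["TP53"],
    )
    return simulate_patient(cfg)


class TestSharingSummary:
    def test_direct_arithmetic(self):
        s = m.SharingSummary("P", n_shared=2, n_unique_a=100, n_unique_b=98)
        assert s.n_total == 200
        # the stated formula: shared / (shared + unique_a + unique_b)
        assert 2 / 200 == pytest.approx(0.01)

    @pytest.mark.parametrize("model,target,seed", [("ME", 0.4, 3), ("MC", 0.0, 4), ("ME", 0.65, 5)])
    def test_matches_brute_force_oracle_on_toy_pairs(self, model, target, seed):
        b = _toy_pair(25, model, target, seed)
        pair = FocusPair.from_bundle(b)
        summary = sharing_summary(pair)
        ev = {k: (e.ref_depth, e.alt_depth, e.hq_flag) for k, e in pair.evidence.items()}
        loh = {
            f: [(s.contig, s.start, s.end) for s in b.segments[f] if s.loh] for f in ("Ca1", "Ca2")
        }
        oracle = sharing_oracle(
            b.somatic["Ca1"], b.somatic["Ca2"], ev, loh["Ca2"], loh["Ca1"],
            pair.sample_a, pair.sample_b, pair.sample_normal,
        )
        assert summary.n_shared == len(oracle["shared"])
        assert summary.n_unique_a == len(oracle["unique_a"])
        assert summary.n_unique_b == len(oracle["unique_b"])
        assert summary.n_excluded_loh == len(oracle["excluded"])
        assert summary.n_failed_coverage == len(oracle["failed"])

    def test_partition_identity_and_symmetry(self):
        b = _toy_pair(40, "ME", 0.5, 9)
        pair = sharing_summary(FocusPair.from_bundle(b))
        union = {v.key for f in ("Ca1", "Ca2") for v in b.somatic[f]}
        assert pair.n_total == len(union)
        # swapping the two foci must preserve the de-duplicated shared set
        fp = FocusPair.from_bundle(b)
        swapped = FocusPair(
            patient_id=fp.patient_id, focus_a=fp.focus_b, focus_b=fp.focus_a,
            variants_a=fp.variants_b, variants_b=fp.variants_a, evidence=fp.evidence,
            segments_a=fp.segments_b, segments_b=fp.segments_a,
            sample_a=fp.sample_b, sample_b=fp.sample_a, sample_normal=fp.sample_normal,
        )
        s2 = sharing_summary(swapped)
        assert s2.n_shared == pair.n_shared
        assert (s2.n_unique_a, s2.n_unique_b) == (pair.n_unique_b, pair.n_unique_a)
        assert s2.shared_fraction_snv == pytest.approx(pair.shared_fraction_snv)

    def test_all_shared_gives_fraction_one(self):
        from multifoci.synthetic import PatientConfig

        cfg = PatientConfig(
            patient_id="TOY", origin_model="ME", target_shared_snv_fraction=1.0,
            n_somatic_per_focus=20, seed=2, germline_total=4, germline_immune=1,
            sv_count_per_focus=5, planted_drivers=[], n_loh_per_focus=0, n_loh_trapped=0,
        )
        b = simulate_patient(cfg)
        s = sharing_summary(FocusPair.from_bundle(b))
        assert s.shared_fraction_snv == 1.0

    def test_empty_denominator_flagged(self):
        pair = FocusPair(
            patient_id="P", focus_a="Ca1", focus_b="Ca2", variants_a=[], variants_b=[],
            evidence={}, segments_a=[], segments_b=[], sample_a="a", sample_b="b",
            sample_normal="n",
        )
        s = sharing_summary(pair)
        assert s.shared_fraction_snv == 0.0 and s.empty_denominator

    def test_missing_partner_evidence_is_an_error(self):
        v = make_variant()
        ev = {(*v.key, "A"): make_evidence(sample="A"), (*v.key, "N"): make_evidence(sample="N")}
        pair = FocusPair(
            patient_id="P", focus_a="Ca1", focus_b="Ca2", variants_a=[v], variants_b=[],
            evidence=ev, segments_a=[], segments_b=[], sample_a="A", sample_b="B",
            sample_normal="N",
        )
        with pytest.raises(InputDataError, match="missing pileup"):
            sharing_summary(pair)


GENES = pd.DataFrame(
    {
        "gene": ["EGFR", "CDKN2A", "MYC", "CCND1"],
        "contig": ["chr1", "chr1", "chr2", "chr2"],
        "start": [100, 5000, 100, 5000],
        "end": [200, 6000, 200, 6000],
    }
)


def _seg(contig, start, end, status):
    cn = {"gain": 4, "loss": 1, "neutral": 2}[status]
    return Segment(contig, start, end, cn, genotype="AB" if status == "neutral" else "A",
                   status=status, loh=status == "loss")


class TestCnvGeneOverlap:
    def test_hand_enumerated_example(self):
        a = [_seg("chr1", 50, 300, "gain"), _seg("chr1", 4500, 6500, "loss")]  # EGFR gain, CDKN2A loss
        b = [_seg("chr1", 50, 300, "gain"), _seg("chr2", 50, 300, "gain")]  # EGFR gain, MYC gain
        shared, frac = cnv_gene_overlap(a, b, GENES)
        assert shared == {"EGFR"} and frac == pytest.approx(1 / 3)

    def test_no_cnv_in_one_focus(self):
        a = [_seg("chr1", 50, 300, "gain")]
        shared, frac = cnv_gene_overlap(a, [], GENES)
        assert shared == set() and frac == 0.0

    def test_direction_mismatch_not_shared(self):
        a = [_seg("chr2", 4500, 6500, "gain")]
        b = [_seg("chr2", 4500, 6500, "loss")]
        shared, frac = cnv_gene_overlap(a, b, GENES)
        assert shared == set() and frac == 0.0


class TestSvOverlap:
    def test_identical_breakpoints_shared(self):
        a = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL")]
        b = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL")]
        matched, frac = sv_overlap(a, b, 10)
        assert len(matched) == 1 and frac == 1.0

    def test_type_mismatch_not_shared(self):
        a = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL")]
        b = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DUP")]
        assert sv_overlap(a, b, 10)[1] == 0.0

    def test_tolerance_rule(self):
        a = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL")]
        b = [SVBreakpoint("chr1", 1025, "chr1", 5000, "DEL")]
        assert sv_overlap(a, b, 10)[1] == 0.0
        assert sv_overlap(a, b, 25)[1] == 1.0

    def test_translocation_matches_with_swapped_ends(self):
        a = [SVBreakpoint("chr1", 1000, "chr2", 9000, "TRA")]
        b = [SVBreakpoint("chr2", 9003, "chr1", 997, "TRA")]
        assert sv_overlap(a, b, 10)[1] == 1.0

    def test_jaccard_denominator(self):
        a = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL"),
             SVBreakpoint("chr3", 100, "chr3", 900000, "INV")]
        b = [SVBreakpoint("chr1", 1000, "chr1", 5000, "DEL")]
        matched, frac = sv_overlap(a, b, 10)
        assert frac == pytest.approx(1 / 2)
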