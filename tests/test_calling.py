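"""Variant calling: pileup counting, call quality, QC boundary behaviour,
and recovery of truth variants from simulated reads."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemoseq.calling import (CallParams, PileupSite, SampleCalls, build_pileup,
                             call_site, call_sample, qc_filter, write_vcf)


def _site(bases, quals=None, strands=None, ref="A", pos=100):
    n = len(bases)
    return PileupSite(
        "chr1",
        pos,
        ref,
        bases=np.array(list(bases)),
        quals=np.array(quals if quals is not None else [30] * n),
        strands=np.array(strands if strands is not None else ["+", "-"] * (n // 2) + ["+"] * (n % 2)),
        mapqs=np.array([60] * n),
    )


def _reads_frame(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "tag", "contig", "start", "end", "strand", "mapq", "bases", "quals"]
    )


class TestBuildPileup:
    def test_depth_counts_overlapping_reads(self, small_panel):
        contig = sorted(small_panel.target_intervals)[0]
        s0, e0 = small_panel.target_intervals[contig][0]
        pos = s0 + 5  # 0-based -> covers 1-based position pos+1
        seq = small_panel.reference[contig][pos : pos + 10]
        rows = [
            (f"r{i}", "AAAAAA", contig, pos + 1, pos + 10, "+", 60, seq, "I" * 10)
            for i in range(10)
        ]
        sites, depth, pos_index, n_off = build_pileup(_reads_frame(rows), small_panel)
        assert sites == []  # reference-identical reads: no mismatch sites
        assert depth[contig][pos_index[contig][pos + 1]] == 10
        assert n_off == 0

    def test_low_base_quality_excluded(self, small_panel):
        contig = sorted(small_panel.target_intervals)[0]
        s0, _ = small_panel.target_intervals[contig][0]
        pos = s0 + 5
        seq = small_panel.reference[contig][pos : pos + 10]
        q15 = chr(15 + 33)
        rows = [("r0", "AAAAAA", contig, pos + 1, pos + 10, "+", 60, seq, q15 * 10)]
        _, depth, pos_index, _ = build_pileup(_reads_frame(rows), small_panel, min_base_qual=20)
        assert depth[contig][pos_index[contig][pos + 1]] == 0

    def test_off_panel_reads_counted(self, small_panel):
        rows = [("r0", "AAAAAA", "chrUn", 1, 10, "+", 60, "A" * 10, "I" * 10)]
        _, _, _, n_off = build_pileup(_reads_frame(rows), small_panel)
        assert n_off == 1

    def test_error_free_observations_match_haplotypes(self, errorfree_cohort, small_panel, errorfree_callsets):
        truth, _, _ = errorfree_cohort
        # every PASS call corresponds to a truth site with a carrier genotype
        truth_keys = {
            (r.contig, int(r.pos), r.alt): si
            for si, r in enumerate(truth.sites.itertuples(index=False))
        }
        order = {s: i for i, s in enumerate(truth.samples["sample"])}
        for sample, cs in errorfree_callsets.items():
            for call in cs.passing():
                key = (call.contig, call.pos, call.alt)
                assert key in truth_keys, f"spurious PASS call {key}"
                g = truth.genotypes[order[sample], truth_keys[key]]
                assert g > 0


class TestCallSite:
    def test_het_at_half_balance(self):
        call = call_site(_site("GGGGG" + "AAAAA"))
        assert call.allele_balance == pytest.approx(0.5)
        assert call.genotype == "het" and call.var_type == "SNV"

    def test_homvar_at_full_balance(self):
        call = call_site(_site("G" * 10))
        assert call.allele_balance == 1.0
        assert call.genotype == "homvar"

    def test_call_quality_equals_binomial_tail(self):
        # 30 observations all Q30, 2 alt: -10 log10 P[X >= 2], X ~ Bin(30, 1e-3)
        call = call_site(_site("GG" + "A" * 28))
        expect = -10 * math.log10(stats.binom.sf(1, 30, 1e-3))
        assert call.call_quality == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(33.696, abs=0.001)

    def test_call_quality_monotone_in_base_quality(self):
        quals = [[40] * 20, [30] * 20, [20] * 20, [10] * 20]
        cqs = [call_site(_site("GGGG" + "A" * 16, quals=q)).call_quality for q in quals]
        assert cqs == sorted(cqs, reverse=True)

    def test_below_min_alt_reads_no_call(self):
        assert call_site(_site("G" + "A" * 20)) is None

    def test_multiallelic_majority_alt_flagged(self):
        call = call_site(_site("GGG" + "TT" + "A" * 10))
        assert call.alt == "G" and call.multiallelic

    def test_deletion_observations_called(self):
        call = call_site(_site("--- ".replace(" ", "") + "A" * 7))
        assert call.var_type == "deletion" and call.alt == "-"


class TestQcFilter:
    def test_allele_balance_boundary(self):
        fail = qc_filter(call_site(_site("GGG" + "A" * 13)))  # AB = 3/16 = 0.1875
        assert "low_allele_balance" in fail.fail_reasons
        ok = qc_filter(call_site(_site("GGGG" + "A" * 16)))  # AB = 0.20 exactly
        assert "low_allele_balance" not in ok.fail_reasons

    def test_strand_bias_requires_both_orientations(self):
        site = _site("GGG" + "A" * 13, strands=["+"] * 3 + ["+", "-"] * 6 + ["+"])
        call = qc_filter(call_site(site))
        assert call.strand_counts == (3, 0)
        assert "strand_bias" in call.fail_reasons
        balanced = qc_filter(call_site(_site("GGGG" + "A" * 12)))
        assert "strand_bias" not in balanced.fail_reasons

    def test_depth_boundary_9_vs_10(self):
        shallow = qc_filter(call_site(_site("GGGG" + "A" * 5)))  # depth 9, AB 0.44
        assert "low_depth" in shallow.fail_reasons
        deep = qc_filter(call_site(_site("GGGG" + "A" * 6)))  # depth 10
        assert "low_depth" not in deep.fail_reasons

    def test_single_strand_site_flagged_distinctly(self):
        site = _site("GGGG" + "A" * 8, strands=["+"] * 12)
        call = qc_filter(call_site(site))
        assert call.single_strand_site and "strand_bias" in call.fail_reasons

    def test_status_consistency(self):
        call = qc_filter(call_site(_site("GGGG" + "A" * 16)))
        assert call.qc_status == "PASS" and call.fail_reasons == ()


class TestRecovery:
    def test_error_free_sensitivity_and_specificity(self, errorfree_cohort, errorfree_callsets, small_panel):
        """Error-free limit: every adequately covered truth variant is PASS-called,
        and there is no PASS call at a non-truth site."""
        truth, _, _ = errorfree_cohort
        order = {s: i for i, s in enumerate(truth.samples["sample"])}
        truth_keys = {
            (r.contig, int(r.pos), r.alt): si
            for si, r in enumerate(truth.sites.itertuples(index=False))
        }
        missed = 0
        total = 0
        for sample, cs in errorfree_callsets.items():
            called = {c.key[:2] + (c.key[3],): c for c in cs.calls}
            for key, si in truth_keys.items():
                g = truth.genotypes[order[sample], si]
                if g == 0:
                    continue
                call = called.get(key)
                depth_ok = cs.depth_at(key[0], key[1]) >= 10
                both_strands = call is not None and min(call.strand_counts) > 0
                if depth_ok and call is not None and both_strands and g == 2:
                    total += 1
                    missed += call.qc_status != "PASS"
                elif depth_ok and call is not None and both_strands and g == 1:
                    total += 1
                    if call.qc_status != "PASS":
                        # hets may legitimately fail AB on a skewed draw
                        assert "low_allele_balance" in call.fail_reasons
            for call in cs.passing():
                assert (call.contig, call.pos, call.alt) in truth_keys
        assert total > 50 and missed == 0

    def test_default_noise_sensitivity_specificity(self, small_cohort, small_callsets):
        """At the default noise model (Q20/Q30 mix, 42X) het sensitivity and
        call specificity both clear 0.95."""
        truth, _, _ = small_cohort
        order = {s: i for i, s in enumerate(truth.samples["sample"])}
        truth_keys = {
            (r.contig, int(r.pos), r.alt): si
            for si, r in enumerate(truth.sites.itertuples(index=False))
        }
        tp = fn = fp = n_pass = 0
        for sample, cs in small_callsets.items():
            pass_keys = {(c.contig, c.pos, c.alt) for c in cs.passing()}
            n_pass += len(pass_keys)
            fp += len(pass_keys - set(truth_keys))
            for key, si in truth_keys.items():
                if truth.genotypes[order[sample], si] == 1:
                    if key in pass_keys:
                        tp += 1
                    else:
                        fn += 1
        sensitivity = tp / (tp + fn)
        specificity = 1 - fp / n_pass
        assert sensitivity >= 0.95, f"het sensitivity {sensitivity:.3f}"
        assert specificity >= 0.95, f"specificity {specificity:.3f}"


def test_vcf_output_parses_with_pysam(tmp_path, small_callsets, small_panel):
    pysam = pytest.importorskip("pysam")
    sample, cs = next(iter(small_callsets.items()))
    path = tmp_path / f"{sample}.vcf"
    write_vcf(cs, small_panel, path)
    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert len(records) == len(cs.calls)
    for rec in records[:20]:
        assert rec.info["DP"] >= rec.info["ALTR"]
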