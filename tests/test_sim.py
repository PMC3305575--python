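"""Cohort simulator: risk model arithmetic, Hardy-Weinberg draws, read statistics."""

import numpy as np
import pandas as pd
import pytest

from hemoseq.sim import (BaseErrorModel, CommonRisk, RareBurden, SimConfig,
                         case_frequency, hwe_genotype_matrix,
                         simulate_genotypes, simulate_reads)


class TestCaseFrequency:
    def test_null_odds_ratio_is_identity(self):
        assert case_frequency(0.25, 1.0) == pytest.approx(0.25)

    def test_worked_example(self):
        # q = 0.22, OR = 1.45 -> 1.45*0.22 / (1 + 0.22*0.45)
        assert case_frequency(0.22, 1.45) == pytest.approx(0.2902638762, abs=1e-9)

    def test_realised_allelic_odds_ratio_equals_parameter(self):
        q, orr = 0.3, 1.8
        p = case_frequency(q, orr)
        assert (p / (1 - p)) / (q / (1 - q)) == pytest.approx(orr)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            case_frequency(0.0, 1.5)
        with pytest.raises(ValueError):
            case_frequency(0.2, -1)


def test_hardy_weinberg_homvar_fraction(small_panel):
    # q = 0.25 -> homozygous-variant fraction q^2 = 0.0625 among controls
    config = SimConfig(
        n_cases=1,
        n_controls=4000,
        common_risk=CommonRisk(q=0.25, odds_ratio=1.0),
        rare_burden=None,
        barcode_length=12,
        n_common_background=0,
        n_rare_background=0,
        n_deletion_sites=0,
        seed=21,
    )
    truth = simulate_genotypes(small_panel, config)
    controls = truth.genotypes[truth.samples["phenotype"] == 1, 0]
    frac = (controls == 2).mean()
    se = np.sqrt(0.0625 * (1 - 0.0625) / len(controls))
    assert abs(frac - 0.0625) < 3 * se


def test_case_allele_frequency_converges_to_risk_model(small_panel):
    q, orr = 0.25, 1.5
    config = SimConfig(
        n_cases=4000,
        n_controls=10,
        common_risk=CommonRisk(q=q, odds_ratio=orr),
        rare_burden=None,
        barcode_length=12,
        n_common_background=0,
        n_rare_background=0,
        n_deletion_sites=0,
        seed=22,
    )
    truth = simulate_genotypes(small_panel, config)
    p_case = case_frequency(q, orr)
    cases = truth.genotypes[truth.samples["phenotype"] == 2, 0]
    freq = cases.sum() / (2 * len(cases))
    se = np.sqrt(p_case * (1 - p_case) / (2 * len(cases)))
    assert abs(freq - p_case) < 3 * se


def test_burden_sites_are_missense_in_designated_set(small_cohort, small_panel):
    truth, _, _ = small_cohort
    burden = truth.sites[truth.sites["site_class"] == "burden"]
    assert len(burden) == len(small_panel.gene_sets["anticoagulant"])
    assert (burden["consequence"] == "missense").all()
    assert set(burden["gene"]) <= small_panel.gene_sets["anticoagulant"]


def test_background_avoids_burden_set_cds(small_cohort, small_panel):
    truth, _, _ = small_cohort
    cds = set()
    for gene in small_panel.gene_sets["anticoagulant"]:
        for tx in small_panel.transcripts_of(gene):
            for s, e in tx.cds:
                cds.update((tx.contig, p) for p in range(s, e + 1))
    background = truth.sites[truth.sites["site_class"].str.startswith("background")]
    hits = [(r.contig, r.pos) for r in background.itertuples(index=False) if (r.contig, r.pos) in cds]
    assert hits == []


def test_truth_sites_lie_in_panel(small_cohort, small_panel):
    truth, _, _ = small_cohort
    for row in truth.sites.itertuples(index=False):
        assert small_panel.in_target(row.contig, int(row.pos))
        assert small_panel.reference[row.contig][row.pos - 1] == row.ref


def test_same_seed_reproduces_everything(small_panel, small_config):
    t1 = simulate_genotypes(small_panel, small_config)
    t2 = simulate_genotypes(small_panel, small_config)
    pd.testing.assert_frame_equal(t1.sites, t2.sites)
    pd.testing.assert_frame_equal(t1.samples, t2.samples)
    assert (t1.genotypes == t2.genotypes).all()
    r1, s1 = simulate_reads(small_panel, t1, small_config)
    r2, s2 = simulate_reads(small_panel, t2, small_config)
    pd.testing.assert_frame_equal(r1, r2)
    assert s1 == s2


def test_mean_depth_matches_poisson_target(small_panel, errorfree_cohort, errorfree_config):
    truth, reads, _ = errorfree_cohort
    # raw per-sample coverage at target sites (pre-dedup, pre-mapq) ~ Poisson(42)
    sample = truth.samples["sample"].iloc[0]
    barcode = truth.samples["barcode"].iloc[0]
    own = reads[reads["tag"] == barcode]
    n_positions = sum(
        len(small_panel.target_positions(c)) for c in small_panel.target_intervals
    )
    depth_total = 0
    for contig in small_panel.target_intervals:
        positions = small_panel.target_positions(contig)
        sub = own[own["contig"] == contig]
        starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
        depth_total += sum(
            int(((starts <= p) & (ends >= p)).sum()) for p in positions
        )
    mean_depth = depth_total / n_positions
    # duplicates add dup_rate on top of the Poisson(42) fragment coverage
    expect = 42 * (1 + errorfree_config.dup_rate)
    se = np.sqrt(expect / n_positions) * 3  # generous: sites are correlated
    assert abs(mean_depth - expect) < max(3 * se, 2.0)


def test_error_free_reads_match_haplotypes(small_panel):
    config = SimConfig(
        base_error_model=BaseErrorModel(quality_levels=(90,), weights=(1.0,)),
        tag_error_rate=0.0,
        common_risk=None,
        rare_burden=None,
        n_common_background=0,
        n_rare_background=0,
        n_deletion_sites=0,
        seed=9,
    )
    truth = simulate_genotypes(small_panel, config)
    reads, _ = simulate_reads(small_panel, truth, config)
    # no variants + no errors -> every read equals the reference
    for row in reads.sample(n=min(len(reads), 300), random_state=0).itertuples(index=False):
        assert row.bases == small_panel.reference[row.contig][row.start - 1 : row.end]


def test_on_target_fraction_bookkeeping(small_cohort, small_config):
    _, _, stats = small_cohort
    frac = stats.on_target_reads / stats.total_reads
    assert frac == pytest.approx(small_config.on_target_fraction, abs=1e-3)


def test_duplicate_bookkeeping_limits(small_panel, errorfree_config):
    from dataclasses import replace

    truth = simulate_genotypes(small_panel, errorfree_config)
    nodup = replace(errorfree_config, dup_rate=0.0)
    reads, stats = simulate_reads(small_panel, truth, nodup)
    assert stats.duplicate_fragments == 0
    heavy = replace(errorfree_config, dup_rate=0.5)
    reads2, stats2 = simulate_reads(small_panel, truth, heavy)
    n_frag = len(reads2) - stats2.duplicate_fragments
    assert stats2.duplicate_fragments / n_frag == pytest.approx(0.5, abs=0.05)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(dup_rate=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(mean_depth=0).validate()
    with pytest.raises(ValueError):
        SimConfig(common_risk=CommonRisk(q=0.2, odds_ratio=0)).validate()
    with pytest.raises(ValueError):
        SimConfig(rare_burden=RareBurden(control_maf=0)).validate()


def test_risk_site_outside_panel_rejected(small_panel, small_config):
    from dataclasses import replace

    bad = replace(small_config, common_risk=CommonRisk(site=("chr1", 10**7)))
    with pytest.raises(ValueError, match="outside"):
        simulate_genotypes(small_panel, bad)


def test_hwe_matrix_shapes_and_freqs():
    rng = np.random.default_rng(4)
    m = hwe_genotype_matrix(500, 600, [0.3, 0.1], [0.3, 0.1], rng)
    assert m.genotypes.shape == (1100, 2)
    stats = m.minor_allele_stats()
    assert stats["maf"].iloc[0] == pytest.approx(0.3, abs=0.03)
    assert m.genotyping_success() == 1.0
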