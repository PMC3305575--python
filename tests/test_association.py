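"""Allelic association screen: tabulation, Fisher test, OR/CI, filters, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoseq.association import (ScreenConfig, allele_table, fisher_two_sided,
                                 min_detectable_mac, odds_ratio_ci, screen,
                                 associate_site)
from hemoseq.gmatrix import HET, HOMREF, HOMVAR, MISSING
from hemoseq.sim import hwe_genotype_matrix

from .conftest import make_matrix
from .oracles import fisher_enumeration


class TestAlleleTable:
    def test_hand_tabulation(self):
        # 10 case hets, nothing else variant -> case minor = 10
        matrix = make_matrix([[HET]] * 10, [[HOMREF]] * 10)
        assert allele_table(matrix, 0) == (10, 10, 0, 20)

    def test_monomorphic_minor_zero(self):
        matrix = make_matrix([[HOMREF]] * 5, [[HOMREF]] * 5)
        assert allele_table(matrix, 0) == (0, 10, 0, 10)

    def test_minor_allele_defined_on_pool(self):
        # alt frequency > 0.5 pooled: the REFERENCE allele is minor
        matrix = make_matrix([[HOMVAR]] * 6, [[HET]] * 4)
        a, b, c, d = allele_table(matrix, 0)
        assert (a, b, c, d) == (0, 12, 4, 4)

    def test_missing_excluded_and_fully_missing_raises(self):
        matrix = make_matrix([[HET], [MISSING]], [[HOMREF]])
        assert allele_table(matrix, 0) == (1, 1, 0, 2)
        empty = make_matrix([[MISSING]], [[MISSING]])
        with pytest.raises(ValueError, match="missing"):
            allele_table(empty, 0)

    def test_known_genotype_counts_tabulate_exactly(self):
        matrix = make_matrix(
            [[HET], [HET], [HOMVAR], [HOMREF]], [[HET], [HOMREF], [HOMREF]]
        )
        # cases: 2 het + 1 homvar = 4 alt of 8; controls: 1 het = 1 of 6
        assert allele_table(matrix, 0) == (4, 4, 1, 5)


class TestFisher:
    def test_worked_example(self):
        assert fisher_two_sided([[10, 10], [4, 20]]) == pytest.approx(0.0253, abs=2e-4)

    def test_identical_rows_p_one(self):
        assert fisher_two_sided([[7, 13], [7, 13]]) == 1.0

    def test_label_symmetry(self):
        assert fisher_two_sided([[10, 10], [4, 20]]) == pytest.approx(
            fisher_two_sided([[4, 20], [10, 10]])
        )

    def test_zero_margin_convention(self):
        assert fisher_two_sided([[0, 0], [5, 5]]) == 1.0
        assert fisher_two_sided([[0, 10], [0, 12]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided([[-1, 2], [3, 4]])

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert fisher_two_sided([[a, b], [c, d]]) == pytest.approx(
            fisher_enumeration(a, b, c, d), abs=1e-9
        )


class TestOddsRatio:
    def test_cross_product_example(self):
        or_, lo, hi = odds_ratio_ci([[453, 965], [312, 1092]])
        assert or_ == pytest.approx(1.643, abs=1e-3)
        assert lo < or_ < hi

    def test_identical_rows_unity(self):
        or_, lo, hi = odds_ratio_ci([[10, 10], [10, 10]])
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_zero_cell_finite_via_haldane(self):
        or_, lo, hi = odds_ratio_ci([[4, 16], [0, 24]])
        assert np.isfinite(or_) and np.isfinite(hi) and or_ > 1

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        table = [[30, 70], [20, 80]]
        or_, lo, hi = odds_ratio_ci(table)
        t22 = sm.Table2x2(np.array(table))
        assert or_ == pytest.approx(t22.oddsratio)
        slo, shi = t22.oddsratio_confint()
        assert lo == pytest.approx(slo) and hi == pytest.approx(shi)


class TestScreen:
    def test_maf_floor_boundary(self):
        # pooled MAF 0.07 < 0.08 excluded; 0.10 kept (50 individuals, complete)
        geno_7 = [[HET]] * 7 + [[HOMREF]] * 18
        geno_10 = [[HET]] * 10 + [[HOMREF]] * 15
        m7 = make_matrix(geno_7, [[HOMREF]] * 25)
        m10 = make_matrix(geno_10, [[HOMREF]] * 25)
        assert screen(m7)[0].empty
        assert len(screen(m10)[0]) == 1

    def test_missingness_boundary_exclusive(self):
        # 2/20 = 0.10 missing -> excluded ("less than 10%" required)
        rows = [[HET]] * 9 + [[MISSING]] * 2 + [[HOMREF]] * 9
        m = make_matrix(rows[:10], rows[10:])
        assert m.missingness()[0] == pytest.approx(0.10)
        assert screen(m)[0].empty
        rows_ok = [[HET]] * 9 + [[MISSING]] + [[HOMREF]] * 10
        m_ok = make_matrix(rows_ok[:10], rows_ok[10:])
        assert len(screen(m_ok)[0]) == 1

    def test_ranking_and_topk(self):
        rng = np.random.default_rng(8)
        case_f = np.array([0.45, 0.25, 0.25, 0.25, 0.25, 0.25, 0.25])
        ctrl_f = np.full(7, 0.25)
        m = hwe_genotype_matrix(300, 300, case_f, ctrl_f, rng)
        ranked, top = screen(m, ScreenConfig(top_k=3))
        assert len(top) == 3
        assert ranked["p"].is_monotonic_increasing
        assert top["site_id"].iloc[0] == "chrS:1:A:G"

    def test_fewer_survivors_than_topk_returns_all(self):
        m = make_matrix([[HET]] * 10, [[HOMREF]] * 15)
        ranked, top = screen(m, ScreenConfig(top_k=5))
        assert len(ranked) == len(top) == 1

    def test_type_one_error_controlled_conservatively(self):
        """Fisher on small discrete tables rejects at no more than the nominal
        rate; at 22 individuals the attainable size is well below 0.05."""
        rng = np.random.default_rng(55)
        n_rej = n_test = 0
        for _ in range(60):
            mafs = rng.uniform(0.08, 0.5, size=96)
            m = hwe_genotype_matrix(10, 12, mafs, mafs, rng)
            ranked, _ = screen(m)
            n_test += len(ranked)
            n_rej += int((ranked["p"] < 0.05).sum())
        rate = n_rej / n_test
        se = np.sqrt(0.05 * 0.95 / n_test)
        assert rate <= 0.05 + 3 * se
        assert rate > 0.001  # the test does reject sometimes


class TestMinDetectableMac:
    def test_worked_example(self):
        # 10 cases + 12 controls -> 20 vs 24 alleles; m = 4 (MAF ~ 9.1%)
        assert min_detectable_mac(20, 24, 0.05) == 4

    def test_alpha_one_returns_single_allele(self):
        assert min_detectable_mac(20, 24, 1.0) == 1

    def test_monotone_in_sample_size(self):
        grid = [(20, 24), (40, 48), (80, 96), (200, 240)]
        macs = [min_detectable_mac(a, b, 0.05) for a, b in grid]
        mafs = [m / (a + b) for m, (a, b) in zip(macs, grid)]
        assert mafs == sorted(mafs, reverse=True)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            min_detectable_mac(0, 10)


def test_power_matches_two_proportion_approximation():
    """Empirical screen power at OR 1.5, q 0.25, 719+719 individuals agrees
    with the closed-form two-proportion approximation."""
    from hemoseq.replication import two_proportion_power
    from hemoseq.sim import case_frequency

    q, orr = 0.25, 1.5
    p_case = case_frequency(q, orr)
    approx = two_proportion_power(p_case, q, 2 * 719, 2 * 719, alpha=0.05)
    rng = np.random.default_rng(99)
    hits = 0
    reps = 150
    for _ in range(reps):
        m = hwe_genotype_matrix(719, 719, [p_case], [q], rng)
        hits += associate_site(m, 0).p < 0.05
    emp = hits / reps
    se = np.sqrt(approx * (1 - approx) / reps)
    assert abs(emp - approx) < 4 * se + 0.02
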