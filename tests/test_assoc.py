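"""Allelic association statistics against independent oracles.

The chi-square oracle is the generic observed-vs-expected Pearson sum
computed cell by cell; the HWE oracle enumerates every heterozygote
configuration with exact rational arithmetic. Both are deliberately
separate code paths from the implementation.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from ibdnet.assoc import (
    AlleleCount2x2,
    DegenerateInputError,
    QcThresholds,
    allelic_chi2,
    chi2_sf,
    count_alleles,
    hwe_exact,
    odds_ratio,
    odds_ratio_from_freqs,
    qc_filter,
    run_association,
)
from ibdnet.io import MISSING, GenotypeMatrix, SnpMeta
from ibdnet.synthetic import SnpSimSpec, simulate_genotypes


def _matrix(case_calls, ctrl_calls):
    calls = np.array([[c] for c in case_calls + ctrl_calls], dtype=np.int8)
    samples = [f"s{i}" for i in range(len(case_calls) + len(ctrl_calls))]
    groups = {
        s: ("CD" if i < len(case_calls) else "HC") for i, s in enumerate(samples)
    }
    return GenotypeMatrix(
        samples=samples, groups=groups, snps=[SnpMeta("rs1")], calls=calls
    )


class TestCountAlleles:
    def test_direct_count(self):
        m = _matrix([2, 1, 0], [0, 0])
        t = count_alleles(m, "rs1", "CD", "HC")
        assert (t.a, t.b, t.c, t.d) == (3, 3, 0, 4)

    def test_missing_excluded(self):
        m = _matrix([1, MISSING], [1])
        t = count_alleles(m, "rs1", "CD", "HC")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_missing_group_is_degenerate(self):
        m = _matrix([MISSING, MISSING], [1])
        with pytest.raises(DegenerateInputError):
            count_alleles(m, "rs1", "CD", "HC")

    @given(
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=20),
        st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=20),
    )
    def test_matches_per_cell_tally(self, case_calls, ctrl_calls):
        if all(c == MISSING for c in case_calls) or all(c == MISSING for c in ctrl_calls):
            return
        m = _matrix(case_calls, ctrl_calls)
        t = count_alleles(m, "rs1", "CD", "HC")
        a = sum(c for c in case_calls if c != MISSING)
        b = sum(2 - c for c in case_calls if c != MISSING)
        c_ = sum(c for c in ctrl_calls if c != MISSING)
        d = sum(2 - c for c in ctrl_calls if c != MISSING)
        assert (t.a, t.b, t.c, t.d) == (a, b, c_, d)


def pearson_oracle(t: AlleleCount2x2) -> float:
    """Observed-vs-expected chi-square summed cell by cell."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    exp = np.outer(rows, cols) / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


class TestAllelicChi2:
    def test_identical_groups_is_zero(self):
        chi2, df = allelic_chi2(AlleleCount2x2(10, 10, 10, 10))
        assert chi2 == 0.0 and df == 1

    def test_perfect_separation_equals_n(self):
        chi2, _ = allelic_chi2(AlleleCount2x2(20, 0, 0, 20))
        assert chi2 == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            allelic_chi2(AlleleCount2x2(0, 10, 0, 10))

    @given(st.tuples(*[st.integers(0, 100)] * 4))
    def test_equals_pearson_cellwise_oracle(self, cells):
        t = AlleleCount2x2(*cells)
        margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
        if 0 in margins:
            return
        chi2, _ = allelic_chi2(t)
        assert chi2 == pytest.approx(pearson_oracle(t), rel=1e-12)


class TestChi2Sf:
    def test_zero_statistic(self):
        assert chi2_sf(0.0, 1) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 1)

    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_df1_closed_form(self, x):
        assert chi2_sf(x, 1) == pytest.approx(2 * (1 - norm.cdf(math.sqrt(x))), abs=1e-10)

    def test_monotone_decreasing(self):
        xs = [0.0, 0.5, 1.0, 3.84, 10.0, 30.0]
        ps = [chi2_sf(x, 1) for x in xs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)


class TestOddsRatio:
    def test_equal_frequencies_give_unity(self):
        or_, lo, hi = odds_ratio(AlleleCount2x2(42, 58, 42, 58))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_cross_product_quotient(self):
        or_, _, _ = odds_ratio(AlleleCount2x2(10, 90, 5, 95))
        assert or_ == pytest.approx((10 * 95) / (90 * 5))

    @given(st.tuples(*[st.integers(1, 50)] * 4), st.integers(2, 9))
    def test_scale_invariance(self, cells, k):
        t1 = AlleleCount2x2(*cells)
        t2 = AlleleCount2x2(*(k * c for c in cells))
        assert odds_ratio(t1)[0] == pytest.approx(odds_ratio(t2)[0], rel=1e-12)

    def test_zero_cell_conventions(self):
        assert odds_ratio(AlleleCount2x2(0, 10, 5, 5))[0] == 0.0
        assert odds_ratio(AlleleCount2x2(5, 0, 5, 5))[0] == math.inf
        or_, lo, hi = odds_ratio(AlleleCount2x2(0, 10, 5, 5))
        assert math.isnan(lo) and math.isnan(hi)

    def test_haldane_correction_mode(self):
        or_, lo, hi = odds_ratio(AlleleCount2x2(0, 10, 5, 5), haldane=True)
        assert or_ == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))
        assert 0 < lo < or_ < hi

    def test_ci_brackets_or(self):
        or_, lo, hi = odds_ratio(AlleleCount2x2(30, 70, 10, 90))
        assert lo <= or_ <= hi

    def test_from_freqs_matches_table(self):
        assert odds_ratio_from_freqs(0.420, 0.345) == pytest.approx(1.3760, rel=0.005)


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Exact-arithmetic enumeration over all heterozygote configurations."""
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het
    n2 = 2 * n - n1

    def prob(h: int) -> Fraction:
        x1 = (n1 - h) // 2
        x2 = (n2 - h) // 2
        num = Fraction(math.factorial(n) * 2**h * math.factorial(n1) * math.factorial(n2))
        den = Fraction(
            math.factorial(x1) * math.factorial(h) * math.factorial(x2) * math.factorial(2 * n)
        )
        return num / den

    feasible = [
        h for h in range(min(n1, n2) + 1)
        if (n1 - h) % 2 == 0 and (n2 - h) % 2 == 0 and h >= 0
    ]
    p_obs = prob(n_het)
    return sum(prob(h) for h in feasible if prob(h) <= p_obs)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact(5, 0, 0) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            hwe_exact(0, 0, 0)

    def test_all_het_small_case_vs_enumeration(self):
        # 4 individuals, all heterozygous: feasible het counts {0, 2, 4}
        expected = float(hwe_enumeration_oracle(0, 4, 0))
        assert hwe_exact(0, 4, 0) == pytest.approx(expected, rel=1e-10)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_equals_enumeration_up_to_50(self, x, y, z):
        if x + y + z == 0 or x + y + z > 50:
            return
        expected = float(hwe_enumeration_oracle(x, y, z))
        assert hwe_exact(x, y, z) == pytest.approx(expected, rel=1e-9)


class TestQcFilter:
    def _matrix_with(self, col, groups):
        calls = np.array(col, dtype=np.int8).reshape(-1, 1)
        samples = [f"s{i}" for i in range(len(col))]
        return GenotypeMatrix(
            samples=samples,
            groups={s: groups[i] for i, s in enumerate(samples)},
            snps=[SnpMeta("rs1")],
            calls=calls,
        )

    def test_clean_snp_kept(self):
        m = self._matrix_with([0, 1, 2, 1, 0, 1], ["CD"] * 3 + ["HC"] * 3)
        kept, report = qc_filter(m, QcThresholds(), control_group="HC")
        assert kept == ["rs1"]
        assert report.loc[0, "kept"]

    def test_fully_missing_dropped_for_missing(self):
        m = self._matrix_with([MISSING] * 4, ["CD", "CD", "HC", "HC"])
        kept, report = qc_filter(m, QcThresholds(), control_group="HC")
        assert kept == []
        assert report.loc[0, "fail_reason"] == "missing"

    def test_rare_allele_dropped_for_maf(self):
        m = self._matrix_with([0] * 19 + [1], ["CD"] * 10 + ["HC"] * 10)
        kept, report = qc_filter(m, QcThresholds(min_maf=0.05), control_group="HC")
        assert kept == []
        assert report.loc[0, "fail_reason"] == "maf"

    def test_planted_hwe_violation_dropped(self):
        # controls: 40 heterozygotes, no homozygotes -- gross HWE violation
        m = self._matrix_with([0, 2] * 5 + [1] * 40, ["CD"] * 10 + ["HC"] * 40)
        kept, report = qc_filter(
            m, QcThresholds(min_hwe_p=1e-6), control_group="HC"
        )
        assert kept == []
        assert report.loc[0, "fail_reason"] == "hwe"
        assert report.loc[0, "hwe_p"] < 1e-6


class TestRunAssociation:
    def test_planted_effect_recovered(self):
        specs = [SnpSimSpec(f"rs{i:03d}", 0.3, 2.5 if i == 0 else 1.0) for i in range(20)]
        m = simulate_genotypes(500, 500, specs, seed=7)
        results = run_association(m, "CD", "HC", alpha=0.05)
        assert "rs000" in [r.snp.snp_id for r in results]
        top = {r.snp.snp_id: r for r in results}["rs000"]
        assert 1.8 < top.or_ < 3.4
        assert top.ci_low <= top.or_ <= top.ci_high

    def test_alpha_one_reports_everything_sorted(self):
        specs = [SnpSimSpec(f"rs{i:03d}", 0.4) for i in range(10)]
        m = simulate_genotypes(50, 50, specs, seed=1)
        results = run_association(m, "CD", "HC", alpha=1.0)
        assert len(results) == 10
        keys = [(r.p, r.snp.snp_id) for r in results]
        assert keys == sorted(keys)

    def test_unknown_group_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            run_association(tiny_matrix, "XX", "HC")

    def test_snp_subset_restriction(self):
        specs = [SnpSimSpec(f"rs{i:03d}", 0.4) for i in range(5)]
        m = simulate_genotypes(50, 50, specs, seed=2)
        results = run_association(m, "CD", "HC", alpha=1.0, snp_ids=["rs001", "rs003"])
        assert {r.snp.snp_id for r in results} <= {"rs001", "rs003"}
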