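"""Agreement statistics: ANOVA components, ICC, CCC/OCCC, SEM, Bland-Altman,
paired t.  Independent oracles: direct sums-of-squares by definition, hand
evaluations of the formulas, and pingouin as an external cross-check for ICC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirrormetry.agreement import (
    AgreementError,
    MeasurementMatrix,
    anova_components,
    bland_altman,
    ccc_pair,
    icc_absolute,
    occc,
    paired_t,
    sem,
    theoretical_icc_avg,
)
from mirrormetry.phantom import simulate_matrix_from_components


def anova_oracle(vals):
    """Two-way sums of squares computed directly from the definition with
    explicit loops — independent of the implementation under test."""
    n, k = vals.shape
    grand = sum(sum(row) for row in vals) / (n * k)
    rows = [sum(vals[i]) / k for i in range(n)]
    cols = [sum(vals[:, j]) / n for j in range(k)]
    ss_s = k * sum((r - grand) ** 2 for r in rows)
    ss_r = n * sum((c - grand) ** 2 for c in cols)
    ss_e = sum((vals[i, j] - rows[i] - cols[j] + grand) ** 2
               for i in range(n) for j in range(k))
    ms_s, ms_r, ms_e = ss_s / (n - 1), ss_r / (k - 1), ss_e / ((n - 1) * (k - 1))
    return (ms_s - ms_e) / k, (ms_r - ms_e) / n, ms_e


class TestAnovaComponents:
    def test_matches_direct_definition_on_integer_matrix(self):
        vals = np.array([[3, 5, 4], [7, 9, 8], [2, 4, 6], [10, 12, 11]], float)
        comp = anova_components(vals)
        s2s, s2r, s2e = anova_oracle(vals)
        assert comp.sigma2_s == pytest.approx(s2s, abs=1e-12)
        assert comp.sigma2_r == pytest.approx(s2r, abs=1e-12)
        assert comp.sigma2_e == pytest.approx(s2e, abs=1e-12)

    def test_column_shift_structure(self):
        """Columns equal to column 1 plus constants: zero residual, observer
        component from the shift spread, subject component from the rows."""
        base = np.array([1.0, 4.0, 2.0, 8.0])
        delta = np.array([0.0, 2.0, 5.0])
        vals = base[:, None] + delta[None, :]
        comp = anova_components(vals)
        assert comp.sigma2_e == pytest.approx(0.0, abs=1e-12)
        s2s, s2r, s2e = anova_oracle(vals)
        assert comp.sigma2_r == pytest.approx(s2r, abs=1e-12)
        assert comp.sigma2_s == pytest.approx(s2s, abs=1e-12)

    def test_constant_matrix_flagged_zero(self):
        comp = anova_components(np.full((5, 3), 7.0))
        assert comp.zero_variance
        assert comp.sigma2_s == comp.sigma2_r == comp.sigma2_e == 0.0

    def test_small_matrices_rejected(self):
        with pytest.raises(AgreementError):
            anova_components(np.ones((1, 3)))
        with pytest.raises(AgreementError):
            anova_components(np.ones((5, 1)))


class TestICC:
    def test_identical_columns_give_perfect_icc(self):
        vals = np.repeat(np.array([[1.0], [3.0], [7.0], [2.0]]), 3, axis=1)
        res = icc_absolute(vals)
        assert res.icc_avg == pytest.approx(1.0, abs=1e-12)
        assert res.icc_single == pytest.approx(1.0, abs=1e-12)
        assert res.ci95_avg == (1.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cross_check_against_pingouin(self, seed):
        """Point estimates, CIs and p-values agree with pingouin's ICC2/ICC2k
        (two-way random, absolute agreement)."""
        import pandas as pd
        import pingouin as pg

        m = simulate_matrix_from_components(25, 3, 1.5, 0.2, 0.7,
                                            rng=np.random.default_rng(seed))
        res = icc_absolute(m)
        df = pd.DataFrame({"subject": np.repeat(np.arange(25), 3),
                           "rater": np.tile(np.arange(3), 25),
                           "score": m.values.ravel()})
        ref = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        assert res.icc_single == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        assert res.icc_avg == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        assert res.p_value == pytest.approx(ref.loc["ICC(A,1)", "pval"], rel=1e-6)
        # pingouin rounds its CI bounds to two decimals
        np.testing.assert_allclose(res.ci95_single, ref.loc["ICC(A,1)", "CI95"], atol=6e-3)
        np.testing.assert_allclose(res.ci95_avg, ref.loc["ICC(A,k)", "CI95"], atol=6e-3)

    def test_no_subject_signal_gives_near_zero_icc(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4000, 3))  # zero subject variance
        res = icc_absolute(vals)
        assert abs(res.icc_avg) < 0.05

    def test_single_below_average_and_ci_brackets_estimate(self):
        m = simulate_matrix_from_components(40, 3, 1.0, 0.1, 0.5,
                                            rng=np.random.default_rng(8))
        res = icc_absolute(m)
        assert res.icc_single <= res.icc_avg <= 1.0
        assert res.ci95_avg[0] <= res.icc_avg <= res.ci95_avg[1]
        assert res.ci95_single[0] <= res.icc_single <= res.ci95_single[1]

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_invariance_to_affine_rescaling(self, shift, scale):
        m = simulate_matrix_from_components(20, 3, 1.0, 0.3, 0.4,
                                            rng=np.random.default_rng(12))
        a = icc_absolute(m.values)
        b = icc_absolute(scale * m.values + shift)
        assert b.icc_avg == pytest.approx(a.icc_avg, abs=1e-9)
        assert b.icc_single == pytest.approx(a.icc_single, abs=1e-9)


class TestCCC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2, 5, 3])
        assert ccc_pair(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_constant_bias_penalized_monotonically(self):
        x = np.array([1.0, 2, 3, 4, 5])
        vals = [ccc_pair(x, x + c) for c in (0.0, 0.5, 1.0, 2.0)]
        assert vals[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_hand_evaluated_example(self):
        """x=(1,2,3), y=(2,4,6) with population moments: cov=4/3, var_x=2/3,
        var_y=8/3, (mean gap)^2=4, so CCC = (8/3)/(22/3) = 4/11."""
        assert ccc_pair([1, 2, 3], [2, 4, 6]) == pytest.approx(4.0 / 11.0, abs=1e-15)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30) + rng.normal() * 2
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc_pair(x, y)) <= abs(r) + 1e-12

    def test_degenerate_pair_is_nan(self):
        assert math.isnan(ccc_pair([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))


class TestOCCC:
    def test_two_raters_reduces_to_pairwise(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.5, 40) + 0.3
        res = occc(np.c_[x, y])
        assert res.overall_ccc == pytest.approx(ccc_pair(x, y), abs=1e-12)

    def test_identical_columns(self):
        vals = np.repeat(np.arange(5.0)[:, None], 3, axis=1)
        assert occc(vals).overall_ccc == pytest.approx(1.0, abs=1e-15)

    def test_overall_is_weighted_average_of_pairwise(self, rng):
        """The overall CCC equals the pairwise CCCs averaged with their own
        denominators as weights, hence lies inside their span."""
        vals = rng.normal(size=(100, 3)) + rng.normal(size=(100, 1)) * 2
        res = occc(vals)
        weights, terms = [], []
        for r in range(2):
            for s in range(r + 1, 3):
                x, y = vals[:, r], vals[:, s]
                w = x.var() + y.var() + (x.mean() - y.mean()) ** 2  # population
                weights.append(w)
                terms.append(w * ccc_pair(x, y))
        assert res.overall_ccc == pytest.approx(sum(terms) / sum(weights), abs=1e-12)
        pw = [res.pairwise[r, s] for r in range(2) for s in range(r + 1, 3)]
        assert min(pw) - 1e-12 <= res.overall_ccc <= max(pw) + 1e-12

    def test_invariance_to_common_shift(self, rng):
        vals = rng.normal(size=(30, 3))
        assert occc(vals + 17.0).overall_ccc == pytest.approx(
            occc(vals).overall_ccc, abs=1e-12)


class TestSEM:
    def test_arithmetic_examples(self):
        vals = np.array([[1.0, 2], [3, 4], [5, 6]])
        res = sem(vals, 0.75)
        assert res.sem == pytest.approx(res.sigma_used * 0.5, abs=1e-15)
        assert sem(vals, 1.0).sem == 0.0

    def test_identity_and_monotonicity(self, rng):
        vals = rng.normal(10, 12.0, size=(200, 3))
        iccs = [0.5, 0.75, 0.91, 0.99]
        sems = [sem(vals, i).sem for i in iccs]
        sigma = vals.std(ddof=1)
        for i, s in zip(iccs, sems):
            assert s == pytest.approx(sigma * math.sqrt(1 - i), abs=1e-12)
        assert all(a > b for a, b in zip(sems, sems[1:]))


class TestBlandAltman:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2, 3, 4])
        res = bland_altman(x, x)
        assert res.mean_diff == res.sd_diff == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.pct_within == 100.0

    def test_antisymmetry_of_sign_convention(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert a.mean_diff == pytest.approx(-b.mean_diff, abs=1e-12)
        assert a.sd_diff == pytest.approx(b.sd_diff, abs=1e-12)
        assert a.pct_within == b.pct_within

    def test_limits_are_mean_plus_minus_1p96_sd(self, rng):
        x, y = rng.normal(size=80), rng.normal(size=80)
        res = bland_altman(x, y)
        d = x - y
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)

    def test_short_input_rejected(self):
        with pytest.raises(AgreementError):
            bland_altman([1.0], [2.0])


class TestPairedT:
    def test_identical_inputs(self):
        x = np.array([1.0, 2, 3])
        res = paired_t(x, x)
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_computed_example(self):
        """pre=(10,12,14,16), post=(5,6,7,8): differences (5,6,7,8), mean 6.5,
        sd sqrt(5/3)=1.29099, t = 6.5/(1.29099/2) = 10.0697."""
        res = paired_t([10, 12, 14, 16], [5, 6, 7, 8])
        assert res.t == pytest.approx(6.5 / (math.sqrt(5.0 / 3.0) / 2.0), abs=1e-12)
        assert res.t == pytest.approx(10.07, abs=0.005)
        assert res.df == 3
        from scipy.stats import ttest_rel
        ref = ttest_rel([10, 12, 14, 16], [5, 6, 7, 8])
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.flagged and math.isnan(res.t)

    def test_strong_reduction_detected(self, rng):
        pre = rng.normal(20, 5, 100)
        post = rng.normal(8, 2, 100)
        res = paired_t(pre, post)
        assert res.t > 0 and res.p < 0.001


class TestMeasurementMatrix:
    def test_listwise_deletion_counts(self):
        vals = np.arange(12.0).reshape(4, 3)
        vals[1, 2] = np.nan
        m = MeasurementMatrix(vals, indicator="d1", phase="pre")
        complete, dropped = m.drop_incomplete()
        assert dropped == 1 and complete.n_subjects == 3
        assert complete.meta["n_dropped"] == 1

    def test_incomplete_matrix_rejected_by_statistics(self):
        vals = np.ones((4, 3))
        vals[0, 0] = np.nan
        with pytest.raises(AgreementError, match="missing"):
            anova_components(vals)
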