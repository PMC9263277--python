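import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import exact_mean_sd
from isofv.agreement_stats import (
    MDC_FACTOR,
    PairedSample,
    agreement_report,
    bland_altman,
    icc_two_way,
    mdc,
    paired_comparison,
    sem_cv,
    shapiro_gate,
)
from isofv.errors import (
    InsufficientSampleError,
    InsufficientVariationError,
    UndefinedCVError,
    UndefinedICCError,
)


def paired_from_diffs(mean_diff, sd_diff, n, cand_mean=20.0, seed=0):
    """PairedSample whose differences have exactly the requested mean and SD."""
    d = exact_mean_sd(mean_diff, sd_diff, n, seed=seed)
    cand = exact_mean_sd(cand_mean, 1.0, n, seed=seed + 1)
    return PairedSample(reference=cand + d, candidate=cand)


class TestPairedComparison:
    def test_published_t_from_summary(self):
        # mean difference -0.2, SD 0.44, n=22 -> t = -2.13
        pc = paired_comparison(paired_from_diffs(-0.2, 0.44, 22))
        assert round(pc.t_statistic, 2) == -2.13
        assert pc.df == 21

    def test_second_published_t(self):
        # mean difference -0.54, SD 0.75, n=22 -> t = -3.38
        pc = paired_comparison(paired_from_diffs(-0.54, 0.75, 22))
        assert round(pc.t_statistic, 2) == -3.38

    def test_identity(self):
        x = np.linspace(1, 5, 10)
        pc = paired_comparison(PairedSample(x, x))
        assert pc.bias == 0.0 and pc.t_statistic == 0.0 and pc.p_value == 1.0

    def test_constant_offset_gives_infinite_t(self):
        x = np.linspace(1, 5, 10)
        pc = paired_comparison(PairedSample(x + 2.0, x))
        assert pc.t_statistic == math.inf and pc.p_value == 0.0

    def test_matches_scipy(self, rng):
        a = rng.normal(10, 2, 22)
        b = a + rng.normal(0.5, 1, 22)
        pc = paired_comparison(PairedSample(a, b))
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert pc.t_statistic == pytest.approx(t_ref, rel=1e-12)
        assert pc.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_effect_size_is_bias_over_sd(self):
        pc = paired_comparison(paired_from_diffs(0.46, 0.41, 22))
        assert pc.effect_size == pytest.approx(0.46 / 0.41, rel=1e-9)
        assert round(pc.effect_size, 2) == 1.12  # magnitude regime of the fit comparison

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 1000))
    def test_antisymmetry_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(10, 2, 12)
        b = rng.normal(11, 2, 12)
        fwd = paired_comparison(PairedSample(a, b))
        rev = paired_comparison(PairedSample(b, a))
        assert fwd.bias == pytest.approx(-rev.bias, rel=1e-9, abs=1e-12)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic, rel=1e-9, abs=1e-12)
        assert fwd.effect_size == pytest.approx(-rev.effect_size, rel=1e-9, abs=1e-12)


def brute_force_icc(data, form, definition):
    """Independent ICC oracle: explicit loop-based ANOVA decomposition."""
    n, k = data.shape
    grand = sum(data[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(data[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(data[i, j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((m - grand) ** 2 for m in row_means)
    ssm = n * sum((m - grand) ** 2 for m in col_means)
    sse = sum(
        (data[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msb = ssb / (n - 1)
    msm = ssm / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if definition == "consistency":
        if form == "single":
            return (msb - mse) / (msb + (k - 1) * mse)
        return (msb - mse) / msb
    if form == "single":
        return (msb - mse) / (msb + (k - 1) * mse + k / n * (msm - mse))
    return (msb - mse) / (msb + (msm - mse) / n)


class TestICC:
    @pytest.mark.parametrize("form", ["single", "average"])
    @pytest.mark.parametrize("definition", ["consistency", "agreement"])
    def test_matches_brute_force_oracle(self, rng, form, definition):
        for _ in range(1000):
            data = rng.normal(20, 5, (6, 2)) + rng.normal(0, 2, (6, 1))
            sample = PairedSample(data[:, 0], data[:, 1])
            got = icc_two_way(sample, form=form, definition=definition)
            want = brute_force_icc(data, form, definition)
            assert got.value == pytest.approx(want, rel=1e-10, abs=1e-12)

    @pytest.mark.parametrize(
        ("form", "definition", "picc_type"),
        [
            ("single", "consistency", "ICC(C,1)"),
            ("average", "consistency", "ICC(C,k)"),
            ("single", "agreement", "ICC(A,1)"),
            ("average", "agreement", "ICC(A,k)"),
        ],
    )
    def test_matches_pingouin(self, rng, form, definition, picc_type):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        a = rng.normal(25, 4, 22)
        b = a + rng.normal(-0.3, 1.2, 22)
        sample = PairedSample(a, b)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(22), 2),
                "rater": np.tile(["A", "B"], 22),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        icc_table = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        got = icc_two_way(sample, form=form, definition=definition)
        row = icc_table.loc[picc_type]
        assert got.value == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin prints its CI rounded to 2 decimals
        assert got.ci_lower == pytest.approx(row["CI95"][0], abs=0.011)
        assert got.ci_upper == pytest.approx(row["CI95"][1], abs=0.011)

    def test_offset_consistency_vs_agreement(self):
        x = np.array([10.0, 12.0, 15.0, 18.0, 21.0, 25.0, 30.0])
        offset = PairedSample(x, x + 3.0)
        cons = icc_two_way(offset, definition="consistency")
        agree = icc_two_way(offset, definition="agreement")
        assert cons.value == pytest.approx(1.0)
        assert agree.value < 1.0

    def test_identity_all_forms_one(self):
        x = np.array([10.0, 12.0, 15.0, 18.0, 21.0])
        for form in ("single", "average"):
            for definition in ("consistency", "agreement"):
                res = icc_two_way(PairedSample(x, x.copy()), form=form, definition=definition)
                assert res.value == pytest.approx(1.0)

    def test_zero_between_subject_variance(self):
        x = np.full(8, 5.0)
        with pytest.raises(UndefinedICCError):
            icc_two_way(PairedSample(x, x + 0.0))

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(50):
            a = rng.normal(20, 5, 15)
            b = a + rng.normal(0, 2, 15)
            res = icc_two_way(PairedSample(a, b))
            assert res.ci_lower <= res.value <= res.ci_upper


class TestSemCV:
    def test_published_cv_kf(self):
        # method means 15.01/15.27, sd_bias 0.63 -> CV 2.94%
        sample = paired_from_diffs(15.01 - 15.27, 0.63, 22, cand_mean=15.27)
        sc = sem_cv(sample)
        assert round(sc.cv_percent, 2) == 2.94

    def test_published_cv_ke(self):
        # method means 27.98/28.13, sd_bias 1.72 -> CV 4.335% (printed as 4.33)
        sample = paired_from_diffs(27.98 - 28.13, 1.72, 22, cand_mean=28.13)
        sc = sem_cv(sample)
        assert sc.cv_percent == pytest.approx(4.33, abs=0.01)
        assert sc.cv_percent == pytest.approx((1.72 / math.sqrt(2)) / 28.055 * 100, rel=1e-9)

    def test_zero_sd(self):
        x = np.linspace(10, 20, 8)
        sc = sem_cv(PairedSample(x, x.copy()))
        assert sc.sem == 0.0 and sc.cv_percent == 0.0

    def test_near_zero_grand_mean(self):
        x = np.array([-1.0, 0.0, 1.0])
        with pytest.raises(UndefinedCVError):
            sem_cv(PairedSample(x, -x))

    def test_ci_ratio_structure_n22(self):
        # bounds/cv = sqrt(21/chi2_{0.975,21}) and sqrt(21/chi2_{0.025,21})
        sample = paired_from_diffs(-0.3, 1.1, 22)
        sc = sem_cv(sample)
        assert sc.cv_ci_lower / sc.cv_percent == pytest.approx(0.7694, abs=1e-4)
        assert sc.cv_ci_upper / sc.cv_percent == pytest.approx(1.4291, abs=1e-4)

    def test_both_sem_variants_reported(self):
        sample = paired_from_diffs(-0.3, 1.0, 22)
        sc = sem_cv(sample)
        assert sc.sem == pytest.approx(1.0 / math.sqrt(2), rel=1e-9)
        assert sc.sem_mean_diff == pytest.approx(1.0 / math.sqrt(22), rel=1e-9)


class TestMDC:
    @pytest.mark.parametrize(
        ("sem", "expected"), [(0.17, 0.47), (0.04, 0.11), (0.0, 0.0)]
    )
    def test_published_values(self, sem, expected):
        assert round(mdc(sem), 2) == expected

    @given(st.floats(0.0, 100.0))
    def test_fixed_ratio(self, sem):
        assert mdc(sem) == pytest.approx(MDC_FACTOR * sem, rel=1e-12)
        if sem > 1e-9:
            assert mdc(sem) / sem == pytest.approx(2.7719, abs=1e-4)


class TestBlandAltman:
    def test_closed_form_limits(self):
        sample = paired_from_diffs(-0.35, 1.42, 22)
        ba = bland_altman(sample)
        assert ba.loa_lower == pytest.approx(-0.35 - 1.96 * 1.42, rel=1e-9)
        assert ba.loa_upper == pytest.approx(-0.35 + 1.96 * 1.42, rel=1e-9)
        assert ba.loa_lower == pytest.approx(-3.13, abs=5e-3)
        assert ba.loa_upper == pytest.approx(2.43, abs=5e-3)

    def test_identical_series(self):
        x = np.linspace(5, 9, 10)
        ba = bland_altman(PairedSample(x, x.copy()))
        assert ba.bias == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_normal_coverage(self, rng):
        d = rng.normal(0, 1, 10_000)
        base = rng.normal(50, 5, 10_000)
        ba = bland_altman(PairedSample(base + d, base))
        inside = np.mean((ba.differences >= ba.loa_lower) & (ba.differences <= ba.loa_upper))
        assert inside == pytest.approx(0.95, abs=0.01)


class TestShapiroGate:
    def test_normal_acceptance_rate(self):
        # at alpha 0.05, ~95% of normal samples should pass
        passed = 0
        rng = np.random.default_rng(42)
        for _ in range(1000):
            passed += shapiro_gate(rng.normal(0, 1, 22)).passed
        assert 0.92 <= passed / 1000 <= 0.98

    def test_skewed_rejection_rate(self):
        rejected = 0
        rng = np.random.default_rng(42)
        for _ in range(1000):
            rejected += not shapiro_gate(rng.exponential(1.0, 22)).passed
        assert rejected / 1000 > 0.30  # well above the 5% nominal rate

    def test_constant_sample(self):
        with pytest.raises(InsufficientVariationError):
            shapiro_gate(np.full(10, 3.0))

    def test_too_small(self):
        with pytest.raises(InsufficientSampleError):
            shapiro_gate([1.0, 2.0])


class TestAgreementReport:
    def test_internal_invariants(self, rng):
        a = rng.normal(25, 4, 22)
        b = a + rng.normal(-0.3, 1.2, 22)
        rep = agreement_report(PairedSample(a, b, "F0"))
        assert rep.loa_lower == pytest.approx(rep.bias - 1.96 * rep.sd_bias, rel=1e-9)
        assert rep.loa_upper == pytest.approx(rep.bias + 1.96 * rep.sd_bias, rel=1e-9)
        assert rep.mdc == pytest.approx(MDC_FACTOR * rep.sem, rel=1e-9)
        assert rep.icc_single.ci_lower <= rep.icc_single.value <= rep.icc_single.ci_upper
        assert rep.cv_ci_lower < rep.cv_percent < rep.cv_ci_upper
        assert rep.n == 22 and rep.df == 21
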