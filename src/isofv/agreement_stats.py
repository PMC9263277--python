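"""Between-method agreement statistics battery.

For each force-velocity parameter, a pair of per-subject series (reference
method vs candidate method) is summarized by: paired t-test with Cohen's d,
two-way mixed intraclass correlations (single- and average-measures, with
F-distribution 95% confidence intervals), standard error of measurement and
within-individual coefficient of variation (chi-square CI), minimal detectable
change, and Bland-Altman limits of agreement.

Conventions chosen deliberately (see the module's documentation of record):

* SEM for the CV is ``sd_bias / sqrt(2)`` — the standard error of measurement
  of a single method estimated from paired differences — and the CV
  denominator is the grand mean of the two method means. The alternative
  ``sd_bias / sqrt(n)`` (standard error of the mean difference) is reported
  alongside as ``sem_mean_diff``, clearly labelled.
* Cohen's d for paired data = mean difference / SD of differences.
* ICC defaults to the consistency definition of the two-way mixed model;
  the absolute-agreement definition is available via ``definition``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientSampleError,
    InsufficientVariationError,
    UndefinedCVError,
    UndefinedICCError,
)

__all__ = [
    "PairedSample",
    "PairedComparison",
    "ICCResult",
    "SemCV",
    "BlandAltman",
    "NormalityResult",
    "AgreementReport",
    "paired_comparison",
    "icc_two_way",
    "sem_cv",
    "mdc",
    "bland_altman",
    "shapiro_gate",
    "agreement_report",
]

#: 1.96 * sqrt(2): multiplier turning a SEM into a minimal detectable change.
MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class PairedSample:
    """Matched per-subject values from a reference and a candidate method."""

    reference: np.ndarray
    candidate: np.ndarray
    parameter_label: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        cand = np.asarray(self.candidate, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "candidate", cand)
        if ref.shape != cand.shape or ref.ndim != 1:
            raise InsufficientSampleError("reference and candidate must be equal-length 1-D")
        if ref.size < 3:
            raise InsufficientSampleError(f"need n >= 3 paired values, got {ref.size}")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(cand))):
            raise InsufficientSampleError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.reference.size)

    @property
    def differences(self) -> np.ndarray:
        return self.reference - self.candidate


@dataclass(frozen=True)
class PairedComparison:
    bias: float
    sd_bias: float
    t_statistic: float
    p_value: float
    df: int
    effect_size: float


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_lower: float
    ci_upper: float
    form: str
    definition: str


@dataclass(frozen=True)
class SemCV:
    """SEM (sd_bias/sqrt(2)), within-individual CV% with chi-square 95% CI."""

    sem: float
    cv_percent: float
    cv_ci_lower: float
    cv_ci_upper: float
    sem_mean_diff: float  # sd_bias / sqrt(n), the SE of the mean difference


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    differences: np.ndarray


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool


@dataclass(frozen=True)
class AgreementReport:
    """The full statistics battery for one parameter and one method comparison."""

    parameter_label: str
    n: int
    mean_ref: float
    sd_ref: float
    mean_cand: float
    sd_cand: float
    bias: float
    sd_bias: float
    t_statistic: float
    p_value: float
    df: int
    effect_size: float
    icc_single: ICCResult
    icc_average: ICCResult
    sem: float
    sem_mean_diff: float
    cv_percent: float
    cv_ci_lower: float
    cv_ci_upper: float
    mdc: float
    loa_lower: float
    loa_upper: float


def paired_comparison(sample: PairedSample) -> PairedComparison:
    """Paired-sample t-test and Cohen's d on reference minus candidate.

    bias = mean(ref - cand); t = bias / (sd_bias / sqrt(n)); p two-sided with
    n-1 df; effect_size = bias / sd_bias. A zero-variance difference series
    yields t = +/-inf with p = 0, or t = 0 with p = 1 when bias is also zero.
    """
    d = sample.differences
    n = sample.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    # constant differences up to float rounding count as zero-variance
    scale = max(float(np.abs(sample.reference).max()), float(np.abs(sample.candidate).max()), 1.0)
    if sd <= 1e-12 * scale:
        if abs(bias) <= 1e-12 * scale:
            return PairedComparison(0.0, 0.0, 0.0, 1.0, df, 0.0)
        t = math.inf if bias > 0 else -math.inf
        return PairedComparison(bias, 0.0, t, 0.0, df, math.copysign(math.inf, bias))
    t = bias / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedComparison(bias, sd, float(t), float(p), df, bias / sd)


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """(MS_subjects, MS_methods, MS_error) of an n x k two-way layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_two_way(
    sample: PairedSample,
    form: Literal["single", "average"] = "single",
    definition: Literal["consistency", "agreement"] = "consistency",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way mixed-model intraclass correlation with 95% CI (k = 2 methods).

    Shrout-Fleiss / McGraw-Wong mean-square formulas on the subjects-by-methods
    ANOVA. ``consistency`` corresponds to ICC(3,1)/ICC(3,k); ``agreement`` to
    the absolute-agreement forms (same point estimates as ICC(2,.) for the
    mixed model). Confidence limits use the F-distribution method.
    """
    if form not in ("single", "average"):
        raise ValueError(f"form must be 'single' or 'average', got {form!r}")
    if definition not in ("consistency", "agreement"):
        raise ValueError(f"unknown definition {definition!r}")
    data = np.column_stack([sample.reference, sample.candidate])
    n, k = data.shape
    if n < 5:
        warnings.warn(f"ICC CI is unstable for n = {n} < 5", UserWarning, stacklevel=2)
    msb, msm, mse = _anova_mean_squares(data)
    if msb <= 0 or np.var(data.mean(axis=1)) < 1e-24:
        raise UndefinedICCError("zero between-subject variance; ICC undefined")

    fdist = stats.f
    if definition == "consistency":
        if mse == 0.0:
            est = 1.0
            return ICCResult(est, est, est, form, definition)
        f_obs = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / fdist.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * fdist.ppf(1 - alpha / 2, df2, df1)
        if form == "single":
            est = (msb - mse) / (msb + (k - 1) * mse)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            est = (msb - mse) / msb
            lo = 1 - 1 / fl
            hi = 1 - 1 / fu
        return ICCResult(float(est), float(lo), float(hi), form, definition)

    # absolute agreement
    denom_s = msb + (k - 1) * mse + (k / n) * (msm - mse)
    if denom_s == 0.0:
        raise UndefinedICCError("degenerate ANOVA decomposition; agreement ICC undefined")
    r_single = (msb - mse) / denom_s
    if mse == 0.0 and msm == 0.0:
        return ICCResult(1.0, 1.0, 1.0, form, definition)
    a = (k * r_single) / (n * (1 - r_single)) if r_single < 1 else math.inf
    b = 1 + (k * r_single * (n - 1)) / (n * (1 - r_single)) if r_single < 1 else math.inf
    if math.isinf(a) or math.isinf(b):
        lo_s = hi_s = 1.0
    else:
        num = (a * msm + b * mse) ** 2
        den = (a * msm) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        nu = num / den if den > 0 else 1.0
        f_lo = fdist.ppf(1 - alpha / 2, n - 1, nu)
        f_up = fdist.ppf(1 - alpha / 2, nu, n - 1)
        common = k * msm + (k * n - k - n) * mse
        lo_s = n * (msb - f_lo * mse) / (f_lo * common + n * msb)
        hi_s = n * (f_up * msb - mse) / (common + n * f_up * msb)
    if form == "single":
        return ICCResult(float(r_single), float(lo_s), float(hi_s), form, definition)
    # average-measures point estimate and Spearman-Brown stepped-up limits
    r_avg = (msb - mse) / (msb + (msm - mse) / n)
    step = lambda r: (k * r) / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else math.nan
    return ICCResult(float(r_avg), float(step(lo_s)), float(step(hi_s)), form, definition)


def sem_cv(sample: PairedSample) -> SemCV:
    """SEM, within-individual CV%, and its chi-square-scaled 95% CI.

    sem = sd_bias/sqrt(2); cv = 100*sem/|grand mean| with grand mean the mean
    of the two method means; CI bounds scale cv by sqrt((n-1)/chi2_{0.975,n-1})
    and sqrt((n-1)/chi2_{0.025,n-1}).
    """
    d = sample.differences
    n = sample.n
    grand = (float(sample.reference.mean()) + float(sample.candidate.mean())) / 2.0
    if abs(grand) < 1e-9:
        raise UndefinedCVError("grand mean is (near) zero; CV undefined")
    sd = float(d.std(ddof=1))
    sem = sd / math.sqrt(2.0)
    cv = 100.0 * sem / abs(grand)
    df = n - 1
    lo = cv * math.sqrt(df / stats.chi2.ppf(0.975, df))
    hi = cv * math.sqrt(df / stats.chi2.ppf(0.025, df))
    return SemCV(sem, cv, lo, hi, sd / math.sqrt(n))


def mdc(sem: float) -> float:
    """Minimal detectable change: 1.96 * sqrt(2) * SEM."""
    if sem < 0:
        raise ValueError(f"sem must be >= 0, got {sem}")
    return MDC_FACTOR * sem


def bland_altman(sample: PairedSample) -> BlandAltman:
    """Bias and 95% limits of agreement, with per-subject (mean, difference) pairs."""
    d = sample.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    means = (sample.reference + sample.candidate) / 2.0
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, means, d)


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality test; ``passed`` is True when p > alpha."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientSampleError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise InsufficientSampleError("Shapiro-Wilk is unreliable for n > 5000")
    if np.ptp(x) == 0:
        raise InsufficientVariationError("constant sample; W undefined")
    w, p = stats.shapiro(x)
    return NormalityResult(float(w), float(p), bool(p > alpha))


def agreement_report(
    sample: PairedSample,
    icc_definition: Literal["consistency", "agreement"] = "consistency",
) -> AgreementReport:
    """Run the complete battery on one paired sample."""
    pc = paired_comparison(sample)
    icc_s = icc_two_way(sample, form="single", definition=icc_definition)
    icc_a = icc_two_way(sample, form="average", definition=icc_definition)
    sc = sem_cv(sample)
    ba = bland_altman(sample)
    return AgreementReport(
        parameter_label=sample.parameter_label,
        n=sample.n,
        mean_ref=float(sample.reference.mean()),
        sd_ref=float(sample.reference.std(ddof=1)),
        mean_cand=float(sample.candidate.mean()),
        sd_cand=float(sample.candidate.std(ddof=1)),
        bias=pc.bias,
        sd_bias=pc.sd_bias,
        t_statistic=pc.t_statistic,
        p_value=pc.p_value,
        df=pc.df,
        effect_size=pc.effect_size,
        icc_single=icc_s,
        icc_average=icc_a,
        sem=sc.sem,
        sem_mean_diff=sc.sem_mean_diff,
        cv_percent=sc.cv_percent,
        cv_ci_lower=sc.cv_ci_lower,
        cv_ci_upper=sc.cv_ci_upper,
        mdc=mdc(sc.sem),
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
    )
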