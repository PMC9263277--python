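"""Screening of all two-velocity combinations against the 9-point method.

For every unordered pair of protocol velocities, each subject's 2-point
profile is compared with their full linear profile; the per-parameter paired
series feed the agreement battery, and validity is judged per parameter by
three criteria: ICC (single) 95% CI lower bound >= 0.75, no systematic bias
(paired-t p >= 0.05), and CV 95% CI lower bound <= 10%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .agreement_stats import AgreementReport, PairedSample, agreement_report
from .errors import InvalidParameterError, NonPhysicalProfileError
from .fv_profiling import FVPoint, FVProfile, fit_linear, two_point_profile

__all__ = [
    "VelocityCombination",
    "ScreeningCriteria",
    "ScreeningResult",
    "PARAMETERS",
    "enumerate_combinations",
    "screen",
    "rank_results",
]

logger = logging.getLogger(__name__)

PARAMETERS = ("F0", "v0", "Sfv", "Pmax")

#: Minimum subjects with a physical 2-point profile for a combination to be evaluable.
MIN_SUBJECTS = 5


class VelocityCombination(NamedTuple):
    low: float
    high: float


@dataclass(frozen=True)
class ScreeningCriteria:
    """Validity thresholds for a 2-point combination.

    ``cv_use_upper_bound=False`` applies the CV criterion to the lower CI bound
    (as published); set True for the conservative upper-bound variant.
    """

    icc_lower_min: float = 0.75
    p_min: float = 0.05
    cv_limit_percent: float = 10.0
    cv_use_upper_bound: bool = False

    def __post_init__(self) -> None:
        if min(self.icc_lower_min, self.p_min, self.cv_limit_percent) <= 0:
            raise InvalidParameterError("all screening thresholds must be positive")

    def is_valid(self, report: AgreementReport) -> bool:
        cv_bound = report.cv_ci_upper if self.cv_use_upper_bound else report.cv_ci_lower
        return (
            report.icc_single.ci_lower >= self.icc_lower_min
            and report.p_value >= self.p_min
            and cv_bound <= self.cv_limit_percent
        )


@dataclass
class ScreeningResult:
    """Agreement battery and validity flags for one combination and one task."""

    task: str
    combination: VelocityCombination
    n_used: int
    n_dropped: int
    evaluable: bool
    reports: dict[str, AgreementReport] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)

    @property
    def overall_valid(self) -> bool:
        return self.evaluable and bool(self.valid) and all(self.valid.values())


def enumerate_combinations(velocities: Iterable[float]) -> list[VelocityCombination]:
    """All unordered pairs of distinct velocities, sorted by (low, high)."""
    vels = [float(v) for v in velocities]
    unique = sorted(set(vels))
    if len(unique) < len(vels):
        warnings.warn("duplicate velocities in input; deduplicated", UserWarning, stacklevel=2)
    if len(unique) < 2:
        return []
    return [
        VelocityCombination(unique[i], unique[j])
        for i in range(len(unique))
        for j in range(i + 1, len(unique))
    ]


def _profile_params(profile: FVProfile) -> dict[str, float]:
    return {"F0": profile.F0, "v0": profile.v0, "Sfv": profile.Sfv, "Pmax": profile.Pmax}


def screen(
    cohort_points: Mapping[str, Sequence[FVPoint]],
    criteria: ScreeningCriteria | None = None,
    task: str = "KE",
    velocities: Sequence[float] | None = None,
    icc_definition: str = "consistency",
) -> list[ScreeningResult]:
    """Screen every two-velocity combination of a cohort against the full linear fit.

    Parameters
    ----------
    cohort_points
        Mapping subject_id -> isokinetic F-v points covering all protocol
        velocities (isometric points must already be excluded).
    criteria
        Validity thresholds; defaults to the published ones.
    velocities
        Protocol set; inferred from the first subject when omitted.

    Subjects whose 2-point profile is non-physical for a given combination are
    dropped pairwise for that combination (count logged and recorded).
    Combinations with fewer than 5 usable subjects are flagged not evaluable.
    """
    if criteria is None:
        criteria = ScreeningCriteria()
    subject_ids = sorted(cohort_points)
    if not subject_ids:
        raise InvalidParameterError("cohort_points is empty")
    if velocities is None:
        velocities = sorted({p.angular_velocity for p in cohort_points[subject_ids[0]]})

    # reference: per-subject full linear profile; subjects failing it drop everywhere
    reference: dict[str, dict[str, float]] = {}
    for sid in subject_ids:
        try:
            profile, _ = fit_linear(list(cohort_points[sid]))
        except NonPhysicalProfileError:
            logger.warning("subject %s: non-physical full linear profile; excluded", sid)
            continue
        reference[sid] = _profile_params(profile)

    by_velocity = {
        sid: {p.angular_velocity: p for p in cohort_points[sid]} for sid in reference
    }

    results: list[ScreeningResult] = []
    for comb in enumerate_combinations(velocities):
        ref_rows: dict[str, list[float]] = {p: [] for p in PARAMETERS}
        cand_rows: dict[str, list[float]] = {p: [] for p in PARAMETERS}
        n_used = 0
        n_dropped = len(subject_ids) - len(reference)
        for sid in reference:
            pts = by_velocity[sid]
            if comb.low not in pts or comb.high not in pts:
                n_dropped += 1
                continue
            try:
                two = two_point_profile(pts[comb.low], pts[comb.high])
            except NonPhysicalProfileError:
                n_dropped += 1
                continue
            cand = _profile_params(two)
            for p in PARAMETERS:
                ref_rows[p].append(reference[sid][p])
                cand_rows[p].append(cand[p])
            n_used += 1
        if n_dropped:
            logger.info(
                "%s %g-%g: %d subject(s) dropped pairwise", task, comb.low, comb.high, n_dropped
            )
        result = ScreeningResult(
            task=task,
            combination=comb,
            n_used=n_used,
            n_dropped=n_dropped,
            evaluable=n_used >= MIN_SUBJECTS,
        )
        if result.evaluable:
            for p in PARAMETERS:
                sample = PairedSample(
                    np.asarray(ref_rows[p]), np.asarray(cand_rows[p]), parameter_label=p
                )
                report = agreement_report(sample, icc_definition=icc_definition)
                result.reports[p] = report
                result.valid[p] = criteria.is_valid(report)
        results.append(result)
    return results


def rank_results(results: Sequence[ScreeningResult], parameter: str) -> list[ScreeningResult]:
    """Order screening results for one parameter: valid first, then by
    descending single-measures ICC, ascending CV, and (low, high) tie-break."""
    if not results:
        raise InvalidParameterError("results must be non-empty")
    if parameter not in PARAMETERS:
        raise InvalidParameterError(f"unknown parameter {parameter!r}")

    def key(r: ScreeningResult):
        if not r.evaluable or parameter not in r.reports:
            return (1, 1, 0.0, float("inf"), r.combination)
        rep = r.reports[parameter]
        return (
            0 if r.valid.get(parameter, False) else 1,
            0,
            -rep.icc_single.value,
            rep.cv_percent,
            r.combination,
        )

    return sorted(results, key=key)
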