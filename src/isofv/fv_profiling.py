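"""Force-velocity profile construction and fitting.

Peak torques are converted to external force (torque divided by lever length,
allometrically normalized by body mass^(2/3)) and linear velocity (angular
velocity in rad/s times lever length). Profiles are summarized by the
force-axis intercept F0, velocity-axis intercept v0 = -F0/Sfv, slope Sfv, and
maximal theoretical power Pmax = F0*v0/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegeneratePairError,
    InvalidMeasurementError,
    InvalidParameterError,
    NonPhysicalProfileError,
    RankDeficiencyError,
)

__all__ = [
    "Anthropometrics",
    "FVPoint",
    "FVProfile",
    "FitQuality",
    "F0Comparison",
    "to_fv_point",
    "normalize_force",
    "fit_linear",
    "fit_polynomial",
    "two_point_profile",
    "derive_parameters",
    "fisher_z",
    "compare_f0_to_isometric",
]

DEG_TO_RAD = math.pi / 180.0

#: Allometric body-mass exponent used for force normalization.
DEFAULT_MASS_EXPONENT = 2.0 / 3.0


@dataclass(frozen=True)
class Anthropometrics:
    """Per-subject body mass (kg) and dynamometer lever length (m)."""

    subject_id: str
    body_mass: float
    lever_length: float

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise InvalidParameterError(f"body_mass must be > 0, got {self.body_mass}")
        if not 0.1 < self.lever_length < 0.6:
            raise InvalidParameterError(
                f"lever_length must be in (0.1, 0.6) m, got {self.lever_length}"
            )


@dataclass(frozen=True)
class FVPoint:
    """One (velocity, normalized force) observation at one isokinetic setting.

    ``velocity`` is linear velocity in m/s; ``force`` is in N kg^(-2/3).
    """

    angular_velocity: float
    velocity: float
    force: float
    task_label: str = "KE"


@dataclass(frozen=True)
class FVProfile:
    """Fitted force-velocity profile for one subject and one method.

    ``Sfv`` is the fitted slope (negative for physical profiles); v0 and Pmax
    are derived as v0 = -F0/Sfv and Pmax = F0*v0/4. For polynomial fits v0 may
    be undefined (no admissible root), flagged via ``v0_defined``.
    """

    method: str
    F0: float
    v0: float
    Sfv: float
    Pmax: float
    velocities_used: tuple[float, ...] = field(default_factory=tuple)
    v0_defined: bool = True


@dataclass(frozen=True)
class FitQuality:
    """Fit diagnostics: correlation r, determination R^2, Fisher-transformed z'.

    For linear fits ``r`` is the signed Pearson correlation of force vs
    velocity (negative for physical profiles). For polynomial fits it is the
    correlation between observed and fitted force. ``z_prime`` is atanh(r),
    +/-inf when |r| == 1 (perfect fit, flagged rather than raised).
    """

    r: float
    r_squared: float
    z_prime: float

    @property
    def perfect(self) -> bool:
        return not math.isfinite(self.z_prime)


@dataclass(frozen=True)
class F0Comparison:
    """Signed difference and ratio of fitted F0 to measured isometric force."""

    difference: float
    ratio: float


def normalize_force(
    peak_torque: float, anthro: Anthropometrics, mass_exponent: float = DEFAULT_MASS_EXPONENT
) -> float:
    """Torque (N m) -> allometrically normalized force (N kg^-exponent)."""
    if peak_torque <= 0:
        raise InvalidMeasurementError(f"peak_torque must be > 0, got {peak_torque}")
    return (peak_torque / anthro.lever_length) / anthro.body_mass**mass_exponent


def to_fv_point(
    peak_torque: float,
    angular_velocity: float,
    anthro: Anthropometrics,
    task_label: str = "KE",
    mass_exponent: float = DEFAULT_MASS_EXPONENT,
) -> FVPoint:
    """Convert one peak torque at one angular velocity to a normalized F-v point.

    Velocity conversion uses radians: v = omega * (pi/180) * lever_length.
    """
    if angular_velocity < 0:
        raise InvalidParameterError("angular_velocity must be >= 0")
    force = normalize_force(peak_torque, anthro, mass_exponent)
    velocity = angular_velocity * DEG_TO_RAD * anthro.lever_length
    return FVPoint(
        angular_velocity=angular_velocity,
        velocity=velocity,
        force=force,
        task_label=task_label,
    )


def derive_parameters(F0: float, Sfv: float) -> tuple[float, float]:
    """(v0, Pmax) from the force intercept and slope: v0 = -F0/Sfv, Pmax = F0*v0/4."""
    if F0 <= 0:
        raise NonPhysicalProfileError(f"F0 must be > 0, got {F0}")
    if Sfv >= 0:
        raise NonPhysicalProfileError(f"Sfv must be < 0, got {Sfv}; v0 undefined")
    v0 = -F0 / Sfv
    return v0, F0 * v0 / 4.0


def fisher_z(r: float) -> float:
    """Fisher z-transformation z' = atanh(r); |r| must be < 1."""
    if not -1.0 < r < 1.0:
        raise InvalidParameterError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def _z_prime(r: float) -> float:
    """atanh with signed infinities at |r| == 1, for perfect-fit flagging."""
    if r >= 1.0:
        return math.inf
    if r <= -1.0:
        return -math.inf
    return math.atanh(r)


def _check_points(points: Sequence[FVPoint], min_distinct: int) -> tuple[np.ndarray, np.ndarray]:
    v = np.array([p.velocity for p in points], dtype=float)
    f = np.array([p.force for p in points], dtype=float)
    if np.unique(v).size < min_distinct:
        raise RankDeficiencyError(
            f"need >= {min_distinct} distinct velocities, got {np.unique(v).size}"
        )
    if np.any(f <= 0):
        raise InvalidMeasurementError("all forces must be > 0")
    return v, f


def fit_linear(points: Sequence[FVPoint], min_points: int = 2) -> tuple[FVProfile, FitQuality]:
    """Ordinary least squares of normalized force on linear velocity.

    F0 is the intercept, Sfv the slope; v0 and Pmax follow from
    :func:`derive_parameters`. A non-negative slope is a non-physical profile.
    """
    v, f = _check_points(points, max(min_points, 2))
    slope, intercept = np.polyfit(v, f, 1)
    if slope >= 0:
        raise NonPhysicalProfileError(
            f"fitted slope {slope:g} >= 0: force does not decrease with velocity"
        )
    v0, pmax = derive_parameters(float(intercept), float(slope))
    fitted = intercept + slope * v
    ss_res = float(np.sum((f - fitted) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    # residuals at float-rounding level count as a perfect fit
    if ss_tot <= 0 or ss_res <= 1e-12 * ss_tot:
        r2 = 1.0
    else:
        r2 = min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)
    # signed correlation of force with velocity: -sqrt(R^2) for a decreasing line
    r = -math.sqrt(r2)
    profile = FVProfile(
        method="linear",
        F0=float(intercept),
        v0=v0,
        Sfv=float(slope),
        Pmax=pmax,
        velocities_used=tuple(sorted({p.angular_velocity for p in points})),
    )
    return profile, FitQuality(r=r, r_squared=r2, z_prime=_z_prime(r))


def fit_polynomial(points: Sequence[FVPoint], degree: int = 2) -> tuple[FVProfile, FitQuality]:
    """Least-squares polynomial (default quadratic) of force on velocity.

    F0 is the value at v = 0. v0 is the smallest real root greater than the
    largest observed velocity when one exists; otherwise the profile carries
    ``v0_defined=False`` and NaN for v0/Pmax. Sfv is reported as the
    polynomial's slope at the midpoint of the observed velocity range.
    """
    v, f = _check_points(points, degree + 1)
    coeffs = np.polynomial.polynomial.polyfit(v, f, degree)  # low -> high order
    f0 = float(coeffs[0])
    fitted = np.polynomial.polynomial.polyval(v, coeffs)

    v_mid = (v.min() + v.max()) / 2.0
    dcoeffs = np.polynomial.polynomial.polyder(coeffs)
    sfv = float(np.polynomial.polynomial.polyval(v_mid, dcoeffs))

    roots = np.polynomial.polynomial.polyroots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    admissible = np.sort(real[real > v.max()])
    if admissible.size:
        v0 = float(admissible[0])
        pmax = f0 * v0 / 4.0
        v0_defined = True
    else:
        v0, pmax, v0_defined = math.nan, math.nan, False

    ss_res = float(np.sum((f - fitted) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    if ss_tot <= 0 or ss_res <= 1e-12 * ss_tot:
        r2, r = 1.0, 1.0
    else:
        r2 = min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)
        r = math.sqrt(r2)
    profile = FVProfile(
        method=f"polynomial{degree}",
        F0=f0,
        v0=v0,
        Sfv=sfv,
        Pmax=pmax,
        velocities_used=tuple(sorted({p.angular_velocity for p in points})),
        v0_defined=v0_defined,
    )
    return profile, FitQuality(r=r, r_squared=r2, z_prime=_z_prime(r))


def two_point_profile(p_low: FVPoint, p_high: FVPoint) -> FVProfile:
    """Exact line through two F-v points; the 2-point method.

    Equivalent to :func:`fit_linear` restricted to the same two points.
    """
    if p_low.velocity == p_high.velocity:
        raise DegeneratePairError(f"both points at velocity {p_low.velocity:g} m/s")
    if p_low.velocity > p_high.velocity:
        p_low, p_high = p_high, p_low
    if p_low.force <= 0 or p_high.force <= 0:
        raise InvalidMeasurementError("forces must be > 0")
    if p_high.force >= p_low.force:
        raise NonPhysicalProfileError(
            "force does not decrease from the low- to the high-velocity point"
        )
    sfv = (p_high.force - p_low.force) / (p_high.velocity - p_low.velocity)
    f0 = p_low.force - sfv * p_low.velocity
    v0, pmax = derive_parameters(f0, sfv)
    return FVProfile(
        method="two_point",
        F0=f0,
        v0=v0,
        Sfv=sfv,
        Pmax=pmax,
        velocities_used=(p_low.angular_velocity, p_high.angular_velocity),
    )


def compare_f0_to_isometric(profile_F0: float, isometric_force: float) -> F0Comparison:
    """Signed difference (F0 - iso) and ratio (F0/iso), both in normalized units."""
    if profile_F0 <= 0 or isometric_force <= 0:
        raise InvalidParameterError("both F0 and isometric force must be > 0")
    return F0Comparison(
        difference=profile_F0 - isometric_force, ratio=profile_F0 / isometric_force
    )
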