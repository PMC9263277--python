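"""Synthetic cohort generator: Hill-type torque-velocity ground truth.

Each simulated subject carries a classical Hill hyperbola per task,
``(T + a)(omega + b) = (T_iso + a) * b`` with ``a = c * T_iso`` and
``b = c * omega_max``, which is concave-up and decreasing on [0, omega_max].
Fitted over the 30-300 deg/s protocol range this yields a quasilinear
relationship whose linear extrapolation F0 sits strictly below the true
isometric force — the structural property the analysis pipeline must detect.

Ground-truth Hill parameters are sampled in normalized-force space (so the
cohort lands in a realistic regime regardless of anthropometrics) and
converted to torque via each subject's lever length and body mass. Measured
peak torques are the noiseless Hill torques perturbed by multiplicative
Gaussian noise. All randomness flows from the single config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import ConfigError, InvalidParameterError
from .fv_profiling import (
    Anthropometrics,
    FitQuality,
    FVPoint,
    FVProfile,
    fit_linear,
    normalize_force,
    to_fv_point,
)
from .signal_processing import TorqueTrace

__all__ = [
    "HillMuscleParams",
    "CohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "hill_torque",
    "sample_cohort",
    "generate_trace",
    "true_linear_profile",
]

PROTOCOL_VELOCITIES = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 300.0)

TASKS = ("KE", "KF")


@dataclass(frozen=True)
class HillMuscleParams:
    """Ground-truth torque-velocity hyperbola for one subject and one task.

    ``curvature`` is the dimensionless Hill constant c = a/T_iso;
    ``max_velocity`` (deg/s) is the torque-axis zero crossing.
    """

    iso_torque: float
    curvature: float
    max_velocity: float
    task_label: str = "KE"

    def __post_init__(self) -> None:
        problems = []
        if self.iso_torque <= 0:
            problems.append(f"iso_torque must be > 0 (got {self.iso_torque})")
        if not 0.1 <= self.curvature <= 0.6:
            problems.append(f"curvature must be in [0.1, 0.6] (got {self.curvature})")
        if self.max_velocity <= 300.0:
            problems.append(f"max_velocity must be > 300 deg/s (got {self.max_velocity})")
        if problems:
            raise ConfigError("; ".join(problems))


def hill_torque(params: HillMuscleParams, omega: float | np.ndarray) -> float | np.ndarray:
    """Hill torque at angular velocity ``omega`` (deg/s), 0 <= omega < max_velocity.

    T(omega) = (T_iso + a) * b / (omega + b) - a with a = c*T_iso, b = c*omega_max,
    so T(0) = T_iso and T(omega_max) = 0 exactly.
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om < 0) or np.any(om >= params.max_velocity):
        raise InvalidParameterError(
            f"omega must lie in [0, max_velocity={params.max_velocity:g}) deg/s"
        )
    a = params.curvature * params.iso_torque
    b = params.curvature * params.max_velocity
    t = (params.iso_torque + a) * b / (om + b) - a
    return float(t) if np.isscalar(omega) else t


@dataclass(frozen=True)
class _TaskRanges:
    """Sampling ranges for one task's Hill parameters (normalized-force space)."""

    iso_force_mean: float
    iso_force_sd: float
    curvature_low: float
    curvature_high: float
    max_velocity_low: float
    max_velocity_high: float


# Defaults calibrated so a 22-subject cohort reproduces the study regimes:
# KE fitted F0 ~ 23-33 N kg^-2/3 > KF F0 ~ 11-19; KF flatter (relatively
# faster), extrapolated v0 ~ 3-3.5 m/s. These are generator defaults, not
# published quantities.
_KE_RANGES = _TaskRanges(31.5, 3.2, 0.20, 0.34, 1000.0, 1500.0)
_KF_RANGES = _TaskRanges(16.6, 2.3, 0.16, 0.28, 1250.0, 1750.0)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; ``seed`` drives every stochastic call."""

    seed: int
    n_subjects: int = 22
    body_mass_mean: float = 63.1
    body_mass_sd: float = 4.4
    lever_mean: float = 0.35
    lever_sd: float = 0.03
    noise_cv: float = 0.03
    velocities: tuple[float, ...] = PROTOCOL_VELOCITIES
    ke_ranges: _TaskRanges = _KE_RANGES
    kf_ranges: _TaskRanges = _KF_RANGES
    sampling_rate: float = 500.0
    trace_noise_nm: float = 1.0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 2:
            problems.append("n_subjects must be >= 2")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if self.body_mass_mean <= 0 or self.body_mass_sd < 0:
            problems.append("body_mass mean/sd invalid")
        if not 0.1 < self.lever_mean < 0.6:
            problems.append("lever_mean must be in (0.1, 0.6) m")
        if len(self.velocities) < 2 or any(v <= 0 for v in self.velocities):
            problems.append("velocities must be >= 2 positive values")
        for task, r in (("ke", self.ke_ranges), ("kf", self.kf_ranges)):
            if r.iso_force_mean <= 0 or r.iso_force_sd < 0:
                problems.append(f"{task}_ranges iso force invalid")
            if not 0.1 <= r.curvature_low <= r.curvature_high <= 0.6:
                problems.append(f"{task}_ranges curvature outside [0.1, 0.6]")
            if not 300.0 < r.max_velocity_low <= r.max_velocity_high:
                problems.append(f"{task}_ranges max_velocity must exceed 300 deg/s")
        if problems:
            raise ConfigError("invalid cohort config: " + "; ".join(problems))


@dataclass(frozen=True)
class SyntheticSubject:
    anthro: Anthropometrics
    hill: dict[str, HillMuscleParams]  # task -> params


@dataclass
class SyntheticCohort:
    """A generated cohort: anthropometrics, Hill truth, and peak-torque tables.

    ``noiseless``/``noisy`` map (task, subject index) rows to torques at the
    protocol velocities; index 0 of each row is the isometric torque (0 deg/s).
    """

    config: CohortConfig
    subjects: list[SyntheticSubject]
    noiseless: dict[str, np.ndarray]  # task -> (n_subjects, 1 + n_velocities)
    noisy: dict[str, np.ndarray]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def torque(self, task: str, subject: int, omega: float, noisy: bool = True) -> float:
        cols = (0.0,) + tuple(self.config.velocities)
        j = cols.index(float(omega))
        table = self.noisy if noisy else self.noiseless
        return float(table[task][subject, j])

    def points(self, task: str, subject: int, noisy: bool = True) -> list[FVPoint]:
        """Normalized isokinetic F-v points for one subject (isometric excluded)."""
        anthro = self.subjects[subject].anthro
        return [
            to_fv_point(self.torque(task, subject, v, noisy=noisy), v, anthro, task_label=task)
            for v in self.config.velocities
        ]

    def isometric_force(self, task: str, subject: int, noisy: bool = True) -> float:
        """Normalized isometric force (N kg^-2/3) for one subject."""
        return normalize_force(
            self.torque(task, subject, 0.0, noisy=noisy), self.subjects[subject].anthro
        )

    def cohort_points(self, task: str, noisy: bool = True) -> dict[str, list[FVPoint]]:
        """subject_id -> isokinetic points, the screening-pipeline input shape."""
        return {
            self.subjects[i].anthro.subject_id: self.points(task, i, noisy=noisy)
            for i in range(self.n_subjects)
        }


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at +/-3 sd (degenerate sd = 0 allowed)."""
    if sd == 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a deterministic cohort from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    masses = _truncnorm(rng, config.body_mass_mean, config.body_mass_sd, n)
    levers = np.clip(_truncnorm(rng, config.lever_mean, config.lever_sd, n), 0.101, 0.599)

    subjects: list[SyntheticSubject] = []
    cols = np.concatenate(([0.0], np.asarray(config.velocities, dtype=float)))
    noiseless = {task: np.empty((n, cols.size)) for task in TASKS}
    noisy = {task: np.empty((n, cols.size)) for task in TASKS}

    for i in range(n):
        anthro = Anthropometrics(f"S{i + 1:02d}", float(masses[i]), float(levers[i]))
        hill: dict[str, HillMuscleParams] = {}
        for task, ranges in (("KE", config.ke_ranges), ("KF", config.kf_ranges)):
            iso_force = float(_truncnorm(rng, ranges.iso_force_mean, ranges.iso_force_sd, 1)[0])
            iso_force = max(iso_force, 1.0)
            iso_torque = iso_force * anthro.lever_length * anthro.body_mass ** (2.0 / 3.0)
            curvature = float(rng.uniform(ranges.curvature_low, ranges.curvature_high))
            max_velocity = float(
                rng.uniform(ranges.max_velocity_low, ranges.max_velocity_high)
            )
            hill[task] = HillMuscleParams(iso_torque, curvature, max_velocity, task)
            truth = hill_torque(hill[task], cols)
            noiseless[task][i] = truth
            eps = rng.normal(0.0, config.noise_cv, size=cols.size) if config.noise_cv else 0.0
            noisy[task][i] = truth * (1.0 + eps)
        subjects.append(SyntheticSubject(anthro, hill))

    return SyntheticCohort(config, subjects, noiseless, noisy)


def true_linear_profile(
    cohort: SyntheticCohort, subject: int, task: str = "KE"
) -> tuple[FVProfile, FitQuality]:
    """Oracle profile: linear fit on the subject's noiseless normalized points."""
    return fit_linear(cohort.points(task, subject, noisy=False))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_trace(
    cohort: SyntheticCohort,
    subject: int,
    omega: float,
    task: str = "KE",
    n_reps: int = 6,
) -> TorqueTrace:
    """Emit a 500 Hz torque-time trace for one subject at one protocol velocity.

    Isokinetic trials contain ``n_reps`` repetitions, each a trapezoidal
    velocity profile (ramp, >=0.3 s plateau, ramp) with a flat-topped torque
    burst peaking inside the plateau. Per-repetition peaks sit slightly below
    the Hill truth except one repetition in the final four that attains it
    exactly, so best-of-last-four recovers the noisy table value. Isometric
    trials (omega == 0) are a 5 s ramp-and-hold at the subject's noisy
    isometric torque. White noise of sd ``config.trace_noise_nm`` scaled by
    ``noise_cv > 0`` is added before output.

    Deterministic: the trace RNG is derived from (config.seed, subject, omega, task).
    """
    cfg = cohort.config
    if omega != 0 and float(omega) not in [float(v) for v in cfg.velocities]:
        raise InvalidParameterError(f"omega {omega} not in protocol set or 0")
    fs = cfg.sampling_rate
    dt = 1.0 / fs
    rng = np.random.default_rng([cfg.seed, subject, int(round(omega * 10)), TASKS.index(task)])
    peak = cohort.torque(task, subject, float(omega), noisy=True)
    noise_sd = cfg.trace_noise_nm if cfg.noise_cv > 0 else 0.0

    if omega == 0:
        t = np.arange(0.0, 5.0, dt)
        torque = peak * _smoothstep(t / 1.5)
        torque = torque + rng.normal(0.0, noise_sd, t.size)
        return TorqueTrace(
            time=t,
            torque=np.maximum(torque, 0.0),
            sampling_rate=fs,
            protocol_velocity=0.0,
            task_label=task,
        )

    # plateau long enough that the torque envelope's flat top (0.2 s) sits
    # fully inside it with 0.7 s smooth edges: keeps zero-phase 5 Hz filter
    # distortion of the peak below 0.2 %
    ramp_s, plateau_s, rest_s, edge_s = 0.15, 1.30, 0.30, 0.70
    rep_len = int(round((rest_s + ramp_s + plateau_s + ramp_s) * fs))
    total = rep_len * n_reps + int(rest_s * fs)
    t = np.arange(total) * dt
    velocity = np.zeros(total)
    torque = np.zeros(total)

    # every rep slightly submaximal except one of the last four at exactly 1.0
    rep_factor = 1.0 - rng.uniform(0.002, 0.02, size=n_reps)
    best = n_reps - 4 + int(rng.integers(0, 4)) if n_reps >= 4 else n_reps - 1
    rep_factor[best] = 1.0

    i_ramp = int(ramp_s * fs)
    i_plat = int(plateau_s * fs)
    for r in range(n_reps):
        start = r * rep_len + int(rest_s * fs)
        sl_up = slice(start, start + i_ramp)
        sl_plat = slice(start + i_ramp, start + i_ramp + i_plat)
        sl_down = slice(start + i_ramp + i_plat, start + 2 * i_ramp + i_plat)
        velocity[sl_up] = omega * np.linspace(0, 1, i_ramp, endpoint=False)
        velocity[sl_plat] = omega
        velocity[sl_down] = omega * np.linspace(1, 0, i_ramp, endpoint=False)
        # smooth flat-topped torque envelope spanning ramps and plateau; the
        # edges are slow relative to the 5 Hz cutoff so zero-phase filtering
        # neither attenuates nor overshoots the flat top
        active = slice(start, start + 2 * i_ramp + i_plat)
        tt = np.arange(2 * i_ramp + i_plat) * dt
        t_end = tt[-1] + dt
        env = _smoothstep(tt / edge_s) * _smoothstep((t_end - tt) / edge_s)
        torque[active] = peak * rep_factor[r] * env

    torque = torque + rng.normal(0.0, noise_sd, total)
    return TorqueTrace(
        time=t,
        torque=torque,
        sampling_rate=fs,
        protocol_velocity=float(omega),
        task_label=task,
        angular_velocity=velocity,
    )
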