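"""Format-stable readers and writers for the pipeline's CSV/JSON tables.

All floating-point output is serialized at 6 significant digits. Every writer
has a matching reader and write -> read -> write is idempotent.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement_stats import BlandAltman
from .combination_screening import PARAMETERS, ScreeningResult
from .errors import MalformedInputError
from .fv_profiling import Anthropometrics, FitQuality, FVPoint, FVProfile
from .signal_processing import TorqueTrace

__all__ = [
    "FLOAT_FORMAT",
    "points_to_frame",
    "frame_to_points",
    "write_points",
    "read_points",
    "profiles_to_frame",
    "write_trace",
    "read_trace",
    "screening_to_frame",
    "write_screening",
    "read_screening",
    "write_agreement_json",
    "write_bland_altman",
]

FLOAT_FORMAT = "%.6g"

POINTS_COLUMNS = ["subject_id", "task", "angular_velocity_dps", "velocity_mps", "force_n_per_kg23"]

PROFILE_COLUMNS = [
    "subject_id", "task", "method", "velocities_used",
    "F0", "v0", "Sfv", "Pmax", "r", "r2", "z_prime",
]

SCREENING_COLUMNS = [
    "task", "parameter", "low_dps", "high_dps",
    "mean_9p", "sd_9p", "mean_2p", "sd_2p",
    "bias", "sd_bias", "t", "p", "es",
    "icc_s", "icc_s_lo", "icc_s_hi", "icc_a", "icc_a_lo", "icc_a_hi",
    "sem", "cv", "cv_lo", "cv_hi", "mdc", "valid", "n",
]


def points_to_frame(points: Mapping[str, Sequence[FVPoint]]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": sid,
            "task": p.task_label,
            "angular_velocity_dps": p.angular_velocity,
            "velocity_mps": p.velocity,
            "force_n_per_kg23": p.force,
        }
        for sid in sorted(points)
        for p in points[sid]
    ]
    return pd.DataFrame(rows, columns=POINTS_COLUMNS)


def frame_to_points(df: pd.DataFrame, task: str | None = None) -> dict[str, list[FVPoint]]:
    missing = set(POINTS_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedInputError(f"points table missing columns: {sorted(missing)}")
    if task is not None:
        df = df[df["task"] == task]
    out: dict[str, list[FVPoint]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), []).append(
            FVPoint(
                angular_velocity=float(row.angular_velocity_dps),
                velocity=float(row.velocity_mps),
                force=float(row.force_n_per_kg23),
                task_label=str(row.task),
            )
        )
    return out


def write_points(points: Mapping[str, Sequence[FVPoint]], path: str | Path) -> None:
    points_to_frame(points).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_points(path: str | Path, task: str | None = None) -> dict[str, list[FVPoint]]:
    return frame_to_points(pd.read_csv(path), task=task)


def profiles_to_frame(
    rows: Sequence[tuple[str, str, FVProfile, FitQuality | None]]
) -> pd.DataFrame:
    """Rows of (subject_id, task, profile, quality-or-None) -> profiles table."""
    out = []
    for sid, task, profile, quality in rows:
        out.append(
            {
                "subject_id": sid,
                "task": task,
                "method": profile.method,
                "velocities_used": ";".join(f"{v:g}" for v in profile.velocities_used),
                "F0": profile.F0,
                "v0": profile.v0,
                "Sfv": profile.Sfv,
                "Pmax": profile.Pmax,
                "r": quality.r if quality else np.nan,
                "r2": quality.r_squared if quality else np.nan,
                "z_prime": quality.z_prime if quality else np.nan,
            }
        )
    return pd.DataFrame(out, columns=PROFILE_COLUMNS)


def write_trace(trace: TorqueTrace, path: str | Path) -> None:
    data = {"time_s": trace.time, "torque_nm": trace.torque}
    if trace.angular_velocity is not None:
        data["velocity_dps"] = trace.angular_velocity
    if trace.angle is not None:
        data["angle_deg"] = trace.angle
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trace(
    path: str | Path,
    sampling_rate: float,
    protocol_velocity: float,
    task_label: str = "KE",
) -> TorqueTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "torque_nm" not in df.columns:
        raise MalformedInputError(f"trace {path} lacks time_s/torque_nm columns")
    return TorqueTrace(
        time=df["time_s"].to_numpy(),
        torque=df["torque_nm"].to_numpy(),
        sampling_rate=sampling_rate,
        protocol_velocity=protocol_velocity,
        task_label=task_label,
        angular_velocity=df["velocity_dps"].to_numpy() if "velocity_dps" in df else None,
        angle=df["angle_deg"].to_numpy() if "angle_deg" in df else None,
    )


def screening_to_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for param in PARAMETERS:
            if param in res.reports:
                rep = res.reports[param]
                rows.append(
                    {
                        "task": res.task,
                        "parameter": param,
                        "low_dps": res.combination.low,
                        "high_dps": res.combination.high,
                        "mean_9p": rep.mean_ref,
                        "sd_9p": rep.sd_ref,
                        "mean_2p": rep.mean_cand,
                        "sd_2p": rep.sd_cand,
                        "bias": rep.bias,
                        "sd_bias": rep.sd_bias,
                        "t": rep.t_statistic,
                        "p": rep.p_value,
                        "es": rep.effect_size,
                        "icc_s": rep.icc_single.value,
                        "icc_s_lo": rep.icc_single.ci_lower,
                        "icc_s_hi": rep.icc_single.ci_upper,
                        "icc_a": rep.icc_average.value,
                        "icc_a_lo": rep.icc_average.ci_lower,
                        "icc_a_hi": rep.icc_average.ci_upper,
                        "sem": rep.sem,
                        "cv": rep.cv_percent,
                        "cv_lo": rep.cv_ci_lower,
                        "cv_hi": rep.cv_ci_upper,
                        "mdc": rep.mdc,
                        "valid": bool(res.valid.get(param, False)),
                        "n": rep.n,
                    }
                )
            else:
                rows.append(
                    {
                        "task": res.task,
                        "parameter": param,
                        "low_dps": res.combination.low,
                        "high_dps": res.combination.high,
                        "valid": False,
                        "n": res.n_used,
                    }
                )
    return pd.DataFrame(rows, columns=SCREENING_COLUMNS)


def write_screening(
    results: Sequence[ScreeningResult],
    path: str | Path,
    header: Mapping[str, object] | None = None,
) -> None:
    """Screening table with '#'-prefixed run-metadata header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        screening_to_frame(results).to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_screening(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_agreement_json(records: Sequence[Mapping[str, object]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(records), indent=1, default=float) + "\n")


def write_bland_altman(
    ba: BlandAltman, subject_ids: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame(
        {"subject_id": list(subject_ids), "mean": ba.means, "value_diff": ba.differences}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)
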