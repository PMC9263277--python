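"""Pipeline orchestration and command-line interface.

Verbs: ``simulate`` (synthetic cohort -> points/anthropometrics/truth),
``signal`` (trace CSVs -> points), ``profile`` (points -> per-subject linear
and polynomial profiles plus fit comparison), ``screen`` (points -> the full
two-velocity combination screening table).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import click
import numpy as np
import pandas as pd
import yaml

from . import io as isofv_io
from .agreement_stats import PairedSample, paired_comparison, shapiro_gate
from .combination_screening import (
    PARAMETERS,
    ScreeningCriteria,
    rank_results,
    screen,
)
from .errors import ConfigError, NonPhysicalProfileError
from .fv_profiling import (
    Anthropometrics,
    compare_f0_to_isometric,
    fit_linear,
    fit_polynomial,
    to_fv_point,
)
from .signal_processing import best_peak_from_trace
from .synthetic_data import (
    PROTOCOL_VELOCITIES,
    CohortConfig,
    _TaskRanges,
    generate_trace,
    sample_cohort,
)

__version__ = "0.1.0"

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration for the profile/screen stages."""

    points: str
    out_dir: str
    tasks: tuple[str, ...] = ("KE", "KF")
    filter_cutoff: float = 5.0
    filter_order: int = 2
    velocities: tuple[float, ...] = PROTOCOL_VELOCITIES
    mass_exponent: float = 2.0 / 3.0
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    icc_definition: str = "consistency"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not Path(self.points).exists():
            problems.append(f"points path does not exist: {self.points}")
        if self.mass_exponent <= 0:
            problems.append("mass_exponent must be > 0")
        if any(t not in ("KE", "KF") for t in self.tasks):
            problems.append(f"tasks must be KE/KF, got {self.tasks}")
        if self.icc_definition not in ("consistency", "agreement"):
            problems.append(f"unknown icc_definition {self.icc_definition!r}")
        if problems:
            raise ConfigError("invalid pipeline config: " + "; ".join(problems))

    def content_hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "criteria": asdict(self.criteria)}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata_header(config: PipelineConfig) -> dict[str, object]:
    return {
        "isofv_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
    }


def run_profile(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Per-subject linear and polynomial profiles plus the group fit comparison.

    The fit comparison runs a paired t-test on |z'| (Fisher-transformed fit
    correlations) of the polynomial vs linear methods; it is skipped with a
    recorded reason when any fit is perfect (infinite z'). When isometric
    points (0 deg/s) are present, fitted F0 is compared with the measured
    normalized isometric force per subject.
    """
    config.validate()
    out: dict = {"tasks": {}}
    profile_rows = []
    for task in config.tasks:
        points = isofv_io.read_points(config.points, task=task)
        if not points:
            continue
        task_summary: dict = {"n_subjects": len(points), "excluded": []}
        lin_z, poly_z, iso_ratios = [], [], []
        for sid in sorted(points):
            iso = [p for p in points[sid] if p.angular_velocity == 0]
            kin = [p for p in points[sid] if p.angular_velocity > 0]
            if len({p.angular_velocity for p in kin}) < 3:
                task_summary["excluded"].append({"subject": sid, "reason": "too few velocities"})
                logger.warning("%s %s excluded: too few velocities", task, sid)
                continue
            try:
                lin_profile, lin_q = fit_linear(kin)
            except NonPhysicalProfileError as exc:
                task_summary["excluded"].append({"subject": sid, "reason": str(exc)})
                continue
            poly_profile, poly_q = fit_polynomial(kin)
            profile_rows.append((sid, task, lin_profile, lin_q))
            profile_rows.append((sid, task, poly_profile, poly_q))
            lin_z.append(abs(lin_q.z_prime))
            poly_z.append(abs(poly_q.z_prime))
            if iso:
                cmp_ = compare_f0_to_isometric(lin_profile.F0, iso[0].force)
                iso_ratios.append(cmp_.ratio)
        # |z'| > 9 means r^2 > 1 - 3e-8: a fit perfect up to serialization
        # rounding, where comparing fit quality is meaningless
        z_perfect = 9.0
        if lin_z and all(math.isfinite(z) and z < z_perfect for z in lin_z + poly_z):
            sample = PairedSample(np.array(lin_z), np.array(poly_z), "z_prime")
            pc = paired_comparison(sample)
            task_summary["fit_comparison"] = {
                "mean_z_linear": float(np.mean(lin_z)),
                "mean_z_polynomial": float(np.mean(poly_z)),
                "bias": pc.bias,
                "sd_bias": pc.sd_bias,
                "t": pc.t_statistic,
                "p": pc.p_value,
                "effect_size": pc.effect_size,
                "n": sample.n,
            }
        else:
            task_summary["fit_comparison"] = {
                "skipped": "perfect fit (infinite z') for at least one subject"
            }
        if iso_ratios:
            task_summary["f0_vs_isometric"] = {
                "mean_ratio": float(np.mean(iso_ratios)),
                "n": len(iso_ratios),
                "fraction_underestimating": float(np.mean(np.array(iso_ratios) < 1.0)),
            }
        out["tasks"][task] = task_summary

    profiles = isofv_io.profiles_to_frame(profile_rows)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles.to_csv(out_dir / "profiles.csv", index=False, float_format=isofv_io.FLOAT_FORMAT)
    (out_dir / "fit_comparison.json").write_text(
        json.dumps({**_metadata_header(config), **out}, indent=1) + "\n"
    )
    return profiles, out


def run_screen(config: PipelineConfig) -> pd.DataFrame:
    """Full two-velocity combination screen for each configured task."""
    config.validate()
    all_results = []
    ranked_summary: dict = {}
    for task in config.tasks:
        points = isofv_io.read_points(config.points, task=task)
        if not points:
            continue
        kin = {
            sid: [p for p in pts if p.angular_velocity > 0] for sid, pts in points.items()
        }
        results = screen(
            kin,
            criteria=config.criteria,
            task=task,
            velocities=[v for v in config.velocities],
            icc_definition=config.icc_definition,
        )
        all_results.extend(results)
        ranked_summary[task] = {
            param: [
                f"{r.combination.low:g}-{r.combination.high:g}"
                for r in rank_results(results, param)[:5]
            ]
            for param in PARAMETERS
        }
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    isofv_io.write_screening(all_results, out_dir / "screening.csv", _metadata_header(config))
    (out_dir / "ranking.json").write_text(
        json.dumps({**_metadata_header(config), "top5": ranked_summary}, indent=1) + "\n"
    )
    return isofv_io.screening_to_frame(all_results)


# ---------------------------------------------------------------------------
# CLI


def _cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("ke_ranges", "kf_ranges"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = _TaskRanges(**raw[key])
    if "velocities" in raw:
        raw["velocities"] = tuple(float(v) for v in raw["velocities"])
    try:
        return CohortConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid cohort config {path}: {exc}") from exc


def _pipeline_config(points: str, out: str, task: str, criteria_path: str | None, seed: int
                     ) -> PipelineConfig:
    tasks = ("KE", "KF") if task == "both" else (task,)
    criteria = ScreeningCriteria()
    if criteria_path:
        raw = yaml.safe_load(Path(criteria_path).read_text()) or {}
        criteria = ScreeningCriteria(**raw)
    return PipelineConfig(points=points, out_dir=out, tasks=tasks, criteria=criteria, seed=seed)


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Isokinetic force-velocity profiling pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML cohort config; defaults used when omitted.")
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--traces/--no-traces", default=False, help="Also emit per-trial trace CSVs.")
def simulate(config_path: str | None, seed: int | None, out_dir: str, traces: bool) -> None:
    """Generate a synthetic cohort: points, anthropometrics, and ground truth."""
    if config_path:
        config = _cohort_config_from_yaml(config_path)
    else:
        config = CohortConfig(seed=0)
    if seed is not None:
        config = replace(config, seed=seed)
    cohort = sample_cohort(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    points: dict[str, list] = {}
    for task in ("KE", "KF"):
        for i, subject in enumerate(cohort.subjects):
            sid = subject.anthro.subject_id
            row = points.setdefault(sid, [])
            row.append(
                to_fv_point(cohort.torque(task, i, 0.0), 0.0, subject.anthro, task_label=task)
            )
            row.extend(cohort.points(task, i))
    isofv_io.write_points(points, out / "points.csv")

    pd.DataFrame(
        [
            {
                "subject_id": s.anthro.subject_id,
                "body_mass_kg": s.anthro.body_mass,
                "lever_m": s.anthro.lever_length,
            }
            for s in cohort.subjects
        ]
    ).to_csv(out / "anthropometrics.csv", index=False, float_format=isofv_io.FLOAT_FORMAT)

    truth = {
        "seed": config.seed,
        "subjects": {
            s.anthro.subject_id: {
                task: {
                    "iso_torque_nm": s.hill[task].iso_torque,
                    "curvature": s.hill[task].curvature,
                    "max_velocity_dps": s.hill[task].max_velocity,
                }
                for task in ("KE", "KF")
            }
            for s in cohort.subjects
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")

    if traces:
        trace_dir = out / "traces"
        trace_dir.mkdir(exist_ok=True)
        for task in ("KE", "KF"):
            for i, subject in enumerate(cohort.subjects):
                sid = subject.anthro.subject_id
                for omega in (0.0,) + tuple(config.velocities):
                    trace = generate_trace(cohort, i, omega, task=task)
                    isofv_io.write_trace(trace, trace_dir / f"{sid}_{task}_{omega:g}.csv")
    click.echo(f"cohort of {cohort.n_subjects} subjects written to {out}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True,
              help="YAML listing trace entries: path, subject_id, task, "
                   "protocol_velocity_dps, body_mass_kg, lever_m, [sampling_rate_hz].")
@click.option("--out", "out_path", type=click.Path(), required=True)
@click.option("--cutoff", type=float, default=5.0, show_default=True)
@click.option("--order", type=int, default=2, show_default=True)
def signal(config_path: str, out_path: str, cutoff: float, order: int) -> None:
    """Extract best peaks from torque-time trace CSVs and emit a points table."""
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    entries = raw.get("traces", [])
    if not entries:
        raise ConfigError(f"{config_path} lists no traces")
    points: dict[str, list] = {}
    for entry in entries:
        anthro = Anthropometrics(
            str(entry["subject_id"]), float(entry["body_mass_kg"]), float(entry["lever_m"])
        )
        omega = float(entry["protocol_velocity_dps"])
        trace = isofv_io.read_trace(
            entry["path"],
            sampling_rate=float(entry.get("sampling_rate_hz", 500.0)),
            protocol_velocity=omega,
            task_label=str(entry.get("task", "KE")),
        )
        peak = best_peak_from_trace(trace, cutoff=cutoff, order=order)
        points.setdefault(anthro.subject_id, []).append(
            to_fv_point(peak, omega, anthro, task_label=trace.task_label)
        )
    isofv_io.write_points(points, out_path)
    click.echo(f"wrote {sum(len(v) for v in points.values())} points to {out_path}")


@cli.command()
@click.option("--points", type=click.Path(exists=True), required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--task", type=click.Choice(["KE", "KF", "both"]), default="both")
@click.option("--seed", type=int, default=0)
def profile(points: str, out_dir: str, task: str, seed: int) -> None:
    """Fit linear and polynomial profiles; compare fits and F0 vs isometric."""
    config = _pipeline_config(points, out_dir, task, None, seed)
    profiles, _summary = run_profile(config)
    click.echo(f"wrote {len(profiles)} profiles to {out_dir}/profiles.csv")


@cli.command("screen")
@click.option("--points", type=click.Path(exists=True), required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--task", type=click.Choice(["KE", "KF", "both"]), default="both")
@click.option("--criteria", "criteria_path", type=click.Path(exists=True), default=None,
              help="YAML with icc_lower_min, p_min, cv_limit_percent, cv_use_upper_bound.")
@click.option("--seed", type=int, default=0)
def screen_cmd(points: str, out_dir: str, task: str, criteria_path: str | None, seed: int) -> None:
    """Screen all two-velocity combinations against the full linear method."""
    config = _pipeline_config(points, out_dir, task, criteria_path, seed)
    table = run_screen(config)
    n_valid = int(table["valid"].sum())
    click.echo(f"wrote {len(table)} rows ({n_valid} valid) to {out_dir}/screening.csv")


if __name__ == "__main__":
    cli()
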