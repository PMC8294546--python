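"""End-to-end orchestration: events -> angles/displacement -> temporal ->
curves -> inference, with a delimited-text report directory.

The report mirrors the layout of a gait-summary table: per parameter and
limb (pair), the median with its 95% CI in seconds and as duty factor, plus
curve tables (100 columns per curve), an exclusion ledger that conserves
records (included + excluded = produced, per parameter), and a provenance
log carrying the configuration and seed.  Reruns with the same inputs and
seed produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import LIMBS, Config
from .curvestats import (
    CurveSummary,
    displacement_curve_set,
    normalize_angle_curves,
    summarize_curves,
)
from .events import (
    GaitEvents,
    StrideIndex,
    detect_trial_events,
    regularity_screen,
    segment_strides,
)
from .inference import IntervalEstimate, MixedModelResult, fit_limb_model, group_bootstrap_summaries
from .io import Trial
from .limbangle import complementary_filter_angle, extract_angle_extrema
from .temporal import (
    speed_normalize,
    stance_stride_durations,
    support_durations,
)
from .vdisp import cut_and_normalize, vertical_displacement

log = logging.getLogger("cowgait")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    cow_id: str
    measurement_id: str
    events: GaitEvents
    strides: list[StrideIndex]
    temporal_records: pd.DataFrame
    angle_records: pd.DataFrame
    angle_curve_records: dict = field(default_factory=dict)
    angle_summaries: dict[str, CurveSummary] = field(default_factory=dict)
    vdisp_curves: dict = field(default_factory=dict)
    vdisp_summaries: dict[str, CurveSummary] = field(default_factory=dict)
    temporal_estimates: list[IntervalEstimate] = field(default_factory=list)
    duty_estimates: list[IntervalEstimate] = field(default_factory=list)
    angle_estimates: list[IntervalEstimate] = field(default_factory=list)
    exclusions: pd.DataFrame | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("events")
def _run_events(trial: Trial, config: Config):
    events = detect_trial_events(trial, config)
    strides = segment_strides(events)
    if not strides:
        raise ValueError("no strides segmented (fewer than 2 LH claw-ons)")
    strides = regularity_screen(strides, events, config)
    return events, strides


@_stage("temporal")
def _run_temporal(events, strides, cow_id, config):
    rec = pd.concat(
        [
            stance_stride_durations(events, strides, cow_id),
            support_durations(events, strides, cow_id),
        ],
        ignore_index=True,
    )
    return speed_normalize(rec, strides)


@_stage("limbangle")
def _run_angles(trial: Trial, events, strides, config):
    rows = []
    curve_records = {}
    summaries = {}
    for limb in LIMBS:
        stream = trial.streams[limb]
        angle = complementary_filter_angle(stream, config, trial.calibration_window)
        recs = extract_angle_extrema(angle, stream.time, strides, events, limb)
        curve_records[limb] = recs
        for r in recs:
            for param, value in (
                ("max_protraction", r.max_protraction),
                ("max_retraction", r.max_retraction),
            ):
                rows.append(
                    {
                        "cow_id": trial.cow_id,
                        "stride_id": r.stride_id,
                        "parameter": param,
                        "group": limb,
                        "value": value,
                        "included": r.included,
                        "exclusion_reason": r.exclusion_reason,
                    }
                )
        included = [r for r in recs if r.included]
        if included:
            cs = normalize_angle_curves(included)
            summaries[limb] = summarize_curves(
                cs, events, strides, config.inference.curve_metric
            )
    return pd.DataFrame(rows), curve_records, summaries


@_stage("vdisp")
def _run_vdisp(trial: Trial, events, strides, config):
    curves = {}
    summaries = {}
    for loc, stream in trial.upper_body_streams().items():
        disp = vertical_displacement(stream, strides, config, trial.calibration_window)
        cs = cut_and_normalize(disp, stream.time, strides, loc, config)
        curves[loc] = cs
        if cs:
            curve_set = displacement_curve_set(
                cs, group={"cow": trial.cow_id, "location": loc}
            )
            summaries[loc] = summarize_curves(
                curve_set, events, strides, config.inference.curve_metric
            )
    return curves, summaries


@_stage("inference")
def _run_inference(temporal_records, angle_records, config):
    inf = config.inference
    t_est = group_bootstrap_summaries(
        temporal_records, "duration", inf.bootstrap_reps, config.seed,
        inf.ci_level, inf.cluster_by_cow,
    )
    d_est = group_bootstrap_summaries(
        temporal_records, "duty", inf.bootstrap_reps, config.seed + 1,
        inf.ci_level, inf.cluster_by_cow,
    )
    a_est = group_bootstrap_summaries(
        angle_records, "value", inf.bootstrap_reps, config.seed + 2,
        inf.ci_level, inf.cluster_by_cow,
    )
    return t_est, d_est, a_est


def exclusion_ledger(*frames: pd.DataFrame) -> pd.DataFrame:
    """Counts per parameter: produced, included, and excluded by reason."""
    rows = []
    for df in frames:
        if df is None or df.empty:
            continue
        for param, sub in df.groupby("parameter"):
            produced = len(sub)
            included = int(sub["included"].sum())
            rows.append(
                {
                    "parameter": param,
                    "produced": produced,
                    "included": included,
                    "excluded": produced - included,
                }
            )
            for reason, n in (
                sub.loc[~sub["included"].astype(bool), "exclusion_reason"]
                .value_counts()
                .items()
            ):
                rows.append(
                    {
                        "parameter": f"{param}: {reason}",
                        "produced": int(n),
                        "included": 0,
                        "excluded": int(n),
                    }
                )
    return pd.DataFrame(rows, columns=["parameter", "produced", "included", "excluded"])


def run_pipeline(
    trial: Trial, config: Config | None = None, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full analysis on one trial; optionally write the report."""
    config = config or Config()
    events, strides = _run_events(trial, config)
    temporal_records = _run_temporal(events, strides, trial.cow_id, config)
    angle_records, angle_curves, angle_summaries = _run_angles(
        trial, events, strides, config
    )
    vdisp_curves, vdisp_summaries = _run_vdisp(trial, events, strides, config)
    t_est, d_est, a_est = _run_inference(temporal_records, angle_records, config)
    result = PipelineResult(
        cow_id=trial.cow_id,
        measurement_id=trial.measurement_id,
        events=events,
        strides=strides,
        temporal_records=temporal_records,
        angle_records=angle_records,
        angle_curve_records=angle_curves,
        angle_summaries=angle_summaries,
        vdisp_curves=vdisp_curves,
        vdisp_summaries=vdisp_summaries,
        temporal_estimates=t_est,
        duty_estimates=d_est,
        angle_estimates=a_est,
        exclusions=exclusion_ledger(temporal_records, angle_records),
    )
    if out_dir is not None:
        write_report(result, out_dir, config)
    return result


def attach_stride_dev(records: pd.DataFrame) -> pd.DataFrame:
    """Add a stride_dev column: stride duration minus the overall median.

    The per-stride stride duration is taken from the records' own
    parameter == 'stride' rows, keyed by (cow_id, stride_id).
    """
    strides = records[records["parameter"] == "stride"]
    key = strides.set_index(["cow_id", "stride_id"])["duration"]
    med = key.median()
    out = records.copy()
    idx = pd.MultiIndex.from_frame(out[["cow_id", "stride_id"]])
    out["stride_dev"] = key.reindex(idx).to_numpy() - med
    return out


def mixed_models_by_parameter(
    records: pd.DataFrame, config: Config | None = None
) -> dict[str, MixedModelResult]:
    """Fit the limb mixed model per parameter, in seconds and as duty.

    The stride-duration-deviation covariate enters the duration models and
    is omitted for the speed-normalized (duty) responses.
    """
    config = config or Config()
    rec = attach_stride_dev(records)
    out = {}
    for param in ("stance", "bipedal", "tripedal"):
        sub = rec[rec["parameter"] == param]
        if sub.empty or sub["group"].nunique() < 2:
            continue
        out[param] = fit_limb_model(
            sub, "duration", use_covariate=True,
            ci_level=config.inference.ci_level, seed=config.seed,
        )
        out[f"{param}_duty"] = fit_limb_model(
            sub, "duty", use_covariate=False,
            ci_level=config.inference.ci_level, seed=config.seed,
        )
    return out


# ---------------------------------------------------------------------------
# report writing


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def write_report(
    result: PipelineResult, out_dir: str | Path, config: Config | None = None
) -> None:
    config = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)

    est_by_key = {
        "s": {(e.parameter, e.group): e for e in result.temporal_estimates},
        "duty": {(e.parameter, e.group): e for e in result.duty_estimates},
    }
    rows = []
    for (param, group), e in sorted(est_by_key["s"].items()):
        d = est_by_key["duty"].get((param, group))
        rows.append([
            param, group, e.estimate, e.ci_low, e.ci_high,
            d.estimate if d else float("nan"),
            d.ci_low if d else float("nan"),
            d.ci_high if d else float("nan"),
            e.n_strides,
        ])
    _write_tsv(
        out / "temporal_summary.tsv",
        ["parameter", "group", "median_s", "ci_low_s", "ci_high_s",
         "median_duty", "ci_low_duty", "ci_high_duty", "n_strides"],
        rows,
    )
    _write_tsv(
        out / "angle_summary.tsv",
        ["parameter", "group", "median_deg", "ci_low_deg", "ci_high_deg", "n_strides"],
        [[e.parameter, e.group, e.estimate, e.ci_low, e.ci_high, e.n_strides]
         for e in result.angle_estimates],
    )
    unit = 1000.0 if config.output_units_mm else 1.0

    def _curve_rows(summary: CurveSummary, scale: float):
        return [
            ["median"] + list(np.asarray(summary.median_curve) * scale),
            ["mad"] + list(np.asarray(summary.mad_curve) * scale),
        ]

    for limb, summary in sorted(result.angle_summaries.items()):
        rows = _curve_rows(summary, 1.0)
        rows.append(["most_typical_id", summary.most_typical_id])
        rows.append(["mean_claw_on"] + [summary.mean_claw_on.get(l, float("nan")) for l in LIMBS])
        rows.append(["mean_claw_off"] + [summary.mean_claw_off.get(l, float("nan")) for l in LIMBS])
        _write_tsv(out / "curves" / f"angle_{limb}.tsv",
                   ["row"] + [f"s{i:02d}" for i in range(len(summary.median_curve))],
                   rows)
    for loc, summary in sorted(result.vdisp_summaries.items()):
        rows = _curve_rows(summary, unit)
        rows.append(["most_typical_id", summary.most_typical_id])
        rows.append(["mean_claw_on"] + [summary.mean_claw_on.get(l, float("nan")) for l in LIMBS])
        rows.append(["mean_claw_off"] + [summary.mean_claw_off.get(l, float("nan")) for l in LIMBS])
        _write_tsv(out / "curves" / f"vdisp_{loc}.tsv",
                   ["row"] + [f"s{i:02d}" for i in range(len(summary.median_curve))],
                   rows)

    ex = result.exclusions
    _write_tsv(
        out / "exclusions.tsv",
        list(ex.columns),
        [list(r) for r in ex.itertuples(index=False)],
    )
    result.temporal_records.to_csv(
        out / "temporal_records.tsv", sep="\t", index=False, float_format="%.9g"
    )
    result.angle_records.to_csv(
        out / "angle_records.tsv", sep="\t", index=False, float_format="%.9g"
    )
    (out / "log.txt").write_text(
        f"cowgait {_version}\n"
        f"cow_id: {result.cow_id}\nmeasurement_id: {result.measurement_id}\n"
        f"seed: {config.seed}\n"
        f"strides: {len(result.strides)} "
        f"({sum(s.included for s in result.strides)} included)\n"
        f"config: {config}\n"
    )
    log.info("report written to %s", out)
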