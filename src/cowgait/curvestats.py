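"""Stride-normalized curve sets and their robust summaries.

Curves (limb angles or vertical displacements) are resampled to 100 points
spanning one stride.  A set of curves is summarized by its pointwise median,
the pointwise median absolute deviation (MAD), the *most typical curve* —
the member with the least total difference to all other members — and the
mean claw-on/claw-off timing of each limb as a percentage of the stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LIMBS
from .events import GaitEvents, StrideIndex
from .limbangle import LimbAngleStride
from .vdisp import DisplacementCurve


@dataclass
class CurveSet:
    """A stack of stride-normalized curves with member identifiers."""

    kind: str                    # 'angle' or 'vdisp'
    group: dict                  # e.g. {'limb': 'LF'} or {'cow': ..., 'location': ...}
    ids: list[int]               # stride ids, parallel to rows of samples
    samples: np.ndarray          # (n_curves, n_points)


@dataclass
class CurveSummary:
    group: dict
    n: int
    median_curve: np.ndarray
    mad_curve: np.ndarray
    most_typical_id: int
    mean_claw_on: dict[str, float] = field(default_factory=dict)
    mean_claw_off: dict[str, float] = field(default_factory=dict)


def normalize_angle_curves(
    records: list[LimbAngleStride], n_samples: int = 100
) -> CurveSet:
    """Resample each included stride's angle trace to ``n_samples`` points.

    Point 0 is the stride-start (LH) claw-on, the last point the next one.
    """
    rows, ids = [], []
    limb = records[0].limb if records else ""
    for rec in records:
        if not rec.included or rec.time.size < 2:
            continue
        t0, t1 = rec.time[0], rec.time[-1]
        target = t0 + np.arange(n_samples) / (n_samples - 1) * (t1 - t0)
        rows.append(np.interp(target, rec.time, rec.angle_curve))
        ids.append(rec.stride_id)
    samples = np.array(rows).reshape(len(rows), -1)
    return CurveSet(kind="angle", group={"limb": limb}, ids=ids, samples=samples)


def displacement_curve_set(
    curves: list[DisplacementCurve], group: dict | None = None
) -> CurveSet:
    rows = [c.samples for c in curves]
    ids = [c.stride_id for c in curves]
    loc = curves[0].location if curves else ""
    return CurveSet(
        kind="vdisp",
        group=group or {"location": loc},
        ids=ids,
        samples=np.array(rows).reshape(len(rows), -1),
    )


def curve_distance_matrix(samples: np.ndarray, metric: str = "rms") -> np.ndarray:
    """Pairwise curve differences: RMS (default) or mean absolute."""
    diff = samples[:, None, :] - samples[None, :, :]
    if metric == "rms":
        return np.sqrt(np.mean(diff ** 2, axis=2))
    if metric == "mean_abs":
        return np.mean(np.abs(diff), axis=2)
    raise ValueError(f"unknown curve metric {metric!r}")


def most_typical_curve(curve_set: CurveSet, metric: str = "rms") -> int:
    """Member id minimizing the summed pointwise distance to all other members.

    Ties break toward the earliest stride id.  A single curve is its own
    most typical curve; an empty set is an error.
    """
    n = curve_set.samples.shape[0]
    if n == 0:
        raise ValueError("most_typical_curve of an empty curve set")
    if n == 1:
        return curve_set.ids[0]
    dist = curve_distance_matrix(curve_set.samples, metric)
    totals = dist.sum(axis=1)
    best = totals.min()
    tied = [curve_set.ids[i] for i in np.flatnonzero(totals <= best + 1e-12)]
    return min(tied)


def median_mad_curves(curve_set: CurveSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise median curve and pointwise MAD about it."""
    if curve_set.samples.shape[0] == 0:
        raise ValueError("median of an empty curve set")
    med = np.median(curve_set.samples, axis=0)
    mad = np.median(np.abs(curve_set.samples - med), axis=0)
    return med, mad


def mean_footfall_fractions(
    events: GaitEvents, strides: list[StrideIndex]
) -> dict[str, dict[str, float]]:
    """Per-limb mean claw-on and claw-off timing as % of stride.

    For each included stride and limb, the first claw-on (claw-off) at or
    after the stride start and before its end contributes
    (event - start)/duration x 100.  The LH claw-on is the stride reference
    and sits at 0 by construction.
    """
    acc: dict[str, dict[str, list[float]]] = {
        limb: {"on": [], "off": []} for limb in LIMBS
    }
    for s in strides:
        if not s.included:
            continue
        T = s.duration
        for limb in LIMBS:
            for kind, times in (("on", events.claw_on), ("off", events.claw_off)):
                arr = np.atleast_1d(times.get(limb, np.array([])))
                hit = arr[(arr >= s.start - 1e-9) & (arr < s.end)]
                if hit.size:
                    acc[limb][kind].append((hit[0] - s.start) / T * 100.0)
    return {
        limb: {
            "on": float(np.mean(v["on"])) if v["on"] else float("nan"),
            "off": float(np.mean(v["off"])) if v["off"] else float("nan"),
        }
        for limb, v in acc.items()
    }


def summarize_curves(
    curve_set: CurveSet,
    events: GaitEvents | None = None,
    strides: list[StrideIndex] | None = None,
    metric: str = "rms",
) -> CurveSummary:
    """Full summary of one curve group: median, MAD, most typical, footfalls."""
    med, mad = median_mad_curves(curve_set)
    typical = most_typical_curve(curve_set, metric)
    summary = CurveSummary(
        group=curve_set.group,
        n=curve_set.samples.shape[0],
        median_curve=med,
        mad_curve=mad,
        most_typical_id=typical,
    )
    if events is not None and strides is not None:
        ff = mean_footfall_fractions(events, strides)
        summary.mean_claw_on = {l: ff[l]["on"] for l in LIMBS}
        summary.mean_claw_off = {l: ff[l]["off"] for l in LIMBS}
    return summary
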