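"""Per-stride temporal gait parameters.

Stance and stride durations per limb, and bipedal/tripedal support
durations from a boundary sweep over the four limbs' stance intervals.
"Simultaneous stance of two (three) limbs" is read as *exactly* two (three)
limbs — the instantaneous support configurations partition the stride — so
the summed configuration durations conserve total limb-stance time.

Speed normalization divides every duration by the LH stride duration of the
corresponding stride, yielding a duty factor; fractions outside [0, 1] and
negative durations are flagged excluded, never deleted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LIMBS
from .events import GaitEvents, StrideIndex

#: the support-phase configurations with a name in standard gait terminology
BIPEDAL_PAIRS = ("LF-RH", "RF-LH", "LF-LH", "RF-RH")
TRIPEDAL_GROUPS = ("noLF", "noRF", "noLH", "noRH")

_COLUMNS = [
    "cow_id", "stride_id", "parameter", "group",
    "duration", "duty", "included", "exclusion_reason",
]


def _record(cow_id, stride_id, parameter, group, duration,
            included=True, reason=""):
    return {
        "cow_id": cow_id,
        "stride_id": stride_id,
        "parameter": parameter,
        "group": group,
        "duration": duration,
        "duty": np.nan,
        "included": included,
        "exclusion_reason": reason,
    }


def _paired_stances(events: GaitEvents, limb: str) -> list[tuple[float, float]]:
    """Pair claw-ons with their following claw-off by order.

    Unlike interval construction this preserves corrupted orderings so a
    negative computed duration can be detected and excluded downstream.
    """
    ons = np.atleast_1d(events.claw_on.get(limb, np.array([])))
    offs = np.atleast_1d(events.claw_off.get(limb, np.array([])))
    if ons.size == 0:
        return []
    offs = offs[offs > ons[0] - 1e-12] if offs.size else offs
    k = min(ons.size, offs.size)
    return list(zip(ons[:k], offs[:k]))


def stance_stride_durations(
    events: GaitEvents, strides: list[StrideIndex], cow_id: str = "unknown"
) -> pd.DataFrame:
    """One stance record per limb per stride plus one stride record.

    The stance attributed to a stride is the one whose claw-on falls inside
    the stride window; a limb without a claw-on in the window yields no
    record (the mechanism behind unequal per-limb stride counts).  Negative
    computed durations are flagged excluded, as are records from strides the
    regularity screen rejected.
    """
    rows = []
    stances = {limb: _paired_stances(events, limb) for limb in LIMBS}
    for s in strides:
        inc, why = s.included, ("" if s.included else (s.exclusion_reason or "stride excluded"))
        rows.append(_record(cow_id, s.stride_id, "stride", "LH", s.duration, inc, why))
        for limb in LIMBS:
            for on, off in stances[limb]:
                if s.start <= on < s.end:
                    dur = off - on
                    if dur <= 0:
                        rows.append(_record(cow_id, s.stride_id, "stance", limb,
                                            dur, False, "negative duration"))
                    else:
                        rows.append(_record(cow_id, s.stride_id, "stance", limb,
                                            dur, inc, why))
                    break
    return pd.DataFrame(rows, columns=_COLUMNS)


def _support_segments(
    events: GaitEvents, t_lo: float, t_hi: float
) -> list[tuple[float, float, frozenset]]:
    """Maximal constant-support segments of [t_lo, t_hi).

    Returns (start, end, limbs-in-stance) triples from a sweep over all
    stance boundaries.
    """
    intervals = {limb: events.stance_intervals(limb) for limb in LIMBS}
    bounds = {t_lo, t_hi}
    for iv in intervals.values():
        for on, off in iv:
            if t_lo < on < t_hi:
                bounds.add(float(on))
            if t_lo < off < t_hi:
                bounds.add(float(off))
    pts = sorted(bounds)
    segments = []
    for lo, hi in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (lo + hi)
        members = frozenset(
            limb for limb, iv in intervals.items()
            if iv.size and np.any((iv[:, 0] <= mid) & (mid < iv[:, 1]))
        )
        segments.append((lo, hi, members))
    return segments


def _config_name(members: frozenset) -> tuple[str, str, bool]:
    """(parameter, group, is_walk_configuration) for a support set."""
    k = len(members)
    ordered = [l for l in LIMBS if l in members]
    if k == 2:
        name = "-".join(ordered)
        if name in BIPEDAL_PAIRS or "-".join(ordered[::-1]) in BIPEDAL_PAIRS:
            canon = name if name in BIPEDAL_PAIRS else "-".join(ordered[::-1])
            return "bipedal", canon, True
        return "bipedal", name, False       # front or hind pair: not a walk config
    if k == 3:
        missing = next(l for l in LIMBS if l not in members)
        return "tripedal", f"no{missing}", True
    if k == 4:
        return "quadrupedal", "all", False
    if k == 1:
        return "single", ordered[0], False
    return "none", "", False


def support_durations(
    events: GaitEvents, strides: list[StrideIndex], cow_id: str = "unknown"
) -> pd.DataFrame:
    """Bipedal/tripedal (and flagged quadrupedal/single) support durations.

    Support segments are swept over the full stride span; each maximal
    constant-configuration segment is attributed to the stride containing
    its midpoint, and same-configuration segments within one stride are
    summed.  Quadrupedal and single-support time is recorded but flagged,
    as are the front/hind bipedal pairs that do not occur in a regular walk.
    """
    if not strides:
        return pd.DataFrame(columns=_COLUMNS)
    t_lo = min(s.start for s in strides)
    t_hi = max(s.end for s in strides)
    starts = np.array([s.start for s in strides])
    ends = np.array([s.end for s in strides])
    acc: dict[tuple[int, str, str, bool], float] = {}
    for lo, hi, members in _support_segments(events, t_lo, t_hi):
        if not members:
            continue
        mid = 0.5 * (lo + hi)
        hit = np.flatnonzero((starts <= mid) & (mid < ends))
        if hit.size == 0:
            continue
        s = strides[hit[0]]
        param, group, walk_cfg = _config_name(members)
        key = (s.stride_id, param, group, walk_cfg)
        acc[key] = acc.get(key, 0.0) + (hi - lo)
    by_id = {s.stride_id: s for s in strides}
    rows = []
    for (sid, param, group, walk_cfg), dur in sorted(acc.items()):
        s = by_id[sid]
        if not walk_cfg:
            rows.append(_record(cow_id, sid, param, group, dur,
                                False, "non-walk support configuration"))
        elif not s.included:
            rows.append(_record(cow_id, sid, param, group, dur,
                                False, s.exclusion_reason or "stride excluded"))
        else:
            rows.append(_record(cow_id, sid, param, group, dur))
    return pd.DataFrame(rows, columns=_COLUMNS)


def speed_normalize(
    records: pd.DataFrame, strides: list[StrideIndex]
) -> pd.DataFrame:
    """Fill the duty column: duration / LH stride duration of the same stride.

    Records whose stride has no LH stride duration are excluded with reason
    "no matching LH stride"; duties outside [0, 1] are excluded as fractions
    the walk model cannot produce.
    """
    out = records.copy()
    stride_dur = {s.stride_id: s.duration for s in strides}
    duty = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        T = stride_dur.get(row.stride_id)
        if T is None or T <= 0:
            out.iat[i, out.columns.get_loc("included")] = False
            out.iat[i, out.columns.get_loc("exclusion_reason")] = "no matching LH stride"
            continue
        duty[i] = row.duration / T
    out["duty"] = duty
    bad = (out["duty"] < 0) | (out["duty"] > 1)
    newly = bad & out["included"].astype(bool)
    out.loc[newly, "included"] = False
    out.loc[newly, "exclusion_reason"] = "duty outside [0,1]"
    return out


def rasterized_support_durations(
    events: GaitEvents, t_lo: float, t_hi: float, dt: float = 1e-3
) -> dict[tuple[str, str], float]:
    """Brute-force oracle: rasterize stance membership on a grid and count.

    Independent of the sweep implementation; intended for verification, not
    analysis.  Returns total duration per (parameter, group) over [t_lo, t_hi).
    """
    grid = np.arange(t_lo + dt / 2, t_hi, dt)
    counts: dict[tuple[str, str], float] = {}
    membership = np.zeros((len(LIMBS), grid.size), dtype=bool)
    for i, limb in enumerate(LIMBS):
        for on, off in events.stance_intervals(limb):
            membership[i] |= (grid >= on) & (grid < off)
    for j in range(grid.size):
        members = frozenset(LIMBS[i] for i in range(4) if membership[i, j])
        if not members:
            continue
        param, group, _ = _config_name(members)
        counts[(param, group)] = counts.get((param, group), 0.0) + dt
    return counts
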