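"""Claw-on/claw-off detection, stride segmentation, and regularity screening.

Detection works on the distal limb's mediolateral gyro channel.  In walk the
distal limb retracts (negative sagittal rate) through stance and protracts
(positive rate) through swing, so swing is flagged where the low-passed rate
exceeds a small fraction of the positive (protraction) peak.  The coarse
boundaries are then refined: claw-off to the nearest negative-to-positive
zero crossing of the rate, claw-on to the accelerometer jerk peak left by
the hoof impact (falling back to the positive-to-negative crossing when no
convincing impact is present).  Events are sample-timestamped; a stance is
the closed-open interval [claw-on, claw-off).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import LIMBS, Config
from .io import SensorStream, Trial

log = logging.getLogger("cowgait")


@dataclass
class GaitEvents:
    """Per-limb alternating claw-on/claw-off time sequences (seconds)."""

    claw_on: dict[str, np.ndarray] = field(default_factory=dict)
    claw_off: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for limb in self.claw_on:
            merged = self.merged(limb)
            times = np.array([t for t, _ in merged])
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"{limb}: events not strictly increasing")
            kinds = [k for _, k in merged]
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise ValueError(f"{limb}: events do not alternate on/off")

    def merged(self, limb: str) -> list[tuple[float, str]]:
        ons = [(t, "on") for t in np.atleast_1d(self.claw_on.get(limb, []))]
        offs = [(t, "off") for t in np.atleast_1d(self.claw_off.get(limb, []))]
        return sorted(ons + offs)

    def stance_intervals(self, limb: str) -> np.ndarray:
        """Complete [on, off) stance intervals, shape (k, 2)."""
        out = []
        offs = np.atleast_1d(self.claw_off.get(limb, np.array([])))
        for on in np.atleast_1d(self.claw_on.get(limb, np.array([]))):
            later = offs[offs > on]
            if later.size:
                out.append((on, later[0]))
        return np.array(out).reshape(-1, 2)


@dataclass
class StrideIndex:
    """One LH-referenced stride window with its inclusion status."""

    stride_id: int
    start: float
    end: float
    included: bool = True
    exclusion_reason: str = ""

    @property
    def duration(self) -> float:
        return self.end - self.start


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as closed-open index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_claw_events(
    stream: SensorStream, config: Config | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect claw-on and claw-off times for one distal-limb stream.

    Returns ``(claw_on_times, claw_off_times)``.  An all-quiet stream (no
    detectable gait) yields empty arrays and a warning.
    """
    config = config or Config()
    ec = config.events
    ac = config.angle
    fs = stream.rate
    omega = ac.sign * stream.gyro[:, ac.mediolateral_axis]
    if ec.lowpass_hz < fs / 2:
        sos = sps.butter(4, ec.lowpass_hz, btype="low", fs=fs, output="sos")
        omf = sps.sosfiltfilt(sos, omega)
    else:
        omf = omega
    pos = omf[omf > 0]
    peak = np.quantile(pos, ec.peak_quantile) if pos.size else 0.0
    if peak < ec.min_peak_dps:
        warnings.warn(
            f"{stream.location}: no detectable gait (quiet gyro)", stacklevel=2
        )
        return np.array([]), np.array([])
    thr = ec.swing_frac * peak
    swing = omf > thr
    min_swing = int(round(ec.min_swing_s * fs))
    min_stance = int(round(ec.min_stance_s * fs))
    runs = [(a, b) for a, b in _runs(swing) if b - a >= min_swing]
    snap = int(round(ec.snap_window_s * fs))
    jerk = np.abs(np.diff(np.linalg.norm(stream.accel, axis=1)))
    jerk_mad = 1.4826 * np.median(np.abs(jerk - np.median(jerk))) + 1e-12

    claw_off_idx: list[int] = []
    claw_on_idx: list[int] = []
    n = stream.n
    for a, b in runs:
        # claw-off: negative-to-positive crossing of the rate near the run start,
        # accepted only if genuine retraction precedes it (rejects a recording
        # that opens mid-swing, where no stance was observed)
        i = _refine_crossing(omf, a, snap, direction=-1)
        if i - min_stance >= 0 and omf[max(i - min_stance, 0):i].min() < -thr:
            claw_off_idx.append(i)
        # claw-on: jerk peak (impact landmark) near the run end, else crossing;
        # accepted only if retraction follows (rejects a truncated final swing)
        j = _snap_to_jerk(jerk, b, snap, ec.jerk_snr_min * jerk_mad)
        if j is None:
            j = _refine_crossing(omf, b, snap, direction=+1)
        if j + min_stance <= n and omf[j:j + min_stance].min() < -thr:
            claw_on_idx.append(j)

    ons = np.array(sorted(set(claw_on_idx)), dtype=int)
    offs = np.array(sorted(set(claw_off_idx)), dtype=int)
    ons, offs = _enforce_alternation(ons, offs, min_stance, min_swing)
    return stream.time[ons], stream.time[offs]


def _refine_crossing(omf: np.ndarray, idx: int, snap: int, direction: int) -> int:
    """Nearest sign crossing of the rate within ±snap of idx.

    direction=-1: stance->swing (last non-positive sample before positive);
    direction=+1: swing->stance (first non-positive sample after positive).
    The crossing sample itself (first sample on the new side) is returned;
    if no crossing is found, idx is kept.
    """
    lo = max(idx - snap, 1)
    hi = min(idx + snap, len(omf) - 1)
    best = None
    for k in range(lo, hi + 1):
        if direction < 0:
            crossed = omf[k - 1] <= 0.0 < omf[k]
        else:
            crossed = omf[k - 1] > 0.0 >= omf[k]
        if crossed and (best is None or abs(k - idx) < abs(best - idx)):
            best = k
    return best if best is not None else idx


def _snap_to_jerk(jerk: np.ndarray, idx: int, snap: int, floor: float) -> int | None:
    """Onset of the largest jerk burst within ±snap of idx, if above noise.

    The impact burst oscillates, so its largest first-difference can trail
    the hoof contact by a sample or two; from the window peak we walk back
    over contiguous elevated samples to the burst onset.  Equidistant ties
    break toward the earlier sample (argmax convention).
    """
    lo = max(idx - snap, 0)
    hi = min(idx + snap, len(jerk))
    if hi <= lo:
        return None
    window = jerk[lo:hi]
    k = int(np.argmax(window))
    peak = window[k]
    if peak < floor:
        return None
    onset_thr = max(0.2 * peak, floor / 2.0)
    i = lo + k
    while i > lo and jerk[i - 1] >= onset_thr:
        i -= 1
    return i


def _enforce_alternation(
    ons: np.ndarray, offs: np.ndarray, min_stance: int, min_swing: int
) -> tuple[np.ndarray, np.ndarray]:
    """Merge candidate indices into a strictly alternating on/off sequence.

    Consecutive same-kind candidates keep the earlier one; stances or swings
    shorter than the minima drop the offending later event.
    """
    merged = sorted([(i, "on") for i in ons] + [(i, "off") for i in offs])
    seq: list[tuple[int, str]] = []
    for idx, kind in merged:
        if seq and seq[-1][1] == kind:
            continue  # earlier event wins
        if seq:
            gap = idx - seq[-1][0]
            need = min_stance if kind == "off" else min_swing
            if gap < need:
                continue
        seq.append((idx, kind))
    out_on = np.array([i for i, k in seq if k == "on"], dtype=int)
    out_off = np.array([i for i, k in seq if k == "off"], dtype=int)
    return out_on, out_off


def detect_trial_events(trial: Trial, config: Config | None = None) -> GaitEvents:
    """Run claw event detection on every limb stream of a trial."""
    trial.require_limbs()
    ev = GaitEvents()
    for limb in LIMBS:
        ons, offs = detect_claw_events(trial.streams[limb], config)
        ev.claw_on[limb] = ons
        ev.claw_off[limb] = offs
    ev.validate()
    return ev


def segment_strides(events: GaitEvents) -> list[StrideIndex]:
    """Cut the timeline into strides between consecutive LH claw-ons.

    Strides lacking full four-limb stance coverage (each limb needs a
    claw-on inside the window with its matching claw-off) are flagged
    excluded with reason "incomplete limb coverage".
    """
    lh_ons = np.atleast_1d(events.claw_on.get("LH", np.array([])))
    if lh_ons.size < 2:
        return []
    strides = []
    stance_by_limb = {limb: events.stance_intervals(limb) for limb in LIMBS}
    for i, (a, b) in enumerate(zip(lh_ons[:-1], lh_ons[1:])):
        s = StrideIndex(stride_id=i, start=float(a), end=float(b))
        for limb in LIMBS:
            iv = stance_by_limb[limb]
            if iv.size == 0 or not np.any((iv[:, 0] >= a) & (iv[:, 0] < b)):
                s.included = False
                s.exclusion_reason = "incomplete limb coverage"
                break
        strides.append(s)
    return strides


def regularity_screen(
    strides: list[StrideIndex],
    events: GaitEvents,
    config: Config | None = None,
) -> list[StrideIndex]:
    """Automated stride-by-stride regularity screen.

    A stride is excluded when any limb's stance duration within it deviates
    from that limb's running median by more than ``rel_tol``, or when the
    four-limb support count reaches 0 or 4 for longer than ``support_tol_s``.
    Contiguous included runs are then capped at ``max_intervals`` per
    measurement (longest kept), mirroring interval-based data selection.
    """
    config = config or Config()
    sc = config.screen
    out = [StrideIndex(s.stride_id, s.start, s.end, s.included, s.exclusion_reason)
           for s in strides]
    stance_by_limb = {limb: events.stance_intervals(limb) for limb in LIMBS}

    # per-limb stance duration per stride (claw-on inside the window)
    durs: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        iv = stance_by_limb[limb]
        d = np.full(len(out), np.nan)
        for k, s in enumerate(out):
            if iv.size == 0:
                continue
            hit = (iv[:, 0] >= s.start) & (iv[:, 0] < s.end)
            if hit.any():
                row = iv[hit][0]
                d[k] = row[1] - row[0]
        durs[limb] = d

    for limb in LIMBS:
        d = durs[limb]
        med = _running_median(d, sc.running_window)
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.abs(d - med) / med
        for k, s in enumerate(out):
            if not s.included:
                continue
            if np.isnan(d[k]):
                continue  # no stance -> handled as incomplete coverage upstream
            if dev[k] > sc.rel_tol:
                s.included = False
                s.exclusion_reason = f"irregular {limb} stance"

    # support-count screen: 0 or 4 limbs in stance beyond the tolerance
    all_iv = [iv for iv in stance_by_limb.values() if iv.size]
    for s in out:
        if not s.included:
            continue
        bad = _extreme_support_duration(all_iv, s.start, s.end)
        if bad > sc.support_tol_s:
            s.included = False
            s.exclusion_reason = "support count 0 or 4"

    _cap_intervals(out, sc.max_intervals)
    n_exc = sum(not s.included for s in out)
    log.info("regularity screen: %d/%d strides excluded", n_exc, len(out))
    return out


def _running_median(d: np.ndarray, window: int) -> np.ndarray:
    """Centered running median ignoring NaNs; global median where short."""
    n = len(d)
    out = np.full(n, np.nan)
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = d[lo:hi]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            out[i] = np.median(seg)
    return out


def _extreme_support_duration(
    intervals: list[np.ndarray], a: float, b: float
) -> float:
    """Total time within [a, b) during which 0 or 4 limbs are in stance."""
    bounds = {a, b}
    for iv in intervals:
        for on, off in iv:
            if a < on < b:
                bounds.add(on)
            if a < off < b:
                bounds.add(off)
    pts = sorted(bounds)
    total = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (lo + hi)
        count = sum(
            bool(np.any((iv[:, 0] <= mid) & (mid < iv[:, 1]))) for iv in intervals
        )
        if count in (0, 4):
            total += hi - lo
    return total


def _cap_intervals(strides: list[StrideIndex], max_intervals: int) -> None:
    """Keep at most ``max_intervals`` contiguous included runs (longest first)."""
    runs: list[list[StrideIndex]] = []
    cur: list[StrideIndex] = []
    for s in strides:
        if s.included:
            cur.append(s)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if len(runs) <= max_intervals:
        return
    keep = set()
    for run in sorted(runs, key=len, reverse=True)[:max_intervals]:
        keep.update(id(s) for s in run)
    for run in runs:
        for s in run:
            if id(s) not in keep:
                s.included = False
                s.exclusion_reason = "interval cap"


def included_intervals(strides: list[StrideIndex]) -> list[tuple[float, float]]:
    """Contiguous included stride runs as (start, end) time intervals."""
    out = []
    cur_start = None
    prev_end = None
    for s in strides:
        if s.included:
            if cur_start is None:
                cur_start = s.start
            prev_end = s.end
        elif cur_start is not None:
            out.append((cur_start, prev_end))
            cur_start = None
    if cur_start is not None:
        out.append((cur_start, prev_end))
    return out


def footfall_table(events: GaitEvents, strides: list[StrideIndex]) -> list[dict]:
    """Footfall-chart rows: per stride and limb, stance start/end as stride fractions."""
    rows = []
    for s in strides:
        T = s.duration
        for limb in LIMBS:
            for on, off in events.stance_intervals(limb):
                if off <= s.start or on >= s.end:
                    continue
                rows.append(
                    {
                        "stride_id": s.stride_id,
                        "limb": limb,
                        "start_frac": (max(on, s.start) - s.start) / T,
                        "end_frac": (min(off, s.end) - s.start) / T,
                    }
                )
    return rows
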