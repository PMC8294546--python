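"""Parameter-recovery benchmarks: simulator-programmed gait through the
full pipeline and back out.

Each function programs the generator with reference gait parameters
(per-limb stance duty factors, angle maxima, displacement phasing), runs the
analysis on the synthesized raw signals, and returns the recovered summary
quantities.  These are the package's end-to-end validation experiments; the
problem sizes (cows, strides) keep each run in the seconds-to-a-minute
range on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Config
from .curvestats import displacement_curve_set, summarize_curves
from .events import detect_trial_events, regularity_screen, segment_strides
from .io import Trial
from .limbangle import complementary_filter_angle, extract_angle_extrema
from .simulate import (
    GaitParams,
    NoiseParams,
    UpperBodyParams,
    simulate_footfalls,
    simulate_limb_streams,
    simulate_trial,
)
from .temporal import (
    speed_normalize,
    stance_stride_durations,
    support_durations,
)
from .events import GaitEvents
from .vdisp import cut_and_normalize, vertical_displacement

#: reference per-limb duty factors (walk medians this package validates against)
REFERENCE_DUTY = {"LF": 0.68, "RF": 0.69, "LH": 0.64, "RH": 0.64}
#: stride duration putting the front stance near 0.91 s at those duties
REFERENCE_STRIDE_S = 1.33


def temporal_recovery(
    seed: int = 0,
    n_cows: int = 5,
    strides_per_cow: int = 42,
    jitter_sd: float = 0.015,
    config: Config | None = None,
) -> dict:
    """Recover stance medians and duty factors from raw synthesized signals.

    Simulates ``n_cows`` trials with the reference per-limb duty factors plus
    boundary jitter and default sensor noise, runs detection, segmentation,
    screening and temporal extraction, and returns pooled medians.
    """
    config = config or Config()
    records = []
    for c in range(n_cows):
        gait = GaitParams(
            stride_duration=REFERENCE_STRIDE_S,
            duty_factor=dict(REFERENCE_DUTY),
            n_strides=strides_per_cow,
            timing_jitter_sd=jitter_sd,
        )
        noise = NoiseParams(seed=seed * 1009 + c)
        streams, _ = simulate_limb_streams(gait, noise)
        trial = Trial(cow_id=f"cow{c}", measurement_id="m1", streams=streams)
        events = detect_trial_events(trial, config)
        strides = regularity_screen(segment_strides(events), events, config)
        rec = pd.concat(
            [
                stance_stride_durations(events, strides, trial.cow_id),
                support_durations(events, strides, trial.cow_id),
            ],
            ignore_index=True,
        )
        records.append(speed_normalize(rec, strides))
    rec = pd.concat(records, ignore_index=True)
    inc = rec[rec.included.astype(bool)]
    stance = inc[inc.parameter == "stance"]
    front = stance[stance.group.isin(["LF", "RF"])]
    hind = stance[stance.group.isin(["LH", "RH"])]
    return {
        "n_strides": int((inc.parameter == "stride").sum()),
        "front_stance_median_s": float(front.duration.median()),
        "hind_stance_median_s": float(hind.duration.median()),
        "pooled_stance_duty": float(stance.duty.median()),
        "front_stance_duty": float(front.duty.median()),
        "hind_stance_duty": float(hind.duty.median()),
        "records": rec,
    }


def support_phase_analytic(n_strides: int = 10) -> dict:
    """Support-phase duty factors of the noise-free quarter-phase walk.

    Runs the interval machinery on exact footfalls with the reference duty
    factors; the resulting normalized bipedal/tripedal durations are an
    analytic property of the walk pattern (exact to rounding).
    """
    gait = GaitParams(
        stride_duration=1.0,
        duty_factor=dict(REFERENCE_DUTY),
        n_strides=n_strides,
        timing_jitter_sd=0.0,
    )
    ff = simulate_footfalls(gait)
    events = GaitEvents(
        claw_on={l: ff[l][0] for l in ff}, claw_off={l: ff[l][1] for l in ff}
    )
    strides = segment_strides(events)
    rec = speed_normalize(support_durations(events, strides), strides)
    inc = rec[rec.included.astype(bool)]
    med = inc.groupby(["parameter", "group"]).duty.median()
    bipedal = inc[inc.parameter == "bipedal"]
    tripedal = inc[inc.parameter == "tripedal"]
    return {
        "diagonal_bipedal_duty": float(
            bipedal[bipedal.group.isin(["LF-RH", "RF-LH"])].duty.median()
        ),
        "ipsilateral_bipedal_duty": float(
            bipedal[bipedal.group.isin(["LF-LH", "RF-RH"])].duty.median()
        ),
        "tripedal_overall_duty": float(tripedal.duty.median()),
        "single_hind_tripedal_duty": float(
            tripedal[tripedal.group.isin(["noLH", "noRH"])].duty.median()
        ),
        "single_front_tripedal_duty": float(
            tripedal[tripedal.group.isin(["noLF", "noRF"])].duty.median()
        ),
        "by_group": med,
    }


#: programmed angle maxima for the recovery benchmark (degrees)
BENCH_PROTRACTION = {"LF": 25.0, "RF": 25.0, "LH": 24.0, "RH": 23.0}
BENCH_RETRACTION = {"LF": -45.0, "RF": -45.0, "LH": -29.0, "RH": -29.0}


def angle_recovery(
    seed: int = 0,
    n_strides: int = 25,
    noisy: bool = True,
    config: Config | None = None,
) -> dict:
    """Recover programmed protraction/retraction maxima through gyro
    synthesis and the complementary filter."""
    config = config or Config()
    gait = GaitParams(
        stride_duration=REFERENCE_STRIDE_S,
        duty_factor=dict(REFERENCE_DUTY),
        n_strides=n_strides,
        timing_jitter_sd=0.01,
        protraction_max=dict(BENCH_PROTRACTION),
        retraction_max=dict(BENCH_RETRACTION),
    )
    noise = NoiseParams(seed=seed * 2003 + 17) if noisy else NoiseParams(0.0, 0.0, seed=seed * 2003 + 17)
    streams, _ = simulate_limb_streams(
        gait, noise, rng=np.random.default_rng(seed * 2003 + 17)
    )
    trial = Trial(cow_id="bench", measurement_id="m1", streams=streams)
    events = detect_trial_events(trial, config)
    strides = regularity_screen(segment_strides(events), events, config)
    out = {}
    for limb in ("LF", "RF", "LH", "RH"):
        s = streams[limb]
        ang = complementary_filter_angle(s, config, (0.0, 5.0))
        recs = [
            r
            for r in extract_angle_extrema(ang, s.time, strides, events, limb)
            if r.included
        ]
        out[limb] = {
            "protraction_deg": float(np.median([r.max_protraction for r in recs])),
            "retraction_deg": float(np.median([r.max_retraction for r in recs])),
            "n": len(recs),
        }
    out["front_protraction_deg"] = float(
        np.mean([out["LF"]["protraction_deg"], out["RF"]["protraction_deg"]])
    )
    out["front_retraction_deg"] = float(
        np.mean([out["LF"]["retraction_deg"], out["RF"]["retraction_deg"]])
    )
    out["hind_retraction_deg"] = float(
        np.mean([out["LH"]["retraction_deg"], out["RH"]["retraction_deg"]])
    )
    return out


def displacement_phase(
    seed: int = 0, n_strides: int = 30, config: Config | None = None
) -> dict:
    """Recover upper-body displacement peak phases from a symmetric walk.

    Returns the sacrum median-curve peak locations (% of stride) and the
    withers mid-stride peak location.
    """
    config = config or Config()
    trial, _ = simulate_trial(
        GaitParams(
            stride_duration=REFERENCE_STRIDE_S,
            duty_factor=dict(REFERENCE_DUTY),
            n_strides=n_strides,
            timing_jitter_sd=0.01,
        ),
        UpperBodyParams(),
        NoiseParams(0.3, 1.0, seed=seed * 3001 + 5),
        cow_id="bench",
    )
    events = detect_trial_events(trial, config)
    strides = regularity_screen(segment_strides(events), events, config)
    out = {}
    for loc in ("sacrum", "withers", "LTC", "RTC"):
        s = trial.streams[loc]
        disp = vertical_displacement(s, strides, config, trial.calibration_window)
        curves = cut_and_normalize(disp, s.time, strides, loc, config)
        med = summarize_curves(displacement_curve_set(curves)).median_curve
        peaks = [
            i for i in range(1, len(med) - 1)
            if med[i] > med[i - 1] and med[i] >= med[i + 1]
        ]
        out[loc] = {"peaks_pct": peaks, "p2p_mm": float(1e3 * (med.max() - med.min()))}
    sac = out["sacrum"]["peaks_pct"]
    first = min(sac, key=lambda p: abs(p - 25))
    second = min(sac, key=lambda p: abs(p - 75))
    out["sacrum_first_peak_pct"] = float(first)
    out["sacrum_second_peak_pct"] = float(second)
    out["withers_mid_peak_pct"] = float(
        min(out["withers"]["peaks_pct"], key=lambda p: abs(p - 50))
    )
    return out
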