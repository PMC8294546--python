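"""Upper-body vertical displacement curves by cyclic double integration.

Integrates the gravity-corrected vertical acceleration stride by stride,
normalizes each stride to 100 samples, and summarizes the curve set with
the pointwise median, MAD band, and the most typical curve.
"""

import numpy as np

from cowgait import Config, detect_trial_events, regularity_screen, segment_strides
from cowgait.curvestats import displacement_curve_set, summarize_curves
from cowgait.simulate import GaitParams, NoiseParams, UpperBodyParams, simulate_trial
from cowgait.vdisp import cut_and_normalize, vertical_displacement

config = Config()
trial, truth = simulate_trial(
    GaitParams(n_strides=20, timing_jitter_sd=0.01),
    UpperBodyParams(),
    NoiseParams(0.3, 1.0, seed=4),
)
events = detect_trial_events(trial, config)
strides = regularity_screen(segment_strides(events), events, config)

for loc in ("sacrum", "withers", "LTC", "RTC"):
    stream = trial.streams[loc]
    disp = vertical_displacement(stream, strides, config, trial.calibration_window)
    curves = cut_and_normalize(disp, stream.time, strides, loc, config)
    summary = summarize_curves(displacement_curve_set(curves), events, strides)
    med = summary.median_curve
    peaks = [i for i in range(1, 99) if med[i] > med[i - 1] and med[i] >= med[i + 1]]
    print(f"{loc:8s} n={summary.n:2d}  peaks at {peaks} % of stride  "
          f"peak-to-peak {1e3 * (med.max() - med.min()):.0f} mm  "
          f"most typical stride #{summary.most_typical_id}")
# The sacrum peaks near 25% and 75% of the stride (hind-limb midstances),
# the withers near 0/50/100% (front-limb midstances); the tuber coxae rise
# highest over their own standing hind limb.
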