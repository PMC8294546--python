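"""Upper-body vertical displacement by cyclic double integration.

Acceleration is rotated into the gravity-aligned world frame using the same
quaternion complementary filter as the limb angles, gravity is subtracted,
and the vertical channel is double-integrated stride by stride (LH claw-on
to claw-on).  Integration drift is removed per cycle: the velocity gets a
linear detrend, the displacement another, and the result is zero-meaned —
the per-cycle analogue of high-pass filtering, chosen because each stride is
one period of the motion.  Strides shorter than ``min_stride_s`` or longer
than ``max_stride_s`` are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .config import GRAVITY, Config
from .events import StrideIndex
from .io import SensorStream
from .limbangle import orientation_quaternions


@dataclass
class DisplacementCurve:
    """One stride-normalized vertical displacement trace (meters).

    samples holds the core stride on the 0-100% scale; lead/trail hold the
    ±pad_fraction display padding outside that scale.
    """

    location: str
    stride_id: int
    samples: np.ndarray
    lead: np.ndarray = field(default_factory=lambda: np.array([]))
    trail: np.ndarray = field(default_factory=lambda: np.array([]))
    pad_fraction: float = 0.10


def world_vertical_acceleration(
    stream: SensorStream,
    config: Config | None = None,
    calibration_window: tuple[float, float] = (0.0, 5.0),
) -> np.ndarray:
    """Gravity-free vertical acceleration (m/s^2, up positive) per sample."""
    config = config or Config()
    q = orientation_quaternions(stream, config, calibration_window)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    # third row of the body->world rotation matrix
    r20 = 2.0 * (x * z - w * y)
    r21 = 2.0 * (y * z + w * x)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    a = stream.accel
    az_world = r20 * a[:, 0] + r21 * a[:, 1] + r22 * a[:, 2]
    return az_world - GRAVITY


def _cyclic_detrend(x: np.ndarray) -> np.ndarray:
    """Remove the endpoint-to-endpoint ramp and the mean.

    Over one gait cycle the true velocity and displacement are periodic, so
    any net change across the cycle is integration drift; removing the
    connecting ramp enforces cyclicity without distorting the harmonic
    content (a least-squares line would: a sinusoid over one period has a
    nonzero best-fit slope).
    """
    n = len(x)
    ramp = (x[-1] - x[0]) * np.arange(n) / (n - 1)
    out = x - ramp
    return out - out.mean()


def vertical_displacement(
    stream: SensorStream,
    strides: list[StrideIndex],
    config: Config | None = None,
    calibration_window: tuple[float, float] = (0.0, 5.0),
) -> np.ndarray:
    """Continuous vertical displacement (m) over the analyzed strides.

    Samples outside any processed stride are NaN.  Each stride's segment is
    independently integrated and drift-corrected, then the segments are
    concatenated on the stream's time base.
    """
    config = config or Config()
    vc = config.vdisp
    acc = world_vertical_acceleration(stream, config, calibration_window)
    t = stream.time
    out = np.full(stream.n, np.nan)
    for s in strides:
        T = s.duration
        if T < vc.min_stride_s or T > vc.max_stride_s:
            warnings.warn(
                f"{stream.location}: stride {s.stride_id} duration {T:.3f} s "
                "outside integrable range; skipped",
                stacklevel=2,
            )
            continue
        sel = (t >= s.start) & (t < s.end)
        if sel.sum() < 4:
            continue
        a = acc[sel]
        v = integrate.cumulative_trapezoid(a, dx=stream.dt, initial=0.0)
        v = _cyclic_detrend(v)
        z = integrate.cumulative_trapezoid(v, dx=stream.dt, initial=0.0)
        z = _cyclic_detrend(z)
        out[sel] = z
    return out


def cut_and_normalize(
    displacement: np.ndarray,
    time: np.ndarray,
    strides: list[StrideIndex],
    location: str = "",
    config: Config | None = None,
) -> list[DisplacementCurve]:
    """Cut the displacement into per-stride 100-sample normalized curves.

    The core stride (claw-on to claw-on) is linearly interpolated onto the
    0-100% scale; the ±pad_fraction of the stride duration either side is
    resampled into separate lead/trail blocks for display.  Strides whose
    core contains non-finite samples (skipped integrations) are dropped.
    """
    config = config or Config()
    vc = config.vdisp
    n = vc.n_samples
    n_pad = max(int(round(vc.pad_fraction * n)), 1)
    finite = np.isfinite(displacement)
    curves = []
    for s in strides:
        if not s.included:
            continue
        T = s.duration
        core_t = s.start + np.arange(n) / (n - 1) * T
        sel = (time >= s.start) & (time < s.end)
        if not sel.any() or not finite[sel].all():
            continue
        core = np.interp(core_t, time[finite], displacement[finite])
        pad = vc.pad_fraction * T
        lead_t = s.start - pad + np.arange(n_pad) / n_pad * pad
        trail_t = s.end + (np.arange(n_pad) + 1) / n_pad * pad
        lead = np.interp(lead_t, time[finite], displacement[finite])
        trail = np.interp(trail_t, time[finite], displacement[finite])
        lead[lead_t < time[finite][0]] = np.nan
        trail[trail_t > time[finite][-1]] = np.nan
        curves.append(
            DisplacementCurve(
                location=location,
                stride_id=s.stride_id,
                samples=core,
                lead=lead,
                trail=trail,
                pad_fraction=vc.pad_fraction,
            )
        )
    return curves
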