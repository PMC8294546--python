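"""Sagittal distal-limb angle from a limb IMU, and per-stride extrema.

Orientation is tracked with a quaternion complementary filter: gyro rates are
integrated at full weight and the accelerometer's gravity direction corrects
the tilt with weight (1 - gyro_weight) per sample, gated off whenever the
accelerometer norm departs from gravity (hoof impacts, transients).  The
filter is initialized from the standing-still calibration window, which
supplies the gravity reference.

The sagittal angle is the rotation about the mediolateral axis, in degrees,
protraction positive.  Per stride the angle is re-zeroed at that limb's
midstance (temporal midpoint of its stance) before the maxima are read off,
so maximal protraction is positive and maximal retraction negative by
construction in a physiological stride; records violating those signs are
flagged excluded rather than deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import GRAVITY, Config
from .events import GaitEvents, StrideIndex
from .io import SensorStream


class CalibrationError(ValueError):
    """Stream lacks the standing-still calibration window."""


@dataclass
class LimbAngleStride:
    """One limb's angle trace over one stride, re-zeroed at midstance."""

    limb: str
    stride_id: int
    time: np.ndarray
    angle_curve: np.ndarray          # degrees, midstance-zeroed, raw sampling
    max_protraction: float
    max_retraction: float
    included: bool = True
    exclusion_reason: str = ""
    midstance_time: float = float("nan")


def _quat_mul(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def _quat_rot(q, v):
    """Rotate vector v from the body frame into the world frame by q."""
    w, x, y, z = q
    vx, vy, vz = v
    # t = 2 q_vec x v
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return (
        vx + w * tx + (y * tz - z * ty),
        vy + w * ty + (z * tx - x * tz),
        vz + w * tz + (x * ty - y * tx),
    )


def _quat_from_two_vectors(a, b):
    """Shortest rotation taking unit vector a to unit vector b."""
    ax, ay, az = a
    bx, by, bz = b
    cx, cy, cz = ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx
    dot = ax * bx + ay * by + az * bz
    w = 1.0 + dot
    norm = math.sqrt(w * w + cx * cx + cy * cy + cz * cz)
    if norm < 1e-12:  # opposite vectors: pick any perpendicular axis
        return (0.0, 1.0, 0.0, 0.0)
    return (w / norm, cx / norm, cy / norm, cz / norm)


def _normalize(q):
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def orientation_quaternions(
    stream: SensorStream,
    config: Config | None = None,
    calibration_window: tuple[float, float] = (0.0, 5.0),
) -> np.ndarray:
    """Body-to-world orientation quaternion (w,x,y,z) per sample."""
    config = config or Config()
    ac = config.angle
    t0, t1 = calibration_window
    if t1 - t0 < 1.0 or stream.time[0] > t0 or stream.time[-1] < t1:
        raise CalibrationError(
            f"{stream.location}: stream does not cover calibration window "
            f"[{t0}, {t1}] s"
        )
    calib = (stream.time >= t0) & (stream.time < t1)
    if not calib.any():
        raise CalibrationError(f"{stream.location}: empty calibration window")
    a0 = stream.accel[calib].mean(axis=0)
    a0 = a0 / np.linalg.norm(a0)
    # initial tilt: rotate the measured gravity direction onto world +z
    q = _quat_from_two_vectors((0.0, 0.0, 1.0), tuple(a0))
    # (q maps world z to body gravity; orientation body->world is its conjugate)
    q = (q[0], -q[1], -q[2], -q[3])

    dt = stream.dt
    alpha = ac.gyro_weight
    gate = ac.accel_gate_ms2
    gyro = np.deg2rad(stream.gyro)
    accel = stream.accel
    anorm = np.linalg.norm(accel, axis=1)
    out = np.empty((stream.n, 4))
    out[0] = q
    for k in range(1, stream.n):
        wx, wy, wz = gyro[k]
        ang = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
        if ang > 1e-12:
            s = math.sin(0.5 * ang) / (ang / dt)
            dq = (math.cos(0.5 * ang), wx * s, wy * s, wz * s)
            q = _quat_mul(q, dq)
        if abs(anorm[k] - GRAVITY) < gate and anorm[k] > 1e-9:
            av = accel[k]
            aw = _quat_rot(q, (av[0] / anorm[k], av[1] / anorm[k], av[2] / anorm[k]))
            # world-frame tilt error: rotation taking predicted gravity to +z
            corr = _quat_from_two_vectors(aw, (0.0, 0.0, 1.0))
            # fractional (linearized slerp from identity) correction
            f = 1.0 - alpha
            corr = _normalize((1.0 - f + f * corr[0], f * corr[1], f * corr[2], f * corr[3]))
            q = _quat_mul(corr, q)
        q = _normalize(q)
        out[k] = q
    return out


def sagittal_angle_from_quat(quats: np.ndarray, sign: float = 1.0) -> np.ndarray:
    """Rotation about the mediolateral (y) axis, degrees, protraction positive."""
    w, x, y, z = quats[:, 0], quats[:, 1], quats[:, 2], quats[:, 3]
    # rotation-matrix entries R[0,2] and R[2,2] of the body->world matrix
    r02 = 2.0 * (x * z + w * y)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    return sign * np.rad2deg(np.arctan2(r02, r22))


def complementary_filter_angle(
    stream: SensorStream,
    config: Config | None = None,
    calibration_window: tuple[float, float] = (0.0, 5.0),
) -> np.ndarray:
    """Continuous sagittal limb angle (degrees) for one limb stream."""
    config = config or Config()
    quats = orientation_quaternions(stream, config, calibration_window)
    return sagittal_angle_from_quat(quats, config.angle.sign)


def extract_angle_extrema(
    angle: np.ndarray,
    time: np.ndarray,
    strides: list[StrideIndex],
    events: GaitEvents,
    limb: str,
) -> list[LimbAngleStride]:
    """Per-stride midstance-zeroed angle curves and protraction/retraction maxima.

    The maxima are taken over the full stride window.  A stride without a
    stance for the limb is flagged "no stance"; a record whose maximal
    retraction is not negative or maximal protraction not positive is flagged
    excluded by the sign rule (kept, not deleted).
    """
    stance = events.stance_intervals(limb)
    out = []
    for s in strides:
        sel = (time >= s.start) & (time < s.end)
        if not sel.any():
            continue
        seg_t = time[sel]
        seg = angle[sel].astype(float)
        rec = LimbAngleStride(
            limb=limb,
            stride_id=s.stride_id,
            time=seg_t,
            angle_curve=seg,
            max_protraction=float("nan"),
            max_retraction=float("nan"),
        )
        hit = None
        if stance.size:
            inside = (stance[:, 0] >= s.start) & (stance[:, 0] < s.end)
            if inside.any():
                hit = stance[inside][0]
        if hit is None:
            rec.included = False
            rec.exclusion_reason = "no stance"
            out.append(rec)
            continue
        mid = 0.5 * (hit[0] + hit[1])
        rec.midstance_time = mid
        zero = float(np.interp(mid, time, angle))
        seg = seg - zero
        rec.angle_curve = seg
        rec.max_protraction = float(seg.max())
        rec.max_retraction = float(seg.min())
        if not s.included:
            rec.included = False
            rec.exclusion_reason = s.exclusion_reason or "stride excluded"
        elif rec.max_retraction >= 0.0 or rec.max_protraction <= 0.0:
            rec.included = False
            rec.exclusion_reason = "sign rule"
        out.append(rec)
    return out
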