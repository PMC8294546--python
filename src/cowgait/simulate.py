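"""Synthetic IMU trials of a walking cow with fully known ground truth.

The generator emulates the statistical structure the analysis assumes:

* lateral-sequence walk footfalls (LH -> LF -> RH -> RF) with per-limb duty
  factors and phase offsets on a common stride clock, plus independent
  Gaussian jitter on every stance boundary;
* a sagittal distal-limb angle per limb — monotone retraction through stance
  (zero at midstance, exact configured extrema at claw-on/claw-off) and a
  raised-cosine protraction swing — emitted as a mediolateral gyro channel
  (its exact derivative) and an accelerometer that sees gravity rotated by
  the same angle plus a decaying impact burst at each claw-on;
* upper-body vertical displacement built from stride-frequency and
  double-stride-frequency harmonics phased to the footfalls (sacrum/tuber
  coxae peaking near hind midstances, withers near front midstances), with a
  slow sinusoidal wander on head and collar for realism;
* white sensor noise and a 5-second standing-still calibration prefix.

Everything stochastic flows from a single seed.  The returned
:class:`SimTruth` carries the exact event times and continuous-trajectory
samples against which recovery is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import GRAVITY, LIMBS, UPPER_BODY
from .io import SensorStream, Trial

DEFAULT_RATE = 200.0       # Hz, matching the hardware configuration emulated
DEFAULT_CALIB_S = 5.0      # standing-still calibration prefix, seconds


class SimulationError(ValueError):
    """Invalid generator parameters or unrecoverable jitter draw."""


def _limb_map(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [l for l in LIMBS if l not in value]
        if missing:
            raise SimulationError(f"{name} missing limbs {missing}")
        return {l: float(value[l]) for l in LIMBS}
    return {l: float(value) for l in LIMBS}


@dataclass
class GaitParams:
    """Walk timing and distal-limb angle amplitudes.

    duty_factor and phase_offset are fractions of the stride; the left hind
    limb is the stride reference and its phase offset is fixed at zero.
    protraction_max (positive, degrees) and retraction_max (negative) are the
    exact per-stride extrema of the generated distal-limb angle.
    """

    stride_duration: float = 1.33
    duty_factor: dict[str, float] | float = field(
        default_factory=lambda: {"LF": 0.68, "RF": 0.69, "LH": 0.64, "RH": 0.64}
    )
    phase_offset: dict[str, float] | float = field(
        default_factory=lambda: {"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75}
    )
    n_strides: int = 20
    timing_jitter_sd: float = 0.015
    protraction_max: dict[str, float] | float = field(
        default_factory=lambda: {"LF": 25.0, "RF": 26.0, "LH": 24.0, "RH": 23.0}
    )
    retraction_max: dict[str, float] | float = field(
        default_factory=lambda: {"LF": -46.0, "RF": -46.0, "LH": -29.0, "RH": -30.0}
    )

    def __post_init__(self) -> None:
        if self.stride_duration <= 0:
            raise SimulationError("stride_duration must be positive")
        if self.n_strides < 1:
            raise SimulationError("n_strides must be >= 1")
        if self.timing_jitter_sd < 0:
            raise SimulationError("timing_jitter_sd must be >= 0")
        self.duty_factor = _limb_map(self.duty_factor, "duty_factor")
        self.protraction_max = _limb_map(self.protraction_max, "protraction_max")
        self.retraction_max = _limb_map(self.retraction_max, "retraction_max")
        if isinstance(self.phase_offset, dict):
            self.phase_offset = _limb_map(self.phase_offset, "phase_offset")
        else:
            raise SimulationError("phase_offset must map each limb to a fraction")
        for limb in LIMBS:
            d = self.duty_factor[limb]
            if not 0.0 < d < 1.0:
                raise SimulationError(f"duty_factor[{limb}]={d} outside (0,1)")
            phi = self.phase_offset[limb]
            if not 0.0 <= phi < 1.0:
                raise SimulationError(f"phase_offset[{limb}]={phi} outside [0,1)")
            if self.protraction_max[limb] <= 0:
                raise SimulationError(f"protraction_max[{limb}] must be > 0")
            if self.retraction_max[limb] >= 0:
                raise SimulationError(f"retraction_max[{limb}] must be < 0")
        if self.phase_offset["LH"] != 0.0:
            raise SimulationError("LH phase offset is the stride reference; must be 0")
        if len({round(v, 12) for v in self.phase_offset.values()}) != 4:
            raise SimulationError("phase offsets must be distinct")


@dataclass
class HarmonicParams:
    """One location's vertical-displacement composition.

    Amplitudes in meters; phases are the stride fraction at which the
    harmonic peaks.  wander_sd adds slow non-stride motion (head/collar).
    """

    amplitude_h1: float = 0.0
    amplitude_h2: float = 0.0
    phase_h1: float = 0.0
    phase_h2: float = 0.0
    wander_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_h1 < 0 or self.amplitude_h2 < 0:
            raise SimulationError("harmonic amplitudes must be >= 0")
        for p in (self.phase_h1, self.phase_h2):
            if not 0.0 <= p < 1.0:
                raise SimulationError("harmonic phases must be in [0,1)")
        if self.wander_sd < 0:
            raise SimulationError("wander_sd must be >= 0")


def default_upper_body() -> dict[str, HarmonicParams]:
    """Default per-location harmonics.

    The double-stride harmonic dominates the trunk: the sacrum peaks at the
    hind-limb midstances (~25/75% of the stride), the withers at the front
    midstances (~0/50%), the back just before both.  The tuber coxae carry a
    strong stride-frequency component so the ipsilateral peak is the higher
    one; head and collar move mostly at stride frequency with added wander.
    """
    return {
        "sacrum": HarmonicParams(0.004, 0.022, 0.25, 0.25),
        "withers": HarmonicParams(0.003, 0.023, 0.0, 0.0),
        "back": HarmonicParams(0.002, 0.012, 0.47, 0.47),
        "LTC": HarmonicParams(0.030, 0.020, 0.25, 0.25),
        "RTC": HarmonicParams(0.030, 0.020, 0.75, 0.25),
        "head": HarmonicParams(0.030, 0.005, 0.5, 0.0, wander_sd=0.010),
        "collar": HarmonicParams(0.015, 0.004, 0.5, 0.0, wander_sd=0.015),
    }


@dataclass
class UpperBodyParams:
    locations: dict[str, HarmonicParams] = field(default_factory=default_upper_body)

    def __post_init__(self) -> None:
        for loc in self.locations:
            if loc not in UPPER_BODY:
                raise SimulationError(f"unknown upper-body location {loc!r}")


@dataclass
class NoiseParams:
    """White sensor noise and the single seed governing all randomness."""

    accel_noise_sd: float = 0.5   # m/s^2
    gyro_noise_sd: float = 2.0    # deg/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise SimulationError("noise SDs must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated trial, on the signal time base."""

    time: np.ndarray | None = None
    true_events: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    true_angle: dict[str, np.ndarray] = field(default_factory=dict)
    true_vdisp: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# footfall timing


def _jittered_stances(
    params: GaitParams,
    rng: np.random.Generator | None,
    k_lo: int,
    k_hi: int,
    max_retries: int = 20,
) -> dict[str, list[tuple[float, float]]]:
    """Per-limb stance intervals for stride indices k_lo..k_hi-1 (walk time).

    Each boundary gets independent Gaussian jitter; a draw that would invert
    an on/off pair or swallow a swing is redrawn up to ``max_retries`` times,
    after which the generator refuses (the requested jitter is then
    inconsistent with an alternating gait).
    """
    T = params.stride_duration
    sd = params.timing_jitter_sd
    if sd > 0 and rng is None:
        raise SimulationError("timing jitter requested without an RNG")
    margin = 0.02 * T  # minimal stance/swing length preserved under jitter
    out: dict[str, list[tuple[float, float]]] = {}
    total_retries = 0
    for limb in LIMBS:
        phi = params.phase_offset[limb]
        d = params.duty_factor[limb]
        bounds: list[float] = []
        for k in range(k_lo, k_hi):
            bounds.append((k + phi) * T)          # claw-on
            bounds.append((k + phi + d) * T)      # claw-off
        if sd > 0:
            jittered: list[float] = []
            prev = -np.inf
            for i, b in enumerate(bounds):
                nxt = bounds[i + 1] if i + 1 < len(bounds) else np.inf
                for attempt in range(max_retries + 1):
                    cand = b + rng.normal(0.0, sd)
                    if cand > prev + margin and cand < nxt - margin:
                        total_retries += attempt
                        break
                else:
                    raise SimulationError(
                        f"timing jitter sd={sd} repeatedly inverted events for "
                        f"{limb} after {max_retries} retries"
                    )
                jittered.append(cand)
                prev = cand
            bounds = jittered
        out[limb] = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(k_hi - k_lo)]
    if total_retries:
        warnings.warn(
            f"timing jitter sd={sd} inverted event boundaries; "
            f"{total_retries} redraws were needed",
            stacklevel=2,
        )
    return out


def simulate_footfalls(
    params: GaitParams, rng: np.random.Generator | int | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Generate per-limb claw-on/claw-off times over ``n_strides`` strides.

    Returns ``{limb: (claw_on_times, claw_off_times)}`` in walk time (LH
    claw-on of stride 0 at t=0 when jitter is zero).  Stances intersecting
    [0, n_strides*T] are kept, so limbs with a phase offset contribute the
    partial leading stance that a real recording would contain.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    span_end = params.n_strides * params.stride_duration
    stances = _jittered_stances(params, rng, -1, params.n_strides + 1)
    out = {}
    for limb in LIMBS:
        ons, offs = [], []
        for on, off in stances[limb]:
            if off <= 0.0 or on > span_end + 1e-12:
                continue
            ons.append(on)
            offs.append(off)
        out[limb] = (np.array(ons), np.array(offs))
    return out


# ---------------------------------------------------------------------------
# limb angle trajectory

def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d(u: np.ndarray) -> np.ndarray:
    return 6.0 * u * (1.0 - u)


def _limb_trajectory(
    stances: list[tuple[float, float]], p_max: float, r_max: float, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the sagittal angle (deg) and its rate (deg/s) at times ``t``.

    Stance: protraction_max -> 0 (midstance) -> retraction_max via two
    smoothstep quarters (C1, monotone, zero slope at the junctions); swing:
    retraction_max -> protraction_max raised cosine.  Extrema are therefore
    exactly the configured values, attained at claw-on and claw-off.
    """
    theta = np.full(t.shape, p_max, dtype=float)
    omega = np.zeros_like(theta)
    for i, (on, off) in enumerate(stances):
        mid = 0.5 * (on + off)
        h = mid - on
        # first stance half: P -> 0
        m = (t >= on) & (t < mid)
        u = (t[m] - on) / h
        theta[m] = p_max * (1.0 - _smoothstep(u))
        omega[m] = -p_max * _smoothstep_d(u) / h
        # second stance half: 0 -> R
        m = (t >= mid) & (t < off)
        u = (t[m] - mid) / h
        theta[m] = r_max * _smoothstep(u)
        omega[m] = r_max * _smoothstep_d(u) / h
        # swing to the next stance
        if i + 1 < len(stances):
            nxt = stances[i + 1][0]
            w = nxt - off
            m = (t >= off) & (t < nxt)
            u = (t[m] - off) / w
            theta[m] = r_max + (p_max - r_max) * 0.5 * (1.0 - np.cos(np.pi * u))
            omega[m] = (p_max - r_max) * 0.5 * np.pi * np.sin(np.pi * u) / w
    # before the first stance: hold the swing-end/protraction value
    first_on = stances[0][0]
    m = t < first_on
    theta[m] = p_max
    omega[m] = 0.0
    return theta, omega


def _impact_burst(
    t: np.ndarray, onset: float, amplitude: float, freq: float, tau: float
) -> np.ndarray:
    """Decaying high-frequency oscillation starting at ``onset`` (claw-on)."""
    dt = t - onset
    m = (dt >= 0) & (dt < 6.0 * tau)
    out = np.zeros_like(t)
    out[m] = amplitude * np.exp(-dt[m] / tau) * np.sin(2.0 * np.pi * freq * dt[m])
    return out


def simulate_limb_streams(
    params: GaitParams,
    noise: NoiseParams | None = None,
    rate: float = DEFAULT_RATE,
    calib_s: float = DEFAULT_CALIB_S,
    impact_amplitude: float = 20.0,
    impact_freq: float = 40.0,
    impact_tau: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SensorStream], SimTruth]:
    """Synthesize the four distal-limb IMU streams plus ground truth.

    The mediolateral gyro channel is the exact derivative of the angle
    trajectory; the accelerometer reads gravity rotated into the sensor frame
    by the same angle, an impact burst at every claw-on, and white noise.
    A ``calib_s`` standing-still window is prepended; walk time starts at
    t = calib_s on the signal clock.
    """
    noise = noise or NoiseParams()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    stances = _jittered_stances(params, rng, -2, params.n_strides + 2)
    return _limb_streams_from_stances(
        params, noise, stances, rate, calib_s,
        impact_amplitude, impact_freq, impact_tau, rng,
    )


def _limb_streams_from_stances(
    params: GaitParams,
    noise: NoiseParams,
    stances: dict[str, list[tuple[float, float]]],
    rate: float,
    calib_s: float,
    impact_amplitude: float,
    impact_freq: float,
    impact_tau: float,
    rng: np.random.Generator,
) -> tuple[dict[str, SensorStream], SimTruth]:
    T = params.stride_duration
    t_end = calib_s + (params.n_strides + 1) * T
    n = int(round(t_end * rate)) + 1
    t = np.arange(n) / rate
    t_walk = t - calib_s
    truth = SimTruth(time=t)
    streams = {}
    for limb in LIMBS:
        p_max = params.protraction_max[limb]
        r_max = params.retraction_max[limb]
        theta, omega = _limb_trajectory(stances[limb], p_max, r_max, t_walk)
        hold = t_walk < 0.0
        theta[hold] = theta[np.argmax(~hold)]
        omega[hold] = 0.0
        th = np.deg2rad(theta)
        ax = -GRAVITY * np.sin(th)
        az = GRAVITY * np.cos(th)
        if impact_amplitude > 0:
            for on, _off in stances[limb]:
                if 0.0 <= on <= t_walk[-1]:
                    burst = _impact_burst(
                        t_walk, on, impact_amplitude, impact_freq, impact_tau
                    )
                    az = az + burst
                    ax = ax + 0.5 * burst
        accel = np.column_stack([ax, np.zeros(n), az])
        gyro = np.column_stack([np.zeros(n), omega, np.zeros(n)])
        if noise.accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, noise.accel_noise_sd, accel.shape)
        if noise.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, gyro.shape)
        streams[limb] = SensorStream(limb, rate, t, accel, gyro)
        truth.true_angle[limb] = theta
        ons = np.array([on + calib_s for on, off in stances[limb] if 0.0 <= on <= t_walk[-1]])
        offs = np.array(
            [off + calib_s for on, off in stances[limb] if 0.0 <= off <= t_walk[-1] and off > 0]
        )
        truth.true_events[limb] = (ons, offs)
    return streams, truth


# ---------------------------------------------------------------------------
# upper body


def _stride_phase(t_walk: np.ndarray, lh_ons: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous stride coordinate u(t) from the LH claw-on sequence.

    u increases by 1 per LH stride, piecewise linearly between claw-ons;
    extrapolated at nominal rate 1/T outside the observed sequence.  Returns
    (u, du/dt).
    """
    ons = np.asarray(lh_ons, dtype=float)
    k = np.arange(len(ons), dtype=float)
    u = np.interp(t_walk, ons, k)
    lo = t_walk < ons[0]
    hi = t_walk > ons[-1]
    u[lo] = (t_walk[lo] - ons[0]) / T
    u[hi] = k[-1] + (t_walk[hi] - ons[-1]) / T
    dudt = np.empty_like(u)
    idx = np.clip(np.searchsorted(ons, t_walk, side="right") - 1, 0, len(ons) - 2)
    dudt[:] = 1.0 / (ons[idx + 1] - ons[idx])
    dudt[lo] = 1.0 / T
    dudt[hi] = 1.0 / T
    return u, dudt


def _harmonic_z(hp: HarmonicParams, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z(u) and d2z/du2 for the two stride harmonics (peak-phase convention)."""
    w1, w2 = 2.0 * np.pi, 4.0 * np.pi
    z = hp.amplitude_h1 * np.cos(w1 * (u - hp.phase_h1)) + hp.amplitude_h2 * np.cos(
        w2 * (u - hp.phase_h2)
    )
    d2z = -hp.amplitude_h1 * w1 ** 2 * np.cos(w1 * (u - hp.phase_h1)) - (
        hp.amplitude_h2 * w2 ** 2 * np.cos(w2 * (u - hp.phase_h2))
    )
    return z, d2z


def simulate_upper_body_streams(
    gait: GaitParams,
    ub: UpperBodyParams | None = None,
    noise: NoiseParams | None = None,
    rate: float = DEFAULT_RATE,
    calib_s: float = DEFAULT_CALIB_S,
    lh_claw_ons: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SensorStream], SimTruth]:
    """Synthesize upper-body IMU streams plus displacement ground truth.

    Each location's vertical displacement is the two-harmonic composition
    phased to the (possibly jittered) LH stride clock; the emitted vertical
    accelerometer channel is gravity plus the exact second derivative plus
    noise.  ``lh_claw_ons`` (walk time) can be passed to share one footfall
    realization with the limb streams.
    """
    ub = ub or UpperBodyParams()
    noise = noise or NoiseParams()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    T = gait.stride_duration
    if lh_claw_ons is None:
        stances = _jittered_stances(gait, rng, -2, gait.n_strides + 2)
        lh_claw_ons = np.array([on for on, _ in stances["LH"]])
    t_end = calib_s + (gait.n_strides + 1) * T
    n = int(round(t_end * rate)) + 1
    t = np.arange(n) / rate
    t_walk = t - calib_s
    u, dudt = _stride_phase(t_walk, np.asarray(lh_claw_ons), T)
    truth = SimTruth(time=t)
    streams = {}
    for loc, hp in ub.locations.items():
        z, d2z_du2 = _harmonic_z(hp, u)
        zacc = d2z_du2 * dudt ** 2
        if hp.wander_sd > 0:
            freqs = rng.uniform(0.05, 0.3, size=3)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
            amp = hp.wander_sd / np.sqrt(1.5)
            for f, ph in zip(freqs, phases):
                w = 2.0 * np.pi * f
                z = z + amp * np.sin(w * t_walk + ph)
                zacc = zacc - amp * w ** 2 * np.sin(w * t_walk + ph)
        hold = t_walk < 0.0
        z[hold] = z[np.argmax(~hold)]
        zacc[hold] = 0.0
        accel = np.column_stack([np.zeros(n), np.zeros(n), GRAVITY + zacc])
        gyro = np.zeros((n, 3))
        if noise.accel_noise_sd > 0:
            accel = accel + rng.normal(0.0, noise.accel_noise_sd, accel.shape)
        if noise.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_noise_sd, gyro.shape)
        streams[loc] = SensorStream(loc, rate, t, accel, gyro)
        truth.true_vdisp[loc] = z
    return streams, truth


# ---------------------------------------------------------------------------
# whole trial


def simulate_trial(
    gait: GaitParams | None = None,
    ub: UpperBodyParams | None = None,
    noise: NoiseParams | None = None,
    cow_id: str = "sim01",
    measurement_id: str = "m01",
    rate: float = DEFAULT_RATE,
    calib_s: float = DEFAULT_CALIB_S,
    impact_amplitude: float = 20.0,
) -> tuple[Trial, SimTruth]:
    """Simulate one full 11-sensor trial sharing a single footfall realization."""
    gait = gait or GaitParams()
    ub = ub or UpperBodyParams()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(noise.seed)
    stances = _jittered_stances(gait, rng, -2, gait.n_strides + 2)
    limb_streams, truth = _limb_streams_from_stances(
        gait, noise, stances, rate, calib_s, impact_amplitude, 40.0, 0.02, rng
    )
    lh_ons = np.array([on for on, _ in stances["LH"]])
    ub_streams, ub_truth = simulate_upper_body_streams(
        gait, ub, noise, rate, calib_s, lh_claw_ons=lh_ons, rng=rng
    )
    truth.true_vdisp = ub_truth.true_vdisp
    streams = {**limb_streams, **ub_streams}
    trial = Trial(
        cow_id=cow_id,
        measurement_id=measurement_id,
        streams=streams,
        calibration_window=(0.0, calib_s),
    )
    return trial, truth


def write_truth(truth: SimTruth, path) -> None:
    """Write ground truth as a long-format sidecar table (kind, key, index, value)."""
    from pathlib import Path

    lines = ["kind\tkey\tindex\tvalue"]
    for limb, (ons, offs) in truth.true_events.items():
        for i, v in enumerate(ons):
            lines.append(f"event\t{limb}:claw_on\t{i}\t{v:.17g}")
        for i, v in enumerate(offs):
            lines.append(f"event\t{limb}:claw_off\t{i}\t{v:.17g}")
    for limb, arr in truth.true_angle.items():
        for i, v in enumerate(arr):
            lines.append(f"angle\t{limb}\t{i}\t{v:.17g}")
    for loc, arr in truth.true_vdisp.items():
        for i, v in enumerate(arr):
            lines.append(f"vdisp\t{loc}\t{i}\t{v:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
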