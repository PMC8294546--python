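import numpy as np
import pytest
from scipy import integrate

from cowgait import GRAVITY
from cowgait.simulate import (
    GaitParams,
    HarmonicParams,
    NoiseParams,
    SimulationError,
    UpperBodyParams,
    simulate_footfalls,
    simulate_upper_body_streams,
)


def quarter_params(duty=0.66, T=1.0, n=3, jitter=0.0, **kw):
    return GaitParams(
        stride_duration=T,
        duty_factor=duty,
        phase_offset={"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75},
        n_strides=n,
        timing_jitter_sd=jitter,
        **kw,
    )


def support_count_at(footfalls, t):
    """Interval-intersection oracle: limbs in stance at time t."""
    n = 0
    for limb, (ons, offs) in footfalls.items():
        for on in ons:
            off = offs[offs > on]
            if off.size and on <= t < off[0]:
                n += 1
    return n


class TestFootfalls:
    def test_jitter_free_stances_are_exact(self):
        ff = simulate_footfalls(quarter_params())
        ons, offs = ff["LH"]
        assert np.allclose(ons[:3], [0.0, 1.0, 2.0])
        assert np.allclose(offs[:3], [0.66, 1.66, 2.66])

    def test_duty_factor_is_exact_without_jitter(self):
        p = quarter_params(duty={"LH": 0.64, "LF": 0.68, "RH": 0.64, "RF": 0.69}, n=5)
        ff = simulate_footfalls(p)
        for limb in ("LH", "LF", "RH", "RF"):
            ons, offs = ff[limb]
            k = min(len(ons), len(offs))
            # stance/stride ratio equals the programmed duty factor exactly
            stance = offs[offs > ons[0]][: k - 1] - ons[: k - 1]
            assert np.allclose(stance, p.duty_factor[limb] * p.stride_duration)

    def test_walk_support_count_alternates_3_2(self):
        p = quarter_params(duty={"LH": 0.64, "LF": 0.68, "RH": 0.64, "RF": 0.69}, n=4)
        ff = simulate_footfalls(p)
        # sample within each elementary interval of one interior stride
        probes = 1.0 + np.array([0.07, 0.20, 0.35, 0.47, 0.57, 0.70, 0.84, 0.97])
        counts = [support_count_at(ff, t) for t in probes]
        assert counts == [3, 2, 3, 2, 3, 2, 3, 2]

    def test_excessive_jitter_errors_or_reports_retries(self):
        # jitter half a stride long cannot keep on/off pairs ordered outright:
        # the generator must either refuse or report its bounded redraws
        p = quarter_params(jitter=0.5)
        with pytest.warns(UserWarning, match="redraws"):
            try:
                ff = simulate_footfalls(p, rng=np.random.default_rng(0))
            except SimulationError:
                pytest.skip("generator refused outright, also acceptable")
        for limb, (ons, offs) in ff.items():
            merged = np.sort(np.concatenate([ons, offs]))
            assert np.all(np.diff(merged) > 0)

    def test_jittered_events_still_alternate(self):
        p = quarter_params(jitter=0.02, n=20)
        ff = simulate_footfalls(p, rng=np.random.default_rng(1))
        for limb, (ons, offs) in ff.items():
            merged = np.sort(np.concatenate([ons, offs]))
            assert np.all(np.diff(merged) > 0)


class TestLimbStreams:
    def test_angle_range_spans_programmed_extrema(self, clean_limb_sim):
        gait, _, truth = clean_limb_sim
        for limb in ("LF", "LH"):
            walk = truth.true_angle[limb][1000:]
            rng_deg = walk.max() - walk.min()
            expect = gait.protraction_max[limb] - gait.retraction_max[limb]
            assert rng_deg == pytest.approx(expect, abs=0.5)

    def test_gyro_integrates_back_to_true_angle(self, clean_limb_sim):
        _, streams, truth = clean_limb_sim
        s = streams["LF"]
        walk = s.time >= 5.0
        om = s.gyro[walk, 1]
        integ = integrate.cumulative_trapezoid(om, dx=s.dt, initial=0.0)
        integ += truth.true_angle["LF"][walk][0]
        assert np.abs(integ - truth.true_angle["LF"][walk]).max() < 0.1

    def test_calibration_prefix_is_still(self, clean_limb_sim):
        _, streams, _ = clean_limb_sim
        s = streams["LH"]
        calib = s.time < 4.5
        assert np.abs(s.gyro[calib]).max() < 1e-9
        assert np.allclose(np.linalg.norm(s.accel[calib], axis=1), GRAVITY)

    def test_positive_retraction_max_is_rejected(self):
        with pytest.raises(SimulationError, match="retraction"):
            GaitParams(retraction_max=5.0)

    def test_nonpositive_protraction_is_rejected(self):
        with pytest.raises(SimulationError, match="protraction"):
            GaitParams(protraction_max=-1.0)


class TestUpperBody:
    def _truth_curve(self, hp, loc="sacrum", n=6):
        gait = GaitParams(n_strides=n, timing_jitter_sd=0.0)
        ub = UpperBodyParams(locations={loc: hp})
        streams, truth = simulate_upper_body_streams(gait, ub, NoiseParams(0, 0, seed=0))
        return gait, streams[loc], truth.true_vdisp[loc], streams[loc].time

    def test_pure_second_harmonic_peaks_at_25_and_75(self):
        gait, _, z, t = self._truth_curve(HarmonicParams(0.0, 0.025, 0.0, 0.25))
        T = gait.stride_duration
        sel = (t >= 5 + T) & (t < 5 + 2 * T)     # one interior stride
        u = (t[sel] - (5 + T)) / T
        zs = z[sel]
        peaks = [u[i] for i in range(1, len(zs) - 1)
                 if zs[i] > zs[i - 1] and zs[i] >= zs[i + 1]]
        assert peaks == pytest.approx([0.25, 0.75], abs=0.02)

    def test_zero_amplitudes_give_constant_gravity(self):
        _, s, z, t = self._truth_curve(HarmonicParams(0.0, 0.0, 0.0, 0.0))
        walk = t >= 5.0
        assert np.allclose(s.accel[walk, 2], GRAVITY)
        assert np.allclose(z, z[0])

    def test_tuber_coxae_first_peak_is_higher(self):
        # analytic evaluation of the two-harmonic sum with the default phases
        hp = HarmonicParams(0.03, 0.02, 0.25, 0.25)
        u = np.linspace(0, 1, 2001)
        z = hp.amplitude_h1 * np.cos(2 * np.pi * (u - 0.25)) + hp.amplitude_h2 * np.cos(
            4 * np.pi * (u - 0.25)
        )
        first = z[(u > 0.1) & (u < 0.4)].max()
        second = z[(u > 0.6) & (u < 0.9)].max()
        assert first > second

    def test_emitted_acceleration_matches_second_difference_of_truth(self):
        gait, s, z, t = self._truth_curve(HarmonicParams(0.004, 0.022, 0.25, 0.25))
        walk = (t >= 6.0) & (t <= 5 + 4 * gait.stride_duration)
        d2z = np.gradient(np.gradient(z, s.dt), s.dt)
        resid = s.accel[walk, 2] - GRAVITY - d2z[walk]
        assert np.abs(resid).max() < 5e-3  # O(dt^2) discretization

    def test_invalid_harmonics_rejected(self):
        with pytest.raises(SimulationError):
            HarmonicParams(-0.01, 0.0, 0.0, 0.0)
        with pytest.raises(SimulationError):
            HarmonicParams(0.01, 0.0, 1.5, 0.0)
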