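import numpy as np
import pytest

from cowgait import Config, GRAVITY
from cowgait.events import (
    GaitEvents,
    detect_claw_events,
    regularity_screen,
    segment_strides,
)
from cowgait.io import SensorStream
from cowgait.simulate import GaitParams, NoiseParams, simulate_limb_streams

from conftest import match_errors


class TestDetection:
    def test_noise_free_events_within_one_sample(self, clean_limb_sim, config):
        _, streams, truth = clean_limb_sim
        dt = streams["LH"].dt
        for limb in ("LH", "LF", "RH", "RF"):
            ons, offs = detect_claw_events(streams[limb], config)
            t_on, t_off = truth.true_events[limb]
            assert match_errors(ons, t_on) <= dt + 1e-9
            assert match_errors(offs, t_off) <= dt + 1e-9

    def test_noisy_events_within_30_ms(self, noisy_limb_sim, config):
        _, streams, truth = noisy_limb_sim
        for limb in ("LH", "LF", "RH", "RF"):
            ons, offs = detect_claw_events(streams[limb], config)
            t_on, t_off = truth.true_events[limb]
            assert match_errors(ons, t_on) <= 0.030
            assert match_errors(offs, t_off) <= 0.030

    def test_quiet_stream_yields_no_events_and_warns(self, config):
        n = 2000
        t = np.arange(n) / 200.0
        accel = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        stream = SensorStream("LH", 200.0, t, accel, np.zeros((n, 3)))
        with pytest.warns(UserWarning, match="no detectable gait"):
            ons, offs = detect_claw_events(stream, config)
        assert ons.size == 0 and offs.size == 0

    def test_detection_is_translation_equivariant(self, config):
        gait = GaitParams(n_strides=6, timing_jitter_sd=0.0)
        streams, _ = simulate_limb_streams(gait, NoiseParams(0, 0, seed=2))
        s = streams["LF"]
        ons, offs = detect_claw_events(s, config)
        delta = 123 * s.dt
        shifted = SensorStream(s.location, s.rate, s.time + delta, s.accel, s.gyro)
        ons2, offs2 = detect_claw_events(shifted, config)
        assert np.allclose(ons2, ons + delta)
        assert np.allclose(offs2, offs + delta)

    @pytest.mark.parametrize("duty,T", [(0.55, 0.9), (0.66, 1.2), (0.75, 1.6)])
    def test_duty_factor_recovery_under_one_percent(self, duty, T, config):
        gait = GaitParams(
            stride_duration=T, duty_factor=duty, n_strides=8, timing_jitter_sd=0.0
        )
        streams, _ = simulate_limb_streams(gait, NoiseParams(0, 0, seed=4))
        ons, offs = detect_claw_events(streams["LH"], config)
        stance = np.array([offs[offs > on][0] - on for on in ons if (offs > on).any()])
        stride = np.diff(ons)
        k = min(len(stance) - 1, len(stride))
        est = (stance[:k] / stride[:k]).mean()
        assert abs(est - duty) < 0.01


class TestSegmentation:
    def _events(self, lh_ons, **others):
        ev = GaitEvents()
        ev.claw_on["LH"] = np.asarray(lh_ons, dtype=float)
        ev.claw_off["LH"] = ev.claw_on["LH"] + 0.6
        for limb in ("LF", "RH", "RF"):
            ons = others.get(limb, ev.claw_on["LH"] + 0.2)
            ev.claw_on[limb] = np.asarray(ons, dtype=float)
            ev.claw_off[limb] = ev.claw_on[limb] + 0.6
        return ev

    def test_consecutive_claw_ons_define_strides(self):
        strides = segment_strides(self._events([1.0, 2.3, 3.6]))
        assert [(s.start, s.end) for s in strides] == [(1.0, 2.3), (2.3, 3.6)]

    def test_n_claw_ons_give_n_minus_one_strides(self):
        ons = np.arange(7) * 1.3
        assert len(segment_strides(self._events(ons))) == 6

    def test_fewer_than_two_claw_ons_give_no_strides(self):
        assert segment_strides(self._events([1.0])) == []

    def test_missing_limb_stance_flags_incomplete_coverage(self):
        ev = self._events([1.0, 2.3, 3.6], RF=[1.2])  # no RF stance in stride 2
        strides = segment_strides(ev)
        assert strides[0].included
        assert not strides[1].included
        assert strides[1].exclusion_reason == "incomplete limb coverage"


class TestRegularityScreen:
    def test_periodic_simulation_has_zero_exclusions(self, clean_trial, config):
        _, _, events, strides = clean_trial
        assert all(s.included for s in strides)

    def test_inflated_stance_excludes_exactly_that_stride(self, config):
        T, d = 1.3, 0.6
        ev = GaitEvents()
        n = 12
        for limb, phi in (("LH", 0.0), ("LF", 0.25), ("RH", 0.5), ("RF", 0.75)):
            ons = (np.arange(n) + phi) * T
            offs = ons + d * T
            ev.claw_on[limb] = ons
            ev.claw_off[limb] = offs
        # inflate one LH stance by 1.3x, staying inside its own stride
        ev.claw_off["LH"] = ev.claw_off["LH"].copy()
        ev.claw_off["LH"][5] = ev.claw_on["LH"][5] + 1.3 * d * T
        strides = regularity_screen(segment_strides(ev), ev, config)
        bad = [s.stride_id for s in strides if not s.included]
        assert bad == [5]
        assert "LH" in strides[5].exclusion_reason

    def test_interval_cap_keeps_longest_runs(self, config):
        config = Config()
        config.screen.max_intervals = 1
        T = 1.3
        ev = GaitEvents()
        for limb, phi in (("LH", 0.0), ("LF", 0.25), ("RH", 0.5), ("RF", 0.75)):
            ons = (np.arange(12) + phi) * T
            ev.claw_on[limb] = ons
            ev.claw_off[limb] = ons + 0.64 * T
        strides = segment_strides(ev)
        strides[4].included = False  # split into runs of 4 and 6
        strides[4].exclusion_reason = "synthetic gap"
        out = regularity_screen(strides, ev, config)
        runs = [s.included for s in out]
        assert sum(runs) == 6  # only the longer run survives the cap
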