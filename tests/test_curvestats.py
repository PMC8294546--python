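import numpy as np
import pytest

from cowgait.curvestats import (
    CurveSet,
    mean_footfall_fractions,
    median_mad_curves,
    most_typical_curve,
    normalize_angle_curves,
    summarize_curves,
)
from cowgait.events import GaitEvents, segment_strides
from cowgait.limbangle import LimbAngleStride
from cowgait.simulate import GaitParams, simulate_footfalls


def _set(samples, ids=None):
    samples = np.asarray(samples, dtype=float)
    ids = list(ids) if ids is not None else list(range(len(samples)))
    return CurveSet(kind="angle", group={}, ids=ids, samples=samples)


class TestMostTypical:
    def test_two_flat_zeros_beat_an_outlier(self):
        cs = _set([np.zeros(100), np.zeros(100), np.full(100, 10.0)], ids=[4, 7, 9])
        assert most_typical_curve(cs) == 4  # earliest of the tied flat curves

    def test_single_curve_is_its_own_typical(self):
        cs = _set([np.ones(100)], ids=[3])
        assert most_typical_curve(cs) == 3

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            most_typical_curve(_set(np.empty((0, 100))))

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(0, 1, (8, 100))
        ids = list(range(8))
        ref = most_typical_curve(_set(samples, ids))
        for _ in range(5):
            perm = rng.permutation(8)
            assert most_typical_curve(_set(samples[perm], [ids[i] for i in perm])) == ref

    def test_matches_brute_force_distance_matrix(self):
        rng = np.random.default_rng(11)
        for metric in ("rms", "mean_abs"):
            samples = rng.normal(0, 1, (10, 100))
            cs = _set(samples)
            # independent brute force: explicit double loop
            totals = np.zeros(10)
            for i in range(10):
                for j in range(10):
                    d = samples[i] - samples[j]
                    totals[i] += (
                        np.sqrt(np.mean(d**2)) if metric == "rms" else np.mean(np.abs(d))
                    )
            assert most_typical_curve(cs, metric) == int(np.argmin(totals))


class TestMedianMad:
    def test_identical_curves_have_zero_mad(self):
        cs = _set([np.sin(np.linspace(0, 6, 100))] * 5)
        med, mad = median_mad_curves(cs)
        assert np.allclose(mad, 0.0)

    def test_symmetric_offsets_give_unit_mad(self):
        base = np.zeros(100)
        cs = _set([base - 1, base, base + 1])
        med, mad = median_mad_curves(cs)
        assert np.allclose(med, 0.0)
        assert np.allclose(mad, 1.0)

    def test_matches_rank_based_oracle_on_random_sets(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, (9, 100))
        med, mad = median_mad_curves(_set(x))
        for col in range(0, 100, 13):
            v = np.sort(x[:, col])
            assert med[col] == v[4]  # middle order statistic of 9
            assert mad[col] == np.sort(np.abs(x[:, col] - v[4]))[4]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (7, 100))
        med1, mad1 = median_mad_curves(_set(x))
        med2, mad2 = median_mad_curves(_set(-2.5 * x))
        assert np.allclose(med2, -2.5 * med1)
        assert np.allclose(mad2, 2.5 * mad1)


class TestNormalization:
    def _record(self, t, angle, stride_id=0):
        return LimbAngleStride(
            limb="LF", stride_id=stride_id, time=t, angle_curve=angle,
            max_protraction=1.0, max_retraction=-1.0,
        )

    def test_ramp_resamples_exactly_to_100_points(self):
        t = np.linspace(2.0, 3.3, 260)
        rec = self._record(t, 5.0 * (t - 2.0))
        cs = normalize_angle_curves([rec])
        assert cs.samples.shape == (1, 100)
        expect = 5.0 * np.linspace(0.0, 1.3, 100)
        assert np.allclose(cs.samples[0], expect, atol=1e-12)

    def test_two_samplings_of_one_curve_agree(self):
        f = lambda t: np.sin(2 * np.pi * t) + 0.3 * np.cos(4 * np.pi * t)
        t1 = np.linspace(0.0, 1.0, 211)
        t2 = np.linspace(0.0, 1.0, 387)
        cs = normalize_angle_curves([self._record(t1, f(t1), 0), self._record(t2, f(t2), 1)])
        assert np.abs(cs.samples[0] - cs.samples[1]).max() < 1e-3

    def test_excluded_strides_are_not_resampled(self):
        t = np.linspace(0, 1, 100)
        good = self._record(t, t, 0)
        bad = self._record(t, t, 1)
        bad.included = False
        cs = normalize_angle_curves([good, bad])
        assert cs.ids == [0]


class TestFootfallFractions:
    def test_quarter_phase_walk_footfall_percentages(self):
        p = GaitParams(
            stride_duration=1.0,
            duty_factor={"LH": 0.64, "LF": 0.68, "RH": 0.64, "RF": 0.69},
            phase_offset={"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75},
            n_strides=8,
            timing_jitter_sd=0.0,
        )
        ff = simulate_footfalls(p)
        ev = GaitEvents(claw_on={l: ff[l][0] for l in ff},
                        claw_off={l: ff[l][1] for l in ff})
        strides = segment_strides(ev)
        frac = mean_footfall_fractions(ev, strides)
        assert frac["LH"]["on"] == pytest.approx(0.0, abs=1e-9)
        assert frac["LF"]["on"] == pytest.approx(25.0, abs=1e-9)
        assert frac["RH"]["on"] == pytest.approx(50.0, abs=1e-9)
        assert frac["RF"]["on"] == pytest.approx(75.0, abs=1e-9)
        assert frac["LH"]["off"] == pytest.approx(64.0, abs=1e-9)

    def test_summary_carries_footfalls_and_valid_typical_id(self):
        rng = np.random.default_rng(8)
        cs = _set(rng.normal(0, 1, (6, 100)), ids=[2, 3, 5, 7, 11, 13])
        summary = summarize_curves(cs)
        assert summary.most_typical_id in cs.ids
        assert summary.n == 6
        assert np.all(summary.mad_curve >= 0)
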