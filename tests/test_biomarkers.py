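"""Biomarker oracles: quadrature, threshold crossings, slopes, series assembly."""

import numpy as np
import pytest

from tdprisk.cell_sim import BeatTrace
from tdprisk.biomarkers import (
    FEATURE_NAMES,
    qnet,
    qinward,
    duration_at_fraction,
    dvmdt_max_repol,
    beat_features,
    variability_series,
    BeatFeatures,
)
from conftest import make_synthetic_beat


def beat_with_currents(currents, cl=2000.0, dt=1.0):
    t = np.arange(0.0, cl + dt / 2, dt)
    zeros = np.zeros_like(t)
    cur = {
        name: currents.get(name, zeros.copy())
        for name in ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito", "INaCa")
    }
    return BeatTrace(beat=1, t=t, vm=zeros - 85.0, cai=zeros + 1e-4, currents=cur)


class TestQnet:
    def test_zero_currents_zero_charge(self):
        assert qnet(beat_with_currents({})) == 0.0

    def test_constant_current_times_cycle_length(self):
        ones = np.ones(2001)
        assert qnet(beat_with_currents({"IKr": ones})) == pytest.approx(2000.0)

    def test_matches_fine_grid_riemann_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 2001.0, 1.0)
        # piecewise-linear synthetic currents from random knots
        currents = {}
        total_fine = 0.0
        t_fine = np.arange(0.0, 2000.0005, 0.001)
        for name in ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito"):
            knots_t = np.linspace(0, 2000, 9)
            knots_v = rng.normal(size=9)
            currents[name] = np.interp(t, knots_t, knots_v)
            total_fine += np.interp(t_fine, knots_t, knots_v)
        expected = float(np.sum(0.5 * (total_fine[1:] + total_fine[:-1]) * 0.001))
        got = qnet(beat_with_currents(currents))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_linear_in_currents(self):
        rng = np.random.default_rng(1)
        a = {n: rng.normal(size=2001) for n in ("INaL", "IKr")}
        b = {n: rng.normal(size=2001) for n in ("INaL", "IKr")}
        summed = {n: a[n] + b[n] for n in a}
        assert qnet(beat_with_currents(summed)) == pytest.approx(
            qnet(beat_with_currents(a)) + qnet(beat_with_currents(b))
        )

    def test_missing_current_named(self):
        beat = beat_with_currents({})
        del beat.currents["IKs"]
        with pytest.raises(ValueError, match="IKs"):
            qnet(beat)


class TestQinward:
    def make_pair(self, scale_cal, scale_nal):
        t = np.arange(0.0, 2001.0, 1.0)
        shape = -np.exp(-(((t - 150) / 60.0) ** 2))
        control = beat_with_currents({"ICaL": shape, "INaL": 0.3 * shape})
        drug = beat_with_currents(
            {"ICaL": scale_cal * shape, "INaL": scale_nal * 0.3 * shape}
        )
        return drug, control

    def test_control_vs_itself_is_one(self):
        drug, control = self.make_pair(1.0, 1.0)
        assert qinward(drug, control) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "s_cal,s_nal,expected", [(0.5, 0.5, 0.5), (0.2, 0.6, 0.4)]
    )
    def test_linear_scaling(self, s_cal, s_nal, expected):
        drug, control = self.make_pair(s_cal, s_nal)
        assert qinward(drug, control) == pytest.approx(expected)

    def test_zero_control_area_rejected(self):
        drug = beat_with_currents({})
        control = beat_with_currents({})
        with pytest.raises(ZeroDivisionError, match="ICaL"):
            qinward(drug, control)


class TestDurationAtFraction:
    def test_square_pulse_both_fractions(self):
        dt = 0.01
        t = np.arange(0.0, 2000.0 + dt / 2, dt)
        v = np.where((t >= 10.0) & (t < 210.0), 40.0, -85.0)
        for frac in (0.5, 0.9):
            d, flag = duration_at_fraction(t, v, frac)
            assert not flag
            assert d == pytest.approx(200.0, abs=2 * dt)

    def test_linear_decay_closed_form(self):
        # peak +40, baseline -85, decay 1 mV/ms: 90% crossing 112.5 ms past peak
        dt = 0.5
        t = np.arange(0.0, 2000.0 + dt / 2, dt)
        v = np.full_like(t, -85.0)
        up = 10.0
        decay = (t >= up) & (t < up + 125.0)
        v[decay] = 40.0 - (t[decay] - up) * 1.0
        d90, _ = duration_at_fraction(t, v, 0.9)
        assert d90 == pytest.approx(0.9 * 125.0, abs=2 * dt)

    def test_fraction_monotonicity(self, synthetic_beat):
        d50, _ = duration_at_fraction(synthetic_beat.t, synthetic_beat.vm, 0.5)
        d90, _ = duration_at_fraction(synthetic_beat.t, synthetic_beat.vm, 0.9)
        assert d90 >= d50

    def test_not_repolarized_sentinel(self):
        t = np.arange(0.0, 2001.0, 1.0)
        v = np.full_like(t, -85.0)
        v[t >= 10.0] = 40.0  # never returns toward baseline
        d, flag = duration_at_fraction(t, v, 0.9)
        assert flag

    @pytest.mark.parametrize("fraction", [0.5, 0.9])
    def test_agrees_with_oversampled_oracle(self, fraction):
        """Crossing times match a 100x-oversampled brute-force search <0.5 ms."""
        coarse = make_synthetic_beat(dt=1.0)
        fine = make_synthetic_beat(dt=0.01)
        d_coarse, _ = duration_at_fraction(coarse.t, coarse.vm, fraction)
        # brute-force oracle on the fine grid: first sample at/below threshold
        v = fine.vm
        iu = int(np.argmax(np.diff(v)))
        after = v[iu:]
        peak = after.max()
        base = float(v[-1000:].mean())
        thr = peak - fraction * (peak - base)
        ipk = iu + int(np.argmax(after))
        j = ipk + int(np.argmax(v[ipk:] <= thr))
        d_oracle = fine.t[j] - fine.t[iu]
        assert abs(d_coarse - d_oracle) < 0.5


class TestDvmdtMaxRepol:
    def test_linear_repolarization_slope(self):
        dt = 0.1
        t = np.arange(0.0, 2000.0 + dt / 2, dt)
        v = np.full_like(t, -85.0)
        up = 10.0
        decay = (t >= up) & (t < up + 125.0)
        v[decay] = 40.0 - (t[decay] - up) * 1.0
        assert dvmdt_max_repol(
            BeatTrace(1, t, v, np.zeros_like(t) + 1e-4, {})
        ) == pytest.approx(-1.0, abs=1e-6)

    def test_injected_bump_detected(self):
        dt = 0.1
        t = np.arange(0.0, 2000.0 + dt / 2, dt)
        v = np.full_like(t, -85.0)
        up = 10.0
        decay = (t >= up) & (t < up + 125.0)
        v[decay] = 40.0 - (t[decay] - up) * 1.0
        bump = (t >= up + 60.0) & (t < up + 65.0)  # inside [APD30, APD90] window
        v[bump] += (t[bump] - (up + 60.0)) * 3.0  # net slope -1 + 3 = +2
        assert dvmdt_max_repol(
            BeatTrace(1, t, v, np.zeros_like(t) + 1e-4, {})
        ) == pytest.approx(2.0, abs=1e-6)

    def test_equals_brute_force_window_max(self, synthetic_beat):
        got = dvmdt_max_repol(synthetic_beat)
        d30, _ = duration_at_fraction(synthetic_beat.t, synthetic_beat.vm, 0.3)
        d90, _ = duration_at_fraction(synthetic_beat.t, synthetic_beat.vm, 0.9)
        iu = int(np.argmax(np.diff(synthetic_beat.vm)))
        t_up = synthetic_beat.t[iu]
        slopes = np.diff(synthetic_beat.vm) / np.diff(synthetic_beat.t)
        mask = (synthetic_beat.t[:-1] >= t_up + d30) & (
            synthetic_beat.t[1:] <= t_up + d90
        )
        assert got == pytest.approx(float(slopes[mask].max()))


class TestBeatFeatures:
    def test_control_vs_itself_identity(self, control_run):
        b = control_run[-1]
        f = beat_features(b, b)
        assert f.qinward == pytest.approx(1.0)
        assert f.apd90 >= f.apd50 >= 0
        assert f.cad90 >= f.cad50 >= 0

    def test_all_features_finite_on_simulated_beat(self, control_run):
        f = beat_features(control_run[-1], control_run[-2])
        vals = f.as_dict()
        assert set(vals) == set(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vals.values())

    def test_missing_cai_rejected(self, control_run):
        b = control_run[-1]
        broken = BeatTrace(b.beat, b.t, b.vm, np.array([]), b.currents)
        with pytest.raises(ValueError, match="Ca"):
            beat_features(broken, b)


class TestVariabilitySeries:
    def make_features(self, n, value=1.0):
        return [
            BeatFeatures(value, value, 1, 2, 3, 4, -1.0) for _ in range(n)
        ]

    def test_window_covers_final_beats(self):
        feats = [
            BeatFeatures(float(i), 1, 1, 2, 3, 4, -1.0) for i in range(1, 1001)
        ]
        out = variability_series(feats, window=500)
        assert len(out["qNet"]) == 500
        assert out["qNet"].values[0] == 501.0
        assert out["qNet"].values[-1] == 1000.0

    def test_constant_features_zero_variance(self):
        out = variability_series(self.make_features(600, 2.5), window=500)
        assert np.var(out["qNet"].values) == 0.0

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            variability_series(self.make_features(499), window=500)

    def test_long_format_export(self):
        from tdprisk.biomarkers import series_to_long_frame

        out = variability_series(
            self.make_features(510), window=500, drug="d", risk="low", sample_id=3
        )
        frame = series_to_long_frame(out.values())
        assert list(frame.columns) == [
            "drug", "risk", "sample_id", "multiplier", "feature", "beat", "value"
        ]
        assert len(frame) == 7 * 500
        assert set(frame["feature"]) == set(out)
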