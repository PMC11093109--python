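"""Filtering, stance detection, off-plate events and radar smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import curvesprint as cs
from curvesprint.preprocess import detect_stance, lowpass_zero_lag, radar_smooth
from curvesprint.pipeline import session_calibrations, process_trial
from conftest import match_stance


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(2000, 3.7)
        np.testing.assert_allclose(lowpass_zero_lag(x, 50, 1000), x, atol=1e-9)

    def test_impulse_response_symmetric(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        y = lowpass_zero_lag(x, 50, 1000)
        np.testing.assert_allclose(y[1000:1900], y[1000:100:-1], atol=1e-10)

    def test_passband_sinusoid_amplitude_and_phase(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        y = lowpass_zero_lag(x, 50, 1000)
        core = slice(1000, 4000)
        # project onto quadrature pair: amplitude within 1%, phase < 0.1 sample
        c = 2 * np.mean(y[core] * np.sin(2 * np.pi * 10 * t[core]))
        s = 2 * np.mean(y[core] * np.cos(2 * np.pi * 10 * t[core]))
        amp = np.hypot(c, s)
        phase_samples = np.arctan2(s, c) / (2 * np.pi * 10) * 1000
        assert abs(amp - 1) < 0.01
        assert abs(phase_samples) < 0.1

    def test_near_idempotent_in_passband(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        y1 = lowpass_zero_lag(x, 50, 1000)
        y2 = lowpass_zero_lag(y1, 50, 1000)
        core = slice(500, 3500)
        assert np.max(np.abs(y2[core] - y1[core])) < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_zero_lag(np.zeros(100), 600, 1000)


class TestDetectStance:
    def test_constant_supra_threshold_spans_record(self):
        t = np.arange(500) / 1000.0
        ev = detect_stance(t, np.full(500, 100.0))
        assert len(ev) == 1
        assert ev[0].t_heelstrike == t[0] and ev[0].t_toeoff == t[-1]

    def test_half_sine_duration_closed_form(self):
        # supra-threshold span of a half-sine: t_c * (1 - (2/pi) asin(thr/peak))
        t = np.arange(0, 0.4, 0.001)
        tc, peak = 0.12, 1500.0
        f = np.where(
            (t >= 0.1) & (t <= 0.1 + tc),
            peak * np.sin(np.pi * np.clip((t - 0.1) / tc, 0, 1)),
            0.0,
        )
        (ev,) = detect_stance(t, f)
        expect = tc * (1 - (2 / np.pi) * np.arcsin(5.0 / peak))
        assert ev.t_c == pytest.approx(expect, abs=1e-3)

    def test_all_zero_force_empty(self):
        t = np.arange(300) / 1000.0
        assert detect_stance(t, np.zeros(300)) == []

    def test_debounce_drops_chatter(self):
        t = np.arange(300) / 1000.0
        f = np.zeros(300)
        f[10:13] = 50.0  # 3 ms blip
        assert detect_stance(t, f) == []


class TestOffplateEvents:
    def test_agreement_with_ground_truth(self, session2, results2):
        _, gt = session2
        off = results2[~results2.on_plate]
        for r in off.itertuples():
            g = match_stance(gt.stances, r.trial_id, r.t_hs)
            assert abs(r.t_hs - g.t_hs) <= 0.005
            assert abs(r.t_to - g.t_to) <= 0.005

    def test_cross_method_agreement_on_plate(self, session2):
        """The same stance timed from force and from markers agrees <= 5 ms."""
        trials, _ = session2
        trial = trials[2]
        cal = session_calibrations(trials[:4])[trial.meta.subject_id]
        from curvesprint.pipeline import _filtered, onplate_events

        _, fmarkers = _filtered(trial)
        (force_ev,) = onplate_events(trial)
        marker_evs = cs.detect_offplate_events(fmarkers, cal, force_ev.leg)
        nearest = min(marker_evs, key=lambda e: abs(e.t_heelstrike - force_ev.t_heelstrike))
        assert abs(nearest.t_heelstrike - force_ev.t_heelstrike) <= 0.005
        assert abs(nearest.t_toeoff - force_ev.t_toeoff) <= 0.005

    def test_rising_marker_yields_no_event(self, session2):
        trials, _ = session2
        cal = session_calibrations(trials[:2])[trials[0].meta.subject_id]
        n = 400
        time = np.arange(n) / 200.0
        z = np.linspace(0.2, 1.0, n)  # never touches down
        markers = cs.MarkerSeries(
            time=time,
            positions={
                lab: np.column_stack([time, time, z])
                for lab in ("LHEEL", "LMET", "RHEEL", "RMET")
            },
        )
        assert cs.detect_offplate_events(markers, cal, "left") == []

    def test_missing_calibration_instructs(self, session2):
        trials, _ = session2
        from curvesprint.preprocess import CalibrationError

        with pytest.raises(CalibrationError, match="on-plate"):
            cs.detect_offplate_events(trials[0].markers, None, "left")


class TestRadarSmooth:
    def test_constant_preserved(self):
        t = np.arange(100) / 47.0
        out = radar_smooth(t, np.full(100, 9.12), 0.32, 47.0)
        np.testing.assert_allclose(out, 9.12)

    def test_spike_attenuated_fifteenfold(self):
        # 0.32 s at 47 Hz rounds to a 15-sample window
        t = np.arange(101) / 47.0
        x = np.full(101, 5.0)
        x[50] += 1.0
        out = radar_smooth(t, x, 0.32, 47.0)
        assert out[50] == pytest.approx(5.0 + 1.0 / 15, abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_max_never_amplified(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 12, size=rng.integers(16, 200))
        t = np.arange(len(x)) / 47.0
        assert radar_smooth(t, x, 0.32, 47.0).max() <= x.max() + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            radar_smooth(np.array([]), np.array([]), 0.32, 47.0)


def test_event_alternation_flagged(results2):
    """Left and right stances alternate along every processed trial."""
    for _, grp in results2.groupby("trial_id"):
        legs = grp.sort_values("t_hs").leg.tolist()
        assert all(a != b for a, b in zip(legs, legs[1:]))
        assert not grp.qc_alternation.any()
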