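"""Biomarker extraction against constructed and closed-form waveforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from cardiopop import (ScalingVector, SurrogateSpec, Trace, detect_alternans,
                       duration_to_recovery, extract_biomarkers,
                       generate_trace_pair, upstroke_time)


def _trace(vm, cai=None, bcl=None):
    n = len(vm)
    bcl = n // 2 if bcl is None else bcl
    cai = np.full(n, 1e-4) if cai is None else cai
    return Trace(time=np.arange(n, dtype=float), vm=np.asarray(vm, float),
                 cai=np.asarray(cai, float), bcl=bcl)


class TestUpstroke:
    def test_linear_ramp_tie_breaks_to_earliest(self):
        sig = np.concatenate([np.full(10, 0.0), np.linspace(0, 50, 11),
                              np.full(19, 50.0)])
        t = upstroke_time(sig, (0, len(sig)))
        assert 10.0 <= t <= 11.0  # earliest max-slope sample

    def test_known_steepest_point_recovered(self):
        """Sigmoid with inflection (steepest slope) at exactly t = 5 ms."""
        t = np.arange(40, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-(t - 5.0) / 1.3))
        assert upstroke_time(sig, (0, 40)) == pytest.approx(5.0, abs=0.5)

    def test_flat_signal_not_captured(self):
        sig = np.full(100, -85.0)
        assert np.isnan(upstroke_time(sig, (0, 100), min_slope=10.0))


class TestDurations:
    def test_triangle_pulse_closed_form(self):
        """Isoceles-ish pulse: instant rise at t=10, linear 100 ms fall from
        peak 40 to baseline -85. The 80% level is crossed 80 ms after the
        peak, so APD80 = (peak time - upstroke) + 80."""
        vm = np.full(200, -85.0)
        vm[10] = 40.0
        vm[10:111] = np.linspace(40.0, -85.0, 101)
        up = upstroke_time(vm, (0, 200))
        d80 = duration_to_recovery(vm, (0, 200), 0.80, upstroke=up)
        d30 = duration_to_recovery(vm, (0, 200), 0.30, upstroke=up)
        assert d80 == pytest.approx((10.0 - up) + 80.0, abs=0.51)
        assert d30 == pytest.approx((10.0 - up) + 30.0, abs=0.51)

    def test_fraction_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tau = rng.uniform(20, 80)
            t = np.arange(400, dtype=float)
            sig = np.where(t < 20, 0.0, 50 * np.exp(-(t - 20) / tau))
            sig[20] = 50.0
            d30 = duration_to_recovery(sig, (0, 400), 0.30)
            d80 = duration_to_recovery(sig, (0, 400), 0.80)
            assert 0 < d30 <= d80

    def test_double_exponential_cat_matches_closed_form(self):
        """Surrogate CaT c(t) = A (e^{-t/tau_d} - e^{-t/tau_r}): the 80%
        recovery time solves the same expression analytically (brentq on the
        exact function is the oracle)."""
        tau_r, tau_d, A = 8.0, 120.0, 5e-4
        t = np.arange(1500, dtype=float)
        cat = 1e-4 + A * (np.exp(-t / tau_d) - np.exp(-t / tau_r))
        cat[0] = 1e-4
        f = lambda x: A * (np.exp(-x / tau_d) - np.exp(-x / tau_r))
        t_peak = np.log(tau_d / tau_r) / (1 / tau_r - 1 / tau_d)
        peak = f(t_peak)
        thr = peak - 0.80 * peak  # baseline is 1e-4, amplitude = peak
        t80 = brentq(lambda x: f(x) - thr, t_peak, 1400.0)
        up = upstroke_time(cat, (0, 1500))
        d80 = duration_to_recovery(cat, (0, 1500), 0.80, upstroke=up)
        assert d80 == pytest.approx(t80 - up, abs=1.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            duration_to_recovery(np.zeros(10), (0, 10), 1.5)

    def test_unresolved_recovery_returns_nan(self):
        """Fused beat: the signal never recovers inside the window."""
        vm = np.full(100, -85.0)
        vm[10:] = 40.0
        assert np.isnan(duration_to_recovery(vm, (0, 100), 0.80))


class TestAlternansRule:
    @pytest.mark.parametrize("pair,expected", [
        ((250.0, 256.0), True),
        ((250.0, 255.0), True),   # boundary: difference of exactly 5 ms
        ((240.0, 242.0), False),
        ((242.0, 240.0), False),
    ])
    def test_threshold_rule_exact(self, pair, expected):
        assert detect_alternans(*pair) is expected

    def test_nan_pair_not_flagged(self):
        assert detect_alternans(np.nan, 250.0) is False


class TestExtraction:
    def test_identical_surrogate_beats_have_no_alternans_and_exact_delay(self):
        spec = SurrogateSpec(targets={"DAPCaT": 13.0})
        trace = generate_trace_pair(ScalingVector(), spec)
        rec = extract_biomarkers(trace)
        assert not rec.alternans_V and not rec.alternans_Ca
        assert rec.DAPCaT == pytest.approx(13.0, abs=0.5)

    def test_injected_alternation_flags_follow_threshold(self):
        spec = SurrogateSpec()
        big = generate_trace_pair(ScalingVector(), spec, alternate_apd80=8.0)
        small = generate_trace_pair(ScalingVector(), spec, alternate_apd80=3.0)
        assert extract_biomarkers(big).alternans_V
        assert not extract_biomarkers(small).alternans_V

    def test_time_shift_invariance(self):
        """Shifting the beat within its window leaves durations unchanged."""
        spec = SurrogateSpec()
        a = extract_biomarkers(generate_trace_pair(ScalingVector(), spec, t_up=10.0))
        b = extract_biomarkers(generate_trace_pair(ScalingVector(), spec, t_up=25.0))
        for name in ("APD80", "APD3080", "CaTD80", "CaTD3080", "CaTMax", "DAPCaT"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-6)

    def test_calcium_amplitude_scale_invariance(self):
        """Scaling Cai by c > 0 scales CaTMax by c and leaves CaTD3080 fixed."""
        trace = generate_trace_pair(ScalingVector(), SurrogateSpec())
        scaled = Trace(time=trace.time, vm=trace.vm, cai=3.0 * trace.cai,
                       bcl=trace.bcl)
        a = extract_biomarkers(trace)
        b = extract_biomarkers(scaled)
        assert b.CaTMax == pytest.approx(3.0 * a.CaTMax, rel=1e-9)
        assert b.CaTD3080 == pytest.approx(a.CaTD3080, abs=1e-9)
        assert b.CaTD80 == pytest.approx(a.CaTD80, abs=1e-9)

    def test_mismatched_trace_length_rejected(self):
        trace = generate_trace_pair(ScalingVector(), SurrogateSpec(), bcl=800)
        with pytest.raises(ValueError, match="BCL"):
            extract_biomarkers(trace, bcl=1000)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(apd80=st.floats(150.0, 400.0), ratio=st.floats(0.3, 0.95),
           dapcat=st.floats(0.0, 40.0))
    def test_surrogate_round_trip_for_arbitrary_targets(self, apd80, ratio,
                                                        dapcat):
        """Extraction inverts the generator across the whole target space."""
        spec = SurrogateSpec(targets={"APD80": apd80, "APD3080": ratio,
                                      "DAPCaT": dapcat})
        rec = extract_biomarkers(generate_trace_pair(ScalingVector(), spec))
        assert rec.APD80 == pytest.approx(apd80, abs=1.0)
        assert rec.APD3080 == pytest.approx(ratio, abs=0.01)
        assert rec.DAPCaT == pytest.approx(dapcat, abs=1.0)

    def test_baseline_cell_invariants(self, baseline_record_1500):
        rec = baseline_record_1500
        assert rec.captured
        assert 0 < rec.APD30 <= rec.APD80 < 1500
        assert 0 < rec.APD3080 <= 1
        assert 0 < rec.CaTD30 <= rec.CaTD80
        assert 0 < rec.CaTD3080 <= 1
        assert rec.CaTMax > 1e-4  # above diastolic calcium
        assert rec.DAPCaT > 0

    def test_beat_choice_mean_averages_the_two_beats(self):
        spec = SurrogateSpec()
        trace = generate_trace_pair(ScalingVector(), spec, alternate_apd80=8.0)
        final = extract_biomarkers(trace, beat="final")
        mean = extract_biomarkers(trace, beat="mean")
        assert mean.APD80 == pytest.approx(final.APD80 + 4.0, abs=0.6)
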