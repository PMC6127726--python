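"""puff_metrics: reference, kinetics, staircase steps, channel counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pufflab import (
    compute_kinetics,
    compute_reference,
    count_channels,
    estimate_unitary_step,
    pool_unitary_step,
)
from pufflab.errors import ValidationError
from pufflab.puff_metrics import StepEstimate

from conftest import DT, make_event


def triangle_trace(n_pre=5, n_up=10, n_down=10, n_post=5, f_pre=1.0, amp=0.5):
    up = f_pre + amp * np.arange(n_up + 1) / n_up
    down = f_pre + amp * (1 - np.arange(1, n_down + 1) / n_down)
    return np.concatenate([np.full(n_pre, f_pre), up, down, np.full(n_post, f_pre)])


def staircase_trace(levels, plateau=5, n_pre=0):
    parts = [np.full(n_pre, levels[0])] if n_pre else []
    parts += [np.full(plateau, lv) for lv in levels]
    return np.concatenate(parts)


class TestReference:
    def test_flat_outside_transient(self):
        trace = triangle_trace()
        ev = make_event(trace, peak_idx=15, core=(6, 24))
        assert compute_reference(ev) == pytest.approx(1.0)
        assert ev.amplitude_dF == pytest.approx(0.5)

    def test_elevated_post_baseline_averages(self):
        trace = np.concatenate([np.full(10, 1.0), [2.0, 2.0], np.full(10, 1.2)])
        ev = make_event(trace, peak_idx=10, core=(10, 11))
        assert compute_reference(ev) == pytest.approx(1.1)

    def test_event_at_end_one_sided(self):
        trace = np.concatenate([np.full(12, 1.0), np.linspace(1.0, 1.5, 5)])
        ev = make_event(trace, peak_idx=16, core=(13, 16))
        f_pre = compute_reference(ev)
        assert f_pre == pytest.approx(1.0)
        assert "one_sided_reference" in ev.flags

    def test_no_reference_frames_flagged(self):
        trace = np.linspace(1.0, 1.5, 6)
        ev = make_event(trace, peak_idx=5, core=(0, 5))
        f_pre = compute_reference(ev)
        assert f_pre == trace[0]
        assert "no_reference" in ev.flags


class TestKinetics:
    def test_triangle_closed_form(self):
        # linear 10-frame rise: 20% level crossed 2 frames up -> rise = 8 frames
        ev = make_event(triangle_trace(), peak_idx=15, core=(6, 24))
        compute_reference(ev)
        k = compute_kinetics(ev)
        assert k.rise_ms == pytest.approx(0.8 * 10 * DT * 1e3, abs=1e-9)
        assert k.decay_ms == pytest.approx(0.8 * 10 * DT * 1e3, abs=1e-9)
        # FWHM of a triangle = half the base
        assert k.fwhm_ms == pytest.approx(10 * DT * 1e3, abs=1e-9)

    def test_symmetric_pulse_rise_equals_decay(self):
        ev = make_event(triangle_trace(n_up=7, n_down=7), peak_idx=12, core=(6, 18))
        compute_reference(ev)
        k = compute_kinetics(ev)
        assert k.rise_ms == pytest.approx(k.decay_ms, abs=1e-9)

    def test_asymmetric_interpolated_crossings(self):
        # rise 4 frames, decay 12 frames; crossings at fractional frames
        ev = make_event(triangle_trace(n_up=4, n_down=12), peak_idx=9, core=(6, 20))
        compute_reference(ev)
        k = compute_kinetics(ev)
        assert k.rise_ms == pytest.approx(0.8 * 4 * DT * 1e3, abs=1e-6)
        assert k.decay_ms == pytest.approx(0.8 * 12 * DT * 1e3, abs=1e-6)
        assert k.fwhm_ms == pytest.approx(0.5 * (4 + 12) * DT * 1e3, abs=1e-6)

    def test_single_frame_spike_bounded_by_dt(self):
        trace = np.concatenate([np.full(12, 1.0), [1.6], np.full(12, 1.0)])
        ev = make_event(trace, peak_idx=12, core=(12, 12))
        compute_reference(ev)
        k = compute_kinetics(ev)
        assert 0 <= k.rise_ms <= DT * 1e3
        assert 0 <= k.decay_ms <= DT * 1e3

    def test_right_censored_decay_flagged(self):
        trace = np.concatenate([np.full(12, 1.0), np.linspace(1.0, 1.6, 8)])
        ev = make_event(trace, peak_idx=19, core=(13, 19))
        compute_reference(ev)
        k = compute_kinetics(ev)
        assert "right_censored" in k.flags
        assert k.decay_ms == pytest.approx((len(trace) - 1 - 19) * DT * 1e3)

    def test_requires_positive_amplitude(self):
        ev = make_event(np.full(20, 1.0), peak_idx=10, core=(10, 10))
        compute_reference(ev)
        with pytest.raises(ValidationError):
            compute_kinetics(ev)

    @given(shift=st.floats(-0.5, 2.0), scale=st.floats(0.1, 10.0),
           n_up=st.integers(3, 12), n_down=st.integers(3, 12))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_and_scale_invariance(self, shift, scale, n_up, n_down):
        base = triangle_trace(n_pre=12, n_up=n_up, n_down=n_down, n_post=12)
        peak = 12 + n_up
        ev1 = make_event(base, peak_idx=peak, core=(13, 12 + n_up + n_down - 1))
        compute_reference(ev1)
        k1 = compute_kinetics(ev1)
        ev2 = make_event(base * scale + shift, peak_idx=peak,
                         core=(13, 12 + n_up + n_down - 1))
        compute_reference(ev2)
        k2 = compute_kinetics(ev2)
        for a, b in [(k1.rise_ms, k2.rise_ms), (k1.decay_ms, k2.decay_ms),
                     (k1.fwhm_ms, k2.fwhm_ms)]:
            assert a == pytest.approx(b, abs=1e-6)
        assert k2.fwhm_ms <= k2.rise_ms + k2.decay_ms + 1e-9


class TestUnitarySteps:
    def test_noise_free_staircase_exact(self):
        trace = staircase_trace([1.303, 1.202, 1.101, 1.000], plateau=4)
        ev = make_event(trace, peak_idx=0, core=(0, 11))
        est = estimate_unitary_step(ev)
        assert est.n_steps == 3
        assert est.unitary_dF == pytest.approx(0.101, abs=1e-9)
        assert est.step_levels == pytest.approx([1.303, 1.202, 1.101, 1.000])

    def test_noisy_staircase_within_tolerance(self, rng):
        trace = staircase_trace([1.404, 1.303, 1.202, 1.101, 1.000], plateau=6)
        trace = trace + rng.normal(0, 0.01, trace.size)
        ev = make_event(trace, peak_idx=0, core=(0, len(trace) - 1))
        est = estimate_unitary_step(ev)
        assert est.n_steps >= 2
        assert est.unitary_dF == pytest.approx(0.101, abs=0.01)

    def test_smooth_decay_not_stairlike(self):
        t = np.arange(40.0)
        trace = 1.0 + 0.5 * np.exp(-t / 6.0)
        ev = make_event(trace, peak_idx=0, core=(0, 39))
        est = estimate_unitary_step(ev)
        assert ("not_stairlike" in est.flags) or est.n_steps <= 2

    def test_short_decay_segment_rejected(self):
        ev = make_event(np.array([1.5, 1.2, 1.0]), peak_idx=0, core=(0, 2))
        with pytest.raises(ValidationError):
            estimate_unitary_step(ev)

    def test_monotone_levels_invariant(self, rng):
        trace = staircase_trace([1.5, 1.35, 1.18, 1.0], plateau=5)
        trace = trace + rng.normal(0, 0.02, trace.size)
        ev = make_event(trace, peak_idx=0, core=(0, len(trace) - 1))
        est = estimate_unitary_step(ev)
        assert all(a > b for a, b in zip(est.step_levels, est.step_levels[1:]))


class TestChannelCounts:
    @pytest.mark.parametrize("dF, expected", [(0.101, 1.0), (0.303, 3.0), (0.505, 5.0)])
    def test_quantal_formula(self, dF, expected):
        ev = make_event(np.array([1.0, 1.0 + dF, 1.0]), peak_idx=1)
        ev.amplitude_dF = dF
        assert count_channels(ev) == pytest.approx(expected)
        assert ev.n_channels_round == int(expected)

    def test_zero_amplitude_reports_zero_with_flag(self):
        ev = make_event(np.full(3, 1.0), peak_idx=1)
        ev.amplitude_dF = 0.0
        assert count_channels(ev) == 0.0
        assert ev.n_channels_round == 0
        assert "nonpositive_amplitude" in ev.flags

    def test_small_positive_amplitude_rounds_to_one(self):
        ev = make_event(np.array([1.0, 1.02, 1.0]), peak_idx=1)
        ev.amplitude_dF = 0.02
        count_channels(ev)
        assert ev.n_channels_round == 1

    def test_invalid_unitary_step_rejected(self):
        ev = make_event(np.array([1.0, 1.2, 1.0]), peak_idx=1)
        ev.amplitude_dF = 0.2
        with pytest.raises(ValidationError):
            count_channels(ev, unitary_dF=0.0)


class TestPooling:
    def test_identical_estimates(self):
        ests = [StepEstimate([1.1, 1.0], 0.1, 1) for _ in range(40)]
        mean, sem, n = pool_unitary_step(ests)
        assert mean == pytest.approx(0.1) and sem == 0.0 and n == 40

    def test_two_values(self):
        ests = [StepEstimate([], 0.09, 1), StepEstimate([], 0.11, 1)]
        mean, sem, n = pool_unitary_step(ests)
        assert mean == pytest.approx(0.10)
        assert sem == pytest.approx(0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            pool_unitary_step([StepEstimate([], math.nan, 0)])
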