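"""detection: baseline stats, normalization, threshold clustering, localization."""

import numpy as np
import pytest

from pufflab import (
    Movie,
    compute_baseline,
    detect_events,
    detect_global_rise,
    fit_centroid,
    normalize_stack,
    render_movie,
)
from pufflab.detection import NormalizedStack, _gauss2d
from pufflab.errors import ValidationError
from pufflab.synthetic_data import GlobalRiseConfig

from conftest import puff_truth, small_config, staircase_puff


def _nstack_from_z(z, pixel_um=0.16, dt_s=0.00532, flash_frame=0):
    z = np.asarray(z, dtype=float)
    shape = z.shape[1:]
    return NormalizedStack(z, np.ones(shape), np.ones(shape),
                           np.ones(shape, dtype=bool), dt_s, pixel_um, flash_frame)


class TestComputeBaseline:
    def test_constant_baseline(self):
        movie = Movie(np.full((20, 4, 4), 100.0), 0.005, 0.16, 10)
        f0, sd = compute_baseline(movie, n_baseline_frames=10)
        assert np.all(f0 == 100) and np.all(sd == 0)

    def test_alternating_pixel_population_sd(self):
        frames = np.full((10, 2, 2), 100.0)
        frames[::2, 0, 0] = 99
        frames[1::2, 0, 0] = 101
        movie = Movie(frames, 0.005, 0.16, 10 - 1)
        # flash at 9 -> odd window; use an even count explicitly
        movie = Movie(frames, 0.005, 0.16, 8)
        f0, sd = compute_baseline(movie, n_baseline_frames=8)
        assert f0[0, 0] == 100 and sd[0, 0] == 1.0  # population s.d. of {99, 101}

    def test_sampling_distribution_of_f0_and_sd(self):
        rng = np.random.default_rng(99)
        frames = rng.normal(100, 5, size=(520, 30, 30))
        movie = Movie(frames, 0.005, 0.16, 510)
        f0, sd = compute_baseline(movie, n_baseline_frames=500)
        # s.e. of mean = 5/sqrt(500) ~ 0.22; of s.d. ~ 5/sqrt(1000) ~ 0.16
        assert (np.abs(f0 - 100) < 1).mean() >= 0.99
        assert (np.abs(sd - 5) < 0.7).mean() >= 0.99

    def test_no_preflash_frames_raises(self):
        movie = Movie(np.zeros((5, 2, 2)), 0.005, 0.16, 0)
        with pytest.raises(ValidationError):
            compute_baseline(movie)


class TestNormalizeStack:
    def test_flat_movie_zero_z(self):
        movie = Movie(np.full((6, 4, 4), 100.0), 0.005, 0.16, 3)
        f0, sd = compute_baseline(movie, 3)
        ns = normalize_stack(movie, f0, np.full((4, 4), 2.0))
        assert np.allclose(ns.z, 0)

    @pytest.mark.parametrize("f_value, expected_z", [(105.0, 2.5), (110.0, 5.0)])
    def test_single_pixel_arithmetic(self, f_value, expected_z):
        # z = ((F/f0) - 1) / (sd/f0): sd is converted to F/F0 units
        frames = np.full((4, 3, 3), 100.0)
        frames[2, 1, 1] = f_value
        movie = Movie(frames, 0.005, 0.16, 1)
        ns = normalize_stack(movie, np.full((3, 3), 100.0), np.full((3, 3), 2.0),
                             gaussian_sigma_px=0.0)
        assert ns.z[2, 1, 1] == pytest.approx(expected_z)

    def test_sigma_zero_matches_arithmetic_oracle_exactly(self, rng):
        frames = rng.uniform(80, 120, size=(5, 6, 6))
        movie = Movie(frames, 0.005, 0.16, 2)
        f0 = rng.uniform(90, 110, size=(6, 6))
        sd = rng.uniform(1, 4, size=(6, 6))
        ns = normalize_stack(movie, f0, sd, gaussian_sigma_px=0.0)
        oracle = (frames / f0 - 1.0) / np.maximum(sd / f0, 1e-3)
        assert np.array_equal(ns.z, oracle)

    def test_dead_pixels_masked(self):
        frames = np.full((4, 3, 3), 100.0)
        f0 = np.full((3, 3), 100.0)
        f0[0, 0] = 0.0
        ns = normalize_stack(Movie(frames, 0.005, 0.16, 1), f0, np.full((3, 3), 2.0))
        assert np.all(ns.z[:, 0, 0] == 0)
        assert not ns.mask_map[0, 0]

    def test_preflash_mean_z_is_zero(self):
        # baseline frames average exactly to f0, so pre-flash z means vanish
        rng = np.random.default_rng(7)
        frames = rng.normal(100, 3, size=(60, 8, 8))
        movie = Movie(frames, 0.005, 0.16, 50)
        f0, sd = compute_baseline(movie, 50)
        ns = normalize_stack(movie, f0, sd)
        mean_pre = ns.z[:50].mean(axis=0)
        assert (np.abs(mean_pre) < 0.1).mean() >= 0.99

    def test_detectability_of_three_channel_puff_with_noise(self):
        # the contract that makes the critical value 0.8 usable at default noise
        cfg = small_config(n_sites=1, noise_model="gaussian", duration_s=4.0)
        truth = staircase_puff(cfg, (3.92, 3.92), onset_s=2.0, n_channels=3, plateau_s=0.1)
        movie = render_movie(cfg, truth)
        f0, sd = compute_baseline(movie, 300)
        ns = normalize_stack(movie, f0, sd)
        fr = int(2.05 / cfg.dt_s)
        assert ns.z[fr, 22:27, 22:27].max() >= 0.8


class TestDetectEvents:
    def test_constant_stack_no_events(self):
        cfg = small_config()
        movie = render_movie(cfg, puff_truth(cfg, np.zeros((0, 2)), []))
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        assert detect_events(ns, movie) == []

    def test_single_puff_recovered(self, single_puff):
        movie, truth, cfg = single_puff
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        events = detect_events(ns, movie)
        assert len(events) == 1
        ev = events[0]
        r, c = ev.peak_rc
        assert abs(r - 24) <= 1 and abs(c - 24) <= 1
        # supra-threshold window covers the true open interval
        p = truth.puffs[0]
        assert ev.core_window[0] <= p.onset_s / cfg.dt_s + 2
        assert ev.core_window[1] >= p.end_s / cfg.dt_s - 2
        assert ev.frame_window[0] <= max(0, ev.core_window[0] - 100) + 1

    def test_two_overlapping_puffs_distinct_sites(self):
        cfg = small_config(n_sites=2)
        truth = puff_truth(
            cfg, [(2.0, 2.0), (5.0, 5.0)],
            [(0, 2.0, 3, [2.2, 2.25, 2.3]), (1, 2.05, 3, [2.25, 2.3, 2.35])],
        )
        movie = render_movie(cfg, truth)
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        events = detect_events(ns, movie)
        assert len(events) == 2
        (x1, y1), (x2, y2) = events[0].centroid_um, events[1].centroid_um
        assert np.hypot(x1 - x2, y1 - y2) > 2.0

    def test_event_count_monotone_in_critical_value(self):
        cfg = small_config(n_sites=3, puff_rate_hz=0.8, duration_s=8.0,
                           noise_model="gaussian", seed=21)
        from pufflab import simulate_movie
        movie, _ = simulate_movie(cfg)
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        counts = [len(detect_events(ns, movie, critical_value=cv))
                  for cv in (0.4, 0.8, 1.6, 3.2)]
        assert counts == sorted(counts, reverse=True)

    def test_trace_is_unfiltered_roi_mean(self, single_puff):
        movie, truth, cfg = single_puff
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        ev = detect_events(ns, movie)[0]
        r, c = ev.peak_rc
        w0, w1 = ev.frame_window
        manual = (movie.frames[w0:w1 + 1, r - 5:r + 6, c - 5:c + 6]
                  / f0[r - 5:r + 6, c - 5:c + 6]).mean(axis=(1, 2))
        assert np.allclose(ev.trace, manual)


class TestFitCentroid:
    def test_symmetric_gaussian_on_pixel_centre(self):
        z = np.zeros((1, 15, 15))
        cols, rows = np.meshgrid(np.arange(15.0), np.arange(15.0))
        z[0] = _gauss2d((cols, rows), 10.0, 7.0, 7.0, 1.5, 0.0)
        ns = _nstack_from_z(z)
        from conftest import make_event
        ev = make_event(np.array([1.0, 2.0, 1.0]), peak_idx=1)
        ev.peak_frame = 0
        ev.peak_rc = (7, 7)
        fit_centroid(ev, ns)
        assert ev.centroid_um[0] == pytest.approx((7 + 0.5) * 0.16, abs=1e-6)
        assert ev.centroid_um[1] == pytest.approx((7 + 0.5) * 0.16, abs=1e-6)

    def test_subpixel_offset_recovered(self):
        # noise-free rendered puff at +0.3, -0.2 px from a pixel centre
        cfg = small_config(n_sites=1)
        x_um = (24 + 0.5 + 0.3) * cfg.pixel_um
        y_um = (24 + 0.5 - 0.2) * cfg.pixel_um
        truth = staircase_puff(cfg, (x_um, y_um), onset_s=2.0, n_channels=3, plateau_s=0.3)
        movie = render_movie(cfg, truth)
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        ev = detect_events(ns, movie)[0]
        fit_centroid(ev, ns)
        assert abs(ev.centroid_um[0] - x_um) / cfg.pixel_um < 0.05
        assert abs(ev.centroid_um[1] - y_um) / cfg.pixel_um < 0.05

    def test_flat_roi_flagged(self):
        from conftest import make_event
        ns = _nstack_from_z(np.zeros((1, 15, 15)))
        ev = make_event(np.array([1.0, 2.0, 1.0]), peak_idx=1)
        ev.peak_frame = 0
        ev.peak_rc = (7, 7)
        before = ev.centroid_um
        fit_centroid(ev, ns)
        assert "centroid_fit_failed" in ev.flags
        assert ev.centroid_um == before


class TestGlobalRise:
    def test_no_rise_returns_none(self, single_puff):
        movie, _, _ = single_puff
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        assert detect_global_rise(ns) is None

    def test_all_zero_stack_none(self):
        assert detect_global_rise(_nstack_from_z(np.zeros((50, 8, 8)))) is None

    def test_onset_detected_within_half_second(self):
        cfg = small_config(
            duration_s=8.0, noise_model="gaussian",
            global_rise=GlobalRiseConfig(onset_s=4.0, wave_speed_um_s=30.0, plateau_dF=1.0),
        )
        movie = render_movie(cfg, puff_truth(cfg, np.zeros((0, 2)), []))
        f0, sd = compute_baseline(movie, 150)
        ns = normalize_stack(movie, f0, sd)
        onset = detect_global_rise(ns)
        assert onset is not None
        assert abs(onset * cfg.dt_s - 4.0) < 0.5
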