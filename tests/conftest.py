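"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; movies are small fields and
short durations so the suite stays fast, with the full acquisition
geometry exercised only where a test's claim depends on it.
"""

from __future__ import annotations

import numpy as np
import pytest

from pufflab.detection import PuffEvent
from pufflab.synthetic_data import (
    ChannelCountDist,
    GroundTruth,
    PuffRecord,
    SimulationConfig,
    render_movie,
)

DT = 0.00532
PX = 0.16


def make_event(
    trace,
    peak_idx: int | None = None,
    core: tuple[int, int] | None = None,
    dt_s: float = DT,
    pixel_um: float = PX,
    centroid_um: tuple[float, float] = (1.0, 1.0),
    event_id: int = 0,
) -> PuffEvent:
    """Build a PuffEvent whose frame_window starts at 0, so trace indices
    and frame numbers coincide."""
    trace = np.asarray(trace, dtype=float)
    if peak_idx is None:
        peak_idx = int(np.argmax(trace))
    if core is None:
        core = (peak_idx, peak_idx)
    return PuffEvent(
        event_id=event_id,
        peak_frame=peak_idx,
        peak_rc=(0, 0),
        centroid_um=centroid_um,
        core_window=core,
        frame_window=(0, len(trace) - 1),
        trace=trace,
        dt_s=dt_s,
        pixel_um=pixel_um,
    )


def make_point_event(x_um: float, y_um: float, peak_frame: int = 0,
                     event_id: int = 0) -> PuffEvent:
    """Minimal event with just a centroid and a time, for site assignment."""
    ev = make_event(np.array([1.0, 2.0, 1.0]), peak_idx=1, core=(1, 1),
                    centroid_um=(x_um, y_um), event_id=event_id)
    ev.peak_frame = peak_frame
    ev.frame_window = (peak_frame - 1, peak_frame + 1)
    ev.core_window = (peak_frame, peak_frame)
    return ev


def small_config(**overrides) -> SimulationConfig:
    """A fast default: small field, short record, no sites unless asked."""
    base = dict(
        n_sites=0,
        field_px=(48, 48),
        duration_s=5.0,
        flash_time_s=1.0,
        site_min_sep_um=2.0,
        puff_rate_hz=0.0,
        latency_scale_s=0.0,
        noise_model="none",
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def puff_truth(config: SimulationConfig, site_xy_um, puffs) -> GroundTruth:
    """GroundTruth from explicit (site, onset_s, n_channels, closure_s) tuples."""
    records = [PuffRecord(site_id=s, onset_s=t, n_channels=n, closure_s=list(c))
               for s, t, n, c in puffs]
    return GroundTruth(np.asarray(site_xy_um, dtype=float), records, None, config)


def staircase_puff(config: SimulationConfig, site_xy_um, onset_s: float,
                   n_channels: int, plateau_s: float) -> GroundTruth:
    """One puff whose channels close one per plateau, giving a clean staircase."""
    peak = onset_s + config.rise_ms / 1000.0
    closures = [peak + (k + 1) * plateau_s for k in range(n_channels)]
    return puff_truth(config, [site_xy_um], [(0, onset_s, n_channels, closures)])


@pytest.fixture
def single_puff():
    """Noise-free rendered movie containing one 3-channel puff with long,
    staggered closures; returns (movie, truth, config)."""
    cfg = small_config(n_sites=1)
    truth = staircase_puff(cfg, (3.84, 3.84), onset_s=2.0, n_channels=3, plateau_s=0.12)
    movie = render_movie(cfg, truth)
    return movie, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fixed_channels(k: int) -> ChannelCountDist:
    return ChannelCountDist(kind="fixed", k=k)
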