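"""End-to-end analysis: movie in, events/sites/summary out.

Chains the stages in their canonical order: background correction (if an
extracellular ROI is given), baseline statistics, normalization and
filtering, global-rise detection (which truncates the effective recording
period), threshold-cluster event detection, sub-pixel centroid refinement,
per-puff metrics, site assignment, discovery-curve fitting and the cell
summary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

from . import detection, puff_metrics, site_analysis
from .detection import NormalizedStack, PuffEvent
from .errors import ValidationError
from .movie_io import Movie, subtract_background
from .site_analysis import CellSummary, DiscoveryCurve, ReleaseSite

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Every tunable of the analysis chain, with the defaults the package
    is calibrated for (see docs/methods.md)."""

    n_baseline_frames: int = 500
    gaussian_sigma_px: float = 1.0
    critical_value: float = detection.DEFAULT_CRITICAL_VALUE
    min_px: int = detection.DEFAULT_MIN_PX
    min_frames: int = detection.DEFAULT_MIN_FRAMES
    pad_frames: int = detection.DEFAULT_PAD_FRAMES
    roi_um: float = detection.DEFAULT_ROI_UM
    sep_um: float = site_analysis.DEFAULT_SEP_UM
    unitary_dF: float = puff_metrics.DEFAULT_UNITARY_DF
    n_ref_frames: int = puff_metrics.DEFAULT_N_REF_FRAMES
    bin_s: float = 10.0
    global_area_fraction: float = 0.5
    global_z_level: float = detection.DEFAULT_CRITICAL_VALUE
    estimate_steps: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown analysis parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class AnalysisResult:
    events: list[PuffEvent]
    sites: list[ReleaseSite]
    summary: CellSummary
    discovery: DiscoveryCurve
    nstack: Optional[NormalizedStack] = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def summary_payload(self) -> dict:
        payload = self.summary.to_dict()
        payload["discovery"] = self.discovery.to_dict()
        return payload


def analyze_movie(movie: Movie, params: Optional[AnalysisParams] = None,
                  keep_nstack: bool = False) -> AnalysisResult:
    """Run the full detection and quantification chain on one movie."""
    params = params or AnalysisParams()
    if movie.background_roi is not None:
        movie = subtract_background(movie)
    f0, sd = detection.compute_baseline(movie, params.n_baseline_frames)
    nstack = detection.normalize_stack(movie, f0, sd, params.gaussian_sigma_px)
    global_onset = detection.detect_global_rise(
        nstack, params.global_area_fraction, params.global_z_level
    )
    events = detection.detect_events(
        nstack, movie,
        critical_value=params.critical_value,
        min_px=params.min_px,
        min_frames=params.min_frames,
        pad_frames=params.pad_frames,
        roi_um=params.roi_um,
        end_frame=global_onset,
    )
    for ev in events:
        detection.fit_centroid(ev, nstack, params.roi_um)
        puff_metrics.compute_reference(ev, params.n_ref_frames)
        if ev.amplitude_dF > 0:
            puff_metrics.compute_kinetics(ev)
        puff_metrics.count_channels(ev, params.unitary_dF)
        if params.estimate_steps and ev.trace.size - ev.peak_index >= 4:
            try:
                puff_metrics.estimate_unitary_step(ev)
            except ValidationError:
                pass
    sites = site_analysis.assign_sites(events, params.sep_um)
    summary = site_analysis.summarize_cell(events, sites, movie, global_onset)
    curve = site_analysis.discovery_curve(
        sites, params.bin_s, (0.0, max(params.bin_s, summary.effective_recording_s))
    )
    try:
        curve = site_analysis.fit_discovery_halftime(curve)
        curve = site_analysis.annotate_coverage(curve, summary.effective_recording_s)
    except ValidationError as exc:
        curve.flags.add("unfit")
        logger.info("discovery half-time not fitted: %s", exc)
    logger.info(
        "analysis: %d puffs at %d sites; effective recording %.2f s; global rise: %s",
        summary.total_puffs, summary.total_sites, summary.effective_recording_s,
        summary.global_rise,
    )
    return AnalysisResult(events, sites, summary, curve,
                          nstack if keep_nstack else None, params)
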