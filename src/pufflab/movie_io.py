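"""Movie container, TIFF I/O, background correction and result serialization.

A :class:`Movie` is a time-ordered T×Y×X intensity stack plus the physical
calibration needed to interpret it: the frame interval ``dt_s``, the pixel
edge ``pixel_um`` and the index of the first post-photolysis frame
``flash_frame``.  Pixel indices are 0-based; physical coordinates refer to
pixel centres, ``x_um = (col + 0.5) * pixel_um``.

Calibration passed explicitly always overrides anything embedded in the
file; both are logged so the provenance is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Background ROI as half-open pixel bounds (row_start, row_stop, col_start, col_stop).
BackgroundROI = tuple[int, int, int, int]


@dataclass
class Movie:
    """Time-lapse fluorescence stack with physical calibration.

    Parameters
    ----------
    frames:
        Array of shape (T, Y, X), non-negative camera intensities.
    dt_s:
        Seconds per frame (e.g. 0.00532 for 188 Hz acquisition).
    pixel_um:
        Micrometres per pixel edge (e.g. 0.16).
    flash_frame:
        Index of the first frame after the photolysis (UV) flash; defines
        time zero of stimulation.
    background_roi:
        Optional rectangle outside the cell, as half-open pixel bounds
        (row_start, row_stop, col_start, col_stop), used by
        :func:`subtract_background`.
    """

    frames: np.ndarray
    dt_s: float
    pixel_um: float
    flash_frame: int
    background_roi: Optional[BackgroundROI] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be a 3D (T, Y, X) stack, got ndim={self.frames.ndim}"
            )
        t, y, x = self.frames.shape
        if t < 2:
            raise ValidationError(f"a movie needs at least 2 frames, got T={t}")
        if y < 1 or x < 1:
            raise ValidationError(f"empty frame shape ({y}, {x})")
        if not (self.dt_s > 0 and self.pixel_um > 0):
            raise ValidationError("dt_s and pixel_um must be positive")
        if not (0 <= int(self.flash_frame) < t):
            raise ValidationError(
                f"flash_frame {self.flash_frame} outside [0, {t})"
            )
        self.flash_frame = int(self.flash_frame)
        if self.background_roi is not None:
            r0, r1, c0, c1 = self.background_roi
            if not (0 <= r0 < r1 <= y and 0 <= c0 < c1 <= x):
                raise ValidationError(
                    f"background_roi {self.background_roi} not inside frame bounds ({y}, {x})"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt_s

    def time_of(self, frame: int) -> float:
        """Absolute time (s from record start) of a frame index."""
        return frame * self.dt_s


def read_movie(
    path: os.PathLike | str,
    dt_s: float,
    pixel_um: float,
    flash_frame: int,
    background_roi: Optional[BackgroundROI] = None,
) -> Movie:
    """Read a single- or multi-page (OME-)TIFF stack as a Movie.

    Explicit calibration arguments always win over file metadata; any
    embedded resolution/interval metadata is logged but not used.
    """
    if not (dt_s > 0 and pixel_um > 0):
        raise ValidationError("calibration values dt_s and pixel_um must be positive")
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            if tif.ome_metadata:
                logger.info("OME metadata present in %s; explicit calibration overrides it", path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read TIFF stack {path!r}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    logger.info(
        "read %s: %d frames of %s, dt_s=%g, pixel_um=%g, flash_frame=%d",
        path, frames.shape[0], frames.shape[1:], dt_s, pixel_um, flash_frame,
    )
    return Movie(frames, dt_s, pixel_um, flash_frame, background_roi)


def write_movie(movie: Movie, path: os.PathLike | str) -> None:
    """Write a Movie as a multi-page 16-bit TIFF (values rounded and clipped)."""
    data = np.clip(np.rint(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def subtract_background(movie: Movie) -> Movie:
    """Subtract, per frame, the mean intensity over the extracellular ROI.

    Camera intensities are non-negative, so results are clipped at 0 after
    subtraction; the pre-clip ROI mean is exactly 0 in every corrected
    frame.  Calibration is shared with the input movie.
    """
    if movie.background_roi is None:
        raise ValidationError(
            "movie has no background_roi; pass one to Movie(...) or skip background correction"
        )
    r0, r1, c0, c1 = movie.background_roi
    bg = movie.frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    corrected = movie.frames.astype(np.float64) - bg[:, None, None]
    np.clip(corrected, 0, None, out=corrected)
    return replace(movie, frames=corrected)


EVENT_COLUMNS = [
    "id", "site_id", "centroid_x_um", "centroid_y_um", "t_peak_s",
    "amplitude_dF", "rise_ms", "decay_ms", "fwhm_ms",
    "n_channels", "n_channels_round", "unitary_dF_local", "flags",
]
SITE_COLUMNS = ["site_id", "x_um", "y_um", "n_puffs", "first_detection_s"]


def events_frame(events: Sequence) -> pd.DataFrame:
    """Tabulate PuffEvents with the stable events.csv schema."""
    rows = []
    for ev in events:
        rows.append({
            "id": ev.event_id,
            "site_id": ev.site_id,
            "centroid_x_um": ev.centroid_um[0],
            "centroid_y_um": ev.centroid_um[1],
            "t_peak_s": ev.t_peak_s,
            "amplitude_dF": ev.amplitude_dF,
            "rise_ms": ev.rise_ms,
            "decay_ms": ev.decay_ms,
            "fwhm_ms": ev.fwhm_ms,
            "n_channels": ev.n_channels,
            "n_channels_round": ev.n_channels_round,
            "unitary_dF_local": ev.unitary_dF_local,
            "flags": ";".join(sorted(ev.flags)),
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def sites_frame(sites: Sequence) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id,
            "x_um": s.centroid_um[0],
            "y_um": s.centroid_um[1],
            "n_puffs": len(s.event_ids),
            "first_detection_s": s.first_detection_s,
        })
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_results(events: Sequence, sites: Sequence, summary, out_dir: os.PathLike | str) -> dict:
    """Write events.csv, sites.csv and summary.json under ``out_dir``.

    CSV is RFC 4180, UTF-8, '.' decimal; numeric fields carry full float
    repr (round-trip exact to well beyond 6 significant figures).  Returns
    the mapping of logical name to written path.
    """
    out_dir = os.fspath(out_dir)
    try:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "events": os.path.join(out_dir, "events.csv"),
            "sites": os.path.join(out_dir, "sites.csv"),
            "summary": os.path.join(out_dir, "summary.json"),
        }
        events_frame(events).to_csv(paths["events"], index=False)
        sites_frame(sites).to_csv(paths["sites"], index=False)
        payload = summary.to_dict() if hasattr(summary, "to_dict") else dict(summary)
        with open(paths["summary"], "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir!r}: {exc}") from exc
    return paths
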