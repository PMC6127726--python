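"""Ground-truth-annotated synthetic TIRF movies of Ca2+ puffs.

The simulator emulates the statistical structure the analysis chain
assumes: fixed release sites scattered over the field with a minimum
separation, per-site Poisson puff trains that start after an exponential
latency following photolysis, quantal puff amplitudes (an integer number
of channels, each contributing one unitary ΔF/F0 step), a linear rise with
all channels open at the peak, independent exponential channel closures
producing a descending staircase, an isotropic 2D Gaussian spatial
footprint per open channel, additive Gaussian (or Poisson) camera noise,
and an optional late global Ca2+ rise propagating as a circular wave.

Default parameters reproduce the acquisition geometry the package targets:
120×120 pixels at 0.16 μm/px, 5.32 ms frames, 2.7 s of pre-flash baseline
followed by 40 s of recording, unitary step ΔF/F0 = 0.101, and mostly
fewer than seven channels per puff (truncated-Poisson channel counts with
mean 2.8 on {1..10}).

Amplitude convention
--------------------
The quantal step 0.101 is, experimentally, a property of the 1.76×1.76 μm
ROI-averaged F/F0 trace, not of the brightest pixel.  By default
(``quantal_convention="roi_mean"``) each open channel therefore adds a
Gaussian footprint whose *ROI-mean* ΔF/F0 equals ``unitary_step_dF``, so
the rendered data carry the same quantal structure the analysis measures.
``"psf_peak"`` instead makes the *peak* added ΔF/F0 equal the unitary step.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

from .errors import SimulationError, ValidationError
from .movie_io import Movie

# 1.76 um ROI at 0.16 um/px -> 11 px; used to calibrate the "roi_mean" convention
_ROI_UM = 1.76


@dataclass
class ChannelCountDist:
    """Distribution of the number of channels contributing to a puff.

    kind "truncated_poisson": Poisson conditioned on {1..k_max}, with the
    underlying rate solved so the truncated mean equals ``mean``.
    kind "fixed": point mass at ``k``.
    kind "pmf": explicit probabilities for {1..len(pmf)}.
    """

    kind: str = "truncated_poisson"
    mean: float = 2.8
    k_max: int = 10
    k: int = 3
    pmf: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("truncated_poisson", "fixed", "pmf"):
            raise ValidationError(f"unknown channel-count distribution kind {self.kind!r}")
        if self.kind == "truncated_poisson":
            if not (1 <= self.mean <= self.k_max):
                raise ValidationError("truncated-Poisson mean must lie in [1, k_max]")
        if self.kind == "fixed" and self.k < 1:
            raise ValidationError("fixed channel count must be >= 1")

    def probabilities(self) -> np.ndarray:
        """PMF over support {1..k_max} (or {1..len(pmf)})."""
        if self.kind == "fixed":
            p = np.zeros(self.k)
            p[-1] = 1.0
            return p
        if self.kind == "pmf":
            p = np.asarray(self.pmf, dtype=float)
            if p.ndim != 1 or p.size < 1 or (p < 0).any() or p.sum() <= 0:
                raise ValidationError("pmf must be a non-negative 1D array with positive sum")
            return p / p.sum()
        ks = np.arange(1, self.k_max + 1)

        def trunc_mean(mu: float) -> float:
            w = stats.poisson.pmf(ks, mu)
            return float((ks * w).sum() / w.sum())

        if self.mean <= 1:
            mu = 1e-9
        else:
            mu = optimize.brentq(lambda m: trunc_mean(m) - self.mean, 1e-9, 10.0 * self.k_max)
        w = stats.poisson.pmf(ks, mu)
        return w / w.sum()

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.probabilities()
        return rng.choice(np.arange(1, p.size + 1), size=size, p=p)


@dataclass
class GlobalRiseConfig:
    """Late global Ca2+ rise, modelled as a circular plateau wave."""

    onset_s: float = 12.0
    wave_speed_um_s: float = 20.0
    plateau_dF: float = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic recording.

    Times are seconds, lengths micrometres, amplitudes ΔF/F0 units,
    intensities camera units.  ``puff_rate_hz`` is per site, post-flash.
    """

    n_sites: int = 30
    field_px: tuple[int, int] = (120, 120)
    pixel_um: float = 0.16
    dt_s: float = 0.00532
    duration_s: float = 42.7
    flash_time_s: float = 2.7
    site_min_sep_um: float = 2.0
    puff_rate_hz: float = 0.15
    latency_scale_s: float = 1.0
    channels_per_puff_dist: ChannelCountDist = field(default_factory=ChannelCountDist)
    unitary_step_dF: float = 0.101
    rise_ms: float = 20.0
    open_dwell_ms: float = 15.0
    psf_sigma_um: float = 0.15
    baseline_f0: float = 1000.0
    noise_model: str = "gaussian"          # "gaussian" | "poisson" | "none"
    noise_sigma_frac: float = 0.02         # gaussian sigma as fraction of baseline_f0
    poisson_gain: float = 1.0              # camera units per photon for "poisson"
    quantal_convention: str = "roi_mean"   # "roi_mean" | "psf_peak"
    global_rise: Optional[GlobalRiseConfig] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.channels_per_puff_dist, dict):
            self.channels_per_puff_dist = ChannelCountDist(**self.channels_per_puff_dist)
        if isinstance(self.global_rise, dict):
            self.global_rise = GlobalRiseConfig(**self.global_rise)
        self.field_px = tuple(int(v) for v in self.field_px)
        if self.n_sites < 0:
            raise ValidationError("n_sites must be >= 0")
        if self.site_min_sep_um < 0:
            raise ValidationError("site_min_sep_um must be >= 0")
        for name in ("pixel_um", "dt_s", "duration_s", "baseline_f0"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("puff_rate_hz", "latency_scale_s", "rise_ms", "open_dwell_ms",
                     "psf_sigma_um", "flash_time_s", "noise_sigma_frac"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.flash_time_s < self.duration_s:
            raise ValidationError("flash_time_s must precede duration_s")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValidationError(f"unknown noise_model {self.noise_model!r}")
        if self.quantal_convention not in ("roi_mean", "psf_peak"):
            raise ValidationError(f"unknown quantal_convention {self.quantal_convention!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.dt_s))

    @property
    def flash_frame(self) -> int:
        return int(round(self.flash_time_s / self.dt_s))

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.field_px[0] * self.pixel_um, self.field_px[1] * self.pixel_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_px"] = list(self.field_px)
        return d


@dataclass
class PuffRecord:
    """One ground-truth puff: who, when and how many channels."""

    site_id: int
    onset_s: float
    n_channels: int
    closure_s: list[float]     # absolute closure time of each channel

    @property
    def end_s(self) -> float:
        return max(self.closure_s) if self.closure_s else self.onset_s


@dataclass
class GroundTruth:
    """Simulator sidecar: everything the recovery tests score against."""

    site_xy_um: np.ndarray                 # (n_sites, 2) as (x, y)
    puffs: list[PuffRecord]
    global_onset_s: Optional[float] = None
    config: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        self.site_xy_um = np.asarray(self.site_xy_um, dtype=float).reshape(-1, 2)
        n = len(self.site_xy_um)
        for p in self.puffs:
            if not (0 <= p.site_id < n):
                raise ValidationError(f"puff references unknown site {p.site_id}")
            if any(c < p.onset_s for c in p.closure_s):
                raise ValidationError("channel closure before puff onset")

    def to_json(self, path: os.PathLike | str) -> None:
        payload = {
            "site_xy_um": self.site_xy_um.tolist(),
            "puffs": [
                {"site_id": p.site_id, "onset_s": p.onset_s,
                 "n_channels": p.n_channels, "closure_s": list(p.closure_s)}
                for p in self.puffs
            ],
            "global_onset_s": self.global_onset_s,
            "config": self.config.to_dict() if self.config else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: os.PathLike | str) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg = SimulationConfig(**payload["config"]) if payload.get("config") else None
        puffs = [PuffRecord(**p) for p in payload["puffs"]]
        return cls(np.asarray(payload["site_xy_um"]), puffs, payload.get("global_onset_s"), cfg)


def place_sites(config: SimulationConfig, rng: np.random.Generator,
                max_tries: int = 20000) -> np.ndarray:
    """Scatter ``n_sites`` positions uniformly with a minimum pairwise separation.

    Rejection sampling with a bounded budget; positions are (x, y) in μm,
    kept half a separation radius inside the field edge so site footprints
    stay on-camera.
    """
    fy, fx = config.field_um
    margin = min(config.site_min_sep_um / 2, fx / 4, fy / 4)
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < config.n_sites:
        if tries >= max_tries:
            raise SimulationError(
                f"could not place {config.n_sites} sites at min separation "
                f"{config.site_min_sep_um} μm in a {fx:.1f}×{fy:.1f} μm field "
                f"after {max_tries} draws; reduce n_sites or the separation"
            )
        tries += 1
        x = rng.uniform(margin, fx - margin)
        y = rng.uniform(margin, fy - margin)
        if all(math.hypot(x - px, y - py) >= config.site_min_sep_um for px, py in placed):
            placed.append((x, y))
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def simulate_puff_train(config: SimulationConfig, sites: np.ndarray,
                        rng: np.random.Generator) -> GroundTruth:
    """Draw per-site puff trains and per-channel closure times.

    Each site starts firing at flash + Exponential(latency_scale_s) and
    then produces puffs as a homogeneous Poisson process at
    ``puff_rate_hz`` until the end of the recording.  Every puff draws its
    channel count, ramps all channels open over ``rise_ms`` and closes them
    independently after Exponential(open_dwell_ms) dwell times, yielding a
    descending staircase.
    """
    sites = np.asarray(sites, dtype=float).reshape(-1, 2)
    puffs: list[PuffRecord] = []
    rise_s = config.rise_ms / 1000.0
    dwell_s = config.open_dwell_ms / 1000.0
    for site_id in range(len(sites)):
        latency = rng.exponential(config.latency_scale_s) if config.latency_scale_s > 0 else 0.0
        t = config.flash_time_s + latency
        while config.puff_rate_hz > 0:
            t += rng.exponential(1.0 / config.puff_rate_hz)
            if t >= config.duration_s:
                break
            n_ch = int(config.channels_per_puff_dist.sample(rng, 1)[0])
            peak = t + rise_s
            dwells = rng.exponential(dwell_s, size=n_ch) if dwell_s > 0 else np.zeros(n_ch)
            closures = (peak + dwells).tolist()
            puffs.append(PuffRecord(site_id, float(t), n_ch, closures))
    puffs.sort(key=lambda p: p.onset_s)
    return GroundTruth(sites, puffs, None, config)


def _pixel_gaussian_footprint(x0_px: float, y0_px: float, sigma_px: float,
                              shape: tuple[int, int],
                              halfwidth_px: int) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated isotropic Gaussian (unit total mass on the infinite plane).

    Returns row/col slices into the frame and the local footprint whose
    entries are the exact integral of the Gaussian over each pixel, so frame
    sums match the analytic mass truncated to the field.
    """
    ny, nx = shape
    c0 = max(0, int(math.floor(x0_px)) - halfwidth_px)
    c1 = min(nx, int(math.floor(x0_px)) + halfwidth_px + 1)
    r0 = max(0, int(math.floor(y0_px)) - halfwidth_px)
    r1 = min(ny, int(math.floor(y0_px)) + halfwidth_px + 1)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    sq2 = sigma_px * math.sqrt(2.0)
    gx = 0.5 * (special.erf((cols + 1 - x0_px) / sq2) - special.erf((cols - x0_px) / sq2))
    gy = 0.5 * (special.erf((rows + 1 - y0_px) / sq2) - special.erf((rows - y0_px) / sq2))
    return slice(r0, r1), slice(c0, c1), np.outer(gy, gx)


def _per_channel_amplitude(config: SimulationConfig) -> float:
    """Camera-unit scale A such that ``added = A * unit-mass footprint`` realises
    one unitary quantal step under the configured convention."""
    sigma_px = config.psf_sigma_um / config.pixel_um
    step_f = config.unitary_step_dF * config.baseline_f0
    if config.quantal_convention == "psf_peak":
        # continuous peak density of a unit-mass Gaussian is 1/(2 pi sigma^2)
        return step_f * 2.0 * math.pi * sigma_px ** 2
    roi_px = int(round(_ROI_UM / config.pixel_um))
    roi_px = max(1, roi_px | 1)  # odd
    n_roi = roi_px * roi_px
    # mass captured by a centred ROI; ~1 for sigma << ROI
    half = roi_px / 2.0
    frac_1d = special.erf(half / (sigma_px * math.sqrt(2.0)))
    return step_f * n_roi / float(frac_1d ** 2)


def render_movie(config: SimulationConfig, truth: GroundTruth,
                 rng: Optional[np.random.Generator] = None) -> Movie:
    """Render a ground-truth puff train into a noisy fluorescence movie.

    The baseline is flat at ``baseline_f0``; each open channel adds a
    pixel-integrated 2D Gaussian footprint (σ = ``psf_sigma_um``) scaled to
    one quantal step; channels ramp open linearly over ``rise_ms`` and drop
    out at their closure times; noise and the optional global rise are
    applied last.  ``rng`` defaults to a stream seeded from ``config.seed``
    (sub-stream 1, so it is independent of site placement / trains drawn
    from the same seed via :func:`simulate_movie`).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    ny, nx = config.field_px
    n_frames = config.n_frames
    frames = np.full((n_frames, ny, nx), config.baseline_f0, dtype=np.float64)
    sigma_px = config.psf_sigma_um / config.pixel_um
    amp = _per_channel_amplitude(config)
    halfwidth = max(3, int(math.ceil(6.0 * sigma_px)))
    rise_s = config.rise_ms / 1000.0

    footprints: dict[int, tuple[slice, slice, np.ndarray]] = {}
    for p in truth.puffs:
        if p.site_id not in footprints:
            x_um, y_um = truth.site_xy_um[p.site_id]
            footprints[p.site_id] = _pixel_gaussian_footprint(
                x_um / config.pixel_um, y_um / config.pixel_um, sigma_px, (ny, nx), halfwidth
            )
        rs, cs, fp = footprints[p.site_id]
        t0 = max(0, int(math.floor(p.onset_s / config.dt_s)))
        t1 = min(n_frames - 1, int(math.ceil(p.end_s / config.dt_s)))
        closures = np.asarray(p.closure_s)
        peak_s = p.onset_s + rise_s
        for fr in range(t0, t1 + 1):
            t = fr * config.dt_s
            if t < p.onset_s:
                continue
            if t < peak_s:
                n_open = p.n_channels * (t - p.onset_s) / rise_s if rise_s > 0 else p.n_channels
            else:
                n_open = float((closures > t).sum())
            if n_open > 0:
                frames[fr, rs, cs] += amp * n_open * fp

    if truth.global_onset_s is None and config.global_rise is not None:
        truth.global_onset_s = config.global_rise.onset_s
    if config.global_rise is not None:
        g = config.global_rise
        oy = rng.uniform(0, ny * config.pixel_um)
        ox = rng.uniform(0, nx * config.pixel_um)
        yy, xx = np.meshgrid(
            (np.arange(ny) + 0.5) * config.pixel_um,
            (np.arange(nx) + 0.5) * config.pixel_um,
            indexing="ij",
        )
        dist = np.hypot(yy - oy, xx - ox)
        first = int(math.floor(g.onset_s / config.dt_s))
        plateau = g.plateau_dF * config.baseline_f0
        for fr in range(max(0, first), n_frames):
            radius = g.wave_speed_um_s * (fr * config.dt_s - g.onset_s)
            if radius <= 0:
                continue
            frames[fr][dist <= radius] += plateau

    if config.noise_model == "gaussian" and config.noise_sigma_frac > 0:
        frames += rng.normal(0.0, config.noise_sigma_frac * config.baseline_f0, frames.shape)
        np.clip(frames, 0, None, out=frames)
    elif config.noise_model == "poisson":
        gain = config.poisson_gain
        frames = rng.poisson(np.clip(frames, 0, None) / gain).astype(np.float64) * gain

    return Movie(frames, config.dt_s, config.pixel_um, config.flash_frame)


def simulate_movie(config: SimulationConfig) -> tuple[Movie, GroundTruth]:
    """Full simulation: place sites, draw puff trains, render.  Deterministic
    under a fixed ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(2)
    rng_truth = np.random.default_rng(ss[0])
    rng_render = np.random.default_rng(ss[1])
    sites = place_sites(config, rng_truth)
    truth = simulate_puff_train(config, sites, rng_truth)
    movie = render_movie(config, truth, rng_render)
    return movie, truth
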