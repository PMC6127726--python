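"""Per-puff amplitude, kinetics, staircase steps and channel counts.

Amplitude is ΔF = F_peak − F_pre on the ROI-mean F/F0 trace, with F_pre
averaged over the ten frames immediately before event onset and the ten
immediately after event end.  Kinetics follow the 20→100% rise, 100→20%
decay and duration-at-half-maximum conventions, with crossing times
linearly interpolated between frames (the peak itself is a sample, not a
crossing).  The number of active channels per puff is N = ΔF / unitary
step, with the unitary step (≈0.101 ΔF/F0 per channel) measured from the
descending staircase of the falling phase by changepoint segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import PuffEvent
from .errors import ValidationError

DEFAULT_UNITARY_DF = 0.101
DEFAULT_N_REF_FRAMES = 10


@dataclass
class KineticsResult:
    """20→100% rise, 100→20% decay and duration at half-maximal amplitude,
    all in ms relative to the f_pre baseline; sub-frame interpolation means
    values below one frame interval are legitimate."""

    rise_ms: float
    decay_ms: float
    fwhm_ms: float
    flags: set[str] = field(default_factory=set)


@dataclass
class StepEstimate:
    """Quantal staircase read from a puff's falling phase."""

    step_levels: list[float]
    unitary_dF: float
    n_steps: int
    flags: set[str] = field(default_factory=set)


def compute_reference(event: PuffEvent, n_ref_frames: int = DEFAULT_N_REF_FRAMES) -> float:
    """Baseline F/F0 reference: mean of the trace over the ``n_ref_frames``
    immediately before event onset and after event end.

    One-sided if the window is clipped (flag ``one_sided_reference``); if no
    reference frames exist at all the first trace value is used and the
    event is flagged ``no_reference``.  Sets ``event.f_pre`` and
    ``event.amplitude_dF`` and returns f_pre.
    """
    c0, c1 = event.core_indices
    pre = event.trace[max(0, c0 - n_ref_frames): c0]
    post = event.trace[c1 + 1: c1 + 1 + n_ref_frames]
    segs = [s for s in (pre, post) if s.size > 0]
    if not segs:
        event.flags.add("no_reference")
        f_pre = float(event.trace[0])
    else:
        if len(segs) == 1 or pre.size < n_ref_frames or post.size < n_ref_frames:
            event.flags.add("one_sided_reference")
        # mean of side-means so a clipped side is not under-weighted
        f_pre = float(np.mean([s.mean() for s in segs]))
    event.f_pre = f_pre
    event.amplitude_dF = float(event.trace[event.peak_index] - f_pre)
    return f_pre


def _cross_time(trace: np.ndarray, i: int, j: int, level: float) -> float:
    """Linearly interpolated index where the trace crosses ``level``
    between samples i and j (j = i ± 1)."""
    y0, y1 = trace[i], trace[j]
    if y1 == y0:
        return float(i)
    return i + (level - y0) / (y1 - y0) * (j - i)


def compute_kinetics(event: PuffEvent) -> KineticsResult:
    """Rise, decay and half-maximum duration of the highest peak.

    Thresholds sit at f_pre + 0.2·ΔF and f_pre + 0.5·ΔF.  Rise runs from
    the last upward 20% crossing before the peak to the peak sample; decay
    from the peak to the first downward 20% crossing after it; FWHM between
    the 50% crossings bracketing the peak.  A trace that never returns
    below a level inside the window is right-censored: the available extent
    is reported and the result flagged.  Sets the event's kinetic fields.
    """
    if not (event.amplitude_dF > 0):
        raise ValidationError("compute_kinetics requires amplitude_dF > 0; run compute_reference first")
    trace = event.trace
    peak = event.peak_index
    f_pre = event.f_pre
    flags: set[str] = set()
    lv20 = f_pre + 0.2 * event.amplitude_dF
    lv50 = f_pre + 0.5 * event.amplitude_dF

    def last_up_cross(level: float) -> float:
        for i in range(peak - 1, -1, -1):
            if trace[i] < level <= trace[i + 1]:
                return _cross_time(trace, i, i + 1, level)
        flags.add("left_censored")
        return 0.0

    def first_down_cross(level: float) -> float:
        for i in range(peak, len(trace) - 1):
            if trace[i] >= level > trace[i + 1]:
                return _cross_time(trace, i, i + 1, level)
        flags.add("right_censored")
        return float(len(trace) - 1)

    ms = event.dt_s * 1000.0
    rise_ms = (peak - last_up_cross(lv20)) * ms
    decay_ms = (first_down_cross(lv20) - peak) * ms
    fwhm_ms = (first_down_cross(lv50) - last_up_cross(lv50)) * ms
    # flag secondary peaks: samples above the 50% level outside the
    # contiguous above-50% lobe containing the main peak
    above50 = trace > lv50
    lo = peak
    while lo > 0 and above50[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(trace) - 1 and above50[hi + 1]:
        hi += 1
    outside = np.r_[above50[:lo], above50[hi + 1:]]
    if outside.any():
        flags.add("secondary_peak")
    result = KineticsResult(float(rise_ms), float(decay_ms), float(fwhm_ms), flags)
    event.rise_ms, event.decay_ms, event.fwhm_ms = result.rise_ms, result.decay_ms, result.fwhm_ms
    event.flags |= flags
    return result


def _binary_segmentation(y: np.ndarray, penalty: float, min_len: int = 2) -> list[int]:
    """Changepoints by recursive binary segmentation on within-segment SSE.

    Returns sorted split indices (segment boundaries); a split is accepted
    when it lowers the SSE by more than ``penalty``.
    """
    n = len(y)
    cum = np.concatenate([[0.0], np.cumsum(y)])
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(a: int, b: int) -> float:  # [a, b)
        s, s2, m = cum[b] - cum[a], cum2[b] - cum2[a], b - a
        return s2 - s * s / m if m else 0.0

    splits: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_len:
            continue
        base = sse(a, b)
        best_gain, best_k = 0.0, -1
        for k in range(a + min_len, b - min_len + 1):
            gain = base - sse(a, k) - sse(k, b)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k >= 0 and best_gain > penalty:
            splits.append(best_k)
            stack.append((a, best_k))
            stack.append((best_k, b))
    return sorted(splits)


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise s.d. from the median absolute successive difference (robust to
    the occasional step)."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def estimate_unitary_step(event: PuffEvent, min_plateau_frames: int = 2) -> StepEstimate:
    """Quantal staircase segmentation of the falling phase.

    The decay segment (peak to window end) is segmented into plateaus by
    binary segmentation with a BIC-like penalty (6·σ̂²·ln n, σ̂ robust);
    the penalty floor is effectively zero so a noise-free k-step staircase
    returns exactly k drops.  Plateaus shorter than ``min_plateau_frames``
    are merged into the closer neighbour, non-decreasing neighbours are
    pooled, and the unitary step is the median of the consecutive drops.
    """
    peak = event.peak_index
    y = np.asarray(event.trace[peak:], dtype=np.float64)
    if y.size < 4:
        raise ValidationError("decay segment needs at least 4 frames for step estimation")
    sd = _robust_noise_sd(y)
    penalty = max(6.0 * sd * sd * math.log(y.size), 1e-18 * max(1.0, float(np.ptp(y)) ** 2))
    splits = _binary_segmentation(y, penalty)
    bounds = [0, *splits, y.size]
    segments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    flags: set[str] = set()
    if segments and np.mean([b - a for a, b in segments]) < min_plateau_frames:
        flags.add("not_stairlike")

    # merge short plateaus into the neighbour with the closer mean
    def seg_mean(seg):
        a, b = seg
        return y[a:b].mean()

    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, (a, b) in enumerate(segments):
            if b - a < min_plateau_frames:
                left = seg_mean(segments[i - 1]) if i > 0 else None
                right = seg_mean(segments[i + 1]) if i < len(segments) - 1 else None
                target = i - 1 if (right is None or (left is not None and
                                  abs(seg_mean((a, b)) - left) <= abs(seg_mean((a, b)) - right))) else i + 1
                lo = min(segments[target][0], a)
                hi = max(segments[target][1], b)
                segments[min(i, target)] = (lo, hi)
                del segments[max(i, target)]
                changed = True
                break

    # enforce a strictly decreasing staircase by pooling non-decreasing neighbours
    levels = [(seg_mean(s), s[1] - s[0]) for s in segments]
    i = 0
    while i < len(levels) - 1:
        if levels[i + 1][0] >= levels[i][0]:
            m1, n1 = levels[i]
            m2, n2 = levels[i + 1]
            levels[i] = ((m1 * n1 + m2 * n2) / (n1 + n2), n1 + n2)
            del levels[i + 1]
            i = max(0, i - 1)
        else:
            i += 1
    step_levels = [float(m) for m, _ in levels]
    drops = [step_levels[i] - step_levels[i + 1] for i in range(len(step_levels) - 1)]
    if not drops:
        flags.add("no_steps")
        est = StepEstimate(step_levels, math.nan, 0, flags)
    else:
        # quantal staircases have near-uniform drops (small integer multiples
        # of the unitary step); a smooth decay segments into geometrically
        # shrinking drops instead
        if len(drops) >= 3 and max(drops) / max(min(drops), 1e-12) > 3.0:
            flags.add("not_stairlike")
        est = StepEstimate(step_levels, float(np.median(drops)), len(drops), flags)
        event.unitary_dF_local = est.unitary_dF
    event.flags |= flags
    return est


def count_channels(event: PuffEvent, unitary_dF: float = DEFAULT_UNITARY_DF) -> float:
    """Active-channel estimate N = ΔF / unitary step.

    The continuous value is stored in ``event.n_channels``; a rounded
    integer max(1, round(N)) — 0 when ΔF ≤ 0, with a flag — is stored in
    ``event.n_channels_round`` for histogramming.
    """
    if not unitary_dF > 0:
        raise ValidationError("unitary_dF must be positive")
    if math.isnan(event.amplitude_dF):
        raise ValidationError("amplitude_dF not set; run compute_reference first")
    n = event.amplitude_dF / unitary_dF
    event.n_channels = float(n)
    if event.amplitude_dF <= 0:
        event.n_channels_round = 0
        event.flags.add("nonpositive_amplitude")
    else:
        event.n_channels_round = max(1, int(round(n)))
    return event.n_channels


def pool_unitary_step(estimates: Sequence[StepEstimate]) -> tuple[float, float, int]:
    """Pooled unitary step: mean, s.e.m. and count over per-puff estimates
    with at least one resolved step."""
    values = [e.unitary_dF for e in estimates if e.n_steps >= 1 and not math.isnan(e.unitary_dF)]
    if not values:
        raise ValidationError("no step estimates with n_steps >= 1 to pool")
    arr = np.asarray(values, dtype=np.float64)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem, int(arr.size)
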