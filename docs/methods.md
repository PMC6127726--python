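# Methods

## The measurement problem

TIRF microscopy with a fast EMCCD camera records fluorescence from a thin
(~90 nm) optical section at the cell's footprint. After uniform
photo-release of an IP₃ analogue, clustered IP₃Rs produce Ca²⁺ puffs:
transients that rise in tens of ms, fall as individual channels close, and
recur at fixed release sites. The analysis must (i) find these events in a
noisy movie, (ii) localize them to sub-pixel precision, (iii) quantify
their amplitude and kinetics, (iv) count the channels behind each event
from its quantal structure, and (v) decide whether the recording was long
enough to have found essentially all sites.

## Detection model

**Baseline.** The last `n_baseline_frames` (default 500, ≈2.7 s at 188 Hz)
before the photolysis frame give a per-pixel mean F₀ and population s.d.
Using the population s.d. matches the estimator of record for a fixed,
fully observed window.

**Normalization.** The analysis stack is z = [(F/F₀) − 1]/s.d. with the
s.d. expressed in F/F₀ units (sd/F₀), so z is a dimensionless per-pixel
z-score and the critical value is scale-free. A floor of 10⁻³ F/F₀ units
keeps z finite on dead pixels; pixels with F₀ ≤ 0 are masked to z = 0 and
counted in a logged report. Each frame is then smoothed with a spatial
Gaussian (σ = 1 px by default; no temporal filtering). With σ = 0 the
stack equals the arithmetic formula exactly, which the tests exploit.

**Threshold clustering.** Voxels with z > 0.8 (the critical value) are
grouped into 26-connected components in (x, y, t), restricted to frames at
or after the flash and before any global rise. Temporal connectivity
breaks at sub-threshold frames, so repeated puffs at one site count as
separate events. A component becomes an event if it reaches `min_px`
pixels in at least one frame **and** spans at least `min_frames` frames.

The critical value 0.8 is deliberately permissive: after σ = 1 px
filtering the noise s.d. of z is ≈0.29, so 0.8 is only ≈2.8 noise s.d.
and correlated noise excursions cross it constantly (thousands of
multi-voxel components per default-scale recording). The two size knobs
therefore carry the entire false-event control, and their defaults were
set by a noise-only calibration at the default acquisition geometry and
2 % Gaussian noise: `min_px = 6, min_frames = 5` yields zero events on
noise-only recordings (several seeds) while retaining ≥92 % of true
puffs in default 30-site simulations (the losses are single-channel
events whose open time ends within ~5 frames). Raising `min_frames`
further costs recall rapidly — at 6 frames recall drops to ~80 % —
because many genuine single-channel puffs are supra-threshold for barely
25 ms. `min_px` is nearly free: while a channel is open its
supra-threshold footprint spans tens of pixels.

**Traces and localization.** Each event's trace is the *unfiltered*
ROI-mean F/F₀ per frame over an 11 × 11 px ROI (1.76 µm at 160 nm/px)
centred on the brightest pixel, over the supra-threshold extent padded by
±100 frames. The centroid is refined by least-squares fitting an
isotropic 2D Gaussian plus offset to the peak-frame z image in that ROI;
a failed, collapsed or out-of-ROI fit falls back to the brightest-pixel
centre with a flag. Physical coordinates are pixel-centre based:
x_µm = (col + 0.5)·pixel_µm. Peak ties break to the earliest frame, then
the smallest (row, col).

**Global rise.** The effective recording ends when ≥50 % of unmasked
pixels exceed z = 0.8 and stay there for ≥0.5 s (or to the end of the
record). Detection, puff frequency and the discovery window are truncated
at that frame.

## Puff metrics

**Amplitude.** F_pre is the mean of the trace over the 10 frames
immediately before event onset and the 10 immediately after event end
(one-sided with a flag when clipped); ΔF = F_peak − F_pre, with F_peak
the trace sample at the peak frame. The peak is a sample, not a crossing,
so no interpolation is applied at the top.

**Kinetics.** Rise = time from the last upward crossing of
F_pre + 0.2·ΔF before the peak to the peak; decay = peak to the first
downward crossing of that level; duration = the time between the 50 %
crossings bracketing the peak. Crossings are linearly interpolated
between frames, so sub-frame values are legitimate. Traces that never
return below a level inside the window are reported at the available
extent and flagged right-censored; secondary peaks above the 50 % level
outside the main lobe are flagged.

**Unitary steps.** The falling phase (peak to window end) is segmented
into plateaus by binary segmentation on within-segment squared error. The
penalty is 6·σ̂²·ln n with σ̂ the robust noise s.d. from median absolute
successive differences; its floor is effectively zero, so a noise-free
k-step staircase returns exactly k drops. Plateaus shorter than 2 frames
merge into the nearer neighbour; non-decreasing neighbours are pooled so
levels decrease strictly. The unitary step is the median inter-plateau
drop. Decays whose drops are strongly non-uniform (max/min > 3 over ≥3
drops) or whose raw segments average under 2 frames are flagged
`not_stairlike` — a smooth exponential decay segments into geometrically
shrinking pseudo-steps, which this test rejects. Pooling across puffs
reports mean ± s.e.m.

**Channel counts.** N = ΔF/unitary step (default 0.101), reported both
continuous and as max(1, round(N)) for histograms; ΔF ≤ 0 reports 0 with
a flag.

## Site analysis

Events are assigned chronologically: each joins the nearest existing site
whose running-mean centroid lies within 0.96 µm, else founds a new site.
The running-centroid variant is robust to localization jitter but splits
chains whose ends are >0.96 µm apart — unlike order-free single-linkage
clustering, which chains them into one site. Both behaviours are
implemented (`assign_sites` and the `single_linkage_sites` oracle); they
provably coincide when clusters are compact (diameter ≤ half the
separation) and mutually distant (> 2× the separation), which is the
regime the tests assert exhaustively over event orderings.

Site first-detection times (supra-threshold onset of the founding event,
measured from the flash) are binned (default 10 s); the per-bin counts of
new sites are fitted by c(t) = A·2^(−t/t½) with unweighted least squares
at bin-centre times, initialized from a log-linear regression. Flat or
rising counts are flagged and reported as t½ = +∞. A geometric sequence
of counts is fitted exactly because the binned model is itself geometric
in the bin index. Coverage is 100·(1 − 2^(−T/t½)) for a window of T
seconds.

## The simulator

The generator emulates the statistical structure the analysis assumes,
at the acquisition scale the package targets by default: 120 × 120 px at
0.16 µm/px, 5.32 ms frames, 2.7 s baseline then flash, 42.7 s total,
baseline 1000 camera units, 2 % Gaussian camera noise (a Poisson
shot-noise option exists). 30 sites are placed uniformly with ≥2 µm
separation (so site identity is unambiguous at the 0.96-µm assignment
scale). Each site starts firing after an Exponential(1 s) latency and
then follows a homogeneous Poisson process at 0.15 Hz — giving a
discovery half-time ln2/0.15 ≈ 4.6 s, inside the 3.76–5.53 s range the
saturation analysis is designed around. Channel counts per puff are
truncated-Poisson on {1..10} with (truncated) mean 2.8, so most puffs
involve fewer than seven channels. Channels ramp open together linearly
over 20 ms and close independently after Exponential(15 ms) dwells,
producing the descending staircase the step estimator consumes.

Each open channel contributes a pixel-integrated isotropic 2D Gaussian
footprint (σ = 0.15 µm). Its amplitude is calibrated, by default, so the
11 × 11 px **ROI-mean** ΔF/F₀ equals one unitary step (0.101) per open
channel — the convention under which the quantal step is defined
experimentally, since 0.101 is a property of the ROI-averaged trace, not
of the brightest pixel. A `psf_peak` convention (peak ΔF/F₀ = 0.101) is
available; with the narrow PSF the two differ by ~20×, and only the
ROI-mean convention makes rendered movies carry the same quantal
structure the analysis measures. Pixel integration uses exact erf
integrals, so the summed fluorescence added per frame equals the
analytic Gaussian mass truncated to the field to float precision.

The optional global rise is a circular plateau wave (default 20 µm/s,
ΔF/F₀ = 1) from a random origin, existing solely to exercise the
effective-recording truncation.

**What the simulator does not model:** Ca²⁺/dye reaction–diffusion (real
puff footprints spread to ~1 µm through Ca²⁺ diffusion; here the
footprint is the static PSF), dye saturation and buffering chemistry,
channel re-openings during the falling phase, site-to-site rate
heterogeneity (available as a config option but off by default), axial
PSF structure, photobleaching and drift. Passing recovery tests
therefore demonstrate correctness of the analysis chain under its own
assumptions, not robustness to every property of real recordings.

## Problem sizes and determinism

Tests run on reduced geometries (48–96 px fields, 4–15 s records) except
where a claim depends on the default scale: site-count recovery and the
discovery statistics use the full 120 × 120 px, 42.7-s configuration, and
quantal-counting checks use 210 rendered puffs across 30 sites. All
randomness flows from `numpy.random.default_rng` seeded per test or from
`SimulationConfig.seed` (sub-streams split via `SeedSequence.spawn`), so
every simulation and analysis is bit-for-bit reproducible; hypothesis
property tests run derandomized.

## Known limitations

- Overlapping puffs at one site are not deconvolved; the later event's
  reference frames can overlap the earlier event's tail, biasing ΔF (the
  events are flagged only through their kinetics when visible).
- With exponential open dwells, a channel often closes before the first
  post-peak frame sample, so trace-peak ΔF slightly under-samples the
  all-open amplitude; channel counting is exact on puffs with ≥1
  full-amplitude frame and degrades gracefully otherwise.
- The discovery fit uses unweighted least squares on small counts;
  Poisson-weighted fitting is a reasonable alternative the interface
  leaves room for.
- `detect_global_rise` assumes an abrupt, sustained rise; slow ramps that
  hover near the threshold can shift the estimated onset by a few hundred
  ms.
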