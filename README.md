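# pufflab

Detection and quantal analysis of **Ca²⁺ puffs** — brief, local Ca²⁺ release
events produced by small clusters of IP₃ receptor (IP₃R) channels — in TIRF
microscopy time-lapse recordings.

When IP₃ is released uniformly in a cell (e.g. by flash photolysis of caged
IP₃), clustered IP₃Rs at fixed **release sites** open nearly simultaneously
and produce fluorescence transients a few hundred ms long and ~1 µm across.
`pufflab` implements the full desk-side analysis for such movies, plus a
ground-truth-annotated simulator so every stage can be validated against
known answers:

- **movie I/O** — multi-page (OME-)TIFF stacks with explicit calibration
  (frame interval, pixel size, photolysis frame), extracellular background
  subtraction, CSV/JSON result serialization;
- **detection** — per-pixel baseline F₀ and s.d. from the pre-flash frames,
  the dimensionless stack z = [(F/F₀) − 1]/s.d., per-frame Gaussian
  filtering, threshold clustering of supra-threshold voxels in (x, y, t)
  at a critical value of 0.8, ROI-averaged F/F₀ traces (1.76 × 1.76 µm),
  and sub-pixel localization by 2D Gaussian fitting;
- **puff metrics** — amplitude ΔF = F_peak − F_pre, 20→100% rise time,
  100→20% decay time, duration at half-maximal amplitude, changepoint
  segmentation of the falling-phase staircase to measure the unitary
  single-channel step (≈0.101 ΔF/F₀), and the active-channel count
  **N = ΔF / 0.101**;
- **site analysis** — greedy chronological assignment of puffs to release
  sites (centroids within 0.96 µm belong to one site), per-cell summaries
  (latency, puff frequency, totals, global-rise truncation), and
  site-discovery saturation: the number of new sites found per interval
  declines mono-exponentially with half-time t½, so a window of
  n = T/t½ half-lives reveals an expected 100·(1 − 2⁻ⁿ) % of all sites;
- **synthetic data** — a simulator that renders fixed sites, per-site
  Poisson puff trains, quantal staircase amplitudes, Gaussian/Poisson
  camera noise and an optional propagating global Ca²⁺ rise, with a JSON
  ground-truth sidecar.

## Worked example

`examples/` contains one short script per capability. Mapping 30 simulated
release sites in a default-scale recording (120×120 px at 160 nm/px,
5.32 ms/frame, 2.7 s baseline + 40 s post-flash, 2 % camera noise):

```sh
$ python examples/04_site_discovery.py
true sites: 30, recovered: 30
puffs: 147 over 40.0 s -> 3.68 Hz; first-puff latency 0.37 s
new sites per 10-s interval: [23, 4, 2, 1]
fitted discovery half-time: 4.27 s (R^2 = 0.993)
9.4 half-lives observed -> expected coverage 99.8% of all sites
```

All 30 ground-truth sites are recovered; the mono-exponential fit to the
per-interval counts of newly discovered sites gives t½ ≈ 4.3 s, so the 40-s
window spans >9 half-lives and essentially saturates site discovery — the
argument that lets site counts be compared across recordings without an
under-sampling confound. `examples/03_quantal_analysis.py` shows the
quantal side: puffs rendered with 1–8 open channels come back with
N_round = 1–8 and a pooled unitary step of 0.101.

The same pipeline is scriptable from a shell:

```sh
pufflab simulate --config config.yaml --out sim/
pufflab analyze sim/movie.tif --dt-s 0.00532 --pixel-um 0.16 \
        --flash-frame 508 --out results/
pufflab benchmark --config config.yaml --replicates 5 --out bench/
```

`analyze` writes `events.csv` (one row per puff with centroid, amplitude,
kinetics and channel count), `sites.csv`, `summary.json` and a
reproducibility manifest.

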