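"""Release-site mapping and discovery-saturation statistics.

Analyses a full default-scale simulation (30 sites, 40-s recording),
assigns puffs to sites with the 0.96-um rule, bins first detections, fits
the mono-exponential decline of new-site discovery and converts its
half-time into the expected fraction of all sites found.
"""

from pufflab import SimulationConfig, analyze_movie, coverage_fraction, simulate_movie

config = SimulationConfig(seed=3)      # 30 sites, 120x120 px, 42.7 s, 2% noise
movie, truth = simulate_movie(config)
result = analyze_movie(movie)

s = result.summary
print(f"true sites: {len(truth.site_xy_um)}, recovered: {s.total_sites}")
print(f"puffs: {s.total_puffs} over {s.effective_recording_s:.1f} s "
      f"-> {s.puff_frequency_hz:.2f} Hz; first-puff latency {s.latency_first_puff_s:.2f} s")

curve = result.discovery
print(f"new sites per 10-s interval: {curve.new_site_counts}")
print(f"fitted discovery half-time: {curve.t_half_s:.2f} s (R^2 = {curve.r_squared:.3f})")
n_half, pct = coverage_fraction(curve.t_half_s, s.effective_recording_s)
print(f"{n_half:.1f} half-lives observed -> expected coverage {pct:.1f}% of all sites")
print("A recording several half-lives long leaves few sites undiscovered,")
print("so low site counts reflect biology, not under-sampling.")
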