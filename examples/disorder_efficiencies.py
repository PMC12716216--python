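"""Static vs dynamic disorder in simulated FRET efficiencies.

Builds a coupling trajectory with two slow conformational states plus fast
Gaussian fluctuations, converts it to instantaneous transfer rates, and
averages in the intermediate regime: rates are averaged inside windows of
the donor lifetime, each window yields one efficiency, and the window
distribution exposes the slow heterogeneity an ensemble mean would hide.
The Förster-inverted distances are then compared with the true (fixed)
separation: orientation/coupling spread masquerades as distance spread.
"""

import numpy as np

from trespfret import (
    PhotophysicsParams,
    distance_bias_analysis,
    efficiency_distribution,
    instantaneous_rate,
)
from trespfret.fixtures import make_two_timescale_trajectory

p = PhotophysicsParams(tau_d=5.0, r0=30.0, n_refr=np.sqrt(2.0),
                       mu_d_mag=1.2, mu_a_mag=2.0)

fx = make_two_timescale_trajectory(
    slow_couplings=[1.5e-5, 4e-5],   # Hartree; two conformational states
    windows_per_state=[150, 100],
    params=p,
    frames_per_window=100,           # 100 frames × 50 ps = 5 ns = τ_D
    fast_sigma=0.4e-5,
    seed=42,
)
rates = instantaneous_rate(fx["series"], p)
dist = efficiency_distribution([rates], p, fast_window=fx["fast_window_ns"],
                               stride_ps=fx["stride_ps"])

print(f"windows: {dist.window_efficiencies.size}, "
      f"window duration: {dist.window_duration:.2f} ns")
print(f"mean efficiency:      {dist.mean_e:.4f}")
print(f"analytic ground truth: {fx['ground_truth']['efficiency']:.4f}")
print(f"window efficiency spread (sd): {dist.window_efficiencies.std():.4f}")

# all frames sit at one true separation; what would Förster inversion say?
md_distances = np.full(rates.size, 30.0)
report = distance_bias_analysis(dist, p.r0, md_distances)
print(f"\ntrue separation: 30.0 Å (no spread)")
print(f"Förster-inverted distances: {report['mean_inverted']:.1f} ± "
      f"{report['inverted_distances'].std():.1f} Å")
print(f"mean signed error {report['mean_signed_error']:+.2f} Å, "
      f"MUE {report['mue']:.2f} Å, max {report['max_deviation']:.2f} Å")
print(
    "\nThe inverted distribution is broad although the geometry never moved: "
    "coupling (orientation)\nfluctuations are misread as distance "
    "fluctuations by the Förster model."
)
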