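"""Fluorescence titration: binding constants and corrected efficiencies.

Generates a synthetic protein–ligand titration (donor quenching at
increasing ligand concentration, with inner-filter attenuation), fits the
double-log binding plot for (K_b, n), corrects the per-concentration
efficiencies by the fraction of protein bound, and ranks candidate
binding sites against the experimental efficiency.
"""

from trespfret import compare_to_simulation, corrected_efficiency, hill_fit
from trespfret.fixtures import make_titration

fx = make_titration(
    kd_um=10.0, n_hill=0.7, e_true=1.0,
    concs_um=(10.0, 50.0, 100.0),
    abs_ex_per_um=0.002, abs_em_per_um=0.001,  # inner-filter absorbances
    noise_sigma=0.0, seed=0,
)
series = fx["series"]
fit = hill_fit(series)                      # inner-filter corrected inside
done = corrected_efficiency(series, fit)

print(f"fitted K_d = {done.kd_um:.2f} µM, Hill n = {done.n_hill:.3f} "
      f"(r² = {done.r_squared:.5f})")
print(done.per_conc.to_string(index=False,
                              float_format=lambda v: f"{v:.4f}"))
print(f"final corrected efficiency E = {done.e_final:.3f}")

# compare against simulated per-site efficiencies (indomethacin-like case)
table = compare_to_simulation(0.73, {"IIA": 1.00, "IB": 0.25, "IIIA": 0.35})
print("\nsite ranking against E_exp = 0.73 (ruled out above |ΔE| = 0.25):")
print(table.to_string(index=False))
print(
    "\nThe site with the smallest deviation is the most plausible dominant "
    "binding model;\nlarge deviations rule sites out, though secondary "
    "binding can blur the comparison."
)
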