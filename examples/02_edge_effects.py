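"""Estimate the penetration depth and magnitude of forest edge effects.

Builds a clean edge-gradient landscape (truth: 20% canopy-height deficit at
the edge, 95% of intact reached at exactly 400 m), profiles RH98 by
distance band, and recovers the scale of the edge effect with both the
95%-of-intact criterion and the ANOVA criterion.
"""

from forestedge.experiments import edge_penetration_experiment

out = edge_penetration_experiment(seed=0, with_anova=True)

print(f"profile footprints: {out['n_profile']}, "
      f"intact reference {out['intact_mean_m']:.1f} m")
print(f"penetration depth (95% criterion): {out['d95_hat_m']:.0f} m "
      f"(truth {out['truth_d95_m']:.0f} m)")
print(f"penetration depth (ANOVA criterion): {out['d_anova_m']:.0f} m, "
      f"F = {out['anova_F']:.0f}, p = {out['anova_p']:.2e}")
print(f"edge magnitude (first-band deficit): "
      f"{100 * out['edge_magnitude_hat']:.1f}% (truth "
      f"{100 * out['truth_edge_magnitude']:.0f}% at d = 0)")
# The 95% criterion lands within one band width of the 400 m truth; the
# ANOVA criterion extends farther because small mean deficits stay
# statistically detectable long after the 5% structural threshold is met.
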