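# forestedge

Quantifying how deforestation degrades the tropical moist forests that
remain standing. `forestedge` implements, as a tested and reusable Python
library, a pantropical-style analysis of forest degradation: it stratifies
annual 30 m forest-change rasters into intact / degraded / edge / regrowth
classes, co-locates quality-filtered spaceborne-LiDAR footprints (RH50,
RH98, AGBD with prediction SE), measures how far and how strongly edge
effects penetrate into standing forest, reconstructs recovery dynamics by
space-for-time substitution, propagates biomass uncertainty through ANOVA,
models the risk that degraded forest is subsequently deforested, and maps
intact forest landscapes. Everything is exercised end-to-end on a bundled
synthetic-landscape simulator with fully known ground truth, so the whole
chain is testable without downloading satellite data.

It is written for landscape ecologists and remote-sensing scientists who
want the analysis machinery of large-scale degradation studies in a form
they can run, audit and extend on their own data or on simulations.

## The core quantities

* **Edge-desiccation gradient.** Latent canopy height at distance *d* from
  the forest/non-forest edge is modelled as the intact height times
  f(d) = 1 − A_e·exp(−d/λ_e), with λ_e = D95 / ln(A_e/0.05), so that f
  reaches 95% of intact at exactly d = D95. Two penetration-depth
  statistics are computed from distance-band profiles: the conservative
  **95%-of-intact criterion** (first crossing of 0.95 × intact mean,
  interpolated between band midpoints) and the **ANOVA criterion** (upper
  bound of the farthest band still significantly different from intact
  under Tukey HSD at p < 0.05, all farther bands non-significant).
* **Space-for-time trajectories.** Footprints are normalised to the intact
  reference of their grid cell (percent of intact) and grouped by 1-based
  age since disturbance; steps require ≥ 30 samples and cells ≥ 600.
* **Error-propagated ANOVA.** For biomass, noise_ij ~ N(0, σ_j²) with σ_j
  the per-footprint prediction SE is added over 500 Monte-Carlo
  iterations and the F distribution inspected; cell statistics are also
  summarised by 500 resamples of 300 observations.
* **Deforestation risk.** Y_i ~ Bernoulli(π_i), logit(π_i) = α + βX_i with
  X the percent-of-intact height (optionally plus distance to edge), fitted
  by maximum likelihood or MCMC (4 chains × 4,000 iterations, 1,000
  warm-up, split-R̂ convergence), evaluated by ROC/AUC.
* **IFL mapping.** The edge-aware intact stratum aggregated to ~1 km and
  reduced to 4-connected components ≥ 500 pixels (≈ 500 km²).

## A worked example

```bash
python examples/02_edge_effects.py
```

prints (numbers from this exact run):

```
profile footprints: 44526, intact reference 28.6 m
penetration depth (95% criterion): 373 m (truth 400 m)
penetration depth (ANOVA criterion): 2580 m, F = 1585, p = 0.00e+00
edge magnitude (first-band deficit): 17.1% (truth 20% at d = 0)
```

A landscape was simulated with a 20% canopy-height deficit at the edge
decaying so that 95% of intact height is reached at 400 m; from 50,000
quality-filtered footprints the 95%-criterion estimate lands within one
band width of that truth, while the ANOVA criterion reaches much farther —
as expected, since small mean deficits stay statistically detectable long
after the 5% structural threshold is met. The first-band (0–60 m) deficit
understates the instantaneous edge magnitude slightly because the band
averages the decaying gradient over its 60 m width.

The other scripts in `examples/` walk through landscape simulation,
recovery trajectories, uncertainty statistics, risk modelling and IFL
mapping in the same style. A thin CLI (`forestedge simulate|all ...`) wraps
the same pipeline for shell use, with YAML configuration and per-run
provenance (config hash, seeds, SHA-256 checksums; identical seed ⇒
byte-identical outputs).

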