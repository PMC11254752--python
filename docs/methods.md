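# Methods

This note records the models, parameter choices and numerical conventions
behind `forestedge`, and what the synthetic validation does and does not
demonstrate about real data.

## The synthetic landscape

The generator emulates the statistical structure of an annual tropical
moist-forest change product (30 m grid, 1990–2022) and of spaceborne-LiDAR
footprint tables, with every parameter held as ground truth.

**Intact canopy field.** Gaussian-smoothed white noise rescaled to a
continental preset (Americas 28.6 ± 7.4 m, Africa 29.3 ± 8.6 m, Asia
34.4 ± 10.7 m RH98), clipped at the 5 m forest floor. The smoothing length
(default 4 px ≈ 120 m) controls spatial autocorrelation; it is a free knob,
not a claim about real forests, and the controlled recovery scenarios
shrink the field SD so parameter recovery is not confounded by landscape
heterogeneity (see below).

**Dynamics.** A deforestation front expands stochastically from pre-1990
converted land; deforested pixels may be abandoned to secondary regrowth
either per pixel or as whole patches (patch-wise abandonment is what makes
regrowth survive the 35 m morphological filter); fire (disks) and selective
logging (rectangles, emitted as polygons) set pixels to the degraded class
for at most three annual maps — the product's maximum 2.5-year disturbed
period discretised to annual snapshots — and leave a dated degradation
history. Fire and logging never re-disturb each other's pixels, so the
analysis-side driver attribution (fire raster precedence, logging honoured
only outside a 300 m fire buffer) can be exact; an optional `driver_zones`
flag additionally confines the two drivers to separate halves of the
landscape.

**Edge gradient.** Standing forest (undisturbed or degraded classes) is
multiplied by f(d) = 1 − A_e·exp(−d/λ_e), λ_e = D95/ln(A_e/0.05), using the
Euclidean distance to non-forest in the acquisition year. The gradient is
deliberately not applied to regrowth: the regrowth curve measures its own
dynamics, and regrowth is non-forest for edge-distance purposes. D95 is
well-defined only for A_e > 0.05; configurations must use A_e = 0 or
A_e ∈ (0.05, 1).

**Disturbance and regrowth multipliers.** Per driver and metric, the
multiplier at 1-based age a is min(1, (1 − loss) + rate/100 · (a − 1));
defaults: fire losses 30/50/40% (RH98/RH50/AGBD) with 0.3%/yr recovery,
logging 15/25/25% with 0.5%/yr. Regrowth follows P(1 − e^(−a/τ)) with
P = 0.6, τ = 5 yr. Biomass uses AGBD = κ·RH98^γ (κ = 0.8, γ = 1.7, chosen
so intact Americas means sit near 240 Mg/ha) with log-normal noise and a
per-footprint prediction SE drawn from 5–20% of AGBD.

**Footprints.** Parallel transects with ~60 m along-track spacing, years
2019–2022 per track; reported coordinates add isotropic N(0, 11 m)
geolocation error; heights add N(0, 0.5 m) measurement noise; metadata
(beam type, quality/degrade flags, day/night, sensitivity, slope, water,
urban, sub-5 m heights) is contaminated independently at configured
marginal rates, so each quality rule fires at a known frequency. Footprint
slope is drawn from a mixture with the configured exceedance fraction
rather than sampled from the slope raster, keeping the QC exercise rates
exact; the raster is still emitted for raster-based workflows. Each
footprint also receives a deforestation outcome drawn from the logistic
risk truth logit(π) = α + β_h·pct + β_d·d (defaults α = 2, β_h = −0.06 per
percent, β_d = 0), enabling coefficient-recovery tests; landscape-level
front expansion is not constrained to follow this model, so stack-derived
cohorts and truth-drawn outcomes are distinct routes.

## Analysis conventions

* Distance bands are half-open (lower, upper]; distances are pixel-centre
  Euclidean (distance transform) times the pixel size; the 17 default
  intervals run 0–60 … 9,000–10,200 m.
* The sieve treats a pixel as isolated when no 4-connected neighbour shares
  its binary class and replaces it with the 5×5 window mode (ties keep the
  original); flipped pixels take the modal class code of the destination
  side.
* Intact forest: undisturbed, > 3,000 m from the (sieved) forest/non-forest
  edge and > 120 m from degraded forest. The sieved mask is used for the
  3 km criterion. Undisturbed forest between 120 m and 3,000 m belongs to
  no named stratum; it carries `undisturbed` / `far_from_degraded` flags so
  the distance profile can use it.
* Edge classes use a 120 m edge width; edge age is the first year a pixel
  entered the edge zone; natural edges (nearest non-forest is water or
  savannah) are masked. Ages are 1-based (reference − event + 1); regrowth
  age walks back the last *uninterrupted* regrowth spell.
* Co-location erodes each stratum by a 35 m-radius disc (at 30 m pixels:
  the 4-neighbour cross) before point lookup and drops footprints whose
  stratum event year falls in the acquisition period.
* Biomass averages are inverse-variance weighted (w = 1/SE²) with effective
  n = (Σw)²/Σw²; "weighted by the SE" is ambiguous, so 1/SE and SE
  weightings are available as sensitivity switches.
* Sample minima: 30 per distance band or age step, 600 per scope or cell;
  cells with ≤ 2% accumulated deforestation relative to 1990 forest are
  excluded from edge-penetration scopes (boundary excluded).
* The ANOVA penetration criterion compares each band against intact via
  Tukey HSD (studentized range, pooled df) and takes the farthest
  significant band whose farther bands are all non-significant; band-vs-
  intact is the default comparison set, all-pairs is available.
* Resampling of cell statistics is without replacement (a resample, not a
  bootstrap); n < m is an error unless the bootstrap flag is passed.
* The risk model's MLE backend is a binomial GLM; the Bayesian backend is
  random-walk Metropolis with flat priors, 4 chains × 4,000 iterations
  (1,000 warm-up), proposals scaled from the MLE covariance (2.4²/d), and
  split-R̂ per parameter. Complete separation falls back to L2-penalised
  likelihood and is flagged. Cohorts (2019–2021) pool with the cohort year
  retained.
* IFL aggregation to 1 km uses a ≥ 0.5 majority rule (the resampling rule
  is otherwise unspecified); components are 4-connected with a ≥ 500 px
  minimum; minimum-width and corridor criteria are deliberately absent.
  On synthetic grids far smaller than 500 km² the pipeline scales the area
  threshold to the grid so the filter stays meaningful.

## Controlled validation scenarios

Parameter-recovery experiments fix their own study conditions
(`forestedge.scenarios`); these are design choices made once, not tuning
knobs.

* **Edge recovery** (A_e = 0.20, D95 = 400 m, 50,000 clean footprints):
  384 px grid (11.5 km extent hosts the full band scheme), field SD 0.5 m
  with 2 px smoothing, a compact deforestation front (sieve-invariant edge
  geometry), no disturbance events, zero contamination. Under these
  conditions the 95%-criterion estimate is dominated by the method's own
  discretisation (band-integrated means interpolated at midpoints, ≈ +30 m
  at this D95) with ~15 m sampling spread — within one band width of truth.
* **Stationary world** (space-for-time validity): constant event rates
  through 1991–2022, patch-wise abandonment, driver zones, A_e = 0, field
  SD 0.5 m, exact footprint positions. Geolocation error is deliberately
  off here because it mixes ages across patch boundaries *within* a
  stratum — a co-location issue exercised separately — whereas these tests
  isolate the space-for-time substitution itself.
* **QC fixture**: wall-to-wall undisturbed forest with default
  contamination, so every rule's violation rate equals its configured
  marginal probability.

## What passing tests do and do not show

The synthetic world realises the analysis assumptions by construction:
stationary disturbance regimes, a single known edge-decay form, exact
class labels, independent contamination and Gaussian noise. Passing the
suite demonstrates that the estimators recover truth when those
assumptions hold and that the numerics (distance transform, sieve,
labelling, resampling algebra, ANOVA decomposition) are exact. It does not
validate the assumptions themselves on real imagery — misclassification,
non-stationary disturbance history, driver attribution error, spatially
correlated measurement error and real geolocation behaviour are outside
the generator's scope; the geolocation experiment above shows one such
interaction (age mixing) explicitly.

## Numerical and reproducibility notes

* One root seed; every stochastic operation draws from a named
  `SeedSequence` substream (CRC-hashed operation/scope keys, PCG64), so
  adding one analysis scope never perturbs another's draws, and identical
  configuration + seed yields byte-identical outputs (TIFFs are written
  without software/date tags; CSVs with fixed float formatting).
* Degenerate inputs: zero within-group variance is an error for ANOVA and
  Tukey; zero SEs are an error for the weighted mean but the zero-noise
  limit of the Monte-Carlo ANOVA is exact by sharing one code path with
  the baseline; an all-forest mask yields flagged +inf distances; ties in
  the sieve window keep the original class.
* Default problem sizes (256 px landscapes, 10–50 k footprints, 500
  Monte-Carlo iterations) keep any full run in seconds to a few minutes on
  one core while leaving every sample-size threshold of the protocol
  binding.

## Known limitations

Logging polygons are synthetic rectangles, not interpreted concessions;
the generator's deforestation front does not follow the logistic risk
truth (outcome-drawn columns exist for that purpose); RH50 is a noisy
fixed ratio of RH98 rather than a waveform-derived quantity; no orbital
geometry, radiometry or reprojection; mangrove/bamboo exclusion is
accepted only as an external mask.
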