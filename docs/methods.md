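# Methods

`lostyears` implements a presence/pseudo-absence habitat-suitability analysis
for oceanic-stage juvenile sea turtles tracked by satellite telemetry, together
with a synthetic ocean in which every stage of the analysis can be validated
against a known, planted habitat preference. This note documents the models,
the defaults and why they were chosen, the numerical choices, and what the
synthetic experiments do and do not demonstrate about real data.

## The analysis

The response is binary: observed daily turtle positions (presence, 1) versus
simulated correlated-random-walk positions (pseudo-absence/background, 0),
each paired with 17 contemporaneous environmental covariates on a daily
0.25° grid. A gradient-boosted tree ensemble with Bernoulli deviance loss
("boosted regression trees", BRT) estimates P(presence | environment), which
is read as habitat suitability in [0, 1]. The fitted model is then applied to
every sea cell and day to produce a suitability cube, from which seasonal
mean maps and habitat-persistence maps derive.

## Track processing

1. **Speed prefilter.** Fixes are removed iteratively (worst first) until all
   adjacent great-circle speeds are ≤ 2.5 m/s, the standard sustained-speed
   ceiling for juvenile loggerheads.
2. **State-space regularization.** Positions are estimated every 24 h (00:00
   UTC anchors) with a linear-Gaussian continuous-time correlated random walk
   (CTCRW): per coordinate the state is (position, velocity) with an
   Ornstein–Uhlenbeck velocity, dv = −βv dt + σ dW. A Kalman filter over the
   merged timeline of fixes and daily anchors, followed by an RTS smoother,
   yields daily positions and standard errors. Defaults β = 1 day⁻¹ and
   σ = 0.7 deg day^−3/2 give a stationary speed scale of ≈ 0.5 deg/day
   (~55 km/day), appropriate for these animals; both are configurable.
   Observation variances come from a configurable Argos location-class table
   (classes 3…B, isotropic, 0.003°–0.2° SD) or, for light-level geolocators,
   the anisotropic 1.0° longitude / 1.8° latitude errors. The treatment is
   deliberately planar per coordinate (no cos-latitude metric coupling);
   at mid-latitude scales and daily steps the induced distortion is well
   below the observation error.
3. **Speed cap.** The smoother itself is unconstrained, so smoothed tracks
   are projected onto the ≤ 2.5 m/s set afterwards: displacements exceeding
   the bound are contracted about their midpoints (0.1% safety margin),
   sweeping until none remain, with a sequential step-clamp as a guaranteed
   fallback. This is a projection, not a likelihood constraint — the cap is
   enforced exactly, at the cost of a small local distortion where it binds.
4. **Land rerouting.** Positions whose nearest grid cell is land move to the
   nearest sea-cell center (error beyond 500 km). This replaces shortest-path
   rerouting around coastlines; on a 0.25° grid with oceanic tracks the
   difference is at most a few cells.
5. **Gap segmentation.** Interpolated days lying strictly inside any raw-fix
   gap > 10 days are discarded; remaining runs of consecutive days become
   segments; segments shorter than 5 days are dropped. The gap rule is
   evaluated on raw fix times, and a gap of exactly 10.0 days does not split.
6. **Shore-release trim.** For animals released from shore, the first 7 days
   are removed (acclimation/escape behavior), with the 5-day minimum
   re-applied. Trimming precedes CRW generation so background tracks never
   include those days.
7. **Migration exclusion.** Directed cross-basin migration is not habitat
   selection, so persistent westward phases are cut. A windowed
   move-persistence index is computed per day from a centered 7-day window:
   γ = ½(1 + mean cos turning angle) × (mean step / max step), clipped to
   [0, 1]; the net heading is the bearing of the window's net displacement.
   The earliest run of ≥ 10 days with γ ≥ 0.75 and heading in (225°, 315°)
   marks onset; that day onward is removed. This is a transparent stand-in
   for a full state-space move-persistence model: it reproduces the γ = 1
   straight-travel and γ = 0 stationary limits and is monotone in
   directedness, but its absolute scale is window-dependent, so the
   thresholds are exposed as configuration rather than presented as
   estimates.

## Pseudo-absences

For each presence segment, 100 CRW replicates are simulated: start at the
segment's first position with a uniform initial bearing, then draw step
lengths and turning angles independently, with replacement, from the
segment's own empirical samples (great-circle step lengths; signed bearing
changes). Replicates are date-matched 1:1 to their segment so covariate
extraction is contemporaneous. Steps proposing land are redrawn (cap
100/step); stuck replicates restart (cap 50); exhausting the budget is an
error naming the segment. A replicate is discarded entirely if any daily
step would require an active swimming speed — |ground velocity − (U, V)
current vector|, current sampled at the step start — strictly above 2 m/s;
a step at exactly 2.0 m/s is kept. Independent resampling of steps and
angles (rather than joint pairs) is used because the two empirical samples
differ in length by construction; for daily-resolution tracks the
step–angle correlation is weak and the choice is isolated behind
`StepDistribution`.

## Covariates

The 17 covariates: bathymetry, rugosity, ADT, ADT SD, SLA, SLA SD, mixed
layer depth, SST, SST SD, chlorophyll-a, micronekton, NPP, zooplankton,
FSLE, EKE, and normalized distances to the closest cyclonic and anticyclonic
eddies. Derivations:

* **Rugosity** = 3×3-cell neighborhood SD of bathymetry (population SD,
  ddof = 0; edge cells use available neighbors). Window configurable.
* **EKE** = ½(u′² + v′²), anomalies relative to the per-cell temporal mean
  over the full series by default (window configurable).
* **Temporal SDs** (SST, ADT, SLA) use a trailing 30-day window including
  the current day (ddof = 0), with shorter history at the series head.
* **Eddy distances**: great-circle distance to the nearest eddy center of
  the requested polarity alive that day, divided by that eddy's radius; only
  eddies detected for strictly more than 10 days qualify; missing when no
  qualifying eddy exists.
* **Point extraction** is bilinear over the four surrounding cell centers
  with land cells dropped from the stencil and weights renormalized; daily
  fields are matched same-day. Missing covariates cause listwise row
  deletion (counts logged); losing more than half the rows aborts, since it
  signals a domain/coverage mismatch rather than scattered gaps.

## Habitat model

Tree induction is scikit-learn's `GradientBoostingClassifier` (Bernoulli
deviance); "tree complexity" maps to `max_depth`, the bag fraction (0.6) to
`subsample`. Everything above single-model fitting is implemented here:

* **Stagewise tree-number selection**: the ensemble grows in increments of
  50 trees simultaneously in k stratified folds (warm-started); the mean
  held-out Bernoulli deviance is tracked and growth stops after 3 stages
  without improvement; the minimizing tree count is selected and the final
  model refit on all rows. Selections under 50 trees trigger the standard
  advice to lower the learning rate. This mirrors the classic stagewise CV
  procedure for BRTs.
* **Ratio experiment**: presence:background ratios 1:1–1:5 at fixed learning
  rate 0.01 and tree complexity 5, pseudo-absences drawn uniformly without
  replacement from the full CRW pool.
* **Grid search** over learning rates (0.0001…0.5) × tree complexities
  (3, 4, 5).
* **Evaluation** in three regimes: 100/100 (train = test), stratified 75/25,
  and 10-fold CV with per-fold refits at the selected tree count. Metrics:
  rank-based AUC (ties ½), C-index (pairwise concordance, ties ½ — equal to
  AUC for binary outcomes, computed independently so the identity is
  verified, not assumed), pseudo-R² = 1 − residual/null deviance, RMSE on
  the probability scale, and predicted/observed ratio Σp/Σy. Winners are
  ranked by the mean AUC of the 100/100 and 75/25 regimes, ties broken by
  pseudo-R² then RMSE. The tree count is selected once on the full dataset
  and reused when refitting inside evaluation regimes; re-selecting per
  regime would multiply cost ~10× without changing the comparison.
* **Relative influence**: per-variable share of total impurity reduction
  across all splits, normalized to sum to 100%; never-used variables are
  exactly 0.

## Prediction and persistence

Daily predictions use cell-center covariate values with the same derivations
as training (contemporaneous, never climatological means, to preserve
mesoscale structure). Seasons are meteorological: spring Mar–May, summer
Jun–Aug, autumn Sep–Nov, winter Dec–Feb, December grouped with the following
January–February; yearly persistence assigns winter to the year containing
its January. The persistence threshold is the 0.75 quantile (linear
interpolation between order statistics) of all pooled cell-day suitability
values after discarding values below 0.1; persistence is the per-cell
fraction of non-missing days strictly above the threshold (a day exactly at
the threshold does not count). The overall map is exactly the day-count-
weighted mean of the four seasonal maps, which is asserted in tests.

## The synthetic ocean

The generator emulates the structure of the real forcing data rather than
ocean physics:

* **Bathymetry**: a −4800 m abyssal plain, a Gaussian meridional ridge, an
  eastern shelf rising into a coastal land strip, three islands, and smooth
  roughness. Land is wherever elevation ≥ 0, so rerouting and CRW land
  rejection are genuinely exercised.
* **SST**: meridional gradient (≈ −0.43 °C/° latitude over the default
  domain), a seasonal cycle with poleward-increasing amplitude peaking in
  early August, and smooth low-rank space–time noise.
* **Currents**: streamfunction-derived, hence divergence-free — a meandering
  zonal jet (peak 0.3 m/s, Azores-Current-like) plus Gaussian eddy vortices
  (0.25 m/s swirl), so advection alone cannot beach an animal. ADT is the
  streamfunction under an f/g geostrophic scaling; SLA is ADT minus its
  temporal mean; FSLE is a stretched function of the current shear.
* **Eddy catalog**: exactly `n_eddies` eddies, all long-lived (> 10 days),
  chained per polarity so that (for n ≥ 2) both polarities are alive every
  day — as in real basin-scale eddy atlases — keeping the eddy-distance
  covariates defined everywhere. Centers drift slowly westward.
* **Biogeochemistry** (chlorophyll, NPP, zooplankton, micronekton): weakly
  coupled saturating functions of one another with smooth noise, a weak
  poleward gradient and coastal enhancement.
* **Tracks**: daily biased CRWs — heading is a weighted compromise (weight
  0.9) between the previous heading and the local uphill direction of true
  suitability, plus 20° heading noise; gamma-distributed swim steps (mean
  45 km/day, capped at 120 km/day ≈ 1.4 m/s, well under the 2.5 m/s
  ceiling); optional advection by the local current (on by default); an
  optional area-restricted-search factor (travel scaled by
  1 − ars·suitability; off by default) for residence-time contrast.
  Release sites are drawn with weight proportional to suitability² —
  animals are tagged where animals are, as in real deployments. Observation:
  ~2 fixes/day at uniform times (positions interpolated within the day),
  Argos-class or geolocator noise, 1%/day chance of a 3–14 day gap.
  Noise-free daily truth is retained for recovery tests.

The **planted preference** is logistic in SST (+0.35 per °C) and bathymetry
(−4 × 10⁻⁴ per m, i.e. deeper is better), with the intercept placing
suitability 0.5 near 21 °C over −3500 m. The weights are sized so the linear
predictor spans roughly ±3 logits across the default 30° × 30° domain: a
saturated truth surface would leave most cells with no recoverable rank
structure, and a jet much stronger than the swimming speed would make
presence/background contrast reflect advection geometry (FSLE, ADT) rather
than the planted drivers. With these defaults the preference is recoverable,
which is the purpose of the synthetic study.

## Problem sizes

The default study — also what `scripts/acceptance.py` runs — uses 40 tracks
of 100–200 days over a 30° × 30°, 2-year, 0.25° ocean with 48 eddies; 100
CRW replicates per segment; ratio 1:1 at learning rate 0.1, tree complexity
5, bag fraction 0.6; stagewise selection in 10 folds with step 50 up to 250
trees; prediction every 7th day; evaluation under the 100/100 and 75/25
regimes (the 10-fold regime is available via configuration and covered by
unit tests). These sizes — far below a basin-scale multi-decadal tagging
programme with a hundred animals — keep a full run in single-digit minutes
on one CPU; every component accepts the full extent via configuration.

## What the synthetic experiments show — and what they do not

Passing the recovery study shows the pipeline is internally consistent: the
filtering rules do what they state, the smoother reduces observation error,
the background model provides availability contrast, and the BRT recovers a
known smooth preference from noisy, advected, irregularly observed tracks.
It does not validate the ecological model for real loggerheads: the
synthetic covariate fields are structurally simpler than CMEMS/AVISO
products (no fronts, no shelf-break dynamics, no cloud-gap missingness),
the planted truth is exactly logistic-additive (real preferences are not),
and the CRW availability model is the same family used to generate the
tracks' step lengths, which flatters the presence/background contrast
relative to field data.

A structural caveat on surface recovery: a presence/background model
estimates the use-to-availability ratio, not the preference surface itself.
Finite, autocorrelated tracks do not equilibrate to the instantaneous
suitability surface (animals transit poor habitat, linger behind fronts,
and are advected), and smooth covariates such as the two eddy distances let
deep trees partially encode position. The held-out discrimination (AUC) and
the driver-influence ranking recover cleanly; the cell-by-cell rank
agreement between the predicted and the true surface is systematically
weaker than either, and the end-to-end recovery test reports exactly how
much.

## Known limitations

* The CTCRW smoother treats longitude and latitude independently in degrees;
  at high latitudes or for basin-crossing tracks a metric (km) state space
  would be preferable.
* The move-persistence index is a windowed heuristic, not an estimated
  latent process; its γ scale depends on the window.
* Rerouting moves positions to cell centers; it does not route around
  coastlines, so a track crossing a wide land barrier is displaced, not
  detoured.
* The eddy-distance covariate follows the "closest eddy center" definition;
  a nearer eddy with a much smaller radius can therefore increase the
  normalized distance.
* `GradientBoostingClassifier` is exact but slow; at basin scale a
  histogram-based learner would be the pragmatic substitute at the cost of
  the bag-fraction semantics.
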