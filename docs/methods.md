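# Methods

This note documents the models, procedures and numerical choices
behind `soilcue`, and what the synthetic-data generator does and does
not emulate.

## Trait derivation

One soil replicate carries the raw measurements of a ¹³C-tracer
incubation: total extractable DNA carbon (DNA-C, µg C g⁻¹ soil, a
microbial-biomass proxy), the label-derived excess ¹³C in DNA
(DNA-¹³C) and in cumulatively respired CO₂ (ΣCO₂-¹³C) after a 16-h
incubation with ¹³C-labelled dissolved organic carbon, basal
respiration (µg C g⁻¹ h⁻¹) and a potential enzyme activity
(nmol g⁻¹ h⁻¹). The derived traits are ratios:

| trait | formula | domain |
|---|---|---|
| CUE | DNA-¹³C / (DNA-¹³C + ΣCO₂-¹³C) | (0, 1) |
| turnover | DNA-¹³C / DNA-C | [0, 1], per 16-h incubation |
| qCO₂ | basal respiration / DNA-C | ≥ 0 |
| enzyme investment | enzyme activity / DNA-C | ≥ 0 |

Turnover is reported per incubation period (16 h), not normalised per
hour; callers convert if they need rates. Undefined traits (zero
denominators) are flagged in a `flags` column and kept as NaN rows, so
downstream sample counts remain auditable. The pipeline accepts either
precomputed excess masses or raw δ values plus isotope constants; the
δ path applies `R = R_std (δ/1000 + 1)`, atom fraction `R/(1+R)`, and
two-pool linear mixing between background and label source. Because
natural ¹³C abundance is already ≈ 1.07 atom %, the "one atom percent"
enrichment of the litter label is interpreted as one atom percent
*excess*: the default label atom fraction is the C3-plant background
(δ ≈ −27 ‰) plus 0.01.

## pH threshold: the slope-failure test

A window of width 1.4 pH units slides along the pH axis in 0.1-unit
steps (both values exposed in `ThresholdConfig`); windows are anchored
on the absolute 0.1 grid and cover `[t, t + 1.4)`. Within each window
with at least 10 records, CUE is regressed on SOC by ordinary least
squares and the R² recorded. Replicates are treated as independent
records throughout.

Interpretation of the profile involves three deliberate choices:

- **Detection.** A threshold is reported only when some window R²
  exceeds the upper quantile of the null R² distribution
  (Beta(1/2, (n−2)/2) for an n-record window), Šidák-adjusted across
  the valid windows at a familywise 5 % level. Pure-noise surveys
  therefore come back `detected=False` (measured false-detection rate
  2–3 % over 100 null simulations).
- **Failure.** "R² dropped dramatically" is operationalised as falling
  below `drop_fraction` (default 0.5) of the maximum window R². A
  failure only counts if it persists for 4 consecutive windows
  (`failure_persistence`): overlapping windows share ~93 % of their
  records, so transient one-to-three-window dips are the signature of
  site-level sampling noise (three replicates share a site's SOC,
  which makes the effective window sample size the number of sites,
  not records), whereas a genuine regime change keeps the R² down for
  every window below the break.
- **Boundary refinement.** Scanning from high to low pH, the intact
  regression is extended downward one grid step at a time; records
  entering the fit are tested against it, and a record whose absolute
  standardised residual exceeds `outlier_sd = 4` stops the scan — the
  piecewise-regression signature of crossing into the other regime,
  where CUE sits far below the extrapolated line. The reported
  threshold is the lowest pH among the records accepted as intact,
  snapped *down* to the 0.1 grid: the break must lie below every
  record that follows the intact regression, and the first such record
  above the break pins it tightly because records are dense on the pH
  axis. If no window ever fails, the profile is flat and the threshold
  is the smallest valid anchor.

Records with pH exactly at a threshold are assigned to the
below-or-equal side everywhere in the package (segregation, contrast
typing); this convention is forced by the packaged contrast table,
whose pair 21 has its high-intensity member at exactly pH 6.2 and
belongs to Type 3 for the counts to come out 11/6/4.

Under the generator's default conditions (56 sites × 3 replicates,
breaks on the 0.1 grid between pH 5 and 7), the detector recovered the
planted break within ±0.1 in 96 of 100 development seeds; the residual
failures are surveys where no site happens to fall within ~0.2 pH
units below the break, which no profile-based estimator can resolve.

## Single-split regression tree

The partitioning variable is chosen by an exhaustive depth-1
regression-tree search: every candidate edaphic variable (pH,
moisture, clay, total C, total N, C:N) and every midpoint between
consecutive sorted unique values is scored by the reduction in pooled
within-node SSE of the response, with at least `min_leaf = 5` records
per side. Ties resolve to the earlier candidate and the smaller split,
so the search is deterministic; candidates with fewer than two
distinct values are skipped. Only the single best split is needed —
the tree exists to rank partitioning variables, so no recursion,
pruning or surrogate splits are implemented. The implementation is
checked in the test suite against a naive brute-force enumeration and
against `sklearn.tree.DecisionTreeRegressor(max_depth=1)`.

## Trait–SOC models

Three functional forms are supported: linear `y = ax + b`, logarithmic
`y = a ln x + b` (requires x > 0) and exponential `y = a e^(bx)`
(requires y > 0 for initialisation). Linear and logarithmic fits are
closed-form OLS; the exponential is true nonlinear least squares on
the original scale (`scipy.optimize.curve_fit`) initialised from the
log-linearised fit, because additive noise on y makes log-space
estimation biased. R² is always computed on the original y scale and
reported as 0 for a constant response. Model selection uses AICc with
k = 3 (two coefficients plus the residual variance); near-ties within
1e−8 go to the simpler form in the order linear, log, exponential, and
an R²-based criterion is available as an alternative. Fits are
reported per pH segment (below / above the threshold) and pooled.

The LOI → C calibration is OLS of total C on loss-on-ignition over the
non-calcareous records; calcareous records (whose combustion signal
includes inorganic carbonate) receive predicted C values.

## Land-use contrasts

Fold change is oriented high-intensity over low-intensity — the effect
*of intensification* — so values above 1 mean the trait increased when
management intensified; the orientation is recorded in the pipeline
manifest. Pair members are aggregated as site means over non-flagged
replicates before the ratio is taken. Types: 1 (both member mean pH
above the threshold), 2 (low at/below, high above), 3 (both
at/below); a reversed pair is flagged unclassified rather than forced
into a type. Distribution summaries per type report count, mean,
median, quartiles and range of the fold changes — the boxplot surface.
No significance tests are attached: with 4–11 pairs per type the
distributions themselves are the result.

## Indicator analysis

For feature *i* and group *j*, specificity `A_ij` is the group mean
abundance divided by the sum of group mean abundances, fidelity
`B_ij` is the fraction of group-*j* samples with abundance > 0
(exactly > 0; spectral-count-like matrices need no epsilon), and
IndVal = A × B on the 0–1 scale (multiply by 100 for the conventional
display scale). Each feature is assigned its argmax group, ties going
to the lexicographically first group with a tie flag.

Significance comes from permuting the group labels jointly across
features (preserving feature correlation). The default test statistic
is the feature's **maximal score over groups**, the classic
indicator-species-analysis statistic: because it is label-symmetric,
the permutation test is exact, and the measured null rejection rate at
α = 0.05 is 0.05 within binomial error. When the number of distinct
two-group label assignments is at most the permutation budget, all of
them are enumerated and the p-value is the exact proportion (the
identity assignment counts, so p ≥ 1/#assignments; note that for a
perfectly concentrated feature the complementary assignment ties the
maximal score, so the smallest attainable p with equal group sizes is
2/#assignments — with 3 + 3 samples that is 0.1, which is why small
contrast designs cannot reach α = 0.05 under the exact test). Monte
Carlo p-values use the add-one estimator, so p is never 0.

A second statistic, `statistic="group"`, scores the permuted matrix
only for the feature's observed best group. It reproduces per-group
p-values (a perfectly concentrated 2+2 feature gets p = 1/6 instead of
2/6) but the group is selected by the data, which makes the test
anticonservative under the null — for two groups
P(p ≤ α) ≈ 1 − (1 − α)², measured at 0.105 for α = 0.05. It is
therefore an option, not the default.

Benjamini–Hochberg adjustment across features is available but off by
default; per-feature permutation significance is the primary output.
Functional-class roll-ups count significant indicators per (group,
class) and sum their in-group mean relative abundances; unmapped
features are binned as "unclassified".

Rarefied richness uses the hypergeometric closed form
`Σ_i [1 − C(N−n_i, d)/C(N, d)]` at depth d = 2000 reads (log-gamma
implementation), which is the exact expectation of the usual
resampling procedure; samples with fewer than d reads are rejected so
callers can flag them rather than silently rarefy.

## Synthetic data generator

The generator plants a known truth with the survey's structure:
56 sites × 3 replicates, site pH uniform over 3.5–8.5 with a 0.05-SD
replicate jitter, and a regime switch at a configurable pH break
(default 6.2, assigned per replicate with at-or-below going to the
acidic regime). Per regime, SOC is lognormal — acidic soils richer
(median 8 % C, log-SD 0.5, clipped to 1.5–25) than near-neutral ones
(median 2.8 %, log-SD 0.55, clipped to 0.5–12), calibrated to the
span of the packaged contrast table — and the traits follow the
regime's trait–SOC model (CUE linear with slopes 0.0004 below vs 0.01
above the break; turnover logarithmic; qCO₂ exponential, DNA-C linear
and enzyme investment logarithmic in all regimes), clipped into their
physical domains at the SOC extremes. Raw measurement columns are then
back-derived (DNA-¹³C = turnover × DNA-C, ΣCO₂-¹³C =
DNA-¹³C (1−CUE)/CUE, basal respiration = qCO₂ × DNA-C, activity =
investment × DNA-C), so trait derivation recovers the planted values
exactly — to 1e−9 relative at zero noise, and bit-identically under a
fixed seed.

Noise (default `noise_sd = 0.2`) is multiplicative lognormal
`exp(N(0, noise_sd))` on the strictly positive traits — a 20 %
coefficient of variation, typical of replicated soil microbial
assays — and **additive** Gaussian on CUE with
sd = `noise_sd` × 0.05 (a reference above-threshold community CUE),
truncated into (0, 1). The additive choice reflects the measurement:
the instrument error lives in the ¹³C-excess signals, so the absolute
CUE error is roughly constant and low-CUE acidic soils are
proportionally much noisier. This is also what makes the generated
below-threshold CUE–SOC relationship collapse (segment R² ≈ 0.01–0.05
versus ≈ 0.75–0.86 above), mirroring the phenomenon the threshold
detector is built to find. Moisture decreases linearly with pH (acidic
sites wetter), C:N centres on 11, and LOI ≈ 1.9 × C + 0.8 with
proportional noise; all auxiliary noise scales with `noise_sd`, so a
zero-noise survey is fully deterministic given the pH placement.

Contrast pairs place member pH according to their planted type (with a
0.15-unit safety margin around the break so replicate jitter cannot
flip a type) and apply per-trait fold changes of `effect_size`
(default 1.6) to the high-intensity member in the configured
directions: SOC decreases in all types; above the break (and when
crossing it) turnover and qCO₂ increase and biomass decreases; CUE
decreases in Type 1 but increases in Type 2; Type 3 plants only the
SOC loss. Feature tables are lognormal abundance × Bernoulli presence,
with planted indicators given full in-group presence, 0.1 out-group
presence and a 6-fold abundance boost.

What the generator does **not** emulate: spatial autocorrelation among
sites (sites are independent), within-site covariance between traits
beyond the shared SOC draw, seasonal or temporal structure,
compositionality or sequencing noise in feature tables, and the
skewed, zero-inflated error structure of real IRMS chromatogram
integration. Passing tests therefore demonstrate correctness of the
estimators under a clean version of the survey's statistical
structure, not robustness to every artefact of real field data.

## Problem sizes

Defaults mirror the survey design: 56 sites × 3 replicates for
threshold work, 21 contrast pairs (11/6/4 per type), 1000 IndVal
permutations. The null-validity check of the permutation test uses
8 samples per group: with the survey's 3 + 3 design the exact test's
p-values are multiples of 1/20 bounded below by 0.1, so no rejection
at α = 0.05 is possible for any statistic and the rejection-rate
calibration would be vacuous; 8 + 8 makes the Monte-Carlo path and the
α = 0.05 band meaningful while remaining a small-sample design.

## Known limitations

- Threshold recovery is limited by site density near the break: with
  ~11 sites per pH unit, about 4 % of surveys have no site close
  enough below the break to localise it within one grid step.
- The exponential fit can fail to converge on pathological data; it
  then falls back to the log-linearised estimate.
- The IndVal exact test's granularity at tiny group sizes (see above)
  means 3-replicate contrasts cannot yield p < 0.1; interpret
  per-contrast indicator lists from such designs accordingly.
- Replicates are treated as independent records (as in the survey's
  own analysis); no mixed-effects site terms are fitted, so segment
  R² values on clustered data are optimistic relative to a
  site-level analysis.
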