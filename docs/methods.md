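# Methods

This note defines the statistical model, the defaults and their rationale,
the scope of the synthetic data generator, and the numerical implementation
choices. Notation: n farms, p explanatory variables, m = 7 crop performance
indicators, A latent components.

## Model

Both blocks are column-centred and scaled to unit variance (sample SD,
ddof = 1); dummies are scaled like any other column, following the usual
chemometric convention (this deliberately inflates rare categories). Response
scaling is configurable (`scale_y`). The PLS2 model is

```
X_s = T P' + E,    Y_s = T Q' + F,    B = W (P'W)⁻¹ Q'
```

with unit-norm X-weights W. Components are extracted sequentially by the
NIPALS iteration (power iteration on the cross-covariance), deflating both X
and Y with the X-scores; a single-response problem reduces to PLS1 through
the same code path. Signs are fixed so the largest-magnitude element of each
weight vector is positive. Predictions for new rows apply the training-set
centring/scaling, project through the rotations W(P'W)⁻¹, and map back to
original response units.

### Cross-validation and component selection

K-fold cross-validation (default K = 7) assigns rows to folds by a seeded
shuffle followed by contiguous blocks, so fold sizes differ by at most one.
Every fold model is refitted from scratch, including its own
centring/scaling statistics — no information leaks from held-out rows.
Held-out squared errors are expressed on the full-fit response scale so
PRESS and residual sums of squares are commensurate. Per component:

```
Q²_a = 1 − PRESS_a / SS_{a−1},     Q²(cum) = 1 − Π_a (PRESS_a / SS_{a−1})
```

with SS₀ the total scaled response sum of squares. Q² is never floored at
zero; negative values are reported as such. A component is retained while its
overall Q²_a exceeds the significance limit (default 0.05, strict
inequality); at least one component is always kept, with a flag when even the
first fails the limit. A vanished residual (perfect fit after a−1
components) gives ratio 1, i.e. zero additional Q² — the guard avoids a 0/0.
The candidate cap defaults to min(4, n − ⌈n/K⌉ − 1, p).

### Variable selection (VIP)

```
VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ),   SSY_a = (t_a·t_a) ‖q_a‖²
```

With unit-norm weights, mean(VIP²) = 1, so at least one variable always
scores ≥ 1 and the filter can never empty the variable set. Variables with
VIP strictly below the threshold (default 1.0) are eliminated — a score equal
to the threshold is retained — and the model is refitted once with a fresh
component selection. Exactly two rounds, no iteration.

### Metrics and diagnostics

- **R²Y (cum)**: fraction of scaled response variance explained; also per
  response.
- **Q²Y (cum)**: cross-validated analogue, from the multiplicative rule above.
- **RMSRE**: 100·sqrt(mean(((y − ŷ)/y)²)) per response, on original units;
  undefined (an error) when an observed value is zero.
- **Hotelling T²** on the first two score columns:
  T²_lim = k(n² − 1)/(n(n − k)) · F(1 − α; k, n − k) with k = 2; rows
  strictly above the limit are flagged. A degenerate latent dimension (zero
  spread) flags nothing.

### The nineteen-model suite

Model 1: all farms (n = 34). Model 2: organic only (n = 22). Model 3:
conventional only (n = 12). Models 4–9: six balanced resamples of 6 organic +
6 conventional farms per region (n = 24). Models 10–19: ten resamples of 6
organic farms per region (n = 12). Resampling is stratified by (region,
organic/conventional), without replacement within a stratum, seeded per model
via `SeedSequence(entropy=master, spawn_key=(index,))` so adding models never
perturbs earlier draws. Before fitting, each subset drops columns whose
minority value count is ≤ ⌈n/K⌉: such columns are constant or can become
constant inside a training fold, which makes scaling impossible (typical
casualties: rare dummies; years-since-transition on the conventional-only
subset). Replicate groups are summarised as mean ± SD of overall R²Y and Q²Y.

## Defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| K (CV folds) | 7 | balanced folds at the n = 34/22/12 subset sizes |
| Q² limit | 0.05 | conventional significance limit for one component |
| VIP threshold | 1.0 | mean(VIP²) = 1 makes 1 the natural cut |
| a_max | min(4, bound, p) | two designed factors plus headroom |
| tol / max_iter | 1e-10 / 5000 | see numerical choices |
| α (Hotelling) | 0.05 | standard 95% region |

## Synthetic generator

Each farm draws a latent score vector t ~ N(0, I_A₀) (A₀ = 2) with a region
offset of ±`region_effect`/2 on the first factor. *Active* variables carry
z = p_j·t + N(0, 1/snr_x) with deterministic unit-norm loading directions
(golden-angle spacing, seed-independent: loadings are design, not noise);
inactive variables are pure N(0, 1) background. The latent propensity z is
then mapped into the variable's declared kind: continuous/percentage/index
values are placed affinely inside the schema range (SD = range/8) and
clipped; dummies threshold z at a normal quantile; ordinal scales use
equal-probability normal bins; years since transition is drawn consistently
with the farm type (conventional 0, young organic 1–5, old organic 11–26).
Responses are y_m = loc_m + scale_m (q_m·t + N(0, 1/snr_y)) with unit-norm
response loadings, so the designed explainable variance fraction is the
closed form `design_r2 = signal / (signal + 1/SNR²)`.

Organic farms draw on a 12-variable active set (soil status, weed pressure,
management history, landscape); conventional farms on a 4-variable set
(current mineral nitrogen and pesticide inputs). Response noise is
type-dependent: `snr_y_of = 3.0` and `snr_y_cf = 0.65`, a design choice fixed
up front so the designed explainable response variance is ≈ 0.9 for organic
and ≈ 0.3 for conventional rows — the qualitative contrast that organic crop
performance is explained by many socio-ecological factors while conventional
performance is dominated by unmodelled current inputs. `SyntheticConfig.recovery()`
is a symmetric preset (five continuous active variables shared by both types,
uniform SNR 3) for parameter-recovery experiments; `.noiseless()` removes all
channel noise for exactness checks.

**Not emulated**: measurement error structure of real surveys, missing
answers, spatial autocorrelation beyond the single region offset, year
effects, nonlinear soil–yield response, and any between-variable dependence
other than the shared latent factors. With the default mixed-kind schema the
latent-to-variable map is not affine (clipping, thresholding, binning), so
even the noiseless limit is not exactly linear; exactness tests use a fully
continuous schema instead.

## Numerical choices

- **SVD warm start**: the NIPALS fixed point for a component is the dominant
  singular pair of XᵀY, so the iteration is seeded with the corresponding
  Y-side direction. A cold power iteration stalls when the top two singular
  values nearly tie (observed on noiseless rank-2 CV folds); the warm start
  makes convergence immediate while keeping the NIPALS update as the
  authoritative computation.
- **max_iter = 5000, tol = 1e-10** on the relative change of the Y-score
  vector u: random small instances occasionally need ≈ 600 iterations at this
  tolerance, so a 500 cap was too tight; 5000 leaves an order-of-magnitude
  margin without masking genuine non-convergence, which raises
  `ConvergenceError`.
- **Zero-residual ratio guard** in cross-validation: PRESS/SS ratios are
  computed with `np.divide(..., where=ss>0)`, giving ratio 1 (zero marginal
  Q²) when a previous component already fits perfectly.
- **Component floor**: when even the first component fails the Q² limit, one
  component is kept and the report carries `component_floor_flag=True` rather
  than returning an empty model.
- **Strict inequalities** throughout: Q² must exceed the limit; VIP equal to
  the threshold is retained; T² equal to the limit is inside.
- Typical problem sizes are tiny (n ≤ 34, p ≤ 34, m = 7, A ≤ 4); all linear
  algebra is dense double precision, and the full nineteen-model suite runs
  in about a second.

## Data model

The shipped schema declares 34 explanatory variables (29 survey/landscape,
5 soil) with label, level, kind (continuous, percentage, dummy, ordinal,
index), unit and pooled valid range. Two variables (seeding time
SD-standardized day, clay content) are flagged `region_standardized`: their
values are median-centred within region before modelling (range validation is
skipped for them since centring shifts units). The landscape heterogeneity
index is LHI = sin 45° · (z₁ + z₂), the sum of the population-standardized
proportions of semi-natural grassland and field borders within 1 km.
Aggregation rules (YAML) map raw survey answers to variables: identity,
proportions, frequencies over three years, ordinal management scales, dummy
coding and the LHI formula, with errors that name the farm and rule on
missing or unmappable answers.
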