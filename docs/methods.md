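# Methods

## Model

Perceived target distance is modelled as maximum-a-posteriori estimation on
a discretized distance axis. The disparity likelihood at each tested target
distance is Gaussian, `N(x; μ_disp, σ_disp)`, with moments taken from the
surface-absent matches at that distance — the baseline condition is assumed
bias-free, so its match variability is read as sensory (likelihood)
uncertainty. The occlusion cue enters as a prior over target distance given
that the target is visible: flat up to the surface, Gaussian fall-off with
SD `σ_opacity` beyond it, mixed over a Gaussian distribution of the
*perceived* surface location (`μ_surf`, `σ_surf`, from probe
localizations). The prediction for a matching trial is the posterior mode.

Assumptions worth keeping in mind:

- The mixture over surface positions treats the visibility fall-off as
  conditionally independent of where the surface is perceived on a given
  trial; the prior is an expectation over surface positions.
- The prior is deliberately left unnormalized (its value is 1 far in front
  of the surface). The posterior mode is invariant to prior scaling, and
  normalizing would add nothing but floating-point traffic.
- Retinal size is not a cue in the model; the size regimes
  (constant-angle vs. constant-physical) affect only stimulus geometry
  reporting, mirroring the finding that size mainly matters under the most
  extreme conflict.
- The surface-absent condition is modelled by a flat prior, equivalently by
  reading the prediction directly off the likelihood mean.

## Numerics

- **Grid**: 0.5–2.5 m at 1 mm steps (2001 points). All experimental
  distances (0.9–1.6 m) and every density's effective support are interior.
  Posterior-mode ties break toward the smaller distance (first argmax);
  they arise only in contrived flat configurations.
- **Prior construction**: surface positions whose normalized weight falls
  below 1e-14 of the peak are dropped from the mixture. The truncation
  error (< 1e-10 in prior values) is orders of magnitude below every
  tolerance used, and it makes prior construction cost scale with σ_surf
  rather than with the grid.
- **Closed-form check**: in the near-delta-surface limit the posterior mode
  is the precision-weighted mean `(x_surf/σ_opacity² + μ_disp/σ_disp²) /
  (1/σ_opacity² + 1/σ_disp²)` behind the surface and `μ_disp` in front. The
  grid implementation agrees to one grid step across a 216-point parameter
  sweep (tested).
- **σ_opacity fit**: sum of squared errors between per-distance mean
  matches and posterior-mode predictions, over all tested distances.
  In-front distances are insensitive to σ_opacity (the prior is flat
  there), so including them cannot bias the fit. The search is a 64-point
  log-spaced pre-scan of the bounds (default 0.001–2.0 m) followed by
  bounded scalar minimization in the bracket around the pre-scan minimum —
  derivative-free and deterministic, which matters because grid-quantized
  predictions make the objective piecewise constant. Exact objective ties
  resolve toward the larger (shallower) σ_opacity, so data exhibiting no
  occlusion conflict at all report the upper bound with a `pinned` flag
  rather than an arbitrary interior plateau point. A trial-level squared
  error objective (`objective="trials"`, the Gaussian MLE up to a constant)
  is available behind a flag; per-distance means are the default because
  they match the granularity at which the model makes predictions.
- **Moment estimators** use the n−1 denominator throughout and sort values
  before reducing, so results are exactly invariant to trial order.
  Cells with fewer than two trials are rejected, never imputed.

## Synthetic observers

The generator exists so every downstream stage is testable without human
data; its defaults are the study conditions of the constant-angle
experiment:

| parameter | default | meaning |
|---|---|---|
| target distances | 0.9–1.6 m, 0.1 m steps | tested letter distances |
| trials per distance | 10 | per condition |
| surface distance | 1.2 m | physical surface position |
| σ_disp | log-uniform 0.02–0.10 m, sorted increasing with distance | disparity uncertainty grows with viewing distance |
| μ_disp | the target distance | unbiased disparity |
| σ_surf | uniform 0.01–0.05 m per condition | surface localization noise |
| σ_opacity | opaque 0.08, semi-transparent 0.10, highly transparent 0.25 m | prior fall-off per opacity |
| σ_resp | 0.03 m | trial-level response noise |

Surface-present matches are the posterior-mode prediction plus
`N(0, σ_resp)`; response noise is this package's construct (a deterministic
responder would generate zero-variance cells), held constant across
distance because matching variability does not grow reliably with distance
in this paradigm. Surface-absent matches are drawn `N(μ_disp, σ_disp)`:
since σ_disp is *defined* as the SD of surface-absent matches, any other
choice would make the generator inconsistent with the fitting pipeline it
is meant to validate. Consequently, with σ_resp = 0 surface-present matches
equal the model predictions exactly while absent-condition matches retain
their sensory variability. Matches are clipped (not resampled) at the grid
bounds, which sit far from the data. Seeds: one master seed; child seeds
`master + 1000·(observer+1) + {1,2,3}` for parameters, trials, and
localizations, recorded in the dataset sidecar.

What the generator does *not* emulate: memory decay over the 1 s
presentation, motor dynamics of the adjustment, learning or order effects
across blocks (block order is metadata only), and any trial-to-trial
coupling between conditions. Passing tests therefore show that the pipeline
is self-consistent under the model's own assumptions — not that those
assumptions exhaust real observers.

## Parameter recovery

`recover_parameters` regenerates trial data from known observer parameters
and refits the *free* parameter σ_opacity per observer × condition, holding
the measured quantities (disparity and surface moments) at their generative
values. This isolates the identifiability of σ_opacity from matching
behaviour: noise-free recovery is exact to grid resolution, and at the
default noise level a 12-observer panel recovers all three condition values
with RMSE well inside 25% while preserving the opacity ordering.

Re-estimating the nuisance moments from 10-trial cells is a much harder
problem: the SD of a 10-sample SD is ~24% of its value, and for a shallow
prior (σ_opacity = 0.25 m) the mapping from predicted underestimation back
to σ_opacity is steep enough that this sampling noise alone produces
order-of-magnitude recovery errors. The full data-analysis path
(`fit_panel`) does re-estimate everything from data — that is its job — but
recovery diagnostics deliberately separate the free parameter from nuisance
estimation noise.

## Analysis conventions

- Within-subject CIs use Cousineau subject-mean normalization with the
  Morey `√(C/(C−1))` correction and a t-based interval; the defining
  property (invariance to subject-specific shifts) is tested.
- Segmented regressions split at the surface distance with the surface
  *included in the front segment* (distances ≤ 1.2 m); slopes are fit to
  per-distance means pooled over observers by default, with a per-observer
  variant behind a flag (fit per observer, slopes averaged).
- Signed differences are baseline-minus-condition, so underestimation is
  positive.

## Known limitations

- Predictions are only made at tested distances; per-distance σ_disp is not
  interpolated.
- σ_surf and σ_opacity are not jointly identifiable from matching data
  alone, which is why surface localizations are a required input for
  fitting.
- For shallow priors the σ_opacity objective is nearly flat; single-subject
  fits in that regime have a heavy-tailed error distribution, and the
  `pinned` flag should be checked before interpreting an individual value.
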