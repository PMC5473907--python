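# Methods

## Signal model

BOLD signal in placental tissue is modeled as arising from two blood
compartments: maternal blood in the intervillous space (volume fraction
V_M = 0.40, baseline oxygen saturation 0.80) and fetal capillary blood
(V_F = 0.10, baseline saturation 0.60). Neither compartment is saturated
at room air, so maternal hyperoxia lowers deoxyhemoglobin concentration
[dHb] in both, lowering R2* and raising the signal. The oxygenation
indicator is

    ΔR2*(t) = ln(S(t) / S_baseline) / TE = −r2* · (V_F·Δ[dHb_F](t) + V_M·Δ[dHb_M](t)),

in s⁻¹, signed to increase with oxygenation. The natural logarithm is
used: with it, the forward signal model S(t) = S₀·exp(TE·ΔR2*) and the
inverse are exact mutual inverses, which the test suite checks to machine
precision. TE stays in seconds; all time axes downstream of I/O are in
minutes.

## Oxygenation response and time-to-plateau

The regional response to the inspired-oxygen step is phenomenological: a
unit step (starting Δ minutes after hyperoxia onset, Δ ≥ 0 the oxygen
arrival delay) convolved with a gamma kernel of shape α ≥ 1 and scale
β ≥ 1 min. With the kernel normalized to unit area the convolution has
the closed form

    ΔR2*(s) = C1 + C2 · P(α, (s − Δ)/β),    s = minutes since hyperoxia onset,

with P the regularized lower incomplete gamma function. Evaluating the
convolution analytically rather than on a discrete grid makes C2 exactly
the plateau amplitude (identifiability) and keeps the model monotone
nondecreasing. Only one Δ-shift is applied (kernel in elapsed time, step
at Δ): a formulation that shifts both the kernel argument and the step by
Δ would apply the same delay twice with identical effect.

Time-to-plateau is TTP = Δ + τ. Two conventions for τ are implemented
and selectable in configuration:

- `as_printed` (default): τ = α·(β − 1);
- `standard_mode`: τ = (α − 1)·β, the mode of the gamma density.

Both are exposed because the field uses the gamma mode while published
TTP work also appears with the first form; no attempt is made to decide
which is "right" — the convention is part of the map's metadata.

All response timing (Δ, TTP) is measured from **hyperoxia onset**, not
from acquisition start. This is the only frame in which healthy placentas
can have "TTP near zero", and it makes TTP independent of the baseline
epoch length.

## Voxel-wise fitting

Each ΔR2* curve is fit by bounded nonlinear least squares over
(α, β, Δ, C1, C2), with defaults α ∈ [1, 20], β ∈ [1, 10] min,
Δ ∈ [0, hyperoxia duration − 1] min, C1 free, C2 ≥ 0. The fit window
defaults to the baseline + hyperoxia epochs, because the fitted step
never turns off; full-window fitting against a boxcar input is available
behind a flag. Initialization is a multi-start: a coarse (α, β, Δ) grid
whose step-response curves are precomputed once per map, with (C1, C2)
solved in closed form per grid point (C2 clipped at 0); the best few grid
points seed a trust-region reflective polish (tolerances 1e−12, at most
300 function evaluations per start). A fitted amplitude below
max(1e−6, 1e−3·sd(curve)) s⁻¹ marks the voxel degenerate: the fit is kept
but its TTP is undefined (NaN, `valid = False`). Optimizer failures are
flagged per voxel and never raised at map level.

Measured recovery behavior (reproduced by the test suite): noiseless
curves over a 27-point truth grid (α ∈ {1.5, 3, 6}, β ∈ {1.2, 2, 4},
Δ ∈ {0, 2, 5} min) are recovered with TTP error below 1e−8 min; at ΔR2*
noise sd 0.5 s⁻¹ and TR 6 s the median TTP error over the generator's
physiological truth range is just under 0.5 min — the residual scatter is
noise-intrinsic (fits initialized at the truth do no better), reflecting
the partial trade-off between Δ and the kernel shape.

## Preprocessing

- **Outlier frames**: the paper-level criterion "unexpected average signal
  change of nearby frames" is formalized as the residual of each frame's
  masked mean against the median of its ±2 temporal neighbors,
  standardized by 1.4826·MAD; frames with robust z > 3 are flagged
  (threshold and neighborhood configurable). Flagged frames are dropped
  and the gap linearly interpolated; both counts are recorded.
- **Spatial smoothing**: separable discrete Gaussian, width 5 pixels,
  σ = 1.5, kernel normalized to unit sum, with renormalization by the
  smoothed support indicator at volume (and optional mask) edges so
  constant signal is preserved.
- **Temporal smoothing**: linear interpolation onto a uniform grid
  (default step: the median TR) followed by a centered moving average of
  10 frames — the middle of the 8–12-frame (~1 min) window; edge frames
  use truncated windows.
- **Baseline**: voxel-wise mean of unflagged frames in the first 10-minute
  normoxic epoch; fewer than 3 usable frames is an error.

Registration and bias-field correction are out of scope: the pipeline
contract states that input is motion-corrected, and the generator emits
motion-free data.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: 10/10/10-minute
paradigm, TR 6 s, TE 35 ms; placental plateau amplitudes 9.83 ± 4.49 s⁻¹
(healthy/AGA) vs 6.55 ± 3.30 s⁻¹ (pathological/SGA); rise slopes at
hyperoxia onset 1.89 vs 0.88 s⁻¹/min; organ amplitude ratio
placenta:liver:brain = 6:3:1; 7 twin pairs, each pair sharing a mother
identifier.

**Post-hyperoxia return.** The rise model never turns oxygen off, so the
return to baseline is a modeling choice: a mirrored gamma decay with its
own shape/scale, anchored at hyperoxia offset with the same arrival
delay, decaying toward a configurable asymptote. SGA organ curves use a
fast decay (β_decay = 2 min) with a negative asymptote (−15% of plateau),
emulating the reported end-of-post undershoot in growth-restricted
fetuses; AGA organs decay slowly (β_decay = 8 min); placentas mirror
moderately (β_decay = 4 min).

**Operational slope definition.** The gamma model's analytic derivative
at hyperoxia onset is 0 for α > 1 and one-sided for α = 1, while group
rise slopes are measured as the B-spline derivative at onset. To make the
generated and measured quantity commensurable, a subject's slope is
*defined* as that spline functional applied to its noiseless curve: the
generator draws (amplitude, slope) per subject and solves the kernel
scale β (α = 1, Δ = 0 exponential-saturation kinetics) by bisection so
the noiseless curve hits both the drawn plateau amplitude (last-2-minute
mean of hyperoxia) and the drawn slope. Pairs that are kinetically
infeasible within β ≥ 1 are rejection-sampled. A by-product is that the
implied group TTPs (≈1.6 min AGA, ≈2.7 min SGA at the default means)
fall in the physiologically observed range.

**Chosen, not derived:** between-subject slope sd (0.4 s⁻¹/min) and
curve measurement noise (0.5 s⁻¹ per sample) are not published
quantities; they were set once to be consistent with tight group bands
relative to amplitude and with ROI-mean noise at this field strength.
Birth weight is intercept − slope·TTP plus a pair-shared random intercept
(defaults 2600 g, 250 g/min, sd 150 g) plus residual noise (sd 100 g) —
this encodes the negative TTP–weight association for recovery testing
without claiming a real-world effect size. Noise is additive Gaussian on
magnitude intensities (a Rician option exists); at the SNR of interest
the Gaussian approximation holds and keeps oracles analytic.

**Phantoms** are an ellipsoidal placenta (split into twin territories at
the midline) plus two small organ blobs on a voxel grid of at least 8 per
axis. The TTP field is uniform, cotyledon-like (distance-to-lobule-center
field, short TTP at lobule centers), or uniform with a contiguous patch
delayed by a configurable offset. Voxel truth uses α = 2 with the TTP
split evenly between arrival delay and kernel mode. The phantoms contain
no motion, B0/B1 artifacts, anastomoses, or realistic anatomy; passing
tests therefore demonstrate correctness of the estimation pipeline under
its stated contract (motion-corrected, bias-corrected input), not
robustness to acquisition artifacts.

## Statistics

- **Friedman rank-sum** over n_pairs × k blocks, mid-ranks for ties,
  χ² = 12/(n·k·(k+1))·ΣRⱼ² − 3n(k+1), k − 1 df. Implemented directly
  (the classic statistic, no tie-correction factor); cross-checked
  against an independent library implementation on tie-free data.
- **Pair-resampled Spearman**: per replicate one twin per pair is drawn
  uniformly; Spearman r and p are computed across the selected fetuses;
  1000 replicates by default. The reported p is that of the replicate
  attaining the median r (keeping r and p from the same resample); the
  median of p is also reported. Degenerate replicates (constant x or y)
  are excluded and counted.
- **Mixed models**: random intercept per mother, REML estimation, Wald
  tests, via statsmodels MixedLM. Constraining the random-intercept
  variance to zero reduces exactly to OLS. Rank-deficient designs raise
  a collinearity error naming the offending columns.
- **Functional comparison**: subject curves are least-squares-projected
  onto a cubic B-spline basis with knots every 2 minutes (the same basis
  used for slope estimation); group mean and sd functions are evaluated
  densely with pointwise Welch t and two-sided p. Welch (unequal
  variance) is used for all group comparisons. No multiple-testing
  correction is applied anywhere; all p-values are raw and labeled as
  such.

## Outcome metrics

The 4-point histopathology score counts minor (m) and moderate (M)
findings: empty or m = 1 → 1; m = 2 or M = 1 → 2; m = 1 and M = 1 → 3;
m ≥ 3, M ≥ 2 or any finding listed severe → 4. The published scale
assigns "three minor findings" to both 3 and 4; this implementation
resolves the overlap (and any unprinted combination) by the maximum of
all applicable rules, which also makes the score monotone — adding a
finding never lowers it. SGA is birth weight ≤ 10th percentile (the
percentile is an input; no growth chart is bundled). Birth-weight
discordance is |w_A − w_B| / max(w_A, w_B).

## Numerical and design notes

- Problem sizes in the test suite (12³–32×32×8 phantoms, 200-voxel noise
  batches, 50 cohort replicates) were chosen as the smallest sizes at
  which the targeted contrasts are statistically resolvable.
- Seeded `numpy.random.Generator` streams are threaded through every
  stochastic operation; identical seeds give bitwise-identical outputs,
  including CLI artifacts.
- NIfTI-1 is the volume format (float64 for series and maps, int32 for
  labels) with JSON sidecars for TR/TE and ROI role dictionaries; CSV for
  tables; YAML for configuration. Masks must share the BOLD grid; no
  resampling is implemented.
- Degenerate inputs (empty masks, all-flagged baselines, single-subject
  groups, constant resamples) raise typed validation errors at the API
  boundary, except inside voxel-wise map fitting, where per-voxel failure
  is recorded in the validity mask.

## Known limitations

- The gamma-step model assumes a monotone response during hyperoxia;
  true biphasic or non-stationary responses would bias TTP.
- TTP precision at realistic noise is ~0.5 min per voxel; within-ROI
  averaging is required for subject-level comparisons.
- The pair-resampled Spearman p-value convention ("the p associated with
  the median correlation") is ambiguous in the field; both conventions
  reported here are approximations to an unspecified original.
- The synthetic cohort's covariate structure (percentiles, Doppler
  grades, organ volumes) is simple and monotone by construction; it
  validates plumbing and statistical machinery, not clinical effect
  sizes.
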