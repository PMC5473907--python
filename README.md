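# placentabold

Quantitative analysis of placental function from BOLD MRI acquired under a
maternal hyperoxia paradigm, aimed at researchers studying placental
insufficiency — in particular in monochorionic (monozygotic) twin
pregnancies, where the co-twins are naturally matched for genetic growth
potential and discordant growth points at discordant placental function.

During the paradigm the mother breathes room air (FiO2 0.21), then 100%
oxygen, then room air again, in three 10-minute epochs, while a 4-D BOLD
series of the uterus is acquired (TR 5–8 s, TE 32–38 ms). As maternal and
fetal deoxyhemoglobin fall, the effective transverse relaxation rate R2*
falls and the BOLD signal rises. The package turns that series into maps
and statistics in four stages:

1. **Preprocessing** (`placentabold.preprocess`): outlier-frame detection
   (robust z of each frame's masked mean against its temporal
   neighborhood), Gaussian spatial smoothing (5-pixel kernel, σ = 1.5),
   temporal interpolation with a ~1-minute moving-average window, and a
   voxel-wise baseline over the first normoxic epoch.
2. **ΔR2\* mapping** (`placentabold.bold_signal`):
   ΔR2\*(t) = ln(S(t)/S_baseline)/TE, in s⁻¹, signed so it increases with
   oxygenation, plus ROI time-activity curves with slope and amplitude
   summaries.
3. **Time-to-plateau fitting** (`placentabold.ttp_fit`): each ΔR2\* curve
   is fit by least squares to a step input convolved with a gamma kernel,

       ΔR2*(s) = C1 + C2 · P(α, (s − Δ)/β),

   where s is minutes since hyperoxia onset, P the regularized lower
   incomplete gamma function, Δ the oxygen arrival delay and C2 the
   plateau amplitude. Time-to-plateau is TTP = Δ + τ with τ = α·(β − 1)
   (an alternative convention τ = (α − 1)·β, the standard gamma-density
   mode, is available via configuration). Voxel-wise fits yield TTP maps
   with validity flags, histograms and ROI summaries.
4. **Twin statistics and outcomes** (`placentabold.twin_stats`,
   `placentabold.outcomes`): Friedman rank-sum over twin-pair blocks,
   pair-resampled Spearman correlation (one twin per pair per replicate,
   median r over 1000 replicates), linear mixed models with the mother as
   a random intercept, functional-data group-curve comparison on a cubic
   B-spline basis with 2-minute knots, the 4-point histopathology score,
   SGA classification (≤ 10th percentile) and birth-weight discordance.

A synthetic module (`placentabold.synthetic`) generates phantoms and twin
cohorts with known ground truth — two-compartment placental blood dynamics
(maternal volume fraction 0.40 at baseline saturation 0.80; fetal 0.10 at
0.60), cotyledon-like spatial TTP structure, and AGA/SGA group differences
in amplitude and rise slope — so every stage is testable without patient
data.

## Worked example

```python
import numpy as np
from placentabold import OxygenParadigm, VoxelTruth, fit_voxel, generate_cohort, CohortSpec
from placentabold.synthetic import delta_r2star_model
from placentabold import twin_stats

paradigm = OxygenParadigm()                       # 10/10/10 min, FiO2 0.21 -> 1.0
t = np.arange(0.0, 30.0001, 0.1)                  # TR = 6 s acquisition grid

rng = np.random.default_rng(0)
truth = VoxelTruth(alpha=2.0, beta=2.0, delta=1.0, c2=9.83)
curve = delta_r2star_model(truth, t, paradigm) + rng.normal(0.0, 0.5, t.shape)
fit = fit_voxel(curve, t, paradigm)
print(f"true TTP  = {truth.ttp_true:.2f} min")
print(f"fitted TTP = {fit.ttp:.2f} min")

cohort = generate_cohort(CohortSpec(n_pairs=7), paradigm, seed=1)
res = twin_stats.group_difference_at(
    cohort.curve_set("placenta"), "slope@t", t=paradigm.hyperoxia_start)
print(f"rise slope at 10 min: AGA {res['means']['AGA']:.2f}, "
      f"SGA {res['means']['SGA']:.2f} s^-1/min (Welch p = {res['p']:.4f})")

sp = twin_stats.pair_resampled_spearman(
    cohort.records, "ttp_true", "birth_weight", reps=1000, seed=1)
print(f"Spearman TTP vs birth weight: median r = {sp['median_r']:.2f}")
```

prints

```
true TTP  = 3.00 min
fitted TTP = 2.53 min
rise slope at 10 min: AGA 1.90, SGA 0.94 s^-1/min (Welch p = 0.0000)
Spearman TTP vs birth weight: median r = -0.96
```

The fitted TTP recovers the generating 3-minute delay-plus-mode to within
the noise-limited precision (~0.5 min at ΔR2* noise sd 0.5 s⁻¹); the
cohort, generated at the AGA/SGA rise slopes of 1.89 vs 0.88 s⁻¹/min,
yields group slope estimates near those values with a strongly significant
Welch test; and birth weight, generated to fall with true TTP, shows the
expected strong negative pair-adjusted Spearman correlation.

The same stages are available from a shell:

```sh
placentabold simulate --seed 1 --out run/sim --shape 32 32 8 --mode pathological_patch
placentabold preprocess --series run/sim/bold.nii --mask run/sim/mask.nii --out run/pre
placentabold dr2s --series run/sim/bold.nii --baseline run/pre/baseline.nii --out run/d
placentabold fit-ttp --dr2s run/d --mask run/sim/mask.nii --role placenta_twinA --out run/fit
placentabold cohort-stats --cohort run/sim/cohort.csv --out run/stats
```

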