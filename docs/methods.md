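# Methods

## Model and assumptions

Whole-blood transverse relaxation is modelled as the sum of an intrinsic
rate 1/T2O and a chemical-exchange term driven by the frequency offset
between erythrocyte and plasma water protons, α·ω₀·(1 − %SbO₂/100):

    1/T2b = 1/T2O + Hct(1−Hct)·τ_ex·[(1 − %SbO₂/100)·α·ω₀]²
            · [1 − (2τ_ex/τ₁₈₀)·tanh(τ₁₈₀/(2τ_ex))]

Assumptions inherited from this parameterization:

- the exchange-site fraction equals the hematocrit (not 0.9·Hct; a config
  option `pa_scale` is deliberately *not* exposed — the 0.9 convention can
  be emulated by passing a rescaled hematocrit if ever needed);
- two-site exchange with a single exchange time; multi-compartment
  extensions are out of scope;
- the nuisance parameters (T2O, τ_ex, α) are subject-level constants, not
  per-stage quantities;
- field strength enters only through ω₀ (default 4×10⁸ rad/s, i.e. 1.5 T).

Units: every public interface uses ms, percent, ppm and rad/s; conversion
to SI happens once inside the model functions. α enters as
`alpha_ppm × 1e-6 × ω₀`. The τ_ex → 0 attenuation limit returns exactly 1
rather than dividing by zero. Saturations outside [0, 100]% raise instead
of clipping, so optimizer pathologies surface rather than hide.

## Estimation

One sample is eight T2 values (venous and arterial pools at τ₁₈₀ =
12/15/20/25 ms) plus the hematocrit and a reference arterial saturation.
Four strategies:

1. **precalibrated** — closed form on one τ₁₈₀ (default 12 ms): invert the
   simplified model for T2O from the arterial pool at the known arterial
   saturation, then solve the venous saturation from the venous T2 with a
   global K (default 25 s⁻¹). A venous T2 above the implied ceiling
   (negative radicand) returns a non-converged result.
2. **unconstrained** — joint NLLS over all eight T2s with {SvO₂, T2O,
   τ_ex, α} free; only non-negativity bounds. Defaults to 5 jittered
   restarts keeping the lowest residual, because the unbounded loss surface
   has local minima and near-flat directions (T2O can run away by orders of
   magnitude).
3. **fixed** — joint NLLS with the nuisance triple pinned to learned
   values (defaults 350 ms / 1.5 ms / 0.92 ppm); only SvO₂ free.
4. **constrained** (the proposed method) — joint NLLS with learned bounds:
   SvO₂ init 0.8 on [0, 1], T2O init 300 ms on [200, 400], τ_ex init 3 ms
   on [0, 6], α init 0.545 ppm on [0.52, 0.57].

Numerical choices: residuals are (measured − model) T2 in ms, unweighted —
the noise is observed on the T2 maps, and T2-space residuals keep the
venous and arterial contributions commensurate; an R2-space option exists
for sensitivity checks. Arterial residuals are always included (all eight
measurements), in every joint mode, for uniformity. The optimizer is
scipy's trust-region-reflective bounded least squares with
ftol = xtol = gtol = 1e-12 and a 500·n evaluation cap; the problems are
four-dimensional, so tight tolerances are free. Saturation is a fraction
internally and percent at interfaces. A bound is reported "active" when
the estimate lies within 1e-6 (parameter units) of it. T2O is floored at
1e-3 ms inside the objective so the unconstrained lower bound of zero
cannot produce a division by zero.

## Learning fixed values and bounds

With training samples whose venous saturation is known from blood-gas
analysis, exhaustive grid search picks the fixed nuisance triple (or the
bounds triple) minimizing the mean absolute venous-saturation error of the
corresponding fit. The search is a joint product grid (small candidate
lists per parameter — the default grid spans literature ranges for whole
blood: T2O 154–372 ms, τ_ex 0.6–12 ms, α 0.1–1.4 ppm); exhaustiveness makes
the search its own oracle. Ties break toward the least restrictive option:
widest bounds, or the fixed triple closest to the defaults
(300 ms / 3 ms / 0.545 ppm) in normalized distance. Only a single
train/test split is supported; cross-validation is out of scope.

## T2 mapping

T2-prepared stacks decay as S(T2p) = S0·exp(−T2p/T2) with T2p = (number of
refocusing pulses)·τ₁₈₀. The per-pixel fit is a two-parameter nonlinear
least squares initialized by a log-linear fit over strictly positive
samples (log-linear alone is noise-biased; the nonlinear refinement is
exact on noiseless data to <1e-6 relative). No constant-offset term.
Constant or growing signals are flagged invalid. Shipped schedules:
{0,24,48,96,144} ms for τ₁₈₀ = 12; {0,30,60,90,180} for 15;
{0,40,80,160} for 20; {0,50,100,200} for 25. The 15 ms list is shipped as
printed in the acquisition design even though the stated pulse counts
(0,2,4,8,12) would give {0,30,60,120,180}; that alternative is available as
`PULSE_COUNT_SCHEDULE_15` and no intent is guessed.

## Synthetic experiments

The generator emulates a graded-hypoxemia validation study: per subject,
hematocrit ~ N(0.25, 0.03) truncated to [0.15, 0.45] and nuisance
parameters drawn around T2O = 300 ms (sd 25), τ_ex = 3 ms (sd 0.5),
α = 0.545 ppm (sd 0.01), all truncated to physical ranges; per stage,
arterial saturation stepped 100 → 70% with the venous pool trailing by a
uniform 15–35 pp extraction gap (this spans the observed venous range of
roughly 45–87%; no circulatory model is attempted). Blood T2 is the full
forward model plus Gaussian noise (default σ = 3 ms, homoscedastic; a
heteroscedastic option grows σ linearly with τ₁₈₀ to mimic flow-dependent
dephasing in long refocusing intervals). Duplicate blood-gas readings are
simulated as truth·(1 + cv·z) with cv = 0.026, and the analysis reference
is the replicate mean. Stages with true venous saturation below 40% are
flagged excluded, mirroring how severely hypoxemic stages are dropped for
image-quality reasons. Everything is reproducible from the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: motion and flow artifacts, partial-volume and
ROI-drawing variability, within-stage saturation drift correlated between
pools (drift is independent here), Rician magnitude noise at low SNR, and
any physiological coupling between hematocrit, cardiac output and
saturation.

## Agreement statistics

Estimator vs reference saturation is summarized by OLS regression (slope
t-test p-value), Bland–Altman bias with 95% limits of agreement
(bias ± 1.96·SD), a t-based CI for the bias (t rather than normal
quantiles, n is small), a one-sample t-test of the bias, and a
proportional-bias regression of differences on pairwise means (the
standard Bland–Altman regressor). RMSE is the root-mean-square paired
difference. Reference reproducibility uses the duplicate-measurement CoV:
root-mean-square within-pair SD over the grand mean. Data points are
pooled across subjects by default (between-subject variability is treated
as non-significant); per-subject grouping can be applied upstream by
filtering the tables.

## Problem sizes and checks

The simulation-based acceptance checks use 200 synthetic stages
(40 subjects × 5 stages) at σ = 3 ms — large enough that the qualitative
error ordering RMSE(constrained) < RMSE(precalibrated) < RMSE(unconstrained)
and a constrained-fit regression slope in [0.8, 1.05] are stable across
seeds, while the full battery completes in about a minute. Noiseless
identifiability is checked on a 20-point truth grid (5 saturations × 4
nuisance triples strictly inside the default bounds): SvO₂ recovered to
<0.5 pp and nuisance parameters to <5% relative. The long-τ₁₈₀ limit
equivalence of the full and simplified models is verified at τ₁₈₀ = 10⁹ ms,
where the residual gap K·2τ_ex/τ₁₈₀ falls below 10⁻⁶ s⁻¹ (at 10⁶ ms it is
still ~10⁻⁴ s⁻¹ — the limit is slow, of order 1/τ₁₈₀).

## Known limitations

- The constrained fit's accuracy depends on the truth lying inside the
  learned bounds; truths outside produce active bounds and bias (reported
  via `active_bounds`).
- The precalibrated route fails outright when noise pushes the venous T2
  above the arterial-implied ceiling; such samples are flagged, not
  imputed.
- The exhaustive search scales as the product of candidate-list lengths;
  it is intended for coarse grids (≤5 candidates per parameter) with
  optional refinement, not for fine joint grids.
- No motion correction, k-space/bSSFP signal simulation, DICOM ingestion
  or scanner integration.
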