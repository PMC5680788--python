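# t2oximetry

Non-invasive blood oximetry from cardiovascular MR T2 relaxometry.

Blood oxygen saturation in the cardiac chambers and great vessels is a key
biomarker in congenital heart disease, heart failure and pulmonary
hypertension, but measuring it normally requires invasive catheterization.
Because deoxyhemoglobin is paramagnetic, the transverse relaxation time T2
of whole blood depends on its oxygen saturation — and, through chemical
exchange of water protons between erythrocytes and plasma, on the
inter-echo spacing τ₁₈₀ of the refocusing train used to measure it. This
package implements a patient-specific oximetry method built on that
dependence, for researchers working with quantitative T2-prepared CMR.

## The model

The Luz–Meiboom exchange model relates the apparent relaxation rate of
blood to its saturation %SbO₂:

    1/T2b = 1/T2O + Hct(1−Hct) · τ_ex · [(1 − %SbO₂/100) · α·ω₀]²
            · [1 − (2τ_ex/τ₁₈₀) · tanh(τ₁₈₀/(2τ_ex))]

where T2O is the T2 of fully oxygenated blood, τ_ex the
erythrocyte–plasma proton exchange time, α (ppm) a
susceptibility/cell-geometry factor, ω₀ the proton resonance frequency and
Hct the hematocrit (taken equal to the exchange-site fraction). Holding the
acquisition fixed collapses the exchange term into a single calibration
constant K, giving the classical simplified model
`1/T2b = 1/T2O + K(1 − %SbO₂/100)²`, which is analytically invertible.

A single T2 measurement cannot separate saturation from the three
subject-specific "nuisance" parameters (T2O, τ_ex, α). The method here
acquires four T2 maps at τ₁₈₀ = 12/15/20/25 ms, reads venous and arterial
blood T2 from each (eight measurements), and — with the hematocrit and the
arterial saturation known — jointly estimates venous saturation and the
nuisance parameters by bound-constrained nonlinear least squares, the
bounds having been learned from training data. Three comparison strategies
are included: a global-K pre-calibrated closed form, a fully unconstrained
joint fit, and a joint fit with the nuisance parameters pinned to learned
values.

## Worked example

```sh
python examples/worked_calibration.py
```

```
K = 25.0 s^-1 (normal Hct calibration): SvO2 = 63.5%
K = 18.94 s^-1 (rescaled to Hct 0.25):   SvO2 = 58.0%
```

A venous T2 of 150 ms with T2O = 300 ms and a global K of 25 s⁻¹ implies a
saturation near 64%; rescaling K by the Hct(1−Hct) ratio for an anemic
hematocrit of 0.25 lowers the answer to 58% — the same measurement means a
different saturation in anemic blood, which is exactly the failure mode of
global calibration that the joint fit avoids.

The end-to-end comparison on a synthetic graded-hypoxemia experiment
(`python examples/simulate_and_fit.py`, 7 subjects × 5 stages, 3 ms T2
noise):

```
 precalibrated: RMSE =   8.6 pp  (n = 34)
 unconstrained: RMSE =  21.7 pp  (n = 34)
         fixed: RMSE =   8.6 pp  (n = 34)
   constrained: RMSE =   1.4 pp  (n = 34)

constrained vs truth: y = 0.98x + 0.65, R^2 = 0.98
```

RMSE is the root-mean-square error of estimated venous saturation against
the generating truth in percentage points; the constrained joint fit is an
order of magnitude more accurate than global calibration, and the
unconstrained fit illustrates why bounds are needed.

Other examples: `examples/t2_map_phantom.py` (pixel-wise mono-exponential
T2 mapping of a two-compartment phantom) and
`examples/train_nuisance_bounds.py` (exhaustive-search learning of nuisance
values and bounds). A thin CLI mirrors the workflow:

```sh
t2ox simulate --subjects 7 --stages 5 --seed 1 --out-samples s.csv --out-truth t.csv
t2ox fit --samples s.csv --mode constrained --out fit.csv
t2ox evaluate --results fit.csv --truth t.csv --out report.csv
```

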