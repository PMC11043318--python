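# Methods

## Model structure and assumptions

The kinetic model is a lumped five-compartment system — central blood,
salivary glands, kidneys, tumor (all segmented lesions as one pool) and a
combined remaining-tissue compartment — with first-order transfer everywhere
except the salivary glands, whose uptake saturates with a maximum binding
capacity B_MAX (a proxy for receptor capacity). Renal excretion (k10) from
the central compartment is the only biological elimination route; no
sub-organ compartmentalization or whole-body compartment is modelled, and no
absorbed-dose (Gy) conversion is attempted. Boluses are instantaneous.

Because quantitative SPECT data are conventionally decay-corrected to the
injection time, the transfer rate constants describe decay-corrected
(biological) kinetics. The engine's canonical internal mode applies ¹⁷⁷Lu
physical decay (λ = ln 2 / 159.528 h, half-life 6.647 d, nuclide reference
data) uniformly to all five activity compartments on top of those rates.
For a linear system this is exactly equivalent to decay-correcting each
dose's contribution to its own injection time, so the mode is unambiguous
for overlapping cycles; a conversion layer regenerates per-cycle
decay-corrected observations for dataset emulation and fitting. The PSA
model is driven by the *physical* tumor activity concentration
C_tumor = A_tumor/TV (decay included), which is also the quantity integrated
into the tumor time-integrated activity (MBq·h/mL), the dosimetric
convention.

PSA dynamics are multiplicative: exponential growth k_G minus a direct kill
term k_D,direct·C_tumor and a delayed kill term k_D,delay·Ce, where Ce is an
effect-compartment level equilibrating with C_tumor at ke0. Ce starts at 0,
is inert until the first administration (no drug effect without treatment)
and keeps decaying via ke0 between treatment series, which produces the
continued post-treatment PSA decline. Coupling is sequential: PK states
drive PSA, never the reverse. The final model uses linear forms for both
effects; Emax and sigmoid-Emax direct-effect forms are selectable
alternatives that were evaluated during model development but not retained.

## Parameters

Defaults are shipped in `src/lupsma/data/defaults.yaml` (overridable via
layered YAML/JSON configs). Key values, with units as conventionally
printed:

- rates (h⁻¹): k10 0.253, k12 0.0105, k21 0.0629, k13 0.0321, k31 0.0625,
  k14 0.00967, k41 0.0150, k15 0.275, k51 0.0247; V1 10.3 L (fixed);
  B_MAX 134 MBq. Half-lives implied: ln2/k41 ≈ 46 h (tumor),
  ln2/k21 ≈ 11 h (salivary); renal clearance k10·V1 = 2.61 L/h.
- covariates: tumor volume power 1.08 on k14 and 0.0910 on k12 (medians
  TV 0.0443 L, WT 79 kg); allometric exponents −0.25 (rates) and 1 (V1);
  cycle fractions on k14: 0.731 / 0.498 / 0.436 for cycles 2 / 3 / 4–7.
  Cycles beyond 7 reuse the 4–7 fraction with a logged warning. The
  salivary-gland cycle effect (84.6% cycle 2, 98.1% cycle 3) is not part of
  the final model and ships as an off-by-default scenario flag.
- PD: baseline PSA 140 µg/L (fixed) + 57.5 µg/L linear tumor-volume term;
  k_G 0.000408 h⁻¹; k_D,direct 0.00335 L·day⁻¹·GBq⁻¹; ke0 0.00128 h⁻¹;
  k_D,delay 3.28·10⁻⁵ L·day⁻¹·MBq⁻¹; box-cox shape −0.822.
- variability (CV%): IIV 33.1 (k10), 33.4 (k13), 63.4 (k14), 29.1 (k15),
  67.0 (B_MAX), 179 (PSA0), 90.9 (k_G), 140 (k_D,direct), 87.5 (k_D,delay);
  IOV 37.8 on k14 per cycle. Residual errors: central combined
  55.5% + 9.57 MBq/L; salivary 39.7%, kidneys 31.9%, tumor 32.7%,
  PSA 29.3% proportional.

Unit normalization: the kill coefficients are stored exactly as printed and
converted internally so that kD·C_tumor (MBq/L) yields h⁻¹ —
k_D,direct × 1/(24·1000), k_D,delay × 1/24. The asymmetric printed units
(GBq⁻¹ vs MBq⁻¹) are preserved verbatim in the config to avoid silent
reinterpretation. A source inconsistency is worth noting: the direct kill
coefficient appears once as 0.000335 and once as 0.00335 with a confidence
interval consistent only with the latter; 0.00335 is the default.

CV%→ω uses the common reporting approximation ω = CV/100; the exact
lognormal alternative ω = √ln(1+CV²) sits behind a config flag
(`flags.cv_to_omega`). For the very large PD CVs the two differ materially
in the tails. The box-cox transform of the k_G random effect is
η* = ((e^η)^θ − 1)/θ (identity as θ→0); with θ = −0.822 it bounds the
individual growth multiplier above by e^{1/0.822} and skews it downward.
No η correlations are modelled (none reported). The baseline-PSA
tumor-volume covariate is applied literally as PSA0 + θ·(TV/TV_median)
(giving 197.5 µg/L at the median volume); a centered variant
PSA0 + θ·(TV/TV_median − 1) is available behind
`flags.baseline_psa_covariate` since the fixed 140 µg/L is described as the
population's typical baseline. The choice cancels exactly in percent-change
endpoints. B_MAX is left out of allometric weight scaling: it is a receptor
amount, neither a volume nor a rate, and no exponent is defined for it.

## Virtual population and trial simulation

Body weight and tumor volume are drawn independently from truncated
lognormal distributions with medians 79 kg and 0.0443 L; the lognormal σ is
set so the untruncated central 99% interval spans (on average in log space)
the observed ranges 61–116 kg and 0.000122–0.546 L, and draws are truncated
to those ranges. Truncating the heavy upper tumor-volume tail pulls the
realized TV median ≈10% below the target; WT is essentially unaffected.
Random effects and per-cycle IOV attach per subject.

Regimens: '4 × 6' is 7400 MBq at weeks 0, 6, 12, 18; '2 × 2 repeated' is
7400 MBq at weeks 0, 2, 12, 14 (the second two-cycle series starting twelve
weeks after the first). Both use a 24-week horizon, i.e. six and ten weeks
after the respective last cycles. All simulated subjects complete the full
regimen — no response-adaptive dropping. Endpoints at 24 weeks on the
noise-free individual prediction: response ⇔ PSA ≤ 0.5 × baseline
(inclusive), stable ⇔ PSA ≤ baseline; residual error is a dataset-emulation
feature only. The VPC summary is a plain simulation band (per-time median
and 10th/90th percentiles with bootstrap 95% CIs), not a
prediction-corrected VPC.

What the generator emulates — per-cycle scan times 4.6 ± 0.95 h,
23.8 ± 4.5 h, 163.2 ± 11.0 h; per-compartment residual noise; the
SPECT-blood correction chain (intercept 6.27 MBq/L, slope 0.828) whose
inversion yields negative early blood values that the study filter drops;
PSA draws every four weeks plus one pre-treatment baseline — and what it
does not: image-reconstruction artifacts, per-lesion heterogeneity,
inter-covariate correlation, real dropout patterns. Passing recovery tests
therefore demonstrates generator/engine self-consistency (no inverse
crime broken), not fidelity to any real cohort.

On the simulated response rates: with these study conditions the n = 2000
comparison yields ≈45/46% stable disease and ≈30% response for the two
schedules — the regimen *difference* is small, as in the source analysis,
but the absolute rates sit some ten percentage points below the published
simulated rates (54.8/56.4% stable, 42.4/44.7% response). A scalar
sensitivity analysis on the analytic log-kill identity (see below) shows the
published rates correspond to a ≈1.4× larger typical exposure·kill product
than the typical parameter set produces here; the typical subject's
first-two-cycle tumor AUC (≈477 MBq·h/mL) is likewise ≈1.4× below the
exposure implied by the published response threshold (709.5 MBq·h/mL at
≈45% response). The most likely sources are the unreported joint covariate /
individual-exposure distribution of the source cohort, or a decay-corrected
(rather than physical) tumor concentration driving the published PSA model.
We keep the physical convention, which the source states explicitly, and do
not rescale any parameter.

## Numerical choices

- Integration: LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8,
  atol 1e-10 MBq, restarted at every dose event (A1 jumps by the dose; all
  other states continuous; per-cycle parameters switch at events).
- The analytic identity
  log PSA(T) = log PSA(0) + k_G·T − k_D,direct·AUC_C(T) − k_D,delay·AUC_Ce(T)
  holds for the linear-effect model and is verified numerically, as is area
  preservation AUC_Ce → AUC_C on long horizons (first-order filter).
- Tumor AUC uses trapezoidal quadrature on the trajectory grid with window
  endpoints inserted; the "first two cycles" exposure window defaults to
  [first dose, +12 weeks] for both regimens (configurable), which covers
  wash-out of cycles 1–2 before any third exposure.
- Estimation: naive-pooled fitting is weighted least squares
  (Levenberg–Marquardt on log-transformed parameters, weights from the
  residual-error models at the starting predictions); MAP estimation
  minimizes −2 log L + Σ η²/ω² by Nelder–Mead with three starts. Full
  nonlinear mixed-effects estimation (FOCE-I) and SIR uncertainty are
  deliberately out of scope; the estimation surface validates the model
  equations (inverse-crime recovery within 1%) and supports
  Bayesian-forecasting use.
- Endpoint ties are inclusive (PSA exactly half of baseline counts as
  response; exactly baseline counts as stable). Degenerate inputs —
  zero tumor volume, nonpositive B_MAX, nonincreasing dose times, constant
  AUC in the exposure regression, nonnegative slope in the threshold
  inversion — raise errors rather than returning silently wrong numbers.
- Problem sizes: the regimen comparison uses n = 2000 subjects per arm
  (Monte-Carlo SE of a rate ≈1.1 pp); recovery checks use 3–20 noise-free
  subjects, which is sufficient because the fits are deterministic.

## Known limitations

- The exposure–response thresholds published for the clinical cohort
  (709.5 and 1188 MBq·h/mL) require patient data and are carried as
  documented reference constants only; the threshold *procedure* is
  implemented and exercised on synthetic cohorts.
- Parameter uncertainty (RSE/CI) is not propagated; simulations condition
  on point estimates.
- The cycle-effect estimates mostly reflect the two-week-interval schedule
  that dominated the source cohort; applying them unchanged to the '4 × 6'
  arm is an extrapolation inherited from the source analysis.
- PSA-flare dynamics, treatment-dependent growth-rate changes and
  resistance over time are not modelled (evaluated and not retained in the
  source analysis).
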