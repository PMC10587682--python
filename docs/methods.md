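# Methods

This note records the modelling conventions, equations, and numerical
choices behind `vpapk`, in the order the pipeline uses them.

## 1. Data model and conventions

A subject record holds covariates, dose events and trough observations.
Datasets use a NONMEM-style CSV (`ID, TIME, EVID, AMT, DV, MDV, II, SS,
TAD`, plus covariate columns); a steady-state dose row (`SS=1`) with
interdose interval `II` encodes the whole maintenance regimen.
Concentrations are total plasma VPA in mg/L, times in hours, ages in
years, weights in kg, albumin in g/L, daily doses in mg/day (with
mg/kg/day derived and consistency-checked). Postmenstrual age, needed
by one maturation model, is derived as `age·365.25/7 + 40` weeks
(term-birth assumption) when not supplied, and flagged as derived.
Values below the quantification limit are flagged, never dropped.
Plausibility validation (default pediatric bounds: age 0.17–15 y,
weight 4–70 kg, albumin 25–75 g/L, dose 5–60 mg/kg/day) reports
violations without mutating data.

## 2. Structural pharmacokinetics

All library models except one are one-compartment with first-order
absorption. At steady state with maintenance dose D every τ hours,

    C(t) = (D·ka) / (V·(ka−ke)) · [ e^(−ke·t)/(1−e^(−ke·τ))
                                   − e^(−ka·t)/(1−e^(−ka·τ)) ],

with `ke = CL/V` and `t` the time after dose (lag times wrap `t` into
the previous interval). The removable singularity at `ka = ke` is
evaluated by its analytic limit (the `t·e^(−kt)` form with the squared
accumulation factor), keeping the function continuous to ~1e−6 relative
across the degeneracy. The two-compartment model uses the standard
macro-constant (α, β, k21) closed form, with an eigenvalue-collision
nudge for the measure-zero case α = β. Correctness is established
against two independent oracles: brute-force superposition of 50+
single doses (<1e−6 relative) and LSODA integration of the compartment
ODEs at rtol 1e−10 (<1e−5 relative).

## 3. The model library

Ten published pediatric VPA popPK models are encoded as immutable
registry entries: covariate equations for the typical parameters,
lognormal between-subject variability (BSV), residual error (additive
in mg/L or proportional), and formulation-specific absorption rules.
Conventions:

* Printed BSV CV% values are read as lognormal SDs (ω = CV/100), the
  standard pharmacometric convention at these magnitudes. Two entries
  printed as variances are converted by square root; printed joint
  variability entries of the two-compartment model are read as
  covariances of the etas (the resulting matrix is positive definite,
  with eta correlations 0.21–0.72).
* One model's clearance equation is printed in a form that is
  internally inconsistent with its own reported typical clearance
  (0.106^(0.98·CO) + 0.0157·AGE would give CL > 1 L/h for an average
  child). The default reading is the multiplicative form
  0.106·0.98^CO + 0.0157·AGE, which reproduces the reported 0.18 L/h at
  the median age of 4.92 y; the literal printed form remains available
  behind a flag.
* One additive covariate model can cross zero for extreme covariates;
  clearance is floored at 1e−6 L/h with a warning.
* One model describes *unbound* drug (hence its apparent volume of
  1680 L/70 kg) with a postmenstrual-age maturation function; its
  observation function maps unbound to total concentration through the
  linear non-saturable binding equation of section 4 below.
* Models published without an absorption rule for a formulation raise
  by default; an explicit `allow_ka_fallback=True` enables a documented
  fallback mapping (nearest published formulation class) so all ten
  models can run on a syrup/sustained-release TDM cohort.

Simulation draws eta vectors from N(0, Ω) via Cholesky factorisation;
residual noise is additive or proportional per model, with simulated
concentrations floored at zero only where a physical concentration is
required (never inside the NPDE machinery, which needs the raw noise).

## 4. Protein-binding non-linearity

VPA is ~90–95% albumin-bound and binding saturates across the
therapeutic range. Five strategies are implemented; the first three are
observation functions (structural model tracks unbound drug, the
measurement is total = unbound + bound), the last two act on apparent
clearance directly:

1. **one_site**: Cb = N·K·Cu·ALB/(1 + K·Cu) evaluated in molar units
   (N = 1.98 sites, K = 15.5 /mM, VPA 144.21 g/mol, albumin
   66,500 g/mol); albumin enters in mM.
2. **langmuir**: Cb = Bm·Cu/(Kd + Cu), Bm = 130 mg/L, Kd = 7.8 mg/L
   (half-saturation: Cb = 65 mg/L at Cu = 7.8 mg/L).
3. **linear_ns**: Cb = Bm·Cu/(Kd + Cu) + NS·Cu with Kd = 2.12,
   Bm = 67.3, NS = 2.25.
4. **dde**: CL = CLp·(1 + Emax·DDW^γ/(DD50^γ + DDW^γ)), Emax = 2.8,
   γ = 1.68, DD50 estimable (factor 2.4 at DDW = DD50, limit 3.8).
5. **exponent**: CL = CLp·(DDW/25)^k, k estimable.

Total→unbound inversion is unique (Ct is strictly increasing in Cu) and
solved by bracketed Brent root-finding on [0, Ct] to 1e−12 mg/L.

### Population fitting

`fit_population` estimates each strategy's free parameters (clp, V,
ω_CL, proportional σ, plus DD50 or k) on steady-state trough data with
a scalar lognormal eta on clearance, by maximising a per-subject
Laplace approximation of the marginal likelihood: the inner MAP over
etas is a vectorised damped Newton iteration with finite-difference
curvature (prior-curvature fallback where the data term is locally
flat), and the outer problem is bounded L-BFGS-B on log-transformed
parameters with deterministic multi-starts. Absorption cannot be
identified from troughs, so ka is fixed by formulation. OFV is −2·log
approximate marginal likelihood; recovery audits on simulated cohorts
show the fitted OFV at or below the OFV at the generating truth.
Identifiability note: the dose exponent k needs dose-per-kg contrast;
on a narrow TDM-like dose distribution (lognormal σ ≈ 0.3) its
standard error is ≈0.1, so recovery studies use a dose-ranging design
(σ = 0.5).

## 5. Prediction-based evaluation

Per observation, PE% = (PRED − OBS)/OBS·100 with PRED the population
prediction (etas at zero). Summaries: MDPE (median, accuracy), MAPE
(median absolute, precision), F20/F30 (fraction of |PE| within
20%/30%; boundary ties count as within). The acceptability verdict
requires all four of |MDPE| ≤ 15%, MAPE ≤ 30%, F20 > 35%, F30 > 50%.
Externally reported metric rows for the ten models (and for the five
binding strategies) ship in `vpapk.reference` as input data for
classification cross-checks; applied to the without-prior rows the
verdict accepts exactly six models.

## 6. MAP Bayesian forecasting

A subject's eta vector is estimated from prior observation(s) by
minimising

    Σ_j [ (y_j − IPRED_j(η))²/σ_j² + ln σ_j² ] + ηᵀ Ω⁻¹ η,

with σ_j the residual SD (proportional error evaluated at IPRED). The
optimiser (L-BFGS-B with a Nelder–Mead polish) never returns a point
worse than η = 0. Limits behave correctly: Ω → 0 gives complete
shrinkage, σ → 0 exact interpolation. The forecasting protocol mirrors
TDM practice: the first trough conditions the etas, the last trough is
predicted; subjects with a single sample are skipped. The individual
errors (IPE%) are summarised with the same four statistics (MDIPE,
MAIPE, IF20, IF30). Eta shrinkage is reported as 1 − SD(η̂)/ω.

## 7. Simulation-based diagnostics

**NPDE.** The dataset is simulated k times (default 500–2000) under the
evaluated model. Per subject, the observed vector and every simulated
vector are decorrelated with the Cholesky factor of the empirical
simulated covariance (ridge-regularised only if singular); the
prediction discrepancy is the fraction of decorrelated simulations
below the decorrelated observation, clamped to [1/(2k), 1 − 1/(2k)] and
mapped through Φ⁻¹. Three tests are applied: Wilcoxon signed-rank
(mean), a two-sided χ² test of the sample variance against 1, and
Shapiro–Wilk (normality), combined by a Bonferroni rule (reject if
min p < α/3, p_global = min(1, 3·min p)). On self-simulated cohorts
the global test's null rejection rate is ≈4–5% at α = 0.05 and its
power against a 1.5× clearance misspecification is ≈100% at n = 202.

**pcVPC.** Observations and simulations are prediction-corrected
within automatic quantile bins on time after dose (duplicate edges from
trough-only sampling collapse into fewer bins):
pcY = Y·median(PRED in bin)/PRED. Observed 2.5/50/97.5 percentiles are
compared with the 95% band of the same percentiles across replicates.

## 8. Synthetic TDM cohort generator

Because the real evaluation datasets behind published external
evaluations are not public, the package ships a generator that emulates
a typical pediatric VPA TDM service: lognormal age (median 4.92 y)
truncated to 0.17–15 y; weight from the growth rule 2·age + 9 kg with
3 kg gaussian noise; lognormal dose per kg (median 23.44 mg/kg/day)
rounded to 10 mg strengths; albumin N(42.2, 3.65) g/L; 76% syrup / 24%
sustained release; realistic co-medication prevalences; 1–3
administrations per day; trough-only sampling with ~26% of subjects
contributing a second trough. Ground truth is any library model or
binding variant; true etas are stored in a sidecar for recovery audits,
and `truth_cl_scale` creates deliberately misspecified cohorts for
power studies. The generator matches its calibration targets at
n = 202 (median trough 50.2 mg/L vs target 50.4; age–weight Spearman
ρ ≈ 0.85).

## 9. Known behaviours and limitations

* Self-evaluation of a model on its own synthetic cohort does not
  guarantee an "acceptable" verdict: the verdict bounds total
  prediction error, which includes the model's own residual magnitude.
  A generating truth with ~28% residual CV yields MAPE near the 30%
  threshold even for the correct model, and models with larger residual
  terms (e.g. 57.7% proportional) cannot pass their own evaluation at
  any sample size. Absolute metric levels on synthetic cohorts are
  therefore pessimistic relative to the reported rows, while the
  *ranking* and the identity of the biased models reproduce.
* Trough-only designs leave absorption parameters unidentifiable; ka is
  always fixed, never estimated.
* The Laplace fitter supports a scalar eta on clearance only — adequate
  for the binding strategies it serves, not a general NLME engine.
* The NPDE variance test uses the χ² construction for the sample
  variance; for very large k the clamping bound (±Φ⁻¹(1/2k)) caps
  extreme npde values by design.
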