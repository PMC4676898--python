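# Methods

## Model structure

The disease model is a cohort-level (expected-value) simulation over a
discrete cycle plan: two 3-month cycles representing the trial period,
followed by 6-month cycles until the horizon — 1 year, 5 years, or
"lifetime", defined as simulation until age 100 (no cap is standard in this
literature; 100 keeps the tail finite while leaving survival effectively
zero before it under any plausible mortality equation). The final lifetime
cycle is truncated so the plan sums exactly to the cap minus the starting
age.

Within a cycle the linked equations are evaluated in two stages:

1. **Intermediate outcomes** — FEV1 (mL), moderate and severe exacerbation
   rates (events/year), dyspnoea and cough/sputum prevalence, 6-minute-walk
   distance — are predicted from the state *entering* the cycle plus the
   fixed baseline covariates.
2. **Final outcomes** — SGRQ, the survival hazard and resource-use counts —
   are predicted from the freshly updated intermediates (and the prior
   SGRQ, for its own increment).

Predicted outcomes become the next cycle's covariates. Baseline-only
covariates (sex, height, smoking status, comorbidity, BMI category,
exacerbation history) stay fixed; there are no cessation or treatment-switch
dynamics.

Each equation is a linear predictor with a link and a *mode*:

- `direct` predictions are annual-unit values that replace the outcome
  (rates, proportions, hazards, counts);
- `change` predictions are annual increments added to the previous level
  and scaled by the cycle length (FEV1, SGRQ, walk distance).

An outcome without an equation carries forward unchanged; the empty
equation set is therefore exactly the identity map, which the test suite
exploits.

Annual event rates rescale linearly to cycle length; annual probabilities
convert through the survival product 1 − (1 − p)^t, so subdividing a year
recomposes exactly. Survival supports three functional forms, selected by
the survival equation's link: log (log annual hazard, exponential
within-cycle survival — the default), identity (annual hazard), and logit
(annual death probability). The configurable form exists because the
functional form of an externally estimated survival equation is a property
of the coefficient file, not of this engine.

Out-of-range predictions (SGRQ outside [0, 100], negative rates or counts,
proportions outside [0, 1]) are clamped with a logged warning rather than
raised, so sampled coefficient tails cannot abort a probabilistic run. In
lifetime runs of the default synthetic equation set the SGRQ ceiling is
reached only in the extreme-old-age tail, where the surviving fraction is
already far below 1%.

## Accounting

Flows in a cycle are weighted by the alive fraction at the cycle start
times the square root of the cycle's survivor fraction — i.e. expected
survival to the cycle midpoint under the within-cycle hazard — which is the
half-cycle-style correction for deaths occurring mid-cycle. A
`start_of_cycle` weighting is available as a switch, since the source
models in this literature do not always state their convention.

Costs are resource counts × unit costs plus drug cost
(30-day price × 365.25·t/30), accrued only while alive (no wastage
modelling). Costs, QALYs and discounted life-years are discounted with the
continuous-time factor (1 + r)^(−t) evaluated at the cycle midpoint, so
3-month and 6-month cycles discount consistently; r defaults to 0.035/year.
Exacerbation counts are reported undiscounted. Life-years are emitted both
discounted and undiscounted, since either convention appears in published
incremental life-year figures.

The ICER is reported as a number only when ΔC and ΔQALY share a sign and
ΔQALY ≠ 0; otherwise the comparison is a verdict — *dominant* (cheaper,
more effective), *dominated* (the reverse), or *no QALY difference*.
Currency is kept at full precision internally and rounded to pennies only
at the reporting boundary.

## Treatment effect

The treated arm receives an additive level shift on FEV1 in mL (or a
subtraction on SGRQ, where lower is better) as a step function of time
since treatment start: full effect while t < duration, zero after, with
lifetime duration as the default. The engine maintains the shift as a
*level* — it applies the difference between the shift in force and the
shift already applied — so the effect does not compound across cycles and
its removal restores the untreated trajectory exactly. With a log-linked
exacerbation equation driven by FEV1, a persistent shift Δ yields the
closed-form rate ratio exp(β·Δ) every cycle, which the tests assert.

The pooled effect is estimated by random-effects meta-analysis with
maximum-likelihood τ²: the marginal model yᵢ ~ N(µ, sᵢ² + τ²), profile
likelihood maximised over τ² ≥ 0 (bounded scalar optimisation with an
explicit boundary check at τ² = 0), inverse-variance weights, and a Wald
95% CI µ̂ ± 1.96/√Σwᵢ. DerSimonian–Laird moment estimation is provided as a
labelled alternative for comparison output. When a study supplies a 95% CI
instead of an SE, se = (hi − lo)/3.92 exactly. The test suite checks the ML
fit against an independent brute-force τ²-grid likelihood maximisation.

## Utility mapping

SGRQ maps to EQ-5D utility through a configurable component. The default is
the published quadratic response-mapping form
u = 0.9617 − 0.0013·SGRQ − 0.0001·SGRQ² + 0.0231·male, clamped to [0, 1];
it is monotone non-increasing in SGRQ over the whole 0–100 range. A linear
mapping u = 1 − SGRQ/100 and a constant mapping are provided for tests and
life-year-only checks. The male term takes the cohort's male fraction in
expected-value mode.

## Probabilistic sensitivity analysis

Each replicate draws:

- **first order** — a baseline profile from the reference cohort table
  (beta for proportions, normal for symmetric continuous parameters, gamma
  for skewed positive ones, all moment-matched to the published mean and
  SE; parameters without a published SE are fixed). In `cohort` mode
  (default) the draw is interpreted as an uncertain cohort mean vector; in
  `individual` mode indicator fields are additionally binarised (Bernoulli,
  multinomial BMI category) to give one sampled patient per replicate. The
  BMI low/high draws renormalise if they sum above one, with medium as the
  complement.
- **second order** — independent normal perturbations of every equation
  coefficient with a stated SE (no coefficient covariance is published for
  such equation sets in general; a full-covariance hook would slot in at
  the same point), and the treatment effect ~ N(mean, SE) with optional
  truncation at zero (off by default).

Both arms are run per replicate, and (ΔC, ΔQALY, ΔLY) recorded. Replicates
use per-replicate child streams of a single seed, so results are
reproducible and independent of execution order; a failed replicate is
logged and excluded with the exclusion count reported. The CEAC is the
fraction of replicates with positive net monetary benefit on a
willingness-to-pay grid (default £0–£50,000 in £1,000 steps, covering the
conventional £20,000 threshold). The default replicate count is 5000.

## Synthetic default equation set

The original risk-equation coefficients for this class of model are
estimated from large observational cohorts and distributed as supplements,
so the package's default set is **synthetic**: its qualitative structure
matches the disease model and its magnitudes are chosen once on
epidemiological grounds, not fitted to any published output.

- FEV1 declines ~30 mL/yr plus 15 mL/yr for current smokers and 0.1 mL/yr
  per year of age (≈ 44 mL/yr at the reference cohort), consistent with
  observed decline in moderate-to-severe COPD.
- Moderate and severe exacerbation rates are log-linear in absolute FEV1
  (−0.0008/mL), prior-year exacerbation count and exacerbation history,
  anchored at 0.30 and 0.24 events/yr at the reference baseline state —
  a low-exacerbation symptomatic cohort.
- SGRQ worsens 0.8 points/yr plus 0.8 and 1.2 points per annual moderate
  and severe exacerbation.
- Symptom prevalences are logistic in FEV1 percent predicted, anchored at
  0.9 (dyspnoea) and 0.6 (cough/sputum) at baseline.
- Mortality is a log-linear (Gompertz-like) hazard: 0.028/yr at baseline,
  ×e^0.09 per year of age, ×e^0.012 per FEV1%p point lost, ×e^0.3 with
  cardiovascular comorbidity. Exacerbations affect mortality only through
  the FEV1 pathway in this set.
- Resource intensities tie hospital use to severe exacerbations
  (1 admission, 6 ward days, 0.2 ICU days per severe event) with
  background outpatient/office visit rates.
- Intercepts are computed from these anchors at the reference baseline
  state rather than hard-coded, and every coefficient carries an SE of
  roughly 10–20% of its magnitude for second-order sampling.

Under this set the reference cohort lives ~12 expected years, accrues
~£2,300/yr in care and drug costs, and a persistent +92 mL FEV1 benefit
yields ~0.1 incremental QALYs over lifetime — the right orders of magnitude
for this disease area.

**What passing tests do and do not show.** The synthetic set exercises every
code path with closed-form, hand-traceable consequences, and reproduces the
*structural* behaviours a real coefficient set must show (cost-effectiveness
worsening monotonically with drug price, QALY gains growing with horizon
under a persistent effect, short-horizon dominance at price parity). It does
not reproduce any particular published point estimate: quantitative
agreement with a published evaluation requires loading that evaluation's own
coefficient file. Real estimated equations also carry coefficient
covariance, richer functional forms and cohort correlations that the
synthetic set does not imitate.

## Numerical choices

- Predicted normal FEV1 (for the mL ↔ percent-predicted conversion) uses
  the ECSC 1993 reference equations, mixed by the cohort's sex split, and
  is frozen at the baseline age per profile so mL and %p remain
  proportional along a trajectory.
- Baseline exacerbation rates split the prior-year count by the severe
  fraction; baseline dyspnoea prevalence is the mMRC ≥ 2 share; baseline
  cough/sputum prevalence is not part of the cohort table and defaults to
  0.6 (configurable).
- The cohort is considered extinct below an alive fraction of 1e−12 and
  remaining cycles are truncated (logged).
- The τ² optimiser runs on [0, max(10·var(y), 10·max sᵢ²)] with xatol
  1e−12 and accepts the boundary when τ² = 0 is at least as likely.
- The two 3-month trial-period cycles use the same equations as all other
  cycles, rescaled to 0.25 years; no separate trial-period equations exist.
- Deterministic scenario results and PSA means are both emitted; they
  coincide only as all SEs → 0 (asserted exactly at SE = 0).

## Limitations

- No treatment switching, escalation, discontinuation or adverse-event
  modelling; adherence is implicit in the trial-estimated effect.
- Cohort expected-value propagation ignores between-patient nonlinearity
  (Jensen gaps) in the link functions; individual-level PSA mode recovers
  part of this at the cost of Monte-Carlo noise.
- Productivity losses and non-health-service costs are out of scope by the
  health-service perspective; no inflation adjustment is applied (the cost
  schedule's currency year is metadata).
- Second-order sampling treats coefficients as independent normals in the
  absence of a published covariance.
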