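# copdsim

A linked-equation disease-progression and cost-effectiveness model for
chronic obstructive pulmonary disease (COPD), built for health-economic
comparison of two bronchodilator maintenance therapies (for example a fixed
LAMA/LABA combination such as umeclidinium/vilanterol against tiotropium
monotherapy) from a health-service perspective.

## What it models

COPD progression is represented by a set of *linked* statistical risk
equations advanced over discrete cycles (two 3-month "trial period" cycles,
then 6-month cycles to a 1-year, 5-year or lifetime horizon). In each cycle
the intermediate outcomes — FEV1 (mL), moderate and severe exacerbation
rates, dyspnoea and cough/sputum symptom prevalence, 6-minute-walk distance
— are predicted from the previous cycle's state through GLM-style linear
predictors (log links for event rates, logit for symptom proportions,
identity for level outcomes); the final outcomes — SGRQ health status,
survival and health-care resource use — are then predicted from the updated
intermediates. Predicted outcomes at cycle *t* become covariates at cycle
*t + 1*.

Economics on top of the trajectory:

- SGRQ is mapped to EQ-5D utility (a quadratic response mapping by default);
  QALYs are survival-weighted utility × time,
- resource counts are costed against an NHS reference-cost schedule plus a
  30-day drug price, discounted at 3.5%/year to each cycle midpoint,
- the two arms are compared as ΔC, ΔQALY, and ICER = ΔC/ΔQALY or a
  dominance verdict, with net monetary benefit NMB = λ·ΔQALY − ΔC,
- probabilistic sensitivity analysis resamples the baseline cohort (beta /
  normal / gamma distributions moment-matched to published means and SEs),
  the equation coefficients and the treatment effect, and summarises the
  replicates as cost-effectiveness acceptability curves,
- trial-level FEV1 treatment differences are pooled by random-effects
  meta-analysis with maximum-likelihood τ² (yᵢ ~ N(µ, sᵢ² + τ²), weights
  1/(sᵢ² + τ²); DerSimonian–Laird available as an alternative).

The treatment effect enters as an additive level shift on the treated arm's
FEV1 (or, alternatively, SGRQ) trajectory, held for a configurable duration
or for life.

Because the original risk-equation coefficients are distributed as
supplementary material to their source studies, they are **consumed from a
structured coefficient file**, never hard-coded. The repository ships a
template (`src/copdsim/data/coefficients_template.yaml`) for users who hold
an estimated equation set, and a documented synthetic default set
(`copdsim.synthetic.paper_like_equations`) with epidemiologically plausible
magnitudes so every stage is testable out of the box.

## Worked example

```python
from copdsim import CostEffectivenessModel, MetaStudy, pool_random_effects

# pool three trials' FEV1 differences (mL, with 95% CIs)
res = pool_random_effects([
    MetaStudy("trial-1", 95.0, ci_low=50.0, ci_high=140.0),
    MetaStudy("trial-2", 60.0, ci_low=18.0, ci_high=102.0),
    MetaStudy("trial-3", 112.0, ci_low=80.0, ci_high=144.0),
])
print(res.summary())

# lifetime base case on the reference cohort, synthetic default equations
model = CostEffectivenessModel.base_case(seed=1)
print(model.fit("base").summary())
```

prints

```
Random-effects meta-analysis
==============================================
method: ml    studies: 3
pooled effect: 92.27  (95% CI 66.94, 117.60)
tau^2: 109.6964    pooled SE: 12.925
----------------------------------------------
study                       weight
trial-1                      0.262
trial-2                      0.294
trial-3                      0.444

Cost-effectiveness results — scenario base (lifetime horizon, 3.5% discount)
========================================================================
                                     UMEC/VI        tiotropium
total cost (GBP)                    26319.02          27016.78
  drug                               3862.66           3801.83
  resource use                      22456.36          23214.95
QALYs (discounted)                    5.1665            5.0622
life-years                           12.2100           11.9714
moderate exacerbations                4.5635            4.7920
severe exacerbations                  3.6508            3.8336
------------------------------------------------------------------------
incremental cost:       -697.76 GBP
incremental QALYs:       0.1043
incremental LYs:         0.2386
ICER:                  Dominant
```

The pooled effect is the inverse-variance weighted mean under the ML τ²
estimate; each weight is the study's share of 1/(sᵢ² + τ²). In the
comparison, the intervention arm gains 0.10 discounted QALYs and 0.24
life-years; at price parity its exacerbation-related resource savings exceed
the extra drug and care costs of longer survival, so it *dominates* the
comparator (cheaper and more effective) and no ICER is reported.
`model.fit_psa(n_iterations=5000)` adds the probabilistic layer and
`.ceac()` / `.plot_ceac()` the acceptability curve.

The same functionality is exposed on the command line:

```bash
copdsim fixtures --out fixtures/               # write example inputs
copdsim run --config fixtures/base_case_config.yaml --out results/
copdsim scenario --which C --config fixtures/base_case_config.yaml
copdsim psa --config fixtures/base_case_config.yaml --n 5000 --out results/
copdsim meta --studies studies.csv
```

## Layout

- `copdsim.equations` — profile/state types, equation evaluation, state
  advancement, rate/probability rescaling, survival, resource use
- `copdsim.treatment` — meta-analysis pooling, treatment specification and
  effect application
- `copdsim.econ` — utility mapping, costing, discounting, ICER/dominance,
  net monetary benefit
- `copdsim.engine` — cycle plans, arm propagation, scenarios, run config
- `copdsim.psa` — parameter distributions, profile sampling, replicates,
  CEAC
- `copdsim.synthetic` — reference cohort table, synthetic equation sets,
  hand-traceable fixtures
- `copdsim.model` — `CostEffectivenessModel` / `CEResults` / `PSAResults`
- `copdsim.config`, `copdsim.results_io`, `copdsim.cli` — files in, files
  out, command line

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
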