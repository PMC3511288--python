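# dcemix

Discrete choice experiments (DCEs) for medication-adherence research: a
Python library covering the full stated-preference workflow — statistically
efficient pairwise choice-set design, synthetic-respondent simulation, panel
mixed multinomial logit estimation by maximum simulated likelihood, response
validity checks, and post-estimation preference analytics.

## The scientific problem

Roughly half of patients prescribed long-term medications do not take them
as prescribed, and much of that non-adherence is *intentional*: patients
weigh side effects, benefits, cost and dosing burden and decide the
medication is not worth continuing. A DCE quantifies these trade-offs by
repeatedly asking respondents to choose between two hypothetical medications
("Medication A" vs "Medication B") described by eight attributes — current
side-effect severity, chance of future unwanted effects, symptom relief,
reduction in the chance of early death, out-of-pocket monthly cost, severity
of daily symptoms, doses per day, and alcohol restrictions.

## The model

Respondent *i* derives utility from alternative *j* of choice task *s*:

```
U_isj = α·1[j = A] + β_i' x_isj + γ'(c_i ⊗ x_isj) + ε_isj
```

with i.i.d. extreme-value noise ε (logit choice), an alternative-specific
constant α capturing left–right bias, linear attribute coding, and
respondent-specific coefficients β_i drawn from mixing distributions:
normal for the health-outcome attributes, and a *sign-constrained
triangular* for cost (support [0, 2μ], mode μ — the spread is tied to the
mean so the price coefficient can never flip sign). Interactions γ (e.g.
cost × private health insurance) shift attribute sensitivity by respondent
covariates. Because one draw of β_i governs all of a respondent's tasks,
the sample likelihood is a mixing-distribution integral of a *product* of
task-level logit probabilities, approximated by maximum simulated
likelihood over R Halton draws:

```
LL = Σ_i log( (1/R) Σ_r Π_t P_it(chosen | β_i^(r)) )
```

Designs are scored by the D-error `det(I(β)⁻¹)^(1/K)` of the multinomial
logit information matrix and improved by a level-balance-preserving
accept-if-better swap search. Each survey version additionally embeds a
repeated task (consistency, summarised by Cohen's κ) and a dominance task
(monotonicity).

## Worked example

```python
import dcemix as dx
from dcemix.estimation import MixedLogitSpec

pop, design = dx.study_emulation_preset()          # 161 respondents, 4 x 10 tasks
data = dx.simulate_dataset(pop, design, seed=1)

report = dx.validity_report(data, design)
spec = MixedLogitSpec(
    attributes=tuple(design.factor_names),
    mixing={"side_effect_severity": "normal", "future_side_effect_risk": "normal",
            "symptom_reduction": "normal", "death_risk_reduction": "normal",
            "cost": "triangular"},
    interactions=(("cost", "phi"),),
    n_draws=500,
)
result = dx.fit(spec, data)
print(result.summary())
```

prints (abridged):

```
monotonicity pass rate: 87.6%   repeat pass rate: 71.4%   Cohen's kappa: 0.43

  parameter                        estimate         se        z        p
  mean:side_effect_severity        -0.15877    0.02014   -7.882   0.0000
  mean:future_side_effect_risk     -0.03109    0.00418   -7.438   0.0000
  mean:death_risk_reduction         0.04405    0.00467    9.432   0.0000
  mean:cost                        -0.02311    0.00337   -6.853   0.0000
  mean:regimen                     -0.11277    0.04047   -2.786   0.0053
  mean:cost:phi                     0.00792    0.00433    1.829   0.0674
  sd:side_effect_severity           0.13287    0.02540    5.232   0.0000

AIC 1644.5 | McFadden pseudo-R2 0.263 | LR chi2 577.7 (df=14, p=2.9e-114)
hit rate: 74.3%
```

Negative means on harms and cost say those attributes push respondents away
from continuing a medication; the significant mixing standard deviations
reveal genuine preference heterogeneity; the positive cost × insurance term
says privately insured respondents are less price-sensitive. Downstream,
`relative_importance` weights each coefficient by its attribute's level
range (death-risk reduction carries ~27% of total leverage here),
`classify_harm_benefit` counts which respondents weigh harms over benefits
from their conditional individual coefficients, and `tradeoff` converts
coefficients into exchange rates between attributes (a 4→1 doses/day switch
is worth +0.34 utility, equivalent to accepting ~11 percentage points more
future side-effect risk).

The `examples/` directory contains one short narrative script per
capability: design generation, simulation + validity, estimation, and
preference analytics.

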