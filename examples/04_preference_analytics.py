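"""Post-estimation analytics: importance, individual heterogeneity, trade-offs.

Relative importance weighs each coefficient by its attribute's level range;
conditional (posterior-mean) individual coefficients let us classify each
respondent by whether medication harms or benefits dominate their choices;
the linear utility supports marginal-rate-of-substitution arithmetic.
"""

import dcemix as dx
from dcemix.estimation import MixedLogitSpec
from dcemix.simulate import PRESET_GROUPING

pop, design = dx.study_emulation_preset()
data = dx.simulate_dataset(pop, design, seed=1)
spec = MixedLogitSpec(
    attributes=tuple(design.factor_names),
    mixing={"side_effect_severity": "normal", "future_side_effect_risk": "normal",
            "symptom_reduction": "normal", "death_risk_reduction": "normal",
            "cost": "triangular"},
    interactions=(("cost", "phi"),),
    n_draws=500,
)
result = dx.fit(spec, data, se_method="none")

imp = dx.relative_importance(result, design, "individual", data)
print("relative importance (population betas, % of total leverage):")
for name, share in imp.shares.sort_values(ascending=False).items():
    print(f"  {name:26s} {share:5.1f}%")

table3 = dx.classify_harm_benefit(imp.individual, PRESET_GROUPING)
print("\nindividual-level harm/benefit classification:")
for _, row in table3.iterrows():
    print(f"  {row['comparison']:46s} {row['count']:4d} ({row['percent']:.0f}%)")

t = dx.tradeoff(result, "regimen", -3.0, "future_side_effect_risk")
print(f"\nswitching from 4 to 1 doses/day raises utility by {t.utility_change:+.4f};")
print(f"respondents would accept a {t.compensating_move_b:+.1f} percentage-point "
      "rise in future side-effect risk in exchange")
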