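"""Synthetic respondents with heterogeneous preferences.

The survey data this package was written around is not deposited, so every
downstream stage is exercised on simulated panels that share the statistical
structure the estimator assumes: each respondent i draws one coefficient
vector beta_i from the population mixing distributions and applies it to all
tasks of their assigned survey version; the chosen alternative in task t is A
with probability

    P(A) = exp(V_A) / (exp(V_A) + exp(V_B)),
    V_j  = alpha * 1[j = A] + (beta_i + gamma' c_i)' x_j

i.e. logit choice, with the alternative-specific constant alpha attached to
the left-hand option and interaction terms gamma shifting attribute
sensitivity by respondent covariates c_i (e.g. cost x private health
insurance).

Mixing distributions:

``fixed``
    degenerate at the mean.
``normal(mean, sd)``
    unconstrained heterogeneity.
``triangular(mean)``
    "constrained triangular": symmetric triangular on [0, 2*mean] (or
    [2*mean, 0] for negative means) with mode at the mean — the spread is
    tied to the mean so every draw keeps the mean's sign.  The conventional
    choice for a cost coefficient that must not turn positive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ChoiceDesign, FactorSpec, add_validity_tasks, generate_efficient_design
from .exceptions import InvalidSpecificationError

ASC_NAME = "asc"

MIXING_FIXED = "fixed"
MIXING_NORMAL = "normal"
MIXING_TRIANGULAR = "triangular"


@dataclass(frozen=True)
class Mixing:
    """Mixing distribution of one coefficient across respondents."""

    kind: str
    mean: float
    sd: float = 0.0  # only meaningful for kind == "normal"

    def __post_init__(self) -> None:
        if self.kind not in (MIXING_FIXED, MIXING_NORMAL, MIXING_TRIANGULAR):
            raise InvalidSpecificationError(f"unknown mixing kind {self.kind!r}")
        if self.kind == MIXING_NORMAL and self.sd < 0:
            raise InvalidSpecificationError("normal mixing needs sd >= 0")
        if self.kind != MIXING_NORMAL and self.sd != 0.0:
            raise InvalidSpecificationError(
                f"{self.kind} mixing takes no sd parameter"
            )

    @property
    def spread(self) -> float:
        """Heterogeneity scale: sd for normal, |mean| for constrained triangular."""
        if self.kind == MIXING_NORMAL:
            return self.sd
        if self.kind == MIXING_TRIANGULAR:
            return abs(self.mean)
        return 0.0

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mean": self.mean, "sd": self.sd}


@dataclass
class PopulationSpec:
    """Data-generating population for simulated panels.

    ``coefficients`` maps attribute names (plus ``"asc"`` for the
    alternative-specific constant) to mixing distributions.
    ``covariates`` maps binary covariate names to Bernoulli prevalences;
    ``interactions`` lists (attribute, covariate, coefficient) triples whose
    coefficient is added to the attribute's individual coefficient for
    respondents with covariate 1.
    """

    coefficients: dict[str, Mixing]
    covariates: dict[str, float] = field(default_factory=dict)
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    n_respondents: int = 161

    def __post_init__(self) -> None:
        for name, prev in self.covariates.items():
            if not 0.0 <= prev <= 1.0:
                raise InvalidSpecificationError(
                    f"prevalence of covariate {name!r} must be in [0, 1]"
                )
        for attr, cov, _ in self.interactions:
            if attr not in self.coefficients:
                raise InvalidSpecificationError(
                    f"interaction attribute {attr!r} has no coefficient"
                )
            if cov not in self.covariates:
                raise InvalidSpecificationError(
                    f"interaction covariate {cov!r} has no prevalence"
                )
        if self.n_respondents < 1:
            raise InvalidSpecificationError("n_respondents must be >= 1")

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: m.to_dict() for k, m in self.coefficients.items()},
            "covariates": dict(self.covariates),
            "interactions": [list(t) for t in self.interactions],
            "n_respondents": self.n_respondents,
        }

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ChoiceDataset:
    """Panel choice data in long format.

    ``choices`` has one row per respondent x task x alternative with columns
    ``respondent, block, task, role, alternative, chosen`` plus one numeric
    column per attribute.  ``covariates`` is indexed by respondent id.
    """

    choices: pd.DataFrame
    covariates: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    ID_COLUMNS = ("respondent", "block", "task", "role", "alternative", "chosen")

    @property
    def attribute_columns(self) -> list[str]:
        return [c for c in self.choices.columns if c not in self.ID_COLUMNS]

    @property
    def respondents(self) -> np.ndarray:
        return self.choices["respondent"].unique()

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def n_choice_observations(self) -> int:
        return len(self.choices) // 2

    def validate(self) -> None:
        """Enforce the long-format contract; raises DataValidationError."""
        from .io import validate_choice_frame

        validate_choice_frame(self.choices)

    def subset(self, respondent_ids) -> "ChoiceDataset":
        keep = set(respondent_ids)
        return ChoiceDataset(
            choices=self.choices[self.choices["respondent"].isin(keep)].reset_index(
                drop=True
            ),
            covariates=self.covariates.loc[
                [r for r in self.covariates.index if r in keep]
            ],
            provenance={**self.provenance, "subset": True},
        )


# ---------------------------------------------------------------------------
# coefficient draws
# ---------------------------------------------------------------------------


def draw_individual_coefficients(
    pop: PopulationSpec, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw one coefficient vector per respondent from the mixing model.

    Returns a DataFrame (n rows, one column per coefficient name, respondent
    ids 1..n as index).  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = {}
    for name, mix in pop.coefficients.items():
        if mix.kind == MIXING_FIXED:
            cols[name] = np.full(n, mix.mean)
        elif mix.kind == MIXING_NORMAL:
            cols[name] = rng.normal(mix.mean, mix.sd, size=n)
        else:  # constrained triangular on [0, 2*mean] with mode = mean
            if mix.mean == 0.0:
                cols[name] = np.zeros(n)
            else:
                lo, hi = sorted((0.0, 2.0 * mix.mean))
                cols[name] = rng.triangular(lo, mix.mean, hi, size=n)
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="respondent"))


def draw_covariates(
    pop: PopulationSpec, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Independent Bernoulli covariates at the spec's prevalences."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols = {
        name: (rng.random(n) < prev).astype(int)
        for name, prev in pop.covariates.items()
    }
    return pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="respondent"))


# ---------------------------------------------------------------------------
# choice simulation
# ---------------------------------------------------------------------------


def choice_probability_A(
    task_alternatives: tuple[dict, dict],
    coefficients: dict[str, float],
    factor_names: list[str],
) -> float:
    """Analytic logit probability that alternative A (index 0) is chosen."""
    from scipy.special import expit

    a, b = task_alternatives
    v = coefficients.get(ASC_NAME, 0.0)
    for name in factor_names:
        v += coefficients[name] * (a[name] - b[name])
    return float(expit(v))


def simulate_choices(
    design: ChoiceDesign,
    coefficients: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    interactions: list[tuple[str, str, float]] | None = None,
    seed: int | np.random.Generator = 0,
    block_assignment: str = "random",
) -> ChoiceDataset:
    """Simulate one panel of choices from per-respondent coefficients.

    Each respondent answers every task of one block.  Choice noise follows
    the Gumbel-difference (logistic) construction: A is chosen when a uniform
    draw falls below sigma(V_A - V_B), which is distributionally identical to
    adding independent extreme-value errors to both utilities.

    Parameters
    ----------
    coefficients
        DataFrame indexed by respondent id, one column per attribute plus
        optionally ``"asc"``.
    covariates, interactions
        Respondent covariate table and (attribute, covariate, coefficient)
        triples shifting attribute sensitivity for covariate==1 respondents.
    block_assignment
        ``"random"`` (respondents sample a survey version uniformly) or
        ``"cycle"`` (deterministic round-robin, exact balance).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = design.factor_names
    missing = [n for n in names if n not in coefficients.columns]
    if missing:
        raise InvalidSpecificationError(
            f"coefficient columns missing for attributes: {missing}"
        )
    interactions = interactions or []
    if interactions and covariates is None:
        raise InvalidSpecificationError("interactions given without covariates")
    for attr, cov, _ in interactions:
        if attr != ASC_NAME and attr not in names:
            raise InvalidSpecificationError(f"unknown interaction attribute {attr!r}")
        if cov not in covariates.columns:
            raise InvalidSpecificationError(f"unknown interaction covariate {cov!r}")

    n = len(coefficients)
    resp_ids = np.asarray(coefficients.index)
    if block_assignment == "random":
        blocks = rng.integers(design.n_blocks, size=n)
    elif block_assignment == "cycle":
        blocks = np.arange(n) % design.n_blocks
    else:
        raise InvalidSpecificationError(f"unknown block_assignment {block_assignment!r}")

    rows = []
    for idx, rid in enumerate(resp_ids):
        beta = coefficients.loc[rid].to_dict()
        beta.setdefault(ASC_NAME, 0.0)
        for attr, cov, gamma in interactions:
            beta[attr] = beta[attr] + gamma * float(covariates.loc[rid, cov])
        b = int(blocks[idx])
        for task in design.tasks_in_block(b):
            p_a = choice_probability_A(task.alternatives, beta, names)
            chose_a = rng.random() < p_a
            for j, alt in enumerate(task.alternatives):
                rows.append(
                    {
                        "respondent": rid,
                        "block": b,
                        "task": task.task_id,
                        "role": task.role,
                        "alternative": "A" if j == 0 else "B",
                        "chosen": int((j == 0) == chose_a),
                        **{name: alt[name] for name in names},
                    }
                )
    choices = pd.DataFrame(rows)
    cov_df = (
        covariates.loc[resp_ids]
        if covariates is not None
        else pd.DataFrame(index=pd.Index(resp_ids, name="respondent"))
    )
    return ChoiceDataset(choices=choices, covariates=cov_df, provenance={})


def simulate_dataset(
    pop: PopulationSpec,
    design: ChoiceDesign,
    seed: int,
    block_assignment: str = "random",
) -> ChoiceDataset:
    """Full generator: covariates, individual coefficients, then choices.

    All randomness flows from a single SeedSequence spawned off ``seed`` so
    identical (pop, design, seed) triples reproduce the dataset exactly.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_beta, s_choice = ss.spawn(3)
    covariates = draw_covariates(pop, pop.n_respondents, np.random.default_rng(s_cov))
    coefficients = draw_individual_coefficients(
        pop, pop.n_respondents, np.random.default_rng(s_beta)
    )
    ds = simulate_choices(
        design,
        coefficients,
        covariates=covariates,
        interactions=pop.interactions,
        seed=np.random.default_rng(s_choice),
        block_assignment=block_assignment,
    )
    ds.provenance = {"seed": seed, "population_hash": pop.spec_hash()}
    return ds


# ---------------------------------------------------------------------------
# study-scale preset
# ---------------------------------------------------------------------------

#: Default attribute registry for the medication-adherence emulation.  The
#: original survey's exact level values are not published; these are
#: synthetic but field-plausible defaults (cost centred around typical
#: prescription co-payments, severity on 0-10 scales, risks in percent).
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec(
        "side_effect_severity", (0.0, 3.0, 5.0, 8.0), -1,
        "Current medication side-effect severity (0-10 scale)",
    ),
    FactorSpec(
        "future_side_effect_risk", (0.0, 10.0, 20.0, 40.0), -1,
        "Chance of future unwanted medication effects (%)",
    ),
    FactorSpec(
        "symptom_reduction", (0.0, 20.0, 40.0, 60.0), +1,
        "Reduction in symptom frequency while on medication (%)",
    ),
    FactorSpec(
        "death_risk_reduction", (0.0, 10.0, 20.0, 40.0), +1,
        "Reduction in chance of early death from illness while on medication (%)",
    ),
    FactorSpec(
        "cost", (5.0, 15.0, 30.0, 60.0), -1,
        "Out-of-pocket monthly cost ($AU, centred about typical co-payments)",
    ),
    FactorSpec(
        "symptom_severity", (0.0, 3.0, 5.0, 8.0), -1,
        "Severity of daily illness symptoms (0-10 scale)",
    ),
    FactorSpec(
        "regimen", (1.0, 2.0, 3.0, 4.0), -1,
        "Doses per day",
    ),
    FactorSpec(
        "alcohol_restriction", (0.0, 1.0, 2.0, 3.0), -1,
        "Alcohol restriction level (0 none - 3 complete)",
    ),
)

#: Synthetic data-generating coefficients.  The original coefficient table is
#: unpublished; these means are illustrative, calibrated once so the emulated
#: panel reproduces the study's qualitative structure: death-risk reduction
#: most important, then current side-effect severity and future side-effect
#: risk; regimen least important among significant factors (beta_regimen =
#: -0.0937 makes a 4->1 doses/day switch worth +0.2811 utility); cost mixing
#: constrained triangular with a cost x private-health-insurance interaction
#: near +0.004; symptom severity and alcohol restrictions negligible; ASC
#: near zero; heterogeneity (sd = |mean| on the four health-outcome factors)
#: strong enough that dominance-task pass rates sit near 0.9 and repeat-task
#: kappa near 0.5 at the 161-respondent scale.
PRESET_COEFFICIENTS: dict[str, Mixing] = {
    ASC_NAME: Mixing(MIXING_FIXED, 0.02),
    "side_effect_severity": Mixing(MIXING_NORMAL, -0.160, 0.160),
    "future_side_effect_risk": Mixing(MIXING_NORMAL, -0.030, 0.030),
    "symptom_reduction": Mixing(MIXING_NORMAL, 0.0100, 0.0100),
    "death_risk_reduction": Mixing(MIXING_NORMAL, 0.0400, 0.0400),
    "cost": Mixing(MIXING_TRIANGULAR, -0.0200),
    "symptom_severity": Mixing(MIXING_FIXED, -0.0050),
    "regimen": Mixing(MIXING_FIXED, -0.0937),
    "alcohol_restriction": Mixing(MIXING_FIXED, -0.0100),
}

#: Harm/benefit x time-horizon grouping of the four health-outcome factors,
#: used by the individual-level preference classifier.
PRESET_GROUPING: dict[str, dict[str, str]] = {
    "side_effect_severity": {"kind": "harm", "horizon": "immediate"},
    "future_side_effect_risk": {"kind": "harm", "horizon": "long_term"},
    "symptom_reduction": {"kind": "benefit", "horizon": "immediate"},
    "death_risk_reduction": {"kind": "benefit", "horizon": "long_term"},
}

PRESET_SEED = 20120620  # fixed so the preset design is one reproducible object


def study_emulation_preset(
    n_respondents: int = 161, design_search_iter: int = 1500
) -> tuple[PopulationSpec, ChoiceDesign]:
    """Population and design emulating the study's structure.

    161 respondents by default; a 32-task D-efficient design split into 4
    survey versions, each augmented with one repeated and one dominance task
    (10 tasks per version); 8 linear attributes; private health insurance
    prevalence 0.48, concession card 0.61, low income 0.37; cost x private
    health insurance interaction +0.004.
    """
    pop = PopulationSpec(
        coefficients=dict(PRESET_COEFFICIENTS),
        covariates={"phi": 0.48, "concession": 0.61, "low_income": 0.37},
        interactions=[("cost", "phi", 0.004)],
        n_respondents=n_respondents,
    )
    base = generate_efficient_design(
        list(DEFAULT_FACTORS), n_tasks=32, n_blocks=4,
        n_iter=design_search_iter, seed=PRESET_SEED,
    )
    design = add_validity_tasks(base, seed=PRESET_SEED + 1)
    return pop, design
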