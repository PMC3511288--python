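"""Preference analytics on a fitted panel mixed logit.

Covers the headline quantities a stated-preference study reports once the
model is estimated: goodness of fit against the choice-shares null
(McFadden's pseudo R^2, AIC, likelihood-ratio test), the predictive hit
rate, attribute relative importance (|coefficient| x level range, normalised
to shares) at the population and the individual level, simulation-based
conditional ("individual") coefficients, a harms-vs-benefits classifier of
individual importance profiles, and marginal-rate-of-substitution trade-off
arithmetic on the linear utility function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import ChoiceDesign
from .estimation import EstimationResult, _prepare, _weights_and_beta
from .exceptions import (
    ConfigurationError,
    DegenerateModelError,
    InvalidSpecificationError,
    NumericUnderflowError,
    UndefinedTradeoffError,
)
from .simulate import ChoiceDataset


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


@dataclass
class FitStatistics:
    loglik: float
    null_loglik: float
    n_parameters: int
    aic: float
    mcfadden_r2: float
    lr_statistic: float
    lr_df: int
    lr_pvalue: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def null_loglik_choice_shares(data: ChoiceDataset, roles=None) -> float:
    """Log-likelihood of the average-utility null model.

    The null predicts every task with the choice shares observed within the
    dataset (share of left/right alternatives chosen overall):
    LL0 = n_A log(s_A) + n_B log(s_B).
    """
    df = data.choices
    if roles is not None:
        df = df[df["role"].isin(roles)]
    chosen = df[df["chosen"] == 1]
    counts = chosen["alternative"].value_counts()
    n = counts.sum()
    ll0 = 0.0
    for _, c in counts.items():
        ll0 += c * np.log(c / n)
    return float(ll0)


def fit_statistics(
    result: EstimationResult, data: ChoiceDataset, null_df: int = 0
) -> FitStatistics:
    """AIC, McFadden pseudo R^2 and the LR test against the shares null.

    ``null_df`` counts the null model's estimated parameters when computing
    the LR degrees of freedom (0 by convention: the observed shares are
    treated as given, so df equals the fitted model's parameter count).
    """
    ll = result.loglik
    ll0 = null_loglik_choice_shares(data, result.roles)
    if ll > 0 or ll0 > 0:
        raise InvalidSpecificationError("log-likelihoods must be non-positive")
    k = result.n_parameters
    lr = 2.0 * (ll - ll0)
    df = k - null_df
    # a fitted model can sit marginally below the null only through
    # simulation noise; clamp the test statistic at zero
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df)) if df > 0 else float("nan")
    return FitStatistics(
        loglik=ll,
        null_loglik=ll0,
        n_parameters=k,
        aic=2.0 * k - 2.0 * ll,
        mcfadden_r2=1.0 - ll / ll0 if ll0 != 0 else float("nan"),
        lr_statistic=lr,
        lr_df=df,
        lr_pvalue=p,
    )


# ---------------------------------------------------------------------------
# predicted vs actual choices
# ---------------------------------------------------------------------------


def hit_rate(
    result: EstimationResult,
    data: ChoiceDataset,
    coefficients: str = "unconditional",
) -> float:
    """Share of observed choices the model predicts correctly.

    A choice counts as a hit when the predicted probability of the chosen
    alternative exceeds 0.5; exact ties count one half, so a completely
    uninformative model scores exactly 50%.

    ``coefficients="unconditional"`` evaluates probabilities at the
    population mean coefficients; ``"conditional"`` uses each respondent's
    conditional (posterior-mean) coefficients.
    """
    spec = result.spec
    prep = _prepare(spec, data, result.roles)
    names = spec.coefficient_names()
    if coefficients == "unconditional":
        beta = np.broadcast_to(
            result.params[: len(names)], (prep.n, 1, len(names))
        )
    elif coefficients == "conditional":
        cond = conditional_individual_coefficients(result, data)
        beta = cond[names].to_numpy()[:, None, :]
    else:
        raise InvalidSpecificationError(
            f"coefficients must be 'unconditional' or 'conditional', got {coefficients!r}"
        )
    V = np.einsum("ntk,nrk->nt", prep.Xd, beta)
    p_a = special.expit(V)
    p_chosen = np.where(prep.y == 1.0, p_a, 1.0 - p_a)
    hits = np.where(np.isclose(p_chosen, 0.5), 0.5, (p_chosen > 0.5).astype(float))
    return float((hits * prep.mask).sum() / prep.mask.sum())


# ---------------------------------------------------------------------------
# relative importance
# ---------------------------------------------------------------------------


@dataclass
class ImportanceTable:
    """Attribute leverage: |coefficient| x level range, as % shares."""

    factors: list[str]
    raw: pd.Series  # population-level raw importances
    shares: pd.Series  # population-level, sums to 100
    individual: pd.DataFrame | None = None  # per-respondent % shares

    def to_dict(self) -> dict:
        return {
            "factors": self.factors,
            "raw": self.raw.to_dict(),
            "shares_percent": self.shares.to_dict(),
        }


def _importance_shares(beta: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    raw = np.abs(beta) * ranges
    total = raw.sum(axis=-1, keepdims=True)
    if np.any(total == 0.0):
        raise DegenerateModelError("all coefficients are zero")
    return 100.0 * raw / total


def relative_importance(
    result: EstimationResult,
    factor_ranges: dict[str, float] | ChoiceDesign,
    coefficients: str = "population",
    data: ChoiceDataset | None = None,
) -> ImportanceTable:
    """Relative importance of each attribute.

    importance_f = |beta_f| x (max level - min level of f), normalised to
    percentage shares.  ``coefficients="population"`` uses the fitted means;
    ``"individual"`` additionally returns a per-respondent share matrix
    computed from conditional individual coefficients (requires ``data``).
    """
    if isinstance(factor_ranges, ChoiceDesign):
        ranges = {f.name: f.level_range for f in factor_ranges.factors}
    else:
        ranges = dict(factor_ranges)
    factors = [a for a in result.spec.attributes if a in ranges]
    if not factors:
        raise ConfigurationError("no fitted attribute has a level range")
    r = np.array([ranges[f] for f in factors])
    means = result.means
    pop_beta = np.array([means[f] for f in factors])
    pop_shares = _importance_shares(pop_beta, r)
    raw = pd.Series(np.abs(pop_beta) * r, index=factors, name="importance")
    table = ImportanceTable(
        factors=factors,
        raw=raw,
        shares=pd.Series(pop_shares, index=factors, name="share_percent"),
    )
    if coefficients == "individual":
        if data is None:
            raise ConfigurationError("individual importance needs the dataset")
        cond = conditional_individual_coefficients(result, data)
        ind = _importance_shares(cond[factors].to_numpy(), r)
        table.individual = pd.DataFrame(ind, index=cond.index, columns=factors)
    elif coefficients != "population":
        raise InvalidSpecificationError(
            f"coefficients must be 'population' or 'individual', got {coefficients!r}"
        )
    return table


# ---------------------------------------------------------------------------
# conditional individual coefficients
# ---------------------------------------------------------------------------


def conditional_individual_coefficients(
    result: EstimationResult, data: ChoiceDataset
) -> pd.DataFrame:
    """Simulation-based conditional means E[beta_i | respondent i's choices].

    For each respondent the mixing draws are re-weighted by the likelihood
    of that respondent's observed choice sequence:

        E[beta_i | y_i] = sum_r beta^(r) prod_t P_it(beta^(r))
                          / sum_r prod_t P_it(beta^(r))

    With zero mixing variance every conditional vector equals the population
    means.  Raises when a respondent's weights all underflow (increase the
    draw count).
    """
    if not result.spec.random_coefficients():
        names = result.spec.coefficient_names()
        prep = _prepare(result.spec, data, result.roles)
        vals = np.tile(result.params[: len(names)], (prep.n, 1))
        return pd.DataFrame(
            vals, index=pd.Index(prep.respondent_ids, name="respondent"),
            columns=names,
        )
    prep, W, beta, ll_i = _weights_and_beta(result, data)
    if not np.isfinite(ll_i).all():
        bad = prep.respondent_ids[~np.isfinite(ll_i)]
        raise NumericUnderflowError(
            f"simulated probabilities underflowed for respondents {list(bad[:5])}; "
            "increase n_draws"
        )
    cond = np.einsum("nr,nrk->nk", W, beta)
    return pd.DataFrame(
        cond,
        index=pd.Index(prep.respondent_ids, name="respondent"),
        columns=result.spec.coefficient_names(),
    )


# ---------------------------------------------------------------------------
# harms vs benefits classification
# ---------------------------------------------------------------------------


def classify_harm_benefit(
    individual_importance: pd.DataFrame,
    grouping: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Count respondents by which factor group dominates their preferences.

    ``grouping`` tags factors as ``{"kind": "harm"|"benefit",
    "horizon": "immediate"|"long_term"}``.  Returns the three standard
    comparisons — overall harms vs benefits, immediate vs long-term harms,
    immediate vs long-term benefits — as counts and percentages of
    respondents whose summed importance is strictly greater on the first
    side.
    """
    for f, tags in grouping.items():
        if f not in individual_importance.columns:
            raise ConfigurationError(f"grouped factor {f!r} not in importance table")
        if tags.get("kind") not in ("harm", "benefit") or tags.get("horizon") not in (
            "immediate",
            "long_term",
        ):
            raise ConfigurationError(f"factor {f!r} has invalid tags {tags!r}")

    def members(kind=None, horizon=None):
        return [
            f
            for f, tags in grouping.items()
            if (kind is None or tags["kind"] == kind)
            and (horizon is None or tags["horizon"] == horizon)
        ]

    harms, benefits = members("harm"), members("benefit")
    if not harms or not benefits:
        raise ConfigurationError("grouping needs at least one harm and one benefit factor")

    n = len(individual_importance)

    def compare(left: list[str], right: list[str]) -> int:
        ls = individual_importance[left].sum(axis=1)
        rs = individual_importance[right].sum(axis=1)
        return int((ls > rs).sum())

    rows = [
        ("Harms (overall) > Benefits (overall)", compare(harms, benefits)),
        (
            "Harms (immediate) > Harms (long-term)",
            compare(members("harm", "immediate"), members("harm", "long_term")),
        ),
        (
            "Benefits (immediate) > Benefits (long-term)",
            compare(members("benefit", "immediate"), members("benefit", "long_term")),
        ),
    ]
    return pd.DataFrame(
        {
            "comparison": [r[0] for r in rows],
            "count": [r[1] for r in rows],
            "percent": [100.0 * r[1] / n for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# trade-offs
# ---------------------------------------------------------------------------


@dataclass
class TradeoffResult:
    factor_a: str
    move_a: float
    factor_b: str
    utility_change: float
    compensating_move_b: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def tradeoff(
    result: EstimationResult, factor_a: str, move_a: float, factor_b: str
) -> TradeoffResult:
    """Utility change of a stated attribute move, and the compensating move.

    Under linear utility, moving attribute a by ``move_a`` changes utility
    by ``beta_a * move_a``; the move in attribute b restoring the original
    utility is ``-beta_a * move_a / beta_b`` (marginal rate of substitution
    times the move).  Undefined when ``beta_b`` is zero.
    """
    means = result.means
    for f in (factor_a, factor_b):
        if f not in means:
            raise InvalidSpecificationError(f"coefficient {f!r} not in the fitted model")
    beta_b = means[factor_b]
    if beta_b == 0.0:
        raise UndefinedTradeoffError(
            f"marginal rate of substitution undefined: coefficient of {factor_b!r} is 0"
        )
    du = means[factor_a] * move_a
    return TradeoffResult(
        factor_a=factor_a,
        move_a=move_a,
        factor_b=factor_b,
        utility_change=du,
        compensating_move_b=-du / beta_b,
    )
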