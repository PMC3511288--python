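"""Response-validity checks from embedded survey tasks.

Two rationality probes are built into every survey version: a *dominance*
task, where one alternative is at least as good on every attribute under the
a-priori preference directions (choosing it passes the monotonicity test),
and a *repeat* of an earlier task (answering identically passes the
consistency test).  Agreement on the repeated task is additionally
summarised by Cohen's kappa, the chance-corrected agreement between the
first and second asking across respondents:

    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement share and p_e the agreement expected from
the two marginal answer distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ROLE_DESIGN, ROLE_DOMINANCE, ROLE_REPEAT, ChoiceDesign, dominates
from .exceptions import (
    InsufficientSampleError,
    MissingValidityTaskError,
    PairingError,
)
from .simulate import ChoiceDataset


@dataclass
class ValidityReport:
    """Pass rates and per-respondent flags for both validity checks."""

    monotonicity_pass_rate: float | None = None
    repeat_pass_rate: float | None = None
    kappa: float | None = None
    monotonicity_flags: pd.Series | None = None
    repeat_flags: pd.Series | None = None
    agreement_table: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "monotonicity_pass_rate": self.monotonicity_pass_rate,
            "repeat_pass_rate": self.repeat_pass_rate,
            "kappa": self.kappa,
            "agreement_table": self.agreement_table,
            "monotonicity_flags": (
                None
                if self.monotonicity_flags is None
                else {str(k): bool(v) for k, v in self.monotonicity_flags.items()}
            ),
            "repeat_flags": (
                None
                if self.repeat_flags is None
                else {str(k): bool(v) for k, v in self.repeat_flags.items()}
            ),
        }


def _chosen_alternative(df: pd.DataFrame, respondent, task_id) -> str:
    rows = df[(df["respondent"] == respondent) & (df["task"] == task_id)]
    chosen = rows[rows["chosen"] == 1]
    if len(chosen) != 1:
        raise PairingError(
            f"respondent {respondent!r} task {task_id!r}: expected exactly one "
            f"chosen alternative, found {len(chosen)}"
        )
    return str(chosen.iloc[0]["alternative"])


def monotonicity_test(
    data: ChoiceDataset, design: ChoiceDesign
) -> tuple[pd.Series, float]:
    """Per-respondent dominance-task pass flags and the pass rate.

    A respondent passes when they chose the dominant alternative of their
    block's dominance task.  Raises if a block lacks a dominance task.
    """
    dom_by_block = {}
    for b in range(design.n_blocks):
        tasks = design.tasks_in_block(b, ROLE_DOMINANCE)
        if not tasks:
            raise MissingValidityTaskError(f"block {b} has no dominance task")
        task = tasks[0]
        a, bb = task.alternatives
        if dominates(a, bb, design.factors):
            dominant = "A"
        elif dominates(bb, a, design.factors):
            dominant = "B"
        else:
            raise MissingValidityTaskError(
                f"dominance task {task.task_id!r} has no dominant alternative"
            )
        dom_by_block[b] = (task.task_id, dominant)

    df = data.choices
    flags = {}
    for resp, grp in df.groupby("respondent", sort=True):
        block = int(grp["block"].iloc[0])
        task_id, dominant = dom_by_block[block]
        flags[resp] = _chosen_alternative(df, resp, task_id) == dominant
    flags = pd.Series(flags, name="monotonicity_pass")
    return flags, float(flags.mean())


def cohens_kappa(table: np.ndarray) -> float:
    """Two-category Cohen's kappa from a 2x2 agreement table.

    Rows index the first answer, columns the repeated answer.  With a
    degenerate chance-agreement of 1 the statistic is defined as 1 for
    perfect observed agreement and NaN otherwise.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise PairingError("empty agreement table")
    po = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    if abs(1.0 - pe) < 1e-12:
        return 1.0 if po >= 1.0 - 1e-12 else float("nan")
    return float((po - pe) / (1.0 - pe))


def repeat_consistency(
    data: ChoiceDataset, design: ChoiceDesign
) -> tuple[pd.Series, float, float, np.ndarray]:
    """Repeat-task agreement: flags, pass rate, kappa and the 2x2 table.

    Answers to the repeated asking are mapped back to the original task's
    alternative labels (the repeat may present them in reversed order), so
    "agreement" means choosing the same *profile*, not the same position.
    """
    pairs = {}
    for b in range(design.n_blocks):
        reps = design.tasks_in_block(b, ROLE_REPEAT)
        if not reps:
            raise PairingError(f"block {b} has no repeat task")
        rep = reps[0]
        if rep.repeat_of is None:
            raise PairingError(f"repeat task {rep.task_id!r} names no original")
        originals = [
            t for t in design.tasks_in_block(b, ROLE_DESIGN) if t.task_id == rep.repeat_of
        ]
        if not originals:
            raise PairingError(
                f"repeat task {rep.task_id!r} pairs to missing task {rep.repeat_of!r}"
            )
        orig = originals[0]
        if rep.alternatives[0] == orig.alternatives[0]:
            mapping = {"A": "A", "B": "B"}
        elif rep.alternatives[0] == orig.alternatives[1]:
            mapping = {"A": "B", "B": "A"}  # repeat shown in reversed order
        else:
            raise PairingError(
                f"repeat task {rep.task_id!r} does not duplicate {orig.task_id!r}"
            )
        pairs[b] = (orig.task_id, rep.task_id, mapping)

    df = data.choices
    flags = {}
    table = np.zeros((2, 2))
    idx = {"A": 0, "B": 1}
    for resp, grp in df.groupby("respondent", sort=True):
        block = int(grp["block"].iloc[0])
        orig_id, rep_id, mapping = pairs[block]
        first = _chosen_alternative(df, resp, orig_id)
        second = mapping[_chosen_alternative(df, resp, rep_id)]
        flags[resp] = first == second
        table[idx[first], idx[second]] += 1
    flags = pd.Series(flags, name="repeat_pass")
    return flags, float(flags.mean()), cohens_kappa(table), table


def validity_report(data: ChoiceDataset, design: ChoiceDesign) -> ValidityReport:
    """Run both checks and bundle the results."""
    m_flags, m_rate = monotonicity_test(data, design)
    r_flags, r_rate, kappa, table = repeat_consistency(data, design)
    return ValidityReport(
        monotonicity_pass_rate=m_rate,
        repeat_pass_rate=r_rate,
        kappa=kappa,
        monotonicity_flags=m_flags,
        repeat_flags=r_flags,
        agreement_table={
            "AA": int(table[0, 0]), "AB": int(table[0, 1]),
            "BA": int(table[1, 0]), "BB": int(table[1, 1]),
        },
    )


def refit_excluding(
    data: ChoiceDataset,
    flags: pd.Series,
    spec,
    min_respondents: int = 10,
    **fit_kwargs,
):
    """Fit on all respondents and on the subsample passing a validity flag.

    The default analysis policy keeps every respondent in the main model;
    this helper quantifies what exclusion would have changed.  Returns
    ``(full_result, excluded_result, comparison)`` where the comparison
    table lists both coefficient sets with sign-agreement and
    rank-of-magnitude-agreement indicators.
    """
    from .estimation import fit

    keep = [r for r, ok in flags.items() if ok]
    if len(keep) < min_respondents:
        raise InsufficientSampleError(
            f"exclusion leaves {len(keep)} respondents (< {min_respondents})"
        )
    full = fit(spec, data, **fit_kwargs)
    sub = fit(spec, data.subset(keep), **fit_kwargs)

    names = spec.coefficient_names()
    full_m, sub_m = full.means, sub.means
    full_rank = pd.Series({n: abs(full_m[n]) for n in names}).rank(ascending=False)
    sub_rank = pd.Series({n: abs(sub_m[n]) for n in names}).rank(ascending=False)
    comparison = pd.DataFrame(
        {
            "coefficient": names,
            "full": [full_m[n] for n in names],
            "excluded": [sub_m[n] for n in names],
            "sign_agrees": [np.sign(full_m[n]) == np.sign(sub_m[n]) for n in names],
            "rank_full": [full_rank[n] for n in names],
            "rank_excluded": [sub_rank[n] for n in names],
            "rank_agrees": [full_rank[n] == sub_rank[n] for n in names],
        }
    )
    return full, sub, comparison
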