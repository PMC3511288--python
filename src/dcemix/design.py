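"""Efficient pairwise choice-set design.

A discrete choice experiment (DCE) presents respondents with a series of
pairwise choice tasks ("Medication A" vs "Medication B"), each alternative
described by the same set of attributes (factors) at varying levels.  This
module generates statistically efficient, level-balanced designs for a linear
multinomial-logit (MNL) utility, blocks them into survey versions, and embeds
the two standard validity tasks: a *repeat* of an earlier task (consistency)
and a *dominance* task in which one alternative is at least as good on every
attribute (monotonicity).

Efficiency is measured by the D-error

    D = det(I(beta)^-1)^(1/K)

where ``I`` is the Fisher information of the MNL model accumulated over the
design's tasks and ``K`` the number of coefficients.  Smaller is better.  By
default the priors are zero (utility-neutral design), the conventional choice
when no pilot estimates exist.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DominanceConstructionError,
    InvalidSpecificationError,
    SingularDesignError,
    UnderIdentifiedDesignError,
)

Profile = dict[str, float]

ROLE_DESIGN = "design"
ROLE_REPEAT = "repeat"
ROLE_DOMINANCE = "dominance"


@dataclass(frozen=True)
class FactorSpec:
    """One attribute of the hypothetical alternatives.

    Parameters
    ----------
    name
        Short identifier used as a column name throughout the package.
    levels
        Ordered numeric level values in the attribute's natural units
        (dollars/month, doses/day, %, severity score, ...). Strictly
        increasing, at least two.
    direction
        Expected utility direction: ``+1`` higher-is-preferred, ``-1``
        lower-is-preferred, ``0`` no prior expectation.
    description
        Free text shown to humans only.
    """

    name: str
    levels: tuple[float, ...]
    direction: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidSpecificationError("factor name must be non-empty")
        levels = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise InvalidSpecificationError(
                f"factor {self.name!r} needs >= 2 levels, got {len(levels)}"
            )
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise InvalidSpecificationError(
                f"levels of factor {self.name!r} must be strictly increasing"
            )
        if self.direction not in (-1, 0, 1):
            raise InvalidSpecificationError(
                f"direction of factor {self.name!r} must be -1, 0 or +1"
            )

    @property
    def level_range(self) -> float:
        return self.levels[-1] - self.levels[0]

    @property
    def best_level(self) -> float:
        """Most-preferred level under the expected direction."""
        if self.direction == 0:
            raise InvalidSpecificationError(
                f"factor {self.name!r} has no preference direction"
            )
        return self.levels[-1] if self.direction == 1 else self.levels[0]

    @property
    def worst_level(self) -> float:
        if self.direction == 0:
            raise InvalidSpecificationError(
                f"factor {self.name!r} has no preference direction"
            )
        return self.levels[0] if self.direction == 1 else self.levels[-1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": list(self.levels),
            "direction": self.direction,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(
            name=d["name"],
            levels=tuple(d["levels"]),
            direction=int(d.get("direction", 0)),
            description=d.get("description", ""),
        )


@dataclass(frozen=True)
class ChoiceTask:
    """One pairwise choice set: exactly two complete attribute profiles."""

    task_id: str
    block: int
    role: str
    alternatives: tuple[Profile, Profile]
    repeat_of: str | None = None  # original task id, when role == "repeat"

    def __post_init__(self) -> None:
        if self.role not in (ROLE_DESIGN, ROLE_REPEAT, ROLE_DOMINANCE):
            raise InvalidSpecificationError(f"unknown task role {self.role!r}")
        if len(self.alternatives) != 2:
            raise InvalidSpecificationError(
                f"task {self.task_id!r} must have exactly 2 alternatives"
            )

    def to_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "block": self.block,
            "role": self.role,
            "alternatives": [dict(a) for a in self.alternatives],
            "repeat_of": self.repeat_of,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChoiceTask":
        return cls(
            task_id=d["task_id"],
            block=int(d["block"]),
            role=d["role"],
            alternatives=(dict(d["alternatives"][0]), dict(d["alternatives"][1])),
            repeat_of=d.get("repeat_of"),
        )


@dataclass
class ChoiceDesign:
    """A blocked set of pairwise choice tasks.

    ``n_blocks`` survey versions; each respondent sees one block.  After
    :func:`add_validity_tasks` every block carries one repeat and one
    dominance task on top of its design-role tasks.
    """

    factors: list[FactorSpec]
    tasks: list[ChoiceTask]
    n_blocks: int
    d_error: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def tasks_in_block(self, block: int, role: str | None = None) -> list[ChoiceTask]:
        return [
            t
            for t in self.tasks
            if t.block == block and (role is None or t.role == role)
        ]

    def design_tasks(self) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.role == ROLE_DESIGN]

    def factor(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def balance_report(self):
        """Level-occurrence counts across design-role tasks.

        Returns a DataFrame with one row per factor x level, the observed
        count over both alternatives of every design task, the ideal
        (perfectly balanced) count, and a flag for deviations greater than
        one occurrence.
        """
        import pandas as pd

        rows = []
        tasks = self.design_tasks()
        n_slots = 2 * len(tasks)
        for f in self.factors:
            ideal = n_slots / len(f.levels)
            for lv in f.levels:
                count = sum(
                    1
                    for t in tasks
                    for alt in t.alternatives
                    if alt[f.name] == lv
                )
                rows.append(
                    {
                        "factor": f.name,
                        "level": lv,
                        "count": count,
                        "ideal": ideal,
                        "flag": abs(count - ideal) > 1,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "factors": [f.to_dict() for f in self.factors],
            "tasks": [t.to_dict() for t in self.tasks],
            "n_blocks": self.n_blocks,
            "d_error": self.d_error,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChoiceDesign":
        return cls(
            factors=[FactorSpec.from_dict(f) for f in d["factors"]],
            tasks=[ChoiceTask.from_dict(t) for t in d["tasks"]],
            n_blocks=int(d["n_blocks"]),
            d_error=d.get("d_error"),
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# profile enumeration and dominance
# ---------------------------------------------------------------------------


def enumerate_full_factorial(factors: list[FactorSpec]) -> list[Profile]:
    """All distinct complete factor-to-level assignments.

    The size is the product of the level counts; for eight 4-level factors
    this is 65536 profiles, so call this for bookkeeping and small designs,
    not as a search space to scan exhaustively.
    """
    if not factors:
        raise InvalidSpecificationError("factor list is empty")
    names = [f.name for f in factors]
    out = []
    for combo in itertools.product(*(f.levels for f in factors)):
        out.append(dict(zip(names, combo)))
    return out


def dominates(a: Profile, b: Profile, factors: list[FactorSpec]) -> bool:
    """True if profile ``a`` weakly dominates ``b`` with at least one strict
    improvement, under the factors' expected directions.

    Factors with no direction (0) must be equal in both profiles for the
    comparison to hold; otherwise the profiles are incomparable.
    """
    strict = False
    for f in factors:
        va, vb = a[f.name], b[f.name]
        if f.direction == 0:
            if va != vb:
                return False
            continue
        diff = f.direction * (va - vb)
        if diff < 0:
            return False
        if diff > 0:
            strict = True
    return strict


# ---------------------------------------------------------------------------
# D-error
# ---------------------------------------------------------------------------


def _information_matrix(
    design: ChoiceDesign, priors: np.ndarray, roles: tuple[str, ...] = (ROLE_DESIGN,)
) -> np.ndarray:
    """MNL Fisher information over the design's tasks at coefficient ``priors``.

    I = sum_tasks sum_j p_j (x_j - xbar)(x_j - xbar)'   with
    p_j = exp(x_j'b) / sum_k exp(x_k'b),  xbar = sum_j p_j x_j.
    """
    names = design.factor_names
    K = len(names)
    info = np.zeros((K, K))
    for t in design.tasks:
        if t.role not in roles:
            continue
        X = np.array([[alt[n] for n in names] for alt in t.alternatives])
        v = X @ priors
        v -= v.max()
        p = np.exp(v)
        p /= p.sum()
        xbar = p @ X
        Xc = X - xbar
        info += (Xc * p[:, None]).T @ Xc
    return info


def d_error(
    design: ChoiceDesign,
    priors: np.ndarray | list[float] | None = None,
    roles: tuple[str, ...] = (ROLE_DESIGN,),
) -> float:
    """D-error of the design at the given coefficient priors (default zero).

    det(I^-1)^(1/K); lower values mean a more informative design.  Raises
    :class:`SingularDesignError` when some coefficient carries no information
    (e.g. a factor constant across all alternatives of all tasks).
    """
    K = len(design.factors)
    if priors is None:
        priors = np.zeros(K)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (K,):
        raise InvalidSpecificationError(
            f"priors must have one value per factor ({K}), got shape {priors.shape}"
        )
    if not any(t.role in roles for t in design.tasks):
        raise InvalidSpecificationError("design has no tasks in the requested roles")
    info = _information_matrix(design, priors, roles)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        raise SingularDesignError(
            "singular information matrix: some coefficient is not identified "
            "by this design"
        )
    return float(np.exp(-logdet / K))


# ---------------------------------------------------------------------------
# design search
# ---------------------------------------------------------------------------


def _balanced_columns(
    factors: list[FactorSpec], n_slots: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One shuffled, level-balanced column of length n_slots per factor."""
    cols = {}
    for f in factors:
        reps = -(-n_slots // len(f.levels))  # ceil
        col = np.tile(np.asarray(f.levels, dtype=float), reps)[:n_slots]
        rng.shuffle(col)
        cols[f.name] = col
    return cols


def _tasks_from_columns(
    factors: list[FactorSpec], cols: dict[str, np.ndarray], n_tasks: int
) -> list[ChoiceTask]:
    tasks = []
    for i in range(n_tasks):
        alts = tuple(
            {f.name: float(cols[f.name][2 * i + j]) for f in factors} for j in range(2)
        )
        tasks.append(
            ChoiceTask(task_id=f"T{i + 1:02d}", block=0, role=ROLE_DESIGN, alternatives=alts)
        )
    return tasks


def _try_d_error(design: ChoiceDesign, priors: np.ndarray) -> float:
    try:
        return d_error(design, priors)
    except SingularDesignError:
        return np.inf


def _assign_blocks(
    factors: list[FactorSpec], tasks: list[ChoiceTask], n_blocks: int
) -> list[ChoiceTask]:
    """Greedy block assignment approximately equalising per-block level counts.

    Tasks are visited in index order; each goes to the block (among those
    with the fewest tasks, ties broken by block index) that minimises the
    squared deviation of its level counts from perfect balance.
    """
    per_block = len(tasks) // n_blocks
    counts = {
        b: {f.name: {lv: 0 for lv in f.levels} for f in factors}
        for b in range(n_blocks)
    }
    sizes = dict.fromkeys(range(n_blocks), 0)
    ideal = {f.name: 2 * per_block / len(f.levels) for f in factors}
    out = []
    for t in tasks:
        open_blocks = [b for b in range(n_blocks) if sizes[b] < per_block]
        min_size = min(sizes[b] for b in open_blocks)
        candidates = [b for b in open_blocks if sizes[b] == min_size]
        best_b, best_cost = None, None
        for b in candidates:
            cost = 0.0
            for f in factors:
                for alt in t.alternatives:
                    lv = alt[f.name]
                    cost += (counts[b][f.name][lv] + 1 - ideal[f.name]) ** 2
            if best_cost is None or cost < best_cost:
                best_b, best_cost = b, cost
        for f in factors:
            for alt in t.alternatives:
                counts[best_b][f.name][alt[f.name]] += 1
        sizes[best_b] += 1
        out.append(replace(t, block=best_b))
    return out


def generate_efficient_design(
    factors: list[FactorSpec],
    n_tasks: int,
    n_blocks: int,
    priors: np.ndarray | list[float] | None = None,
    n_iter: int = 2000,
    seed: int | None = None,
) -> ChoiceDesign:
    """Search for a low-D-error, level-balanced pairwise design.

    The start design assigns each factor a shuffled level-balanced column
    over the ``2 * n_tasks`` alternative slots.  The search then repeatedly
    proposes swapping two slots of one factor's column — a move that keeps
    the column's level counts intact — and accepts the swap when it strictly
    lowers the D-error at ``priors``.  Deterministic given ``seed``.
    """
    if not factors:
        raise InvalidSpecificationError("factor list is empty")
    K = len(factors)
    if n_tasks < K:
        raise UnderIdentifiedDesignError(
            f"{n_tasks} tasks cannot identify {K} coefficients"
        )
    if n_blocks < 1 or n_tasks % n_blocks:
        raise InvalidSpecificationError(
            f"n_tasks={n_tasks} must be a positive multiple of n_blocks={n_blocks}"
        )
    if priors is None:
        priors = np.zeros(K)
    priors = np.asarray(priors, dtype=float)
    rng = np.random.default_rng(seed)
    n_slots = 2 * n_tasks

    cols = _balanced_columns(factors, n_slots, rng)
    tasks = _tasks_from_columns(factors, cols, n_tasks)
    current = ChoiceDesign(factors=list(factors), tasks=tasks, n_blocks=n_blocks)
    current_err = _try_d_error(current, priors)
    start_err = current_err

    names = [f.name for f in factors]
    for _ in range(int(n_iter)):
        fname = names[rng.integers(K)]
        i, j = rng.integers(n_slots, size=2)
        if i == j or cols[fname][i] == cols[fname][j]:
            continue
        cols[fname][i], cols[fname][j] = cols[fname][j], cols[fname][i]
        cand_tasks = _tasks_from_columns(factors, cols, n_tasks)
        cand = ChoiceDesign(factors=list(factors), tasks=cand_tasks, n_blocks=n_blocks)
        cand_err = _try_d_error(cand, priors)
        if cand_err < current_err:
            current, current_err = cand, cand_err
        else:  # revert
            cols[fname][i], cols[fname][j] = cols[fname][j], cols[fname][i]

    if not np.isfinite(current_err):
        raise SingularDesignError(
            "search could not reach a non-singular design; "
            "increase n_tasks or n_iter"
        )
    blocked = _assign_blocks(factors, current.tasks, n_blocks)
    return ChoiceDesign(
        factors=list(factors),
        tasks=blocked,
        n_blocks=n_blocks,
        d_error=current_err,
        meta={
            "seed": seed,
            "n_iter": int(n_iter),
            "start_d_error": None if not np.isfinite(start_err) else float(start_err),
            "priors": priors.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# validity tasks
# ---------------------------------------------------------------------------


def _make_dominance_task(
    factors: list[FactorSpec],
    template: Profile,
    task_id: str,
    block: int,
) -> ChoiceTask:
    """Dominant alternative = template with every directional factor at its
    best level; direction-0 factors are held equal across both alternatives."""
    directional = [f for f in factors if f.direction != 0]
    if not directional:
        raise DominanceConstructionError(
            "cannot construct a dominance task: no factor has a preference direction"
        )
    dominated = dict(template)
    dominant = dict(template)
    for f in directional:
        dominant[f.name] = f.best_level
    if all(dominant[f.name] == dominated[f.name] for f in directional):
        # template already direction-best everywhere; worsen one factor of the
        # dominated side to keep the dominance strict
        f = directional[0]
        dominated[f.name] = f.worst_level
    return ChoiceTask(
        task_id=task_id,
        block=block,
        role=ROLE_DOMINANCE,
        alternatives=(dominant, dominated),
    )


def add_validity_tasks(
    design: ChoiceDesign, seed: int | None = None, swap_repeat: bool = False
) -> ChoiceDesign:
    """Append one repeat and one dominance task to every block.

    The repeat duplicates a randomly chosen design task of the block (with
    the alternative order reversed when ``swap_repeat``); the dominance task
    is built from a randomly chosen design profile with one alternative set
    to its direction-best level on every directional factor.  Existing tasks
    are never modified.
    """
    if all(f.direction == 0 for f in design.factors):
        raise DominanceConstructionError(
            "cannot construct dominance tasks: all factors have direction 0"
        )
    rng = np.random.default_rng(seed)
    new_tasks = list(design.tasks)
    for b in range(design.n_blocks):
        block_tasks = design.tasks_in_block(b, ROLE_DESIGN)
        if not block_tasks:
            raise InvalidSpecificationError(f"block {b} has no design tasks")
        src = block_tasks[rng.integers(len(block_tasks))]
        alts = src.alternatives[::-1] if swap_repeat else src.alternatives
        new_tasks.append(
            ChoiceTask(
                task_id=f"{src.task_id}R",
                block=b,
                role=ROLE_REPEAT,
                alternatives=(dict(alts[0]), dict(alts[1])),
                repeat_of=src.task_id,
            )
        )
        tmpl_task = block_tasks[rng.integers(len(block_tasks))]
        template = dict(tmpl_task.alternatives[rng.integers(2)])
        new_tasks.append(
            _make_dominance_task(
                design.factors, template, task_id=f"D{b + 1}", block=b
            )
        )
    return ChoiceDesign(
        factors=list(design.factors),
        tasks=new_tasks,
        n_blocks=design.n_blocks,
        d_error=design.d_error,
        meta={**design.meta, "validity_tasks": True, "swap_repeat": swap_repeat},
    )
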