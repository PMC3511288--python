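"""Panel mixed multinomial logit by maximum simulated likelihood.

Model
-----
Respondent i derives utility ``U_ij = V_ij + e_ij`` from alternative j of a
pairwise task, with i.i.d. extreme-value noise ``e`` and systematic part

    V_ij = alpha * 1[j = A] + beta_i' x_ij + gamma' (c_i * x_ij)

where ``beta_i`` varies across respondents according to per-coefficient
mixing distributions (fixed, normal, or sign-constrained triangular) and the
interaction terms ``gamma`` shift attribute sensitivity by binary respondent
covariates ``c_i`` (e.g. cost x private health insurance).  Because one draw
of ``beta_i`` governs all of a respondent's tasks (the panel structure), the
likelihood contribution of respondent i is an integral over the mixing
distribution of a *product* of task-level logit probabilities:

    L_i = E_beta [ prod_t P_it(chosen | beta) ].

Maximum simulated likelihood replaces the integral with an average over R
draws — here Halton (low-discrepancy) sequences by default, which reach a
given simulation accuracy with far fewer draws than pseudo-random numbers:

    LL = sum_i log( (1/R) sum_r prod_t P_it(chosen | beta_i^(r)) ).

Coefficient transforms: a normal coefficient is ``m + s * ndtri(u)``; a
constrained-triangular coefficient is ``m * T(u)`` with ``T`` the inverse CDF
of the symmetric triangular distribution on [0, 2] (mode 1), so every draw
lies in [0, 2m] and keeps the sign of the mean — one free parameter, used for
cost coefficients that must not change sign.

The optimizer maximises the simulated log-likelihood with analytic gradients;
standard errors come from the numerical Hessian of the simulated
log-likelihood (finite differences of the analytic gradient), or optionally
from the BHHH outer-product or the robust sandwich.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import (
    DataValidationError,
    IdentificationError,
    InvalidSpecificationError,
)
from .simulate import (
    ASC_NAME,
    MIXING_FIXED,
    MIXING_NORMAL,
    MIXING_TRIANGULAR,
    ChoiceDataset,
)

# first 25 primes: supports up to 25 random coefficients
_PRIMES = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
    53, 59, 61, 67, 71, 73, 79, 83, 89, 97,
)

#: probability floor applied (in the log domain) before summing task
#: log-probabilities; hits are counted and reported as a diagnostic.
PROB_FLOOR = 1e-300
_LOG_FLOOR = math.log(PROB_FLOOR)

DRAW_HALTON = "halton"
DRAW_PSEUDO = "pseudo_random"


# ---------------------------------------------------------------------------
# Halton draws
# ---------------------------------------------------------------------------


def _radical_inverse(indices: np.ndarray, base: int) -> np.ndarray:
    """Van der Corput radical inverse of integer indices in the given base."""
    result = np.zeros(len(indices), dtype=float)
    f = 1.0 / base
    i = indices.astype(np.int64).copy()
    while i.any():
        result += (i % base) * f
        i //= base
        f /= base
    return result


def halton_draws(
    dimension: int,
    n_draws: int,
    n_respondents: int = 1,
    discard: int = 10,
    permutation_seed: int | None = None,
) -> np.ndarray:
    """Halton points in (0,1), shaped (n_respondents, n_draws, dimension).

    Dimension d uses the d-th prime base.  The first ``discard`` points of
    each sequence are dropped (burn-in against the start-up correlation of
    high-base sequences), then the sequence is cut into consecutive
    per-respondent blocks so every respondent gets a distinct sub-sequence.
    With ``permutation_seed`` the pooled sequence of each dimension is
    independently shuffled (randomised Halton).
    """
    if dimension < 1:
        raise InvalidSpecificationError("dimension must be >= 1")
    if dimension > len(_PRIMES):
        raise InvalidSpecificationError(
            f"unsupported dimension {dimension}: prime table has {len(_PRIMES)} bases"
        )
    if n_draws < 1 or n_respondents < 1:
        raise InvalidSpecificationError("n_draws and n_respondents must be >= 1")
    total = n_draws * n_respondents
    indices = np.arange(discard + 1, discard + total + 1)
    rng = (
        np.random.default_rng(permutation_seed)
        if permutation_seed is not None
        else None
    )
    out = np.empty((n_respondents, n_draws, dimension))
    for d in range(dimension):
        seq = _radical_inverse(indices, _PRIMES[d])
        if rng is not None:
            rng.shuffle(seq)
        out[:, :, d] = seq.reshape(n_respondents, n_draws)
    return out


def _triangular_ppf01(u: np.ndarray) -> np.ndarray:
    """Inverse CDF of the symmetric triangular distribution on [0, 2]."""
    u = np.asarray(u)
    lo = np.sqrt(2.0 * u)
    hi = 2.0 - np.sqrt(2.0 * (1.0 - u))
    return np.where(u <= 0.5, lo, hi)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedLogitSpec:
    """What to estimate: attributes, mixing, interactions, draw settings.

    ``mixing`` maps coefficient names (attributes or ``"asc"``) to
    ``"fixed"`` (default for unlisted names), ``"normal"`` or
    ``"triangular"``; interaction coefficients are always fixed.
    """

    attributes: tuple[str, ...]
    mixing: dict = field(default_factory=dict)
    include_asc: bool = True
    interactions: tuple[tuple[str, str], ...] = ()
    n_draws: int = 1000
    draw_type: str = DRAW_HALTON
    halton_discard: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(
            self, "interactions", tuple((a, c) for a, c in self.interactions)
        )
        if not self.attributes and not self.include_asc:
            raise InvalidSpecificationError("no coefficients to estimate")
        if self.n_draws < 1:
            raise InvalidSpecificationError("n_draws must be >= 1")
        if self.draw_type not in (DRAW_HALTON, DRAW_PSEUDO):
            raise InvalidSpecificationError(f"unknown draw_type {self.draw_type!r}")
        valid_targets = set(self.attributes) | {ASC_NAME}
        for name, kind in self.mixing.items():
            if name not in valid_targets:
                raise InvalidSpecificationError(
                    f"mixing given for unknown coefficient {name!r}"
                )
            if kind not in (MIXING_FIXED, MIXING_NORMAL, MIXING_TRIANGULAR):
                raise InvalidSpecificationError(f"unknown mixing kind {kind!r}")
        for attr, _cov in self.interactions:
            if attr != ASC_NAME and attr not in self.attributes:
                raise InvalidSpecificationError(
                    f"interaction on unknown attribute {attr!r}"
                )

    def coefficient_names(self) -> list[str]:
        names = ([ASC_NAME] if self.include_asc else []) + list(self.attributes)
        names += [f"{a}:{c}" for a, c in self.interactions]
        return names

    def mixing_of(self, name: str) -> str:
        if ":" in name:  # interaction terms are always fixed
            return MIXING_FIXED
        return self.mixing.get(name, MIXING_FIXED)

    def random_coefficients(self) -> list[str]:
        return [
            n for n in self.coefficient_names()
            if self.mixing_of(n) != MIXING_FIXED
        ]

    def normal_coefficients(self) -> list[str]:
        return [
            n for n in self.coefficient_names()
            if self.mixing_of(n) == MIXING_NORMAL
        ]

    def param_names(self) -> list[str]:
        """Flat parameter layout: all means, then sds of normal coefficients."""
        return [f"mean:{n}" for n in self.coefficient_names()] + [
            f"sd:{n}" for n in self.normal_coefficients()
        ]

    def n_parameters(self) -> int:
        return len(self.param_names())

    def to_dict(self) -> dict:
        return {
            "attributes": list(self.attributes),
            "mixing": dict(self.mixing),
            "include_asc": self.include_asc,
            "interactions": [list(p) for p in self.interactions],
            "n_draws": self.n_draws,
            "draw_type": self.draw_type,
            "halton_discard": self.halton_discard,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _Prep:
    """Rectangularised estimation arrays.

    Xd : (n, T, K) attribute differences A - B per coefficient column
    y  : (n, T) 1 when alternative A was chosen
    mask : (n, T) 1 for real observations, 0 for padding
    """

    Xd: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    names: list[str]
    respondent_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.Xd.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def _prepare(
    spec: MixedLogitSpec,
    data: ChoiceDataset,
    roles=None,
    check_identification: bool = False,
) -> _Prep:
    df = data.choices
    required = {"respondent", "task", "alternative", "chosen"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"choice table missing columns {sorted(missing)}")
    for a in spec.attributes:
        if a not in df.columns:
            raise DataValidationError(f"attribute column {a!r} not in choice table")
    if roles is not None:
        if "role" not in df.columns:
            raise DataValidationError("role filter requested but no 'role' column")
        df = df[df["role"].isin(roles)]
        if df.empty:
            raise DataValidationError(f"no rows with role in {roles!r}")

    df = df.sort_values(["respondent", "task", "alternative"], kind="mergesort")
    a_rows = df[df["alternative"] == "A"].reset_index(drop=True)
    b_rows = df[df["alternative"] == "B"].reset_index(drop=True)
    if len(a_rows) != len(b_rows) or not (
        (a_rows["respondent"].values == b_rows["respondent"].values).all()
        and (a_rows["task"].values == b_rows["task"].values).all()
    ):
        raise DataValidationError(
            "each respondent x task must have exactly one 'A' and one 'B' row"
        )
    if not ((a_rows["chosen"].values + b_rows["chosen"].values) == 1).all():
        raise DataValidationError("exactly one alternative must be chosen per task")

    attrs = list(spec.attributes)
    diff = a_rows[attrs].to_numpy(dtype=float) - b_rows[attrs].to_numpy(dtype=float)
    if not np.isfinite(diff).all():
        raise DataValidationError("non-numeric or missing attribute values")
    y_flat = a_rows["chosen"].to_numpy(dtype=float)
    resp_flat = a_rows["respondent"].to_numpy()

    # interaction columns: attribute difference scaled by the respondent's
    # covariate value; missing covariates are an explicit error
    inter_cols = []
    for attr, cov in spec.interactions:
        if cov not in data.covariates.columns:
            raise DataValidationError(f"covariate {cov!r} not in covariate table")
        cov_series = data.covariates[cov].reindex(resp_flat)
        if cov_series.isna().any():
            bad = resp_flat[cov_series.isna().to_numpy()][:5]
            raise DataValidationError(
                f"covariate {cov!r} missing for respondents {list(bad)}"
            )
        cov_vals = cov_series.to_numpy(dtype=float)
        if attr == ASC_NAME:
            base = np.ones(len(a_rows))
        else:
            base = diff[:, attrs.index(attr)]
        inter_cols.append(base * cov_vals)

    names = spec.coefficient_names()
    cols = []
    if spec.include_asc:
        cols.append(np.ones(len(a_rows)))
    cols.extend(diff[:, j] for j in range(len(attrs)))
    cols.extend(inter_cols)
    X_flat = np.column_stack(cols)

    resp_ids = np.unique(resp_flat)
    counts = pd.Series(resp_flat).value_counts()
    T = int(counts.max())
    n = len(resp_ids)
    K = X_flat.shape[1]
    Xd = np.zeros((n, T, K))
    y = np.zeros((n, T))
    mask = np.zeros((n, T))
    pos = {r: 0 for r in resp_ids}
    row_of = {r: i for i, r in enumerate(resp_ids)}
    for k in range(len(resp_flat)):
        r = resp_flat[k]
        i, t = row_of[r], pos[r]
        Xd[i, t] = X_flat[k]
        y[i, t] = y_flat[k]
        mask[i, t] = 1.0
        pos[r] = t + 1

    if check_identification:
        # every estimated coefficient's column must vary somewhere
        for j, name in enumerate(names):
            if name == ASC_NAME:
                continue
            if np.abs(Xd[:, :, j] * mask).max() == 0.0:
                raise IdentificationError(
                    f"coefficient {name!r} is not identified: its attribute never "
                    "differs between the alternatives of any task"
                )
    return _Prep(Xd=Xd, y=y, mask=mask, names=names, respondent_ids=resp_ids)


# ---------------------------------------------------------------------------
# simulated likelihood core
# ---------------------------------------------------------------------------


def _build_draws(spec: MixedLogitSpec, n_respondents: int) -> np.ndarray | None:
    """Uniform draws (n, R, n_random) feeding the mixing transforms."""
    k_rand = len(spec.random_coefficients())
    if k_rand == 0:
        return None
    if spec.draw_type == DRAW_HALTON:
        return halton_draws(
            k_rand, spec.n_draws, n_respondents, discard=spec.halton_discard
        )
    rng = np.random.default_rng(spec.seed)
    u = rng.random((n_respondents, spec.n_draws, k_rand))
    # keep strictly inside (0,1) for the ndtri transform
    return np.clip(u, 1e-12, 1.0 - 1e-12)


@dataclass
class _Transforms:
    """Precomputed draw transforms, constant across optimizer iterations."""

    z: np.ndarray | None  # ndtri(u) columns for normal coefficients (n,R,#normal)
    tri: np.ndarray | None  # triangular ppf columns (n,R,#triangular)
    normal_idx: list[int]  # coefficient indices with normal mixing
    tri_idx: list[int]  # coefficient indices with triangular mixing


def _make_transforms(spec: MixedLogitSpec, u: np.ndarray | None) -> _Transforms:
    names = spec.coefficient_names()
    rand = spec.random_coefficients()
    normal_idx, tri_idx = [], []
    z_cols, tri_cols = [], []
    for pos, name in enumerate(rand):
        j = names.index(name)
        if spec.mixing_of(name) == MIXING_NORMAL:
            normal_idx.append(j)
            z_cols.append(special.ndtri(u[:, :, pos]))
        else:
            tri_idx.append(j)
            tri_cols.append(_triangular_ppf01(u[:, :, pos]))
    z = np.stack(z_cols, axis=-1) if z_cols else None
    tri = np.stack(tri_cols, axis=-1) if tri_cols else None
    return _Transforms(z=z, tri=tri, normal_idx=normal_idx, tri_idx=tri_idx)


def _unpack(spec: MixedLogitSpec, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = len(spec.coefficient_names())
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_parameters(),):
        raise InvalidSpecificationError(
            f"expected {spec.n_parameters()} parameters, got {params.shape}"
        )
    return params[:K], params[K:]


def _beta_draws(
    spec: MixedLogitSpec, tf: _Transforms, means: np.ndarray, sds: np.ndarray,
    n: int,
) -> np.ndarray:
    """Per-respondent, per-draw coefficient vectors (n, R, K)."""
    R = spec.n_draws if (tf.z is not None or tf.tri is not None) else 1
    beta = np.broadcast_to(means, (n, R, len(means))).copy()
    for pos, j in enumerate(tf.normal_idx):
        beta[:, :, j] = means[j] + sds[pos] * tf.z[:, :, pos]
    for pos, j in enumerate(tf.tri_idx):
        beta[:, :, j] = means[j] * tf.tri[:, :, pos]
    return beta


def _core(prep: _Prep, beta: np.ndarray, want_grad: bool):
    """Simulated panel log-likelihood pieces for given coefficient draws.

    Returns (ll, ll_i, W, G, floor_hits) where W are the per-respondent draw
    weights softmax_r(Lambda_ir) and G = dLambda/dbeta (n,R,K); W and G are
    None when want_grad is False.
    """
    V = np.einsum("ntk,nrk->nrt", prep.Xd, beta)
    q = (2.0 * prep.y - 1.0)[:, None, :]
    logP = special.log_expit(q * V)
    floor_hits = int((logP < _LOG_FLOOR).sum())
    if floor_hits:
        logP = np.maximum(logP, _LOG_FLOOR)
    logP = logP * prep.mask[:, None, :]
    Lam = logP.sum(axis=2)  # (n, R)
    R = Lam.shape[1]
    ll_i = special.logsumexp(Lam, axis=1) - math.log(R)
    ll = float(ll_i.sum())
    if not want_grad:
        return ll, ll_i, None, None, floor_hits
    W = special.softmax(Lam, axis=1)
    g = special.expit(-q * V) * q * prep.mask[:, None, :]
    G = np.einsum("nrt,ntk->nrk", g, prep.Xd)
    return ll, ll_i, W, G, floor_hits


def _ll_and_scores(
    spec: MixedLogitSpec, prep: _Prep, tf: _Transforms, params: np.ndarray,
    want_grad: bool = True,
):
    """Log-likelihood, per-respondent score matrix (n, P), floor hits."""
    means, sds = _unpack(spec, params)
    beta = _beta_draws(spec, tf, means, sds, prep.n)
    ll, _ll_i, W, G, floor_hits = _core(prep, beta, want_grad)
    if not want_grad:
        return ll, None, floor_hits
    # d beta / d mean: 1 except triangular columns, where it is the ppf draw
    D = np.ones_like(G)
    for pos, j in enumerate(tf.tri_idx):
        D[:, :, j] = tf.tri[:, :, pos]
    score_m = np.einsum("nr,nrk->nk", W, G * D)
    pieces = [score_m]
    if tf.normal_idx:
        GS = np.stack(
            [G[:, :, j] * tf.z[:, :, pos] for pos, j in enumerate(tf.normal_idx)],
            axis=-1,
        )
        pieces.append(np.einsum("nr,nrj->nj", W, GS))
    scores = np.concatenate(pieces, axis=1)
    return ll, scores, floor_hits


def panel_simulated_loglik(
    spec: MixedLogitSpec,
    data: ChoiceDataset,
    params: np.ndarray | list[float],
    roles=None,
) -> float:
    """Simulated panel log-likelihood at a flat parameter vector.

    The layout follows ``spec.param_names()``: all coefficient means first,
    then the standard deviations of the normally-mixed coefficients.  With
    every mixing spread zero (or no random coefficients) this equals the
    analytic conditional-logit log-likelihood.
    """
    prep = _prepare(spec, data, roles)
    u = _build_draws(spec, prep.n)
    tf = _make_transforms(spec, u)
    ll, _, _ = _ll_and_scores(spec, prep, tf, np.asarray(params, float), want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class EstimationResult:
    """Fitted panel mixed logit.

    ``means``/``spreads`` are point estimates by coefficient name (spreads:
    sd for normal mixing, |mean| for constrained triangular); ``se_*``,
    ``z_*`` and ``p_*`` the matching asymptotic normal inference.  ``params``
    is the raw optimizer vector (layout ``spec.param_names()``), kept so
    downstream analytics can rebuild draws exactly.
    """

    spec: MixedLogitSpec
    params: np.ndarray
    cov: np.ndarray | None
    loglik: float
    n_obs: int
    n_respondents: int
    converged: bool
    grad_norm: float
    n_iter: int
    floor_hits: int
    se_method: str
    roles: tuple | None = None

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters()

    def _se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(self.n_parameters, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def _table(self) -> pd.DataFrame:
        names = self.spec.param_names()
        est = self.params.copy()
        # normal sds are identified up to sign: report magnitudes
        for i, nm in enumerate(names):
            if nm.startswith("sd:"):
                est[i] = abs(est[i])
        se = self._se()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        p = 2.0 * special.ndtr(-np.abs(z))
        return pd.DataFrame(
            {"parameter": names, "estimate": est, "se": se, "z": z, "p": p}
        )

    @property
    def means(self) -> dict[str, float]:
        K = len(self.spec.coefficient_names())
        return dict(zip(self.spec.coefficient_names(), self.params[:K].tolist()))

    @property
    def spreads(self) -> dict[str, float]:
        """Heterogeneity scale per random coefficient."""
        out = {}
        K = len(self.spec.coefficient_names())
        sds = self.params[K:]
        for pos, name in enumerate(self.spec.normal_coefficients()):
            out[name] = abs(float(sds[pos]))
        for name in self.spec.random_coefficients():
            if self.spec.mixing_of(name) == MIXING_TRIANGULAR:
                out[name] = abs(self.means[name])
        return out

    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names(), self._se().tolist()))

    def p_values(self) -> dict[str, float]:
        t = self._table()
        return dict(zip(t["parameter"], t["p"]))

    def summary(self) -> str:
        t = self._table()
        lines = [
            "Panel mixed multinomial logit (maximum simulated likelihood)",
            f"  respondents: {self.n_respondents}   choice observations: {self.n_obs}",
            f"  draws: {self.spec.n_draws} ({self.spec.draw_type})   "
            f"parameters: {self.n_parameters}",
            f"  log-likelihood: {self.loglik:.4f}   converged: {self.converged} "
            f"(grad norm {self.grad_norm:.2e}, {self.n_iter} iterations)",
            "",
            f"  {'parameter':28s} {'estimate':>12s} {'se':>10s} {'z':>8s} {'p':>8s}",
        ]
        for _, r in t.iterrows():
            lines.append(
                f"  {r['parameter']:28s} {r['estimate']:12.5f} {r['se']:10.5f} "
                f"{r['z']:8.3f} {r['p']:8.4f}"
            )
        if self.floor_hits:
            lines.append(f"  [diagnostic] probability floor hit {self.floor_hits} times")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        t = self._table()
        return {
            "spec": self.spec.to_dict(),
            "coefficients": t.to_dict(orient="records"),
            "means": self.means,
            "spreads": self.spreads,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_respondents": self.n_respondents,
            "n_parameters": self.n_parameters,
            "converged": bool(self.converged),
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "floor_hits": self.floor_hits,
            "se_method": self.se_method,
        }


def _numerical_hessian(fun_grad, x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient callable."""
    P = len(x)
    H = np.zeros((P, P))
    for j in range(P):
        h = 1e-5 * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (fun_grad(xp) - fun_grad(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(
    spec: MixedLogitSpec,
    data: ChoiceDataset,
    start: np.ndarray | list[float] | None = None,
    se_method: str = "hessian",
    gtol: float = 1e-5,
    maxiter: int = 500,
    roles=None,
) -> EstimationResult:
    """Maximum simulated likelihood fit of the panel mixed logit.

    Parameters
    ----------
    start
        Flat start vector (layout ``spec.param_names()``).  Default: zeros
        for means, 0.1 for normal standard deviations.
    se_method
        ``"hessian"`` (numerical Hessian of the simulated log-likelihood,
        default), ``"bhhh"`` (outer product of per-respondent scores),
        ``"sandwich"`` (H^-1 B H^-1) or ``"none"``.
    gtol
        Convergence threshold on the infinity norm of the *per-respondent*
        average gradient; the ``converged`` flag reports this criterion
        honestly rather than echoing the optimizer.
    roles
        Optional task-role filter, e.g. ``("design",)`` to drop validity
        tasks from estimation.  Default: all tasks.

    Deterministic: the same spec (including its seed and draw settings) and
    data always produce the same result.
    """
    if se_method not in ("hessian", "bhhh", "sandwich", "none"):
        raise InvalidSpecificationError(f"unknown se_method {se_method!r}")
    prep = _prepare(spec, data, roles, check_identification=True)
    u = _build_draws(spec, prep.n)
    tf = _make_transforms(spec, u)
    P = spec.n_parameters()
    K = len(spec.coefficient_names())
    if start is None:
        x0 = np.zeros(P)
        x0[K:] = 0.1
    else:
        x0 = np.asarray(start, dtype=float)
        if x0.shape != (P,):
            raise InvalidSpecificationError(
                f"start vector must have length {P}, got {x0.shape}"
            )
    n = prep.n

    floor_counter = {"hits": 0}

    def nll_scaled(x):
        ll, scores, hits = _ll_and_scores(spec, prep, tf, x)
        floor_counter["hits"] = hits
        return -ll / n, -scores.sum(axis=0) / n

    res = optimize.minimize(
        nll_scaled,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12, "maxcor": 25},
    )
    x_hat = res.x
    ll, scores, _ = _ll_and_scores(spec, prep, tf, x_hat)
    grad_norm = float(np.abs(scores.sum(axis=0)).max() / n)
    converged = bool(grad_norm < gtol * 10)  # small slack over the L-BFGS-B target

    cov = None
    if se_method != "none":
        def neg_grad(x):
            _, s, _ = _ll_and_scores(spec, prep, tf, x)
            return -s.sum(axis=0)

        B = scores.T @ scores
        if se_method == "bhhh":
            cov = _safe_inv(B)
        else:
            H = _numerical_hessian(neg_grad, x_hat)
            Hinv = _safe_inv(H)
            cov = Hinv if se_method == "hessian" else Hinv @ B @ Hinv

    return EstimationResult(
        spec=spec,
        params=x_hat,
        cov=cov,
        loglik=ll,
        n_obs=prep.n_obs,
        n_respondents=n,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(res.nit),
        floor_hits=floor_counter["hits"],
        se_method=se_method,
        roles=tuple(roles) if roles is not None else None,
    )


def _safe_inv(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


# ---------------------------------------------------------------------------
# interactions and stepwise covariate selection
# ---------------------------------------------------------------------------


def add_interactions(
    spec: MixedLogitSpec,
    data: ChoiceDataset,
    pairs: list[tuple[str, str]],
) -> tuple[MixedLogitSpec, ChoiceDataset]:
    """Materialise attribute x covariate columns into the dataset.

    Each pair appends a fixed-coefficient column named ``"attr:cov"`` whose
    row values are the attribute level times the respondent's covariate; the
    coefficient on it measures the covariate group's deviation in attribute
    sensitivity.  Estimating via the returned (spec, data) is numerically
    identical to listing the pairs in ``spec.interactions``.
    """
    df = data.choices.copy()
    new_attrs = list(spec.attributes)
    for attr, cov in pairs:
        if attr not in df.columns:
            raise DataValidationError(f"unknown attribute {attr!r}")
        if cov not in data.covariates.columns:
            raise DataValidationError(f"unknown covariate {cov!r}")
        cov_series = data.covariates[cov].reindex(df["respondent"])
        if cov_series.isna().any():
            raise DataValidationError(f"covariate {cov!r} has missing values")
        name = f"{attr}:{cov}"
        df[name] = df[attr].to_numpy() * cov_series.to_numpy(dtype=float)
        new_attrs.append(name)
    new_spec = replace(spec, attributes=tuple(new_attrs))
    new_data = ChoiceDataset(
        choices=df, covariates=data.covariates, provenance=dict(data.provenance)
    )
    return new_spec, new_data


def stepwise_covariates(
    base_spec: MixedLogitSpec,
    data: ChoiceDataset,
    candidates: list,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    roles=None,
    **fit_kwargs,
):
    """Forward-then-backward selection of covariate interaction terms.

    ``candidates`` are (attribute, covariate) pairs; a bare covariate name is
    shorthand for an interaction with the alternative-specific constant.
    Forward passes add the candidate with the best log-likelihood improvement
    when its term's p-value is below ``alpha_in``; backward passes then drop
    included terms whose p-value rises above ``alpha_out``.  Returns
    ``(trace, final_spec, final_result)`` where the trace records every
    step's decision, log-likelihood and AIC.
    """
    cand = [
        (ASC_NAME, c) if isinstance(c, str) else (c[0], c[1]) for c in candidates
    ]
    included: list[tuple[str, str]] = list(base_spec.interactions)
    remaining = [p for p in cand if p not in included]
    trace: list[dict] = []

    def _fit_with(pairs):
        sp = replace(base_spec, interactions=tuple(pairs))
        return sp, fit(sp, data, roles=roles, **fit_kwargs)

    spec_now, result_now = _fit_with(included)
    trace.append(
        {"step": "start", "term": None, "loglik": result_now.loglik,
         "aic": 2 * spec_now.n_parameters() - 2 * result_now.loglik}
    )

    # forward
    while remaining and alpha_in > 0:
        best = None
        for pair in remaining:
            sp, rs = _fit_with(included + [pair])
            p = rs.p_values()[f"mean:{pair[0]}:{pair[1]}"]
            if best is None or rs.loglik > best[2].loglik:
                best = (pair, sp, rs, p)
        pair, sp, rs, p = best
        if p < alpha_in:
            included.append(pair)
            remaining.remove(pair)
            spec_now, result_now = sp, rs
            trace.append(
                {"step": "add", "term": f"{pair[0]}:{pair[1]}", "p": p,
                 "loglik": rs.loglik,
                 "aic": 2 * sp.n_parameters() - 2 * rs.loglik}
            )
        else:
            trace.append(
                {"step": "reject", "term": f"{pair[0]}:{pair[1]}", "p": p,
                 "loglik": rs.loglik,
                 "aic": 2 * sp.n_parameters() - 2 * rs.loglik}
            )
            break

    # backward
    changed = True
    while changed and included:
        changed = False
        pvals = result_now.p_values()
        worst_pair, worst_p = None, alpha_out
        for pair in included:
            p = pvals[f"mean:{pair[0]}:{pair[1]}"]
            if p > worst_p:
                worst_pair, worst_p = pair, p
        if worst_pair is not None:
            included.remove(worst_pair)
            spec_now, result_now = _fit_with(included)
            trace.append(
                {"step": "drop", "term": f"{worst_pair[0]}:{worst_pair[1]}",
                 "p": worst_p, "loglik": result_now.loglik,
                 "aic": 2 * spec_now.n_parameters() - 2 * result_now.loglik}
            )
            changed = True

    return trace, spec_now, result_now


# ---------------------------------------------------------------------------
# internals shared with post-estimation analytics
# ---------------------------------------------------------------------------


def _weights_and_beta(result: EstimationResult, data: ChoiceDataset):
    """Draw weights W_ir and coefficient draws beta (n,R,K) at the optimum,
    rebuilt exactly as during estimation (same Halton sub-sequences)."""
    spec = result.spec
    prep = _prepare(spec, data, result.roles)
    u = _build_draws(spec, prep.n)
    tf = _make_transforms(spec, u)
    means, sds = _unpack(spec, result.params)
    beta = _beta_draws(spec, tf, means, sds, prep.n)
    _, ll_i, W, _, _ = _core(prep, beta, want_grad=True)
    return prep, W, beta, ll_i
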