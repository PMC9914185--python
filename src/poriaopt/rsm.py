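"""Response-surface modelling: modified-cubic fits, ANOVA and desirability optimization.

The response surface is a polynomial in the coded factors,

    Y = a0 + sum_i ai*Xi + sum_i aii*Xi^2 + sum_{i<j} aij*Xi*Xj
           + sum aiij*Xi^2*Xj,

fit by ordinary least squares to the run means of a Box–Behnken
experiment.  Terms are represented as tuples of factor indices, e.g.
``()`` intercept, ``(0,)`` X1, ``(0, 0)`` X1², ``(0, 1)`` X1·X2 and
``(0, 0, 2)`` X1²·X3.

A note on estimability: on a 3-factor BBD the three cross-cubic terms
with i < j are collectively aliased with a linear term
(X1²X3 + X2²X3 ≡ X3, because on every non-centre run with X3 = ±1
exactly one of X1, X2 is at ±1), so the 13-column "full modified cubic"
model matrix has rank 12.  ``fit_rsm`` raises on rank deficiency by
default; ``on_alias="drop"`` discards the dependent columns (pivoted QR)
and fits the projection, which leaves fitted values, R² and the centre
prediction unchanged.

Multi-response optimization uses Derringer–Suich desirability: each
response is mapped to d ∈ [0, 1] against its goal and the composite
D is the importance-weighted geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from .dataset import ResponseTable
from .design import FactorSpace, actual_to_coded, coded_to_actual

__all__ = [
    "Term",
    "TermBasis",
    "RSMFit",
    "AnovaTable",
    "DesirabilityGoal",
    "OptimizationResult",
    "HierarchyError",
    "AliasingError",
    "quadratic_basis",
    "modified_cubic_basis",
    "term_name",
    "build_basis",
    "fit_rsm",
    "anova_table",
    "predict",
    "desirability",
    "composite_desirability",
    "goals_from_table",
    "optimize_desirability",
    "surface_grid",
    "select_terms",
]

Term = tuple[int, ...]


class HierarchyError(ValueError):
    """Raised when a basis omits the parent terms of an included term."""


class AliasingError(ValueError):
    """Raised when the model matrix is rank-deficient on the given design."""


def term_name(term: Term) -> str:
    if not term:
        return "1"
    parts = []
    for i in sorted(set(term)):
        p = term.count(i)
        parts.append(f"X{i + 1}" + (f"^{p}" if p > 1 else ""))
    return "*".join(parts)


@dataclass(frozen=True)
class TermBasis:
    """An ordered, hierarchical set of polynomial terms (intercept first)."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        terms = tuple(tuple(sorted(t)) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        if () not in terms:
            raise HierarchyError("the intercept term () must be present")
        have = set(terms)
        for t in terms:
            degs: dict[int, int] = {}
            for i in t:
                degs[i] = degs.get(i, 0) + 1
            if len(degs) >= 2:  # interaction / cross-cubic: parents required
                for i, p in degs.items():
                    if (i,) not in have:
                        raise HierarchyError(f"{term_name(t)} requires linear parent X{i + 1}")
                    if p == 2 and (i, i) not in have:
                        raise HierarchyError(f"{term_name(t)} requires quadratic parent X{i + 1}^2")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(term_name(t) for t in self.terms)


def quadratic_basis(n_factors: int = 3) -> TermBasis:
    """Intercept + linear + pure quadratic + two-way interactions (10 terms for 3 factors)."""
    terms: list[Term] = [()]
    terms += [(i,) for i in range(n_factors)]
    terms += [(i, i) for i in range(n_factors)]
    terms += [(i, j) for i, j in combinations(range(n_factors), 2)]
    return TermBasis(tuple(terms))


def modified_cubic_basis(n_factors: int = 3, all_orderings: bool = False) -> TermBasis:
    """Quadratic basis plus the cross-cubic Xi²Xj terms.

    ``all_orderings=False`` (default) adds the three i < j terms;
    ``True`` adds all six i ≠ j orderings (16 columns, rank ≤ 13 on a BBD).
    """
    terms = list(quadratic_basis(n_factors).terms)
    if all_orderings:
        pairs = [(i, j) for i, j in permutations(range(n_factors), 2)]
    else:
        pairs = list(combinations(range(n_factors), 2))
    terms += [(i, i, j) for i, j in pairs]
    return TermBasis(tuple(terms))


def build_basis(coded: np.ndarray, basis: TermBasis) -> np.ndarray:
    """Evaluate the basis columns at coded run coordinates (one column per term)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = []
    for t in basis.terms:
        c = np.ones(coded.shape[0])
        for i in t:
            c = c * coded[:, i]
        cols.append(c)
    return np.column_stack(cols)


@dataclass(frozen=True)
class RSMFit:
    """An OLS response-surface fit on coded factors."""

    basis: TermBasis
    coefficients: np.ndarray
    response_name: str
    factor_space: FactorSpace
    fitted: np.ndarray
    residuals: np.ndarray
    dropped_terms: tuple[Term, ...] = field(default_factory=tuple)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        return build_basis(coded, self.basis) @ self.coefficients


def _independent_columns(M: np.ndarray) -> tuple[list[int], list[int]]:
    """Greedy earliest-first maximal independent column set via pivoted QR."""
    rank = np.linalg.matrix_rank(M)
    keep: list[int] = []
    for j in range(M.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(M[:, trial]) == len(trial):
            keep.append(j)
        if len(keep) == rank:
            break
    drop = [j for j in range(M.shape[1]) if j not in keep]
    return keep, drop


def fit_rsm(
    table: ResponseTable,
    response: str,
    basis: TermBasis,
    on_alias: str = "error",
) -> RSMFit:
    """Fit the response surface to the run means by ordinary least squares.

    ``on_alias`` controls rank-deficient bases: ``"error"`` (default)
    raises :class:`AliasingError` naming the dependent columns,
    ``"drop"`` removes them and fits the reduced (full-rank) basis.
    """
    y = table.response(response)
    coded = table.design.coded_matrix
    M = build_basis(coded, basis)
    rank = np.linalg.matrix_rank(M)
    dropped: tuple[Term, ...] = ()
    if rank < M.shape[1]:
        keep, drop = _independent_columns(M)
        names = [basis.names[j] for j in drop]
        if on_alias == "drop":
            dropped = tuple(basis.terms[j] for j in drop)
            basis = TermBasis(tuple(basis.terms[j] for j in keep))
            M = M[:, keep]
        else:
            raise AliasingError(
                f"model matrix rank {rank} < {M.shape[1]} columns; aliased terms: {names}"
            )
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    fitted = M @ beta
    return RSMFit(
        basis=basis,
        coefficients=beta,
        response_name=response,
        factor_space=table.design.factor_space,
        fitted=fitted,
        residuals=y - fitted,
        dropped_terms=dropped,
    )


def predict(fit: RSMFit, x_actual) -> np.ndarray | float:
    """Evaluate the fitted polynomial at actual factor settings (extrapolation allowed)."""
    x_actual = np.asarray(x_actual, dtype=float)
    single = x_actual.ndim == 1
    coded = actual_to_coded(fit.factor_space, np.atleast_2d(x_actual))
    out = fit.predict_coded(coded)
    return float(out[0]) if single else out


@dataclass(frozen=True)
class AnovaTable:
    """Model / lack-of-fit / pure-error decomposition of a response-surface fit."""

    response_name: str
    ss_model: float
    df_model: int
    ms_model: float
    f_model: float
    p_model: float
    ss_residual: float
    df_residual: int
    ss_lack_of_fit: float
    df_lof: int
    f_lof: float | None
    p_lof: float | None
    ss_pure_error: float
    df_pe: int
    r_squared: float
    std_dev: float
    adequate_precision: float
    lof_testable: bool


def anova_table(fit: RSMFit, table: ResponseTable) -> AnovaTable:
    """ANOVA of the fit with the lack-of-fit / pure-error split.

    Pure error is the dispersion of the centre-replicate run means about
    their own mean (the only replicated design point when fitting on run
    means); lack of fit is the remainder of the residual.  Adequate
    precision is the fitted-value range over the average prediction
    standard error, sqrt(p * MS_residual / n).
    """
    y = table.response(fit.response_name)
    n = len(y)
    p = fit.n_params
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_res = float((fit.residuals**2).sum())
    ss_model = ss_total - ss_res
    df_model = p - 1
    df_res = n - p
    ms_model = ss_model / df_model
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    f_model = ms_model / ms_res if df_res > 0 else np.inf
    p_model = float(stats.f.sf(f_model, df_model, df_res)) if df_res > 0 else 0.0

    center = table.design.center_mask
    yc = y[center]
    ss_pe = float(((yc - yc.mean()) ** 2).sum())
    df_pe = int(center.sum()) - 1
    if df_pe < 1:
        raise ValueError("lack-of-fit partition needs replicated centre points")
    ss_lof = max(ss_res - ss_pe, 0.0)
    df_lof = df_res - df_pe
    testable = df_lof >= 1 and ss_pe > 0  # zero pure error leaves no F denominator
    if testable:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        f_lof = None
        p_lof = None

    mean_pred_var = p * ms_res / n
    adeq = float((fit.fitted.max() - fit.fitted.min()) / np.sqrt(mean_pred_var))
    return AnovaTable(
        response_name=fit.response_name,
        ss_model=ss_model,
        df_model=df_model,
        ms_model=ms_model,
        f_model=float(f_model),
        p_model=p_model,
        ss_residual=ss_res,
        df_residual=df_res,
        ss_lack_of_fit=ss_lof,
        df_lof=df_lof,
        f_lof=f_lof,
        p_lof=p_lof,
        ss_pure_error=ss_pe,
        df_pe=df_pe,
        r_squared=1.0 - ss_res / ss_total,
        std_dev=float(np.sqrt(ms_res)),
        adequate_precision=adeq,
        lof_testable=testable,
    )


@dataclass(frozen=True)
class DesirabilityGoal:
    """A Derringer–Suich goal for one response.

    For ``goal="maximize"`` (the default) d = 0 at or below ``lower``,
    1 at or above ``upper`` and ((y − lower)/(upper − lower))**weight in
    between; ``"minimize"`` mirrors this.  ``importance`` is the relative
    exponent in the composite geometric mean.
    """

    response_name: str
    lower: float
    upper: float
    goal: str = "maximize"
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.response_name}: require lower < upper")
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError("weight and importance must be positive")
        if self.goal not in ("maximize", "minimize"):
            raise ValueError(f"unsupported goal {self.goal!r}")


def desirability(value, goal: DesirabilityGoal) -> np.ndarray | float:
    """Per-response desirability d in [0, 1]."""
    value = np.asarray(value, dtype=float)
    frac = (value - goal.lower) / (goal.upper - goal.lower)
    if goal.goal == "minimize":
        frac = 1.0 - frac
    d = np.clip(frac, 0.0, 1.0) ** goal.weight
    return float(d) if d.ndim == 0 else d


def composite_desirability(values, goals: list[DesirabilityGoal]) -> np.ndarray | float:
    """Importance-weighted geometric mean D of per-response desirabilities.

    ``values`` has one column (or entry) per goal, in goal order.
    """
    if not goals:
        raise ValueError("at least one goal is required")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    total = sum(g.importance for g in goals)
    logD = np.zeros(values.shape[0])
    zero = np.zeros(values.shape[0], dtype=bool)
    for k, g in enumerate(goals):
        d = np.asarray(desirability(values[:, k], g))
        zero |= d == 0
        with np.errstate(divide="ignore"):
            logD += g.importance * np.where(d > 0, np.log(np.maximum(d, 1e-300)), 0.0)
    D = np.exp(logD / total)
    D[zero] = 0.0
    return float(D[0]) if D.shape == (1,) else D


def goals_from_table(
    table: ResponseTable, names, weight: float = 1.0, importance: float = 1.0
) -> list[DesirabilityGoal]:
    """Maximize goals with each response's observed min/max as the d = 0/1 anchors."""
    return [
        DesirabilityGoal(n, *table.observed_range(n), weight=weight, importance=importance)
        for n in names
    ]


@dataclass(frozen=True)
class OptimizationResult:
    """A located optimum: factor settings, predicted responses and composite D."""

    x_actual: np.ndarray
    predicted: dict[str, float]
    composite_desirability: float
    method: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_actual", np.asarray(self.x_actual, dtype=float))


def _unclipped_mean_d(values: np.ndarray, goals) -> np.ndarray:
    """Mean of per-goal desirabilities without the [0, 1] clip (plateau tie-break)."""
    acc = np.zeros(values.shape[0])
    for k, g in enumerate(goals):
        frac = (values[:, k] - g.lower) / (g.upper - g.lower)
        if g.goal == "minimize":
            frac = 1.0 - frac
        acc += frac
    return acc / len(goals)


def optimize_desirability(
    fits: list[RSMFit],
    goals: list[DesirabilityGoal],
    factor_space: FactorSpace | None = None,
    grid_resolution: int = 21,
    n_starts: int = 20,
    tol: float = 1e-6,
) -> OptimizationResult:
    """Maximize composite desirability over the factor box.

    Deterministic multistart: D is evaluated on a ``grid_resolution``³
    coded grid, the best ``n_starts`` grid points seed L-BFGS-B polishes,
    and the best polished point is returned.  If the maximum saturates at
    D = 1 (possible under observed min/max goal ranges when the surface
    predictions exceed every observed value) the maximizer is a region;
    the reported point then additionally maximizes the mean *unclipped*
    desirability over that region, which selects the most-desirable-on-
    average point and keeps the result unique and reproducible.
    """
    if not goals:
        raise ValueError("at least one goal is required")
    if not fits:
        raise ValueError("at least one fit is required")
    factor_space = factor_space or fits[0].factor_space
    by_name = {f.response_name: f for f in fits}
    gfits = [by_name[g.response_name] for g in goals]

    nf = factor_space.n_factors
    axes = [np.linspace(-1.0, 1.0, grid_resolution)] * nf
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, nf)
    P = np.column_stack([f.predict_coded(G) for f in gfits])
    D = np.atleast_1d(composite_desirability(P, goals))

    def neg_d(xc: np.ndarray) -> float:
        vals = np.array([[f.predict_coded(xc[None, :])[0] for f in gfits]])
        return -float(composite_desirability(vals, goals))

    order = np.argsort(-D, kind="stable")[:n_starts]
    bounds = [(-1.0, 1.0)] * nf
    candidates = []
    for i in order:
        res = minimize(neg_d, G[i], method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol * 1e-3, "gtol": 1e-10})
        candidates.append((float(-res.fun), np.clip(res.x, -1, 1)))
    best_D = max(c[0] for c in candidates)
    best_x = min((c for c in candidates if c[0] >= best_D - tol), key=lambda c: tuple(c[1]))[1]

    if best_D >= 1.0 - 1e-12:
        # saturated plateau: secondary maximization of the mean unclipped d
        def neg_secondary(xc: np.ndarray) -> float:
            vals = np.array([[f.predict_coded(xc[None, :])[0] for f in gfits]])
            g = float(_unclipped_mean_d(vals, goals)[0])
            Dv = float(composite_desirability(vals, goals))
            return -g + 1e4 * max(0.0, best_D - 1e-9 - Dv) ** 2

        plateau_starts = [x for v, x in candidates if v >= best_D - tol]
        mask = D >= best_D - tol
        if mask.any():
            S = _unclipped_mean_d(P[mask], goals)
            plateau_starts.append(G[mask][int(np.argmax(S))])
        best2 = None
        for x0 in plateau_starts:
            res = minimize(neg_secondary, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-12, "gtol": 1e-10})
            if best2 is None or res.fun < best2.fun:
                best2 = res
        cand = np.clip(best2.x, -1, 1)
        vals = np.array([[f.predict_coded(cand[None, :])[0] for f in gfits]])
        if composite_desirability(vals, goals) >= best_D - 1e-9:
            best_x = cand

    x_actual = coded_to_actual(factor_space, best_x)
    preds = {f.response_name: float(f.predict_coded(best_x[None, :])[0]) for f in gfits}
    vals = np.array([[preds[g.response_name] for g in goals]])
    return OptimizationResult(
        x_actual=x_actual,
        predicted=preds,
        composite_desirability=float(composite_desirability(vals, goals)),
        method="rsm-desirability",
    )


def surface_grid(
    fit: RSMFit, free: tuple[int, int], fixed_value: float, resolution: int = 21
):
    """Predictions on a regular coded grid over two factors at a fixed third slice.

    ``fixed_value`` is the coded value of the held factor.  Returns a
    DataFrame with actual factor columns and the prediction, suitable for
    contour/surface plotting or CSV export.
    """
    import pandas as pd

    if resolution < 2:
        raise ValueError("grid resolution must be >= 2")
    i, j = free
    (k,) = [a for a in range(3) if a not in free]
    g = np.linspace(-1.0, 1.0, resolution)
    A, B = np.meshgrid(g, g, indexing="ij")
    coded = np.zeros((resolution * resolution, 3))
    coded[:, i] = A.ravel()
    coded[:, j] = B.ravel()
    coded[:, k] = fixed_value
    pred = fit.predict_coded(coded)
    actual = coded_to_actual(fit.factor_space, coded)
    names = fit.factor_space.names
    return pd.DataFrame(
        {
            names[0]: actual[:, 0],
            names[1]: actual[:, 1],
            names[2]: actual[:, 2],
            "prediction": pred,
        }
    )


def select_terms(table: ResponseTable, response: str, mode: str = "auto") -> TermBasis:
    """Choose the term basis for one response.

    ``"quadratic"``: the 10-term full quadratic model.
    ``"full_modified_cubic"``: quadratic plus the three i < j cross-cubic
    terms (rank-deficient on a BBD; pair with ``on_alias="drop"``).
    ``"auto"``: quadratic plus the single cross-cubic candidate (all six
    orderings considered) with the smallest partial-F p-value, added only
    if p < 0.05 — reproducing the uniform 10-model-df structure the
    published ANOVA shows.
    """
    if mode == "quadratic":
        return quadratic_basis()
    if mode == "full_modified_cubic":
        return modified_cubic_basis()
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    y = table.response(response)
    coded = table.design.coded_matrix
    base = quadratic_basis()
    M0 = build_basis(coded, base)
    b0, *_ = np.linalg.lstsq(M0, y, rcond=None)
    ss0 = float(((y - M0 @ b0) ** 2).sum())

    best: tuple[float, Term] | None = None
    for i, j in permutations(range(3), 2):
        cand: Term = (i, i, j)
        terms = base.terms + (cand,)
        M1 = build_basis(coded, TermBasis(terms))
        if np.linalg.matrix_rank(M1) < M1.shape[1]:
            continue
        b1, *_ = np.linalg.lstsq(M1, y, rcond=None)
        ss1 = float(((y - M1 @ b1) ** 2).sum())
        df2 = len(y) - M1.shape[1]
        f = (ss0 - ss1) / (ss1 / df2) if ss1 > 0 else np.inf
        pval = float(stats.f.sf(f, 1, df2))
        if best is None or pval < best[0]:
            best = (pval, cand)
    if best is not None and best[0] < 0.05:
        return TermBasis(base.terms + (best[1],))
    return base
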