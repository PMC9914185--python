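"""PCA over the response matrix and correlation-threshold response grouping.

Principal component analysis summarises how the eight extraction
responses co-vary across the design runs; responses that load together
motivate joint optimization.  The default is correlation-matrix PCA of
the run means (the responses span four orders of magnitude in raw units,
so covariance PCA is dominated by a single column and is offered only as
a flag).  Two further conventions are provided because published
explained-variance figures from desktop stats packages often include the
design-factor columns and/or operate on replicate-level rows:

* ``include_factors`` appends the three factor columns to the matrix;
* ``replicate_level`` expands each run into ``n_reps`` replicate rows
  reconstructed to match the run mean and SD exactly (the raw replicate
  values are not recoverable from a mean ± SD table, but any
  reconstruction with those exact moments gives near-identical
  correlation structure; the residual Monte-Carlo spread of the explained
  percentages is a few hundredths of a point).

Grouping by thresholded correlation is a diagnostic: responses joined by
pairwise Pearson r at or above ``r_high`` form single-linkage groups, and
leftover singletons attach to the group they correlate with at moderate
strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dataset import ResponseGroup, ResponseTable

__all__ = [
    "PCAResult",
    "GroupingRule",
    "DegenerateColumnError",
    "run_pca",
    "correlation_groups",
]


class DegenerateColumnError(ValueError):
    """Raised when a constant column makes standardization or correlation undefined."""


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition summary: explained variance, loadings and scores."""

    variable_names: tuple[str, ...]
    explained_pct: np.ndarray  # (n_components,), sums to 100
    loadings: np.ndarray  # (n_variables, n_components)
    scores: np.ndarray  # (n_rows, n_components)


@dataclass(frozen=True)
class GroupingRule:
    """Correlation thresholds: r >= r_high joins, moderate band attaches singletons."""

    r_high: float = 0.6
    r_moderate_low: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.r_moderate_low < self.r_high < 1.0:
            raise ValueError("require 0 < r_moderate_low < r_high < 1")


def _replicate_rows(
    table: ResponseTable, rng: np.random.Generator, n_reps: int
) -> np.ndarray:
    """Expand run means ± SD into replicate rows with exact per-run moments."""
    if n_reps < 2:
        raise ValueError("replicate expansion needs n_reps >= 2")
    rows = []
    for i in range(table.n_runs):
        e = rng.standard_normal((n_reps, table.n_responses))
        e = e - e.mean(axis=0)
        sd = e.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        e = e / sd
        rows.append(table.means[i] + e * table.sds[i])
    return np.vstack(rows)


def run_pca(
    table: ResponseTable,
    standardize: bool = True,
    include_factors: bool = False,
    replicate_level: bool = False,
    seed: int = 0,
) -> PCAResult:
    """PCA of the response matrix (optionally the full design matrix).

    With ``standardize`` (default) the eigendecomposition is of the
    Pearson correlation matrix, so the result is invariant to per-column
    affine rescaling.  Components are ordered by decreasing explained
    variance and each loading vector is signed so its largest-magnitude
    entry is positive.
    """
    names = list(table.response_names)
    X = table.means
    if replicate_level:
        rng = np.random.default_rng(seed)
        X = _replicate_rows(table, rng, table.n_reps)
    if include_factors:
        F = table.design.actual_matrix
        if replicate_level:
            F = np.repeat(F, table.n_reps, axis=0)
        X = np.hstack([F, X])
        names = list(table.design.factor_space.names) + names

    X = np.asarray(X, dtype=float)
    col_sd = X.std(axis=0, ddof=1)
    if standardize and np.any(col_sd == 0):
        bad = names[int(np.argmax(col_sd == 0))]
        raise DegenerateColumnError(f"column {bad!r} is constant; correlation PCA undefined")

    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / col_sd
    C = (Xc.T @ Xc) / (X.shape[0] - 1)

    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading entry positive
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]

    explained = 100.0 * eigval / eigval.sum()
    scores = Xc @ eigvec
    return PCAResult(
        variable_names=tuple(names),
        explained_pct=explained,
        loadings=eigvec,
        scores=scores,
    )


def correlation_groups(
    table: ResponseTable, rule: GroupingRule | None = None
) -> list[ResponseGroup]:
    """Partition the responses by thresholded Pearson correlation.

    Responses are joined single-linkage over the graph with an edge
    wherever r >= ``rule.r_high``; each resulting singleton is attached to
    the group with which its maximum correlation lies in the moderate
    band (r_moderate_low, r_high), otherwise it stays a singleton.
    """
    rule = rule or GroupingRule()
    if table.n_runs < 3:
        raise ValueError("correlation grouping needs at least 3 runs")
    Y = table.means
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = table.response_names[int(np.argmax(sd == 0))]
        raise DegenerateColumnError(f"response {bad!r} has zero variance")
    R = np.corrcoef(Y, rowvar=False)

    adj = (R >= rule.r_high).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        members.setdefault(int(lab), []).append(idx)

    multi = {lab: idxs for lab, idxs in members.items() if len(idxs) > 1}
    singles = [idxs[0] for idxs in members.values() if len(idxs) == 1]

    # attach singletons whose best correlation with a group is moderate
    for idx in singles:
        best_lab, best_r = None, -np.inf
        for lab, idxs in multi.items():
            r = max(R[idx, j] for j in idxs)
            if r > best_r:
                best_lab, best_r = lab, r
        if best_lab is not None and rule.r_moderate_low < best_r < rule.r_high:
            multi[best_lab].append(idx)
        else:
            multi[len(members) + idx + 1000] = [idx]  # keep as its own group

    groups = []
    for k, idxs in enumerate(sorted(multi.values(), key=min), start=1):
        names = tuple(table.response_names[i] for i in sorted(idxs))
        groups.append(ResponseGroup(f"group_{k}", names))
    return groups
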