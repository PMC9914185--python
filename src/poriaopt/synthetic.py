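"""Synthetic Box–Behnken datasets from known ground-truth surfaces.

The generator emulates the structure the response-surface model assumes:
each response is a polynomial surface over the coded factors plus
homoscedastic Gaussian replicate noise; run means and SDs are the sample
moments of ``n_reps`` replicate draws.  Known coefficients make every
pipeline stage testable — coefficient recovery by the OLS fit, optimum
recovery by the desirability and GA optimizers — without external data.
A relative-noise mode scales the noise SD with the surface range, since
real assay SDs tend to grow with the measured level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .dataset import ResponseTable
from .design import FactorSpace, build_bbd, coded_to_actual, default_factor_space
from .rsm import (
    DesirabilityGoal,
    OptimizationResult,
    TermBasis,
    build_basis,
    composite_desirability,
    quadratic_basis,
)

__all__ = ["SyntheticSpec", "sample_spec", "generate_bbd_dataset", "ground_truth_optimum"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic experiment.

    ``true_coefficients`` is (n_responses, n_terms) over ``basis`` in the
    coded factors; ``noise_sd`` is the per-response replicate SD (absolute
    units, or a fraction of the surface range when ``relative_noise``).
    """

    factor_space: FactorSpace
    basis: TermBasis
    true_coefficients: np.ndarray
    noise_sd: np.ndarray
    n_reps: int = 3
    seed: int = 0
    n_center: int = 5
    relative_noise: bool = False
    response_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coefs = np.atleast_2d(np.asarray(self.true_coefficients, dtype=float))
        object.__setattr__(self, "true_coefficients", coefs)
        noise = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (coefs.shape[0],)
        ).copy()
        object.__setattr__(self, "noise_sd", noise)
        if coefs.shape[1] != self.basis.n_terms:
            raise ValueError("coefficient vectors must conform to the declared basis")
        if np.any(noise < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.response_names:
            object.__setattr__(
                self,
                "response_names",
                tuple(f"Y{k + 1}" for k in range(coefs.shape[0])),
            )

    @property
    def n_responses(self) -> int:
        return self.true_coefficients.shape[0]

    def surface(self, coded: np.ndarray) -> np.ndarray:
        """True surface values, (n_points, n_responses)."""
        M = build_basis(coded, self.basis)
        return M @ self.true_coefficients.T


def sample_spec(
    n_responses: int,
    basis: TermBasis | None = None,
    magnitude: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    factor_space: FactorSpace | None = None,
) -> SyntheticSpec:
    """Seeded random coefficients with |α| ≤ magnitude on non-intercept terms.

    The intercept is raised so that every design-point mean is positive
    (min surface value over the design plus a one-magnitude margin).
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    basis = basis or quadratic_basis()
    factor_space = factor_space or default_factor_space()
    rng = np.random.default_rng(seed)
    coefs = rng.uniform(-magnitude, magnitude, size=(n_responses, basis.n_terms))
    design = build_bbd(factor_space, n_center=5)
    M = build_basis(design.coded_matrix, basis)
    vals = M @ coefs.T
    # shift intercepts so all design-point means are positive
    coefs[:, 0] += magnitude - vals.min(axis=0)
    return SyntheticSpec(
        factor_space=factor_space,
        basis=basis,
        true_coefficients=coefs,
        noise_sd=np.full(n_responses, float(noise_sd)),
        n_reps=n_reps,
        seed=seed,
    )


def generate_bbd_dataset(spec: SyntheticSpec) -> ResponseTable:
    """Realise a BBD dataset from the spec: run means and SDs of noisy replicates."""
    design = build_bbd(spec.factor_space, n_center=spec.n_center)
    truth = spec.surface(design.coded_matrix)  # (n_runs, n_resp)
    sd = spec.noise_sd.copy()
    if spec.relative_noise:
        sd = sd * (truth.max(axis=0) - truth.min(axis=0))
    rng = np.random.default_rng(spec.seed)
    if spec.n_reps >= 2:
        draws = rng.normal(0.0, 1.0, size=(design.n_runs, spec.n_reps, spec.n_responses)) * sd
        means = truth + draws.mean(axis=1)
        sds = draws.std(axis=1, ddof=1)
    else:
        draws = rng.normal(0.0, 1.0, size=(design.n_runs, spec.n_responses)) * sd
        means = truth + draws
        sds = np.zeros_like(means)
    return ResponseTable(
        design=design,
        response_names=spec.response_names,
        means=means,
        sds=sds,
        n_reps=spec.n_reps,
        units={n: "" for n in spec.response_names},
    )


def ground_truth_optimum(
    spec: SyntheticSpec,
    goals: list[DesirabilityGoal],
    grid_resolution: int = 101,
) -> OptimizationResult:
    """Brute-force composite-desirability optimum of the *true* surfaces.

    Evaluates D on a ``grid_resolution``³ coded grid and polishes the
    best point with a bounded local search; serves as the oracle for the
    desirability and GA optimizers.
    """
    names = list(spec.response_names)
    sel = [names.index(g.response_name) for g in goals]

    nf = spec.factor_space.n_factors
    axes = [np.linspace(-1.0, 1.0, grid_resolution)] * nf
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, nf)
    vals = spec.surface(G)[:, sel]
    D = np.atleast_1d(composite_desirability(vals, goals))
    i0 = int(np.argmax(D))

    def neg_d(xc: np.ndarray) -> float:
        v = spec.surface(xc[None, :])[:, sel]
        return -float(composite_desirability(v, goals))

    res = minimize(neg_d, G[i0], method="L-BFGS-B", bounds=[(-1.0, 1.0)] * nf,
                   options={"ftol": 1e-12, "gtol": 1e-10})
    best = np.clip(res.x, -1, 1) if -res.fun >= D[i0] else G[i0]
    v = spec.surface(best[None, :])[0, :]
    preds = {names[k]: float(v[k]) for k in sel}
    vsel = v[sel][None, :]
    return OptimizationResult(
        x_actual=coded_to_actual(spec.factor_space, best),
        predicted=preds,
        composite_desirability=float(composite_desirability(vsel, goals)),
        method="grid-oracle",
    )
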