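"""Feed-forward neural-network surrogate for the extraction responses.

The surrogate is a single-hidden-layer perceptron with the fixed layout
3 inputs → 10 tansig hidden units → m linear outputs (one network per
response group, m = group size).  Inputs and outputs are min–max scaled
to [−1, 1] using training-set ranges.  Training minimises the mean
squared error

    MSE = (1/N) * sum (Y_ann − Y_exp)²

over the training subset with a damped Gauss–Newton (Levenberg–
Marquardt) schedule — the conventional choice for tiny regression
MLPs — with early stopping on the validation subset; plain gradient
descent with momentum is available by config.  The run set is split
70/15/15 into training/validation/test by a seeded shuffle with
largest-remainder apportionment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ResponseGroup, ResponseTable

__all__ = [
    "tansig",
    "AffineScaler",
    "Network",
    "DataSplit",
    "TrainConfig",
    "TrainingReport",
    "ScalingError",
    "split_runs",
    "mse",
    "init_network",
    "flatten_params",
    "unflatten_params",
    "n_params",
    "mse_loss_and_grad",
    "train",
    "regression_diagnostics",
]


class ScalingError(ValueError):
    """Raised when a zero-range column makes min–max scaling degenerate."""


def tansig(n):
    """Hyperbolic-tangent sigmoid activation, 2/(1 + e^(−2n)) − 1 ≡ tanh(n).

    Evaluated as ``tanh`` for numerical stability at large |n|.
    """
    return np.tanh(n)


@dataclass(frozen=True)
class AffineScaler:
    """Per-column min–max map to [−1, 1]: x ↦ 2 (x − lo) / (hi − lo) − 1."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "AffineScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = X.min(axis=0), X.max(axis=0)
        if np.any(hi - lo == 0):
            j = int(np.argmax(hi - lo == 0))
            raise ScalingError(f"column {j} has zero range; cannot min-max scale")
        return cls(lo=lo, hi=hi)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(X, float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z, float) + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


@dataclass(frozen=True)
class Network:
    """MLP weights plus the input/output scalers that define its units."""

    layout: tuple[int, int, int]  # (n_in, n_hidden, n_out)
    hidden_weights: np.ndarray  # (n_hidden, n_in)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_out, n_hidden)
    output_biases: np.ndarray  # (n_out,)
    input_scaler: AffineScaler
    output_scaler: AffineScaler
    response_names: tuple[str, ...] = ()

    def forward_scaled(self, Z: np.ndarray) -> np.ndarray:
        """Forward pass in scaled space; hidden activations lie in (−1, 1)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        H = tansig(Z @ self.hidden_weights.T + self.hidden_biases)
        return H @ self.output_weights.T + self.output_biases

    def predict(self, X_actual: np.ndarray) -> np.ndarray:
        """Predict responses in original units from actual factor settings."""
        X_actual = np.asarray(X_actual, dtype=float)
        single = X_actual.ndim == 1
        out = self.output_scaler.inverse(
            self.forward_scaled(self.input_scaler.apply(np.atleast_2d(X_actual)))
        )
        return out[0] if single else out

    def to_json_dict(self) -> dict:
        return {
            "layout": list(self.layout),
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
            "input_scaler": {"lo": self.input_scaler.lo.tolist(), "hi": self.input_scaler.hi.tolist()},
            "output_scaler": {"lo": self.output_scaler.lo.tolist(), "hi": self.output_scaler.hi.tolist()},
            "response_names": list(self.response_names),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Network":
        return cls(
            layout=tuple(d["layout"]),
            hidden_weights=np.array(d["hidden_weights"], float),
            hidden_biases=np.array(d["hidden_biases"], float),
            output_weights=np.array(d["output_weights"], float),
            output_biases=np.array(d["output_biases"], float),
            input_scaler=AffineScaler(np.array(d["input_scaler"]["lo"], float),
                                      np.array(d["input_scaler"]["hi"], float)),
            output_scaler=AffineScaler(np.array(d["output_scaler"]["lo"], float),
                                       np.array(d["output_scaler"]["hi"], float)),
            response_names=tuple(d.get("response_names", ())),
        )


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/validation/test run indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        n = len(all_idx)
        if len(np.unique(all_idx)) != n or set(all_idx) != set(range(n)):
            raise ValueError("train/val/test indices must partition the run set")


def split_runs(
    n_runs: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15), seed: int = 0
) -> DataSplit:
    """Seeded shuffle + largest-remainder apportionment into train/val/test.

    Fractions are (train, validation, test) and must sum to 1.  Remainder
    ties are broken in the order train > validation > test, so 17 runs at
    70/15/15 give sizes (12, 3, 2).
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    ideal = fr * n_runs
    sizes = np.floor(ideal).astype(int)
    remainders = ideal - sizes
    # assign leftover slots by largest remainder; ties favour train, then val
    for _ in range(n_runs - sizes.sum()):
        k = max(range(3), key=lambda i: (remainders[i], -i))
        sizes[k] += 1
        remainders[k] = -1.0
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_runs)
    t, v = sizes[0], sizes[0] + sizes[1]
    return DataSplit(
        train_idx=np.sort(perm[:t]),
        val_idx=np.sort(perm[t:v]),
        test_idx=np.sort(perm[v:]),
        fractions=tuple(fr),
        seed=seed,
    )


def mse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean over all entries of the squared prediction error."""
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch {predicted.shape} vs {observed.shape}")
    return float(np.mean((predicted - observed) ** 2))


def n_params(layout: tuple[int, int, int]) -> int:
    ni, nh, no = layout
    return nh * ni + nh + no * nh + no


def flatten_params(net: Network) -> np.ndarray:
    return np.concatenate([
        net.hidden_weights.ravel(), net.hidden_biases,
        net.output_weights.ravel(), net.output_biases,
    ])


def unflatten_params(theta: np.ndarray, layout: tuple[int, int, int]):
    ni, nh, no = layout
    theta = np.asarray(theta, float)
    if theta.size != n_params(layout):
        raise ValueError(f"expected {n_params(layout)} parameters, got {theta.size}")
    a = 0
    W1 = theta[a:a + nh * ni].reshape(nh, ni); a += nh * ni
    b1 = theta[a:a + nh]; a += nh
    W2 = theta[a:a + no * nh].reshape(no, nh); a += no * nh
    b2 = theta[a:a + no]
    return W1, b1, W2, b2


def init_network(
    layout: tuple[int, int, int],
    input_scaler: AffineScaler,
    output_scaler: AffineScaler,
    seed: int = 0,
    init_range: float = 0.5,
    response_names: tuple[str, ...] = (),
) -> Network:
    """Seeded uniform(−init_range, init_range) weight initialisation."""
    ni, nh, no = layout
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-init_range, init_range, size=n_params(layout))
    W1, b1, W2, b2 = unflatten_params(theta, layout)
    return Network(layout, W1, b1, W2, b2, input_scaler, output_scaler, response_names)


def _forward_resid_jac(theta, layout, Z, T, need_jac=True):
    """Residuals (and Jacobian) of the scaled-space fit at parameters theta."""
    ni, nh, no = layout
    W1, b1, W2, b2 = unflatten_params(theta, layout)
    n = Z.shape[0]
    A = Z @ W1.T + b1  # (n, nh)
    H = np.tanh(A)
    Y = H @ W2.T + b2  # (n, no)
    R = (Y - T).ravel()  # residuals, sample-major then output
    if not need_jac:
        return R, None
    P = n_params(layout)
    J = np.zeros((n * no, P))
    dH = 1.0 - H**2  # (n, nh)
    for o in range(no):
        # R.ravel() of (n, no) is sample-major: residual rows s*no + o
        idx = np.arange(n) * no + o
        # dY/dW2[o, k] = H[:, k]
        a = nh * ni + nh + o * nh
        J[idx, a:a + nh] = H
        # dY/db2[o] = 1
        J[idx, nh * ni + nh + no * nh + o] = 1.0
        # dY/dW1[k, i] = W2[o, k] * dH[:, k] * Z[:, i]
        G = W2[o] * dH  # (n, nh)
        J[idx, :nh * ni] = (G[:, :, None] * Z[:, None, :]).reshape(n, nh * ni)
        # dY/db1[k] = W2[o, k] * dH[:, k]
        J[idx, nh * ni:nh * ni + nh] = G
    return R, J


def mse_loss_and_grad(theta, layout, Z, T):
    """Training MSE and its analytic gradient (for optimisation and checking)."""
    R, J = _forward_resid_jac(np.asarray(theta, float), layout, np.asarray(Z, float),
                              np.asarray(T, float), need_jac=True)
    N = R.size
    return float(R @ R) / N, (2.0 / N) * (J.T @ R)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (documented defaults; all stochastic steps seeded)."""

    max_epochs: int = 1000
    patience: int = 6
    seed: int = 0
    init_range: float = 0.5
    optimizer: str = "lm"  # "lm" or "gd"
    mu0: float = 1e-3
    mu_max: float = 1e10
    learning_rate: float = 0.05
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class TrainingReport:
    """Per-epoch scaled-space MSE curves and the stopping summary."""

    mse_train: tuple[float, ...]
    mse_val: tuple[float, ...]
    mse_test: tuple[float, ...]
    stop_epoch: int
    best_val_epoch: int
    stop_reason: str
    seed: int


def train(
    network: Network | None,
    table: ResponseTable,
    group: ResponseGroup,
    split: DataSplit,
    config: TrainConfig | None = None,
) -> tuple[Network, TrainingReport]:
    """Train the surrogate on a response group; returns the best-validation network.

    Scalers are fit on the training subset.  If ``network`` is given
    (e.g. GA-seeded) its weights are the starting point and its scalers
    are reused; otherwise weights are drawn uniform(−init_range,
    init_range) from the config seed.  Early stopping halts when the
    validation MSE has not improved for ``patience`` consecutive epochs;
    the returned weights are those of the best-validation epoch.
    """
    config = config or TrainConfig()
    idx_resp = [table.response_index(n) for n in group.members]
    X = table.design.actual_matrix
    Y = table.means[:, idx_resp]
    layout = (X.shape[1], 10, len(idx_resp))

    if network is None:
        in_sc = AffineScaler.fit(X[split.train_idx])
        out_sc = AffineScaler.fit(Y[split.train_idx])
        network = init_network(layout, in_sc, out_sc, seed=config.seed,
                               init_range=config.init_range,
                               response_names=tuple(group.members))
    else:
        if network.layout != layout:
            raise ValueError(f"network layout {network.layout} != required {layout}")
        in_sc, out_sc = network.input_scaler, network.output_scaler

    Z = in_sc.apply(X)
    T = out_sc.apply(Y)
    subsets = {
        "train": (Z[split.train_idx], T[split.train_idx]),
        "val": (Z[split.val_idx], T[split.val_idx]),
        "test": (Z[split.test_idx], T[split.test_idx]),
    }
    Ztr, Ttr = subsets["train"]
    theta = flatten_params(network)
    P = theta.size

    def subset_mse(th, key):
        Zs, Ts = subsets[key]
        if len(Zs) == 0:
            return np.nan
        R, _ = _forward_resid_jac(th, layout, Zs, Ts, need_jac=False)
        return float(R @ R) / R.size

    curves = {k: [] for k in ("train", "val", "test")}
    monitor = "val" if len(split.val_idx) > 0 else "train"
    best_val = np.inf
    best_theta = theta.copy()
    best_epoch = 0
    stall = 0
    stop_reason = "max_epochs"
    mu = config.mu0
    velocity = np.zeros(P)
    epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        if config.optimizer == "lm":
            R, J = _forward_resid_jac(theta, layout, Ztr, Ttr)
            sse = float(R @ R)
            g = J.T @ R
            JtJ = J.T @ J
            accepted = False
            for _ in range(30):
                try:
                    delta = np.linalg.solve(JtJ + mu * np.eye(P), -g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                R_new, _ = _forward_resid_jac(theta + delta, layout, Ztr, Ttr, need_jac=False)
                if float(R_new @ R_new) < sse:
                    theta = theta + delta
                    mu = max(mu * 0.1, 1e-12)
                    accepted = True
                    break
                mu *= 10.0
                if mu > config.mu_max:
                    break
            if not accepted:
                stop_reason = "mu_max"
        elif config.optimizer == "gd":
            _, grad = mse_loss_and_grad(theta, layout, Ztr, Ttr)
            velocity = config.momentum * velocity - config.learning_rate * grad
            theta = theta + velocity
        else:
            raise ValueError(f"unknown optimizer {config.optimizer!r}")

        for k in ("train", "val", "test"):
            curves[k].append(subset_mse(theta, k))
        mv = curves[monitor][-1]
        if mv < best_val - 1e-15:
            best_val = mv
            best_theta = theta.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
        if stop_reason == "mu_max":
            break
        if stall >= config.patience:
            stop_reason = "early_stop"
            break

    W1, b1, W2, b2 = unflatten_params(best_theta, layout)
    trained = Network(layout, W1, b1, W2, b2, in_sc, out_sc, tuple(group.members))
    report = TrainingReport(
        mse_train=tuple(curves["train"]),
        mse_val=tuple(curves["val"]),
        mse_test=tuple(curves["test"]),
        stop_epoch=epoch,
        best_val_epoch=best_epoch,
        stop_reason=stop_reason,
        seed=config.seed,
    )
    return trained, report


def regression_diagnostics(
    network: Network, table: ResponseTable, group: ResponseGroup, split: DataSplit
) -> dict:
    """Per-subset and pooled squared correlation of predicted vs observed.

    Predictions are in original units; R² is the squared Pearson
    correlation over all (run, response) pairs of the subset.  A constant
    prediction vector has undefined correlation and is reported as 0.
    """
    idx_resp = [table.response_index(n) for n in group.members]
    pred = network.predict(table.design.actual_matrix)
    obs = table.means[:, idx_resp]

    def r2(idx):
        if len(idx) == 0:
            return np.nan
        p, o = pred[idx].ravel(), obs[idx].ravel()
        if p.std() == 0 or o.std() == 0:
            return 0.0
        return float(np.corrcoef(p, o)[0, 1] ** 2)

    all_idx = np.arange(table.n_runs)
    return {
        "r2_train": r2(split.train_idx),
        "r2_val": r2(split.val_idx),
        "r2_test": r2(split.test_idx),
        "r2_pooled": r2(all_idx),
        "predictions": pred,
        "response_names": tuple(group.members),
    }
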