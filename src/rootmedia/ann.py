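"""Feed-forward surrogate networks for the five rooting responses.

Each response (RN, RL, R%, FW, DW) gets its own single-output network with
the fixed topology used in the study: 5 inputs (ion concentrations), one
hidden layer of 8 tansig units, one linear output.  For a hidden unit i,

    S_i = sum_n w_ni x_n + b_i,    h_i = tansig(S_i) = tanh(S_i)

and the output is a linear combination of the h_i plus a bias.  Training
minimizes squared error on min–max normalized data with a damped Gauss–
Newton (Levenberg–Marquardt) loop using the analytic Jacobian; a full-batch
gradient-descent-with-momentum trainer is available as a fallback.
Training stops when the per-sample training MSE reaches the goal (0.01 in
normalized units) or after 800 epochs, whichever comes first, and the
weights with the lowest recorded training MSE are returned.

Fit quality is reported with R², RMSE and the signed mean bias error (MBE);
an absolute-error variant (MAE) is exposed separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .synth import RESPONSES, NormalizationSpec

__all__ = [
    "NetworkWeights",
    "TrainingConfig",
    "FitReport",
    "ResponseModel",
    "tansig",
    "forward",
    "train",
    "r_squared",
    "rmse",
    "mbe",
    "mae",
    "mse",
]

N_HIDDEN = 8


def tansig(n):
    """Hyperbolic tangent sigmoid, 2/(1+exp(−2n)) − 1 ≡ tanh(n)."""
    return np.tanh(n)


@dataclass
class NetworkWeights:
    """All parameters of one n_in–8–1 network (normalized space).

    ``hidden_weights`` is (8, n_in), ``hidden_biases`` (8,),
    ``output_weights`` (8,), ``output_bias`` scalar.
    """

    hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        n_hidden, _ = self.hidden_weights.shape
        if self.hidden_biases.shape != (n_hidden,) or self.output_weights.shape != (n_hidden,):
            raise ValueError("inconsistent network shapes")
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite network parameter")

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    # flat parameter vector <-> structured, used by the LM trainer
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.hidden_biases,
                self.output_weights,
                [self.output_bias],
            ]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, n_inputs: int, n_hidden: int = N_HIDDEN):
        k = n_hidden * n_inputs
        return cls(
            hidden_weights=theta[:k].reshape(n_hidden, n_inputs),
            hidden_biases=theta[k : k + n_hidden],
            output_weights=theta[k + n_hidden : k + 2 * n_hidden],
            output_bias=float(theta[-1]),
        )

    def to_dict(self) -> dict:
        return {
            "topology": [self.n_inputs, self.n_hidden, 1],
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkWeights":
        return cls(
            np.array(d["hidden_weights"]),
            np.array(d["hidden_biases"]),
            np.array(d["output_weights"]),
            float(d["output_bias"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkWeights":
        return cls.from_dict(json.loads(Path(path).read_text()))


def forward(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Network output (normalized space) for inputs ``X`` of shape (n, n_in)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.n_inputs:
        raise ValueError(f"expected {weights.n_inputs} inputs, got {X.shape[1]}")
    H = tansig(X @ weights.hidden_weights.T + weights.hidden_biases)
    return H @ weights.output_weights + weights.output_bias


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters (study defaults)."""

    max_epochs: int = 800
    mse_goal: float = 0.01
    algorithm: Literal["levenberg_marquardt", "gradient_descent_momentum"] = (
        "levenberg_marquardt"
    )
    lm_damping_init: float = 1e-3
    lm_damping_factor: float = 10.0
    lm_damping_max: float = 1e10
    learning_rate: float = 0.05
    momentum: float = 0.9
    n_hidden: int = N_HIDDEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.mse_goal <= 0:
            raise ValueError("mse_goal must be > 0")


def _init_weights(n_inputs: int, n_hidden: int, rng: np.random.Generator) -> NetworkWeights:
    # symmetric small-scale init, scaled by fan-in, fully seeded
    return NetworkWeights(
        hidden_weights=rng.uniform(-0.5, 0.5, (n_hidden, n_inputs)) / np.sqrt(n_inputs),
        hidden_biases=rng.uniform(-0.5, 0.5, n_hidden),
        output_weights=rng.uniform(-0.5, 0.5, n_hidden) / np.sqrt(n_hidden),
        output_bias=float(rng.uniform(-0.5, 0.5)),
    )


def _jacobian(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """d(prediction)/d(theta), shape (n_samples, n_params)."""
    H = tansig(X @ weights.hidden_weights.T + weights.hidden_biases)  # (n, h)
    G = (1.0 - H**2) * weights.output_weights  # (n, h): dy/dS_i
    J_W1 = G[:, :, None] * X[:, None, :]  # (n, h, n_in)
    n = X.shape[0]
    return np.concatenate(
        [J_W1.reshape(n, -1), G, H, np.ones((n, 1))], axis=1
    )


@dataclass
class TrainResult:
    weights: NetworkWeights
    train_mse: float
    epochs: int
    stop_reason: str
    mse_history: list[float] = field(default_factory=list, repr=False)


def train(X: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None) -> TrainResult:
    """Fit a network to normalized inputs/targets.

    ``X`` is (n, n_in), ``y`` (n,), both on the [−1, 1] scale.  Deterministic
    given ``config.seed`` (the seed controls weight initialization only).
    Raises on non-finite data; a constant target yields a constant predictor
    with a warning.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, n_in) with one target per row")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    n, n_in = X.shape
    if np.ptp(y) == 0.0:
        warnings.warn("constant training target; returning constant predictor")
        w = NetworkWeights(
            np.zeros((config.n_hidden, n_in)), np.zeros(config.n_hidden),
            np.zeros(config.n_hidden), float(y[0]),
        )
        return TrainResult(w, 0.0, 0, "constant_target", [0.0])

    rng = np.random.default_rng(config.seed)
    weights = _init_weights(n_in, config.n_hidden, rng)

    if config.algorithm == "levenberg_marquardt":
        return _train_lm(X, y, weights, config)
    if config.algorithm == "gradient_descent_momentum":
        return _train_gdm(X, y, weights, config)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")


def _train_lm(X, y, weights: NetworkWeights, config: TrainingConfig) -> TrainResult:
    n, n_in = X.shape
    theta = weights.to_vector()
    lam = config.lm_damping_init
    residual = forward(weights, X) - y
    sse = float(residual @ residual)
    history = [sse / n]
    best_theta, best_sse = theta.copy(), sse
    stop_reason = "max_epochs"
    epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        if sse / n <= config.mse_goal:
            stop_reason = "mse_goal"
            epoch -= 1
            break
        J = _jacobian(weights, X)
        JtJ = J.T @ J
        g = J.T @ residual
        accepted = False
        while lam <= config.lm_damping_max:
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= config.lm_damping_factor
                continue
            cand = NetworkWeights.from_vector(theta + delta, n_in, config.n_hidden)
            cand_res = forward(cand, X) - y
            cand_sse = float(cand_res @ cand_res)
            if np.isfinite(cand_sse) and cand_sse < sse:
                theta = theta + delta
                weights, residual, sse = cand, cand_res, cand_sse
                lam = max(lam / config.lm_damping_factor, 1e-15)
                accepted = True
                break
            lam *= config.lm_damping_factor
        history.append(sse / n)
        if sse < best_sse:
            best_theta, best_sse = theta.copy(), sse
        if not accepted:
            stop_reason = "damping_limit"
            break
    else:
        if sse / n <= config.mse_goal:
            stop_reason = "mse_goal"

    if not np.isfinite(best_sse):
        raise FloatingPointError("training diverged to non-finite loss")
    best = NetworkWeights.from_vector(best_theta, n_in, config.n_hidden)
    return TrainResult(best, best_sse / n, epoch, stop_reason, history)


def _train_gdm(X, y, weights: NetworkWeights, config: TrainingConfig) -> TrainResult:
    n, n_in = X.shape
    theta = weights.to_vector()
    velocity = np.zeros_like(theta)
    best_theta, best_mse = theta.copy(), np.inf
    history: list[float] = []
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        w = NetworkWeights.from_vector(theta, n_in, config.n_hidden)
        residual = forward(w, X) - y
        cur = float(residual @ residual) / n
        history.append(cur)
        if not np.isfinite(cur):
            raise FloatingPointError("training diverged to non-finite loss")
        if cur < best_mse:
            best_theta, best_mse = theta.copy(), cur
        if cur <= config.mse_goal:
            stop_reason = "mse_goal"
            break
        grad = 2.0 / n * (_jacobian(w, X).T @ residual)
        velocity = config.momentum * velocity - config.learning_rate * grad
        theta = theta + velocity
    best = NetworkWeights.from_vector(best_theta, n_in, config.n_hidden)
    return TrainResult(best, best_mse, epoch, stop_reason, history)


# ---------------------------------------------------------------------------
# Goodness-of-fit metrics


def _check_pair(observed, predicted):
    O = np.asarray(observed, dtype=float).ravel()
    M = np.asarray(predicted, dtype=float).ravel()
    if O.size == 0 or O.shape != M.shape:
        raise ValueError("observed/predicted must be equal-length, nonzero-length")
    return O, M


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − Σ(M−O)² / Σ(O−Ō)²."""
    O, M = _check_pair(observed, predicted)
    denom = float(np.sum((O - O.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("R² undefined: observed values have zero variance")
    return 1.0 - float(np.sum((M - O) ** 2)) / denom


def rmse(observed, predicted) -> float:
    """Root mean squared error, sqrt(Σ(M−O)²/n)."""
    O, M = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((M - O) ** 2)))


def mbe(observed, predicted) -> float:
    """Signed mean bias error, (1/n)Σ(M−O): positive = over-prediction."""
    O, M = _check_pair(observed, predicted)
    return float(np.mean(M - O))


def mae(observed, predicted) -> float:
    """Mean absolute error, (1/n)Σ|M−O|."""
    O, M = _check_pair(observed, predicted)
    return float(np.mean(np.abs(M - O)))


def mse(observed, predicted) -> float:
    """Per-sample mean squared error."""
    O, M = _check_pair(observed, predicted)
    return float(np.mean((M - O) ** 2))


def _metric_block(observed, predicted) -> dict:
    return {
        "r2": r_squared(observed, predicted),
        "rmse": rmse(observed, predicted),
        "mbe": mbe(observed, predicted),
        "mae": mae(observed, predicted),
        "mse": mse(observed, predicted),
    }


@dataclass
class FitReport:
    """Train/test goodness-of-fit in both original and normalized units."""

    response: str
    train: dict
    test: dict
    train_normalized: dict
    test_normalized: dict
    epochs: int
    stop_reason: str

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "train": self.train,
            "test": self.test,
            "train_normalized": self.train_normalized,
            "test_normalized": self.test_normalized,
            "epochs": self.epochs,
            "stop_reason": self.stop_reason,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class ResponseModel:
    """A trained network bundled with its normalization, predicting on the
    original (mM in, response units out) scale."""

    response: str
    weights: NetworkWeights
    norm: NormalizationSpec

    def predict(self, ions_mM: np.ndarray, clip_domain: bool = True) -> np.ndarray:
        """Predict the response for (n, 5) ion concentrations in mM.

        By default predictions are clamped to the response's physical domain
        (non-negative; rooting percentage within [0, 1]), mirroring the
        clamping applied to observed replicates — the linear output unit is
        otherwise free to extrapolate outside the meaningful range.
        """
        Xn = self.norm.transform_ions(np.atleast_2d(ions_mM))
        y = self.norm.inverse_value(forward(self.weights, Xn))
        if clip_domain and self.response in RESPONSES:
            lo, hi = RESPONSES[self.response][1]
            y = np.clip(y, lo, hi)
        return y

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "weights": self.weights.to_dict(),
            "normalization": self.norm.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseModel":
        return cls(
            d["response"],
            NetworkWeights.from_dict(d["weights"]),
            NormalizationSpec.from_dict(d["normalization"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ResponseModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_report(
    response: str,
    weights: NetworkWeights,
    norm: NormalizationSpec,
    Xn_train: np.ndarray,
    yn_train: np.ndarray,
    Xn_test: np.ndarray,
    yn_test: np.ndarray,
    epochs: int,
    stop_reason: str,
) -> FitReport:
    """Assemble a FitReport from normalized partitions.

    Original-scale metrics come from denormalized observations/predictions;
    R² is scale-invariant but RMSE/MBE are not, so both scales are kept.
    """
    pred_train_n = forward(weights, Xn_train)
    pred_test_n = forward(weights, Xn_test)
    return FitReport(
        response=response,
        train=_metric_block(norm.inverse_value(yn_train), norm.inverse_value(pred_train_n)),
        test=_metric_block(norm.inverse_value(yn_test), norm.inverse_value(pred_test_n)),
        train_normalized=_metric_block(yn_train, pred_train_n),
        test_normalized=_metric_block(yn_test, pred_test_n),
        epochs=epochs,
        stop_reason=stop_reason,
    )
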