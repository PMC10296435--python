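"""Multi-layer perceptron with tanh activations and Levenberg-Marquardt training.

The network is fully connected with bias units, tanh on every layer
(including the output), and one-hot +/-1 targets decoded by argmax. Training
minimizes the summed squared error E = 1/2 * sum (o_d - o)^2 with damped
Gauss-Newton steps: the residual Jacobian is assembled by backpropagation
and each update solves (J^T J + lambda I) dw = J^T r, shrinking lambda on
accepted steps and inflating it on rejected ones, so the error over
accepted steps never increases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class MLPArchitecture:
    input_dim: int
    hidden_layers: tuple[int, ...] = (10, 10, 10)
    output_dim: int = 6
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValueError("all layer sizes must be >= 1")
        if self.activation != "tanh":
            raise ValueError("only the hyperbolic tangent activation is supported")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *self.hidden_layers, self.output_dim]


@dataclass(frozen=True)
class TrainConfig:
    """LM damping schedule and stopping rule.

    ``lambda_init`` is the initial damping (the only "learning-rate-like"
    knob of damped Gauss-Newton); it is multiplied by ``lambda_down`` after
    an accepted step and by ``lambda_up`` after a rejected one, within
    [1e-12, 1e12].
    """

    lambda_init: float = 1e-4
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    max_epochs: int = 300
    grad_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_init <= 0:
            raise ValueError("lambda_init must be positive")
        if not (self.lambda_up > 1 > self.lambda_down > 0):
            raise ValueError("need lambda_up > 1 > lambda_down > 0")


@dataclass
class MLPModel:
    """Weights (with bias column: shape (fan_in + 1, fan_out) per layer)."""

    architecture: MLPArchitecture
    weights: list[np.ndarray]
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    classes: tuple | None = None
    epochs_run: int = 0
    final_error: float = float("nan")
    seed: int = 0
    # E after the initial point and each accepted LM step (not persisted)
    error_trace: list = field(default_factory=list)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        blob = {
            "layer_sizes": self.architecture.layer_sizes,
            "activation": self.architecture.activation,
            "weights": [w.tolist() for w in self.weights],
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_std": None if self.scaler_std is None else self.scaler_std.tolist(),
            "classes": None if self.classes is None else list(self.classes),
            "epochs_run": self.epochs_run,
            "final_error": self.final_error,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        blob = json.loads(Path(path).read_text())
        sizes = blob["layer_sizes"]
        arch = MLPArchitecture(
            input_dim=sizes[0],
            hidden_layers=tuple(sizes[1:-1]),
            output_dim=sizes[-1],
            activation=blob["activation"],
        )
        return cls(
            architecture=arch,
            weights=[np.array(w) for w in blob["weights"]],
            scaler_mean=None if blob["scaler_mean"] is None else np.array(blob["scaler_mean"]),
            scaler_std=None if blob["scaler_std"] is None else np.array(blob["scaler_std"]),
            classes=None if blob["classes"] is None else tuple(blob["classes"]),
            epochs_run=blob["epochs_run"],
            final_error=blob["final_error"],
            seed=blob["seed"],
        )


def init_weights(arch: MLPArchitecture, seed: int = 0) -> list[np.ndarray]:
    """Uniform init in +/- 1/sqrt(fan_in), bias row included."""
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes
    return [
        rng.uniform(-1.0, 1.0, size=(fan_in + 1, fan_out)) / np.sqrt(fan_in)
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
    ]


def _forward_all(weights: list[np.ndarray], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer (including input), tanh everywhere."""
    acts = [X]
    a = X
    for W in weights:
        a = np.tanh(np.hstack([a, np.ones((a.shape[0], 1))]) @ W)
        acts.append(a)
    return acts


def forward(model: MLPModel, v: np.ndarray) -> np.ndarray:
    """Network output for a single input vector (or (n, d) batch)."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    X = v[None, :] if single else v
    if X.shape[1] != model.architecture.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, expected {model.architecture.input_dim}"
        )
    out = _forward_all(model.weights, X)[-1]
    return out[0] if single else out


def sse_loss(outputs: np.ndarray, desired: np.ndarray) -> float:
    """E = 1/2 * sum over outputs of (desired - actual)^2."""
    o = np.asarray(outputs, dtype=float)
    d = np.asarray(desired, dtype=float)
    if o.shape != d.shape:
        raise ValueError("output/target length mismatch")
    return 0.5 * float(((d - o) ** 2).sum())


def _pack(weights: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights])


def _unpack(flat: np.ndarray, shapes: list[tuple[int, int]]) -> list[np.ndarray]:
    out, k = [], 0
    for shp in shapes:
        size = shp[0] * shp[1]
        out.append(flat[k : k + size].reshape(shp))
        k += size
    return out


def residual_jacobian(
    weights: list[np.ndarray], X: np.ndarray, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals r = (T - O).ravel() and their Jacobian wrt all weights.

    Backpropagates one sensitivity per output unit through the tanh layers;
    rows are ordered sample-major, columns follow the packed weight layout.
    """
    n = X.shape[0]
    n_out = weights[-1].shape[1]
    acts = _forward_all(weights, X)
    r = (T - acts[-1]).ravel()
    n_w = sum(w.size for w in weights)
    J = np.zeros((n * n_out, n_w))
    # delta[s, k, j]: d o_k / d (pre-activation j of current layer)
    L = len(weights)
    deriv = [1.0 - a**2 for a in acts[1:]]  # tanh'
    delta = np.einsum("sk,kj->skj", deriv[-1], np.eye(n_out))
    col = n_w
    for l in range(L - 1, -1, -1):
        a_prev = np.hstack([acts[l], np.ones((n, 1))])  # (n, fan_in+1)
        # dr/dW_l = -delta ; J rows for residuals (T - O): d r / d w = -d o / d w
        # grad of o_k wrt W_l[i, j] = delta[s, k, j] * a_prev[s, i]
        block = np.einsum("si,skj->skij", a_prev, delta)  # (n, n_out, fan_in+1, fan_out)
        size = weights[l].size
        col -= size
        J[:, col : col + size] = -block.reshape(n * n_out, size)
        if l > 0:
            W_no_bias = weights[l][:-1, :]  # (fan_in, fan_out)
            delta = np.einsum("skj,ij->ski", delta, W_no_bias) * deriv[l - 1][:, None, :]
    return r, J


def one_hot_targets(labels: np.ndarray, classes: list) -> np.ndarray:
    """+/-1 one-hot coding (tanh-compatible targets)."""
    T = -np.ones((len(labels), len(classes)))
    lut = {c: i for i, c in enumerate(classes)}
    for s, lab in enumerate(labels):
        T[s, lut[lab]] = 1.0
    return T


def train_lm(
    X: np.ndarray,
    labels: np.ndarray,
    arch: MLPArchitecture | None = None,
    cfg: TrainConfig | None = None,
    *,
    classes: list | None = None,
    standardize: bool = True,
) -> MLPModel:
    """Train by full-batch Levenberg-Marquardt on +/-1 one-hot targets.

    Features are z-scored with training statistics (stored on the model and
    re-applied at prediction). Training stops at ``max_epochs``, when the
    gradient norm falls below ``grad_tol``, or when the damping leaves its
    working range.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    cls = list(classes) if classes is not None else sorted(np.unique(labels).tolist())
    if len(cls) < 2:
        raise ValueError("need at least 2 classes")
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        Xs = (X - mean) / std
    else:
        mean, std = None, None
        Xs = X
    arch = arch or MLPArchitecture(input_dim=X.shape[1], output_dim=len(cls))
    T = one_hot_targets(labels, cls)

    weights = init_weights(arch, cfg.seed)
    shapes = [w.shape for w in weights]
    w_flat = _pack(weights)
    lam = cfg.lambda_init
    r, J = residual_jacobian(weights, Xs, T)
    err = 0.5 * float(r @ r)
    error_trace = [err]
    epochs = 0
    for _ in range(cfg.max_epochs):
        g = J.T @ r
        if np.linalg.norm(g) <= cfg.grad_tol:
            break
        H = J.T @ J
        accepted = False
        while lam <= 1e12:
            try:
                # residual r = T - O, J = dr/dw, so Gauss-Newton step is
                # dw = -(J'J + lam I)^{-1} J'r
                dw = np.linalg.solve(H + lam * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                raise RuntimeError("singular LM system despite damping")
            cand = _unpack(w_flat + dw, shapes)
            r_new, J_new = residual_jacobian(cand, Xs, T)
            err_new = 0.5 * float(r_new @ r_new)
            if err_new < err:
                w_flat = w_flat + dw
                weights = cand
                r, J, err = r_new, J_new, err_new
                lam = max(lam * cfg.lambda_down, 1e-12)
                accepted = True
                error_trace.append(err)
                break
            lam *= cfg.lambda_up
        epochs += 1
        if not accepted:
            break  # damping exhausted: local minimum to working precision
    return MLPModel(
        architecture=arch,
        weights=weights,
        scaler_mean=mean,
        scaler_std=std,
        classes=tuple(cls),
        epochs_run=epochs,
        final_error=err,
        seed=cfg.seed,
        error_trace=error_trace,
    )


def predict(model: MLPModel, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and raw score vectors; argmax with lowest-index ties.

    Requires a trained model (class list attached).
    """
    if model.classes is None:
        raise ValueError("model has no classes: train it first")
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    X = v[None, :] if single else v
    if model.scaler_mean is not None:
        X = (X - model.scaler_mean) / model.scaler_std
    scores = forward(model, X)
    idx = np.argmax(scores, axis=1)  # np.argmax takes the first (lowest) index on ties
    labels = np.array([model.classes[i] for i in idx])
    if single:
        return labels[0], scores[0]
    return labels, scores
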