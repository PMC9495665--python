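"""Dense regression network for per-sample ECG channel reconstruction.

The reconstruction task is framed as instantaneous regression: the
network maps the value(s) of one or two input channels at a sample to the
value of the target channel at the same sample (no temporal windowing).
Candidate architectures are fully connected stacks of 3-8 hidden layers,
each with 5-255 units and one of six activation functions; training uses
minibatch RMSProp (or Adam/SGD), MSE or MAE loss, early stopping with a
patience of 10 epochs on the validation loss, and a checkpoint that
restores the weights of the best epoch before evaluation.

The network is implemented directly on numpy so that per-layer
activations, the RMSProp update and checkpoint-restore semantics are
exactly as specified and fully deterministic under a seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .metrics import MetricReport, PredictionPair, metric_report

__all__ = [
    "ACTIVATIONS",
    "SELU_ALPHA",
    "SELU_BETA",
    "activation_eval",
    "ArchitectureSpec",
    "TrialResult",
    "build_and_train",
]

#: Constants of the scaled exponential-linear unit variant used here:
#: f(x) = x for x > 0, alpha * beta * (e^x - 1) otherwise.
SELU_ALPHA = 1.76
SELU_BETA = 1.05

ACTIVATIONS = ("relu", "elu", "selu", "sigmoid", "tanh", "linear")

OPTIMIZERS = ("rmsprop", "adam", "sgd")
LOSSES = ("mse", "mae", "val_loss")
EPOCH_LEVELS = (10, 100, 200)


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "elu":  # alpha = 1
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if name == "selu":
        return np.where(x > 0, x, SELU_ALPHA * SELU_BETA * np.expm1(np.minimum(x, 0.0)))
    if name == "sigmoid":
        # overflow-safe equivalent of 1 / (1 + e^-x)
        return 0.5 * (1.0 + np.tanh(0.5 * x))
    if name == "tanh":
        return np.tanh(x)
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")


def _act_grad(name: str, x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    """Derivative of the activation, reusing the forward value where cheap."""
    if name == "relu":
        return (x > 0).astype(x.dtype)
    if name == "elu":
        return np.where(x > 0, 1.0, fx + 1.0)
    if name == "selu":
        return np.where(x > 0, 1.0, fx + SELU_ALPHA * SELU_BETA)
    if name == "sigmoid":
        return fx * (1.0 - fx)
    if name == "tanh":
        return 1.0 - fx * fx
    if name == "linear":
        return np.ones_like(x)
    raise ValueError(f"unknown activation {name!r}")


def activation_eval(kind: str, x):
    """Evaluate one activation function elementwise.

    ``kind`` is one of relu, elu, selu, sigmoid, tanh, linear.  The selu
    variant keeps the positive branch at plain ``x`` and scales only the
    exponential branch by alpha*beta = 1.76 * 1.05.
    """
    arr = np.asarray(x, dtype=float)
    out = _act(kind, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ArchitectureSpec:
    """One concrete network configuration.

    Attributes
    ----------
    n_inputs : int
        Input width (1 or 2 channels for the three-channel recording sets).
    units : tuple of int
        Hidden-layer widths, each in [5, 255]; the length sets the depth
        (3-8 hidden layers).
    activations : tuple of str
        Per-hidden-layer activation names, same length as ``units``.
    optimizer : str
        rmsprop (default), adam or sgd.
    loss : str
        Training objective: mse, mae, or val_loss (trains on MSE while
        model selection tracks the validation MSE, which it does for the
        other losses as well).
    epochs : int
        Maximum training epochs, one of {10, 100, 200}.
    patience : int
        Early-stopping patience on the validation loss (default 10).
    batch_size : int
        Minibatch size (default 32).
    sigmoid_head : bool
        If True, squash the single linear output unit with a sigmoid;
        default False (plain linear regression head).
    """

    n_inputs: int
    units: tuple
    activations: tuple
    optimizer: str = "rmsprop"
    loss: str = "mse"
    epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    sigmoid_head: bool = False

    def __post_init__(self) -> None:
        units = tuple(int(u) for u in self.units)
        acts = tuple(str(a).lower() for a in self.activations)
        object.__setattr__(self, "units", units)
        object.__setattr__(self, "activations", acts)
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if not 3 <= len(units) <= 8:
            raise ValueError(f"depth must be 3-8 hidden layers, got {len(units)}")
        if len(acts) != len(units):
            raise ValueError("one activation per hidden layer required")
        if any(not 5 <= u <= 255 for u in units):
            raise ValueError("units per layer must lie in [5, 255]")
        for a in acts:
            if a not in ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if int(self.epochs) not in EPOCH_LEVELS:
            raise ValueError(f"epochs must be one of {EPOCH_LEVELS}")
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.units)

    def as_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "units": list(self.units),
            "activations": list(self.activations),
            "optimizer": self.optimizer,
            "loss": self.loss,
            "epochs": self.epochs,
            "patience": self.patience,
            "batch_size": self.batch_size,
            "sigmoid_head": self.sigmoid_head,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            n_inputs=int(d["n_inputs"]),
            units=tuple(d["units"]),
            activations=tuple(d["activations"]),
            optimizer=d.get("optimizer", "rmsprop"),
            loss=d.get("loss", "mse"),
            epochs=int(d.get("epochs", 100)),
            patience=int(d.get("patience", 10)),
            batch_size=int(d.get("batch_size", 32)),
            sigmoid_head=bool(d.get("sigmoid_head", False)),
        )


@dataclass(frozen=True)
class TrialResult:
    """Outcome of training and evaluating one architecture.

    Test metrics are computed on the held-out block only, after restoring
    the checkpointed best-epoch weights.  ``failed`` marks trials whose
    loss became non-finite; their metrics are NaN and they rank last.
    """

    spec: ArchitectureSpec
    metrics: MetricReport
    best_epoch: int
    seed: int
    epochs_run: int = 0
    wall_clock: float = 0.0
    failed: bool = False
    val_history: tuple = ()  # per-epoch validation MSE (diagnostic)

    @property
    def r2(self) -> float:
        return self.metrics.r2

    def sort_key(self, metric: str = "r2") -> float:
        """Ranking key: higher is better (error metrics are negated)."""
        value = getattr(self.metrics, metric)
        if self.failed or not np.isfinite(value):
            return -np.inf
        return value if metric == "r2" else -value

    def as_dict(self) -> dict:
        return {
            "spec": self.spec.as_dict(),
            "metrics": self.metrics.as_dict(),
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "epochs_run": self.epochs_run,
            "wall_clock": self.wall_clock,
            "failed": self.failed,
        }


# ---------------------------------------------------------------------------
# network internals


class _Network:
    """Weights + forward/backward for a dense stack (float32 throughout)."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        widths = [spec.n_inputs, *spec.units, 1]
        self.acts = [*spec.activations, "sigmoid" if spec.sigmoid_head else "linear"]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)
            )
            self.b.append(np.zeros(fan_out, dtype=np.float32))

    def forward(self, X: np.ndarray):
        zs, hs = [], [X]
        h = X
        for W, b, act in zip(self.W, self.b, self.acts):
            z = h @ W + b
            h = _act(act, z)
            zs.append(z)
            hs.append(h)
        return zs, hs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1][-1][:, 0]

    def backward(self, zs, hs, dloss: np.ndarray):
        """Gradient of the loss w.r.t. every weight; dloss = dL/d(output)."""
        grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
        delta = dloss[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            delta = delta * _act_grad(self.acts[i], zs[i], hs[i + 1])
            grads_W[i] = hs[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return grads_W, grads_b

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


class _Optimizer:
    """SGD / RMSProp / Adam with the conventional default settings."""

    def __init__(self, name: str, params):
        self.name = name
        self.lr = {"sgd": 0.01, "rmsprop": 0.001, "adam": 0.001}[name]
        self.t = 0
        self.cache = [np.zeros_like(p) for p in params]
        if name == "adam":
            self.cache2 = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        self.t += 1
        eps, rho, b1, b2 = 1e-7, 0.9, 0.9, 0.999
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g.astype(np.float32)
            if self.name == "sgd":
                p -= self.lr * g
            elif self.name == "rmsprop":
                self.cache[i] = rho * self.cache[i] + (1 - rho) * g * g
                p -= self.lr * g / (np.sqrt(self.cache[i]) + eps)
            else:  # adam
                self.cache[i] = b1 * self.cache[i] + (1 - b1) * g
                self.cache2[i] = b2 * self.cache2[i] + (1 - b2) * g * g
                m_hat = self.cache[i] / (1 - b1**self.t)
                v_hat = self.cache2[i] / (1 - b2**self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)


def _loss_and_grad(name: str, y: np.ndarray, yhat: np.ndarray):
    resid = yhat - y
    if name == "mae":
        return float(np.mean(np.abs(resid))), np.sign(resid) / y.size
    # mse, and val_loss (which trains on MSE)
    return float(np.mean(resid**2)), 2.0 * resid / y.size


def build_and_train(
    spec: ArchitectureSpec,
    train: tuple,
    test: tuple,
    seed: int = 0,
) -> TrialResult:
    """Train one architecture and evaluate it on the held-out block."""
    return build_train_predict(spec, train, test, seed=seed)[0]


def build_train_predict(
    spec: ArchitectureSpec,
    train: tuple,
    test: tuple,
    seed: int = 0,
) -> tuple:
    """Train one architecture; return (TrialResult, test predictions).

    Training runs for at most ``spec.epochs`` epochs of shuffled
    minibatches, monitoring the MSE on the held-out block after every
    epoch.  Early stopping halts after ``spec.patience`` epochs without
    a new best validation loss, and the weights of the best epoch are
    restored before the test metrics are computed.  A non-finite loss
    marks the trial as failed (NaN metrics) instead of raising.

    Parameters
    ----------
    spec : ArchitectureSpec
        Network configuration; ``spec.n_inputs`` must match the data.
    train, test : (X, y) pairs
        Already filtered/normalized splits; X is (n, d), y is (n,).
    seed : int
        Seeds both weight initialization and minibatch shuffling.
    """
    t0 = time.perf_counter()
    Xtr = np.asarray(train[0], dtype=np.float32)
    ytr = np.asarray(train[1], dtype=np.float32).ravel()
    Xte = np.asarray(test[0], dtype=np.float32)
    yte = np.asarray(test[1], dtype=np.float32).ravel()
    if Xtr.ndim == 1:
        Xtr = Xtr[:, None]
    if Xte.ndim == 1:
        Xte = Xte[:, None]
    if Xtr.shape[1] != spec.n_inputs:
        raise ValueError(
            f"spec expects {spec.n_inputs} input(s) but data has {Xtr.shape[1]}"
        )

    rng = np.random.default_rng(seed)
    net = _Network(spec, rng)
    params = [*net.W, *net.b]
    opt = _Optimizer(spec.optimizer, params)

    best_val = np.inf
    best_epoch = -1
    best_weights = net.get_weights()
    wait = 0
    failed = False
    n = ytr.size
    epochs_run = 0
    val_history = []

    for epoch in range(spec.epochs):
        epochs_run = epoch + 1
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            zs, hs = net.forward(Xtr[idx])
            loss, dloss = _loss_and_grad(spec.loss, ytr[idx], hs[-1][:, 0])
            if not np.isfinite(loss):
                failed = True
                break
            gW, gb = net.backward(zs, hs, dloss)
            opt.step([*net.W, *net.b], [*gW, *gb])
        if failed:
            break
        val_pred = net.predict(Xte)
        val_loss = float(np.mean((val_pred - yte) ** 2))
        if not np.isfinite(val_loss):
            failed = True
            break
        val_history.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= spec.patience:
                break

    wall = time.perf_counter() - t0
    if failed and best_epoch < 0:
        nan_report = MetricReport(r2=np.nan, mae=np.nan, mse=np.nan, sd=np.nan)
        result = TrialResult(
            spec=spec, metrics=nan_report, best_epoch=-1, seed=seed,
            epochs_run=epochs_run, wall_clock=wall, failed=True,
            val_history=tuple(val_history),
        )
        return result, np.full(yte.size, np.nan)

    net.set_weights(best_weights)
    pred = net.predict(Xte).astype(float)
    try:
        report = metric_report(PredictionPair(yte.astype(float), pred))
    except ValueError:
        report = MetricReport(r2=np.nan, mae=np.nan, mse=np.nan, sd=np.nan)
        failed = True
    result = TrialResult(
        spec=spec, metrics=report, best_epoch=best_epoch, seed=seed,
        epochs_run=epochs_run, wall_clock=wall, failed=failed,
        val_history=tuple(val_history),
    )
    return result, pred
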