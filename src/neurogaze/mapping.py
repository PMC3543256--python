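"""The gaze mapping function: two single-output feed-forward networks.

The mapping from the 8 extracted eye coordinates (pupil centre + three
glint centroids) to the on-screen point of gaze is learned, not derived
from a geometric eye/camera model.  Two separate one-hidden-layer
networks — tanh hidden units, a single linear output each — estimate the
X and Y screen coordinates independently and are trained by standard
full-batch backpropagation (gradient descent with momentum) on the
calibration set.  Screen coordinates are produced by quantizing the two
network outputs to integer pixels.  An ordinary-least-squares linear
mapping over the same features serves as the comparison baseline.

Inputs and targets are affinely normalized to [-1, 1] before training;
the normalizers are part of the persisted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .features import EyeFeatures
from .geometry import ScreenGeometry

__all__ = [
    "MFNN",
    "Normalizer",
    "TrainingSet",
    "TrainConfig",
    "GazeModel",
    "init_mfnn",
    "mfnn_forward",
    "loss_and_gradients",
    "train_backprop",
    "fit_gaze_model",
    "fit_linear_baseline",
    "predict_pog",
    "save_model",
    "load_model",
]


@dataclass
class MFNN:
    """One-hidden-layer feed-forward net, tanh hidden / linear output."""

    W1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        h, n_in = self.W1.shape
        if self.b1.shape != (h,) or self.W2.shape != (1, h) or self.b2.shape != (1,):
            raise ValueError("inconsistent network shapes")
        for a in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(a)):
                raise ValueError("network weights must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "MFNN":
        return MFNN(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        """Outputs for a (N, n_inputs) batch; returns shape (N,)."""
        H = np.tanh(X @ self.W1.T + self.b1)
        return (H @ self.W2.T + self.b2).ravel()


def init_mfnn(n_in: int, n_hidden: int, init_scale: float, seed: int) -> MFNN:
    """Uniform [-init_scale, init_scale] weights, zero biases, seeded."""
    if n_in < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    return MFNN(
        W1=rng.uniform(-init_scale, init_scale, size=(n_hidden, n_in)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-init_scale, init_scale, size=(1, n_hidden)),
        b2=np.zeros(1),
    )


def mfnn_forward(net: MFNN, x: np.ndarray) -> float:
    """Scalar output y = W2 . tanh(W1 x + b1) + b2 for one input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"expected input of length {net.n_inputs}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return float(net.forward_batch(x[None, :])[0])


def loss_and_gradients(net: MFNN, X: np.ndarray, t: np.ndarray):
    """Mean-squared-error loss and its gradients w.r.t. all weights.

    Returns ``(loss, dW1, db1, dW2, db2)``.  Exposed so the gradients
    can be cross-checked against finite differences.
    """
    N = X.shape[0]
    H = np.tanh(X @ net.W1.T + net.b1)  # (N, h)
    y = (H @ net.W2.T + net.b2).ravel()  # (N,)
    e = y - t
    loss = float(np.mean(e**2))
    dy = (2.0 / N) * e  # (N,)
    dW2 = (dy[None, :] @ H)  # (1, h)
    db2 = np.array([dy.sum()])
    dH = dy[:, None] * net.W2  # (N, h)
    dZ = dH * (1.0 - H**2)
    dW1 = dZ.T @ X
    db1 = dZ.sum(axis=0)
    return loss, dW1, db1, dW2, db2


@dataclass
class TrainConfig:
    """Backpropagation settings.

    Training always runs for exactly ``epochs`` full-batch epochs.  By
    default the classic adaptive-learning-rate schedule is used: after
    an epoch that lowers the loss the rate grows by ``lr_inc``; an epoch
    that would raise the loss by more than ``max_loss_increase`` is
    rejected, the rate shrinks by ``lr_dec`` and the momentum term is
    reset.  This keeps batch backpropagation both stable and fast on the
    strongly collinear eye-feature inputs.  ``adaptive=False`` gives
    plain fixed-rate gradient descent with momentum.
    """

    epochs: int = 1000
    learning_rate: float = 0.05
    momentum: float = 0.95
    init_scale: float = 0.5
    seed: int = 0
    mode: str = "batch"
    adaptive: bool = True
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_loss_increase: float = 1.04

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must lie in [0, 1)")
        if self.mode != "batch":
            raise ValueError("only full-batch training is implemented")
        if not (self.lr_inc >= 1.0 and 0 < self.lr_dec < 1.0
                and self.max_loss_increase >= 1.0):
            raise ValueError("invalid adaptive learning-rate constants")


def train_backprop(
    net: MFNN, X: np.ndarray, t: np.ndarray, cfg: TrainConfig
) -> tuple[MFNN, np.ndarray]:
    """Full-batch backpropagation (gradient descent with momentum) on the MSE.

    ``X``/``t`` are expected in normalized [-1, 1] units.  Returns the
    trained network (a copy) and the per-epoch training MSE history of
    length ``cfg.epochs``.  Deterministic given the initial network.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[0] != t.shape[0]:
        raise ValueError("need a nonempty (N, n_in) input batch with matching targets")
    net = net.copy()
    lr = cfg.learning_rate
    vel = [np.zeros_like(a) for a in (net.W1, net.b1, net.W2, net.b2)]
    loss, *grads = loss_and_gradients(net, X, t)
    if not np.isfinite(loss):
        raise FloatingPointError(
            "non-finite loss at initialization; check the training data"
        )
    history = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        params = (net.W1, net.b1, net.W2, net.b2)
        new_vel = [cfg.momentum * v - lr * g for v, g in zip(vel, grads)]
        candidate = MFNN(*[p + v for p, v in zip(params, new_vel)])
        new_loss, *new_grads = loss_and_gradients(candidate, X, t)
        if cfg.adaptive:
            if not np.isfinite(new_loss) or new_loss > loss * cfg.max_loss_increase:
                # reject the step: shrink the rate, restart the momentum
                lr *= cfg.lr_dec
                vel = [np.zeros_like(v) for v in vel]
            else:
                if new_loss < loss:
                    lr *= cfg.lr_inc
                net, vel, loss, grads = candidate, new_vel, new_loss, new_grads
        else:
            if not np.isfinite(new_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    f"reduce learning_rate={cfg.learning_rate}"
                )
            net, vel, loss, grads = candidate, new_vel, new_loss, new_grads
        history[epoch] = loss
    return net, history


@dataclass(frozen=True)
class Normalizer:
    """Affine per-dimension map raw -> [-1, 1] and back."""

    offset: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("normalizer scales must be positive")

    @classmethod
    def from_range(cls, lo: np.ndarray, hi: np.ndarray) -> "Normalizer":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        bad = np.nonzero(hi <= lo)[0]
        if bad.size:
            raise ValueError(
                f"degenerate range (zero spread) in dimension(s) {bad.tolist()}"
            )
        return cls(offset=(lo + hi) / 2.0, scale=(hi - lo) / 2.0)

    @classmethod
    def from_data(cls, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        return cls.from_range(X.min(axis=0), X.max(axis=0))

    def normalize(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.offset) / self.scale

    def denormalize(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) * self.scale + self.offset


@dataclass
class TrainingSet:
    """Calibration features paired with the known grid-point targets."""

    inputs: np.ndarray  # (N, 8) image px
    targets: np.ndarray  # (N, 2) screen px
    point_index: np.ndarray  # (N,) source grid point per row

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.point_index = np.asarray(self.point_index, dtype=int)
        if self.inputs.ndim != 2 or self.inputs.shape[0] == 0:
            raise ValueError("training set must be a nonempty (N, d) array")
        if self.targets.shape != (self.inputs.shape[0], 2):
            raise ValueError("targets must be (N, 2)")
        if self.point_index.shape != (self.inputs.shape[0],):
            raise ValueError("point_index must have one entry per row")
        if not (np.all(np.isfinite(self.inputs)) and np.all(np.isfinite(self.targets))):
            raise ValueError("training set contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]


@dataclass
class GazeModel:
    """A fitted feature -> POG mapping (neural or linear baseline)."""

    kind: str  # "mfnn" | "linear"
    net_x: Union[MFNN, np.ndarray]
    net_y: Union[MFNN, np.ndarray]
    input_norm: Normalizer
    output_norm: Normalizer
    screen: ScreenGeometry

    def _forward(self, xn: np.ndarray) -> np.ndarray:
        """Normalized outputs (2,) for one normalized input vector."""
        if self.kind == "mfnn":
            return np.array(
                [mfnn_forward(self.net_x, xn), mfnn_forward(self.net_y, xn)]
            )
        z = np.concatenate([[1.0], xn])
        return np.array([float(self.net_x @ z), float(self.net_y @ z)])


def _output_normalizer(screen: ScreenGeometry) -> Normalizer:
    return Normalizer.from_range(
        np.array([0.0, 0.0]),
        np.array([screen.width_px - 1.0, screen.height_px - 1.0]),
    )


def fit_gaze_model(
    train: TrainingSet, screen: ScreenGeometry, cfg: Optional[TrainConfig] = None
) -> GazeModel:
    """Train the two networks on a calibration set.

    The input normalizer is built from the per-feature min/max of the
    calibration data; outputs are trained in [-1, 1] units mapped from
    the screen pixel ranges.  The X net uses ``cfg.seed``, the Y net
    ``cfg.seed + 1`` so the two start from independent weights.
    """
    cfg = cfg or TrainConfig()
    input_norm = Normalizer.from_data(train.inputs)
    output_norm = _output_normalizer(screen)
    Xn = input_norm.normalize(train.inputs)
    Tn = output_norm.normalize(train.targets)
    nets = []
    for j, seed in enumerate((cfg.seed, cfg.seed + 1)):
        net0 = init_mfnn(train.inputs.shape[1], 10, cfg.init_scale, seed)
        net, _ = train_backprop(net0, Xn, Tn[:, j], cfg)
        nets.append(net)
    return GazeModel(
        kind="mfnn",
        net_x=nets[0],
        net_y=nets[1],
        input_norm=input_norm,
        output_norm=output_norm,
        screen=screen,
    )


def fit_linear_baseline(train: TrainingSet, screen: ScreenGeometry) -> GazeModel:
    """Ordinary least squares per coordinate over the 8 features + intercept."""
    d = train.inputs.shape[1]
    if train.n_samples < d + 1:
        raise ValueError(
            f"need at least {d + 1} samples for the linear baseline, "
            f"got {train.n_samples}"
        )
    input_norm = Normalizer.from_data(train.inputs)
    output_norm = _output_normalizer(screen)
    Xn = input_norm.normalize(train.inputs)
    Tn = output_norm.normalize(train.targets)
    A = np.hstack([np.ones((train.n_samples, 1)), Xn])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design matrix: features are collinear")
    coef, *_ = np.linalg.lstsq(A, Tn, rcond=None)
    return GazeModel(
        kind="linear",
        net_x=coef[:, 0].copy(),
        net_y=coef[:, 1].copy(),
        input_norm=input_norm,
        output_norm=output_norm,
        screen=screen,
    )


def predict_pog(
    model: GazeModel, features: Union[EyeFeatures, np.ndarray]
) -> tuple[int, int]:
    """Point of gaze in integer screen pixels (quantized network output).

    The two network outputs are denormalized to pixels, rounded to the
    nearest integer and clamped to the screen.
    """
    vec = features.vector if isinstance(features, EyeFeatures) else np.asarray(
        features, dtype=float
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite values")
    xn = model.input_norm.normalize(vec)
    out = model.output_norm.denormalize(model._forward(xn))
    x = int(np.rint(out[0]))
    y = int(np.rint(out[1]))
    x = min(max(x, 0), model.screen.width_px - 1)
    y = min(max(y, 0), model.screen.height_px - 1)
    return x, y


# --- persistence -----------------------------------------------------------

def _net_to_dict(net) -> dict:
    if isinstance(net, MFNN):
        return {
            "type": "mfnn",
            "W1": net.W1.tolist(),
            "b1": net.b1.tolist(),
            "W2": net.W2.tolist(),
            "b2": net.b2.tolist(),
        }
    return {"type": "linear", "coef": np.asarray(net).tolist()}


def _net_from_dict(d: dict):
    if d["type"] == "mfnn":
        return MFNN(np.array(d["W1"]), np.array(d["b1"]),
                    np.array(d["W2"]), np.array(d["b2"]))
    return np.array(d["coef"], dtype=float)


def save_model(model: GazeModel, path: Union[str, Path]) -> None:
    doc = {
        "kind": model.kind,
        "net_x": _net_to_dict(model.net_x),
        "net_y": _net_to_dict(model.net_y),
        "input_norm": {
            "offset": model.input_norm.offset.tolist(),
            "scale": model.input_norm.scale.tolist(),
        },
        "output_norm": {
            "offset": model.output_norm.offset.tolist(),
            "scale": model.output_norm.scale.tolist(),
        },
        "screen": {
            "width_px": model.screen.width_px,
            "height_px": model.screen.height_px,
            "diagonal_cm": model.screen.diagonal_cm,
            "viewing_distance_cm": model.screen.viewing_distance_cm,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: Union[str, Path]) -> GazeModel:
    doc = json.loads(Path(path).read_text())
    return GazeModel(
        kind=doc["kind"],
        net_x=_net_from_dict(doc["net_x"]),
        net_y=_net_from_dict(doc["net_y"]),
        input_norm=Normalizer(
            np.array(doc["input_norm"]["offset"]),
            np.array(doc["input_norm"]["scale"]),
        ),
        output_norm=Normalizer(
            np.array(doc["output_norm"]["offset"]),
            np.array(doc["output_norm"]["scale"]),
        ),
        screen=ScreenGeometry(**doc["screen"]),
    )
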