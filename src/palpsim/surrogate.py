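"""Neural-network surrogate mapping (x, y, force) to the ROI stress field.

A multilayer perceptron with five hidden layers (3 -> 64 -> 128 -> 256 ->
512 -> ROI size), positive-linear (poslin, i.e. max(0, x)) hidden
activations and a linear output layer.  Training is classical full-batch
gradient descent with momentum and an adaptive learning rate: the rate
grows by a small factor after an improving epoch, and a step that worsens
the error beyond a threshold is rejected, the rate cut and the momentum
reset.  Everything is plain NumPy and deterministic under a fixed seed.

Inputs are min–max normalised to [0, 1] per feature on the training
partition; outputs are standardised by the pooled training mean/std.
The goodness-of-fit metric is the pooled coefficient of determination
expressed as a percentage:

    fit = 100 * (1 - sum_k (y_k - yhat_k)^2 / sum_k (y_k - ybar)^2)

pooled over all test records and ROI elements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .sweep import PalpationRecord

__all__ = [
    "SurrogateModel",
    "TrainConfig",
    "FitReport",
    "build_network",
    "records_to_xy",
    "train",
    "fit_metric",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1
DEFAULT_HIDDEN = (64, 128, 256, 512)


def poslin(x: np.ndarray) -> np.ndarray:
    """Positive-linear activation max(0, x)."""
    return np.maximum(x, 0.0)


@dataclass
class SurrogateModel:
    """Weights, biases and normalisation of the stress-field surrogate."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_min: np.ndarray | None = None
    input_max: np.ndarray | None = None
    output_mean: float = 0.0
    output_std: float = 1.0
    trained: bool = False

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    @property
    def roi_size(self) -> int:
        return self.weights[-1].shape[1]

    def forward(self, x_norm: np.ndarray) -> np.ndarray:
        """Normalised-space forward pass (poslin hiddens, linear output)."""
        h = np.atleast_2d(x_norm)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = poslin(h @ w + b)
        return h @ self.weights[-1] + self.biases[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Momentum + adaptive-learning-rate gradient descent settings.

    An epoch whose MSE exceeds the previous one by more than
    ``worsen_threshold`` is rejected: weights are restored, the learning
    rate is multiplied by ``lr_decrease`` and the momentum memory is
    cleared.  After an improving epoch the rate is multiplied by
    ``lr_increase``.  Training stops at ``max_epochs`` or when the
    normalised-output MSE falls below ``goal_mse``.
    """

    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    worsen_threshold: float = 0.04
    max_epochs: int = 20000
    goal_mse: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if not (self.lr_increase > 1.0 > self.lr_decrease > 0.0):
            raise ValueError("need lr_increase > 1 > lr_decrease > 0")


@dataclass
class FitReport:
    """Pooled fit (%) with its error/variance components and per-element view."""

    fit_percent: float
    sq_error: float
    variance: float
    per_element_sq_error: np.ndarray
    per_element_variance: np.ndarray

    @property
    def per_element_fit(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 100.0 * (1.0 - self.per_element_sq_error / self.per_element_variance)


def build_network(
    roi_size: int, seed: int = 0, hidden: tuple[int, ...] = DEFAULT_HIDDEN
) -> SurrogateModel:
    """Fresh surrogate with seeded scaled-uniform (He-style) initialisation."""
    if roi_size < 1:
        raise ValueError("roi_size must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [3, *hidden, roi_size]
    weights, biases = [], []
    for nin, nout in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / nin)
        weights.append(rng.uniform(-bound, bound, size=(nin, nout)))
        biases.append(np.zeros(nout))
    return SurrogateModel(weights=weights, biases=biases)


def records_to_xy(records: list[PalpationRecord], partition: str | None = None):
    """Stack records into input (n, 3) and output (n, roi) matrices."""
    sel = [r for r in records if partition is None or r.partition == partition]
    if not sel:
        raise ValueError(f"no records in partition {partition!r}")
    x = np.array([[r.x, r.y, r.force_N] for r in sel])
    y = np.array([r.sigma3 for r in sel])
    return x, y


def _normalise_inputs(model: SurrogateModel, x: np.ndarray, clamp_warn: bool = False) -> np.ndarray:
    span = np.where(model.input_max > model.input_min, model.input_max - model.input_min, 1.0)
    if clamp_warn and (np.any(x < model.input_min - 1e-9) or np.any(x > model.input_max + 1e-9)):
        logger.warning("surrogate input outside the training bounding box; clamping")
    xc = np.clip(x, model.input_min, model.input_max)
    return (xc - model.input_min) / span


def train(
    model: SurrogateModel,
    train_records: list[PalpationRecord] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[SurrogateModel, dict[str, np.ndarray]]:
    """Full-batch gradient descent with momentum and adaptive learning rate.

    Normalisation is fitted on the training partition only.  Returns the
    trained model and a history dict (per-epoch ``mse`` and ``lr``; the
    MSE is in normalised output units).  If the error turns non-finite
    the last good weights are restored and training stops.
    """
    config = config or TrainConfig()
    if isinstance(train_records, tuple):
        x_raw, y_raw = train_records
    else:
        x_raw, y_raw = records_to_xy(train_records, partition="train")
    if len(x_raw) < 1:
        raise ValueError("need at least one training record")
    if y_raw.shape[1] != model.roi_size:
        raise ValueError("record stress dimension does not match network output size")

    model.input_min = x_raw.min(axis=0)
    model.input_max = x_raw.max(axis=0)
    model.output_mean = float(y_raw.mean())
    std = float(y_raw.std())
    model.output_std = std if std > 0 else 1.0
    x = _normalise_inputs(model, x_raw)
    y = (y_raw - model.output_mean) / model.output_std

    w = [wi.copy() for wi in model.weights]
    b = [bi.copy() for bi in model.biases]
    dw = [np.zeros_like(wi) for wi in w]
    db = [np.zeros_like(bi) for bi in b]
    n_layers = len(w)
    n, m = y.shape

    def forward_all(wl, bl):
        acts = [x]
        h = x
        for i in range(n_layers - 1):
            h = poslin(h @ wl[i] + bl[i])
            acts.append(h)
        out = h @ wl[-1] + bl[-1]
        return acts, out

    lr = config.learning_rate
    acts, out = forward_all(w, b)
    mse = float(np.mean((out - y) ** 2))
    history_mse, history_lr = [], []
    best = (mse, [wi.copy() for wi in w], [bi.copy() for bi in b])

    for epoch in range(config.max_epochs):
        # backprop of the full-batch MSE
        delta = 2.0 * (out - y) / (n * m)
        grads_w = [None] * n_layers
        grads_b = [None] * n_layers
        for i in range(n_layers - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ w[i].T) * (acts[i] > 0)

        dw_new = [config.momentum * dwi - lr * gw for dwi, gw in zip(dw, grads_w)]
        db_new = [config.momentum * dbi - lr * gb for dbi, gb in zip(db, grads_b)]
        w_new = [wi + d for wi, d in zip(w, dw_new)]
        b_new = [bi + d for bi, d in zip(b, db_new)]
        acts_new, out_new = forward_all(w_new, b_new)
        mse_new = float(np.mean((out_new - y) ** 2))

        if not np.isfinite(mse_new):
            logger.warning("training diverged at epoch %d; restoring last good weights", epoch)
            _, w, b = best
            break
        if mse_new > mse * (1.0 + config.worsen_threshold):
            # reject the step, cool down, clear momentum
            lr *= config.lr_decrease
            dw = [np.zeros_like(wi) for wi in w]
            db = [np.zeros_like(bi) for bi in b]
        else:
            if mse_new < mse:
                lr *= config.lr_increase
            w, b, dw, db = w_new, b_new, dw_new, db_new
            acts, out, mse = acts_new, out_new, mse_new
            if mse < best[0]:
                best = (mse, [wi.copy() for wi in w], [bi.copy() for bi in b])
        history_mse.append(mse)
        history_lr.append(lr)
        if mse <= config.goal_mse:
            break

    _, w, b = best
    model.weights, model.biases = w, b
    model.trained = True
    return model, {"mse": np.array(history_mse), "lr": np.array(history_lr)}


def fit_metric(y: np.ndarray, y_hat: np.ndarray) -> FitReport:
    """Pooled coefficient-of-determination fit, as a percentage.

    ``y`` and ``y_hat`` are (records, elements) stress matrices.  The
    denominator uses the pooled mean of ``y``; a constant ``y`` leaves
    the metric undefined and raises.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have matching shapes")
    ybar = y.mean()
    sq_err = float(np.sum((y - y_hat) ** 2))
    var = float(np.sum((y - ybar) ** 2))
    if var == 0.0:
        raise ValueError("fit metric undefined: actual values have zero variance")
    per_err = np.sum((y - y_hat) ** 2, axis=0)
    per_var = np.sum((y - ybar) ** 2, axis=0)
    return FitReport(
        fit_percent=100.0 * (1.0 - sq_err / var),
        sq_error=sq_err,
        variance=var,
        per_element_sq_error=per_err,
        per_element_variance=per_var,
    )


def predict(model: SurrogateModel, x: float, y: float, force: float) -> np.ndarray:
    """Predicted sigma3 vector (GPa) at a palpation input.

    Inputs outside the training bounding box are clamped to it (with a
    logged warning).  Requires a trained model.
    """
    if not model.trained or model.input_min is None:
        raise ValueError("model is not trained")
    xin = np.array([[x, y, force]], dtype=float)
    xn = _normalise_inputs(model, xin, clamp_warn=True)
    out = model.forward(xn)[0]
    return out * model.output_std + model.output_mean


def predict_batch(model: SurrogateModel, xyF: np.ndarray) -> np.ndarray:
    if not model.trained or model.input_min is None:
        raise ValueError("model is not trained")
    xn = _normalise_inputs(model, np.atleast_2d(xyF))
    return model.forward(xn) * model.output_std + model.output_mean


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------


def save_checkpoint(model: SurrogateModel, path) -> None:
    """Lossless JSON checkpoint (weights, biases, normalisation, version)."""
    payload = {
        "version": CHECKPOINT_VERSION,
        "layer_sizes": model.layer_sizes,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_min": None if model.input_min is None else model.input_min.tolist(),
        "input_max": None if model.input_max is None else model.input_max.tolist(),
        "output_mean": model.output_mean,
        "output_std": model.output_std,
        "trained": model.trained,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> SurrogateModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: corrupt or truncated surrogate checkpoint") from err
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version {payload.get('version')!r}")
    model = SurrogateModel(
        weights=[np.array(w) for w in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        input_min=None if payload["input_min"] is None else np.array(payload["input_min"]),
        input_max=None if payload["input_max"] is None else np.array(payload["input_max"]),
        output_mean=payload["output_mean"],
        output_std=payload["output_std"],
        trained=payload["trained"],
    )
    if model.layer_sizes != payload["layer_sizes"]:
        raise ValueError(f"{path}: inconsistent layer sizes in checkpoint")
    return model
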