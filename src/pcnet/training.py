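"""Mini-batch training driver feeding algorithm updates into an optimizer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .algorithms import PCResult, PrecisionSpec, pc_infer
from .exceptions import ConfigurationError, DivergenceError, NumericError
from .network.losses import get_loss
from .network.model import NetworkModel
from .synthetic import SyntheticDataset

__all__ = ["SGD", "Adam", "optimizer_step", "TrainConfig", "train", "evaluate"]


class SGD:
    """Plain gradient descent: ``theta <- theta - lr * grad``."""

    def __init__(self, learning_rate: float):
        if learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        self.learning_rate = learning_rate

    def update(self, key: tuple, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return param - self.learning_rate * grad


class Adam:
    """Adaptive moment estimation with standard bias correction.

    On a constant gradient the per-step magnitude approaches
    ``learning_rate`` (the second moment normalizes the scale away).
    """

    def __init__(self, learning_rate: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        self.learning_rate = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state: dict[tuple, dict] = {}

    def update(self, key: tuple, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        st = self.state.setdefault(
            key, {"m": np.zeros_like(param), "v": np.zeros_like(param), "t": 0})
        st["t"] += 1
        st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * grad
        st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * grad * grad
        m_hat = st["m"] / (1 - self.beta1 ** st["t"])
        v_hat = st["v"] / (1 - self.beta2 ** st["t"])
        return param - self.learning_rate * m_hat / (np.sqrt(v_hat) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "adam": Adam}


def optimizer_step(model: NetworkModel, dtheta: list[dict], optimizer) -> None:
    """Apply one optimizer step in place.

    ``dtheta`` is in the negative-gradient sense, so the optimizer is fed
    ``-dtheta`` as its gradient; with SGD this yields
    ``theta <- theta + learning_rate * dtheta``.
    """
    for l, layer in enumerate(model.layers):
        for name, upd in dtheta[l].items():
            if not np.all(np.isfinite(upd)):
                raise NumericError(
                    f"non-finite update for parameter {name!r} of layer {l + 1}"
                )
            new = optimizer.update((l, name), layer.get_param(name), -upd)
            layer.set_param(name, new)


@dataclass
class TrainConfig:
    """Training hyperparameters; the seed drives all shuffling."""

    seed: int
    err_type: str = "exact"
    eta: float = 1.0
    n_iters: int | None = None          # default: network depth
    optimizer: str = "sgd"
    learning_rate: float = 0.05
    batch_size: int = 32
    epochs: int = 1
    eval_every: int = 10
    loss: str = "squared_euclidean"
    precision: PrecisionSpec | None = None
    infer_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory")
        if self.batch_size < 1 or self.epochs < 0 or self.eval_every < 1:
            raise ConfigurationError("batch_size/epochs/eval_every out of range")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.optimizer not in _OPTIMIZERS:
            raise ConfigurationError(
                f"optimizer must be one of {sorted(_OPTIMIZERS)}"
            )


def evaluate(model: NetworkModel, dataset: SyntheticDataset,
             loss="squared_euclidean") -> tuple[float, float]:
    """Mean loss and argmax accuracy on a dataset; no parameter mutation.

    Ties in the argmax resolve to the lowest class index.
    """
    if len(dataset) == 0:
        raise ConfigurationError("cannot evaluate on an empty dataset")
    loss = get_loss(loss)
    scores = model.forward(dataset.x)
    value, _ = loss.value_and_grad(scores, dataset.targets(loss.kind))
    pred = np.argmax(scores.reshape(len(dataset), -1), axis=1)
    accuracy = float(np.mean(pred == dataset.y))
    return value, accuracy


def train(model: NetworkModel, dataset: SyntheticDataset, cfg: TrainConfig,
          test_dataset: SyntheticDataset | None = None) -> pd.DataFrame:
    """Run mini-batch training; returns one metrics row per logged step.

    Deterministic given the configuration (seed included).  Divergence of
    the inference loop aborts training with the failing step index
    attached to the raised :class:`~pcnet.exceptions.DivergenceError`.
    """
    loss = get_loss(cfg.loss)
    n_iters = cfg.n_iters if cfg.n_iters is not None else model.depth
    optimizer = _OPTIMIZERS[cfg.optimizer](cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    step = 0

    def log_row():
        train_loss, train_acc = evaluate(model, dataset, loss)
        row = {"step": step, "train_loss": train_loss, "train_accuracy": train_acc,
               "test_loss": np.nan, "test_accuracy": np.nan}
        if test_dataset is not None:
            row["test_loss"], row["test_accuracy"] = evaluate(
                model, test_dataset, loss)
        rows.append(row)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(dataset))
        for start in range(0, len(dataset), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = dataset.x[idx]
            yb = dataset.targets(loss.kind)[idx]
            try:
                result: PCResult = pc_infer(
                    model, loss, xb, yb, err_type=cfg.err_type, eta=cfg.eta,
                    n=n_iters, precision=cfg.precision, **cfg.infer_kwargs)
            except DivergenceError as err:
                raise DivergenceError(
                    f"inference diverged at training step {step}: {err}",
                    iteration=err.iteration,
                ) from err
            optimizer_step(model, result.dtheta, optimizer)
            step += 1
            if step % cfg.eval_every == 0:
                log_row()
    if cfg.epochs > 0 and (step % cfg.eval_every != 0 or step == 0):
        log_row()
    return pd.DataFrame(rows, columns=["step", "train_loss", "train_accuracy",
                                       "test_loss", "test_accuracy"])
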