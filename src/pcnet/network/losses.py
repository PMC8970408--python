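"""Loss functions with mean-over-batch reduction.

Two gradient views are provided:

* ``value_and_grad`` returns the gradient of the *mean* loss with respect
  to the network output (carries the ``1/m`` factor) — this is the
  quantity reported as ``dLdy`` in results.
* ``output_error`` returns the per-sample gradient (no ``1/m``), which is
  what flows through the layer adjoints; the batch-mean reduction is then
  applied once, inside the parameter VJPs.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError, NumericError

__all__ = [
    "Loss",
    "SquaredEuclidean",
    "SoftmaxCrossEntropy",
    "get_loss",
    "loss_and_output_grad",
]


def _as_batch(y_hat: np.ndarray) -> np.ndarray:
    y_hat = np.asarray(y_hat, dtype=float)
    if not np.all(np.isfinite(y_hat)):
        raise NumericError("non-finite values in loss input")
    return y_hat


class Loss:
    kind: str = "abstract"

    def value_and_grad(self, y_hat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        value, per_sample = self._value_and_per_sample_grad(y_hat, y)
        return value, per_sample / y_hat.shape[0]

    def output_error(self, y_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample gradient of the loss w.r.t. the output."""
        return self._value_and_per_sample_grad(y_hat, y)[1]

    def _value_and_per_sample_grad(self, y_hat, y):
        raise NotImplementedError


class SquaredEuclidean(Loss):
    """``L = mean_i 0.5 * ||y_hat_i - y_i||^2``."""

    kind = "squared_euclidean"

    def _value_and_per_sample_grad(self, y_hat, y):
        y_hat = _as_batch(y_hat)
        y = np.asarray(y, dtype=float)
        if y.shape != y_hat.shape:
            raise ConfigurationError(
                f"squared_euclidean targets shape {y.shape} != output shape {y_hat.shape}"
            )
        diff = y_hat - y
        m = y_hat.shape[0]
        value = 0.5 * float(np.sum(diff * diff)) / m
        return value, diff


class SoftmaxCrossEntropy(Loss):
    """Cross-entropy of a softmax over the last axis.

    Targets may be integer class indices of shape ``(m,)`` or a one-hot
    (more generally, probability) matrix of shape ``(m, K)``.
    """

    kind = "softmax_cross_entropy"

    @staticmethod
    def _one_hot_targets(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
        y = np.asarray(y)
        m, k = y_hat.shape
        if y.ndim == 1:
            y = y.astype(int)
            if y.min() < 0 or y.max() >= k:
                raise ConfigurationError(f"class index outside [0, {k})")
            hot = np.zeros((m, k))
            hot[np.arange(m), y] = 1.0
            return hot
        if y.shape != y_hat.shape:
            raise ConfigurationError(
                f"cross-entropy targets shape {y.shape} != output shape {y_hat.shape}"
            )
        return np.asarray(y, dtype=float)

    def _value_and_per_sample_grad(self, y_hat, y):
        y_hat = _as_batch(y_hat)
        if y_hat.ndim != 2:
            raise ConfigurationError("softmax_cross_entropy expects (m, K) logits")
        hot = self._one_hot_targets(y, y_hat)
        z = y_hat - y_hat.max(axis=1, keepdims=True)
        log_norm = np.log(np.sum(np.exp(z), axis=1, keepdims=True))
        log_p = z - log_norm
        value = -float(np.sum(hot * log_p)) / y_hat.shape[0]
        return value, np.exp(log_p) - hot


_LOSSES = {cls.kind: cls for cls in (SquaredEuclidean, SoftmaxCrossEntropy)}


def get_loss(kind) -> Loss:
    if isinstance(kind, Loss):
        return kind
    try:
        return _LOSSES[kind]()
    except KeyError:
        raise ConfigurationError(
            f"unknown loss {kind!r}; choose from {sorted(_LOSSES)}"
        ) from None


def loss_and_output_grad(loss, y_hat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss and its gradient w.r.t. ``y_hat`` (with the 1/m factor)."""
    return get_loss(loss).value_and_grad(np.asarray(y_hat, dtype=float), y)
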