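"""Layer primitives: forward maps and their row-form adjoints.

Every layer implements three operations on batched activations (leading
axis is the batch):

* ``forward(x)`` — apply the layer map ``f(x; theta)``.
* ``vjp_input(v_in, a)`` — contract a row-adjoint ``a`` (same shape as the
  layer output) against the Jacobian of ``f`` with respect to its input,
  linearized at ``v_in``.  Returns an adjoint with the shape of the input.
  The full Jacobian is never materialized.
* ``vjp_params(v_in, a)`` — contract ``a`` against the Jacobian with
  respect to each parameter, summed over the batch and divided by the
  batch size.  This is the single point where the batch-mean reduction
  happens, so adjoints flowing between layers stay per-sample.

Shapes are per-sample: ``(n,)`` for vector layers, ``(C, H, W)`` for image
layers; batched arrays carry a leading batch axis ``m``.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from ..exceptions import ConfigurationError, NumericError

__all__ = [
    "Layer",
    "Affine",
    "Conv2d",
    "Relu",
    "Tanh",
    "Flatten",
    "Block",
]


def _check_finite(name: str, *arrays: np.ndarray) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise NumericError(f"non-finite values passed to {name}")


def _init_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """A differentiable stage of a feedforward chain."""

    kind: str = "abstract"

    def __init__(self, input_shape: tuple[int, ...], output_shape: tuple[int, ...]):
        self.input_shape = tuple(int(s) for s in input_shape)
        self.output_shape = tuple(int(s) for s in output_shape)
        self.params: dict[str, np.ndarray] = {}

    # -- parameter access ------------------------------------------------
    def param_items(self) -> Iterator[tuple[str, np.ndarray]]:
        yield from self.params.items()

    def get_param(self, name: str) -> np.ndarray:
        return self.params[name]

    def set_param(self, name: str, value: np.ndarray) -> None:
        current = self.params[name]
        value = np.asarray(value, dtype=float)
        if value.shape != current.shape:
            raise ConfigurationError(
                f"parameter {name!r} of {self.kind} layer has shape "
                f"{current.shape}, got {value.shape}"
            )
        self.params[name] = value

    @property
    def n_params(self) -> int:
        return sum(p.size for _, p in self.param_items())

    # -- contracts -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def vjp_params(self, v_in: np.ndarray, a: np.ndarray) -> dict[str, np.ndarray]:
        """Batch-mean adjoint w.r.t. parameters; empty for parameter-free kinds."""
        return {}

    def _check_in(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim < 1 or x.shape[1:] != self.input_shape:
            raise ConfigurationError(
                f"{self.kind} layer expects per-sample input shape "
                f"{self.input_shape}, got array of shape {x.shape}"
            )
        return x

    def _check_adjoint(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if a.shape[1:] != self.output_shape:
            raise ConfigurationError(
                f"{self.kind} layer expects adjoint of per-sample shape "
                f"{self.output_shape}, got array of shape {a.shape}"
            )
        _check_finite(f"{self.kind}.vjp", a)
        return a

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(in={self.input_shape}, out={self.output_shape})"


class Affine(Layer):
    """Fully connected map ``v -> v @ W + b``.

    ``W`` has shape ``(n_in, n_out)`` and ``b`` shape ``(n_out,)``.
    Parameters are initialized uniformly on ``[-1/sqrt(n_in), 1/sqrt(n_in)]``
    from the given seed.
    """

    kind = "affine"

    def __init__(self, n_in: int, n_out: int, *, seed: int | None = None,
                 weight: np.ndarray | None = None, bias: np.ndarray | None = None):
        super().__init__((n_in,), (n_out,))
        if weight is None:
            rng = np.random.default_rng(seed)
            weight = _init_uniform(rng, (n_in, n_out), n_in)
            bias = _init_uniform(rng, (n_out,), n_in) if bias is None else bias
        elif bias is None:
            bias = np.zeros(n_out)
        weight = np.asarray(weight, dtype=float)
        bias = np.asarray(bias, dtype=float)
        if weight.shape != (n_in, n_out) or bias.shape != (n_out,):
            raise ConfigurationError(
                f"affine parameter shapes {weight.shape}/{bias.shape} do not "
                f"match (n_in={n_in}, n_out={n_out})"
            )
        self.params = {"weight": weight, "bias": bias}

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_in(x)
        return x @ self.params["weight"] + self.params["bias"]

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        a = self._check_adjoint(a)
        return a @ self.params["weight"].T

    def vjp_params(self, v_in: np.ndarray, a: np.ndarray) -> dict[str, np.ndarray]:
        v_in = self._check_in(v_in)
        a = self._check_adjoint(a)
        m = v_in.shape[0]
        return {"weight": v_in.T @ a / m, "bias": a.sum(axis=0) / m}


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride 1, zero padding.

    Weight shape ``(out_channels, in_channels, k, k)``; implemented with
    explicit loops over kernel offsets — correctness over speed, shapes in
    this package are small.
    """

    kind = "conv2d"

    def __init__(self, in_shape: tuple[int, int, int], out_channels: int,
                 kernel_size: int, *, padding: int = 0, seed: int | None = None,
                 weight: np.ndarray | None = None, bias: np.ndarray | None = None):
        c, h, w = (int(s) for s in in_shape)
        k = int(kernel_size)
        p = int(padding)
        h_out = h + 2 * p - k + 1
        w_out = w + 2 * p - k + 1
        if h_out < 1 or w_out < 1:
            raise ConfigurationError(
                f"conv2d kernel {k} with padding {p} does not fit input {in_shape}"
            )
        super().__init__((c, h, w), (int(out_channels), h_out, w_out))
        self.kernel_size = k
        self.padding = p
        fan_in = c * k * k
        if weight is None:
            rng = np.random.default_rng(seed)
            weight = _init_uniform(rng, (out_channels, c, k, k), fan_in)
            bias = _init_uniform(rng, (out_channels,), fan_in) if bias is None else bias
        elif bias is None:
            bias = np.zeros(out_channels)
        self.params = {
            "weight": np.asarray(weight, dtype=float),
            "bias": np.asarray(bias, dtype=float),
        }

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_in(x)
        xp = self._pad(x)
        weight, bias = self.params["weight"], self.params["bias"]
        k = self.kernel_size
        _, h_out, w_out = self.output_shape
        out = np.zeros((x.shape[0],) + self.output_shape)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + h_out, dj:dj + w_out]
                out += np.einsum("mcij,oc->moij", patch, weight[:, :, di, dj])
        return out + bias[None, :, None, None]

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        a = self._check_adjoint(a)
        weight = self.params["weight"]
        k, p = self.kernel_size, self.padding
        _, h_out, w_out = self.output_shape
        c, h, w = self.input_shape
        gpad = np.zeros((a.shape[0], c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                gpad[:, :, di:di + h_out, dj:dj + w_out] += np.einsum(
                    "moij,oc->mcij", a, weight[:, :, di, dj]
                )
        if p == 0:
            return gpad
        return gpad[:, :, p:-p, p:-p]

    def vjp_params(self, v_in: np.ndarray, a: np.ndarray) -> dict[str, np.ndarray]:
        v_in = self._check_in(v_in)
        a = self._check_adjoint(a)
        xp = self._pad(v_in)
        k = self.kernel_size
        _, h_out, w_out = self.output_shape
        m = v_in.shape[0]
        g_w = np.zeros_like(self.params["weight"])
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + h_out, dj:dj + w_out]
                g_w[:, :, di, dj] = np.einsum("moij,mcij->oc", a, patch)
        return {"weight": g_w / m, "bias": a.sum(axis=(0, 2, 3)) / m}


class Relu(Layer):
    """Rectifier; the subgradient at 0 is taken to be 0."""

    kind = "relu"

    def __init__(self, shape: tuple[int, ...]):
        super().__init__(shape, shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(self._check_in(x), 0.0)

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        v_in = self._check_in(v_in)
        return self._check_adjoint(a) * (v_in > 0)


class Tanh(Layer):
    kind = "tanh"

    def __init__(self, shape: tuple[int, ...]):
        super().__init__(shape, shape)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(self._check_in(x))

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        v_in = self._check_in(v_in)
        t = np.tanh(v_in)
        return self._check_adjoint(a) * (1.0 - t * t)


class Flatten(Layer):
    kind = "flatten"

    def __init__(self, shape: tuple[int, ...]):
        super().__init__(shape, (int(np.prod(shape)),))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._check_in(x)
        return x.reshape(x.shape[0], -1)

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        a = self._check_adjoint(a)
        return a.reshape((a.shape[0],) + self.input_shape)


class Block(Layer):
    """An ordered chain of sub-layers acting as a single layer.

    Parameters of sub-layer ``i`` are exposed under names ``"{i}.{name}"``.
    """

    kind = "block"

    def __init__(self, layers: list[Layer]):
        if not layers:
            raise ConfigurationError("block requires at least one sub-layer")
        for i in range(1, len(layers)):
            if layers[i].input_shape != layers[i - 1].output_shape:
                raise ConfigurationError(
                    f"block sub-layer {i} ({layers[i].kind}) expects input "
                    f"{layers[i].input_shape} but sub-layer {i - 1} produces "
                    f"{layers[i - 1].output_shape}"
                )
        super().__init__(layers[0].input_shape, layers[-1].output_shape)
        self.layers = list(layers)

    def param_items(self) -> Iterator[tuple[str, np.ndarray]]:
        for i, layer in enumerate(self.layers):
            for name, p in layer.param_items():
                yield f"{i}.{name}", p

    def get_param(self, name: str) -> np.ndarray:
        idx, sub = name.split(".", 1)
        return self.layers[int(idx)].get_param(sub)

    def set_param(self, name: str, value: np.ndarray) -> None:
        idx, sub = name.split(".", 1)
        self.layers[int(idx)].set_param(sub, value)

    def _intermediates(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [self._check_in(x)]
        for layer in self.layers:
            acts.append(layer.forward(acts[-1]))
        return acts

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._intermediates(x)[-1]

    def vjp_input(self, v_in: np.ndarray, a: np.ndarray) -> np.ndarray:
        acts = self._intermediates(v_in)
        a = self._check_adjoint(a)
        for i in range(len(self.layers) - 1, -1, -1):
            a = self.layers[i].vjp_input(acts[i], a)
        return a

    def vjp_params(self, v_in: np.ndarray, a: np.ndarray) -> dict[str, np.ndarray]:
        acts = self._intermediates(v_in)
        a = self._check_adjoint(a)
        grads: dict[str, np.ndarray] = {}
        for i in range(len(self.layers) - 1, -1, -1):
            sub = self.layers[i].vjp_params(acts[i], a)
            for name, g in sub.items():
                grads[f"{i}.{name}"] = g
            a = self.layers[i].vjp_input(acts[i], a)
        return grads
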