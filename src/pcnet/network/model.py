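"""Feedforward chain models and the forward pass."""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError, NumericError
from .layers import Affine, Layer, Relu, Tanh

__all__ = ["NetworkModel", "forward_pass", "sequential_mlp"]


class NetworkModel:
    """An ordered chain of :class:`~pcnet.network.layers.Layer` objects.

    The chain must be shape-consistent: the output shape of layer ``l``
    equals the input shape of layer ``l + 1``.
    """

    def __init__(self, layers: list[Layer]):
        if len(layers) < 1:
            raise ConfigurationError("a network needs at least one layer")
        for i in range(1, len(layers)):
            if layers[i].input_shape != layers[i - 1].output_shape:
                raise ConfigurationError(
                    f"layer {i + 1} ({layers[i].kind}) expects input shape "
                    f"{layers[i].input_shape} but layer {i} ({layers[i - 1].kind}) "
                    f"produces {layers[i - 1].output_shape}"
                )
        self.layers = list(layers)

    @property
    def depth(self) -> int:
        return len(self.layers)

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.layers[0].input_shape

    @property
    def output_shape(self) -> tuple[int, ...]:
        return self.layers[-1].output_shape

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_params(self) -> list[dict[str, np.ndarray]]:
        """Copies of all parameter arrays, one dict per layer."""
        return [{name: p.copy() for name, p in layer.param_items()}
                for layer in self.layers]

    def set_params(self, params: list[dict[str, np.ndarray]]) -> None:
        if len(params) != self.depth:
            raise ConfigurationError(
                f"expected {self.depth} per-layer parameter dicts, got {len(params)}"
            )
        for layer, layer_params in zip(self.layers, params):
            for name, value in layer_params.items():
                layer.set_param(name, value)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return forward_pass(self, x)[-1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(layer.kind for layer in self.layers)
        return f"NetworkModel([{inner}])"


def forward_pass(model: NetworkModel, x: np.ndarray) -> list[np.ndarray]:
    """Run the chain on a batch; returns all activations, input included.

    The returned list has length ``L + 1``: element 0 is ``x`` itself and
    element ``l`` is the activation after layer ``l``.  Deterministic given
    the model and input.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1:] != model.input_shape:
        raise ConfigurationError(
            f"layer 1 ({model.layers[0].kind}) expects per-sample input shape "
            f"{model.input_shape}, got array of shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise NumericError("non-finite values in forward_pass input")
    activations = [x]
    for layer in model.layers:
        activations.append(layer.forward(activations[-1]))
    return activations


_ACTIVATIONS = {"relu": Relu, "tanh": Tanh}


def sequential_mlp(sizes: list[int], activation: str = "tanh", *,
                   seed: int | None = None,
                   final_activation: bool = False) -> NetworkModel:
    """Build an MLP ``affine - act - affine - act - ... - affine``.

    Each affine stage and each activation counts as one layer of the chain,
    so ``sizes=[4, 8, 3]`` with one hidden activation yields depth 3.
    """
    if activation not in _ACTIVATIONS:
        raise ConfigurationError(f"unknown activation {activation!r}")
    act_cls = _ACTIVATIONS[activation]
    seeds = np.random.SeedSequence(seed).generate_state(len(sizes) - 1)
    layers: list[Layer] = []
    for i in range(len(sizes) - 1):
        layers.append(Affine(sizes[i], sizes[i + 1], seed=int(seeds[i])))
        if i < len(sizes) - 2 or final_activation:
            layers.append(act_cls((sizes[i + 1],)))
    return NetworkModel(layers)
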