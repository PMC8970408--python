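"""JSON model descriptions and parameter checkpoints.

A model is described by a JSON document::

    {"seed": 0,
     "layers": [
        {"kind": "affine", "n_in": 4, "n_out": 8},
        {"kind": "tanh", "shape": [8]},
        {"kind": "affine", "n_in": 8, "n_out": 3, "seed": 7}
     ]}

Parameter-free kinds (``relu``, ``tanh``, ``flatten``) take a ``shape``
field; ``affine`` takes ``n_in``/``n_out``; ``conv2d`` takes ``in_shape``,
``out_channels``, ``kernel_size`` and optional ``padding``; ``block`` takes
a nested ``layers`` list.  Per-layer ``seed`` overrides the top-level seed,
from which per-layer seeds are otherwise derived deterministically.

Checkpoints are a directory with ``manifest.json`` (layer kinds and
parameter shapes) plus ``params.npz`` holding one named array per
parameter (``layer{i}.{name}``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..exceptions import ConfigurationError
from .layers import Affine, Block, Conv2d, Flatten, Layer, Relu, Tanh
from .model import NetworkModel

__all__ = ["build_model", "model_spec", "save_checkpoint", "load_checkpoint"]


def _build_layer(entry: dict, seed: int | None) -> Layer:
    if not isinstance(entry, dict) or "kind" not in entry:
        raise ConfigurationError(f"layer entry must be a dict with a 'kind': {entry!r}")
    kind = entry["kind"]
    layer_seed = entry.get("seed", seed)
    if kind == "affine":
        return Affine(int(entry["n_in"]), int(entry["n_out"]), seed=layer_seed)
    if kind == "conv2d":
        return Conv2d(
            tuple(entry["in_shape"]),
            int(entry["out_channels"]),
            int(entry["kernel_size"]),
            padding=int(entry.get("padding", 0)),
            seed=layer_seed,
        )
    if kind in ("relu", "tanh", "flatten"):
        shape = tuple(entry["shape"]) if not isinstance(entry["shape"], int) \
            else (entry["shape"],)
        cls = {"relu": Relu, "tanh": Tanh, "flatten": Flatten}[kind]
        return cls(shape)
    if kind == "block":
        subs = entry.get("layers", [])
        sub_seeds = np.random.SeedSequence(layer_seed).generate_state(max(len(subs), 1))
        return Block([_build_layer(s, int(sub_seeds[i])) for i, s in enumerate(subs)])
    raise ConfigurationError(f"unknown layer kind {kind!r}")


def build_model(spec: dict | list) -> NetworkModel:
    """Instantiate a :class:`NetworkModel` from a JSON-style description."""
    if isinstance(spec, list):
        spec = {"layers": spec}
    entries = spec.get("layers")
    if not entries:
        raise ConfigurationError("model spec must contain a non-empty 'layers' list")
    top_seed = spec.get("seed")
    seeds = np.random.SeedSequence(top_seed).generate_state(len(entries))
    return NetworkModel(
        [_build_layer(e, int(seeds[i]) if "seed" not in e else None)
         for i, e in enumerate(entries)]
    )


def _layer_spec(layer: Layer) -> dict:
    if isinstance(layer, Affine):
        return {"kind": "affine", "n_in": layer.input_shape[0],
                "n_out": layer.output_shape[0]}
    if isinstance(layer, Conv2d):
        return {"kind": "conv2d", "in_shape": list(layer.input_shape),
                "out_channels": layer.output_shape[0],
                "kernel_size": layer.kernel_size, "padding": layer.padding}
    if isinstance(layer, Block):
        return {"kind": "block", "layers": [_layer_spec(s) for s in layer.layers]}
    return {"kind": layer.kind, "shape": list(layer.input_shape)}


def model_spec(model: NetworkModel) -> dict:
    """Architecture description of a model (parameters not included)."""
    return {"layers": [_layer_spec(layer) for layer in model.layers]}


def save_checkpoint(model: NetworkModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    manifest: dict = {"format": "pcnet-checkpoint-v1",
                      "architecture": model_spec(model), "parameters": []}
    for i, layer in enumerate(model.layers):
        for name, p in layer.param_items():
            key = f"layer{i}.{name}"
            arrays[key] = p
            manifest["parameters"].append(
                {"layer": i, "name": name, "key": key, "shape": list(p.shape)}
            )
    np.savez(directory / "params.npz", **arrays)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_checkpoint(model: NetworkModel, directory: str | Path) -> NetworkModel:
    """Load parameters from a checkpoint directory into ``model`` (in place)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    with np.load(directory / "params.npz") as arrays:
        for entry in manifest["parameters"]:
            model.layers[entry["layer"]].set_param(entry["name"], arrays[entry["key"]])
    return model
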