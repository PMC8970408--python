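"""Seeded, download-free synthetic datasets.

Every generator is a pure function of its descriptor: regenerating from
the stored descriptor is bit-identical.  Class counts are balanced within
one sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .network.model import NetworkModel
from .network.serialize import build_model

__all__ = [
    "SyntheticDataset",
    "one_hot",
    "make_blobs",
    "make_teacher_dataset",
    "make_image_batches",
    "from_descriptor",
    "save_dataset",
    "load_dataset",
]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot encode integer class labels into an ``(m, K)`` matrix."""
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ConfigurationError("labels must be a 1-D integer array")
    labels = labels.astype(int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ConfigurationError(f"labels must lie in [0, {n_classes})")
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


@dataclass
class SyntheticDataset:
    """Inputs, integer labels, and the descriptor that regenerates them."""

    x: np.ndarray
    y: np.ndarray
    n_classes: int
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.x.shape[0] != self.y.shape[0]:
            raise ConfigurationError("x and y must share the batch dimension")

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def y_onehot(self) -> np.ndarray:
        return one_hot(self.y, self.n_classes)

    def targets(self, loss_kind: str) -> np.ndarray:
        """Targets in the encoding the given loss expects."""
        if loss_kind == "squared_euclidean":
            return self.y_onehot
        return self.y

    def subset(self, idx) -> "SyntheticDataset":
        return SyntheticDataset(self.x[idx], self.y[idx], self.n_classes,
                                dict(self.descriptor, subset=True))


def _balanced_labels(rng: np.random.Generator, n_samples: int, n_classes: int
                     ) -> np.ndarray:
    base = np.arange(n_samples) % n_classes
    return rng.permutation(base)


def make_blobs(seed: int, n_samples: int, dim: int, n_classes: int,
               separation: float = 6.0, noise_sd: float = 1.0) -> SyntheticDataset:
    """Gaussian clusters with centers at pairwise distance >= ``separation``.

    With ``dim >= n_classes`` the centers are a randomly rotated scaled
    orthonormal frame (pairwise distances exactly ``separation``);
    otherwise centers are rejection-sampled.
    """
    if n_classes < 2:
        raise ConfigurationError("make_blobs requires n_classes >= 2")
    rng = np.random.default_rng(seed)
    if dim >= n_classes:
        q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
        centers = (separation / np.sqrt(2.0)) * q[:, :n_classes].T
    else:
        scale = 2.0 * separation
        for _ in range(1000):
            centers = rng.standard_normal((n_classes, dim)) * scale
            dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            if np.min(dists[np.triu_indices(n_classes, 1)]) >= separation:
                break
            scale *= 1.5
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("failed to place blob centers")
    labels = _balanced_labels(rng, n_samples, n_classes)
    x = centers[labels] + noise_sd * rng.standard_normal((n_samples, dim))
    descriptor = {"kind": "blobs", "seed": int(seed), "n_samples": int(n_samples),
                  "dim": int(dim), "n_classes": int(n_classes),
                  "separation": float(separation), "noise_sd": float(noise_sd)}
    return SyntheticDataset(x, labels, n_classes, descriptor)


def make_teacher_dataset(seed: int, architecture, n_samples: int,
                         label_noise: float = 0.0) -> SyntheticDataset:
    """Labels from the argmax of a frozen random teacher network.

    ``architecture`` is a model description accepted by
    :func:`~pcnet.network.serialize.build_model` (a ``NetworkModel`` is
    also accepted, but then the descriptor cannot regenerate the data).
    ``label_noise`` replaces that fraction of labels with uniform draws.
    """
    rng = np.random.default_rng(seed)
    if isinstance(architecture, NetworkModel):
        teacher, arch_spec = architecture, None
    else:
        arch_spec = architecture if isinstance(architecture, dict) \
            else {"layers": list(architecture)}
        arch_spec = dict(arch_spec)
        arch_spec.setdefault("seed", int(rng.integers(2**31)))
        teacher = build_model(arch_spec)
    x = rng.standard_normal((n_samples,) + teacher.input_shape)
    scores = teacher.forward(x)
    labels = np.argmax(scores.reshape(n_samples, -1), axis=1)
    n_classes = int(np.prod(teacher.output_shape))
    if label_noise > 0:
        flip = rng.random(n_samples) < label_noise
        labels = np.where(flip, rng.integers(0, n_classes, n_samples), labels)
    descriptor = {"kind": "teacher", "seed": int(seed),
                  "architecture": arch_spec, "n_samples": int(n_samples),
                  "label_noise": float(label_noise)}
    return SyntheticDataset(x, labels, n_classes, descriptor)


def make_image_batches(seed: int, n_samples: int, channels: int, height: int,
                       width: int, n_classes: int) -> SyntheticDataset:
    """Class-conditional smoothed random textures with values in [0, 1]."""
    if min(channels, height, width, n_classes) < 1:
        raise ConfigurationError("image dimensions and class count must be positive")
    rng = np.random.default_rng(seed)
    shape = (channels, height, width)
    prototypes = np.stack([
        gaussian_filter(rng.standard_normal(shape), sigma=(0, 1.5, 1.5))
        for _ in range(n_classes)
    ])
    labels = _balanced_labels(rng, n_samples, n_classes)
    noise = gaussian_filter(
        rng.standard_normal((n_samples,) + shape), sigma=(0, 0, 1.0, 1.0))
    x = prototypes[labels] + 0.5 * noise
    # min-max normalize each sample into [0, 1]
    flat = x.reshape(n_samples, -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    flat = (flat - lo) / np.where(hi > lo, hi - lo, 1.0)
    x = flat.reshape((n_samples,) + shape)
    descriptor = {"kind": "images", "seed": int(seed), "n_samples": int(n_samples),
                  "channels": int(channels), "height": int(height),
                  "width": int(width), "n_classes": int(n_classes)}
    return SyntheticDataset(x, labels, n_classes, descriptor)


def from_descriptor(descriptor: dict) -> SyntheticDataset:
    """Regenerate a dataset from its descriptor (bit-identical)."""
    d = dict(descriptor)
    kind = d.pop("kind", None)
    d.pop("subset", None)
    if kind == "blobs":
        return make_blobs(d["seed"], d["n_samples"], d["dim"], d["n_classes"],
                          d.get("separation", 6.0), d.get("noise_sd", 1.0))
    if kind == "teacher":
        return make_teacher_dataset(d["seed"], d["architecture"], d["n_samples"],
                                    d.get("label_noise", 0.0))
    if kind == "images":
        return make_image_batches(d["seed"], d["n_samples"], d["channels"],
                                  d["height"], d["width"], d["n_classes"])
    raise ConfigurationError(f"unknown dataset kind {kind!r}")


def save_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "data.npz", x=dataset.x, y=dataset.y)
    meta = {"n_classes": dataset.n_classes, "descriptor": dataset.descriptor}
    (directory / "descriptor.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    meta = json.loads((directory / "descriptor.json").read_text())
    with np.load(directory / "data.npz") as arrays:
        return SyntheticDataset(arrays["x"], arrays["y"], meta["n_classes"],
                                meta["descriptor"])
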