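"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pcnet as pc


# ---------------------------------------------------------------------------
# independent finite-difference oracles (never call the package adjoints)
# ---------------------------------------------------------------------------

def fd_vjp_input(layer, v_in, a, h=1e-6):
    """Central-difference oracle for a . df/dv_in."""
    v_in = np.asarray(v_in, dtype=float)
    grad = np.zeros_like(v_in)
    flat_v = v_in.ravel()
    flat_g = grad.ravel()
    for idx in range(flat_v.size):
        orig = flat_v[idx]
        flat_v[idx] = orig + h
        f_plus = float(np.sum(a * layer.forward(v_in)))
        flat_v[idx] = orig - h
        f_minus = float(np.sum(a * layer.forward(v_in)))
        flat_v[idx] = orig
        flat_g[idx] = (f_plus - f_minus) / (2 * h)
    return grad


def fd_vjp_params(layer, v_in, a, h=1e-6):
    """Central-difference oracle for a . df/dtheta, batch-mean reduced."""
    m = np.asarray(v_in).shape[0]
    out = {}
    for name, _ in layer.param_items():
        p = layer.get_param(name)
        g = np.zeros_like(p)
        flat_p = p.ravel()
        flat_g = g.ravel()
        for idx in range(flat_p.size):
            orig = flat_p[idx]
            flat_p[idx] = orig + h
            layer.set_param(name, p)
            f_plus = float(np.sum(a * layer.forward(v_in)))
            flat_p[idx] = orig - h
            layer.set_param(name, p)
            f_minus = float(np.sum(a * layer.forward(v_in)))
            flat_p[idx] = orig
            layer.set_param(name, p)
            flat_g[idx] = (f_plus - f_minus) / (2 * h)
        out[name] = g / m
    return out


def rel(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-300)


def rel_dict(da, db):
    keys = sorted(db)
    va = np.concatenate([np.ravel(da[k]) for k in keys])
    vb = np.concatenate([np.ravel(db[k]) for k in keys])
    return rel(va, vb)


# ---------------------------------------------------------------------------
# model factories
# ---------------------------------------------------------------------------

def scalar_chain():
    """f1(x) = 2x, f2(v) = 3v — the hand-traceable two-layer chain."""
    return pc.NetworkModel([
        pc.Affine(1, 1, weight=np.array([[2.0]]), bias=np.zeros(1)),
        pc.Affine(1, 1, weight=np.array([[3.0]]), bias=np.zeros(1)),
    ])


def random_mlp(seed, sizes=(4, 6, 5, 3), activation="tanh"):
    return pc.sequential_mlp(list(sizes), activation, seed=seed)


def random_conv_net(seed):
    """Small mixed conv/affine network for image inputs."""
    return pc.NetworkModel([
        pc.Conv2d((1, 5, 5), 2, 3, padding=1, seed=seed),
        pc.Relu((2, 5, 5)),
        pc.Flatten((2, 5, 5)),
        pc.Affine(50, 4, seed=seed + 1),
    ])


def saturated_tanh_net(seed=0, w2_scale=25.0, out_scale=0.02, a_target=2.0):
    """3-layer tanh net whose middle pre-activations sit at ``a_target``.

    Strong middle-layer weights with saturated tanh units give large
    curvature at small Jacobian norm; a weak output map keeps top-down
    feedback gentle.  In this regime strict predictive coding converges
    and reproduces the similar-at-the-output / different-in-early-layers
    update pattern.  Built for a single input (m = 1).
    """
    rng = np.random.default_rng(seed + 10)
    x = rng.standard_normal((1, 4))
    block1 = pc.Block([pc.Affine(4, 6, seed=seed), pc.Tanh((6,))])
    mid = pc.Affine(6, 6, seed=seed + 1)
    mid.set_param("weight", mid.get_param("weight") * w2_scale)
    v1 = block1.forward(x)
    mid.set_param("bias", a_target * np.ones(6) - (v1 @ mid.get_param("weight")).ravel())
    block2 = pc.Block([mid, pc.Tanh((6,))])
    head = pc.Affine(6, 3, seed=seed + 2)
    head.set_param("weight", head.get_param("weight") * out_scale)
    model = pc.NetworkModel([block1, block2, head])
    y = model.forward(x) + 0.3 * np.random.default_rng(seed + 99).standard_normal((1, 3))
    return model, x, y


def random_xy(model, seed, m=4, loss="squared_euclidean"):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((m,) + model.input_shape)
    if loss == "squared_euclidean":
        y = rng.standard_normal((m,) + model.output_shape)
    else:
        y = rng.integers(0, int(np.prod(model.output_shape)), m)
    return x, y


@pytest.fixture
def rng():
    return np.random.default_rng(0)
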