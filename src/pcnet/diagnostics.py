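"""Agreement metrics, fixed-point checks, and the finite-difference oracle."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .algorithms import backprop_update, pc_infer
from .exceptions import DivergenceError, OracleCapError
from .network.losses import get_loss
from .network.model import NetworkModel

__all__ = [
    "flatten_update",
    "relative_error",
    "update_angle",
    "finite_difference_grad",
    "fixed_point_residual",
    "fixed_point_closed_form",
    "sweep_compare",
    "iteration_schedule",
]

#: layer label used for the whole-model aggregate row in sweep tables
AGGREGATE_LAYER = 0


def flatten_update(update) -> np.ndarray:
    """Flatten a per-layer update dict (or array) to a 1-D vector.

    Dict entries are concatenated in sorted-key order so that two updates
    for the same layer always align.
    """
    if isinstance(update, dict):
        if not update:
            return np.zeros(0)
        return np.concatenate([np.ravel(update[k]) for k in sorted(update)])
    return np.ravel(np.asarray(update, dtype=float))


def relative_error(update_a, update_b) -> float:
    """``||a - b|| / ||b||`` on flattened update vectors; ``b`` is the reference."""
    a = flatten_update(update_a)
    b = flatten_update(update_b)
    ref = np.linalg.norm(b)
    if ref == 0:
        raise ValueError("relative_error is undefined for a zero reference update")
    return float(np.linalg.norm(a - b) / ref)


def _angle_deg(a: np.ndarray, b: np.ndarray, na: float, nb: float) -> float:
    # Kahan's arctan formulation: well-conditioned near 0 and 180 degrees,
    # unlike arccos of a (clipped) cosine
    u, v = a / na, b / nb
    return float(np.degrees(
        2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))))


def update_angle(update_a, update_b) -> float:
    """Angle between flattened update vectors, in degrees."""
    a = flatten_update(update_a)
    b = flatten_update(update_b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("update_angle is undefined for a zero update vector")
    return _angle_deg(a, b, na, nb)


def finite_difference_grad(model: NetworkModel, loss, x, y, h: float = 1e-5,
                           max_params: int = 2000) -> list[dict[str, np.ndarray]]:
    """Central finite differences of the mean loss w.r.t. every parameter.

    Returns the *positive* gradient ``dL/dtheta`` per layer (so it equals
    ``-dtheta`` of :func:`~pcnet.algorithms.backprop_update`).  Cost is two
    forward passes per scalar parameter; refuses models above
    ``max_params`` parameters.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be > 0")
    if model.n_params > max_params:
        raise OracleCapError(
            f"model has {model.n_params} parameters, oracle cap is {max_params}; "
            "the finite-difference oracle is intended for small test networks"
        )
    loss = get_loss(loss)

    def loss_value() -> float:
        return loss.value_and_grad(model.forward(x), y)[0]

    grads: list[dict[str, np.ndarray]] = []
    for layer in model.layers:
        layer_grads: dict[str, np.ndarray] = {}
        for name, _ in layer.param_items():
            p = layer.get_param(name)
            g = np.zeros_like(p)
            flat_p = p.ravel()
            flat_g = g.ravel()
            for idx in range(flat_p.size):
                orig = flat_p[idx]
                flat_p[idx] = orig + h
                layer.set_param(name, p)
                f_plus = loss_value()
                flat_p[idx] = orig - h
                layer.set_param(name, p)
                f_minus = loss_value()
                flat_p[idx] = orig
                layer.set_param(name, p)
                flat_g[idx] = (f_plus - f_minus) / (2.0 * h)
            layer_grads[name] = g
        grads.append(layer_grads)
    return grads


def fixed_point_residual(eps: Sequence[np.ndarray], model: NetworkModel,
                         points: Sequence[np.ndarray], floor: float = 1e-12
                         ) -> list[float]:
    """Per-layer violation of the error fixed-point recursion.

    For ``l = 1 .. L-1`` returns
    ``||eps_l - eps_{l+1} J_{l+1}(points[l])|| / max(||eps_l||, floor)``
    where ``points[l]`` is the linearization point of layer ``l+1``'s
    Jacobian (beliefs for strict inference, forward activations for the
    fixed prediction assumption).  A converged run drives all entries
    toward zero.
    """
    depth = model.depth
    if len(eps) != depth:
        raise ValueError(f"expected {depth} error arrays, got {len(eps)}")
    residuals = []
    for l in range(1, depth):
        back = model.layers[l].vjp_input(np.asarray(points[l], dtype=float), eps[l])
        num = np.linalg.norm(eps[l - 1] - back)
        residuals.append(float(num / max(np.linalg.norm(eps[l - 1]), floor)))
    return residuals


def fixed_point_closed_form(model: NetworkModel, loss, y,
                            beliefs: Sequence[np.ndarray],
                            mode: str = "strict"
                            ) -> tuple[list[np.ndarray], list[dict[str, np.ndarray]]]:
    """Assemble the converged errors and updates directly from beliefs.

    Starting from the output error implied by the beliefs, the error of
    each layer is obtained by one Jacobian contraction per layer and the
    parameter updates by one parameter-adjoint per layer — the closed-form
    value the iterative inference converges to.

    ``beliefs`` has length ``L + 1`` with ``beliefs[0]`` the clamped input.
    ``mode="strict"`` linearizes at the beliefs themselves and recomputes
    the output prediction from ``beliefs[L-1]``; ``mode="fixed_pred"``
    expects ``beliefs`` to be forward-pass activations.
    """
    loss = get_loss(loss)
    depth = model.depth
    if mode not in ("strict", "fixed_pred"):
        raise ValueError(f"mode must be 'strict' or 'fixed_pred', got {mode!r}")
    points = [np.asarray(b, dtype=float) for b in beliefs]
    if mode == "strict":
        y_pred = model.layers[-1].forward(points[depth - 1])
    else:
        y_pred = points[depth]
    eps_star: list[np.ndarray] = [None] * depth
    eps_star[depth - 1] = loss.output_error(y_pred, y)
    for l in range(depth - 1, 0, -1):
        eps_star[l - 1] = model.layers[l].vjp_input(points[l], eps_star[l])
    dtheta_star = [
        {name: -g for name, g in
         model.layers[l].vjp_params(points[l], eps_star[l]).items()}
        for l in range(depth)
    ]
    return eps_star, dtheta_star


def _param_layers(model: NetworkModel) -> list[int]:
    return [l for l, layer in enumerate(model.layers) if layer.n_params > 0]


def _safe_metrics(a, b) -> tuple[float, float]:
    """Sweep-table metrics tolerating zero vectors (NaN-valued instead of raising)."""
    av, bv = flatten_update(a), flatten_update(b)
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if nb == 0:
        return (0.0, 0.0) if na == 0 else (np.nan, np.nan)
    err = float(np.linalg.norm(av - bv) / nb)
    if na == 0:
        return err, np.nan
    return err, _angle_deg(av, bv, na, nb)


def _compare_rows(model, dtheta_pc, dtheta_bp, eta, n) -> list[dict]:
    rows = []
    for l in _param_layers(model):
        err, ang = _safe_metrics(dtheta_pc[l], dtheta_bp[l])
        rows.append({"eta": eta, "n": n, "layer": l + 1,
                     "relative_error": err, "angle_deg": ang,
                     "diverged": False})
    whole_pc = np.concatenate([flatten_update(d) for d in dtheta_pc])
    whole_bp = np.concatenate([flatten_update(d) for d in dtheta_bp])
    err, ang = _safe_metrics(whole_pc, whole_bp)
    rows.append({"eta": eta, "n": n, "layer": AGGREGATE_LAYER,
                 "relative_error": err, "angle_deg": ang,
                 "diverged": False})
    return rows


def sweep_compare(model: NetworkModel, loss, x, y, err_type: str,
                  etas: Sequence[float], ns: Sequence[int],
                  **infer_kwargs) -> pd.DataFrame:
    """Per-layer agreement with backpropagation over an ``(eta, n)`` grid.

    One mini-batch, fixed parameters.  Columns: ``eta, n, layer,
    relative_error, angle_deg, diverged``; layer ``0`` is the whole-model
    aggregate and divergent runs yield flagged rows with NaN metrics.
    """
    bp = backprop_update(model, loss, x, y)
    rows: list[dict] = []
    for eta in etas:
        for n in ns:
            try:
                res = pc_infer(model, loss, x, y, err_type=err_type,
                               eta=eta, n=n, **infer_kwargs)
            except DivergenceError:
                labels = [l + 1 for l in _param_layers(model)] + [AGGREGATE_LAYER]
                for label in labels:
                    rows.append({
                        "eta": eta, "n": n, "layer": label,
                        "relative_error": np.nan, "angle_deg": np.nan,
                        "diverged": True,
                    })
                continue
            rows.extend(_compare_rows(model, res.dtheta, bp.dtheta, eta, n))
    return pd.DataFrame(rows, columns=["eta", "n", "layer", "relative_error",
                                       "angle_deg", "diverged"])


def iteration_schedule(model: NetworkModel, loss, x, y, eta: float = 1.0,
                       n_iters: int | None = None) -> pd.DataFrame:
    """Track per-iteration agreement of fixed-prediction updates with backprop.

    Runs a single fixed-prediction inference recording the in-sweep errors
    of every iteration, converts each snapshot into the parameter updates
    the pseudocode would produce if stopped right after that sweep, and
    compares them layer-wise with backpropagation.  Columns: ``iteration,
    layer, relative_error``.
    """
    if n_iters is None:
        n_iters = model.depth
    res = pc_infer(model, loss, x, y, err_type="fixed_pred", eta=eta,
                   n=n_iters, record_history=True)
    bp = backprop_update(model, loss, x, y)
    vhat = res.vhat
    rows = []
    for i, eps_snapshot in enumerate(res.history["eps"], start=1):
        for l in _param_layers(model):
            upd = {name: -g for name, g in
                   model.layers[l].vjp_params(vhat[l], eps_snapshot[l]).items()}
            ref = flatten_update(bp.dtheta[l])
            err = float(np.linalg.norm(flatten_update(upd) - ref)
                        / np.linalg.norm(ref)) if np.linalg.norm(ref) > 0 else 0.0
            rows.append({"iteration": i, "layer": l + 1, "relative_error": err})
    return pd.DataFrame(rows, columns=["iteration", "layer", "relative_error"])
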