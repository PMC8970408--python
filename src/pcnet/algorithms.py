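"""Learning algorithms: backpropagation, strict predictive coding, and
predictive coding under the fixed prediction assumption (with optional
precision weighting).

All algorithms return a :class:`PCResult` with the same contract:
``eps[l - 1]`` is the (row-form, per-sample) error at layer ``l`` and
``dtheta[l - 1]`` the parameter update for layer ``l`` in the
negative-gradient sense — an optimizer minimizing the loss should step
along ``+dtheta`` (equivalently treat ``-dtheta`` as its gradient).

Sign conventions
----------------
Strict inference uses errors ``eps_l = f_l(v_{l-1}; theta_l) - v_l`` so
that the belief increment ``dv_l = eps_l - eps_{l+1} @ J_{l+1}(v_l)`` is
exactly the negative gradient of the free energy with respect to ``v_l``.
Fixed-prediction inference uses ``eps_l = vhat_l - v_l`` with all
Jacobians linearized at the forward-pass activations ``vhat``; this is
the convention under which the error recursion telescopes and the
eta=1, n=L run reproduces backpropagation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DivergenceError
from .network.losses import Loss, get_loss
from .network.model import NetworkModel, forward_pass

__all__ = [
    "PCConfig",
    "PCResult",
    "PrecisionSpec",
    "backprop_update",
    "strict_pc_update",
    "fixed_pred_pc_update",
    "precision_fixed_pred_update",
    "free_energy",
    "pc_infer",
]

ERR_TYPES = ("exact", "strict", "fixed_pred")


# ---------------------------------------------------------------------------
# configuration / result containers
# ---------------------------------------------------------------------------

class PrecisionSpec:
    """Per-layer precision (inverse covariance) matrices.

    Parameters
    ----------
    hidden
        Sequence of length ``L - 1``; entry ``l - 1`` applies to hidden
        layer ``l``.  Each entry is ``None`` (identity), a positive 1-D
        vector (diagonal precision), or a symmetric positive-definite 2-D
        matrix.  Matrix precisions require vector-shaped activations.
    output
        Optional precision for the output layer; only meaningful with the
        squared-Euclidean loss.
    """

    def __init__(self, hidden: Sequence | None = None, output=None):
        self.hidden = list(hidden) if hidden is not None else []
        self.output = None if output is None else np.asarray(output, dtype=float)

    @staticmethod
    def _check_entry(p, where: str) -> np.ndarray | None:
        if p is None:
            return None
        p = np.asarray(p, dtype=float)
        if p.ndim == 1:
            if np.any(p <= 0):
                raise ConfigurationError(f"diagonal precision at {where} must be > 0")
            return p
        if p.ndim == 2:
            if p.shape[0] != p.shape[1] or not np.allclose(p, p.T, atol=1e-10):
                raise ConfigurationError(f"precision matrix at {where} must be symmetric")
            if np.min(np.linalg.eigvalsh(p)) <= 0:
                raise ConfigurationError(
                    f"precision matrix at {where} must be positive definite"
                )
            return p
        raise ConfigurationError(f"precision at {where} must be 1-D or 2-D")

    def validate(self, model: NetworkModel) -> "PrecisionSpec":
        depth = model.depth
        if len(self.hidden) not in (0, depth - 1):
            raise ConfigurationError(
                f"need {depth - 1} hidden precision entries, got {len(self.hidden)}"
            )
        checked = []
        for i, p in enumerate(self.hidden):
            p = self._check_entry(p, f"hidden layer {i + 1}")
            if p is not None:
                shape = model.layers[i].output_shape
                if len(shape) != 1 or p.shape[0] != shape[0]:
                    raise ConfigurationError(
                        f"precision at hidden layer {i + 1} has size {p.shape[0]}, "
                        f"layer activation shape is {shape} (vector layers only)"
                    )
            checked.append(p)
        self.hidden = checked
        self.output = self._check_entry(self.output, "output layer")
        if self.output is not None:
            shape = model.layers[-1].output_shape
            if len(shape) != 1 or self.output.shape[0] != shape[0]:
                raise ConfigurationError(
                    f"output precision size {self.output.shape[0]} does not match "
                    f"output shape {shape}"
                )
        return self

    def weight(self, eps: np.ndarray, layer: int, depth: int) -> np.ndarray:
        """Apply layer ``layer``'s precision to a raw error (``eps @ P``)."""
        p = self.output if layer == depth else (
            self.hidden[layer - 1] if self.hidden else None)
        if p is None:
            return eps
        if p.ndim == 1:
            return eps * p
        return eps @ p

    def quad(self, eps: np.ndarray, layer: int, depth: int) -> float:
        """Precision-weighted squared norm ``eps @ P @ eps.T`` summed over batch."""
        p = self.output if layer == depth else (
            self.hidden[layer - 1] if self.hidden else None)
        if p is None:
            return float(np.sum(eps * eps))
        if p.ndim == 1:
            return float(np.sum(eps * eps * p))
        return float(np.einsum("mi,ij,mj->", eps, p, eps))


@dataclass
class PCConfig:
    """Hyperparameters of the inference loop.

    ``eta`` and ``n_iters`` are ignored for ``err_type="exact"``.  When
    ``tol`` is set the loop stops early once ``max_l ||dv_l||_inf < tol``
    (capped at ``max_iters`` sweeps).
    """

    err_type: str = "fixed_pred"
    eta: float = 0.1
    n_iters: int = 20
    v_init: list | None = None
    refresh_errors_before_update: bool = False
    precision: PrecisionSpec | None = None
    divergence_bound: float = 1e8
    tol: float | None = None
    max_iters: int = 10_000
    record_history: bool = False

    def __post_init__(self):
        if self.err_type not in ERR_TYPES:
            raise ConfigurationError(
                f"err_type must be one of {ERR_TYPES}, got {self.err_type!r}"
            )
        if self.err_type != "exact":
            if self.eta <= 0:
                raise ConfigurationError("eta must be > 0")
            if self.n_iters < 0:
                raise ConfigurationError("n_iters must be >= 0")


@dataclass
class PCResult:
    """Common return contract of every algorithm."""

    vhat: list          # forward-pass activations, length L + 1
    loss: float         # mean-over-batch loss at the forward-pass output
    dLdy: np.ndarray    # gradient of the mean loss w.r.t. the output
    v: list             # beliefs, length L + 1 (v[0] = x; see module docs)
    eps: list           # per-layer errors, length L
    dtheta: list        # per-layer parameter updates (negative-gradient sense)
    diagnostics: dict = field(default_factory=dict)
    history: dict | None = None


def _neg(updates: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {name: -g for name, g in updates.items()}


def _check_divergence(beliefs: list[np.ndarray], bound: float, iteration: int) -> None:
    for v in beliefs:
        if v is None:
            continue
        if not np.all(np.isfinite(v)) or np.linalg.norm(v) > bound:
            raise DivergenceError(
                f"belief norm exceeded {bound:g} at inference iteration {iteration}; "
                "reduce eta or n_iters",
                iteration=iteration,
            )


# ---------------------------------------------------------------------------
# backpropagation reference
# ---------------------------------------------------------------------------

def backprop_update(model: NetworkModel, loss, x, y) -> PCResult:
    """Exact gradients via the standard backward recursion.

    ``eps[l - 1]`` holds ``delta_l``, the per-sample gradient of the
    (sum-over-batch) loss with respect to the layer-``l`` activation;
    ``dtheta`` holds the negative gradients of the mean loss.
    """
    loss = get_loss(loss)
    vhat = forward_pass(model, x)
    value, grad_mean = loss.value_and_grad(vhat[-1], y)
    depth = model.depth
    deltas: list[np.ndarray] = [None] * depth
    deltas[-1] = loss.output_error(vhat[-1], y)
    for l in range(depth - 1, 0, -1):
        deltas[l - 1] = model.layers[l].vjp_input(vhat[l], deltas[l])
    dtheta = [_neg(model.layers[l].vjp_params(vhat[l], deltas[l]))
              for l in range(depth)]
    return PCResult(
        vhat=vhat, loss=value, dLdy=grad_mean,
        v=[a.copy() for a in vhat], eps=deltas, dtheta=dtheta,
        diagnostics={"n_iters_run": 0},
    )


# ---------------------------------------------------------------------------
# strict predictive coding (Algorithm-2 style)
# ---------------------------------------------------------------------------

def strict_pc_update(model: NetworkModel, loss, x, y, cfg: PCConfig) -> PCResult:
    """Gradient descent of the free energy on beliefs, predictions live.

    Each sweep recomputes the output prediction from the current belief at
    layer ``L - 1`` and re-linearizes every Jacobian at the current
    beliefs.  For non-Euclidean losses the output error is recomputed as
    the per-sample loss gradient each sweep while the belief increment
    keeps its first-order form (second-order loss terms are dropped); the
    meaning of the resulting parameter updates is then heuristic.
    """
    if cfg.err_type != "strict":
        raise ConfigurationError(f"strict_pc_update requires err_type='strict', got {cfg.err_type!r}")
    if cfg.precision is not None:
        raise ConfigurationError("precision weighting is only supported with err_type='fixed_pred'")
    loss = get_loss(loss)
    vhat = forward_pass(model, x)
    depth = model.depth
    value, grad_mean = loss.value_and_grad(vhat[-1], y)

    # beliefs: index 0 is the clamped input, 1..L-1 are free
    if cfg.v_init is not None:
        if len(cfg.v_init) != depth - 1:
            raise ConfigurationError(
                f"v_init must hold {depth - 1} hidden-layer beliefs"
            )
        v = [vhat[0]] + [np.array(b, dtype=float) for b in cfg.v_init]
    else:
        v = [vhat[0]] + [a.copy() for a in vhat[1:depth]]

    eps: list[np.ndarray] = [None] * depth
    vtilde = model.layers[-1].forward(v[depth - 1])
    eps[depth - 1] = loss.output_error(vtilde, y)
    dv_norm_log: list[list[float]] = []
    history = {"free_energy": [], "dv": [], "v": []} if cfg.record_history else None
    n_iters = cfg.max_iters if cfg.tol is not None else cfg.n_iters

    iters_run = 0
    for i in range(1, n_iters + 1):
        vtilde = model.layers[-1].forward(v[depth - 1])
        eps[depth - 1] = loss.output_error(vtilde, y)
        dv_sweep: list[np.ndarray] = [None] * depth
        for l in range(depth - 1, 0, -1):
            eps[l - 1] = model.layers[l - 1].forward(v[l - 1]) - v[l]
            dv = eps[l - 1] - model.layers[l].vjp_input(v[l], eps[l])
            v[l] = v[l] + cfg.eta * dv
            dv_sweep[l - 1] = dv
        iters_run = i
        _check_divergence(v[1:], cfg.divergence_bound, i)
        dv_norm_log.append(
            [float(np.linalg.norm(d)) if d is not None else 0.0 for d in dv_sweep]
        )
        if history is not None:
            history["dv"].append([None if d is None else d.copy() for d in dv_sweep])
            history["v"].append([b.copy() for b in v])
            history["free_energy"].append(
                free_energy(_strict_errors(model, loss, v, y)))
        if cfg.tol is not None:
            max_dv = max(
                (float(np.max(np.abs(d))) for d in dv_sweep if d is not None),
                default=0.0,
            )
            if max_dv < cfg.tol:
                break

    if cfg.refresh_errors_before_update:
        eps = _strict_errors(model, loss, v, y)
    vtilde = model.layers[-1].forward(v[depth - 1])
    dtheta = [_neg(model.layers[l].vjp_params(v[l], eps[l])) for l in range(depth)]
    v_out = v + [vtilde]
    return PCResult(
        vhat=vhat, loss=value, dLdy=grad_mean, v=v_out, eps=eps, dtheta=dtheta,
        diagnostics={"n_iters_run": iters_run, "dv_norms": dv_norm_log},
        history=history,
    )


def _strict_errors(model: NetworkModel, loss: Loss, v: list, y) -> list[np.ndarray]:
    """Errors implied by a belief configuration (all recomputed fresh)."""
    depth = model.depth
    eps = [model.layers[l - 1].forward(v[l - 1]) - v[l] for l in range(1, depth)]
    vtilde = model.layers[-1].forward(v[depth - 1])
    eps.append(loss.output_error(vtilde, y))
    return eps


# ---------------------------------------------------------------------------
# fixed prediction assumption (Algorithm-3 style)
# ---------------------------------------------------------------------------

def fixed_pred_pc_update(model: NetworkModel, loss, x, y, cfg: PCConfig) -> PCResult:
    """Inference with predictions and Jacobians frozen at ``vhat``.

    The output error is held fixed at the loss gradient of the forward
    pass.  Errors used for the final parameter updates are always
    refreshed from the final beliefs (``eps_l = vhat_l - v_l``), so a run
    with ``n_iters=0`` returns zero updates in all hidden layers.  The
    recorded history keeps the in-sweep (stale) errors — the quantities
    tracked by the layer-by-layer convergence schedule.
    """
    if cfg.err_type != "fixed_pred":
        raise ConfigurationError(
            f"fixed_pred_pc_update requires err_type='fixed_pred', got {cfg.err_type!r}"
        )
    loss = get_loss(loss)
    precision = cfg.precision
    vhat = forward_pass(model, x)
    depth = model.depth
    value, grad_mean = loss.value_and_grad(vhat[-1], y)

    if cfg.v_init is not None:
        if len(cfg.v_init) != depth - 1:
            raise ConfigurationError(f"v_init must hold {depth - 1} hidden-layer beliefs")
        v = [vhat[0]] + [np.array(b, dtype=float) for b in cfg.v_init]
    else:
        v = [vhat[0]] + [a.copy() for a in vhat[1:depth]]

    def weighted(raw: np.ndarray, layer: int) -> np.ndarray:
        if precision is None:
            return raw
        return precision.weight(raw, layer, depth)

    eps: list[np.ndarray] = [np.zeros_like(a) for a in vhat[1:depth]]
    if precision is not None and precision.output is not None:
        # squared-Euclidean only (validated upstream): eps_L = (vhat_L - y) P_L
        eps_L = weighted(vhat[-1] - np.asarray(y, dtype=float), depth)
    else:
        eps_L = loss.output_error(vhat[-1], y)
    eps.append(eps_L)

    dv_norm_log: list[list[float]] = []
    history = {"eps": [], "v": []} if cfg.record_history else None
    n_iters = cfg.max_iters if cfg.tol is not None else cfg.n_iters

    iters_run = 0
    for i in range(1, n_iters + 1):
        dv_sweep: list[np.ndarray] = [None] * depth
        for l in range(depth - 1, 0, -1):
            eps[l - 1] = weighted(vhat[l] - v[l], l)
            dv = eps[l - 1] - model.layers[l].vjp_input(vhat[l], eps[l])
            v[l] = v[l] + cfg.eta * dv
            dv_sweep[l - 1] = dv
        iters_run = i
        _check_divergence(v[1:], cfg.divergence_bound, i)
        dv_norm_log.append(
            [float(np.linalg.norm(d)) if d is not None else 0.0 for d in dv_sweep]
        )
        if history is not None:
            history["eps"].append([e.copy() for e in eps])
            history["v"].append([b.copy() for b in v])
        if cfg.tol is not None:
            max_dv = max(
                (float(np.max(np.abs(d))) for d in dv_sweep if d is not None),
                default=0.0,
            )
            if max_dv < cfg.tol:
                break

    # refresh from final beliefs (always, for this mode)
    for l in range(1, depth):
        eps[l - 1] = weighted(vhat[l] - v[l], l)
    dtheta = [_neg(model.layers[l].vjp_params(vhat[l], eps[l])) for l in range(depth)]
    v_out = v + [vhat[-1].copy()]
    return PCResult(
        vhat=vhat, loss=value, dLdy=grad_mean, v=v_out, eps=eps, dtheta=dtheta,
        diagnostics={"n_iters_run": iters_run, "dv_norms": dv_norm_log},
        history=history,
    )


def precision_fixed_pred_update(model: NetworkModel, loss, x, y, cfg: PCConfig) -> PCResult:
    """Fixed-prediction inference with precision-weighted errors.

    Hidden-layer precisions reshape the inference trajectory but leave the
    converged parameter updates unchanged; an output-layer precision
    (squared-Euclidean loss only) re-weights the converged updates by
    ``P_L``.
    """
    loss = get_loss(loss)
    if cfg.precision is None:
        cfg = PCConfig(**{**cfg.__dict__, "precision": PrecisionSpec()})
    cfg.precision.validate(model)
    if cfg.precision.output is not None and loss.kind != "squared_euclidean":
        raise ConfigurationError(
            "output-layer precision is only supported with the squared_euclidean loss"
        )
    return fixed_pred_pc_update(model, loss, x, y, cfg)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def free_energy(eps: Sequence[np.ndarray], precision: PrecisionSpec | None = None) -> float:
    """Half the summed (precision-weighted) squared norms of the errors.

    ``eps`` are raw per-sample errors; with a :class:`PrecisionSpec` the
    layer-``l`` term is the quadratic form ``eps_l P_l eps_l^T`` (the
    precision-weighted norm), otherwise the plain squared Frobenius norm.
    """
    depth = len(eps)
    total = 0.0
    for l, e in enumerate(eps, start=1):
        e = np.asarray(e, dtype=float)
        if precision is None:
            total += float(np.sum(e * e))
        else:
            total += precision.quad(e.reshape(e.shape[0], -1) if e.ndim > 2 else e,
                                    l, depth)
    return 0.5 * total


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def pc_infer(model: NetworkModel, loss, x, y, err_type: str = "fixed_pred",
             eta: float = 0.1, n: int = 20, v_init=None, **kwargs) -> PCResult:
    """Single entry point dispatching on ``err_type``.

    ``err_type="exact"`` ignores ``eta``, ``n`` and ``v_init`` and returns
    backpropagation's gradients.
    """
    if err_type == "exact":
        return backprop_update(model, loss, x, y)
    cfg = PCConfig(err_type=err_type, eta=eta, n_iters=n, v_init=v_init, **kwargs)
    if err_type == "strict":
        return strict_pc_update(model, loss, x, y, cfg)
    if err_type == "fixed_pred":
        if cfg.precision is not None:
            return precision_fixed_pred_update(model, loss, x, y, cfg)
        return fixed_pred_pc_update(model, loss, x, y, cfg)
    raise ConfigurationError(f"unknown err_type {err_type!r}")
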