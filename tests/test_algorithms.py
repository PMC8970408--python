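"""Tests for backprop, strict PC, fixed-prediction PC, and precision variants."""

import numpy as np
import pytest

import pcnet as pc
from pcnet.algorithms import PCConfig, PrecisionSpec
from pcnet.exceptions import ConfigurationError, DivergenceError

from conftest import (
    fd_vjp_input,
    random_mlp,
    random_xy,
    rel,
    rel_dict,
    saturated_tanh_net,
    scalar_chain,
)


class TestBackprop:
    def test_scalar_chain_hand_trace(self):
        model = scalar_chain()
        res = pc.backprop_update(model, "squared_euclidean",
                                 np.array([[1.0]]), np.array([[0.0]]))
        np.testing.assert_allclose([e.item() for e in res.eps], [18.0, 6.0])
        assert res.dtheta[0]["weight"].item() == pytest.approx(-18.0)
        assert res.dtheta[1]["weight"].item() == pytest.approx(-12.0)
        assert res.loss == pytest.approx(18.0)

    def test_zero_at_critical_point(self):
        model = random_mlp(0)
        x = np.random.default_rng(0).standard_normal((3, 4))
        y = model.forward(x)
        res = pc.backprop_update(model, "squared_euclidean", x, y)
        for d in res.dtheta:
            for g in d.values():
                np.testing.assert_array_equal(g, np.zeros_like(g))

    def test_matches_finite_differences(self):
        model = random_mlp(1, sizes=(3, 4, 2))
        x, y = random_xy(model, 2, m=3)
        res = pc.backprop_update(model, "squared_euclidean", x, y)
        fd = pc.finite_difference_grad(model, "squared_euclidean", x, y)
        for l in range(model.depth):
            if not res.dtheta[l]:
                continue
            neg = {k: -v for k, v in res.dtheta[l].items()}
            assert rel_dict(neg, fd[l]) < 1e-5

    def test_batch_size_invariance(self):
        model = random_mlp(3)
        x, y = random_xy(model, 4, m=2)
        single = pc.backprop_update(model, "squared_euclidean", x, y)
        doubled = pc.backprop_update(
            model, "squared_euclidean", np.vstack([x, x]), np.vstack([y, y]))
        for d1, d2 in zip(single.dtheta, doubled.dtheta):
            for k in d1:
                np.testing.assert_allclose(d1[k], d2[k], atol=1e-12)

    def test_dLdy_is_mean_loss_gradient(self):
        model = random_mlp(5)
        x, y = random_xy(model, 5, m=4)
        res = pc.backprop_update(model, "squared_euclidean", x, y)
        np.testing.assert_allclose(res.dLdy, (res.vhat[-1] - y) / 4)


class TestStrictPC:
    def test_zero_error_fixed_point(self):
        model = random_mlp(0)
        x = np.random.default_rng(1).standard_normal((2, 4))
        y = model.forward(x)
        res = pc.strict_pc_update(model, "squared_euclidean", x, y,
                                  PCConfig(err_type="strict", eta=0.1, n_iters=5))
        for e in res.eps:
            np.testing.assert_allclose(e, 0.0, atol=1e-12)
        for d in res.dtheta:
            for g in d.values():
                np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_scalar_chain_one_iteration(self):
        # hand-trace of the pseudocode order, eta=0.1, n=1
        model = scalar_chain()
        res = pc.strict_pc_update(
            model, "squared_euclidean", np.array([[1.0]]), np.array([[0.0]]),
            PCConfig(err_type="strict", eta=0.1, n_iters=1))
        assert res.eps[1].item() == pytest.approx(6.0)
        assert res.eps[0].item() == pytest.approx(0.0)
        assert res.v[1].item() == pytest.approx(0.2)     # 2 + 0.1 * (-18)
        # stale eps_1 = 0 -> literal post-loop dtheta_1 = 0
        assert res.dtheta[0]["weight"].item() == 0.0

    def test_converges_to_fixed_point_equations(self):
        model = pc.NetworkModel([pc.Affine(4, 6, seed=7), pc.Tanh((6,)),
                                 pc.Affine(6, 3, seed=8)])
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 4))
        y = rng.standard_normal((4, 3))
        res = pc.strict_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="strict", eta=0.05, n_iters=0, tol=1e-8))
        residuals = pc.fixed_point_residual(res.eps, model, res.v)
        assert max(residuals) <= 1e-4
        eps_star, dtheta_star = pc.fixed_point_closed_form(
            model, "squared_euclidean", y, res.v[:model.depth], mode="strict")
        for l in range(model.depth):
            if res.dtheta[l]:
                assert rel_dict(dtheta_star[l], res.dtheta[l]) <= 1e-4

    def test_free_energy_descends(self):
        model = random_mlp(9, sizes=(3, 5, 4, 2))
        x, y = random_xy(model, 11, m=3)
        res = pc.strict_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="strict", eta=0.05, n_iters=200,
                     record_history=True))
        f = res.history["free_energy"]
        assert all(f[i + 1] <= f[i] + 1e-10 for i in range(len(f) - 1))

    def test_dv_is_negative_free_energy_gradient(self):
        # eta=0 freezes the beliefs, so the recorded dv is evaluated at the
        # supplied configuration; compare with central differences of -F.
        model = pc.NetworkModel([pc.Affine(3, 4, seed=20), pc.Tanh((4,)),
                                 pc.Affine(4, 2, seed=21)])
        rng = np.random.default_rng(22)
        x = rng.standard_normal((2, 3))
        y = rng.standard_normal((2, 2))
        v_init = [rng.standard_normal((2, 4)), rng.standard_normal((2, 4))]
        res = pc.strict_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="strict", eta=1e-12, n_iters=1,
                     v_init=v_init, record_history=True))
        dv = res.history["dv"][0]
        loss = pc.get_loss("squared_euclidean")

        def f_of(v_hidden):
            eps = []
            v_full = [x] + list(v_hidden)
            for l in range(1, model.depth):
                eps.append(model.layers[l - 1].forward(v_full[l - 1]) - v_full[l])
            vtilde = model.layers[-1].forward(v_full[-1])
            eps.append(loss.output_error(vtilde, y))
            return pc.free_energy(eps)

        h = 1e-6
        for l_idx in range(model.depth - 1):
            grad = np.zeros_like(v_init[l_idx])
            flat = grad.ravel()
            base = [vi.copy() for vi in v_init]
            for j in range(flat.size):
                vplus = [vi.copy() for vi in base]
                vminus = [vi.copy() for vi in base]
                vplus[l_idx].ravel()[j] += h
                vminus[l_idx].ravel()[j] -= h
                flat[j] = (f_of(vplus) - f_of(vminus)) / (2 * h)
            assert rel(dv[l_idx], -grad) < 1e-5

    def test_divergence_guard(self):
        model = random_mlp(4, sizes=(4, 8, 8, 3))
        for layer in model.layers:
            for name, p in list(layer.param_items()):
                layer.set_param(name, p * 6.0)
        x, y = random_xy(model, 5, m=2)
        with pytest.raises(DivergenceError):
            pc.strict_pc_update(model, "squared_euclidean", x, y,
                                PCConfig(err_type="strict", eta=2.0,
                                         n_iters=400, divergence_bound=1e6))

    def test_refresh_errors_before_update(self):
        model = scalar_chain()
        res = pc.strict_pc_update(
            model, "squared_euclidean", np.array([[1.0]]), np.array([[0.0]]),
            PCConfig(err_type="strict", eta=0.1, n_iters=1,
                     refresh_errors_before_update=True))
        # refreshed eps_1 = f1(x) - v_1 = 2 - 0.2 = 1.8 -> dtheta_1 nonzero
        assert res.eps[0].item() == pytest.approx(1.8)
        assert res.dtheta[0]["weight"].item() == pytest.approx(-1.8)

    def test_precision_rejected(self):
        model = scalar_chain()
        with pytest.raises(ConfigurationError):
            pc.strict_pc_update(
                model, "squared_euclidean", np.array([[1.0]]), np.array([[0.0]]),
                PCConfig(err_type="strict", precision=PrecisionSpec()))


class TestFixedPredPC:
    def test_scalar_chain_equivalence(self):
        model = scalar_chain()
        res = pc.fixed_pred_pc_update(
            model, "squared_euclidean", np.array([[1.0]]), np.array([[0.0]]),
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=2))
        np.testing.assert_allclose([e.item() for e in res.eps], [18.0, 6.0])
        assert res.dtheta[0]["weight"].item() == pytest.approx(-18.0)
        assert res.dtheta[1]["weight"].item() == pytest.approx(-12.0)

    @pytest.mark.parametrize("activation", ["relu", "tanh"])
    @pytest.mark.parametrize("loss", ["squared_euclidean", "softmax_cross_entropy"])
    def test_unit_step_exact_equivalence(self, activation, loss):
        model = random_mlp(17, sizes=(4, 7, 6, 3), activation=activation)
        x, y = random_xy(model, 18, m=8, loss=loss)
        bp = pc.backprop_update(model, loss, x, y)
        fp = pc.fixed_pred_pc_update(
            model, loss, x, y,
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=model.depth))
        for l in range(model.depth):
            assert rel(fp.eps[l], bp.eps[l]) <= 1e-6
            if bp.dtheta[l]:
                assert rel_dict(fp.dtheta[l], bp.dtheta[l]) <= 1e-6

    def test_layer_schedule_under_unit_step(self):
        # eps_l stays zero for i < L - l + 1 and equals delta_l afterwards
        model = random_mlp(23, sizes=(3, 5, 5, 4, 2))
        depth = model.depth
        x, y = random_xy(model, 24, m=2)
        bp = pc.backprop_update(model, "squared_euclidean", x, y)
        res = pc.fixed_pred_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=depth,
                     record_history=True))
        for i, eps in enumerate(res.history["eps"], start=1):
            for l in range(1, depth + 1):
                if i < depth - l + 1:
                    np.testing.assert_allclose(eps[l - 1], 0.0, atol=1e-12)
                else:
                    assert rel(eps[l - 1], bp.eps[l - 1]) <= 1e-9

    def test_zero_iterations_gives_zero_hidden_updates(self):
        model = random_mlp(31)
        x, y = random_xy(model, 32, m=2)
        res = pc.fixed_pred_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=0))
        for l in range(model.depth - 1):
            for g in res.dtheta[l].values():
                np.testing.assert_array_equal(g, np.zeros_like(g))

    def test_zero_output_error(self):
        model = random_mlp(33)
        x = np.random.default_rng(33).standard_normal((2, 4))
        y = model.forward(x)
        res = pc.fixed_pred_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=model.depth))
        for e in res.eps:
            np.testing.assert_allclose(e, 0.0, atol=1e-12)

    def test_jacobians_frozen_at_vhat(self):
        # with eta < 1 the trajectory differs from strict PC even at the
        # first iteration on a curved network
        model = random_mlp(35, sizes=(3, 6, 2))
        x, y = random_xy(model, 36, m=2)
        fp = pc.fixed_pred_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=0.5, n_iters=30))
        bp = pc.backprop_update(model, "squared_euclidean", x, y)
        # converges toward backprop (contraction), though not exactly
        for l in range(model.depth):
            if bp.dtheta[l]:
                assert rel_dict(fp.dtheta[l], bp.dtheta[l]) < 0.05


class TestPrecision:
    def test_identity_precision_bit_identical(self):
        model = random_mlp(41)
        x, y = random_xy(model, 42, m=3)
        plain = pc.fixed_pred_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=0.5, n_iters=10))
        spec = PrecisionSpec(hidden=[None] * (model.depth - 1))
        weighted = pc.precision_fixed_pred_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=0.5, n_iters=10, precision=spec))
        for l in range(model.depth):
            assert np.array_equal(weighted.eps[l], plain.eps[l])
            for k in plain.dtheta[l]:
                assert np.array_equal(weighted.dtheta[l][k], plain.dtheta[l][k])

    def test_hidden_precision_invariance(self):
        model = random_mlp(43, sizes=(4, 6, 5, 3))
        x, y = random_xy(model, 44, m=4)
        rng = np.random.default_rng(45)
        hidden = []
        for layer in model.layers[:-1]:
            if len(layer.output_shape) == 1:
                hidden.append(rng.uniform(0.5, 2.0, layer.output_shape[0]))
            else:
                hidden.append(None)
        spec = PrecisionSpec(hidden=hidden)
        res = pc.precision_fixed_pred_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=0.2, n_iters=4000,
                     precision=spec, tol=1e-12))
        bp = pc.backprop_update(model, "squared_euclidean", x, y)
        for l in range(model.depth):
            if bp.dtheta[l]:
                assert rel_dict(res.dtheta[l], bp.dtheta[l]) <= 1e-3

    def test_hidden_precision_changes_trajectory(self):
        model = random_mlp(47, sizes=(4, 6, 3))
        x, y = random_xy(model, 48, m=2)
        spec = PrecisionSpec(hidden=[2.0 * np.ones(6), None])
        cfg = dict(err_type="fixed_pred", eta=0.3, n_iters=3)
        plain = pc.fixed_pred_pc_update(model, "squared_euclidean", x, y,
                                        PCConfig(**cfg))
        weighted = pc.precision_fixed_pred_update(
            model, "squared_euclidean", x, y, PCConfig(**cfg, precision=spec))
        assert not np.allclose(weighted.v[1], plain.v[1])

    def test_output_precision_rescales_updates(self):
        model = random_mlp(49, sizes=(4, 6, 3))
        x, y = random_xy(model, 50, m=4)
        c = 2.0
        spec = PrecisionSpec(hidden=[None] * (model.depth - 1),
                             output=c * np.eye(3))
        res = pc.precision_fixed_pred_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="fixed_pred", eta=1.0, n_iters=model.depth,
                     precision=spec))
        bp = pc.backprop_update(model, "squared_euclidean", x, y)
        for l in range(model.depth):
            for k in bp.dtheta[l]:
                np.testing.assert_allclose(res.dtheta[l][k], c * bp.dtheta[l][k],
                                           rtol=1e-9, atol=1e-12)

    def test_output_precision_with_cross_entropy_rejected(self):
        model = random_mlp(51, sizes=(4, 6, 3))
        x, y = random_xy(model, 52, m=2, loss="softmax_cross_entropy")
        spec = PrecisionSpec(hidden=[None] * (model.depth - 1), output=np.eye(3))
        with pytest.raises(ConfigurationError, match="squared_euclidean"):
            pc.precision_fixed_pred_update(
                model, "softmax_cross_entropy", x, y,
                PCConfig(err_type="fixed_pred", precision=spec))

    def test_invalid_precision_rejected(self):
        model = random_mlp(53, sizes=(4, 6, 3))
        x, y = random_xy(model, 54, m=2)
        bad_sym = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ConfigurationError, match="symmetric"):
            PrecisionSpec._check_entry(bad_sym, "test")
        with pytest.raises(ConfigurationError, match="positive definite"):
            PrecisionSpec._check_entry(np.diag([1.0, -1.0]), "test")
        with pytest.raises(ConfigurationError, match="> 0"):
            PrecisionSpec._check_entry(np.array([1.0, 0.0]), "test")
        spec = PrecisionSpec(hidden=[np.ones(7), None])
        with pytest.raises(ConfigurationError):
            pc.precision_fixed_pred_update(
                model, "squared_euclidean", x, y,
                PCConfig(err_type="fixed_pred", precision=spec))


class TestFreeEnergy:
    def test_zero(self):
        assert pc.free_energy([np.zeros((1, 3)), np.zeros((1, 2))]) == 0.0

    def test_hand_value(self):
        eps = [np.array([[3.0, 4.0]]), np.array([[0.0]])]
        assert pc.free_energy(eps) == pytest.approx(12.5)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(55)
        eps = [rng.standard_normal((2, 3)), rng.standard_normal((2, 2))]
        base = pc.free_energy(eps)
        assert pc.free_energy([3.0 * e for e in eps]) == pytest.approx(9.0 * base)

    def test_precision_weighted(self):
        eps = [np.array([[1.0, 2.0]]), np.array([[1.0]])]
        spec = PrecisionSpec(hidden=[np.array([2.0, 1.0])])
        # 0.5 * (2*1 + 1*4) + 0.5 * 1 = 3.5
        assert pc.free_energy(eps, spec) == pytest.approx(3.5)


class TestDispatch:
    def test_exact_matches_backprop(self):
        model = random_mlp(57)
        x, y = random_xy(model, 58, m=2)
        a = pc.pc_infer(model, "squared_euclidean", x, y, err_type="exact")
        b = pc.backprop_update(model, "squared_euclidean", x, y)
        for l in range(model.depth):
            np.testing.assert_array_equal(a.eps[l], b.eps[l])

    def test_unknown_err_type(self):
        model = random_mlp(59)
        x, y = random_xy(model, 60, m=1)
        with pytest.raises(ConfigurationError):
            pc.pc_infer(model, "squared_euclidean", x, y, err_type="loose")

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            PCConfig(err_type="strict", eta=-1.0)
        with pytest.raises(ConfigurationError):
            PCConfig(err_type="strict", n_iters=-1)


class TestStrictDiffersFromBackprop:
    def test_hidden_layers_deviate_output_agrees(self):
        model, x, y = saturated_tanh_net(seed=0)
        res = pc.strict_pc_update(
            model, "squared_euclidean", x, y,
            PCConfig(err_type="strict", eta=0.05, n_iters=0, tol=1e-8,
                     max_iters=20000))
        bp = pc.backprop_update(model, "squared_euclidean", x, y)
        hidden = [rel_dict(res.dtheta[l], bp.dtheta[l])
                  for l in range(model.depth - 1) if bp.dtheta[l]]
        out = rel_dict(res.dtheta[-1], bp.dtheta[-1])
        assert max(hidden) > 0.01
        assert out <= 1e-3
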