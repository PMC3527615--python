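"""Network forward passes, analytic Jacobians and initialisation."""

import numpy as np
import pytest

from arcann.networks import (
    ArchitectureSpec,
    FFWNetwork,
    RBFNetwork,
    init_network,
    network_from_json,
    network_to_json,
)


def _rand_ffw(rng, h=3, d=2):
    return FFWNetwork(
        w_hidden=rng.normal(size=(h, d)),
        b_hidden=rng.normal(size=h),
        w_out=rng.normal(size=h),
        b_out=float(rng.normal()),
    )


def _rand_rbf(rng, h=3, d=2):
    return RBFNetwork(
        centers=rng.normal(size=(h, d)),
        widths=rng.uniform(0.5, 2.0, size=h),
        w_out=rng.normal(size=h),
        b_out=float(rng.normal()),
    )


class TestForward:
    def test_ffw_zero_weights_returns_bias(self):
        net = FFWNetwork(np.zeros((4, 2)), np.zeros(4), np.zeros(4), 1.0)
        X = np.random.default_rng(0).normal(size=(10, 2))
        np.testing.assert_array_equal(net.forward(X), np.ones(10))

    def test_ffw_hand_computed_value(self):
        # 1 input, 1 hidden unit: 2*sigmoid(0) + 1 = 2 at x = 0
        net = FFWNetwork(np.array([[1.0]]), np.array([0.0]), np.array([2.0]), 1.0)
        assert net.forward(np.array([[0.0]]))[0] == pytest.approx(2.0)

    def test_ffw_hidden_unit_permutation_invariance(self):
        rng = np.random.default_rng(1)
        net = _rand_ffw(rng, h=4)
        perm = [2, 0, 3, 1]
        net2 = FFWNetwork(
            net.w_hidden[perm], net.b_hidden[perm], net.w_out[perm], net.b_out
        )
        X = rng.normal(size=(20, 2))
        np.testing.assert_allclose(net.forward(X), net2.forward(X))

    def test_rbf_value_at_center(self):
        net = RBFNetwork(np.array([[1.0, -1.0]]), np.array([0.7]),
                         np.array([3.0]), 0.5)
        assert net.forward(np.array([[1.0, -1.0]]))[0] == pytest.approx(3.5)

    def test_rbf_far_field_tends_to_bias(self):
        rng = np.random.default_rng(2)
        net = _rand_rbf(rng)
        X = np.full((1, 2), 1e4)
        assert net.forward(X)[0] == pytest.approx(net.b_out, abs=1e-12)

    def test_rbf_opposite_weights_cancel(self):
        c = np.array([[0.5, 0.5], [0.5, 0.5]])
        net = RBFNetwork(c, np.array([1.0, 1.0]), np.array([2.0, -2.0]), 0.3)
        X = np.random.default_rng(3).normal(size=(15, 2))
        np.testing.assert_allclose(net.forward(X), np.full(15, 0.3))


class TestParameterVector:
    @pytest.mark.parametrize("family", ["FFW", "RBF"])
    def test_round_trip_and_count(self, family):
        rng = np.random.default_rng(4)
        net = _rand_ffw(rng, 5, 3) if family == "FFW" else _rand_rbf(rng, 5, 3)
        v = net.to_vector()
        expected = 5 * 4 + 6 if family == "FFW" else 5 * 5 + 1
        assert v.size == net.n_params == expected
        np.testing.assert_array_equal(net.from_vector(v).to_vector(), v)

    def test_json_round_trip(self):
        rng = np.random.default_rng(5)
        spec = ArchitectureSpec("RBF", ("chl_a_ug_l", "depth_m"), 3, "v2")
        net = _rand_rbf(rng)
        net2, spec2 = network_from_json(network_to_json(net, spec))
        np.testing.assert_array_equal(net.to_vector(), net2.to_vector())
        assert spec2 == spec


class TestJacobian:
    @pytest.mark.parametrize("family", ["FFW", "RBF"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, family, seed):
        rng = np.random.default_rng(seed)
        net = _rand_ffw(rng) if family == "FFW" else _rand_rbf(rng)
        X = rng.normal(size=(12, 2))
        J = net.residual_jacobian(X)
        v = net.to_vector()
        eps = 1e-6
        for k in range(v.size):
            vp, vm = v.copy(), v.copy()
            vp[k] += eps
            vm[k] -= eps
            fd = (net.from_vector(vp).forward(X) - net.from_vector(vm).forward(X)) / (
                2 * eps
            )
            np.testing.assert_allclose(
                J[:, k], fd, rtol=1e-5, atol=1e-7,
                err_msg=f"{family} parameter {k}",
            )

    @pytest.mark.parametrize("family", ["FFW", "RBF"])
    def test_output_bias_column_is_ones(self, family):
        rng = np.random.default_rng(6)
        net = _rand_ffw(rng) if family == "FFW" else _rand_rbf(rng)
        J = net.residual_jacobian(rng.normal(size=(8, 2)))
        np.testing.assert_array_equal(J[:, -1], np.ones(8))

    def test_zero_output_weights_kill_hidden_gradients(self):
        rng = np.random.default_rng(7)
        net = _rand_ffw(rng)
        net.w_out[:] = 0.0
        J = net.residual_jacobian(rng.normal(size=(8, 2)))
        h, d = net.w_hidden.shape
        np.testing.assert_array_equal(J[:, : h * d + h], 0.0)


class TestInit:
    spec_ffw = ArchitectureSpec("FFW", ("a", "b"), 4, "hna")
    spec_rbf = ArchitectureSpec("RBF", ("a", "b"), 4, "hna")

    def test_rbf_centers_within_data_range_widths_positive(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(-3, 5, size=(40, 2))
        for _ in range(10):
            net = init_network(self.spec_rbf, X, rng)
            assert (net.centers >= X.min(axis=0)).all()
            assert (net.centers <= X.max(axis=0)).all()
            assert (net.widths > 0).all()

    def test_ffw_inflection_inside_data_box(self):
        """Each hidden unit's pre-activation must change sign (or vanish)
        somewhere in the data box, i.e. its sigmoid inflection hyperplane
        crosses the input range."""
        rng = np.random.default_rng(9)
        X = rng.uniform(-2, 2, size=(30, 2))
        corners = np.array([[x, y] for x in (-2, 2) for y in (-2, 2)])
        lo, hi = X.min(axis=0), X.max(axis=0)
        corners = np.array(
            [[a, b] for a in (lo[0], hi[0]) for b in (lo[1], hi[1])]
        )
        for _ in range(10):
            net = init_network(self.spec_ffw, X, rng)
            pre = corners @ net.w_hidden.T + net.b_hidden
            assert (pre.min(axis=0) <= 1e-12).all()
            assert (pre.max(axis=0) >= -1e-12).all()

    def test_seeds_give_different_parameters(self):
        X = np.random.default_rng(0).uniform(size=(20, 2))
        a = init_network(self.spec_ffw, X, np.random.default_rng(1))
        b = init_network(self.spec_ffw, X, np.random.default_rng(2))
        assert not np.array_equal(a.to_vector(), b.to_vector())

    def test_degenerate_column_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="zero-range"):
            init_network(self.spec_ffw, X, np.random.default_rng(0))


class TestArchitectureSpec:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("FFW", ("a",), 1, "hna")
        with pytest.raises(ValueError):
            ArchitectureSpec("FFW", ("a", "b", "c", "d"), 5, "hna")
        with pytest.raises(ValueError):
            ArchitectureSpec("MLP", ("a",), 5, "hna")
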