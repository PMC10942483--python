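"""Residual operator, physics-informed concentration and loss assembly."""

import numpy as np
import pytest

from pinndiff.fields import PointCloud
from pinndiff.pinn import (
    MLP,
    DegenerateDataError,
    LossBreakdown,
    NetworkSpec,
    PinnModel,
    loss,
    physics_informed_concentration,
    residual_f,
    softplus_inverse,
)


class AnalyticField:
    """Closed-form stand-in satisfying the differentiable-field protocol.

    ``terms`` maps exponent tuples (px, py, pt) to coefficients of
    c = Σ k · x^px · y^py · t^pt, so all derivatives are exact.
    """

    def __init__(self, terms: dict):
        self.terms = terms

    @staticmethod
    def _dpow(v, p, d):
        if d > p:
            return np.zeros_like(v)
        fac = 1.0
        for j in range(d):
            fac *= p - j
        return fac * v ** (p - d)

    def _eval(self, X, dx=0, dy=0):
        x, y = X[:, 0], X[:, 1]
        t = X[:, 2] if X.shape[1] > 2 else np.zeros(len(X))
        out = np.zeros(len(X))
        for (px, py, pt), k in self.terms.items():
            out += k * self._dpow(x, px, dx) * self._dpow(y, py, dy) * t**pt
        return out.reshape(-1, 1)

    def evaluate(self, X):
        return self._eval(np.asarray(X, float)).ravel()

    def evaluate_with_derivatives(self, X, dims, second=False):
        X = np.asarray(X, float)
        out = self._eval(X)
        derivs = {}
        for k in dims:
            d1 = self._eval(X, dx=1 if k == 0 else 0, dy=1 if k == 1 else 0)
            d2 = self._eval(X, dx=2 if k == 0 else 0, dy=2 if k == 1 else 0) if second else None
            derivs[k] = (d1, d2)
        return out, derivs


class SumField:
    def __init__(self, a, b):
        self.a, self.b = a, b

    def evaluate_with_derivatives(self, X, dims, second=False):
        oa, da = self.a.evaluate_with_derivatives(X, dims, second)
        ob, db = self.b.evaluate_with_derivatives(X, dims, second)
        combined = {
            k: (da[k][0] + db[k][0], None if da[k][1] is None else da[k][1] + db[k][1])
            for k in dims
        }
        return oa + ob, combined


def _zero_weight_net(bias=0.0, transform="identity", n_in=3):
    spec = NetworkSpec(2, 8, output_transform=transform)
    net = MLP.create(spec, n_in, np.random.default_rng(0))
    for w in net.weights:
        w[:] = 0.0
    net.biases[-1][:] = bias
    return net


class TestResidual:
    def test_constant_concentration_has_zero_residual(self, rng):
        c_net = _zero_weight_net(bias=0.7)
        d_net = MLP.create(NetworkSpec(2, 8, output_transform="softplus"), 2,
                           np.random.default_rng(5))
        pts = rng.uniform(0, 1, (12, 3))
        np.testing.assert_allclose(residual_f(c_net, d_net, pts), 0.0, atol=1e-14)

    def test_quadratic_field_constant_d_gives_four_d(self, rng):
        # c = x² + y², D = D0  =>  f = D0 * (2 + 2) = 4 D0
        c = AnalyticField({(2, 0, 0): 1.0, (0, 2, 0): 1.0})
        d0 = 0.37
        d = AnalyticField({(0, 0, 0): d0})
        pts = rng.uniform(0, 1, (9, 3))
        np.testing.assert_allclose(residual_f(c, d, pts), 4 * d0, rtol=1e-12)

    def test_matches_finite_difference_oracle_on_random_networks(self):
        """Exact derivatives agree with a brute-force FD oracle to 1e-4."""
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            c_net = MLP.create(NetworkSpec(3, 16), 3, rng)
            d_net = MLP.create(NetworkSpec(2, 12, output_transform="softplus"), 2,
                               rng, output_bias=0.3)
            pts = rng.uniform(0.2, 0.8, (25, 3))
            h = 1e-5

            def cval(p):
                return c_net.evaluate(p)

            def dval(p):
                return d_net.evaluate(p[:, :2])

            f_fd = np.zeros(len(pts))
            lap = np.zeros(len(pts))
            for k in (0, 1):
                e = np.zeros(3)
                e[k] = h
                f_fd += ((cval(pts + e) - cval(pts - e)) / (2 * h)
                         * (dval(pts + e) - dval(pts - e)) / (2 * h))
                lap += (cval(pts + e) - 2 * cval(pts) + cval(pts - e)) / h**2
            f_fd += dval(pts) * lap
            f = residual_f(c_net, d_net, pts)
            scale = np.abs(f_fd).max()
            assert np.abs(f - f_fd).max() / scale < 1e-4

    def test_residual_linear_in_concentration(self, rng):
        """Superposition: f(c1 + c2, D) = f(c1, D) + f(c2, D)."""
        c1 = AnalyticField({(2, 1, 0): 0.6, (1, 0, 1): -0.2})
        c2 = AnalyticField({(0, 3, 0): 1.1, (2, 2, 0): 0.4})
        d = AnalyticField({(1, 0, 0): 0.2, (0, 1, 0): 0.3, (0, 0, 0): 0.5})
        pts = rng.uniform(0, 1, (15, 3))
        f_sum = residual_f(SumField(c1, c2), d, pts)
        np.testing.assert_allclose(
            f_sum, residual_f(c1, d, pts) + residual_f(c2, d, pts), rtol=1e-10
        )

    def test_graph_and_numpy_paths_agree(self, rng):
        from pinndiff.pinn import _residual_terms

        c_net = MLP.create(NetworkSpec(3, 10), 3, np.random.default_rng(3))
        d_net = MLP.create(NetworkSpec(2, 10, output_transform="softplus"), 2,
                           np.random.default_rng(4))
        pts = rng.uniform(0, 1, (8, 3))
        _, f_np = _residual_terms(c_net, d_net, pts)
        _, f_graph = _residual_terms(c_net, d_net, pts,
                                     c_params=c_net.wrap_parameters(),
                                     d_params=d_net.wrap_parameters())
        np.testing.assert_allclose(np.asarray(f_np).ravel(), f_graph.value.ravel(),
                                   rtol=1e-12)


class TestPhysicsInformedConcentration:
    def test_small_dt_limit_approaches_c(self, rng):
        c_net = MLP.create(NetworkSpec(2, 12), 3, np.random.default_rng(2))
        d_net = MLP.create(NetworkSpec(2, 12, output_transform="softplus"), 2,
                           np.random.default_rng(3))
        pts = rng.uniform(0.1, 0.8, (10, 3))
        gaps = []
        for dt in (1e-2, 1e-3, 1e-4):
            m = PinnModel(c_net, d_net, dt=dt)
            gaps.append(np.abs(physics_informed_concentration(m, pts)
                               - c_net.evaluate(pts)).max())
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 1e-3

    def test_zero_residual_reduces_to_shifted_evaluation(self, rng):
        c_net = _zero_weight_net(bias=0.4)
        d_net = _zero_weight_net(bias=0.2, transform="softplus", n_in=2)
        m = PinnModel(c_net, d_net, dt=0.05)
        pts = rng.uniform(0, 0.9, (7, 3))
        shifted = pts.copy()
        shifted[:, 2] += 0.05
        np.testing.assert_allclose(
            physics_informed_concentration(m, pts), c_net.evaluate(shifted), atol=1e-14
        )

    def test_linear_in_time_field_is_reproduced_exactly(self, rng):
        """c = a + b t + (b / 4D0)(x² + y²) has f ≡ b, so the backward-Euler
        correction cancels the time shift exactly."""
        a, b, d0 = 0.3, 0.8, 0.25
        c = AnalyticField({(0, 0, 0): a, (0, 0, 1): b,
                           (2, 0, 0): b / (4 * d0), (0, 2, 0): b / (4 * d0)})
        d = AnalyticField({(0, 0, 0): d0})
        m = PinnModel(c, d, dt=0.07)
        pts = rng.uniform(0, 0.9, (11, 3))
        c_here, _ = c.evaluate_with_derivatives(pts, dims=())
        np.testing.assert_allclose(
            physics_informed_concentration(m, pts), c_here.ravel(), rtol=1e-12
        )


class TestLoss:
    def _simple_model(self):
        c_net = MLP.create(NetworkSpec(2, 10), 3, np.random.default_rng(0))
        d_net = MLP.create(NetworkSpec(2, 10, output_transform="softplus"), 2,
                           np.random.default_rng(1), output_bias=0.2)
        return PinnModel(c_net, d_net, dt=0.02)

    def test_perfect_interpolation_gives_zero_loss(self, rng):
        a, b, d0 = 0.2, 0.5, 0.3
        c = AnalyticField({(0, 0, 0): a, (0, 0, 1): b,
                           (2, 0, 0): b / (4 * d0), (0, 2, 0): b / (4 * d0)})
        d = AnalyticField({(0, 0, 0): d0})
        m = PinnModel(c, d, dt=0.05)
        pts = rng.uniform(0, 0.9, (20, 3))
        c_obs = c.evaluate(pts)
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2], c_obs)
        lb = loss(m, cloud, pts)
        assert lb.data_term == pytest.approx(0.0, abs=1e-24)
        assert lb.consistency_term == pytest.approx(0.0, abs=1e-20)
        assert lb.total == pytest.approx(0.0, abs=1e-20)

    def test_unit_normalized_misfit_gives_data_term_one(self):
        sigma = 0.13
        c_net = _zero_weight_net(bias=0.5)
        d_net = _zero_weight_net(bias=0.2, transform="softplus", n_in=2)
        m = PinnModel(c_net, d_net, dt=0.02)
        cloud = PointCloud([0.4], [0.4], [0.1], [0.5 - sigma])
        lb = loss(m, cloud, np.array([[0.4, 0.4, 0.1]]), sigma_c=sigma)
        assert lb.data_term == pytest.approx(1.0, rel=1e-12)
        assert lb.consistency_term == pytest.approx(0.0, abs=1e-18)

    def test_matches_double_loop_resummation(self, rng):
        """Vectorized loss equals a record-by-record re-summation to 1e-12."""
        m = self._simple_model()
        pts = rng.uniform(0.1, 0.9, (17, 3))
        c_obs = rng.uniform(0, 1, 17)
        eq_pts = rng.uniform(0.1, 0.8, (9, 3))
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2], c_obs)
        sigma = cloud.sigma_c
        lb = loss(m, cloud, eq_pts)

        data_sum = 0.0
        for i in range(17):
            chat = m.c_net.evaluate(pts[i: i + 1])[0]
            data_sum += ((chat - c_obs[i]) / sigma) ** 2
        cons_sum = 0.0
        for i in range(9):
            cpi = physics_informed_concentration(m, eq_pts[i: i + 1])[0]
            chat = m.c_net.evaluate(eq_pts[i: i + 1])[0]
            cons_sum += ((cpi - chat) / sigma) ** 2
        assert lb.data_term == pytest.approx(data_sum / 17, rel=1e-12)
        assert lb.consistency_term == pytest.approx(cons_sum / 9, rel=1e-12)
        assert lb.total == pytest.approx(data_sum / 17 + cons_sum / 9, rel=1e-12)

    def test_invariant_under_point_permutation(self, rng):
        m = self._simple_model()
        pts = rng.uniform(0.1, 0.9, (12, 3))
        c_obs = rng.uniform(0, 1, 12)
        eq = rng.uniform(0.1, 0.8, (7, 3))
        cloud = PointCloud(pts[:, 0], pts[:, 1], pts[:, 2], c_obs)
        perm = rng.permutation(12)
        cloud_p = PointCloud(pts[perm, 0], pts[perm, 1], pts[perm, 2], c_obs[perm])
        lb = loss(m, cloud, eq)
        lb_p = loss(m, cloud_p, eq[rng.permutation(7)])
        assert lb.total == pytest.approx(lb_p.total, rel=1e-12)

    def test_constant_data_rejected(self):
        m = self._simple_model()
        cloud = PointCloud([0.1, 0.2], [0.1, 0.2], [0.0, 0.5], [0.4, 0.4])
        with pytest.raises(DegenerateDataError, match="sigma_c"):
            loss(m, cloud, np.array([[0.1, 0.1, 0.1]]))

    def test_breakdown_total_is_sum(self):
        lb = LossBreakdown(0.25, 0.5, 1.0)
        assert lb.total == pytest.approx(0.75)


class TestModelPlumbing:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path, rng):
        from pinndiff.fields import Scaling

        c_net = MLP.create(NetworkSpec(3, 12), 3, np.random.default_rng(7))
        d_net = MLP.create(NetworkSpec(3, 12, output_transform="softplus"), 2,
                           np.random.default_rng(8), output_bias=0.15)
        m = PinnModel(c_net, d_net, dt=0.01, scaling=Scaling(0.0125, 3600.0, 255.0))
        path = tmp_path / "ckpt.npz"
        m.save(path)
        back = PinnModel.load(path)
        pts = rng.uniform(0, 1, (20, 3))
        np.testing.assert_array_equal(back.predict_concentration(pts),
                                      m.predict_concentration(pts))
        np.testing.assert_array_equal(back.predict_diffusivity(pts[:, :2]),
                                      m.predict_diffusivity(pts[:, :2]))
        assert back.dt == m.dt
        assert back.scaling.length == pytest.approx(0.0125)

    def test_network_spec_validation(self):
        with pytest.raises(ValueError, match="hidden_layers"):
            NetworkSpec(0, 8)
        with pytest.raises(ValueError, match="activation"):
            NetworkSpec(2, 8, activation="relu")
        with pytest.raises(ValueError, match="output_transform"):
            NetworkSpec(2, 8, output_transform="exp")

    def test_softplus_inverse_is_inverse(self):
        for y in (0.01, 0.2, 3.0):
            x = softplus_inverse(y)
            assert np.log1p(np.exp(x)) == pytest.approx(y, rel=1e-10)
        with pytest.raises(ValueError):
            softplus_inverse(-1.0)

    def test_positive_dt_required(self):
        c_net = _zero_weight_net()
        d_net = _zero_weight_net(transform="softplus", n_in=2)
        with pytest.raises(ValueError, match="dt"):
            PinnModel(c_net, d_net, dt=0.0)
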