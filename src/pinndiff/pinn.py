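"""Physics-informed networks for inverse identification of D(x, y).

Two dense networks are trained jointly: ``c̃(x, y, t; θ)`` regresses the
observed concentration point cloud and ``D̃(x, y; φ)`` represents the
spatially varying diffusion coefficient.  They are tied together through
the diffusion operator

    f(c, D) = ∂x c ∂x D + ∂y c ∂y D + D (∂xx c + ∂yy c) = ∇·(D ∇c),

evaluated with exact derivatives of the networks, and a backward-Euler
physics-informed concentration

    c_pi(t, x, y) = c̃(t + Δt, x, y) − Δt · f(c̃, D̃)|_(t + Δt),

which must agree with the regressed c̃ at time t wherever the physics is
enforced.  The training objective is the sum of the data misfit and this
consistency residual, both normalized by the standard deviation σ_c of the
observed concentrations:

    MSE = mean[((c̃ − c)/σ_c)²] + mean[((c_pi − c̃)/σ_c)²].

Derivatives with respect to network inputs are propagated with exact
forward-mode chain rules (machine precision — no finite differencing);
parameter gradients come from the reverse sweep of :mod:`.autodiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fields import PointCloud, Scaling

__all__ = [
    "NetworkSpec",
    "MLP",
    "PinnModel",
    "LossBreakdown",
    "DegenerateDataError",
    "residual_f",
    "physics_informed_concentration",
    "loss",
]


class DegenerateDataError(ValueError):
    """Observed concentrations are constant: σ_c = 0 and D is unidentifiable."""


# -- generic math that works on both ndarrays and autodiff Tensors -------

def _tanh(x):
    return ad.tanh(x) if isinstance(x, Tensor) else np.tanh(x)


def _sigmoid(x):
    if isinstance(x, Tensor):
        return ad.sigmoid(x)
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softplus(x):
    if isinstance(x, Tensor):
        return ad.softplus(x)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _dtanh_mul(a, zu):
    if isinstance(a, Tensor):
        return ad.dtanh_mul(a, zu)
    return (1.0 - a * a) * zu


def _d2tanh_comb(a, zu, zv):
    if isinstance(a, Tensor):
        return ad.d2tanh_comb(a, zu, zv)
    s2 = 1.0 - a * a
    curve = -2.0 * a * s2 * zu * zu
    return curve if zv is None else s2 * zv + curve


def softplus_inverse(y: float) -> float:
    """Scalar inverse of softplus, used to seed the D-network output bias."""
    if y <= 0:
        raise ValueError("softplus is positive; cannot invert a nonpositive value")
    return float(np.log(np.expm1(y)))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one dense network."""

    hidden_layers: int = 8
    width: int = 128
    activation: str = "tanh"
    output_transform: str = "identity"

    def __post_init__(self):
        if self.hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.activation != "tanh":
            raise ValueError(
                f"unsupported activation {self.activation!r}; the physics residual "
                "requires a twice-differentiable activation and only 'tanh' is provided"
            )
        if self.output_transform not in ("identity", "softplus"):
            raise ValueError("output_transform must be 'identity' or 'softplus'")


class MLP:
    """Dense tanh network with exact input-derivative propagation.

    Inputs are affinely mapped to [-1, 1] internally (``input_shift`` /
    ``input_scale``) for conditioning; the mapping is invisible at the
    interface and the chain-rule factor is folded into the seeded tangents.
    """

    def __init__(self, spec: NetworkSpec, n_inputs: int, weights, biases,
                 input_shift=None, input_scale=None):
        self.spec = spec
        self.n_inputs = n_inputs
        self.weights = list(weights)
        self.biases = list(biases)
        self.input_shift = (
            np.full(n_inputs, 0.5) if input_shift is None else np.asarray(input_shift, float)
        )
        self.input_scale = (
            np.full(n_inputs, 2.0) if input_scale is None else np.asarray(input_scale, float)
        )

    @classmethod
    def create(cls, spec: NetworkSpec, n_inputs: int, rng: np.random.Generator,
               output_bias: float = 0.0, dtype=np.float64, **kw) -> "MLP":
        """Glorot-uniform initialized network; output bias optionally seeded."""
        sizes = [n_inputs] + [spec.width] * spec.hidden_layers + [1]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype))
            biases.append(np.zeros((1, fan_out), dtype=dtype))
        biases[-1][:] = output_bias
        return cls(spec, n_inputs, weights, biases, **kw)

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [np.asarray(p, float) for p in params[:k]]
        self.biases = [np.asarray(p, float) for p in params[k:]]

    def wrap_parameters(self) -> tuple[list[Tensor], list[Tensor]]:
        Ws = [Tensor(w, requires_grad=True) for w in self.weights]
        bs = [Tensor(b, requires_grad=True) for b in self.biases]
        return Ws, bs

    # -- forward with exact input derivatives ----------------------------
    def _forward_stacked(self, X: np.ndarray, dims=(), second: bool = False, params=None):
        """Core evaluation with tangents stacked along a leading axis.

        Forward-mode derivative propagation: per layer, with a = tanh(z),
        the first-derivative tangent updates as u ← tanh'(z)·(u W) and the
        pure second derivative as v ← tanh'(z)·(v W) + tanh''(z)·(u W)².
        All requested input dimensions ride in one (k, N, width) array so
        the per-layer work is three matrix products regardless of how many
        derivatives are taken.

        Returns ``(out, d1, d2)``: out is (N, 1); d1/d2 are (k, N, 1)
        stacks over ``dims`` (d2 is None unless ``second``).
        """
        tensor_mode = params is not None
        Ws, bs = params if tensor_mode else (self.weights, self.biases)
        dtype = Ws[0].value.dtype if tensor_mode else Ws[0].dtype
        X = np.asarray(X, dtype=np.float64)
        a_np = ((X - self.input_shift) * self.input_scale).astype(dtype)
        a = Tensor(a_np) if tensor_mode else a_np
        u = v = None
        if dims:
            seed = np.zeros((len(dims), 1, self.n_inputs), dtype=dtype)
            for j, dim in enumerate(dims):
                seed[j, 0, dim] = self.input_scale[dim]
            u = Tensor(seed) if tensor_mode else seed
        n_hidden = self.spec.hidden_layers
        for li in range(n_hidden):
            W, b = Ws[li], bs[li]
            z = a @ W + b
            zu = u @ W if u is not None else None
            zv = v @ W if v is not None else None
            a = _tanh(z)
            if u is not None:
                if second:
                    v = _d2tanh_comb(a, zu, zv)
                u = _dtanh_mul(a, zu)
        W, b = Ws[n_hidden], bs[n_hidden]
        out = a @ W + b
        d1 = u @ W if u is not None else None
        d2 = v @ W if v is not None else None
        if self.spec.output_transform == "softplus":
            s = _sigmoid(out)
            if d2 is not None:
                d2 = s * d2 + (s * (1.0 - s)) * (d1 * d1)
            if d1 is not None:
                d1 = s * d1
            out = _softplus(out)
        return out, d1, d2

    def forward(self, X: np.ndarray, dims=(), second: bool = False, params=None):
        """Evaluate the network and its derivatives along input dimensions.

        Parameters
        ----------
        X : (N, n_inputs) array of evaluation points.
        dims : input dimensions along which first (and optionally second)
            derivatives are propagated.
        second : also propagate the pure second derivative per dimension
            (mixed derivatives are never needed by the diffusion operator).
        params : optional (weights, biases) lists of autodiff Tensors; when
            given, the returned quantities are graph nodes differentiable
            with respect to the parameters.

        Returns
        -------
        out, derivs : output of shape (N, 1) and ``{dim: (d1, d2-or-None)}``.
        """
        out, d1, d2 = self._forward_stacked(X, dims=dims, second=second, params=params)

        def _slice(stack, j):
            if stack is None:
                return None
            return stack.take0(j) if isinstance(stack, Tensor) else stack[j]

        return out, {k: (_slice(d1, j), _slice(d2, j)) for j, k in enumerate(dims)}

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Plain value evaluation; returns a float64 (N,) array."""
        out, _ = self.forward(X)
        return out.ravel().astype(np.float64)

    def evaluate_with_derivatives(self, X, dims, second=False):
        """Numpy-path evaluation satisfying the differentiable-field protocol."""
        return self.forward(X, dims=dims, second=second)


@dataclass
class PinnModel:
    """The paired networks plus the Δt used by the physics residual."""

    c_net: MLP
    d_net: MLP
    dt: float
    scaling: Scaling | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def predict_concentration(self, points: np.ndarray) -> np.ndarray:
        return self.c_net.evaluate(np.asarray(points, float))

    def predict_diffusivity(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return self.d_net.evaluate(pts[:, :2])

    def diffusivity_field(self, x_coords, y_coords):
        from .fields import ScalarField2D

        X, Y = np.meshgrid(np.asarray(x_coords, float), np.asarray(y_coords, float), indexing="ij")
        vals = self.d_net.evaluate(np.column_stack([X.ravel(), Y.ravel()]))
        return ScalarField2D(vals.reshape(X.shape), x_coords, y_coords)

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "dt": self.dt,
            "c_spec": vars(self.c_net.spec).copy(),
            "d_spec": vars(self.d_net.spec).copy(),
            "scaling": None if self.scaling is None else
                [self.scaling.length, self.scaling.time, self.scaling.concentration_max],
        }
        arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for tag, net in (("c", self.c_net), ("d", self.d_net)):
            arrays[f"{tag}_shift"] = net.input_shift
            arrays[f"{tag}_scale"] = net.input_scale
            for i, w in enumerate(net.weights):
                arrays[f"{tag}_W{i}"] = w
            for i, b in enumerate(net.biases):
                arrays[f"{tag}_b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "PinnModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            nets = {}
            for tag, n_in in (("c", 3), ("d", 2)):
                spec = NetworkSpec(**meta[f"{tag}_spec"])
                n_layers = spec.hidden_layers + 1
                weights = [data[f"{tag}_W{i}"] for i in range(n_layers)]
                biases = [data[f"{tag}_b{i}"] for i in range(n_layers)]
                nets[tag] = MLP(spec, n_in, weights, biases,
                                input_shift=data[f"{tag}_shift"],
                                input_scale=data[f"{tag}_scale"])
        scaling = None if meta["scaling"] is None else Scaling(*meta["scaling"])
        return cls(nets["c"], nets["d"], dt=meta["dt"], scaling=scaling)


@dataclass(frozen=True)
class LossBreakdown:
    """The two normalized terms of the training objective."""

    data_term: float
    consistency_term: float
    sigma_c: float

    @property
    def total(self) -> float:
        return self.data_term + self.consistency_term


# -- the diffusion operator applied to a pair of fields --------------------

def _residual_terms(c_field, d_field, points, c_params=None, d_params=None):
    X = np.asarray(points, dtype=np.float64)
    if c_params is not None or (isinstance(c_field, MLP) and isinstance(d_field, MLP)):
        # stacked fast path: gradients and Laplacian as one contraction
        c_out, cd1, cd2 = c_field._forward_stacked(
            X, dims=(0, 1), second=True, params=c_params
        )
        d_out, dd1, _ = d_field._forward_stacked(
            X[:, :2], dims=(0, 1), second=False, params=d_params
        )
        f = (cd1 * dd1).sum(axis=0) + d_out * cd2.sum(axis=0)
        return c_out, f
    c_out, cd = c_field.evaluate_with_derivatives(X, dims=(0, 1), second=True)
    d_out, dd = d_field.evaluate_with_derivatives(X[:, :2], dims=(0, 1), second=False)
    cx, cxx = cd[0]
    cy, cyy = cd[1]
    f = cx * dd[0][0] + cy * dd[1][0] + d_out * (cxx + cyy)
    return c_out, f


def residual_f(c_field, d_field, points: np.ndarray) -> np.ndarray:
    """Evaluate f = ∇·(D∇c) at a batch of (x, y, t) points.

    ``c_field``/``d_field`` may be :class:`MLP` instances or any object
    exposing ``evaluate_with_derivatives(X, dims, second)``; every
    derivative is exact (chain rule), never a finite difference.
    """
    _, f = _residual_terms(c_field, d_field, points)
    return np.asarray(f).ravel()


def physics_informed_concentration(model: PinnModel, points: np.ndarray) -> np.ndarray:
    """Backward-Euler physics prediction c_pi(t) = c̃(t+Δt) − Δt·f|_(t+Δt)."""
    X = np.asarray(points, dtype=np.float64)
    X_next = X.copy()
    X_next[:, 2] += model.dt
    c_next, f = _residual_terms(model.c_net, model.d_net, X_next)
    return (c_next - model.dt * f).ravel()


def _loss_graph(model: PinnModel, c_params, d_params,
                X_data: np.ndarray, c_obs: np.ndarray,
                X_eq: np.ndarray, sigma_c: float):
    """Differentiable loss; returns (total Tensor, data float, cons float)."""
    inv_sigma = 1.0 / sigma_c
    n_data = X_data.shape[0]
    c_obs = c_obs.astype(c_params[0][0].value.dtype)
    # one value-only pass covers both the data fit and c̃ at the physics points
    c_both, _, _ = model.c_net._forward_stacked(
        np.vstack([X_data, X_eq]), params=c_params
    )
    c_hat = c_both.rows(0, n_data)
    c_here = c_both.rows(n_data, n_data + X_eq.shape[0])
    r_data = (c_hat - c_obs.reshape(-1, 1)) * inv_sigma
    data_term = r_data.square().mean()

    X_next = X_eq.copy()
    X_next[:, 2] += model.dt
    c_next, f = _residual_terms(model.c_net, model.d_net, X_next,
                                c_params=c_params, d_params=d_params)
    r_cons = (c_next - model.dt * f - c_here) * inv_sigma
    cons_term = r_cons.square().mean()
    total = data_term + cons_term
    return total, float(data_term.value), float(cons_term.value)


def loss(model: PinnModel, data: PointCloud, eq_points, sigma_c: float | None = None
         ) -> LossBreakdown:
    """Evaluate the two-term objective on full point sets (no sampling).

    ``eq_points`` is a PointCloud or an (N_e, 3) array of (x, y, t)
    locations where the physics consistency is enforced.  ``sigma_c``
    defaults to the standard deviation of the observed concentrations.
    """
    if sigma_c is None:
        sigma_c = data.sigma_c
    # rounding can leave a std of ~1e-17 on constant data; treat as zero
    if sigma_c <= 1e-12 * max(1.0, float(np.abs(data.c).max())):
        raise DegenerateDataError(
            "observed concentration field is constant (sigma_c = 0): the loss "
            "normalization is undefined and the data carry no gradient information"
        )
    X_eq = eq_points.xyt() if hasattr(eq_points, "xyt") else np.asarray(eq_points, float)
    if X_eq.ndim != 2 or X_eq.shape[1] != 3 or X_eq.shape[0] < 1:
        raise ValueError("eq_points must provide an (N_e, 3) batch of (x, y, t)")
    c_hat = model.c_net.evaluate(data.xyt())
    data_term = float(np.mean(((c_hat - data.c) / sigma_c) ** 2))
    c_pi = physics_informed_concentration(model, X_eq)
    c_here = model.c_net.evaluate(X_eq)
    cons_term = float(np.mean(((c_pi - c_here) / sigma_c) ** 2))
    return LossBreakdown(data_term, cons_term, sigma_c)
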