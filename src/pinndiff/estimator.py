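"""Scikit-learn style front end for the inverse diffusivity solver.

``DiffusivityPINN`` is a regressor over spatio-temporal concentration
samples: ``fit(X, y)`` takes an (n, 3) array of dimensionless (x, y, t)
coordinates with observed concentrations ``y`` and jointly trains the
concentration surrogate and the diffusivity network; ``predict`` returns
the regressed concentration and ``predict_diffusivity`` the recovered
D(x, y).  It composes with sklearn tooling (clone, get_params, pipelines).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .fields import PointCloud, Scaling
from .pinn import MLP, NetworkSpec, PinnModel, softplus_inverse
from .train import TrainConfig, fit as _fit

__all__ = ["DiffusivityPINN"]


class DiffusivityPINN(RegressorMixin, BaseEstimator):
    """Joint regression of c̃(x, y, t) and D̃(x, y) from a point cloud.

    Parameters
    ----------
    hidden_layers, width
        Architecture shared by both dense tanh networks (the full-scale
        reference configuration is 8 layers of 128 neurons; smaller nets
        train much faster and suffice for smooth diffusivity landscapes).
    d_transform
        Output transform of the diffusivity network; "softplus" (default)
        keeps D̃ strictly positive, "identity" leaves it unconstrained.
    d_init
        Initial spatially-uniform diffusivity value the D network starts
        from (softplus bias seeding); order-of-magnitude of the expected D.
    dt
        Time step of the backward-Euler physics residual.  ``None`` infers
        the median frame spacing of the training times.
    iterations, batch_size, lr_initial, lr_decay_rate, lr_decay_steps
        Optimization budget and exponential-staircase learning schedule.
    seed
        Seeds network initialization and minibatch sampling.
    dtype
        Parameter/compute precision for training ("float32" default, the
        customary choice for this model class; use "float64" for strict
        reproducibility studies).
    scaling
        Optional physical :class:`Scaling`, stored with the model so
        recovered diffusivities can be reported in physical units.

    Attributes
    ----------
    model_ : PinnModel
        Trained networks plus residual Δt.
    loss_history_ : pandas.DataFrame
        Logged loss breakdown over training.
    sigma_c_ : float
        Standard deviation of the training concentrations (loss normalizer).
    """

    def __init__(
        self,
        hidden_layers: int = 8,
        width: int = 64,
        d_transform: str = "softplus",
        d_init: float = 0.2,
        dt: float | None = None,
        iterations: int = 10000,
        batch_size: int = 5000,
        lr_initial: float = 1e-3,
        lr_decay_rate: float = 0.8,
        lr_decay_steps: int | None = None,
        seed: int = 0,
        log_every: int = 250,
        scaling: Scaling | None = None,
        dtype: str = "float32",
        eq_times: str = "data",
    ):
        self.hidden_layers = hidden_layers
        self.width = width
        self.d_transform = d_transform
        self.d_init = d_init
        self.dt = dt
        self.iterations = iterations
        self.batch_size = batch_size
        self.lr_initial = lr_initial
        self.lr_decay_rate = lr_decay_rate
        self.lr_decay_steps = lr_decay_steps
        self.seed = seed
        self.log_every = log_every
        self.scaling = scaling
        self.dtype = dtype
        self.eq_times = eq_times

    # ------------------------------------------------------------------
    def _build_model(self, dt: float) -> PinnModel:
        ss = np.random.SeedSequence(self.seed)
        rng_c, rng_d = (np.random.default_rng(s) for s in ss.spawn(2))
        c_spec = NetworkSpec(self.hidden_layers, self.width, "tanh", "identity")
        d_spec = NetworkSpec(self.hidden_layers, self.width, "tanh", self.d_transform)
        dtype = np.dtype(self.dtype)
        c_net = MLP.create(c_spec, 3, rng_c, dtype=dtype)
        d_bias = (softplus_inverse(self.d_init) if self.d_transform == "softplus"
                  else self.d_init)
        d_net = MLP.create(d_spec, 2, rng_d, output_bias=d_bias, dtype=dtype)
        return PinnModel(c_net, d_net, dt=dt, scaling=self.scaling)

    def fit(self, X, y):
        """Train on an (n, 3) array of (x, y, t) with concentrations ``y``."""
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] != 3:
            raise ValueError(f"X must have 3 columns (x, y, t); got {X.shape[1]}")
        self.n_features_in_ = 3
        cloud = PointCloud(X[:, 0], X[:, 1], X[:, 2], y)
        if self.dt is None:
            spacings = np.diff(np.unique(cloud.t))
            if spacings.size == 0:
                raise ValueError(
                    "cannot infer dt from a single observation time; pass dt explicitly"
                )
            dt = float(np.median(spacings))
        else:
            dt = float(self.dt)
        model = self._build_model(dt)
        config = TrainConfig(
            iterations=self.iterations,
            batch_size=self.batch_size,
            lr_initial=self.lr_initial,
            lr_decay_rate=self.lr_decay_rate,
            lr_decay_steps=self.lr_decay_steps,
            seed=int(np.random.SeedSequence(self.seed).spawn(3)[2].generate_state(1)[0]
                     % (2**31)),
            log_every=self.log_every,
            eq_times=self.eq_times,
        )
        self.model_, self.loss_history_ = _fit(model, cloud, config)
        self.sigma_c_ = cloud.sigma_c
        self.c_net_ = self.model_.c_net
        self.d_net_ = self.model_.d_net
        self.dt_ = dt
        return self

    def predict(self, X):
        """Regressed concentration c̃ at (x, y, t) points."""
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != 3:
            raise ValueError("X must have 3 columns (x, y, t)")
        return self.model_.predict_concentration(X)

    def predict_diffusivity(self, XY):
        """Recovered D̃ at (x, y) points (extra columns are ignored)."""
        check_is_fitted(self, "model_")
        XY = check_array(XY)
        return self.model_.predict_diffusivity(XY)

    def diffusivity_field(self, x_coords, y_coords):
        """Recovered D̃ evaluated on a grid, as a ScalarField2D."""
        check_is_fitted(self, "model_")
        return self.model_.diffusivity_field(x_coords, y_coords)
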