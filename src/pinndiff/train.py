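"""Adam training loop for the inverse solver.

Each iteration draws a fresh minibatch from the observation cloud, places
physics-consistency points at the same spatial locations with uniformly
resampled times (shifted so t + Δt stays inside the observed window), and
takes one Adam step on the normalized two-term objective.  The learning
rate follows an exponential staircase.  All randomness flows from one
seeded generator, so a run is reproducible bit for bit on a platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import PointCloud
from .pinn import DegenerateDataError, PinnModel, _loss_graph

__all__ = ["TrainConfig", "TrainingDivergedError", "lr_schedule", "fit"]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite; the model keeps the last
    finite checkpoint."""

    def __init__(self, iteration: int):
        super().__init__(
            f"training loss became non-finite at iteration {iteration}; "
            "model restored to the last finite checkpoint"
        )
        self.iteration = iteration


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and sampling hyperparameters."""

    iterations: int = 10000
    batch_size: int = 5000
    lr_initial: float = 1e-3
    lr_decay_rate: float = 0.8
    lr_decay_steps: int | None = None  # default: iterations // 20
    seed: int = 0
    log_every: int = 250
    checkpoint_every: int = 1000
    eq_times: str = "data"

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")
        if not 0 < self.lr_decay_rate <= 1:
            raise ValueError("lr_decay_rate must lie in (0, 1]")
        if self.eq_times not in ("data", "uniform"):
            raise ValueError("eq_times must be 'data' or 'uniform'")

    @property
    def decay_steps(self) -> int:
        if self.lr_decay_steps is not None:
            return max(1, int(self.lr_decay_steps))
        return max(1, self.iterations // 20)


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Exponential staircase: lr_initial · rate^(step // decay_steps)."""
    return config.lr_initial * config.lr_decay_rate ** (step // config.decay_steps)


def fit(model: PinnModel, data: PointCloud, config: TrainConfig) -> tuple[PinnModel, pd.DataFrame]:
    """Train the paired networks on a point cloud; returns (model, history).

    The history records the loss breakdown and learning rate every
    ``log_every`` iterations (plus the final one).  The model is updated in
    place and also returned.
    """
    sigma_c = data.sigma_c
    if sigma_c <= 1e-12 * max(1.0, float(np.abs(data.c).max())):
        raise DegenerateDataError(
            "cannot train on a constant concentration field (sigma_c = 0)"
        )
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    if config.iterations == 0:
        return model, pd.DataFrame(history, columns=["iteration", "lr", "data_term",
                                                     "consistency_term", "total"])

    n = data.n
    batch = min(config.batch_size, n)
    t_lo = float(data.t.min())
    t_hi = max(t_lo, float(data.t.max()) - model.dt)

    params = (model.c_net.weights + model.c_net.biases
              + model.d_net.weights + model.d_net.biases)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    checkpoint = [p.copy() for p in params]

    for it in range(config.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        X_data = np.column_stack([data.x[idx], data.y[idx], data.t[idx]])
        c_obs = data.c[idx]
        # physics points share the batch's spatial locations
        if config.eq_times == "data":
            # enforce at the observation times themselves, so both ends of
            # the backward-Euler pair sit on data-anchored frames; points in
            # the last frame shift down one step to stay inside the window
            t_eq = data.t[idx].copy()
            over = t_eq > t_hi
            t_eq[over] = np.maximum(t_lo, t_eq[over] - model.dt)
        else:
            t_eq = rng.uniform(t_lo, t_hi, size=batch)
        X_eq = np.column_stack([data.x[idx], data.y[idx], t_eq])

        c_params = model.c_net.wrap_parameters()
        d_params = model.d_net.wrap_parameters()
        total, data_term, cons_term = _loss_graph(
            model, c_params, d_params, X_data, c_obs, X_eq, sigma_c
        )
        if not np.isfinite(total.value):
            for p, cp in zip(params, checkpoint):
                p[...] = cp
            raise TrainingDivergedError(it)
        total.backward()
        grads = [t.grad if t.grad is not None else np.zeros_like(t.value)
                 for pair in (c_params, d_params) for group in pair for t in group]

        lr = lr_schedule(it, config)
        b1c = 1.0 - beta1 ** (it + 1)
        b2c = 1.0 - beta2 ** (it + 1)
        for p, g, mi, vi in zip(params, grads, m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g * g
            p -= lr * (mi / b1c) / (np.sqrt(vi / b2c) + eps)

        if it % config.log_every == 0 or it == config.iterations - 1:
            history.append({
                "iteration": it,
                "lr": lr,
                "data_term": data_term,
                "consistency_term": cons_term,
                "total": data_term + cons_term,
            })
        if it % config.checkpoint_every == 0:
            for cp, p in zip(checkpoint, params):
                cp[...] = p

    return model, pd.DataFrame(history)
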