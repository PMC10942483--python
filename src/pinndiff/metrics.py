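"""Error metrics, cross-sections, sparsity sweep and map rendering.

The headline metric is the mean-deviation-normalized two-norm error

    ℒ(a, a_pred) = ‖a − a_pred‖₂ / ‖a − ā‖₂,

with ā the mean of the reference; adding a constant to both fields or
scaling both by a constant leaves it unchanged, which makes it meaningful
for diffusivities known only up to the nondimensionalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import clone

from .fields import BenchmarkCase, ScalarField2D, benchmark_diffusivity
from .forward import default_benchmark_problem, simulate
from .sampling import sample_pointcloud
from .train import TrainingDivergedError

__all__ = [
    "ConstantFieldError",
    "relative_error",
    "cross_section",
    "sparsity_sweep",
    "render_comparison",
]


class ConstantFieldError(ValueError):
    """Reference field is constant: the error normalizer is zero."""


def _values(a) -> np.ndarray:
    return a.values if isinstance(a, ScalarField2D) else np.asarray(a, dtype=np.float64)


def relative_error(a, a_pred) -> float:
    """Two-norm error of ``a_pred`` against ``a``, normalized by ‖a − ā‖₂.

    Accepts ScalarField2D or plain arrays of matching shape; 0 exactly when
    the fields agree, 1 when the prediction is the constant mean of ``a``.
    """
    av = _values(a)
    pv = _values(a_pred)
    if av.shape != pv.shape:
        raise ValueError(f"shape mismatch: {av.shape} vs {pv.shape}")
    denom = np.linalg.norm(av - av.mean())
    if denom == 0:
        raise ConstantFieldError(
            "reference field is constant; the normalized error is undefined"
        )
    return float(np.linalg.norm(av - pv) / denom)


def cross_section(field: ScalarField2D, axis: str = "x", position: float = 0.5
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Profile along one axis at the grid line nearest to ``position``.

    ``axis="x"`` returns values versus x at fixed y ≈ position (the
    horizontal mid-section when position = 0.5).  Pure extraction, no
    interpolation.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    fixed = field.y_coords if axis == "x" else field.x_coords
    h = fixed[1] - fixed[0] if fixed.size > 1 else 1.0
    if not (fixed[0] - 0.5 * h <= position <= fixed[-1] + 0.5 * h):
        raise ValueError(
            f"position {position} lies outside the grid extent "
            f"[{fixed[0] - 0.5 * h:.4g}, {fixed[-1] + 0.5 * h:.4g}]"
        )
    k = int(np.argmin(np.abs(fixed - position)))
    if axis == "x":
        return field.x_coords.copy(), field.values[:, k].copy()
    return field.y_coords.copy(), field.values[k, :].copy()


def sparsity_sweep(
    case_id: BenchmarkCase | str,
    sample_counts,
    seeds,
    estimator,
    nx: int = 128,
    nt: int = 50,
    series=None,
    d_true: ScalarField2D | None = None,
) -> pd.DataFrame:
    """Data-sparsity study: error in D̃ as spatial observations shrink.

    For each (count, seed) pair the simulated series is subsampled to
    ``count`` spatial locations (all frames kept), a fresh clone of
    ``estimator`` is trained on the resulting cloud, and the normalized
    error of D̃ against the true field is recorded.  Diverged runs are kept
    as rows with ``diverged = True`` and NaN error.
    """
    if series is None:
        series = simulate(default_benchmark_problem(case_id, nx=nx, nt=nt))
    if d_true is None:
        d_true = benchmark_diffusivity(case_id, series.x_coords, series.y_coords)
    rows = []
    for count in sample_counts:
        for seed in seeds:
            cloud = sample_pointcloud(series, count, seed=seed)
            est = clone(estimator)
            est.set_params(seed=seed)
            diverged = False
            err = np.nan
            try:
                est.fit(cloud.xyt(), cloud.c)
                d_pred = est.diffusivity_field(series.x_coords, series.y_coords)
                err = relative_error(d_true, d_pred)
            except TrainingDivergedError:
                diverged = True
            rows.append({
                "case": str(getattr(case_id, "value", case_id)),
                "n_spatial": int(count),
                "seed": int(seed),
                "n_records": cloud.n,
                "error_d": err,
                "diverged": diverged,
            })
    return pd.DataFrame(rows)


def render_comparison(true_field: ScalarField2D, pred_field: ScalarField2D, path,
                      titles=("true D", "recovered D")) -> None:
    """Side-by-side maps with one shared colorbar, written as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmin = min(true_field.values.min(), pred_field.values.min())
    vmax = max(true_field.values.max(), pred_field.values.max())
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), constrained_layout=True)
    for ax, f, title in zip(axes, (true_field, pred_field), titles):
        im = ax.imshow(
            f.values.T,
            origin="lower",
            extent=(f.x_coords[0], f.x_coords[-1], f.y_coords[0], f.y_coords[-1]),
            vmin=vmin,
            vmax=vmax,
            cmap="viridis",
        )
        ax.set_title(title)
        ax.set_xlabel("x")
        ax.set_ylabel("y")
    fig.colorbar(im, ax=axes, shrink=0.9)
    fig.savefig(path, dpi=120)
    plt.close(fig)
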