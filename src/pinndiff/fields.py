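"""Domain containers, benchmark diffusivity fields and nondimensionalization.

All analysis runs on the dimensionless unit square: space scaled by a length
``L``, time by ``T``, concentration by its global maximum ``c_max`` and
diffusivity by ``T / L**2``.  Grids are cell-centered, matching the
finite-volume forward solver, so an ``n``-cell axis has coordinates
``(i + 0.5) / n``.

Array convention: ``values[i, j]`` is the sample at ``(x_coords[i],
y_coords[j])`` — axis 0 is x, axis 1 is y.  Image I/O transposes to the
row-major pixel convention at the boundary of the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Scaling",
    "ScalarField2D",
    "ConcentrationSeries",
    "PointCloud",
    "BenchmarkCase",
    "cell_centered_coords",
    "benchmark_diffusivity",
    "nondimensionalize",
    "nondimensionalize_diffusivity",
    "redimensionalize_diffusivity",
]


@dataclass(frozen=True)
class Scaling:
    """Physical-to-dimensionless scales: length L, time T, intensity c_max."""

    length: float
    time: float
    concentration_max: float = 1.0

    def __post_init__(self):
        for name in ("length", "time", "concentration_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Scaling.{name} must be strictly positive, got {v!r}")

    @property
    def diffusivity_factor(self) -> float:
        """Multiply a physical diffusivity by this to make it dimensionless."""
        return self.time / self.length**2


@dataclass
class ScalarField2D:
    """A scalar sampled on a rectangular grid with dimensionless coordinates."""

    values: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.x_coords = np.asarray(self.x_coords, dtype=np.float64)
        self.y_coords = np.asarray(self.y_coords, dtype=np.float64)
        if self.values.shape != (self.x_coords.size, self.y_coords.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match coordinate "
                f"lengths ({self.x_coords.size}, {self.y_coords.size})"
            )
        for name, c in (("x_coords", self.x_coords), ("y_coords", self.y_coords)):
            if c.size > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_coords, self.y_coords, indexing="ij")

    def copy(self) -> "ScalarField2D":
        return ScalarField2D(self.values.copy(), self.x_coords.copy(), self.y_coords.copy())

    # -- I/O -------------------------------------------------------------
    def to_hdf5(self, path, dataset: str = "field") -> None:
        with h5py.File(path, "a") as f:
            g = f.require_group(dataset)
            for k in ("values", "x_coords", "y_coords"):
                if k in g:
                    del g[k]
            g["values"] = self.values
            g["x_coords"] = self.x_coords
            g["y_coords"] = self.y_coords

    @classmethod
    def from_hdf5(cls, path, dataset: str = "field") -> "ScalarField2D":
        with h5py.File(path, "r") as f:
            g = f[dataset]
            return cls(g["values"][...], g["x_coords"][...], g["y_coords"][...])

    def to_csv(self, path) -> None:
        """Long-format CSV (x, y, value); intended for small grids."""
        X, Y = self.meshgrid()
        pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "value": self.values.ravel()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScalarField2D":
        df = pd.read_csv(path)
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        vals = df["value"].to_numpy().reshape(x.size, y.size)
        return cls(vals, x, y)


@dataclass
class ConcentrationSeries:
    """Time-ordered concentration frames sharing one spatial grid."""

    frames: np.ndarray  # (nt, nx, ny)
    times: np.ndarray  # (nt,)
    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.x_coords = np.asarray(self.x_coords, dtype=np.float64)
        self.y_coords = np.asarray(self.y_coords, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (nt, nx, ny) array")
        nt, nx, ny = self.frames.shape
        if nt != self.times.size:
            raise ValueError("number of frames must match number of times")
        if (nx, ny) != (self.x_coords.size, self.y_coords.size):
            raise ValueError("frame shape does not match grid coordinates")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("concentration values must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, k: int) -> ScalarField2D:
        return ScalarField2D(self.frames[k], self.x_coords, self.y_coords)

    def to_hdf5(self, path, dataset: str = "series") -> None:
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            g = f.create_group(dataset)
            g["frames"] = self.frames
            g["times"] = self.times
            g["x_coords"] = self.x_coords
            g["y_coords"] = self.y_coords

    @classmethod
    def from_hdf5(cls, path, dataset: str = "series") -> "ConcentrationSeries":
        with h5py.File(path, "r") as f:
            g = f[dataset]
            return cls(g["frames"][...], g["times"][...], g["x_coords"][...], g["y_coords"][...])


@dataclass
class PointCloud:
    """Unordered dimensionless (x, y, t, c) samples — the solver's input."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        arrs = []
        for name in ("x", "y", "t", "c"):
            a = np.asarray(getattr(self, name), dtype=np.float64).ravel()
            arrs.append(a)
            object.__setattr__(self, name, a)
        n = arrs[0].size
        if n < 1:
            raise ValueError("a point cloud needs at least one record")
        if any(a.size != n for a in arrs):
            raise ValueError("x, y, t, c must have equal lengths")
        if not all(np.all(np.isfinite(a)) for a in arrs):
            raise ValueError("point-cloud records must be finite")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def sigma_c(self) -> float:
        """Standard deviation of the observed concentrations (loss normalizer)."""
        return float(np.std(self.c))

    def xyt(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.t])

    def subset(self, idx: np.ndarray) -> "PointCloud":
        return PointCloud(self.x[idx], self.y[idx], self.t[idx], self.c[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "t": self.t, "c": self.c})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PointCloud":
        df = pd.read_csv(path)
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["t"].to_numpy(), df["c"].to_numpy())

    def to_hdf5(self, path, dataset: str = "points") -> None:
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            g = f.create_group(dataset)
            for k in ("x", "y", "t", "c"):
                g[k] = getattr(self, k)

    @classmethod
    def from_hdf5(cls, path, dataset: str = "points") -> "PointCloud":
        with h5py.File(path, "r") as f:
            g = f[dataset]
            return cls(g["x"][...], g["y"][...], g["t"][...], g["c"][...])


class BenchmarkCase(enum.Enum):
    """The four synthetic diffusivity landscapes used for validation."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def cell_centered_coords(n: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Centers of ``n`` equal cells tiling [lo, hi]."""
    if n < 1:
        raise ValueError("need at least one cell")
    h = (hi - lo) / n
    return lo + (np.arange(n) + 0.5) * h


def _case_formula(case: BenchmarkCase, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if case is BenchmarkCase.I:
        return 0.05 + 0.1 * (X * (1 - X) + Y * (1 - Y))
    if case is BenchmarkCase.II:
        return 0.25 + 0.1 * (np.sin(2 * np.pi * X) + np.sin(2 * np.pi * Y))
    if case is BenchmarkCase.III:
        return 0.25 + 0.1 * (np.sin(4 * np.pi * X) + np.sin(4 * np.pi * Y))
    # IV: smoothed four-quadrant step; the two common spellings
    # 0.3 + 0.15 tanh(20(x-0.5)) + 0.1 tanh(20(y-0.35)) and
    # 0.3 + 0.15 tanh(20x-10)    + 0.1 tanh(20y-7) are identical.
    return 0.3 + 0.15 * np.tanh(20.0 * X - 10.0) + 0.1 * np.tanh(20.0 * Y - 7.0)


def benchmark_diffusivity(
    case_id: BenchmarkCase | str,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
) -> ScalarField2D:
    """Evaluate one of the four named analytic diffusivity fields on a grid.

    Parameters
    ----------
    case_id
        ``BenchmarkCase`` member or its name: "I" (paraboloid),
        "II"/"III" (sinusoidal at two frequencies), "IV" (tanh-smoothed
        quadrant steps mimicking tissue heterogeneity).
    x_coords, y_coords
        Dimensionless grid coordinates inside [0, 1].
    """
    try:
        case = BenchmarkCase(case_id) if not isinstance(case_id, BenchmarkCase) else case_id
    except ValueError:
        raise KeyError(f"unknown benchmark case {case_id!r}; expected one of I, II, III, IV")
    x = np.asarray(x_coords, dtype=np.float64)
    y = np.asarray(y_coords, dtype=np.float64)
    if x.size and (x.min() < -1e-12 or x.max() > 1 + 1e-12):
        raise ValueError("x_coords must lie in [0, 1]")
    if y.size and (y.min() < -1e-12 or y.max() > 1 + 1e-12):
        raise ValueError("y_coords must lie in [0, 1]")
    X, Y = np.meshgrid(x, y, indexing="ij")
    return ScalarField2D(_case_formula(case, X, Y), x, y)


def nondimensionalize(
    frames: np.ndarray,
    x_phys: np.ndarray,
    y_phys: np.ndarray,
    t_phys: np.ndarray,
    scaling: Scaling,
) -> ConcentrationSeries:
    """Scale a physical concentration movie onto the unit square/interval.

    Coordinates divide by ``L``, times by ``T`` and intensities by
    ``c_max``; with ``c_max`` the global maximum the returned values lie in
    [0, 1].
    """
    return ConcentrationSeries(
        np.asarray(frames, dtype=np.float64) / scaling.concentration_max,
        np.asarray(t_phys, dtype=np.float64) / scaling.time,
        np.asarray(x_phys, dtype=np.float64) / scaling.length,
        np.asarray(y_phys, dtype=np.float64) / scaling.length,
    )


def nondimensionalize_diffusivity(d_physical, scaling: Scaling):
    """Physical diffusivity (length²/time) → dimensionless, via D·T/L²."""
    f = scaling.diffusivity_factor
    if isinstance(d_physical, ScalarField2D):
        return ScalarField2D(
            d_physical.values * f,
            d_physical.x_coords / scaling.length,
            d_physical.y_coords / scaling.length,
        )
    return np.asarray(d_physical, dtype=np.float64) * f


def redimensionalize_diffusivity(d_dimless, scaling: Scaling):
    """Inverse of :func:`nondimensionalize_diffusivity`: D·L²/T."""
    f = scaling.diffusivity_factor
    if isinstance(d_dimless, ScalarField2D):
        return ScalarField2D(
            d_dimless.values / f,
            d_dimless.x_coords * scaling.length,
            d_dimless.y_coords * scaling.length,
        )
    return np.asarray(d_dimless, dtype=np.float64) / f
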