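"""Point-cloud construction, image-stack ingestion and synthetic movies.

The inverse solver consumes unordered (x, y, t, c) records.  This module
builds them either by subsampling a simulated :class:`ConcentrationSeries`
(the sparsity protocol keeps a random subset of *spatial* locations across
all frames) or by reading a time-lapse grayscale image stack under the
minimal assumption that pixel intensity is proportional to concentration.

``generate_movie`` fabricates experiment-like data end to end: a two-region
piecewise diffusivity, dye influx from chosen edges, additive Gaussian
intensity noise and 16-bit quantization — the in-silico stand-in for the
cuvette / hydrogel recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fields import (
    ConcentrationSeries,
    PointCloud,
    ScalarField2D,
    Scaling,
    cell_centered_coords,
)
from .forward import BoundaryCondition, ForwardProblem, simulate

__all__ = [
    "MovieSpec",
    "IngestError",
    "sample_pointcloud",
    "series_to_pointcloud",
    "series_to_image_stack",
    "image_stack_to_frames",
    "write_tiff_stack",
    "read_image",
    "ingest_image_stack",
    "generate_movie",
]

_QUANT = 65535  # 16-bit dynamic range


class IngestError(ValueError):
    """Raised for unreadable, inconsistent or empty image-stack input."""


def sample_pointcloud(series: ConcentrationSeries, n_spatial: int, seed: int) -> PointCloud:
    """Keep ``n_spatial`` random grid locations, all frames, no interpolation.

    Locations are drawn uniformly without replacement, so the cloud holds
    exactly ``n_spatial * n_frames`` records and every stored c equals the
    grid value — pure selection.  Reproducible for a fixed seed.
    """
    nx = series.x_coords.size
    ny = series.y_coords.size
    total = nx * ny
    if not 1 <= n_spatial <= total:
        raise ValueError(f"n_spatial must be in [1, {total}], got {n_spatial}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_spatial, replace=False)
    ix, iy = np.unravel_index(np.sort(flat), (nx, ny))
    nt = series.n_frames
    x = np.tile(series.x_coords[ix], nt)
    y = np.tile(series.y_coords[iy], nt)
    t = np.repeat(series.times, n_spatial)
    c = series.frames[:, ix, iy].ravel()
    return PointCloud(x, y, t, c)


def series_to_pointcloud(series: ConcentrationSeries) -> PointCloud:
    """Every grid sample of every frame as one cloud (the dense baseline)."""
    return sample_pointcloud(series, series.x_coords.size * series.y_coords.size, seed=0)


# -- image conventions ----------------------------------------------------
# A frame's pixel (row r, col col) maps to x = x_coords[col] and
# y = y_coords[H - 1 - r]: row 0 is the top of the picture, largest y.

def series_to_image_stack(series: ConcentrationSeries) -> np.ndarray:
    """Render frames to a (nt, H, W) uint16 stack, clipping to [0, 1]."""
    imgs = np.clip(series.frames, 0.0, 1.0)
    imgs = imgs.transpose(0, 2, 1)[:, ::-1, :]  # (nt, x, y) -> (nt, row, col)
    return np.round(imgs * _QUANT).astype(np.uint16)


def image_stack_to_frames(stack: np.ndarray) -> np.ndarray:
    """Inverse orientation mapping: (nt, row, col) -> (nt, x, y), float64."""
    return np.asarray(stack, dtype=np.float64)[:, ::-1, :].transpose(0, 2, 1)


def write_tiff_stack(stack: np.ndarray, directory, prefix: str = "frame") -> list[Path]:
    """Write one 16-bit grayscale TIFF per frame; returns the paths."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = directory / f"{prefix}_{i:04d}.tif"
        tifffile.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def read_image(path) -> np.ndarray:
    """Read a single grayscale frame (TIFF via tifffile, else imageio)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
    except Exception as exc:
        raise IngestError(f"could not read image {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:  # collapse color channels if present
        img = img.mean(axis=-1)
    if img.ndim != 2:
        raise IngestError(f"{path} is not a 2-D grayscale image (shape {img.shape})")
    return img.astype(np.float64)


def ingest_image_stack(
    paths,
    scaling: Scaling,
    roi: tuple[int, int, int, int] | None = None,
    frame_interval: float = 1.0,
    pixel_size: float | None = None,
) -> ConcentrationSeries:
    """Turn a time-lapse image stack into a dimensionless concentration series.

    Intensity is assumed proportional to concentration and divided by the
    stack-wide maximum (per-frame scaling would corrupt the temporal signal
    the physics residual depends on).  Pixel indices map to dimensionless
    coordinates through ``pixel_size / L`` (default: the ROI width spans one
    length scale) and frame indices to times through ``frame_interval / T``.

    Parameters
    ----------
    paths
        Ordered image files, or a (nt, H, W) array already in memory.
    roi
        ``(row0, row1, col0, col1)`` crop in pixel (slice) coordinates.
    frame_interval
        Physical time between consecutive frames.
    """
    if isinstance(paths, np.ndarray):
        frames_img = np.asarray(paths, dtype=np.float64)
        if frames_img.ndim != 3:
            raise IngestError("in-memory stack must be (nt, H, W)")
        frames_img = [f for f in frames_img]
    else:
        paths = list(paths)
        if not paths:
            raise IngestError("no frames supplied")
        frames_img = [read_image(p) for p in paths]
    shapes = {f.shape for f in frames_img}
    if len(shapes) != 1:
        raise IngestError(f"frames have mixed sizes: {sorted(shapes)}")
    stack = np.stack(frames_img)
    if roi is not None:
        r0, r1, c0, c1 = roi
        stack = stack[:, r0:r1, c0:c1]
        if stack.shape[1] == 0 or stack.shape[2] == 0:
            raise IngestError(f"roi {roi} selects an empty region")
    nt, H, W = stack.shape
    peak = stack.max()
    if peak <= 0:
        raise IngestError("image stack is identically zero; cannot normalize")
    frames = image_stack_to_frames(stack) / peak
    if pixel_size is None:
        pixel_size = scaling.length / W
    px = pixel_size / scaling.length  # dimensionless pixel pitch
    x = (np.arange(W) + 0.5) * px
    y = (np.arange(H) + 0.5) * px
    t = np.arange(nt) * (frame_interval / scaling.time)
    return ConcentrationSeries(frames, t, x, y)


@dataclass
class MovieSpec:
    """Recipe for a synthetic two-region 'experimental' movie.

    ``two_layer_horizontal`` mimics two stacked liquids (``d_inner`` fills
    the upper layer); ``disc_in_square`` mimics a gel inclusion (``d_inner``
    inside a centered disc).  ``source`` holds per-edge boundary
    concentrations driving dye influx; absent edges are no-flux walls.
    """

    layout: str = "two_layer_horizontal"
    d_inner: float = 0.405
    d_outer: float = 0.236
    source: dict = field(default_factory=lambda: {"top": 1.0})
    noise_sd: float = 0.01
    frames: int = 50
    size: int = 64
    seed: int = 0
    t_end: float = 1.0
    disc_radius: float = 0.2
    layer_split: float = 0.5

    def __post_init__(self):
        if self.layout not in ("two_layer_horizontal", "disc_in_square"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.d_inner <= 0 or self.d_outer <= 0:
            raise ValueError("diffusivities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.frames < 2 or self.size < 2:
            raise ValueError("frames and size must be at least 2")


def _region_mask(spec: MovieSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if spec.layout == "two_layer_horizontal":
        return Y >= spec.layer_split
    return (X - 0.5) ** 2 + (Y - 0.5) ** 2 <= spec.disc_radius**2


def true_diffusivity_map(spec: MovieSpec) -> ScalarField2D:
    """The exact piecewise-constant D field the movie was generated with."""
    x = cell_centered_coords(spec.size)
    y = cell_centered_coords(spec.size)
    X, Y = np.meshgrid(x, y, indexing="ij")
    inner = _region_mask(spec, X, Y)
    vals = np.where(inner, spec.d_inner, spec.d_outer)
    return ScalarField2D(vals, x, y)


def generate_movie(spec: MovieSpec) -> tuple[np.ndarray, ScalarField2D]:
    """Simulate a two-region experiment and render it as a noisy uint16 stack.

    Returns the (nt, H, W) image stack and the ground-truth diffusivity map.
    Deterministic for a fixed ``spec.seed``.
    """
    d_true = true_diffusivity_map(spec)
    x, y = d_true.x_coords, d_true.y_coords
    ic = ScalarField2D(np.zeros((spec.size, spec.size)), x, y)
    bc = BoundaryCondition.fixed_value(**{e: v for e, v in spec.source.items()})
    problem = ForwardProblem(d_true, ic, bc, nt=spec.frames, t_end=spec.t_end)
    series = simulate(problem)
    rng = np.random.default_rng(spec.seed)
    noisy = series.frames + rng.normal(0.0, spec.noise_sd, size=series.frames.shape)
    noisy_series = ConcentrationSeries(np.clip(noisy, 0.0, 1.0), series.times, x, y)
    return series_to_image_stack(noisy_series), d_true
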