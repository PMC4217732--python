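"""Land-cover proportions around points and moving-window proportion surfaces.

Window semantics, shared by point buffers and per-pixel surfaces: a cell
belongs to the window of a focal cell iff its centre lies within Euclidean
distance ``radius`` of the focal cell centre (inclusive).  Near raster edges
the denominator is the number of in-bounds window cells only.

The moving window is evaluated by FFT convolution of class-indicator rasters
with a disc kernel; because both operands are 0/1, the convolution output is
an integer count and is rounded back to the exact integer, so the fast path
agrees with a brute-force per-pixel loop exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .grids import PREDICTOR_CLASSES, GridError, Landscape, code_of
from .synthgen import SitePoint


class WindowError(ValueError):
    pass


def disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean disc: offsets whose centre distance is <= radius (inclusive)."""
    if radius < cell_size:
        raise WindowError(f"radius {radius} m is smaller than one cell ({cell_size} m)")
    r_cells = int(np.floor(radius / cell_size + 1e-9))
    offs = np.arange(-r_cells, r_cells + 1)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    dist = cell_size * np.hypot(dr, dc)
    return dist <= radius + 1e-9


def group_classes(cover: np.ndarray, mapping: dict[int, int],
                  other_code: int = 8) -> np.ndarray:
    """Relabel a categorical raster through a code->code lookup.

    Codes absent from ``mapping`` collapse into ``other_code``.
    """
    cover = np.asarray(cover)
    out = np.full(cover.shape, other_code, dtype=np.int16)
    for src, dst in mapping.items():
        out[cover == src] = dst
    return out


def _window_counts(indicator: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    counts = fftconvolve(indicator.astype(float), kernel.astype(float), mode="same")
    return np.rint(counts)


def proportion_surface(cover: np.ndarray, group: int | str, radius: float,
                       cell_size: float,
                       class_codes: dict[int, str] | None = None) -> np.ndarray:
    """Per-pixel fraction of ``group`` within the circular window."""
    cover = np.asarray(cover)
    code = group if isinstance(group, (int, np.integer)) else code_of(group, class_codes)
    kernel = disc_kernel(radius, cell_size)
    hits = _window_counts(cover == code, kernel)
    denom = _window_counts(np.ones_like(cover, dtype=bool), kernel)
    return hits / denom


@dataclass
class ProportionStack:
    """Aligned (G, F, W, A) proportion rasters at a stated radius."""

    grassland: np.ndarray
    forest: np.ndarray
    wind: np.ndarray
    flowering_annual: np.ndarray
    radius: float
    cell_size: float

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands().values()}
        if len(shapes) != 1:
            raise GridError(f"proportion bands disagree on shape: {shapes}")
        total = sum(self.bands().values())
        # tolerance admits single-precision on-disk round trips
        if np.nanmax(total) > 1.0 + 1e-6:
            raise GridError("per-pixel predictor proportions exceed 1")

    def bands(self) -> dict[str, np.ndarray]:
        return {
            "grassland": self.grassland,
            "forest": self.forest,
            "wind": self.wind,
            "flowering_annual": self.flowering_annual,
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.grassland.shape


def proportion_stack(landscape: Landscape, radius: float) -> ProportionStack:
    """Moving-window proportion surfaces for the four predictor classes."""
    kernel = disc_kernel(radius, landscape.cell_size)
    denom = _window_counts(np.ones(landscape.shape, dtype=bool), kernel)
    bands = {}
    for name in PREDICTOR_CLASSES:
        code = landscape.code_of(name)
        bands[name] = _window_counts(landscape.cover == code, kernel) / denom
    return ProportionStack(radius=radius, cell_size=landscape.cell_size, **bands)


def class_proportions_at_points(landscape: Landscape, points: list[SitePoint],
                                radius: float) -> pd.DataFrame:
    """Predictor-class proportions in the circular buffer around each site.

    The buffer must be fully in-bounds (site placement guarantees this);
    an out-of-bounds buffer raises an error naming the site.
    """
    kernel = disc_kernel(radius, landscape.cell_size)
    r = kernel.shape[0] // 2
    n_rows, n_cols = landscape.shape
    codes = {name: landscape.code_of(name) for name in PREDICTOR_CLASSES}
    records = []
    for pt in points:
        if not (r <= pt.row < n_rows - r and r <= pt.col < n_cols - r):
            raise WindowError(
                f"buffer of radius {radius} m around site {pt.site_id} extends out of bounds")
        window = landscape.cover[pt.row - r:pt.row + r + 1, pt.col - r:pt.col + r + 1]
        in_disc = window[kernel]
        total = in_disc.size
        records.append(
            {"site_id": pt.site_id}
            | {name: float(np.count_nonzero(in_disc == code)) / total
               for name, code in codes.items()}
        )
    return pd.DataFrame.from_records(records).set_index("site_id")
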