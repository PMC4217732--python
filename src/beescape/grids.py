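"""Raster containers and plain-text grid I/O.

Rasters live on a regular square grid, row/column indexed, 0-based, with the
origin at the top-left cell centre; ``x = col * cell_size`` and
``y = row * cell_size`` in metres.  On disk a raster is an ESRI ASCII grid
(`.asc`): a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by whitespace-separated rows, top row first.  A
categorical cover raster travels with a JSON sidecar mapping integer codes to
class names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical nine grouped land-cover classes and their integer codes.
CLASS_CODES: dict[int, str] = {
    0: "wind",
    1: "flowering_annual",
    2: "grassland",
    3: "forest",
    4: "perennial_flowering",
    5: "wetland",
    6: "suburb",
    7: "city",
    8: "other",
}

#: The four classes used as model predictors, in (G, F, W, A) reporting order.
PREDICTOR_CLASSES: tuple[str, ...] = ("grassland", "forest", "wind", "flowering_annual")

NODATA = -9999


class GridError(ValueError):
    """Raised for malformed rasters or mismatched grids."""


def code_of(class_name: str, class_codes: dict[int, str] | None = None) -> int:
    codes = class_codes or CLASS_CODES
    for code, name in codes.items():
        if name == class_name:
            return code
    raise GridError(f"unknown land-cover class {class_name!r}")


@dataclass
class Landscape:
    """A categorical land-cover raster plus a marginal-land mask on one grid.

    Parameters
    ----------
    cover : integer array of class codes, shape (n_rows, n_cols)
    marginal : boolean array, same shape; True where soils are marginal
        (emulating land-capability classes 3-8, i.e. severe limitations for
        row crops)
    cell_size : cell edge length in metres
    class_codes : mapping of integer code to class name
    """

    cover: np.ndarray
    marginal: np.ndarray
    cell_size: float
    class_codes: dict[int, str] = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover)
        self.marginal = np.asarray(self.marginal, dtype=bool)
        if self.cover.ndim != 2:
            raise GridError("cover must be a 2-D raster")
        if self.cover.shape != self.marginal.shape:
            raise GridError(
                f"cover shape {self.cover.shape} != marginal shape {self.marginal.shape}"
            )
        if self.cell_size <= 0:
            raise GridError("cell_size must be positive")
        declared = set(self.class_codes)
        present = set(np.unique(self.cover).tolist())
        if not present <= declared:
            raise GridError(f"undeclared cover codes {sorted(present - declared)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cover.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def code_of(self, class_name: str) -> int:
        return code_of(class_name, self.class_codes)

    def class_fractions(self) -> dict[str, float]:
        """Realized fraction of each declared class over the whole raster."""
        n = self.cover.size
        return {
            name: float(np.count_nonzero(self.cover == code)) / n
            for code, name in sorted(self.class_codes.items())
        }


def write_ascii_grid(path: str | Path, values: np.ndarray, cell_size: float,
                     nodata: float = NODATA, fmt: str = "%.8g") -> None:
    values = np.asarray(values)
    if values.ndim != 2:
        raise GridError("only 2-D rasters can be written")
    n_rows, n_cols = values.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {-cell_size / 2.0:.6f}\n"
        f"yllcorner {-(n_rows - 0.5) * cell_size:.6f}\n"
        f"cellsize {cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    out = np.where(np.isfinite(values.astype(float)), values, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read an ESRI ASCII grid; returns (values, cell_size, nodata)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridError(f"grid body shape {values.shape} disagrees with header in {path}")
    return values, header["cellsize"], header.get("nodata_value", NODATA)


def write_landscape(landscape: Landscape, directory: str | Path,
                    stem: str = "landscape") -> dict[str, Path]:
    """Write cover and marginal rasters plus the class-code sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cover": directory / f"{stem}_cover.asc",
        "marginal": directory / f"{stem}_marginal.asc",
        "classes": directory / f"{stem}_classes.json",
    }
    write_ascii_grid(paths["cover"], landscape.cover.astype(np.int16), landscape.cell_size, fmt="%d")
    write_ascii_grid(paths["marginal"], landscape.marginal.astype(np.uint8), landscape.cell_size, fmt="%d")
    with open(paths["classes"], "w") as fh:
        json.dump({str(k): v for k, v in landscape.class_codes.items()}, fh, indent=2)
    return paths


def read_landscape(directory: str | Path, stem: str = "landscape") -> Landscape:
    directory = Path(directory)
    cover, cell_size, _ = read_ascii_grid(directory / f"{stem}_cover.asc")
    marginal, cell_size_m, _ = read_ascii_grid(directory / f"{stem}_marginal.asc")
    if abs(cell_size - cell_size_m) > 1e-9:
        raise GridError("cover and marginal rasters disagree on cell size")
    with open(directory / f"{stem}_classes.json") as fh:
        class_codes = {int(k): v for k, v in json.load(fh).items()}
    return Landscape(cover.astype(np.int16), marginal.astype(bool), cell_size, class_codes)
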