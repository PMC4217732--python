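"""Per-pixel metric prediction, change surfaces, and summaries.

A fitted averaged model is applied to a moving-window proportion stack to
give a per-pixel bee-metric surface,

    Y = b + g*G + f*F + w*W + a*A,

under the current landscape and under each conversion scenario.  Abundance
and diversity changes are summarized as percent change relative to the
current surface; composition (an NMDS axis score, which crosses zero) uses
the plain difference.  Summaries are taken either over all grassland and
cropland pixels ("landscape" level) or over changed pixels and their
immediate neighbors ("local" level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .grids import GridError, Landscape
from .landcover import ProportionStack
from .lmselect import AveragedModel

#: Denominator guard for percent change; pixels with |current| below this
#: are masked (NaN) and counted, not summarized.
EPSILON = 1e-6

#: Classes over which landscape-level summaries are taken.
LANDSCAPE_DOMAIN = ("grassland", "wind", "flowering_annual")


@dataclass
class MetricRaster:
    metric: str
    values: np.ndarray
    radius: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SummaryStats:
    domain: str
    mean: float
    min: float
    max: float
    q05: float
    q95: float
    n_pixels: int


def predict_surface(props: ProportionStack, model: AveragedModel) -> MetricRaster:
    """Evaluate the averaged linear model at every pixel of the stack."""
    bands = props.bands()
    c = model.coefficients
    values = (model.intercept
              + c.get("grassland", 0.0) * bands["grassland"]
              + c.get("forest", 0.0) * bands["forest"]
              + c.get("wind", 0.0) * bands["wind"]
              + c.get("flowering_annual", 0.0) * bands["flowering_annual"])
    return MetricRaster(metric=model.metric, values=values, radius=props.radius)


def _check_match(current: MetricRaster, scen: MetricRaster) -> None:
    if current.metric != scen.metric:
        raise GridError(f"metric mismatch: {current.metric} vs {scen.metric}")
    if current.shape != scen.shape:
        raise GridError(f"grid mismatch: {current.shape} vs {scen.shape}")


def percent_change_surface(current: MetricRaster, scen: MetricRaster,
                           eps: float = EPSILON) -> np.ndarray:
    """((Y_s - Y_c) / Y_c) * 100 per pixel; tiny denominators become NaN."""
    _check_match(current, scen)
    cur, sc = current.values, scen.values
    masked = np.abs(cur) < eps
    n_masked = int(masked.sum())
    if n_masked:
        warnings.warn(f"percent change: {n_masked} pixels masked (|current| < {eps})")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(masked, np.nan, (sc - cur) / np.where(masked, 1.0, cur) * 100.0)
    return out


def difference_surface(current: MetricRaster, scen: MetricRaster) -> np.ndarray:
    """Y_s - Y_c per pixel (used for metrics that cross zero)."""
    _check_match(current, scen)
    return scen.values - current.values


def _summarize(values: np.ndarray, domain_mask: np.ndarray, domain: str) -> SummaryStats:
    sel = values[domain_mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise GridError(f"{domain} summary domain is empty")
    return SummaryStats(
        domain=domain,
        mean=float(sel.mean()),
        min=float(sel.min()),
        max=float(sel.max()),
        q05=float(np.quantile(sel, 0.05)),
        q95=float(np.quantile(sel, 0.95)),
        n_pixels=int(sel.size),
    )


def landscape_summary(change: np.ndarray, landscape: Landscape,
                      domain_classes: tuple[str, ...] = LANDSCAPE_DOMAIN) -> SummaryStats:
    """Summary over all current grassland and cropland pixels."""
    codes = [landscape.code_of(c) for c in domain_classes]
    mask = np.isin(landscape.cover, codes)
    return _summarize(np.asarray(change, dtype=float), mask, "landscape")


def local_summary(change: np.ndarray, changed_mask: np.ndarray,
                  adjacency: str = "queen") -> SummaryStats:
    """Summary over changed pixels and their immediate neighbors.

    "Immediate neighbors" defaults to queen (8-cell) adjacency; rook
    (4-cell) adjacency is available by option.
    """
    changed_mask = np.asarray(changed_mask, dtype=bool)
    if not changed_mask.any():
        raise GridError("changed mask is empty; no local domain")
    if adjacency == "queen":
        structure = np.ones((3, 3), dtype=bool)
    elif adjacency == "rook":
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    else:
        raise GridError(f"unknown adjacency {adjacency!r}")
    domain = binary_dilation(changed_mask, structure=structure)
    return _summarize(np.asarray(change, dtype=float), domain, "local")
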