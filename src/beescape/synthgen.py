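"""Synthetic landscapes, survey sites, and bee-visitation tables.

This module stands in for a field campaign and its GIS inputs: a categorical
land-cover raster with a marginal-soil mask, a set of survey sites spread
across it, and per-visit species counts whose expectation is driven by the
land-cover proportions around each site.  Everything is deterministic given
one integer seed, which is split per sub-generator.

The count model works on the analysis scale used downstream: the square root
of the mean per-visit wild-bee count at a site has expectation

    mu_i = b + g*G_i + f*F_i + w*W_i + a*A_i + eps_i,   eps_i ~ N(0, sd)

where (G, F, W, A) are the proportions of grassland, forest, wind-pollinated
crops and flowering annual crops within the survey radius.  Per-visit totals
are Poisson with mean mu_i**2, partitioned over species by a softmax of
per-species loadings on a second, composition, gradient; the managed
honeybee *Apis mellifera* receives a fixed share on top so that the
exclusion path downstream is always exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import CLASS_CODES, Landscape

HONEYBEE = "Apis mellifera"


class ValidationError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when the requested number of sites cannot be placed."""


# ---------------------------------------------------------------------------
# specs


@dataclass
class LandscapeSpec:
    """Target composition and spatial texture of a synthetic landscape.

    class_weights are target area fractions over the nine grouped classes
    (they must sum to 1); marginal_fraction_by_class gives, per class, the
    fraction of that class's cells flagged as marginal soil; patchiness is
    the spatial correlation length in metres controlling patch size.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    class_weights: dict[str, float]
    marginal_fraction_by_class: dict[str, float] = field(default_factory=dict)
    patchiness: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValidationError("raster dimensions must be positive")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        if self.patchiness <= 0:
            raise ValidationError("patchiness must be positive")
        unknown = set(self.class_weights) - set(CLASS_CODES.values())
        if unknown:
            raise ValidationError(f"unknown classes in class_weights: {sorted(unknown)}")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_weights sum to {total}, expected 1")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValidationError("class_weights must be nonnegative")
        for cls, frac in self.marginal_fraction_by_class.items():
            if cls not in CLASS_CODES.values():
                raise ValidationError(f"unknown class in marginal fractions: {cls}")
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"marginal fraction for {cls} outside [0, 1]")


@dataclass(frozen=True)
class SitePoint:
    """A survey location, both in grid indices and metric coordinates."""

    site_id: str
    row: int
    col: int
    x: float
    y: float


@dataclass(frozen=True)
class LinearTruth:
    """Intercept and coefficients on the four predictor proportions."""

    intercept: float
    grassland: float
    forest: float
    wind: float
    flowering_annual: float

    def predict(self, g: float, f: float, w: float, a: float) -> float:
        return (self.intercept + self.grassland * g + self.forest * f
                + self.wind * w + self.flowering_annual * a)

    def as_dict(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "grassland": self.grassland,
            "forest": self.forest,
            "wind": self.wind,
            "flowering_annual": self.flowering_annual,
        }


@dataclass(frozen=True)
class SpeciesTruth:
    name: str
    loading: float   # response to the composition gradient; + favours crop-dominated sites
    baseline: float  # log relative share at gradient 0


# Defaults mirror the sign structure estimated from the field data this
# module emulates: abundance rises with grassland and forest and falls with
# annual crops, on the sqrt(bees per hour) scale; the composition gradient
# runs from grassland/forest-associated communities (negative) to
# annual-crop-associated ones (positive).
DEFAULT_ABUNDANCE_TRUTH = LinearTruth(0.95, 1.13, 2.84, -0.04, -0.50)
DEFAULT_GRADIENT_TRUTH = LinearTruth(-0.33, -0.76, -0.42, 1.26, 0.62)

DEFAULT_SPECIES_POOL: tuple[SpeciesTruth, ...] = (
    SpeciesTruth("Augochlorella aurata", 1.6, 0.4),
    SpeciesTruth("Halictus ligatus", -1.8, 0.4),
    SpeciesTruth("Bombus impatiens", -1.2, 0.2),
    SpeciesTruth("Lasioglossum pilosum", 0.9, 0.0),
    SpeciesTruth("Agapostemon virescens", -0.7, -0.2),
    SpeciesTruth("Melissodes bimaculatus", 1.1, -0.3),
    SpeciesTruth("Ceratina calcarata", 0.3, -0.5),
    SpeciesTruth("Halictus confusus", -0.4, -0.6),
    SpeciesTruth("Bombus griseocollis", -1.5, -0.8),
    SpeciesTruth("Peponapis pruinosa", 0.6, -1.0),
    SpeciesTruth("Andrena carlini", -0.9, -1.2),
    SpeciesTruth("Lasioglossum admirandum", 0.2, -1.3),
)


@dataclass
class TruthParams:
    """Ground-truth generative parameters for the synthetic surveys."""

    abundance: LinearTruth = DEFAULT_ABUNDANCE_TRUTH
    gradient: LinearTruth = DEFAULT_GRADIENT_TRUTH
    residual_sd: float = 0.25
    species_pool: tuple[SpeciesTruth, ...] = DEFAULT_SPECIES_POOL
    honeybee_share: float = 0.25

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be nonnegative")
        if not 0.0 <= self.honeybee_share < 1.0:
            raise ValidationError("honeybee_share must be in [0, 1)")
        if len(self.species_pool) == 0:
            raise ValidationError("species pool is empty")
        for sp in self.species_pool:
            if not (np.isfinite(sp.loading) and np.isfinite(sp.baseline)):
                raise ValidationError(f"non-finite loading for species {sp.name}")


# ---------------------------------------------------------------------------
# generators


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministically split one integer seed into named substreams.

    Python's str hash is salted per process, so the stream id is derived from
    the raw bytes instead.
    """
    stream_id = int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little") % (2**31)
    return np.random.default_rng([int(seed), stream_id])


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_cells > 0:
        noise = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return noise


def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Realize a landscape with (near-)exact class fractions and patchy texture.

    A Gaussian random field smoothed to the requested correlation length is
    thresholded at its own empirical quantiles, so realized class fractions
    match ``class_weights`` up to integer rounding while patches remain
    contiguous.  Class order along the field is shuffled per seed so that
    adjacency structure varies between realizations.  The marginal mask is a
    second smoothed field thresholded class-by-class at the per-class
    marginal fraction, giving patchy marginal soils with exact per-class
    coverage.
    """
    shape = (spec.n_rows, spec.n_cols)
    sigma = spec.patchiness / spec.cell_size
    rng_field = _stream_rng(spec.seed, "cover-field")
    rng_order = _stream_rng(spec.seed, "class-order")
    rng_soil = _stream_rng(spec.seed, "marginal-field")

    field = _smoothed_field(rng_field, shape, sigma)

    names = sorted(spec.class_weights)  # canonical order, then seeded shuffle
    order = rng_order.permutation(len(names))
    shuffled = [names[i] for i in order]
    weights = np.array([spec.class_weights[n] for n in shuffled])

    n = field.size
    # rank of each cell in the field → class by cumulative-weight cut points
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(field.ravel(), kind="stable")] = np.arange(n)
    cuts = np.floor(np.cumsum(weights) * n + 0.5).astype(np.int64)
    cuts[-1] = n
    class_idx = np.searchsorted(cuts, ranks, side="right")
    name_by_code = dict(CLASS_CODES)
    code_by_name = {v: k for k, v in name_by_code.items()}
    codes = np.array([code_by_name[nm] for nm in shuffled], dtype=np.int16)
    cover = codes[class_idx].reshape(shape)

    soil = _smoothed_field(rng_soil, shape, sigma)
    marginal = np.zeros(shape, dtype=bool)
    for cls, frac in spec.marginal_fraction_by_class.items():
        if frac <= 0:
            continue
        mask = cover == code_by_name[cls]
        n_cls = int(mask.sum())
        if n_cls == 0:
            continue
        k = int(round(frac * n_cls))
        if k == 0:
            continue
        vals = soil[mask]
        cut = np.partition(vals, k - 1)[k - 1]
        chosen = mask & (soil <= cut)
        # ties at the cut could overshoot; trim deterministically
        extra = int(chosen.sum()) - k
        if extra > 0:
            idx = np.flatnonzero(chosen.ravel() & (soil.ravel() == cut))[:extra]
            chosen.ravel()[idx] = False
        marginal |= chosen

    return Landscape(cover=cover, marginal=marginal, cell_size=spec.cell_size)


def generate_sites(landscape: Landscape, n_sites: int, min_separation: float,
                   seed: int = 0, edge_margin: float = 1500.0,
                   max_tries: int = 10_000,
                   gradient: np.ndarray | None = None) -> list[SitePoint]:
    """Place survey sites by rejection sampling.

    All pairwise distances are at least ``min_separation`` metres and every
    site is at least ``edge_margin`` metres from the raster edge, so a buffer
    of that radius is fully in-bounds.

    When ``gradient`` (a raster on the landscape grid, e.g. a grassland
    proportion surface) is given, sites are additionally stratified across
    its quantiles, emulating a field design where sites are deliberately
    chosen to span the landscape gradient rather than placed at random.
    """
    if n_sites <= 0:
        raise ValidationError("n_sites must be positive")
    rng = _stream_rng(seed, "sites")
    cs = landscape.cell_size
    n_rows, n_cols = landscape.shape
    margin_cells = int(np.ceil(edge_margin / cs))
    lo_r, hi_r = margin_cells, n_rows - 1 - margin_cells
    lo_c, hi_c = margin_cells, n_cols - 1 - margin_cells
    if lo_r > hi_r or lo_c > hi_c:
        raise PlacementError(
            f"edge margin {edge_margin} m leaves no interior cells; placed 0 of {n_sites}")

    cdf = None
    targets: list[float] = []
    if gradient is not None:
        gradient = np.asarray(gradient, dtype=float)
        if gradient.shape != landscape.shape:
            raise ValidationError("gradient raster must share the landscape grid")
        interior = gradient[lo_r:hi_r + 1, lo_c:hi_c + 1].ravel()
        order = np.sort(interior)
        cdf = lambda v: np.searchsorted(order, v, side="right") / order.size  # noqa: E731
        targets = [(i + 0.5) / n_sites for i in rng.permutation(n_sites)]

    placed: list[tuple[int, int]] = []
    tries = 0
    band = 0.05
    while len(placed) < n_sites and tries < max_tries:
        tries += 1
        if tries % 500 == 0:
            band *= 1.5  # relax the stratum if placement is hard
        r = int(rng.integers(lo_r, hi_r + 1))
        c = int(rng.integers(lo_c, hi_c + 1))
        if any(cs * np.hypot(r - pr, c - pc) < min_separation for pr, pc in placed):
            continue
        if cdf is not None and abs(cdf(gradient[r, c]) - targets[len(placed)]) > band:
            continue
        placed.append((r, c))
    if len(placed) < n_sites:
        raise PlacementError(
            f"could not place {n_sites} sites with {min_separation} m separation; "
            f"achieved {len(placed)} after {max_tries} tries")
    return [
        SitePoint(site_id=f"S{i + 1:02d}", row=r, col=c, x=c * cs, y=r * cs)
        for i, (r, c) in enumerate(placed)
    ]


def _species_shares(truth: TruthParams, gradient_value: float) -> tuple[list[str], np.ndarray]:
    """Softmax shares of the wild-bee pool, plus the honeybee share on top."""
    logits = np.array([sp.baseline + sp.loading * gradient_value for sp in truth.species_pool])
    logits -= logits.max()
    shares = np.exp(logits)
    shares /= shares.sum()
    return [sp.name for sp in truth.species_pool], shares


def generate_surveys(sites: list[SitePoint], proportions: pd.DataFrame,
                     truth: TruthParams, visits_per_site: tuple[int, int] = (3, 5),
                     seed: int = 0) -> pd.DataFrame:
    """Simulate per-visit, per-species counts for every site.

    ``proportions`` is indexed by site_id with columns
    (grassland, forest, wind, flowering_annual).  The returned long-format
    table has one row per (site, visit, species) including explicit zero
    counts, so the number of visits per site is always recoverable.
    """
    if len(truth.species_pool) == 0:
        raise ValidationError("species pool is empty")
    lo, hi = visits_per_site
    if not (1 <= lo <= hi):
        raise ValidationError("visits_per_site must satisfy 1 <= lo <= hi")
    rng = _stream_rng(seed, "surveys")
    rows: list[tuple[str, int, str, int]] = []
    for site in sites:
        p = proportions.loc[site.site_id]
        g, f = float(p["grassland"]), float(p["forest"])
        w, a = float(p["wind"]), float(p["flowering_annual"])
        mu = truth.abundance.predict(g, f, w, a) + rng.normal(0.0, truth.residual_sd)
        mu = max(mu, 0.0)
        wild_mean = mu**2  # per-visit expected wild-bee count
        grad = truth.gradient.predict(g, f, w, a)
        names, shares = _species_shares(truth, grad)
        hb_mean = wild_mean * truth.honeybee_share / (1.0 - truth.honeybee_share)
        n_visits = int(rng.integers(lo, hi + 1))
        for visit in range(1, n_visits + 1):
            counts = rng.poisson(wild_mean * shares)
            for name, count in zip(names, counts):
                rows.append((site.site_id, visit, name, int(count)))
            rows.append((site.site_id, visit, HONEYBEE, int(rng.poisson(hb_mean))))
    return pd.DataFrame(rows, columns=["site_id", "visit", "species", "count"])


def sites_to_frame(sites: list[SitePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.site_id, s.row, s.col, s.x, s.y) for s in sites],
        columns=["site_id", "row", "col", "x", "y"],
    )


def frame_to_sites(frame: pd.DataFrame) -> list[SitePoint]:
    return [
        SitePoint(str(r.site_id), int(r.row), int(r.col), float(r.x), float(r.y))
        for r in frame.itertuples(index=False)
    ]
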