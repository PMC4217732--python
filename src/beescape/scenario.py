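"""Bioenergy land-conversion scenarios on marginal land.

Two contrasting scenarios are modelled.  In the *annual* scenario, marginal
grassland is converted to annual row-crop bioenergy production, split
between wind-pollinated crops (corn) and flowering annual crops (soybean)
by their shares of the current annual-crop landscape.  In the *perennial*
scenario, marginal annual cropland is converted to perennial grassland,
with fixed area quotas for the wind-pollinated and flowering-annual source
classes.

Conversion operates on individual cells, selected uniformly at random
without replacement from the eligible set (cells of the source class that
lie on marginal soil).  Target classes within one conversion line are
apportioned by exact largest-remainder quota, so realized class shares are
deterministic given the cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Landscape


class ScenarioError(ValueError):
    pass


#: Corn/soybean shares of converted area in the annual scenario; they are
#: quoted as 0.58/0.41 (summing to 0.99) and normalized here so the total
#: converted area is preserved exactly.
ANNUAL_ALLOCATION = {"wind": 0.58, "flowering_annual": 0.41}


@dataclass
class Conversion:
    """One conversion line: source class -> target class(es) over an area."""

    source: str
    area_ha: float
    target: str | None = None
    allocation: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.area_ha < 0:
            raise ScenarioError("area_ha must be nonnegative")
        if (self.target is None) == (self.allocation is None):
            raise ScenarioError("give exactly one of target or allocation")
        if self.allocation is not None:
            if any(v <= 0 for v in self.allocation.values()):
                raise ScenarioError("allocation fractions must be positive")

    def normalized_allocation(self) -> dict[str, float]:
        if self.target is not None:
            return {self.target: 1.0}
        total = sum(self.allocation.values())
        return {k: v / total for k, v in self.allocation.items()}


@dataclass
class ScenarioSpec:
    name: str
    conversions: list[Conversion]
    seed: int = 0


def annual_scenario(area_ha: float = 600_000.0, seed: int = 0,
                    allocation: dict[str, float] | None = None) -> ScenarioSpec:
    """Marginal grassland -> annual bioenergy crops (corn/soy split)."""
    return ScenarioSpec(
        name="annual",
        conversions=[Conversion(source="grassland", area_ha=area_ha,
                                allocation=dict(allocation or ANNUAL_ALLOCATION))],
        seed=seed,
    )


def perennial_scenario(wind_area_ha: float = 360_000.0,
                       fa_area_ha: float = 240_000.0, seed: int = 0) -> ScenarioSpec:
    """Marginal annual cropland -> perennial grassland (fixed quotas)."""
    return ScenarioSpec(
        name="perennial",
        conversions=[
            Conversion(source="wind", target="grassland", area_ha=wind_area_ha),
            Conversion(source="flowering_annual", target="grassland", area_ha=fa_area_ha),
        ],
        seed=seed,
    )


def eligible_cells(landscape: Landscape, source_group: str) -> np.ndarray:
    """Flat indices of marginal cells of the source class."""
    code = landscape.code_of(source_group)
    mask = (landscape.cover == code) & landscape.marginal
    return np.flatnonzero(mask.ravel())


def largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Apportion n items to categories by largest-remainder quota."""
    names = list(fractions)
    quotas = np.array([fractions[k] * n for k in names])
    base = np.floor(quotas).astype(int)
    remainder = n - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    for i in order[:remainder]:
        base[i] += 1
    return {name: int(c) for name, c in zip(names, base)}


@dataclass
class ScenarioResult:
    cover_after: np.ndarray
    changed: np.ndarray
    converted_area_ha: dict[tuple[str, str], float]
    log: dict = field(default_factory=dict)


def convert(landscape: Landscape, spec: ScenarioSpec) -> ScenarioResult:
    """Apply every conversion line of a scenario to a copy of the landscape.

    Exactly round(area_ha / cell_area) cells are converted per line, chosen
    uniformly at random without replacement from the eligible cells of the
    line's source class.  Any rounding residual is logged.  Selection is
    deterministic given the scenario seed.
    """
    rng = np.random.default_rng(spec.seed)
    cell_area = landscape.cell_area_ha
    before = landscape.cover
    after = before.copy()
    flat = after.ravel()
    converted: dict[tuple[str, str], float] = {}
    log: dict = {"seed": spec.seed, "cell_area_ha": cell_area, "lines": []}
    for conv in spec.conversions:
        eligible = eligible_cells(landscape, conv.source)
        n_cells = int(round(conv.area_ha / cell_area))
        residual_ha = conv.area_ha - n_cells * cell_area
        if n_cells > eligible.size:
            shortfall = (n_cells - eligible.size) * cell_area
            raise ScenarioError(
                f"conversion {conv.source!r}: requested {conv.area_ha} ha but only "
                f"{eligible.size * cell_area} ha eligible (shortfall {shortfall} ha)")
        chosen = rng.choice(eligible, size=n_cells, replace=False)
        counts = largest_remainder(n_cells, conv.normalized_allocation())
        start = 0
        for target, count in counts.items():
            cells = chosen[start:start + count]
            start += count
            flat[cells] = landscape.code_of(target)
            converted[(conv.source, target)] = converted.get((conv.source, target), 0.0) \
                + count * cell_area
        log["lines"].append({
            "source": conv.source,
            "requested_ha": conv.area_ha,
            "realized_cells": n_cells,
            "residual_ha": residual_ha,
            "targets": counts,
        })
    changed = after != before
    return ScenarioResult(cover_after=after, changed=changed,
                          converted_area_ha=converted, log=log)
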