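"""Population-at-risk estimation from a hazard map and population grids.

Three estimators bracket the exposed population consuming untreated
groundwater:

* ``high``  - every cell contributes population x probability;
* ``low``   - cells above a probability cutoff (default 0.5, the
  sensitivity-specificity crossover) contribute their full population;
* ``hybrid``- cells above half the crossover (default 0.25) contribute
  population x probability.

Cutoff comparisons are strict (p > cutoff). Cells with nodata probability
contribute nothing and are reported as uncovered population. Counts stay
real-valued internally; round only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Raster
from .mapping import HazardMap


def groundwater_population(
    rural: Raster,
    urban: Raster,
    usage: pd.DataFrame,
    countries: Raster,
) -> Raster:
    """Cellwise population consuming untreated groundwater.

    rural_pop x rural_fraction + urban_pop x urban_fraction, with the
    fractions looked up per country. Raises if a populated cell's country
    has no usage entry.
    """
    for other in (urban, countries):
        if not rural.aligned_with(other):
            raise ValueError("population and country rasters must share one grid")
    frac = usage.set_index("country_id")[["rural_fraction", "urban_fraction"]]
    if ((frac < 0) | (frac > 1)).any().any():
        raise ValueError("usage fractions must lie in [0, 1]")
    ids = countries.data.astype(int)
    present = np.unique(ids[countries.mask])
    missing = sorted(set(present) - set(frac.index))
    if missing:
        populated = [
            int(c) for c in missing
            if (rural.data[ids == c].sum() + urban.data[ids == c].sum()) > 0
        ]
        if populated:
            raise ValueError(f"no usage rates for country ids: {populated}")
    rural_f = np.zeros_like(rural.data)
    urban_f = np.zeros_like(urban.data)
    for cid in frac.index.intersection(present):
        sel = ids == cid
        rural_f[sel] = frac.at[cid, "rural_fraction"]
        urban_f[sel] = frac.at[cid, "urban_fraction"]
    return Raster(rural.data * rural_f + urban.data * urban_f, rural.grid)


@dataclass
class ExposureEstimate:
    """Exposed-population count by one estimator, with optional breakdowns."""

    method: str
    cutoff: float | None
    total: float
    total_consuming: float
    uncovered_population: float
    per_country: dict[int, float] = field(default_factory=dict)
    per_continent: dict[str, float] = field(default_factory=dict)

    @property
    def percentage_of_consuming(self) -> float:
        return 100.0 * self.total / self.total_consuming if self.total_consuming else 0.0


def _estimate(
    method: str,
    cutoff: float | None,
    consuming: Raster,
    hazard: HazardMap | Raster,
    countries: Raster | None,
    continents: dict[int, str] | None,
) -> ExposureEstimate:
    raster = hazard.raster if isinstance(hazard, HazardMap) else hazard
    if not consuming.aligned_with(raster):
        raise ValueError("consuming-population raster is not aligned to the hazard map")
    p = raster.data
    covered = raster.mask
    pop = consuming.data

    if method == "high":
        weight = np.where(covered, p, 0.0)
    elif method == "low":
        weight = np.where(covered & (p > cutoff), 1.0, 0.0)
    elif method == "hybrid":
        weight = np.where(covered & (p > cutoff), p, 0.0)
    else:
        raise ValueError(f"unknown estimator {method!r}")
    exposed = pop * weight

    est = ExposureEstimate(
        method=method,
        cutoff=cutoff,
        total=float(exposed.sum()),
        total_consuming=float(pop[covered].sum()),
        uncovered_population=float(pop[~covered].sum()),
    )
    if countries is not None:
        ids = countries.data.astype(int)
        for cid in np.unique(ids[countries.mask]):
            est.per_country[int(cid)] = float(exposed[ids == cid].sum())
        if continents:
            for cid, count in est.per_country.items():
                cont = continents.get(cid, "unknown")
                est.per_continent[cont] = est.per_continent.get(cont, 0.0) + count
    return est


def exposed_high(
    consuming: Raster, hazard: HazardMap | Raster,
    countries: Raster | None = None, continents: dict[int, str] | None = None,
) -> ExposureEstimate:
    """Probability-weighted count: sum of population x probability."""
    return _estimate("high", None, consuming, hazard, countries, continents)


def exposed_low(
    consuming: Raster, hazard: HazardMap | Raster, cutoff: float = 0.5,
    countries: Raster | None = None, continents: dict[int, str] | None = None,
) -> ExposureEstimate:
    """Cutoff count: full population of cells with probability > cutoff."""
    return _estimate("low", cutoff, consuming, hazard, countries, continents)


def exposed_hybrid(
    consuming: Raster, hazard: HazardMap | Raster, cutoff: float = 0.25,
    countries: Raster | None = None, continents: dict[int, str] | None = None,
) -> ExposureEstimate:
    """Probability-weighted count restricted to cells above half the
    sensitivity-specificity crossover (0.25 when the crossover is 0.5)."""
    return _estimate("hybrid", cutoff, consuming, hazard, countries, continents)


def aggregate_exposure(
    consuming: Raster,
    hazard: HazardMap | Raster,
    countries: Raster,
    continents: dict[int, str],
    low_cutoff: float = 0.5,
    hybrid_cutoff: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked per-country table (hybrid with low-high range) and continent totals."""
    high = exposed_high(consuming, hazard, countries, continents)
    low = exposed_low(consuming, hazard, low_cutoff, countries, continents)
    hybrid = exposed_hybrid(consuming, hazard, hybrid_cutoff, countries, continents)

    ids = countries.data.astype(int)
    pop_by_country = {
        int(c): float(consuming.data[ids == c].sum())
        for c in np.unique(ids[countries.mask])
    }
    country_table = pd.DataFrame(
        {
            "country_id": list(hybrid.per_country),
            "continent": [continents.get(c, "unknown") for c in hybrid.per_country],
            "exposed_hybrid": list(hybrid.per_country.values()),
            "exposed_low": [low.per_country[c] for c in hybrid.per_country],
            "exposed_high": [high.per_country[c] for c in hybrid.per_country],
            "consuming_population": [pop_by_country[c] for c in hybrid.per_country],
        }
    ).sort_values("exposed_hybrid", ascending=False, kind="stable").reset_index(drop=True)
    country_table.insert(0, "rank", np.arange(1, len(country_table) + 1))

    continent_table = (
        country_table.groupby("continent", as_index=False)[
            ["exposed_hybrid", "exposed_low", "exposed_high", "consuming_population"]
        ].sum()
    )
    continent_table["percent_exposed_hybrid"] = 100.0 * (
        continent_table["exposed_hybrid"] / continent_table["consuming_population"]
    )
    return country_table, continent_table
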