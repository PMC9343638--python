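"""Hazard mapping: harmonize a stack, apply a model cellwise, summarize area.

Coarse bands are block-replicated (nearest neighbour) onto the finest grid
before prediction, which leaves their values untouched. Prediction runs in
row tiles so memory stays bounded by the tile size regardless of grid
extent; tiled and whole-grid evaluation agree bit-exactly. A cell whose
selected covariates contain nodata in any band gets nodata probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forest import BalancedForestModel
from .grids import Band, CovariateStack, Raster

logger = logging.getLogger(__name__)


def harmonize_stack(stack: CovariateStack) -> CovariateStack:
    """Bring every band onto the finest grid by block replication.

    Coarse resolutions must be integer multiples of the finest; values are
    unchanged (each coarse value simply covers a factor x factor block).
    """
    fine = stack.fine_grid
    out = CovariateStack()
    for name, band in stack.bands.items():
        g = band.raster.grid
        if g.shape == fine.shape:
            out.add(band)
            continue
        ratio = g.cell_size / fine.cell_size
        factor = round(ratio)
        if not np.isclose(ratio, factor) or g.nrows * factor != fine.nrows:
            raise ValueError(
                f"band {name!r} resolution {g.cell_size} is not an integer "
                f"multiple of the finest {fine.cell_size}"
            )
        data = np.repeat(np.repeat(band.raster.data, factor, 0), factor, 1)
        out.add(Band(name, Raster(data, fine), kind=band.kind, categories=band.categories))
    return out


@dataclass
class HazardMap:
    """Modeled exceedance-probability surface with provenance."""

    raster: Raster
    feature_names: tuple[str, ...]
    provenance: str = ""

    @property
    def data(self) -> np.ndarray:
        return self.raster.data

    @property
    def mask(self) -> np.ndarray:
        return self.raster.mask


def predict_map(
    model: BalancedForestModel, stack: CovariateStack, tile_rows: int = 128
) -> HazardMap:
    """Apply a fitted model to every cell of a (harmonizable) stack."""
    missing = [f for f in model.feature_names if f not in stack.bands]
    if missing:
        raise ValueError(f"stack lacks selected feature bands: {missing}")
    stack = harmonize_stack(stack.subset(list(model.feature_names)))
    grid = stack.fine_grid
    arrays = [stack.bands[f].raster.data for f in model.feature_names]
    masks = [stack.bands[f].raster.mask for f in model.feature_names]
    valid = np.logical_and.reduce(masks)
    out = np.full(grid.shape, grid.nodata, dtype=float)
    for r0 in range(0, grid.nrows, tile_rows):
        r1 = min(r0 + tile_rows, grid.nrows)
        tile_valid = valid[r0:r1]
        if not tile_valid.any():
            continue
        X = np.column_stack([a[r0:r1][tile_valid] for a in arrays])
        tile_out = out[r0:r1]
        tile_out[tile_valid] = model.predict_proba(X)
        out[r0:r1] = tile_out
    n_nodata = int((~valid).sum())
    if n_nodata:
        logger.info("hazard map: %d of %d cells without full covariate coverage",
                    n_nodata, valid.size)
    return HazardMap(
        raster=Raster(out, grid),
        feature_names=tuple(model.feature_names),
        provenance=f"balanced forest ({len(model.trees)} trees)",
    )


def area_fraction_above(
    hazard: HazardMap | Raster,
    cutoff: float = 0.5,
    region_mask: np.ndarray | None = None,
    cell_areas: Raster | None = None,
) -> float:
    """(Area-weighted) fraction of valid region cells with probability > cutoff.

    With no area raster every cell counts equally (planar equal-area cells);
    an optional per-cell area raster supports latitude-corrected fractions.
    """
    raster = hazard.raster if isinstance(hazard, HazardMap) else hazard
    valid = raster.mask
    if region_mask is not None:
        if region_mask.shape != raster.data.shape:
            raise ValueError("region mask is not aligned to the map")
        valid = valid & region_mask.astype(bool)
    if not valid.any():
        raise ValueError("region contains no valid cells")
    weights = np.ones(raster.data.shape) if cell_areas is None else cell_areas.data
    above = valid & (raster.data > cutoff)
    return float(weights[above].sum() / weights[valid].sum())
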