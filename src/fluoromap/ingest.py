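"""Point-measurement ingestion: deduplication, labeling, covariate extraction.

Replicate measurements from one well are averaged *before* the guideline
comparison — binarizing per replicate and averaging labels would not give
the same result, so the order is fixed here. Exceedance is strict
(concentration > threshold). Coordinates are taken in the grid's own
coordinate system; no reprojection happens at this stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import CovariateStack

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.5

#: canonical column names expected after renaming via `name_map`
CANONICAL = ("well_id", "lon", "lat", "concentration")


def dedupe_wells(
    raw: pd.DataFrame, name_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Collapse replicate rows to one row per well by arithmetic averaging.

    Concentration, depth and any in-situ columns are averaged over their
    non-missing replicate values; coordinates are taken from the first row
    (replicates share the well's location). Rows with negative
    concentration are rejected with a logged warning.
    """
    df = raw.rename(columns=name_map or {}).copy()
    missing = [c for c in ("well_id", "concentration") if c not in df.columns]
    if missing:
        raise ValueError(f"raw table lacks required columns: {missing}")

    bad = df["concentration"] < 0
    if bad.any():
        logger.warning("rejecting %d rows with negative concentration", int(bad.sum()))
        df = df[~bad]

    numeric = [
        c for c in df.columns
        if c not in ("well_id", "lon", "lat") and pd.api.types.is_numeric_dtype(df[c])
    ]
    agg = {c: "mean" for c in numeric}
    for c in ("lon", "lat"):
        if c in df.columns:
            agg[c] = "first"
    out = df.groupby("well_id", as_index=False, sort=True).agg(agg)
    ordered = [c for c in df.columns if c in out.columns]
    return out[ordered].reset_index(drop=True)


def binarize(
    concentration: np.ndarray | pd.Series, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """1 where concentration strictly exceeds the guideline, else 0."""
    c = np.asarray(concentration, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be nonnegative")
    return (c > threshold).astype(int)


def label_table(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Attach the binary exceedance label to a deduplicated table."""
    out = table.copy()
    out["label"] = binarize(out["concentration"].to_numpy(), threshold)
    return out


def extract_covariates(
    points: pd.DataFrame,
    stack: CovariateStack,
    bands: list[str] | None = None,
) -> pd.DataFrame:
    """Annotate each point with the covariate value of its containing cell.

    Points outside the stack bounds, or hitting nodata in any requested
    band, are dropped with a logged count. Raises if no point is inside.
    """
    names = bands if bands is not None else stack.names
    out = points.reset_index(drop=True).copy()
    x = out["lon"].to_numpy(float)
    y = out["lat"].to_numpy(float)

    keep = np.ones(len(out), dtype=bool)
    values: dict[str, np.ndarray] = {}
    n_outside = 0
    for name in names:
        band = stack.bands[name]
        vals, inside = band.raster.sample(x, y)
        nodata = inside & np.isclose(
            np.where(inside, vals, 0.0), band.raster.grid.nodata
        )
        if name == names[0]:
            n_outside = int((~inside).sum())
        keep &= inside & ~nodata
        values[name] = vals
    if not keep.any():
        raise ValueError("all points fall outside the covariate stack bounds")
    n_nodata = int(keep.size - keep.sum() - n_outside)
    if n_outside or n_nodata:
        logger.info(
            "dropped %d points outside bounds and %d hitting nodata",
            n_outside, n_nodata,
        )
    for name in names:
        out[name] = values[name]
    return out[keep].reset_index(drop=True)


def build_model_table(
    raw: pd.DataFrame,
    stack: CovariateStack,
    threshold: float = DEFAULT_THRESHOLD,
    name_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """dedupe -> label -> extract, the standard ingestion chain."""
    table = dedupe_wells(raw, name_map=name_map)
    table = label_table(table, threshold)
    return extract_covariates(table, stack)
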