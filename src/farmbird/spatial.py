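"""Downscaling of coarse grid fields to agricultural regions.

Grid-scale quantities (climatic suitability, land-cover class fractions at
~0.5 degree resolution) are averaged into each region weighted by the
fraction of the region's area falling in each grid cell. Overlap fractions
are region-normalized: they must sum to 1 per region, and input that does
not (e.g. cell-normalized matrices) is rejected rather than silently
renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MissingCoverageError",
    "OverlapMatrix",
    "downscale_to_regions",
    "farmland_proportion",
    "temporal_mean",
]


class MissingCoverageError(ValueError):
    """A region has no (or incomplete) grid coverage."""


@dataclass
class OverlapMatrix:
    """Region-normalized cell x region overlap fractions.

    ``table`` has columns cell_id, region_id, fraction, where ``fraction`` is
    the share of the region's area lying in that cell.
    """

    table: pd.DataFrame
    tol: float = 1e-6

    def __post_init__(self) -> None:
        required = {"cell_id", "region_id", "fraction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"overlap table missing columns: {sorted(missing)}")
        frac = self.table["fraction"].to_numpy(dtype=float)
        if (frac < -1e-12).any() or (frac > 1 + 1e-12).any():
            raise ValueError("overlap fractions must lie in [0, 1]")
        sums = self.table.groupby("region_id")["fraction"].sum()
        bad = sums[(sums - 1.0).abs() > self.tol]
        if len(bad):
            raise MissingCoverageError(
                "per-region overlap fractions must sum to 1; offending regions: "
                f"{dict(bad.round(6))}"
            )

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.table["region_id"].unique())


def downscale_to_regions(
    grid_field: Mapping[str, float] | pd.Series,
    overlaps: OverlapMatrix,
) -> pd.Series:
    """Overlap-weighted average of a cell-keyed field, per region.

    Each region's value is ``sum_c fraction(c, r) * field(c)``; because the
    fractions are convex weights, the result lies in the convex hull of the
    cell values. A cell referenced by the overlaps but absent from the field
    is a hard error (renormalizing around missing cells would bias the
    averages).
    """
    field = pd.Series(grid_field, dtype=float)
    tab = overlaps.table
    unknown = set(tab["cell_id"]) - set(field.index)
    if unknown:
        raise MissingCoverageError(f"grid field missing values for cells: {sorted(unknown)}")
    vals = field.reindex(tab["cell_id"]).to_numpy() * tab["fraction"].to_numpy()
    out = pd.Series(vals, index=tab["region_id"].to_numpy()).groupby(level=0).sum()
    out.index.name = "region_id"
    return out


def farmland_proportion(pasture, cultivated, mosaic):
    """Farmland-habitat proportion of a cell (or array of cells).

    The sum of the three farmland land-cover classes — herbaceous/cultivated
    pasture, cultivated and managed areas, and mosaic cropland/natural
    vegetation — capped at 1 (class fractions from independent layers can
    overshoot slightly).
    """
    p = np.asarray(pasture, dtype=float)
    c = np.asarray(cultivated, dtype=float)
    m = np.asarray(mosaic, dtype=float)
    for name, arr in (("pasture", p), ("cultivated", c), ("mosaic", m)):
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError(f"{name} fraction outside [0, 1]")
    out = np.minimum(p + c + m, 1.0)
    return float(out) if out.ndim == 0 else out


def temporal_mean(yearly_fields: Iterable[pd.Series], window: Iterable = None) -> pd.Series:
    """Element-wise arithmetic mean of a stack of cell-keyed fields.

    Used both for averaging a historical window of yearly layers (e.g.
    1960-1990 land cover) and for the unweighted mean across emission-scenario
    layers of a future projection. If ``window`` is given, ``yearly_fields``
    is treated as a mapping year -> field and only those years are averaged.
    """
    if window is not None:
        mapping = dict(yearly_fields)
        window = list(window)
        if not window:
            raise ValueError("window must be non-empty")
        missing = [y for y in window if y not in mapping]
        if missing:
            raise ValueError(f"window years not available: {missing}")
        fields = [pd.Series(mapping[y], dtype=float) for y in window]
    else:
        fields = [pd.Series(f, dtype=float) for f in yearly_fields]
        if not fields:
            raise ValueError("at least one field is required")
    df = pd.concat(fields, axis=1)
    if df.isna().any().any():
        raise ValueError("fields do not share a common cell set")
    return df.mean(axis=1)
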