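"""Prediction-grid construction and risk surfaces.

A regular grid of cell centres (1 km default spacing) covers the study
region; cells in excluded (e.g. highly populated urban) units are masked.
For every retained cell the fitted model yields the posterior mean and SD
of the snakebite risk, and combining the mean risk with household density
gives the expected number of affected households per cell-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geo_io import RasterGrid
from .model import SpatialLogisticGP

__all__ = [
    "PredictionGrid",
    "RiskSurface",
    "build_grid",
    "map_risk",
    "households_at_risk",
    "people_from_households",
    "PEOPLE_PER_HOUSEHOLD",
]

#: Average household size in the study region (people per household).
PEOPLE_PER_HOUSEHOLD = 5.27


@dataclass
class PredictionGrid:
    """Raster geometry plus the per-cell design values and exclusion mask."""

    geometry: RasterGrid          # template raster (values unused)
    design: pd.DataFrame | None   # one row per retained cell, scaled
    cell_rows: np.ndarray         # raster indices of retained cells
    cell_cols: np.ndarray
    coords: np.ndarray            # (n_retained, 2) cell centres, km

    @property
    def n_cells(self) -> int:
        return len(self.cell_rows)

    def raster_from(self, values: np.ndarray) -> RasterGrid:
        """Scatter per-retained-cell values into a full nodata-filled raster."""
        full = np.full((self.geometry.n_rows, self.geometry.n_cols), self.geometry.nodata)
        full[self.cell_rows, self.cell_cols] = values
        return self.geometry.copy_with(full)


@dataclass
class RiskSurface:
    """Posterior mean risk, its SD, and expected affected households per cell-year."""

    mean: RasterGrid
    sd: RasterGrid
    households: RasterGrid | None = None

    def __post_init__(self) -> None:
        if not self.mean.same_geometry(self.sd):
            raise ValueError("mean and SD rasters must share geometry")
        if self.households is not None and not self.mean.same_geometry(self.households):
            raise ValueError("households raster must share geometry")


def build_grid(
    region: BaseGeometry,
    spacing: float = 1.0,
    exclusions: list[BaseGeometry] | None = None,
) -> PredictionGrid:
    """Cell centres of the region's bounding box at ``spacing`` km.

    A w x h bounding box yields floor(w/s) x floor(h/s) candidate centres;
    centres outside the region or inside an exclusion polygon are masked.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    xmin, ymin, xmax, ymax = region.bounds
    ncols = int(np.floor((xmax - xmin) / spacing + 1e-9))
    nrows = int(np.floor((ymax - ymin) / spacing + 1e-9))
    if ncols < 1 or nrows < 1:
        raise ValueError("spacing larger than the region extent")

    template = RasterGrid(
        origin=(xmin, ymin),
        cell_size=spacing,
        values=np.full((nrows, ncols), -9999.0),
    )
    cx, cy = template.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    keep = shapely.covers(region, pts)
    if exclusions:
        for ex in exclusions:
            keep &= ~shapely.covers(ex, pts)
    keep = keep.reshape(nrows, ncols)
    rows, cols = np.nonzero(keep)
    return PredictionGrid(
        geometry=template,
        design=None,
        cell_rows=rows,
        cell_cols=cols,
        coords=np.column_stack([cx[rows, cols], cy[rows, cols]]),
    )


def attach_design(grid: PredictionGrid, design: pd.DataFrame) -> PredictionGrid:
    """Attach a per-retained-cell scaled design table to the grid."""
    if len(design) != grid.n_cells:
        raise ValueError("design rows must match retained grid cells")
    grid.design = design
    return grid


def map_risk(
    fitted: SpatialLogisticGP,
    grid: PredictionGrid,
    random_state=None,
) -> RiskSurface:
    """Predict posterior mean/SD risk for every retained grid cell.

    The grid design must contain exactly the fitted covariates (scaled);
    masked cells carry nodata in the output rasters.
    """
    if grid.n_cells == 0:
        nodata_full = grid.geometry.copy_with(
            np.full((grid.geometry.n_rows, grid.geometry.n_cols), grid.geometry.nodata)
        )
        return RiskSurface(mean=nodata_full, sd=grid.geometry.copy_with(nodata_full.values.copy()))
    if grid.design is None:
        raise ValueError("grid has no design attached; call attach_design first")
    missing = [c for c in fitted.feature_names_in_ if c not in grid.design.columns]
    if missing:
        raise ValueError(f"grid design is missing fitted covariates: {missing}")
    X = grid.design[list(fitted.feature_names_in_)]
    mean, sd = fitted.predict_risk(X, coords=grid.coords, random_state=random_state)
    return RiskSurface(mean=grid.raster_from(mean), sd=grid.raster_from(sd))


def households_at_risk(mean_risk: RasterGrid, household_density: RasterGrid) -> RasterGrid:
    """Expected bitten households per cell-year: risk x households per cell.

    Nodata in either input propagates to the output.
    """
    if not mean_risk.same_geometry(household_density):
        raise ValueError("risk and household-density rasters are not aligned")
    ok = mean_risk.mask() & household_density.mask()
    out = np.full_like(mean_risk.values, mean_risk.nodata)
    out[ok] = mean_risk.values[ok] * household_density.values[ok]
    return mean_risk.copy_with(out)


def people_from_households(households, people_per_household: float = PEOPLE_PER_HOUSEHOLD):
    """Convert household counts to people (default 5.27 people/household)."""
    if isinstance(households, RasterGrid):
        ok = households.mask()
        if (households.values[ok] < 0).any():
            raise ValueError("household counts must be non-negative")
        out = households.values.copy()
        out[ok] = out[ok] * people_per_household
        return households.copy_with(out)
    arr = np.asarray(households, float)
    if (arr < 0).any():
        raise ValueError("household counts must be non-negative")
    out = arr * people_per_household
    return float(out) if out.ndim == 0 else out
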