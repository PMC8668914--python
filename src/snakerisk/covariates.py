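"""Design-matrix construction: PPI scoring, distance to water, raster
extraction and the multiplicative covariate scalings.

Continuous covariates enter the model scaled down by powers of ten
(temperatures in tens of degrees, precipitation in hundreds of mm, livestock
in thousands of head, distances in km) so that all coefficients live on a
comparable logit scale and vague Gaussian priors behave well.  The design
table carries a ``scaled`` attribute so the scaling can never be applied
twice silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
import shapely

from .geo_io import PointTable, RasterGrid

__all__ = [
    "PpiLookup",
    "ScalingMap",
    "default_scalings",
    "ppi_score",
    "distance_to_water",
    "extract_at_points",
    "scale_covariates",
]

#: Multiplicative factors applied to raw covariate columns before modelling.
#: Distances are recorded in metres in raw survey exports (hence x0.001 to
#: km); PPI is recorded as a percent likelihood (x0.01 to a fraction);
#: temperatures are in 0.1 degC units after x0.1, precipitation in 100 mm
#: units, livestock head counts in thousands.
DEFAULT_SCALINGS: dict[str, float] = {
    "ndvi": 1.0,
    "dist_water": 0.001,
    "hmts": 1.0,
    "bio1": 0.1,
    "bio6": 0.1,
    "bio17": 0.01,
    "ppi": 0.01,
    "pig_density": 0.001,
    "sheep_density": 0.001,
}


def default_scalings() -> "ScalingMap":
    return ScalingMap(dict(DEFAULT_SCALINGS))


@dataclass
class ScalingMap:
    """Covariate name -> multiplicative factor."""

    factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALINGS))

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"scaling factor for {name!r} must be positive")

    def __getitem__(self, name: str) -> float:
        return self.factors[name]

    def __contains__(self, name: str) -> bool:
        return name in self.factors


@dataclass
class PpiLookup:
    """Poverty Probability Index lookup: integer score -> poverty likelihood.

    The national calibration tables map a 0-100 questionnaire score to the
    likelihood that the household falls under a poverty line.  The real
    country tables are distributed by their publishers and are supplied by
    the user as CSV (columns ``score``, ``likelihood``); scores must be
    unique and contiguous, likelihoods in [0, 1].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not {"score", "likelihood"} <= set(t.columns):
            raise ValueError("PPI lookup needs 'score' and 'likelihood' columns")
        scores = t["score"].to_numpy()
        if len(np.unique(scores)) != len(scores):
            raise ValueError("PPI lookup scores must be unique")
        t_sorted = t.sort_values("score").reset_index(drop=True)
        s = t_sorted["score"].to_numpy(int)
        if not np.array_equal(s, np.arange(s[0], s[0] + len(s))):
            raise ValueError("PPI lookup scores must be contiguous")
        lik = t_sorted["likelihood"].to_numpy(float)
        if ((lik < 0) | (lik > 1)).any():
            raise ValueError("PPI likelihoods must lie in [0, 1]")
        self.table = t_sorted
        self._map = dict(zip(s.tolist(), lik.tolist()))

    @classmethod
    def from_csv(cls, path) -> "PpiLookup":
        return cls(pd.read_csv(path))

    @classmethod
    def synthetic_linear(cls, max_score: int = 100) -> "PpiLookup":
        """Synthetic stand-in table mapping score s -> s/max_score.

        The real national tables are not redistributable; this linear table
        preserves the structure (monotone score -> likelihood in [0, 1]) for
        simulation and testing.
        """
        s = np.arange(max_score + 1)
        return cls(pd.DataFrame({"score": s, "likelihood": s / max_score}))

    def __call__(self, score: int) -> float:
        if score not in self._map:
            raise ValueError(f"PPI score {score} outside lookup domain")
        return self._map[score]


def ppi_score(
    answers: pd.DataFrame | dict,
    lookup: PpiLookup,
    items: tuple[str, ...] | None = None,
) -> np.ndarray | float:
    """Sum per-item questionnaire points and map through the lookup table.

    ``answers`` holds one integer point value per PPI item (columns of a
    DataFrame for many households, or a dict for one).  ``items`` names the
    item columns; by default every column starting with ``ppi_item`` is used.
    Returns the poverty likelihood in [0, 1].
    """
    single = isinstance(answers, dict)
    df = pd.DataFrame([answers]) if single else answers
    if items is None:
        items = tuple(c for c in df.columns if c.startswith("ppi_item"))
    if not items:
        raise ValueError("no PPI item columns found")
    missing = [c for c in items if c not in df.columns]
    if missing:
        raise ValueError(f"missing PPI items: {missing}")
    totals = df[list(items)].to_numpy(int).sum(axis=1)
    liks = np.array([lookup(int(t)) for t in totals])
    return float(liks[0]) if single else liks


def distance_to_water(points, water) -> np.ndarray:
    """Euclidean distance (km) from each point to the nearest water feature.

    ``points`` is a PointTable or an (n, 2) km array; ``water`` a sequence of
    shapely geometries (polylines or polygons, km).  Distance to a polygon's
    boundary-enclosed interior is zero for points inside it, matching the
    plain Euclidean nearest-waterbody definition.
    """
    if isinstance(points, PointTable):
        xy = points.coords
    else:
        xy = np.atleast_2d(np.asarray(points, float))
    water = list(water) if not isinstance(water, BaseGeometry) else [water]
    if len(water) == 0:
        raise ValueError("empty water feature set")
    tree = STRtree(water)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    nearest = tree.nearest(pts)
    return shapely.distance(pts, np.asarray(water, dtype=object)[nearest])


def extract_at_points(raster: RasterGrid, points, errors: str = "record"):
    """Raster value of the cell containing each point.

    Uses the half-open cell convention of :class:`RasterGrid`.  Nodata cells
    yield NaN.  Points outside the raster footprint yield NaN and are counted
    (``errors='record'``, the default) or raise (``errors='raise'``).

    Returns ``(values, n_outside)``.
    """
    if isinstance(points, PointTable):
        xy = points.coords
    else:
        xy = np.atleast_2d(np.asarray(points, float))
    row, col = raster.cell_index(xy[:, 0], xy[:, 1])
    outside = (row < 0) | (col < 0)
    n_outside = int(outside.sum())
    if n_outside and errors == "raise":
        raise ValueError(f"{n_outside} point(s) outside raster footprint")
    vals = np.full(len(xy), np.nan)
    ok = ~outside
    vals[ok] = raster.values[row[ok], col[ok]]
    vals[ok & np.isclose(vals, raster.nodata)] = np.nan
    return vals, n_outside


def scale_covariates(design: pd.DataFrame, scaling: ScalingMap) -> pd.DataFrame:
    """Multiply each named covariate column by its factor, exactly once.

    Columns not named in the map pass through unchanged (binary survey
    answers need no scaling).  A map entry naming a column absent from the
    table is an error, as is re-scaling an already-scaled table.
    """
    if design.attrs.get("scaled", False):
        raise ValueError("design table is already scaled; refusing to rescale")
    unknown = [name for name in scaling.factors if name not in design.columns]
    if unknown:
        raise ValueError(f"scaling map names absent covariates: {unknown}")
    out = design.copy()
    for name, f in scaling.factors.items():
        out[name] = out[name] * f
    out.attrs["scaled"] = True
    return out
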