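"""Risk classification and population-at-risk aggregation by admin unit.

Risk is classed by thresholds (default 0.01, 0.05, 0.1; comparison is
closed, >=); per administrative unit the population in cells at or above
each threshold is summed and expressed as a percentage of the unit's
adjusted population (cells masked out of the risk surface -- e.g. excluded
urban areas -- count in neither numerator nor denominator).  Cells are
assigned to the unit containing their centre, which keeps sums
partition-consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .geo_io import RasterGrid

__all__ = ["classify_risk", "zonal_population", "expected_cases", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.01, 0.05, 0.1)


def classify_risk(
    mean_risk: RasterGrid, thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
) -> dict[float, np.ndarray]:
    """Boolean mask per threshold: valid cells with risk >= t (nested)."""
    ts = list(thresholds)
    if ts != sorted(ts) or len(set(ts)) != len(ts):
        raise ValueError("thresholds must be strictly increasing")
    if any(not (0 < t < 1) for t in ts):
        raise ValueError("thresholds must lie in (0, 1)")
    valid = mean_risk.mask()
    return {t: valid & (mean_risk.values >= t) for t in ts}


def zonal_population(
    population: RasterGrid,
    masks: dict[float, np.ndarray],
    admin: dict,
    risk: RasterGrid | None = None,
) -> pd.DataFrame:
    """Population at risk per admin unit and threshold.

    ``population`` is a people-per-cell raster aligned with the risk raster
    the masks came from.  Rows carry the unit's adjusted population (valid
    cells only), the population in cells at or above each threshold, and
    the percentage of the adjusted population that represents.  Units with
    no valid cell are emitted with zeros and flagged.
    """
    if risk is not None and not population.same_geometry(risk):
        raise ValueError("population raster is not aligned with the risk raster")
    for m in masks.values():
        if m.shape != population.values.shape:
            raise ValueError("mask shape does not match the population raster")
    ids = list(admin)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate admin unit ids")

    cx, cy = population.cell_centers()
    pts = shapely.points(cx.ravel(), cy.ravel())
    pop_valid = population.mask()
    risk_valid = risk.mask() if risk is not None else np.ones_like(pop_valid)
    # a cell contributes only where both population and risk are defined
    base_valid = (pop_valid & risk_valid).ravel()
    pop_flat = population.values.ravel()

    rows = []
    for uid, geom in admin.items():
        inside = shapely.covers(geom, pts) & base_valid
        adjusted = float(pop_flat[inside].sum()) if inside.any() else 0.0
        row = {
            "unit_id": uid,
            "adjusted_pop": adjusted,
            "no_valid_cells": bool(not inside.any()),
        }
        for t, mask in masks.items():
            at_risk = float(pop_flat[inside & mask.ravel()].sum())
            row[f"pop_ge_{t:g}"] = at_risk
            row[f"pct_ge_{t:g}"] = 100.0 * at_risk / adjusted if adjusted > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def expected_cases(population_at_risk: float, risk_level: float) -> float:
    """Expected annual cases: population at risk x risk level.

    Report-layer convention rounds to the nearest ten; this returns the
    exact product.
    """
    if population_at_risk < 0:
        raise ValueError("population must be non-negative")
    if not (0 <= risk_level <= 1):
        raise ValueError("risk level must lie in [0, 1]")
    return float(population_at_risk) * float(risk_level)


def round_cases(cases: float) -> int:
    """Nearest-ten rounding used when reporting expected case counts."""
    return int(round(cases / 10.0) * 10)
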