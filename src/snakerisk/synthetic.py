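"""Synthetic survey landscapes with the statistical structure the analysis
assumes.

The generator emulates a Terai-style setting: a long plains region surveyed
by a multi-cluster random household survey (249 clusters of ~53 households
by default, ~13,000 households), with smooth gridded environmental
covariates (NDVI, bioclimatic temperature/precipitation surfaces within
their reported real-world ranges, livestock densities, a human-modification
index, household density), random permanent-water polylines, an
administrative partition, and binary snakebite outcomes drawn from the
hierarchical logistic model: logit risk = intercept + scaled covariates
times their logit-scale effects + a Matérn (nu=1) spatial random field.
Default effect sizes are the fitted human-model posterior means; an animal
preset carries the animal-model effects with its much longer spatial range.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist
from scipy.special import expit
from shapely.geometry import LineString, box

from .covariates import PpiLookup, ScalingMap, distance_to_water, extract_at_points, ppi_score, scale_covariates
from .geo_io import PointTable, RasterGrid
from .model import matern_correlation

__all__ = [
    "SyntheticConfig",
    "SyntheticSurvey",
    "simulate_matern_grf",
    "generate_covariate_surfaces",
    "sample_households",
    "generate_outcomes",
    "generate_survey",
]

#: Human-model posterior-mean effects (logit scale, on scaled covariates).
HUMAN_EFFECTS: dict[str, float] = {
    "food_storage": 1.02,
    "straw_storage": 0.58,
    "sleep_floor": -0.77,
    "ppi": 4.16,
    "ndvi": -1.43,
    "dist_water": 0.32,
}

#: Animal-model posterior-mean effects (logit scale, on scaled covariates).
ANIMAL_EFFECTS: dict[str, float] = {
    "animal_shed": 1.84,
    "straw_storage": 0.50,
    "hmts": -2.01,
    "bio6": 3.15,
    "pig_density": 0.82,
    "sheep_density": 2.09,
}

#: Per-surface (smoothness_km, (low, high)) value ranges.  BIO6 and BIO17
#: spans follow the reported Terai ranges (1.8-10.9 degC; 18-71 mm); the
#: others are realistic plains values.
DEFAULT_SURFACES: dict[str, tuple[float, tuple[float, float]]] = {
    "ndvi": (10.0, (0.0, 1.0)),
    "bio1": (40.0, (17.0, 25.0)),
    "bio6": (40.0, (1.8, 10.9)),
    "bio17": (40.0, (18.0, 71.0)),
    "hmts": (15.0, (0.0, 1.0)),
    "pig_density": (15.0, (0.0, 2000.0)),
    "sheep_density": (15.0, (0.0, 3000.0)),
    "household_density": (15.0, (0.0, 300.0)),
}

#: Binary survey-answer prevalences.
DEFAULT_ANSWER_PREVALENCE: dict[str, float] = {
    "food_storage": 0.5,
    "straw_storage": 0.4,
    "sleep_floor": 0.3,
    "animal_shed": 0.5,
}

#: Scalings matching the units this generator produces: distances are
#: already km and the PPI is already a likelihood in [0, 1], so only the
#: climatic and livestock surfaces are scaled down.
GENERATOR_SCALINGS: dict[str, float] = {
    "ndvi": 1.0,
    "dist_water": 1.0,
    "hmts": 1.0,
    "bio1": 0.1,
    "bio6": 0.1,
    "bio17": 0.01,
    "ppi": 1.0,
    "pig_density": 0.001,
    "sheep_density": 0.001,
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic survey; defaults are the study conditions."""

    region_extent: tuple[float, float] = (800.0, 50.0)  # km
    n_clusters: int = 249
    households_per_cluster: int = 53
    cluster_radius: float = 1.5  # km
    true_beta: dict[str, float] = field(default_factory=lambda: dict(HUMAN_EFFECTS))
    intercept: float = -2.21
    spatial_sd: float = 1.0
    spatial_range: float = 30.0  # km
    covariate_field_params: dict = field(default_factory=lambda: dict(DEFAULT_SURFACES))
    answer_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANSWER_PREVALENCE)
    )
    outcome_prevalence_target: float | None = 0.0118
    raster_cell_km: float = 1.0
    n_water_features: int = 15
    admin_grid: tuple[int, int] = (8, 2)
    dense_limit: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.region_extent
        if not (w > 0 and h > 0):
            raise ValueError("region extent must be positive")
        if self.n_clusters < 1 or self.households_per_cluster < 1:
            raise ValueError("need at least one cluster and one household per cluster")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be non-negative")
        if not self.spatial_range > 0:
            raise ValueError("spatial_range must be positive")
        if 2 * self.cluster_radius > min(w, h):
            raise ValueError("cluster_radius too large for the region")

    @classmethod
    def animal(cls, **overrides) -> "SyntheticConfig":
        """Preset with the animal-model effects and its long spatial range."""
        defaults = dict(
            true_beta=dict(ANIMAL_EFFECTS),
            intercept=-5.38,
            spatial_sd=0.77,
            spatial_range=430.0,
            outcome_prevalence_target=0.007,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticSurvey:
    """One realized survey: households, landscape, and the generating truth."""

    households: pd.DataFrame          # hh_id, cluster_id, x, y, answers, outcome
    rasters: dict[str, RasterGrid]
    water: list
    admin: dict
    design: pd.DataFrame              # scaled model design matrix
    design_raw: pd.DataFrame
    u_true: np.ndarray                # realized latent field per household
    config: SyntheticConfig
    intercept_realized: float         # after prevalence calibration

    def point_table(self) -> PointTable:
        return PointTable(data=self.households.copy())

    @property
    def coords(self) -> np.ndarray:
        return self.households[["x", "y"]].to_numpy(float)


# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_matern_grf(locations, sigma: float, range_rho: float, seed=None) -> np.ndarray:
    """One draw of a zero-mean Matérn (nu=1) Gaussian field at given km points.

    Dense Cholesky factorisation of the correlation matrix; coincident
    points are handled by a 1e-8 diagonal jitter (warned).  ``sigma = 0``
    returns exact zeros.
    """
    locs = np.atleast_2d(np.asarray(locations, float))
    if not np.isfinite(locs).all():
        raise ValueError("locations must be finite")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    n = len(locs)
    if sigma == 0:
        return np.zeros(n)
    rng = _rng(seed)
    d = cdist(locs, locs)
    if n > 1 and (d[~np.eye(n, dtype=bool)] == 0).any():
        warnings.warn("coincident locations; adding diagonal jitter", stacklevel=2)
    R = matern_correlation(d, range_rho) + 1e-8 * np.eye(n)
    L = np.linalg.cholesky(R)
    return sigma * (L @ rng.standard_normal(n))


def generate_covariate_surfaces(config: SyntheticConfig, seed=None):
    """Smooth random surfaces, water polylines and an admin partition.

    Each surface is white noise low-pass filtered at its configured
    smoothness (km) and min-max rescaled into its configured value range;
    smoothness 0 leaves pure white noise within the range.  Returns
    ``(rasters, water, admin)``.
    """
    rng = _rng(config.seed if seed is None else seed)
    w, h = config.region_extent
    cs = config.raster_cell_km
    n_cols = max(int(round(w / cs)), 1)
    n_rows = max(int(round(h / cs)), 1)

    rasters: dict[str, RasterGrid] = {}
    for name, (smooth_km, (lo, hi)) in config.covariate_field_params.items():
        z = rng.standard_normal((n_rows, n_cols))
        if smooth_km > 0:
            z = gaussian_filter(z, sigma=smooth_km / cs, mode="reflect")
        zmin, zmax = z.min(), z.max()
        if zmax > zmin:
            z = (z - zmin) / (zmax - zmin)
        else:  # constant field (e.g. 1x1 raster)
            z = np.full_like(z, 0.5)
        rasters[name] = RasterGrid(
            origin=(0.0, 0.0), cell_size=cs, values=lo + z * (hi - lo)
        )

    water = []
    for _ in range(config.n_water_features):
        n_pts = int(rng.integers(3, 7))
        xs = np.sort(rng.uniform(0, w, n_pts))
        ys = rng.uniform(0, h, n_pts)
        water.append(LineString(np.column_stack([xs, ys])))

    gx, gy = config.admin_grid
    admin = {}
    for i in range(gx):
        for j in range(gy):
            uid = f"U{i * gy + j + 1:02d}"
            admin[uid] = box(i * w / gx, j * h / gy, (i + 1) * w / gx, (j + 1) * h / gy)
    return rasters, water, admin


def sample_households(config: SyntheticConfig, seed=None) -> pd.DataFrame:
    """Cluster centres uniform in the region, households uniform in discs.

    Cluster centres are inset by the cluster radius so every household falls
    inside the region.  Binary survey answers are Bernoulli draws at the
    configured prevalences; ten PPI items carry integer points 0-10 so the
    summed score spans the 0-100 lookup domain.
    """
    rng = _rng(config.seed if seed is None else seed)
    w, h = config.region_extent
    r = config.cluster_radius
    nc, hpc = config.n_clusters, config.households_per_cluster

    cx = rng.uniform(r, w - r, nc)
    cy = rng.uniform(r, h - r, nc)
    cluster_id = np.repeat(np.arange(1, nc + 1), hpc)
    theta = rng.uniform(0, 2 * np.pi, nc * hpc)
    rad = r * np.sqrt(rng.uniform(0, 1, nc * hpc))
    x = np.repeat(cx, hpc) + rad * np.cos(theta)
    y = np.repeat(cy, hpc) + rad * np.sin(theta)

    df = pd.DataFrame(
        {
            "hh_id": np.arange(1, nc * hpc + 1),
            "cluster_id": cluster_id,
            "x": x,
            "y": y,
        }
    )
    for name, prev in config.answer_prevalence.items():
        df[name] = (rng.uniform(size=len(df)) < prev).astype(int)
    for k in range(1, 11):
        df[f"ppi_item_{k}"] = rng.integers(0, 11, len(df))
    return df


def _assemble_design(
    households: pd.DataFrame,
    rasters: dict[str, RasterGrid],
    water,
    ppi_lookup: PpiLookup | None = None,
) -> pd.DataFrame:
    """Raw (unscaled) design matrix for the generator's covariate set."""
    pts = households[["x", "y"]].to_numpy(float)
    design = pd.DataFrame(index=households.index)
    for name, grid in rasters.items():
        if name == "household_density":
            continue
        vals, n_out = extract_at_points(grid, pts)
        if n_out:
            raise ValueError(f"{n_out} households outside the {name} raster")
        design[name] = vals
    design["dist_water"] = distance_to_water(pts, water)
    lookup = ppi_lookup or PpiLookup.synthetic_linear()
    design["ppi"] = ppi_score(households, lookup)
    for name in DEFAULT_ANSWER_PREVALENCE:
        if name in households.columns:
            design[name] = households[name].to_numpy(float)
    return design


def generate_outcomes(
    households: pd.DataFrame,
    rasters: dict[str, RasterGrid],
    water,
    config: SyntheticConfig,
    seed=None,
    ppi_lookup: PpiLookup | None = None,
):
    """Draw binary outcomes from the hierarchical model.

    eta = intercept + X beta + u, with X the scaled design and u one Matérn
    field draw; outcomes ~ Bernoulli(expit(eta)).  When the config sets a
    prevalence target, the intercept is calibrated by bisection on the
    realized mean of expit(eta).  Above the dense limit the field is drawn
    at cluster centres and shared within clusters (within-cluster variation
    is negligible when the range is much larger than the cluster radius).

    Returns ``(outcome, u, design_scaled, design_raw, intercept_used)``.
    """
    rng = _rng(config.seed if seed is None else seed)
    design_raw = _assemble_design(households, rasters, water, ppi_lookup)
    missing = [c for c in config.true_beta if c not in design_raw.columns]
    if missing:
        raise ValueError(f"true_beta names covariates absent from the design: {missing}")

    scaling = ScalingMap({c: GENERATOR_SCALINGS.get(c, 1.0) for c in design_raw.columns})
    design = scale_covariates(design_raw, scaling)

    coords = households[["x", "y"]].to_numpy(float)
    if len(households) <= config.dense_limit:
        u = simulate_matern_grf(coords, config.spatial_sd, config.spatial_range, rng)
    else:
        centers = households.groupby("cluster_id")[["x", "y"]].mean()
        u_c = simulate_matern_grf(
            centers.to_numpy(float), config.spatial_sd, config.spatial_range, rng
        )
        u = pd.Series(u_c, index=centers.index).loc[households["cluster_id"]].to_numpy()

    names = list(config.true_beta)
    fixed = design[names].to_numpy(float) @ np.array([config.true_beta[c] for c in names])
    base = fixed + u

    b0 = config.intercept
    if config.outcome_prevalence_target is not None:
        target = config.outcome_prevalence_target

        def realized(b):
            return float(np.mean(expit(b + base))) - target

        lo, hi = -40.0, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if realized(mid) > 0:
                hi = mid
            else:
                lo = mid
        b0 = 0.5 * (lo + hi)

    pi = expit(b0 + base)
    outcome = (rng.uniform(size=len(pi)) < pi).astype(int)
    return outcome, u, design, design_raw, b0


def write_survey(survey: SyntheticSurvey, outdir) -> None:
    """Write a survey to disk: CSV households (metres), .asc rasters,
    GeoJSON water/admin, YAML truth sidecar plus a truth CSV of u."""
    import yaml
    from pathlib import Path

    from .geo_io import write_point_csv, write_polygons, write_polylines, write_raster

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_point_csv(survey.point_table(), outdir / "households.csv")
    (outdir / "rasters").mkdir(exist_ok=True)
    for name, grid in survey.rasters.items():
        write_raster(grid, outdir / "rasters" / f"{name}.asc")
    write_polylines(survey.water, outdir / "water.geojson")
    write_polygons(survey.admin, outdir / "admin.geojson")
    truth = asdict(survey.config)
    truth["intercept_realized"] = survey.intercept_realized
    for key in ("region_extent", "admin_grid"):
        truth[key] = list(truth[key])
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=False))
    pd.DataFrame(
        {"hh_id": survey.households["hh_id"], "u_true": survey.u_true}
    ).to_csv(outdir / "truth_u.csv", index=False)


def generate_survey(config: SyntheticConfig) -> SyntheticSurvey:
    """Full deterministic survey generation from one config."""
    rng = _rng(config.seed)
    rasters, water, admin = generate_covariate_surfaces(config, rng)
    households = sample_households(config, rng)
    outcome, u, design, design_raw, b0 = generate_outcomes(
        households, rasters, water, config, rng
    )
    households = households.copy()
    households["outcome_human"] = outcome
    return SyntheticSurvey(
        households=households,
        rasters=rasters,
        water=water,
        admin=admin,
        design=design,
        design_raw=design_raw,
        u_true=u,
        config=config,
        intercept_realized=b0,
    )
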