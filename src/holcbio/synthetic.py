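"""Synthetic HOLC study regions and contributory observation data.

Generates planar study regions (cities of rectangular graded neighborhoods
plus an impervious-surface grid) and two kinds of observation data with known
ground truth:

* model mode — per-neighborhood richness counts drawn directly from the
  hierarchical Poisson richness model (:func:`simulate_richness`), used for
  parameter-recovery checks;
* record mode — individual observation records drawn from grade/city species
  pools with geometric-series abundances and negative-binomial per-
  neighborhood effort (:func:`simulate_observation_records`), used to
  exercise the full ingest → accumulation → model → beta-diversity pipeline.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from .errors import ConfigurationError, FormatError
from .ingest import (
    CLADES,
    GRADES,
    ImperviousGrid,
    attach_impervious,
    write_esri_ascii,
)

from . import __version__ as _VERSION

#: Observation window emulating the five-year contributory-data slice.
DEFAULT_WINDOW = ("2017-01-01", "2022-01-01")

_CITY_SPACING_FACTOR = 1.35  # city bounding boxes are spread apart by this


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class RegionConfig:
    """Layout of the synthetic study region.

    Defaults emulate four HOLC-mapped cities with graded neighborhoods of
    around a square kilometre, impervious surface increasing from grade A
    ("greenlined") to grade D ("redlined"), and heavy-tailed per-neighborhood
    observation effort.
    """

    n_cities: int = 4
    grades: tuple[str, ...] = GRADES
    neighborhoods_per_grade_per_city: int = 11
    area_range_km2: tuple[float, float] = (0.5, 2.5)
    impervious_by_grade: Mapping[str, float] = field(
        default_factory=lambda: {"A": 35.0, "B": 45.0, "C": 55.0, "D": 65.0}
    )
    impervious_noise_sd: float = 5.0
    grid_cell_km: float = 0.25
    effort_mean: float = 150.0
    effort_dispersion: float = 5.0

    def __post_init__(self) -> None:
        _check(self.n_cities >= 1, "n_cities must be >= 1")
        _check(len(self.grades) >= 1, "at least one grade required")
        _check(
            self.neighborhoods_per_grade_per_city >= 1,
            "neighborhoods_per_grade_per_city must be >= 1",
        )
        lo, hi = self.area_range_km2
        _check(0 < lo <= hi, "area_range_km2 must be a positive interval")
        for g in self.grades:
            _check(g in self.impervious_by_grade, f"no impervious mean for grade {g}")
            _check(
                0 <= self.impervious_by_grade[g] <= 100,
                "impervious means must lie in [0, 100]",
            )
        _check(self.grid_cell_km > 0, "grid_cell_km must be positive")
        _check(self.effort_mean > 0, "effort_mean must be positive")
        _check(self.effort_dispersion > 0, "effort_dispersion must be positive")


@dataclass
class TruthParams:
    """Generative parameters of the richness model (log scale).

    ``b_grade`` holds effects for the non-reference grades (grade A fixed at
    0); ``b_imp`` is per standard deviation of impervious surface.
    ``city_effects`` holds realized city deviations; when ``None`` they are
    drawn from Normal(0, sigma) at simulation time.
    """

    b0: float = -2.2
    b_grade: dict[str, float] = field(
        default_factory=lambda: {"B": -0.33, "C": -0.55, "D": -1.30}
    )
    b_imp: float = -0.1
    sigma_city_intercept: float = 0.5
    sigma_city_slope: float = 0.3
    city_effects: dict | None = None

    def __post_init__(self) -> None:
        _check(self.sigma_city_intercept > 0, "sigma_city_intercept must be > 0")
        _check(self.sigma_city_slope > 0, "sigma_city_slope must be > 0")


@dataclass(frozen=True)
class CommunityConfig:
    """Species-pool and effort structure for record-mode simulation.

    Grade pools are nested: the grade-A master pool is drawn first and each
    lower grade reuses ``pool_overlap`` of the adjacent grade's pool. Each
    city substitutes a fraction ``1 - city_overlap`` of the master species
    with city-specific counterparts, preserving the within-city grade-overlap
    structure exactly (``pool_overlap=1`` gives identical grade pools within
    every city — the beta-diversity null).
    """

    pool_size_by_grade: Mapping[str, int] = field(
        default_factory=lambda: {"A": 160, "B": 130, "C": 100, "D": 70}
    )
    pool_overlap: float = 0.7
    city_overlap: float = 0.7
    native_fraction: float = 0.7
    abundance_shape: float = 0.03
    effort_mean: float = 150.0
    effort_dispersion: float = 5.0
    clade_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "bird": 0.45,
            "insect": 0.25,
            "mammal": 0.12,
            "reptile": 0.08,
            "amphibian": 0.05,
            "arachnid": 0.05,
        }
    )

    def __post_init__(self) -> None:
        for g, n in self.pool_size_by_grade.items():
            _check(n >= 1, f"pool size for grade {g} must be >= 1")
        for name, val in (
            ("pool_overlap", self.pool_overlap),
            ("city_overlap", self.city_overlap),
            ("native_fraction", self.native_fraction),
            ("abundance_shape", self.abundance_shape),
        ):
            _check(0 <= val <= 1, f"{name} must lie in [0, 1]")
        _check(
            abs(sum(self.clade_weights.values()) - 1.0) < 1e-9,
            "clade_weights must sum to 1",
        )
        _check(self.effort_mean > 0, "effort_mean must be positive")
        _check(self.effort_dispersion > 0, "effort_dispersion must be positive")


@dataclass
class Region:
    """A generated study region: neighborhood table + impervious grid.

    The neighborhood table carries id, city, grade, rectangle bounds,
    area (km²), zonal-mean impervious %, and a model-mode effort column.
    """

    neighborhoods: pd.DataFrame
    grid: ImperviousGrid
    seed: int
    config: RegionConfig


def _negbin(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial draws parameterized by mean and dispersion (size) k."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def make_region(config: RegionConfig, seed: int) -> Region:
    """Generate a study region: rectangular neighborhoods on per-city grids.

    Deterministic given (config, seed). Polygons are non-overlapping
    axis-aligned rectangles; each neighborhood's impervious value is the
    zonal mean of the generated grid over its polygon.
    """
    rng = np.random.default_rng(seed)
    n_grades = len(config.grades)
    m_city = n_grades * config.neighborhoods_per_grade_per_city
    lo, hi = config.area_range_km2
    slot = math.sqrt(hi) * 1.8  # rectangle always fits with a margin
    ncols_city = math.ceil(math.sqrt(m_city))
    nrows_city = math.ceil(m_city / ncols_city)
    city_w = ncols_city * slot
    city_h = nrows_city * slot
    cities_per_row = math.ceil(math.sqrt(config.n_cities))

    rows = []
    for ci in range(config.n_cities):
        city = f"City{ci + 1:02d}"
        cx0 = (ci % cities_per_row) * city_w * _CITY_SPACING_FACTOR
        cy0 = (ci // cities_per_row) * city_h * _CITY_SPACING_FACTOR
        # interleave grades across the city grid
        labels = [config.grades[k % n_grades] for k in range(m_city)]
        for k, grade in enumerate(labels):
            r, c = divmod(k, ncols_city)
            area = rng.uniform(lo, hi)
            aspect = rng.uniform(0.7, 1.4)
            w = math.sqrt(area * aspect)
            h = area / w
            x0 = cx0 + c * slot + 0.5 * (slot - w)
            y0 = cy0 + r * slot + 0.5 * (slot - h)
            idx = k // n_grades
            rows.append(
                {
                    "neighborhood_id": f"{city}-{grade}-{idx:03d}",
                    "city": city,
                    "holc_grade": grade,
                    "x0": x0,
                    "y0": y0,
                    "x1": x0 + w,
                    "y1": y0 + h,
                    "area_km2": area,
                }
            )
    nb = pd.DataFrame(rows)
    nb["geometry"] = [
        shapely_box(r.x0, r.y0, r.x1, r.y1) for r in nb.itertuples()
    ]
    nb["effort"] = np.maximum(
        1, _negbin(rng, config.effort_mean, config.effort_dispersion, len(nb))
    )

    grid = _make_impervious_grid(nb, config, rng)
    nb = attach_impervious(nb, grid)
    order = np.argsort(nb["neighborhood_id"].to_numpy())
    nb = nb.iloc[order].reset_index(drop=True)
    return Region(neighborhoods=nb, grid=grid, seed=seed, config=config)


def _make_impervious_grid(
    nb: pd.DataFrame, config: RegionConfig, rng: np.random.Generator
) -> ImperviousGrid:
    cell = config.grid_cell_km
    pad = 2 * cell
    xmin = float(nb["x0"].min()) - pad
    ymin = float(nb["y0"].min()) - pad
    xmax = float(nb["x1"].max()) + pad
    ymax = float(nb["y1"].max()) + pad
    ncols = math.ceil((xmax - xmin) / cell)
    nrows = math.ceil((ymax - ymin) / cell)
    background = float(np.mean([config.impervious_by_grade[g] for g in config.grades]))
    values = np.full((nrows, ncols), background)
    # fill each rectangle's covered cells with the grade mean + noise
    for r in nb.itertuples():
        c0 = int(np.floor((r.x0 - xmin) / cell))
        c1 = int(np.ceil((r.x1 - xmin) / cell))
        row_hi = nrows - int(np.floor((r.y0 - ymin) / cell))
        row_lo = nrows - int(np.ceil((r.y1 - ymin) / cell))
        mean = config.impervious_by_grade[r.holc_grade]
        blockshape = (max(row_hi - row_lo, 1), max(c1 - c0, 1))
        noise = rng.normal(0.0, config.impervious_noise_sd, size=blockshape)
        values[row_lo:row_lo + blockshape[0], c0:c0 + blockshape[1]] = np.clip(
            mean + noise, 0.0, 100.0
        )
    return ImperviousGrid(values=values, xll=xmin, yll=ymin, cellsize=cell)


# ---------------------------------------------------------------------------
# Model mode
# ---------------------------------------------------------------------------


def simulate_richness(
    region: Region,
    truth: TruthParams,
    seed: int,
    offset_mode: str = "product",
) -> tuple[pd.DataFrame, TruthParams]:
    """Draw per-neighborhood richness counts from the Poisson richness model.

    log mu_i = offset_i + b0 + u0_city + (b_g + u_{g,city}) + b_imp * z_i
    with the offset log(area_i * effort_i) (or log(area_i + effort_i) under
    ``offset_mode="sum"``) and z the standardized impervious percentage.
    Returns the richness table and the truth with realized city effects
    filled in (drawn from Normal(0, sigma) when not supplied).
    """
    nb = region.neighborhoods
    if (nb["effort"] < 1).any():
        raise ConfigurationError("every neighborhood needs effort >= 1 (offset)")
    rng = np.random.default_rng(seed)
    cities = sorted(nb["city"].unique())
    nonref = [g for g in region.config.grades if g != region.config.grades[0]]

    if truth.city_effects is None:
        city_effects = {
            "intercept": {
                c: float(rng.normal(0.0, truth.sigma_city_intercept)) for c in cities
            },
            "slope": {
                g: {c: float(rng.normal(0.0, truth.sigma_city_slope)) for c in cities}
                for g in nonref
            },
        }
        truth = TruthParams(
            b0=truth.b0,
            b_grade=dict(truth.b_grade),
            b_imp=truth.b_imp,
            sigma_city_intercept=truth.sigma_city_intercept,
            sigma_city_slope=truth.sigma_city_slope,
            city_effects=city_effects,
        )
    eff = truth.city_effects

    imp = nb["impervious"].to_numpy(float)
    z = (imp - imp.mean()) / imp.std() if imp.std() > 0 else np.zeros_like(imp)
    area = nb["area_km2"].to_numpy(float)
    effort = nb["effort"].to_numpy(float)
    if offset_mode == "product":
        offset = np.log(area) + np.log(effort)
    elif offset_mode == "sum":
        offset = np.log(area + effort)
    else:
        raise ConfigurationError(f"unknown offset_mode {offset_mode!r}")

    eta = offset + truth.b0 + truth.b_imp * z
    for i, r in enumerate(nb.itertuples()):
        eta[i] += eff["intercept"][r.city]
        if r.holc_grade != region.config.grades[0]:
            eta[i] += truth.b_grade[r.holc_grade] + eff["slope"][r.holc_grade][r.city]
    y = rng.poisson(np.exp(eta))

    out = nb[
        ["neighborhood_id", "city", "holc_grade", "area_km2", "impervious"]
    ].copy()
    out["richness"] = y
    out["n_obs"] = nb["effort"].to_numpy()
    return out, truth


# ---------------------------------------------------------------------------
# Record mode
# ---------------------------------------------------------------------------


def _build_species_pools(
    config: CommunityConfig, cities: list[str], grades: tuple[str, ...],
    rng: np.random.Generator
) -> dict:
    """Master grade pools with nested overlap, then per-city substitution.

    Returns per-(city, grade) lists of species indices into a global species
    table with name / clade / native columns.
    """
    clade_names = list(config.clade_weights.keys())
    clade_p = np.array([config.clade_weights[c] for c in clade_names])

    species: list[dict] = []

    def new_species() -> int:
        i = len(species)
        clade = clade_names[rng.choice(len(clade_names), p=clade_p)]
        native = rng.random() < config.native_fraction
        species.append(
            {
                "species": f"Species {i:05d}",
                "clade": clade,
                "native": "native" if native else "introduced",
            }
        )
        return i

    # nested master pools, ordered by abundance rank
    master: dict[str, list[int]] = {}
    prev: list[int] = []
    for g in grades:
        size = int(config.pool_size_by_grade[g])
        pool: list[int] = []
        n_shared = min(len(prev), int(round(config.pool_overlap * size)))
        if n_shared:
            shared = rng.choice(len(prev), size=n_shared, replace=False)
            pool.extend(prev[j] for j in sorted(shared))
        while len(pool) < size:
            pool.append(new_species())
        master[g] = pool
        prev = pool

    # per-city substitution: each master species is either kept city-wide or
    # replaced by a city-specific counterpart (same clade and native status)
    all_master = sorted({s for pool in master.values() for s in pool})
    pools: dict[tuple[str, str], list[int]] = {}
    for city in cities:
        subst: dict[int, int] = {}
        for s in all_master:
            if rng.random() < config.city_overlap:
                subst[s] = s
            else:
                i = len(species)
                species.append(
                    {
                        "species": f"Species {i:05d}",
                        "clade": species[s]["clade"],
                        "native": species[s]["native"],
                    }
                )
                subst[s] = i
        for g in grades:
            pools[(city, g)] = [subst[s] for s in master[g]]

    return {"table": pd.DataFrame(species), "pools": pools}


def simulate_observation_records(
    region: Region,
    community: CommunityConfig,
    seed: int,
    window: tuple[str, str] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Draw an observation-record table from the region's species pools.

    Per-neighborhood record counts are negative binomial (mean, dispersion);
    species are drawn from the neighborhood's (city, grade) pool with
    geometric-series abundances; points are uniform within the neighborhood
    rectangle; dates uniform within the half-open window. The returned frame
    carries a ``true_neighborhood`` column with the generating neighborhood.
    """
    nb = region.neighborhoods
    if nb.empty:
        raise ConfigurationError("region has no neighborhoods")
    rng = np.random.default_rng(seed)
    cities = sorted(nb["city"].unique())
    built = _build_species_pools(community, cities, region.config.grades, rng)
    sp_table: pd.DataFrame = built["table"]
    pools = built["pools"]

    t0 = pd.Timestamp(window[0])
    t1 = pd.Timestamp(window[1])
    n_days = (t1 - t0).days
    if n_days <= 0:
        raise ConfigurationError("window must be a positive date range")

    theta = community.abundance_shape
    frames = []
    rid = 0
    for r in nb.itertuples():
        n = int(_negbin(rng, community.effort_mean, community.effort_dispersion, None))
        if n == 0:
            continue
        pool = np.asarray(pools[(r.city, r.holc_grade)])
        if theta > 0:
            w = (1 - theta) ** np.arange(len(pool))
            w = w / w.sum()
        else:
            w = np.full(len(pool), 1.0 / len(pool))
        idx = pool[rng.choice(len(pool), size=n, p=w)]
        xs = rng.uniform(r.x0, r.x1, size=n)
        ys = rng.uniform(r.y0, r.y1, size=n)
        days = rng.integers(0, n_days, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "id": np.arange(rid, rid + n),
                    "observed_on": t0 + pd.to_timedelta(days, unit="D"),
                    "latitude": ys,
                    "longitude": xs,
                    "scientific_name": sp_table["species"].to_numpy()[idx],
                    "clade": sp_table["clade"].to_numpy()[idx],
                    "quality_grade": "research",
                    "establishment": sp_table["native"].to_numpy()[idx],
                    "true_neighborhood": r.neighborhood_id,
                }
            )
        )
        rid += n
    if not frames:
        raise ConfigurationError("no records generated (effort too low)")
    return pd.concat(frames, ignore_index=True)


def as_ingested(records: pd.DataFrame) -> pd.DataFrame:
    """Rename a simulated record table to the ingest-side logical columns.

    Shortcut for in-memory analyses that skip the CSV round trip; the
    ``neighborhood_id`` column is taken from the generator's ground truth.
    """
    return pd.DataFrame(
        {
            "record_id": records["id"].astype(str),
            "observed_on": pd.to_datetime(records["observed_on"]),
            "latitude": records["latitude"],
            "longitude": records["longitude"],
            "species": records["scientific_name"],
            "clade": records["clade"],
            "quality": records["quality_grade"],
            "native": records["establishment"],
            "neighborhood_id": records["true_neighborhood"],
        }
    )


# ---------------------------------------------------------------------------
# Writers / readers
# ---------------------------------------------------------------------------


def write_region_geojson(region: Region, path) -> None:
    """Write neighborhoods as a GeoJSON FeatureCollection (deterministic bytes)."""
    features = []
    for r in region.neighborhoods.itertuples():
        coords = [
            [r.x0, r.y0], [r.x1, r.y0], [r.x1, r.y1], [r.x0, r.y1], [r.x0, r.y0]
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "neighborhood_id": r.neighborhood_id,
                    "city": r.city,
                    "holc_grade": r.holc_grade,
                    "area_km2": r.area_km2,
                },
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "metadata": {"generator": f"holcbio {_VERSION}", "seed": region.seed},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_records_csv(records: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the observation table with a metadata comment line."""
    cols = [
        "id", "observed_on", "latitude", "longitude", "scientific_name",
        "clade", "quality_grade", "establishment",
    ]
    out = records[cols].copy()
    out["observed_on"] = pd.to_datetime(out["observed_on"]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(f"# holcbio {_VERSION} seed={seed}\n")
        out.to_csv(fh, index=False)


def write_impervious_grid(region: Region, path) -> None:
    write_esri_ascii(region.grid, path)


_TRUTH_REQUIRED = (
    "b0", "b_grade", "b_imp", "sigma_city_intercept", "sigma_city_slope"
)


def write_truth(truth: TruthParams, path, seed: int | None = None) -> None:
    doc = {"generator": f"holcbio {_VERSION}", "seed": seed, **asdict(truth)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_truth(path) -> TruthParams:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"truth file is not valid JSON: {exc}") from exc
    for name in _TRUTH_REQUIRED:
        if name not in doc:
            raise FormatError(f"truth file missing required field {name!r}")
    return TruthParams(
        b0=float(doc["b0"]),
        b_grade={k: float(v) for k, v in doc["b_grade"].items()},
        b_imp=float(doc["b_imp"]),
        sigma_city_intercept=float(doc["sigma_city_intercept"]),
        sigma_city_slope=float(doc["sigma_city_slope"]),
        city_effects=doc.get("city_effects"),
    )
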