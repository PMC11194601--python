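"""Ingest HOLC polygons, observation CSVs, and impervious-surface grids.

Applies the record filters used throughout the analysis (research-grade
quality, species present, five-year date window), assigns observation points
to HOLC neighborhood polygons, applies the per-city grade-by-clade inclusion
rule, computes zonal mean impervious surface, and builds the per-neighborhood
species-richness table that the alpha-diversity model consumes.

All geometry is planar: synthetic data is generated in planar km and real
data must be pre-projected before ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.strtree import STRtree

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

GRADES = ("A", "B", "C", "D")
CLADES = ("bird", "mammal", "insect", "arachnid", "reptile", "amphibian")

#: Common taxon labels mapped onto the closed six-clade vocabulary.
CLADE_ALIASES: dict[str, str] = {
    "aves": "bird",
    "bird": "bird",
    "birds": "bird",
    "mammalia": "mammal",
    "mammal": "mammal",
    "mammals": "mammal",
    "insecta": "insect",
    "insect": "insect",
    "insects": "insect",
    "arachnida": "arachnid",
    "arachnid": "arachnid",
    "arachnids": "arachnid",
    "reptilia": "reptile",
    "reptile": "reptile",
    "reptiles": "reptile",
    "amphibia": "amphibian",
    "amphibian": "amphibian",
    "amphibians": "amphibian",
}

#: Logical record fields and the default (synthetic-writer) column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "record_id": "id",
    "observed_on": "observed_on",
    "latitude": "latitude",
    "longitude": "longitude",
    "species": "scientific_name",
    "clade": "clade",
    "quality": "quality_grade",
    "establishment": "establishment",
}


# ---------------------------------------------------------------------------
# Filter bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Counts of records dropped by each named rule, in application order.

    Invariant: for every step, retained + dropped = input.
    """

    steps: list[dict] = field(default_factory=list)
    retained_cities: list[str] = field(default_factory=list)

    def add(self, rule: str, n_in: int, n_dropped: int) -> None:
        if n_dropped < 0 or n_dropped > n_in:
            raise ValueError(f"rule {rule!r}: dropped {n_dropped} of {n_in}")
        self.steps.append(
            {"rule": rule, "n_in": int(n_in), "n_dropped": int(n_dropped),
             "n_out": int(n_in - n_dropped)}
        )

    def dropped(self, rule: str) -> int:
        for s in self.steps:
            if s["rule"] == rule:
                return s["n_dropped"]
        raise KeyError(rule)

    def validate(self) -> None:
        for s in self.steps:
            if s["n_out"] + s["n_dropped"] != s["n_in"]:
                raise AssertionError(f"conservation violated at rule {s['rule']!r}")

    def to_dict(self) -> dict:
        return {"steps": self.steps, "retained_cities": self.retained_cities}

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Impervious-surface grid (ESRI ASCII)
# ---------------------------------------------------------------------------


@dataclass
class ImperviousGrid:
    """Regular planar grid of impervious-surface percentages.

    ``values[0, 0]`` is the *top-left* cell, following ESRI ASCII row order.
    ``xll``/``yll`` locate the lower-left corner; cells are square.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, flattened row-major."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()


def write_esri_ascii(grid: ImperviousGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_esri_ascii(path) -> ImperviousGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value") and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise FormatError(f"bad grid data line: {line!r}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"ESRI ASCII grid missing header field {req!r}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"grid shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return ImperviousGrid(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def zonal_mean_impervious(grid: ImperviousGrid, polygon) -> float:
    """Mean grid value over cells whose centers fall inside ``polygon``.

    Falls back to the value of the cell nearest the polygon centroid when no
    cell center is covered (sliver polygons), with a log message.
    """
    minx, miny, maxx, maxy = polygon.bounds
    gmaxx = grid.xll + grid.ncols * grid.cellsize
    gmaxy = grid.yll + grid.nrows * grid.cellsize
    if maxx < grid.xll or minx > gmaxx or maxy < grid.yll or miny > gmaxy:
        raise ValueError("polygon lies entirely outside the grid extent")
    xs, ys = grid.cell_centers()
    vals = grid.values.ravel()
    # restrict to the polygon's bounding box before the point-in-polygon test
    box = (xs >= minx - grid.cellsize) & (xs <= maxx + grid.cellsize) & \
          (ys >= miny - grid.cellsize) & (ys <= maxy + grid.cellsize)
    inside = np.zeros_like(box)
    if box.any():
        inside[box] = shapely.intersects_xy(polygon, xs[box], ys[box])
    inside &= vals != grid.nodata
    if inside.any():
        return float(vals[inside].mean())
    cx, cy = polygon.centroid.x, polygon.centroid.y
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    d2[vals == grid.nodata] = np.inf
    j = int(np.argmin(d2))
    logger.warning("no cell center inside polygon; using nearest cell value")
    return float(vals[j])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_holc_geojson(path) -> tuple[pd.DataFrame, FilterReport]:
    """Read a Mapping-Inequality-style GeoJSON of HOLC neighborhoods.

    Features whose ``holc_grade`` is outside {A, B, C, D} are dropped and
    counted, as are features with unreadable geometry. Area (km²) is taken
    from an ``area_km2`` property when present, else computed as the planar
    polygon area.
    """
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    if not features:
        raise FormatError("GeoJSON contains no features")
    if not any("holc_grade" in (f.get("properties") or {}) for f in features):
        raise FormatError("no feature carries a 'holc_grade' property")

    report = FilterReport()
    rows = []
    n_bad_grade = 0
    n_bad_geom = 0
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        grade = props.get("holc_grade")
        if grade not in GRADES:
            n_bad_grade += 1
            continue
        try:
            geom = shapely_shape(feat["geometry"])
            if geom.is_empty or geom.area <= 0:
                raise ValueError("empty or zero-area geometry")
        except Exception:
            logger.warning("feature %d: unreadable geometry, dropped", i)
            n_bad_geom += 1
            continue
        area = props.get("area_km2")
        if area is None:
            area = geom.area
        rows.append(
            {
                "neighborhood_id": str(props.get("neighborhood_id", f"f{i}")),
                "city": str(props.get("city", "unknown")),
                "holc_grade": grade,
                "area_km2": float(area),
                "geometry": geom,
            }
        )
    report.add("holc_grade_in_closed_set", len(features), n_bad_grade)
    report.add("readable_geometry", len(features) - n_bad_grade, n_bad_geom)
    df = pd.DataFrame(rows)
    if not df.empty and df["neighborhood_id"].duplicated().any():
        raise FormatError("duplicate neighborhood_id values in GeoJSON")
    return df, report


def read_observations_csv(
    path, column_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Read an iNaturalist-export-like observation CSV.

    ``column_map`` maps the logical field names of :data:`DEFAULT_COLUMN_MAP`
    to the actual CSV columns. Rows with unparseable dates or coordinates are
    dropped and counted; clade labels are normalized to the six-label set and
    rows with unrecognized clades are dropped and counted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, comment="#", dtype=str)
    for logical, col in cmap.items():
        if logical == "establishment":
            continue  # optional; filled with "unknown" when absent
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r} (field {logical!r})")

    report = FilterReport()
    df = pd.DataFrame(
        {
            "record_id": raw[cmap["record_id"]],
            "observed_on": pd.to_datetime(
                raw[cmap["observed_on"]], errors="coerce", format="mixed"
            ),
            "latitude": pd.to_numeric(raw[cmap["latitude"]], errors="coerce"),
            "longitude": pd.to_numeric(raw[cmap["longitude"]], errors="coerce"),
            "species": raw[cmap["species"]],
            "clade": raw[cmap["clade"]].astype(str).str.strip().str.lower(),
            "quality": raw[cmap["quality"]].astype(str).str.strip().str.lower(),
        }
    )
    if cmap["establishment"] in raw.columns:
        est = raw[cmap["establishment"]].astype(str).str.strip().str.lower()
        df["native"] = est.where(est.isin(["native", "introduced"]), "unknown")
    else:
        df["native"] = "unknown"

    n0 = len(df)
    ok_date = df["observed_on"].notna()
    report.add("parseable_date", n0, int((~ok_date).sum()))
    df = df[ok_date]

    n1 = len(df)
    ok_coord = (
        df["latitude"].notna()
        & df["longitude"].notna()
        & df["latitude"].between(-90, 90)
        & df["longitude"].between(-180, 180)
    )
    report.add("valid_coordinates", n1, int((~ok_coord).sum()))
    df = df[ok_coord]

    n2 = len(df)
    df = df.assign(clade=df["clade"].map(CLADE_ALIASES))
    ok_clade = df["clade"].notna()
    report.add("recognized_clade", n2, int((~ok_clade).sum()))
    df = df[ok_clade].reset_index(drop=True)

    if df["record_id"].duplicated().any():
        raise FormatError("duplicate record_id values in CSV")
    report.validate()
    return df, report


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_records(
    records: pd.DataFrame,
    window_start: date,
    window_end: date,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the quality → species-present → date-window rule chain.

    The date window is half-open [start, end): a record dated exactly
    ``window_end`` is dropped.
    """
    if window_end <= window_start:
        raise ConfigurationError("window_end must be after window_start")
    report = report if report is not None else FilterReport()

    n0 = len(records)
    keep = records["quality"].astype(str).str.lower() == "research"
    report.add("quality_research_grade", n0, int((~keep).sum()))
    df = records[keep]

    n1 = len(df)
    has_sp = df["species"].notna() & (df["species"].astype(str).str.strip() != "")
    report.add("species_present", n1, int((~has_sp).sum()))
    df = df[has_sp]

    n2 = len(df)
    ts = pd.to_datetime(df["observed_on"])
    in_window = (ts >= pd.Timestamp(window_start)) & (ts < pd.Timestamp(window_end))
    report.add("date_window", n2, int((~in_window).sum()))
    df = df[in_window].reset_index(drop=True)

    report.validate()
    return df, report


def assign_points_to_polygons(
    records: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, int, FilterReport]:
    """Spatially join records to neighborhood polygons (boundary-inclusive).

    Records outside every polygon are dropped and counted. When a point falls
    in several polygons (abutting boundaries), the lowest ``neighborhood_id``
    wins and a warning is logged.
    """
    report = report if report is not None else FilterReport()
    n0 = len(records)
    if n0 == 0 or neighborhoods.empty:
        report.add("inside_a_neighborhood", n0, n0)
        out = records.iloc[0:0].assign(neighborhood_id=pd.Series(dtype=str))
        return out, n0, report

    geoms = list(neighborhoods["geometry"])
    ids = neighborhoods["neighborhood_id"].to_numpy()
    tree = STRtree(geoms)
    pts = shapely.points(
        records["longitude"].to_numpy(float), records["latitude"].to_numpy(float)
    )
    # 'intersects' on a point is boundary-inclusive containment
    rec_idx, poly_idx = tree.query(pts, predicate="intersects")

    assigned = np.full(n0, None, dtype=object)
    n_multi = 0
    if len(rec_idx):
        order = np.lexsort((ids[poly_idx], rec_idx))
        rec_sorted = rec_idx[order]
        id_sorted = ids[poly_idx][order]
        first = np.ones(len(rec_sorted), dtype=bool)
        first[1:] = rec_sorted[1:] != rec_sorted[:-1]
        assigned[rec_sorted[first]] = id_sorted[first]
        n_multi = len(rec_sorted) - int(first.sum())
    if n_multi:
        logger.warning(
            "%d point-polygon assignments were ambiguous; lowest id kept", n_multi
        )

    mask = np.array([a is not None for a in assigned])
    n_unassigned = int((~mask).sum())
    report.add("inside_a_neighborhood", n0, n_unassigned)
    out = records.loc[mask].copy()
    out["neighborhood_id"] = assigned[mask].astype(str)
    report.validate()
    return out.reset_index(drop=True), n_unassigned, report


def city_clade_inclusion(
    records: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    min_per_cell: int = 5,
    report: FilterReport | None = None,
) -> tuple[list[str], pd.DataFrame, FilterReport]:
    """Retain only cities with ≥ ``min_per_cell`` records in every grade × clade cell.

    Every retained city must have at least ``min_per_cell`` records for each
    of the 4 HOLC grades crossed with each of the 6 clades. All records of
    dropped cities are removed.
    """
    report = report if report is not None else FilterReport()
    meta = neighborhoods.set_index("neighborhood_id")
    recs = records.assign(
        city=records["neighborhood_id"].map(meta["city"]),
        grade=records["neighborhood_id"].map(meta["holc_grade"]),
    )
    counts = recs.groupby(["city", "grade", "clade"], observed=True).size()
    retained: list[str] = []
    diagnostics: dict[str, dict] = {}
    for city in sorted(neighborhoods["city"].unique()):
        ok = True
        cells = {}
        for g in GRADES:
            for c in CLADES:
                n = int(counts.get((city, g, c), 0))
                cells[f"{g}x{c}"] = n
                if n < min_per_cell:
                    ok = False
        diagnostics[city] = cells
        if ok:
            retained.append(city)
    if not retained:
        raise ConfigurationError(
            f"no city satisfies the {min_per_cell}-per-grade-per-clade rule; "
            f"cell counts: {diagnostics}"
        )
    keep = recs["city"].isin(retained)
    report.add("city_grade_clade_inclusion", len(recs), int((~keep).sum()))
    report.retained_cities = retained
    report.validate()
    return retained, records[keep.to_numpy()].reset_index(drop=True), report


def richness_table(
    records: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    subset: str = "all",
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Per-neighborhood distinct-species counts and observation counts.

    ``subset`` is one of ``all``, ``native``, ``nonnative``, or ``clade:<name>``.
    Records with unknown establishment count toward ``all`` but neither
    ``native`` nor ``nonnative``. Neighborhoods with no records under the
    subset are excluded from the table and counted in the report.
    """
    report = report if report is not None else FilterReport()
    if subset == "all":
        sub = records
    elif subset == "native":
        sub = records[records["native"] == "native"]
    elif subset == "nonnative":
        sub = records[records["native"] == "introduced"]
    elif subset.startswith("clade:"):
        clade = subset.split(":", 1)[1]
        if clade not in CLADES:
            raise ValueError(f"unknown clade {clade!r}")
        sub = records[records["clade"] == clade]
    else:
        raise ValueError(f"unknown subset {subset!r}")

    grouped = sub.groupby("neighborhood_id")
    table = pd.DataFrame(
        {
            "richness": grouped["species"].nunique(),
            "n_obs": grouped.size(),
        }
    ).reset_index()
    n_total = len(neighborhoods)
    n_empty = n_total - len(table)
    report.add(f"neighborhood_nonempty[{subset}]", n_total, n_empty)
    meta = neighborhoods[
        ["neighborhood_id", "city", "holc_grade", "area_km2", "impervious"]
        if "impervious" in neighborhoods.columns
        else ["neighborhood_id", "city", "holc_grade", "area_km2"]
    ]
    table = table.merge(meta, on="neighborhood_id", how="inner")
    return table.sort_values("neighborhood_id").reset_index(drop=True), report


def attach_impervious(
    neighborhoods: pd.DataFrame, grid: ImperviousGrid
) -> pd.DataFrame:
    """Zonal-mean impervious percentage for every neighborhood polygon."""
    vals = [zonal_mean_impervious(grid, g) for g in neighborhoods["geometry"]]
    out = neighborhoods.copy()
    out["impervious"] = vals
    return out
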