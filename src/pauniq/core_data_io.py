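"""Data model, file I/O and geometric coverage computation.

The analysis operates on three tables:

* a planar grid of square cells (km coordinates) partitioned into nations,
  with a land/marine flag;
* species occurrences, each species owning the set of grid cells it is
  reported from;
* protected areas (PAs), each with a polygon or — when no boundary data
  exist — a centroid plus reported surface area from which a circular
  buffer of exactly that area is constructed.

Coverage of a grid cell by a PA is the fraction of the *cell's* area that
the PA polygon overlaps; these fractions are the per-cell presence
probabilities that the probabilistic species-to-PA assignment consumes.

All geometry is planar (projected coordinates in km). Grid and occurrence
tables are CSV with WKT geometry columns; PA collections can also be read
from / written to GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, shape, mapping

from .errors import (
    DomainError,
    GeometryError,
    JoinError,
    SchemaError,
    ValidationError,
)

DESIGNATIONS = ("NP", "MAB")

TAXON_GROUPS = (
    "bird",
    "fish",
    "mammal",
    "amphibian",
    "reptile",
    "arthropod",
    "mollusc",
    "other invertebrate",
    "non-vascular plant",
    "vascular plant",
    "other",
)

_GRID_COLUMNS = ("cell_id", "nation", "is_land", "geometry")
_OCC_COLUMNS = ("species_id", "taxon_group", "cell_id")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class GridCellTable:
    """Validated table of square grid cells.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``cell_id`` (str), ``nation`` (str, ISO3-style code),
        ``is_land`` (bool) and ``geometry`` (shapely polygon).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _GRID_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"grid table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["cell_id"] = df["cell_id"].astype(str)
        df["nation"] = df["nation"].astype(str)
        df["is_land"] = df["is_land"].astype(bool)
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].unique()
            raise ValidationError(f"duplicate cell_ids: {list(dupes)[:5]}")
        for geom in df["geometry"]:
            if geom is None or geom.is_empty or not geom.is_valid or geom.area <= 0:
                raise GeometryError("grid cell geometry degenerate or invalid")
        self.df = df
        self._index: dict[str, int] = {
            cid: i for i, cid in enumerate(df["cell_id"])
        }

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df["cell_id"])

    @property
    def land(self) -> pd.DataFrame:
        return self.df[self.df["is_land"]]

    @property
    def land_cell_ids(self) -> list[str]:
        return list(self.land["cell_id"])

    def nation_of(self) -> pd.Series:
        """cell_id -> nation mapping as a Series."""
        return self.df.set_index("cell_id")["nation"]

    def geometry_of(self, cell_id: str) -> Polygon:
        try:
            return self.df["geometry"].iloc[self._index[cell_id]]
        except KeyError as exc:  # pragma: no cover - defensive
            raise JoinError(f"unknown cell_id {cell_id!r}") from exc

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._index

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "GridCellTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, dtype={"cell_id": str, "nation": str})
        if df.empty and not set(_GRID_COLUMNS) <= set(df.columns):
            # a headerless empty file still yields an empty, valid table
            df = pd.DataFrame(columns=list(_GRID_COLUMNS))
        if "geometry" in df.columns:
            df["geometry"] = [
                shapely.from_wkt(w) if isinstance(w, str) else None
                for w in df["geometry"]
            ]
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["geometry"] = [
            shapely.to_wkt(g, rounding_precision=-1) for g in out["geometry"]
        ]
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class SpeciesOccurrence:
    """A species and the set of grid cells it is reported from."""

    species_id: str
    occupied_cells: frozenset[str]
    taxon_group: str = "other"

    def __post_init__(self):
        if not self.occupied_cells:
            raise ValidationError(
                f"species {self.species_id!r} has no occupied cells"
            )
        object.__setattr__(self, "occupied_cells", frozenset(self.occupied_cells))

    @property
    def frequency(self) -> int:
        """Number of occupied grid cells (the rarity denominator)."""
        return len(self.occupied_cells)


@dataclass(frozen=True)
class ProtectedArea:
    """A protected area: national park (NP) or biosphere reserve (MAB)."""

    pa_id: str
    designation: str
    nations: frozenset[str]
    reported_area: float  # km^2
    geometry: Polygon | None = None
    centroid: Point | None = None
    transboundary: bool = False

    def __post_init__(self):
        if self.designation not in DESIGNATIONS:
            raise ValidationError(
                f"designation must be one of {DESIGNATIONS}, got {self.designation!r}"
            )
        if not self.reported_area > 0:
            raise DomainError("reported_area must be > 0 km^2")
        if self.geometry is None and self.centroid is None:
            raise GeometryError(
                f"PA {self.pa_id!r}: either geometry or centroid is required"
            )
        if self.geometry is not None:
            if self.geometry.is_empty or not self.geometry.is_valid:
                raise GeometryError(f"PA {self.pa_id!r}: invalid geometry")
            if self.geometry.area <= 0:
                raise GeometryError(f"PA {self.pa_id!r}: zero-area geometry")
        object.__setattr__(self, "nations", frozenset(self.nations))

    def resolve_geometry(self, n_vertices: int = 256) -> Polygon:
        """Polygon boundary, falling back to a circular buffer of the
        reported surface area around the centroid when no boundary exists."""
        if self.geometry is not None:
            return self.geometry
        return make_circular_buffer(self.centroid, self.reported_area, n_vertices)


class CoverageMatrix:
    """Fractions of each grid cell's area covered by each PA.

    ``values`` is a dense (pa_id x cell_id) DataFrame of fractions in [0, 1].
    Entries are fractions of *cell* area, not of PA area.
    """

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12):
            raise ValidationError("coverage fractions must lie in [0, 1]")
        self.values = values.clip(lower=0.0, upper=1.0)

    @property
    def pa_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, pa_id: str) -> pd.Series:
        try:
            return self.values.loc[pa_id]
        except KeyError as exc:
            raise JoinError(f"unknown pa_id {pa_id!r}") from exc

    def to_csv(self, path: str | Path) -> None:
        self.values.rename_axis("pa_id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoverageMatrix":
        return cls(pd.read_csv(path, index_col="pa_id"))


# ---------------------------------------------------------------------------
# geometry operations
# ---------------------------------------------------------------------------


def make_circular_buffer(
    centroid: Point | tuple[float, float],
    reported_area: float,
    n_vertices: int = 256,
) -> Polygon:
    """Circle of the given area (km^2) around ``centroid``, as a polygon.

    The polygon is a regular ``n_vertices``-gon inscribed in the circle of
    radius sqrt(area/pi); at the default 256 vertices its area is within
    1e-4 relative error of the requested area.
    """
    if not reported_area > 0:
        raise DomainError("buffer area must be > 0")
    if n_vertices < 8:
        raise DomainError("need at least 8 vertices to approximate a circle")
    if not isinstance(centroid, Point):
        centroid = Point(*centroid)
    radius = float(np.sqrt(reported_area / np.pi))
    return centroid.buffer(radius, quad_segs=max(2, n_vertices // 4))


def compute_coverage(
    pa: ProtectedArea, grid: GridCellTable, n_vertices: int = 256
) -> pd.Series:
    """Row of the coverage matrix: fraction of each land cell covered by ``pa``.

    Cells with no intersection are stored as 0.
    """
    geom = pa.resolve_geometry(n_vertices)
    if not geom.is_valid:
        raise GeometryError(f"PA {pa.pa_id!r}: invalid geometry")
    land = grid.land
    out = np.zeros(len(land))
    if len(land):
        tree = shapely.STRtree(list(land["geometry"]))
        hits = tree.query(geom, predicate="intersects")
        cell_geoms = land["geometry"].to_numpy()
        for i in hits:
            cell = cell_geoms[i]
            out[i] = geom.intersection(cell).area / cell.area
    return pd.Series(out, index=land["cell_id"].to_numpy(), name=pa.pa_id)


def coverage_matrix(
    pas: Sequence[ProtectedArea], grid: GridCellTable, n_vertices: int = 256
) -> CoverageMatrix:
    """Dense coverage matrix over all PAs and land cells."""
    rows = [compute_coverage(pa, grid, n_vertices) for pa in pas]
    if rows:
        values = pd.DataFrame(rows)
        values.index = [pa.pa_id for pa in pas]
    else:
        values = pd.DataFrame(columns=grid.land_cell_ids)
    return CoverageMatrix(values)


# ---------------------------------------------------------------------------
# occurrence / PA file I/O
# ---------------------------------------------------------------------------


def read_occurrences(path: str | Path) -> list[SpeciesOccurrence]:
    """Read long-format occurrences (species_id, taxon_group, cell_id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _OCC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table missing columns: {missing}")
    out = []
    for (sid, taxon), grp in df.groupby(["species_id", "taxon_group"], sort=True):
        cells = grp["cell_id"]
        if cells.duplicated().any():
            raise ValidationError(f"species {sid!r}: duplicate cell ids")
        out.append(
            SpeciesOccurrence(
                species_id=sid, taxon_group=taxon, occupied_cells=frozenset(cells)
            )
        )
    return out


def write_occurrences(
    occurrences: Iterable[SpeciesOccurrence], path: str | Path
) -> None:
    rows = [
        (occ.species_id, occ.taxon_group, cid)
        for occ in occurrences
        for cid in sorted(occ.occupied_cells)
    ]
    pd.DataFrame(rows, columns=list(_OCC_COLUMNS)).to_csv(path, index=False)


def read_protected_areas(path: str | Path) -> list[ProtectedArea]:
    """Read PAs from CSV (WKT geometry / centroid columns) or GeoJSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        return _read_pas_geojson(path)
    df = pd.read_csv(path)
    required = {"pa_id", "designation", "nations", "reported_area_km2"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"PA table missing columns: {missing}")
    pas = []
    for _, row in df.iterrows():
        geom = None
        cent = None
        wkt = row.get("geometry")
        if isinstance(wkt, str) and wkt.strip():
            geom = shapely.from_wkt(wkt)
        if geom is None:
            if pd.isna(row.get("centroid_x")) or pd.isna(row.get("centroid_y")):
                raise SchemaError(
                    f"PA {row['pa_id']!r}: neither geometry nor centroid given"
                )
            cent = Point(float(row["centroid_x"]), float(row["centroid_y"]))
        pas.append(
            ProtectedArea(
                pa_id=str(row["pa_id"]),
                designation=str(row["designation"]),
                nations=frozenset(str(row["nations"]).split(";")),
                reported_area=float(row["reported_area_km2"]),
                geometry=geom,
                centroid=cent,
                transboundary=bool(row.get("transboundary", False)),
            )
        )
    _check_unique_pa_ids(pas)
    return pas


def _read_pas_geojson(path: Path) -> list[ProtectedArea]:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise SchemaError("PA GeoJSON must be a FeatureCollection")
    pas = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"]) if feat.get("geometry") else None
        cent = None
        if geom is not None and geom.geom_type == "Point":
            cent, geom = geom, None
        pas.append(
            ProtectedArea(
                pa_id=str(props["pa_id"]),
                designation=str(props["designation"]),
                nations=frozenset(str(props["nations"]).split(";")),
                reported_area=float(props["reported_area_km2"]),
                geometry=geom,
                centroid=cent,
                transboundary=bool(props.get("transboundary", False)),
            )
        )
    _check_unique_pa_ids(pas)
    return pas


def _check_unique_pa_ids(pas: Sequence[ProtectedArea]) -> None:
    ids = [pa.pa_id for pa in pas]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate pa_ids in PA table")


def write_protected_areas(
    pas: Iterable[ProtectedArea], path: str | Path
) -> None:
    path = Path(path)
    if path.suffix.lower() in {".json", ".geojson"}:
        feats = []
        for pa in pas:
            geom = pa.geometry if pa.geometry is not None else pa.centroid
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geom),
                    "properties": {
                        "pa_id": pa.pa_id,
                        "designation": pa.designation,
                        "nations": ";".join(sorted(pa.nations)),
                        "reported_area_km2": pa.reported_area,
                        "transboundary": pa.transboundary,
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
        return
    rows = []
    for pa in pas:
        rows.append(
            {
                "pa_id": pa.pa_id,
                "designation": pa.designation,
                "nations": ";".join(sorted(pa.nations)),
                "reported_area_km2": pa.reported_area,
                "transboundary": pa.transboundary,
                "geometry": (
                    shapely.to_wkt(pa.geometry, rounding_precision=-1)
                    if pa.geometry is not None
                    else ""
                ),
                "centroid_x": pa.centroid.x if pa.centroid is not None else np.nan,
                "centroid_y": pa.centroid.y if pa.centroid is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis dataset
# ---------------------------------------------------------------------------


@dataclass
class AnalysisDataset:
    """Everything one analysis run needs, with occurrence cells already
    restricted to land and marine species dropped."""

    grid: GridCellTable
    occurrences: list[SpeciesOccurrence]
    pas: list[ProtectedArea]
    coverage: CoverageMatrix

    @property
    def pa_ids(self) -> list[str]:
        return [pa.pa_id for pa in self.pas]

    @property
    def species_ids(self) -> list[str]:
        return [occ.species_id for occ in self.occurrences]

    @property
    def areas(self) -> pd.Series:
        """Reported PA surface areas (km^2), indexed by pa_id."""
        return pd.Series(
            {pa.pa_id: pa.reported_area for pa in self.pas}, name="area_km2"
        ).loc[self.pa_ids]

    def pa_nation(self) -> pd.Series:
        """Single nation per PA; transboundary PAs map to NaN."""
        vals = {}
        for pa in self.pas:
            if pa.transboundary or len(pa.nations) != 1:
                vals[pa.pa_id] = np.nan
            else:
                vals[pa.pa_id] = next(iter(pa.nations))
        return pd.Series(vals, name="nation").loc[self.pa_ids]

    def pa_centroids(self) -> pd.DataFrame:
        rows = {}
        for pa in self.pas:
            pt = pa.centroid if pa.centroid is not None else pa.geometry.centroid
            rows[pa.pa_id] = (pt.x, pt.y)
        return pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y"]).loc[
            self.pa_ids
        ]


def build_dataset(
    grid: GridCellTable,
    occurrences: Sequence[SpeciesOccurrence],
    pas: Sequence[ProtectedArea],
    n_vertices: int = 256,
    exclude_pas: Iterable[str] = (),
) -> AnalysisDataset:
    """Validate, filter and assemble the analysis dataset.

    * occurrence cells must exist in the grid (unknown ids raise
      :class:`JoinError`); marine (non-land) cells are dropped at load
      time and species left without land cells are removed entirely;
    * PAs listed in ``exclude_pas`` (e.g. those with known incomplete
      species reporting) are removed;
    * the coverage matrix is computed over the land grid.
    """
    if len(grid) == 0:
        raise ValidationError("empty grid: downstream analysis refused")
    land = set(grid.land_cell_ids)
    filtered: list[SpeciesOccurrence] = []
    for occ in occurrences:
        unknown = [c for c in occ.occupied_cells if c not in grid]
        if unknown:
            raise JoinError(
                f"species {occ.species_id!r}: unknown cell ids {unknown[:5]}"
            )
        kept = occ.occupied_cells & land
        if kept:
            filtered.append(replace(occ, occupied_cells=frozenset(kept)))
    excluded = set(exclude_pas)
    kept_pas = [pa for pa in pas if pa.pa_id not in excluded]
    _check_unique_pa_ids(kept_pas)
    cov = coverage_matrix(kept_pas, grid, n_vertices)
    return AnalysisDataset(
        grid=grid, occurrences=filtered, pas=kept_pas, coverage=cov
    )


def subset_dataset(
    dataset: AnalysisDataset,
    designation: str | None = None,
    taxon: str | None = None,
) -> AnalysisDataset:
    """Restrict to one PA designation (NP/MAB) and/or one taxon group.

    Coverage rows are subset, not recomputed; metric tables downstream are
    therefore recomputed per subset over the subset's species pool.
    """
    pas = dataset.pas
    if designation is not None:
        if designation not in DESIGNATIONS:
            raise ValidationError(f"unknown designation {designation!r}")
        pas = [pa for pa in pas if pa.designation == designation]
    occs = dataset.occurrences
    if taxon is not None:
        occs = [o for o in occs if o.taxon_group == taxon]
    cov = CoverageMatrix(dataset.coverage.values.loc[[pa.pa_id for pa in pas]])
    return AnalysisDataset(
        grid=dataset.grid, occurrences=list(occs), pas=list(pas), coverage=cov
    )
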