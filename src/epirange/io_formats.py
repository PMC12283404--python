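"""Readers and writers for the formats the pipeline touches.

Occurrence tables and checklists are CSV/TSV with Darwin-Core-like default
column names (``decimalLatitude``, ``stateProvince``, ...), phylogenies are
Newick, region polygons are GeoJSON (WGS84, lon-lat axis order) and the
per-species range table is a fixed-column CSV. Readers validate strictly
but never silently drop information: rows that cannot become records are
counted as rejects, and suspicious values (out-of-range latitudes,
non-binomial names) are retained with an entry in the validation log.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "OccurrenceRecord",
    "ChecklistEntry",
    "RegionAtlas",
    "RefPoint",
    "ValidationIssue",
    "TableReadResult",
    "DWC_COLUMNS",
    "LIFEFORMS",
    "RANGE_TABLE_COLUMNS",
    "read_occurrences",
    "write_occurrences",
    "read_checklist",
    "write_checklist",
    "read_trees",
    "read_ref_points",
    "write_ref_points",
    "read_range_table",
    "write_range_table",
    "normalize_species_label",
]

LIFEFORMS = ("epiphyte", "terrestrial")

#: Default (Darwin Core) column names, overridable via ``column_map``.
DWC_COLUMNS: dict[str, str] = {
    "record_id": "gbifID",
    "species": "species",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "coord_uncertainty_m": "coordinateUncertaintyInMeters",
    "country_code": "countryCode",
    "region_code": "regionCode",
    "locality": "locality",
    "year": "year",
    "admin_unit": "stateProvince",
    "basis": "basisOfRecord",
}


@dataclass(frozen=True, slots=True)
class OccurrenceRecord:
    """One specimen-based occurrence record.

    Coordinates are WGS84 decimal degrees; a record is *georeferenced* iff
    both latitude and longitude are present. ``admin_unit`` corresponds to
    GBIF's ``stateProvince``.
    """

    record_id: str
    species: str
    latitude: float | None = None
    longitude: float | None = None
    coord_uncertainty_m: float | None = None
    country_code: str | None = None
    region_code: str | None = None
    locality: str | None = None
    year: int | None = None
    admin_unit: str | None = None
    basis: str | None = None

    @property
    def georeferenced(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True, slots=True)
class ChecklistEntry:
    """Species identity, lifeform, family and native botanical countries.

    Only ``epiphyte`` and ``terrestrial`` lifeforms are representable;
    hemi-epiphytes (and any other token) are excluded at load time.
    """

    species: str
    lifeform: str
    family: str
    native_regions: frozenset[str]

    def __post_init__(self) -> None:
        if self.lifeform not in LIFEFORMS:
            raise ValueError(f"unsupported lifeform {self.lifeform!r}")
        if not self.native_regions:
            raise ValueError(f"{self.species}: native_regions must be nonempty")


@dataclass(frozen=True, slots=True)
class RefPoint:
    """A reference point whose neighbourhood is suspect (centroid/capital/institution)."""

    lat: float
    lon: float
    kind: str = "reference"


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    row: int
    record_id: str
    field: str
    value: str
    message: str


@dataclass
class TableReadResult:
    """Records plus the validation log produced while reading them.

    Iterates over ``records``; ``n_rows == len(records) + n_rejected``.
    """

    records: list
    issues: list[ValidationIssue]
    n_rows: int

    @property
    def n_rejected(self) -> int:
        return self.n_rows - len(self.records)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def normalize_species_label(label: str, underscores_to_spaces: bool = True) -> str:
    """Canonical form used to match checklist species to tree tip labels."""
    s = label.strip()
    if underscores_to_spaces:
        s = s.replace("_", " ")
    return " ".join(s.split())


def _sniff_delimiter(header_line: str) -> str:
    has_tab = "\t" in header_line
    has_comma = "," in header_line
    if has_tab and has_comma:
        raise ValueError("mixed delimiters in header (both tab and comma present)")
    return "\t" if has_tab else ","


def _parse_float(text: str | None) -> tuple[float | None, bool]:
    """Return (value, ok). Empty cells are missing-and-ok."""
    if text is None:
        return None, True
    text = text.strip()
    if not text:
        return None, True
    try:
        v = float(text)
    except ValueError:
        return None, False
    if not math.isfinite(v):
        return None, False
    return v, True


def _parse_int(text: str | None) -> tuple[int | None, bool]:
    if text is None:
        return None, True
    text = text.strip()
    if not text:
        return None, True
    try:
        return int(text), True
    except ValueError:
        return None, False


def _clean_str(text: str | None) -> str | None:
    if text is None:
        return None
    text = text.strip()
    return text or None


def read_occurrences(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> TableReadResult:
    """Read an occurrence CSV/TSV into :class:`OccurrenceRecord` objects.

    Unparsable or out-of-range coordinates become missing (with a log
    entry); longitudes are normalized to (-180, 180]; latitudes are never
    wrapped — an out-of-range latitude invalidates the coordinate pair.
    Rows without a species name are rejected (counted, logged). Row order
    is preserved.
    """
    cmap = dict(DWC_COLUMNS)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(header_line)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        fields = reader.fieldnames or []
        if cmap["species"] not in fields:
            raise ValueError(
                f"{path}: mandatory species column {cmap['species']!r} missing"
            )
        records: list[OccurrenceRecord] = []
        issues: list[ValidationIssue] = []
        n_rows = 0
        for i, row in enumerate(reader):
            n_rows += 1
            species = _clean_str(row.get(cmap["species"]))
            rid = _clean_str(row.get(cmap["record_id"])) or str(i)
            if species is None:
                issues.append(
                    ValidationIssue(i, rid, "species", "", "missing species; row rejected")
                )
                continue
            if len(species.split()) != 2:
                issues.append(
                    ValidationIssue(
                        i, rid, "species", species,
                        "species name is not a binomial (possible fuzzy-match artefact)",
                    )
                )
            lat, ok = _parse_float(row.get(cmap["latitude"]))
            if not ok:
                issues.append(
                    ValidationIssue(
                        i, rid, "latitude", row.get(cmap["latitude"], ""),
                        "unparsable latitude set missing",
                    )
                )
            lon, ok = _parse_float(row.get(cmap["longitude"]))
            if not ok:
                issues.append(
                    ValidationIssue(
                        i, rid, "longitude", row.get(cmap["longitude"], ""),
                        "unparsable longitude set missing",
                    )
                )
            if lat is not None and not (-90.0 <= lat <= 90.0):
                issues.append(
                    ValidationIssue(
                        i, rid, "latitude", str(lat),
                        "latitude out of [-90, 90]; coordinates set missing",
                    )
                )
                lat = None
                lon = None
            if lon is not None and not (-180.0 < lon <= 180.0):
                old = lon
                lon = ((lon + 180.0) % 360.0) - 180.0
                if lon == -180.0:
                    lon = 180.0
                issues.append(
                    ValidationIssue(
                        i, rid, "longitude", str(old),
                        f"longitude normalized to {lon}",
                    )
                )
            unc, ok = _parse_float(row.get(cmap["coord_uncertainty_m"]))
            if not ok:
                issues.append(
                    ValidationIssue(
                        i, rid, "coord_uncertainty_m",
                        row.get(cmap["coord_uncertainty_m"], ""),
                        "unparsable coordinate uncertainty set missing",
                    )
                )
            year, ok = _parse_int(row.get(cmap["year"]))
            if not ok:
                issues.append(
                    ValidationIssue(
                        i, rid, "year", row.get(cmap["year"], ""),
                        "unparsable year set missing",
                    )
                )
            records.append(
                OccurrenceRecord(
                    record_id=rid,
                    species=species,
                    latitude=lat,
                    longitude=lon,
                    coord_uncertainty_m=unc,
                    country_code=_clean_str(row.get(cmap["country_code"])),
                    region_code=_clean_str(row.get(cmap["region_code"])),
                    locality=_clean_str(row.get(cmap["locality"])),
                    year=year,
                    admin_unit=_clean_str(row.get(cmap["admin_unit"])),
                    basis=_clean_str(row.get(cmap["basis"])),
                )
            )
    return TableReadResult(records=records, issues=issues, n_rows=n_rows)


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    """Write records as CSV with the default Darwin-Core column names."""
    cols = [
        "record_id", "species", "latitude", "longitude", "coord_uncertainty_m",
        "country_code", "region_code", "locality", "year", "admin_unit", "basis",
    ]
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([DWC_COLUMNS[c] for c in cols])
        for r in records:
            w.writerow(["" if getattr(r, c) is None else getattr(r, c) for c in cols])


CHECKLIST_COLUMNS = {
    "species": "species",
    "lifeform": "lifeform",
    "family": "family",
    "native_regions": "native_regions",
}


def read_checklist(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    region_sep: str = ";",
) -> TableReadResult:
    """Read a species checklist CSV.

    ``native_regions`` holds botanical-country codes joined by
    ``region_sep``. Rows with a lifeform other than epiphyte/terrestrial
    (e.g. hemi-epiphytes) are excluded with a log entry; duplicate species
    and empty native-region sets are hard errors.
    """
    cmap = dict(CHECKLIST_COLUMNS)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    entries: list[ChecklistEntry] = []
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    n_rows = 0
    with path.open(newline="") as fh:
        delim = _sniff_delimiter(fh.readline())
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        for col in cmap.values():
            if col not in (reader.fieldnames or []):
                raise ValueError(f"{path}: checklist column {col!r} missing")
        for i, row in enumerate(reader):
            n_rows += 1
            species = _clean_str(row.get(cmap["species"]))
            if species is None:
                issues.append(ValidationIssue(i, str(i), "species", "", "missing species; row rejected"))
                continue
            if species in seen:
                raise ValueError(f"{path}: duplicate species {species!r}")
            seen.add(species)
            lifeform = (_clean_str(row.get(cmap["lifeform"])) or "").lower()
            if lifeform not in LIFEFORMS:
                issues.append(
                    ValidationIssue(
                        i, species, "lifeform", lifeform,
                        "unsupported lifeform (hemi-epiphytes etc. are excluded); row rejected",
                    )
                )
                continue
            raw = _clean_str(row.get(cmap["native_regions"])) or ""
            regions = frozenset(t.strip() for t in raw.split(region_sep) if t.strip())
            if not regions:
                raise ValueError(f"{path}: {species}: empty native_regions")
            entries.append(
                ChecklistEntry(
                    species=species,
                    lifeform=lifeform,
                    family=_clean_str(row.get(cmap["family"])) or "unknown",
                    native_regions=regions,
                )
            )
    return TableReadResult(records=entries, issues=issues, n_rows=n_rows)


def write_checklist(entries: Sequence[ChecklistEntry], path: str | Path,
                    region_sep: str = ";") -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "lifeform", "family", "native_regions"])
        for e in entries:
            w.writerow([e.species, e.lifeform, e.family,
                        region_sep.join(sorted(e.native_regions))])


def read_trees(path: str | Path) -> dendropy.TreeList:
    """Read one or more Newick trees; every non-root edge must have a length.

    Tip labels are preserved verbatim (underscores are not converted);
    polytomies are allowed.
    """
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    if len(trees) == 0:
        raise ValueError(f"{path}: no trees found")
    for ti, tree in enumerate(trees):
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.edge.length is None:
                label = nd.taxon.label if nd.taxon else "<internal>"
                raise ValueError(
                    f"{path}: tree {ti}: edge above {label!r} has no branch length "
                    "(phylogenetic covariances undefined)"
                )
    return trees


def read_ref_points(path: str | Path) -> list[RefPoint]:
    """Read a reference-point table (columns: lat, lon, kind)."""
    df = pd.read_csv(path)
    lat_col = "lat" if "lat" in df.columns else "latitude"
    lon_col = "lon" if "lon" in df.columns else "longitude"
    kind_col = "kind" if "kind" in df.columns else None
    out = []
    for _, row in df.iterrows():
        out.append(
            RefPoint(
                lat=float(row[lat_col]),
                lon=float(row[lon_col]),
                kind=str(row[kind_col]) if kind_col else "reference",
            )
        )
    return out


def write_ref_points(points: Sequence[RefPoint], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lat", "lon", "kind"])
        for p in points:
            w.writerow([p.lat, p.lon, p.kind])


@dataclass
class RegionAtlas:
    """Botanical-country polygons plus centroid, ISO and island metadata.

    ``regions`` maps region code to a WGS84 polygon; ``centroids`` maps
    region code to (lat, lon); ``iso_map`` maps ISO 3166-1 alpha-2 codes to
    the set of region codes they cover; ``oceanic_islands`` flags regions
    that are oceanic islands.
    """

    regions: dict[str, BaseGeometry]
    centroids: dict[str, tuple[float, float]] = field(default_factory=dict)
    iso_map: dict[str, frozenset[str]] = field(default_factory=dict)
    oceanic_islands: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for code, geom in self.regions.items():
            if code not in self.centroids:
                c = geom.centroid
                self.centroids[code] = (c.y, c.x)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionAtlas":
        with Path(path).open() as fh:
            gj = json.load(fh)
        regions: dict[str, BaseGeometry] = {}
        centroids: dict[str, tuple[float, float]] = {}
        iso_map: dict[str, set[str]] = {}
        oceanic: set[str] = set()
        for feat in gj.get("features", []):
            props = feat.get("properties", {})
            code = props.get("region_code")
            if not code:
                raise ValueError(f"{path}: feature without region_code")
            regions[code] = shape(feat["geometry"])
            if "centroid" in props:
                lat, lon = props["centroid"]
                centroids[code] = (float(lat), float(lon))
            iso = props.get("iso")
            if iso:
                iso_list = iso if isinstance(iso, list) else [iso]
                for c in iso_list:
                    iso_map.setdefault(c, set()).add(code)
            if props.get("oceanic_island"):
                oceanic.add(code)
        return cls(
            regions=regions,
            centroids=centroids,
            iso_map={k: frozenset(v) for k, v in iso_map.items()},
            oceanic_islands=frozenset(oceanic),
        )

    def to_geojson(self, path: str | Path) -> None:
        region_iso: dict[str, list[str]] = {c: [] for c in self.regions}
        for iso, codes in self.iso_map.items():
            for c in codes:
                region_iso.setdefault(c, []).append(iso)
        features = []
        for code in sorted(self.regions):
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "region_code": code,
                        "centroid": list(self.centroids[code]),
                        "iso": sorted(region_iso.get(code, [])),
                        "oceanic_island": code in self.oceanic_islands,
                    },
                    "geometry": shapely_mapping(self.regions[code]),
                }
            )
        with Path(path).open("w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def regions_for_iso(self, country_code: str) -> frozenset[str]:
        return self.iso_map.get(country_code, frozenset())

    def validate_checklist(self, entries: Sequence[ChecklistEntry]) -> None:
        """Every native region code of every entry must resolve to a polygon."""
        missing = sorted(
            {c for e in entries for c in e.native_regions if c not in self.regions}
        )
        if missing:
            raise ValueError(f"region codes without polygons in atlas: {missing}")


RANGE_TABLE_COLUMNS = (
    "species",
    "lifeform",
    "family",
    "n_botanical_countries",
    "specimen_count",
    "eoo_km2",
    "eligible_le4",
    "rare_by_eoo",
    "rare_by_specimens",
)

_BOOL_COLS = ("eligible_le4", "rare_by_eoo", "rare_by_specimens")


def write_range_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a range table as CSV with a fixed column order.

    Missing values are written as empty fields; EOO is formatted to 12
    significant digits so a write/read round trip reproduces it to that
    precision (integers round-trip exactly).
    """
    df = table.copy()
    for col in RANGE_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    eoo = pd.to_numeric(df["eoo_km2"], errors="raise").astype(float).to_numpy()
    if np.isinf(eoo).any():
        raise ValueError("non-finite eoo_km2 values; table must be finite")
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RANGE_TABLE_COLUMNS)
        for _, row in df.iterrows():
            out = []
            for col in RANGE_TABLE_COLUMNS:
                v = row[col]
                if pd.isna(v):
                    out.append("")
                elif col == "eoo_km2":
                    out.append(format(float(v), ".12g"))
                elif col in ("n_botanical_countries", "specimen_count"):
                    out.append(str(int(v)))
                elif col in _BOOL_COLS:
                    out.append("true" if bool(v) else "false")
                else:
                    out.append(str(v))
            w.writerow(out)


def read_range_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RANGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: range table columns missing: {missing}")
    out = pd.DataFrame()
    out["species"] = df["species"]
    out["lifeform"] = df["lifeform"]
    out["family"] = df["family"]
    out["n_botanical_countries"] = pd.to_numeric(
        df["n_botanical_countries"].replace("", pd.NA)
    ).astype("Int64")
    out["specimen_count"] = pd.to_numeric(
        df["specimen_count"].replace("", pd.NA)
    ).astype("Int64")
    out["eoo_km2"] = pd.to_numeric(df["eoo_km2"].replace("", pd.NA)).astype(float)
    for col in _BOOL_COLS:
        out[col] = df[col].map({"true": True, "false": False, "": pd.NA}).astype("boolean")
    return out
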