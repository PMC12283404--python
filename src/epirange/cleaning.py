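"""Occurrence-record cleaning: two arms with per-filter audit counts.

Georeferenced records pass, in order: a native-range filter (point in any
native botanical-country polygon), a coordinate-precision filter, a
suspect-coordinate filter (zero or equal coordinates; proximity to country
centroids, capitals or biodiversity institutions) and per-species
deduplication with spatial thinning. Non-georeferenced records are
deduplicated on collection locality and on (year, administrative unit) and
checked against native countries via an ISO-to-botanical-country mapping.

Every filter is individually callable, returns ``(kept, removed)`` with a
reason per removed record, preserves input order and conserves counts
(``len(in) == len(kept) + len(removed)``). Ties in deduplication keep the
first record in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import Point

from .geodesy import grid_cell, haversine_m
from .io_formats import ChecklistEntry, OccurrenceRecord, RefPoint, RegionAtlas

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "Removal",
    "FilterStage",
    "filter_suspect_coordinates",
    "filter_low_precision",
    "filter_native_geo",
    "dedup_and_thin",
    "clean_nongeo",
    "clean_all",
    "partition_records",
]


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable cleaning parameters.

    ``round_dp`` — decimal places for coordinate-duplicate detection;
    ``grid_m`` — spatial thinning cell size (one record kept per
    ``grid_m`` x ``grid_m`` cell per species); ``max_uncertainty_m`` —
    records with larger stated coordinate uncertainty are removed;
    ``ref_buffer_m`` — great-circle radius around reference points within
    which records are discarded.
    """

    round_dp: int = 3
    grid_m: float = 110.0
    max_uncertainty_m: float = 100_000.0
    ref_buffer_m: float = 1_000.0
    apply_native_filter: bool = True

    def __post_init__(self) -> None:
        if self.round_dp <= 0:
            raise ValueError("round_dp must be > 0")
        for name in ("grid_m", "max_uncertainty_m", "ref_buffer_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True, slots=True)
class Removal:
    record: OccurrenceRecord
    reason: str


@dataclass(frozen=True, slots=True)
class FilterStage:
    arm: str
    name: str
    records_in: int
    records_removed: int


@dataclass
class CleaningReport:
    """Ordered per-filter audit: counts plus the removed records themselves."""

    stages: list[FilterStage] = field(default_factory=list)
    removals: dict[str, list[Removal]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "arm": s.arm,
                    "filter": s.name,
                    "records_in": s.records_in,
                    "records_removed": s.records_removed,
                }
                for s in self.stages
            ]
        )

    def removed_ids(self, filter_name: str) -> list[str]:
        return [r.record.record_id for r in self.removals.get(filter_name, [])]


def partition_records(
    records: Iterable[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Split records into (georeferenced, non-georeferenced), order preserved."""
    geo, nongeo = [], []
    for r in records:
        (geo if r.georeferenced else nongeo).append(r)
    return geo, nongeo


def _ref_tuple(p) -> tuple[float, float, str]:
    if isinstance(p, RefPoint):
        return (p.lat, p.lon, p.kind)
    lat, lon, kind = p
    return (float(lat), float(lon), str(kind))


def filter_suspect_coordinates(
    records: Sequence[OccurrenceRecord],
    ref_points: Sequence,
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[OccurrenceRecord], list[Removal]]:
    """Remove records with zero or equal coordinates, or near a reference point.

    Equality/zero tests are exact on the parsed decimal values (not rounded).
    Proximity uses great-circle distance against ``config.ref_buffer_m``.
    """
    refs = [_ref_tuple(p) for p in ref_points]
    kept: list[OccurrenceRecord] = []
    removed: list[Removal] = []
    for r in records:
        if not r.georeferenced:
            raise ValueError(f"record {r.record_id} is not georeferenced")
        reason = None
        if r.latitude == 0.0:
            reason = "lat_zero"
        elif r.longitude == 0.0:
            reason = "lon_zero"
        elif r.latitude == r.longitude:
            reason = "lat_eq_lon"
        else:
            for rlat, rlon, kind in refs:
                if haversine_m(r.latitude, r.longitude, rlat, rlon) <= config.ref_buffer_m:
                    reason = f"near_reference_point:{kind}"
                    break
        if reason is None:
            kept.append(r)
        else:
            removed.append(Removal(r, reason))
    return kept, removed


def filter_low_precision(
    records: Sequence[OccurrenceRecord],
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[OccurrenceRecord], list[Removal]]:
    """Remove records with stated coordinate uncertainty above the cutoff.

    The comparison is strict (``> max_uncertainty_m``); records with no
    stated uncertainty are retained, negative uncertainties are removed as
    invalid.
    """
    kept, removed = [], []
    for r in records:
        u = r.coord_uncertainty_m
        if u is None:
            kept.append(r)
        elif u < 0:
            removed.append(Removal(r, "invalid_uncertainty"))
        elif u > config.max_uncertainty_m:
            removed.append(Removal(r, "low_precision"))
        else:
            kept.append(r)
    return kept, removed


def filter_native_geo(
    records: Sequence[OccurrenceRecord],
    checklist: Sequence[ChecklistEntry] | Mapping[str, ChecklistEntry],
    atlas: RegionAtlas,
) -> tuple[list[OccurrenceRecord], list[Removal]]:
    """Keep records whose point falls inside any native-region polygon.

    Polygon boundaries count as inside. Species absent from the checklist
    are removed (``unknown_species``); a native region code without a
    polygon in the atlas is a hard error.
    """
    by_species = (
        dict(checklist)
        if isinstance(checklist, Mapping)
        else {e.species: e for e in checklist}
    )
    kept, removed = [], []
    for r in records:
        entry = by_species.get(r.species)
        if entry is None:
            removed.append(Removal(r, "unknown_species"))
            continue
        missing = [c for c in entry.native_regions if c not in atlas.regions]
        if missing:
            raise ValueError(
                f"species {r.species}: native region(s) without polygon: {sorted(missing)}"
            )
        pt = Point(r.longitude, r.latitude)
        if any(atlas.regions[c].covers(pt) for c in entry.native_regions):
            kept.append(r)
        else:
            removed.append(Removal(r, "outside_native_range"))
    return kept, removed


def dedup_and_thin(
    records: Sequence[OccurrenceRecord],
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[OccurrenceRecord], list[Removal]]:
    """Per-species coordinate deduplication plus spatial thinning.

    Coordinates are rounded to ``round_dp`` decimals for duplicate
    detection; among records sharing a rounded coordinate the first in
    input order is kept. Additionally at most one record per species is
    kept per ``grid_m`` x ``grid_m`` cell (equirectangular projection at
    the record's latitude). Deterministic given input order.
    """
    seen_coord: set[tuple] = set()
    seen_cell: set[tuple] = set()
    kept, removed = [], []
    for r in records:
        if not r.georeferenced:
            raise ValueError(f"record {r.record_id} is not georeferenced")
        ckey = (
            r.species,
            round(r.latitude, config.round_dp),
            round(r.longitude, config.round_dp),
        )
        if ckey in seen_coord:
            removed.append(Removal(r, "duplicate_coordinates"))
            continue
        gkey = (r.species,) + grid_cell(r.latitude, r.longitude, config.grid_m)
        if gkey in seen_cell:
            seen_coord.add(ckey)
            removed.append(Removal(r, "grid_thinned"))
            continue
        seen_coord.add(ckey)
        seen_cell.add(gkey)
        kept.append(r)
    return kept, removed


def _norm_text(s: str | None) -> str | None:
    if s is None:
        return None
    t = " ".join(s.split()).casefold()
    return t or None


def clean_nongeo(
    records: Sequence[OccurrenceRecord],
    checklist: Sequence[ChecklistEntry] | Mapping[str, ChecklistEntry],
    atlas: RegionAtlas,
) -> tuple[list[OccurrenceRecord], list[Removal]]:
    """Clean non-georeferenced records.

    Per species, applied in order (any rule suffices to remove):

    1. drop records whose normalized locality (case-folded, whitespace
       collapsed) duplicates an earlier record's;
    2. drop records whose (year, admin unit) pair duplicates an earlier
       record's, when both fields are present;
    3. drop records whose country code maps (via the atlas ISO mapping) to
       no native region of the species; missing country codes are kept.
    """
    by_species = (
        dict(checklist)
        if isinstance(checklist, Mapping)
        else {e.species: e for e in checklist}
    )
    seen_locality: set[tuple[str, str]] = set()
    seen_year_admin: set[tuple[str, int, str]] = set()
    kept, removed = [], []
    for r in records:
        loc = _norm_text(r.locality)
        if loc is not None:
            lkey = (r.species, loc)
            if lkey in seen_locality:
                removed.append(Removal(r, "duplicate_locality"))
                continue
            seen_locality.add(lkey)
        admin = _norm_text(r.admin_unit)
        if r.year is not None and admin is not None:
            ykey = (r.species, r.year, admin)
            if ykey in seen_year_admin:
                removed.append(Removal(r, "duplicate_year_admin"))
                continue
            seen_year_admin.add(ykey)
        entry = by_species.get(r.species)
        if entry is None:
            removed.append(Removal(r, "unknown_species"))
            continue
        if r.country_code is not None:
            if not (atlas.regions_for_iso(r.country_code) & entry.native_regions):
                removed.append(Removal(r, "nonnative_country"))
                continue
        kept.append(r)
    return kept, removed


#: Filter order of the georeferenced arm (cheap/implausible removals before
#: spatial thinning, so thinning operates on plausible records).
GEO_FILTER_ORDER = ("native_range", "low_precision", "suspect_coordinates", "dedup_thin")


def clean_all(
    geo_records: Sequence[OccurrenceRecord],
    nongeo_records: Sequence[OccurrenceRecord],
    checklist: Sequence[ChecklistEntry] | Mapping[str, ChecklistEntry],
    atlas: RegionAtlas,
    ref_points: Sequence = (),
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], CleaningReport]:
    """Run both cleaning arms and return cleaned records plus an audit report.

    The record partition into georeferenced/non-georeferenced must already
    have been performed (see :func:`partition_records`).
    """
    report = CleaningReport()

    def run(arm: str, name: str, recs, fn):
        kept, removed = fn(recs)
        report.stages.append(FilterStage(arm, name, len(recs), len(removed)))
        report.removals.setdefault(name, []).extend(removed)
        return kept

    geo = list(geo_records)
    if config.apply_native_filter:
        geo = run("geo", "native_range", geo,
                  lambda r: filter_native_geo(r, checklist, atlas))
    geo = run("geo", "low_precision", geo,
              lambda r: filter_low_precision(r, config))
    geo = run("geo", "suspect_coordinates", geo,
              lambda r: filter_suspect_coordinates(r, ref_points, config))
    geo = run("geo", "dedup_thin", geo, lambda r: dedup_and_thin(r, config))

    nongeo = run("nongeo", "nongeo_dedup_native", list(nongeo_records),
                 lambda r: clean_nongeo(r, checklist, atlas))
    return geo, nongeo, report
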