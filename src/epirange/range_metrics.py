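"""The three range-size metrics and their eligibility rules.

* number of native botanical countries — taken directly from the checklist,
  defined for every species;
* specimen count — number of cleaned occurrence records (georeferenced plus
  non-georeferenced), computed only for species native to four or fewer
  botanical countries;
* extent of occurrence (EOO) — area of the minimum convex polygon around
  the cleaned georeferenced points of a species, in km^2, requiring at
  least three georeferenced records and the same eligibility rule.

The convex hull is computed in the lon-lat plane (valid for the
small-extent species the metric targets; point sets spanning the
antimeridian are recentred first, polar caps are unsupported) and its area
is evaluated as a geodesic polygon on the authalic sphere.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .geodesy import spherical_polygon_area_km2
from .io_formats import ChecklistEntry, OccurrenceRecord

__all__ = [
    "ELIGIBLE_MAX_REGIONS",
    "MIN_EOO_POINTS",
    "count_botanical_countries",
    "specimen_count",
    "compute_eoo",
    "build_range_table",
]

#: Specimen count and EOO are computed only for species native to at most
#: this many botanical countries (up to four units can meet at one point,
#: so even point-like ranges can span four of them).
ELIGIBLE_MAX_REGIONS = 4
#: Minimum number of georeferenced records for an EOO estimate.
MIN_EOO_POINTS = 3


def count_botanical_countries(entry: ChecklistEntry) -> int:
    """Number of native botanical countries of a species."""
    if not entry.native_regions:
        raise ValueError(f"{entry.species}: empty native_regions")
    return len(entry.native_regions)


def specimen_count(
    clean_geo: Iterable[OccurrenceRecord],
    clean_nongeo: Iterable[OccurrenceRecord],
    species: str,
) -> int:
    """Cleaned records (both arms) for one species. Zero is allowed."""
    n = sum(1 for r in clean_geo if r.species == species)
    n += sum(1 for r in clean_nongeo if r.species == species)
    return n


def _recenter_lons(lons: np.ndarray) -> np.ndarray:
    if np.ptp(lons) <= 180.0:
        return lons
    shifted = np.mod(lons, 360.0)
    if np.ptp(shifted) <= 180.0:
        return shifted
    raise ValueError(
        "longitudinal extent exceeds 180 degrees even after recentring; "
        "EOO in the lon-lat plane is undefined for such point sets"
    )


def compute_eoo(points: Sequence[tuple[float, float]]) -> float | None:
    """Extent of occurrence (km^2) of a set of (lat, lon) points.

    Returns ``None`` for fewer than three points, and 0.0 for degenerate
    (collinear or duplicated) point sets whose hull has zero area.
    Otherwise the convex hull is taken in the lon-lat plane and its area
    evaluated as a geodesic polygon on the authalic sphere.
    """
    pts = list(points)
    for p in pts:
        if p[0] is None or p[1] is None:
            raise ValueError("point with missing coordinate (clean upstream)")
    if len(pts) < MIN_EOO_POINTS:
        return None
    arr = np.asarray(pts, dtype=float)
    lats, lons = arr[:, 0], arr[:, 1]
    if np.max(np.abs(lats)) >= 89.9999:
        raise ValueError("polar point sets are unsupported")
    lons = _recenter_lons(lons)
    try:
        hull = ConvexHull(np.column_stack([lons, lats]))
    except QhullError:
        return 0.0  # collinear/degenerate: zero-area hull
    v = hull.vertices
    return spherical_polygon_area_km2(lats[v], lons[v])


def build_range_table(
    checklist: Sequence[ChecklistEntry],
    clean_geo: Sequence[OccurrenceRecord],
    clean_nongeo: Sequence[OccurrenceRecord],
    *,
    zero_records_missing: bool = True,
) -> pd.DataFrame:
    """Assemble the per-species range table from cleaned inputs.

    Specimen count and EOO are left missing for ineligible species (more
    than four botanical countries); EOO additionally requires at least
    three georeferenced records. With ``zero_records_missing`` (default) a
    species with no cleaned records gets a missing specimen count — "never
    observed" rather than "observed zero times" — and is thereby excluded
    from the occurrence-based regressions downstream.

    Species appearing in occurrence data but absent from the checklist are
    excluded; their names are available as ``df.attrs['unknown_species']``.
    """
    geo_pts: dict[str, list[tuple[float, float]]] = defaultdict(list)
    for r in clean_geo:
        geo_pts[r.species].append((r.latitude, r.longitude))
    nongeo_n: dict[str, int] = defaultdict(int)
    for r in clean_nongeo:
        nongeo_n[r.species] += 1

    known = {e.species for e in checklist}
    unknown = sorted(
        (set(geo_pts) | set(nongeo_n)) - known
    )

    rows = []
    for entry in checklist:
        n_bc = count_botanical_countries(entry)
        eligible = n_bc <= ELIGIBLE_MAX_REGIONS
        count: int | None = None
        eoo: float | None = None
        if eligible:
            c = len(geo_pts.get(entry.species, ())) + nongeo_n.get(entry.species, 0)
            if c > 0 or not zero_records_missing:
                count = c
            pts = geo_pts.get(entry.species, [])
            if len(pts) >= MIN_EOO_POINTS:
                eoo = compute_eoo(pts)
        rows.append(
            {
                "species": entry.species,
                "lifeform": entry.lifeform,
                "family": entry.family,
                "n_botanical_countries": n_bc,
                "specimen_count": count,
                "eoo_km2": eoo,
                "eligible_le4": eligible,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "species", "lifeform", "family", "n_botanical_countries",
            "specimen_count", "eoo_km2", "eligible_le4",
        ],
    )
    df["n_botanical_countries"] = df["n_botanical_countries"].astype("int64")
    df["specimen_count"] = df["specimen_count"].astype("Int64")
    df["eoo_km2"] = df["eoo_km2"].astype(float)
    df["eligible_le4"] = df["eligible_le4"].astype(bool)
    df.attrs["unknown_species"] = unknown
    return df
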