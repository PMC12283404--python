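"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the real study inputs: a Yule
phylogeny; a binary lifeform trait with phylogenetic clustering (two-state
Markov evolution along the tree); log range size generated as
``intercept + lifeform effect + multivariate normal noise`` whose
covariance is the Pagel's-lambda transform of the Brownian tree
covariance; and per-species occurrence records — clean records drawn in a
disc inside the species' native region, plus planted violations of every
cleaning rule (duplicates, zero/equal coordinates, low-precision records,
out-of-native-range points, reference-point collisions, and
non-georeferenced duplicate localities / collection events).

Violations are non-overlapping by construction: every record carries
exactly one role (clean, or a single violation class), so the attribution
of each cleaning filter can be tested with precision and recall of 1.

The region atlas is a built-in toy: rectangular "botanical countries" on
the equatorial band, which keeps geometry trivial while exercising the
same code paths as real polygons. One global seed expands into per-stage
child seeds by fixed offsets, so stages are independently reproducible.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import box

from .geodesy import KM_PER_DEG, grid_cell, haversine_m
from .io_formats import (
    ChecklistEntry,
    OccurrenceRecord,
    RefPoint,
    RegionAtlas,
    write_checklist,
    write_occurrences,
    write_ref_points,
)
from .phylo_regression import lambda_transform, phylo_vcv

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "SCENARIO_NAMES",
    "VIOLATION_CLASSES",
    "simulate_tree",
    "simulate_lifeform",
    "simulate_phylo_noise",
    "simulate_log_range",
    "simulate_occurrences",
    "make_toy_atlas",
    "make_scenario",
    "make_rarity_table",
    "polytomy_resolutions",
    "expected_hull_fraction",
]

SCENARIO_NAMES = ("baseline", "confounded_clades", "null_effect")

#: Violation classes and the cleaning stage expected to remove each.
VIOLATION_CLASSES = {
    "duplicate_exact": "dedup_thin",
    "duplicate_3dp": "dedup_thin",
    "zero_or_equal": "suspect_coordinates",
    "low_precision": "low_precision",
    "foreign_region": "native_range",
    "reference_point": "suspect_coordinates",
    "nongeo_locality_dup": "nongeo_dedup_native",
    "nongeo_year_admin_dup": "nongeo_dedup_native",
    "nongeo_nonnative": "nongeo_dedup_native",
}

_DEFAULT_VIOLATION_RATES = {
    "duplicate_exact": 0.08,
    "duplicate_3dp": 0.05,
    "zero_or_equal": 0.04,
    "low_precision": 0.06,
    "foreign_region": 0.06,
    "reference_point": 0.04,
    "nongeo_locality_dup": 0.10,
    "nongeo_year_admin_dup": 0.10,
    "nongeo_nonnative": 0.08,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    ``mk_rates`` are the (gain, loss) rates of the epiphytic lifeform;
    ``alpha``/``beta_lifeform`` are the intercept and lifeform effect on
    log range size (natural log, km^2 scale for the EOO analogue);
    ``lambda_true``/``sigma2`` parameterize the phylogenetic noise;
    ``occ_mean`` is the mean number of occurrence records per species
    before violations are added; ``violation_rates`` are the per-class
    planting probabilities (per clean georeferenced record).

    ``stem_length`` and ``clade_epiphyte_probs`` apply only to the
    two-clade confounded scenario.
    """

    name: str = "baseline"
    n_species: int = 200
    birth_rate: float = 1.0
    mk_rates: tuple[float, float] = (0.25, 0.5)
    alpha: float = 9.0
    beta_lifeform: float = math.log(1.5)
    lambda_true: float = 0.8
    sigma2: float = 0.2
    n_trees: int = 1
    occ_mean: float = 16.0
    violation_rates: dict = field(default_factory=lambda: dict(_DEFAULT_VIOLATION_RATES))
    seed: int = 0
    stem_length: float = 1000.0
    clade_epiphyte_probs: tuple[float, float] = (0.9, 0.1)

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.birth_rate <= 0 or self.sigma2 <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")


def _child_seed(seed: int, offset: int) -> int:
    # fixed-offset expansion keeps each stage independently reproducible
    return (seed * 1009 + offset) % (2**31 - 1)


def simulate_tree(
    n_species: int, birth_rate: float, seed: int, *, label_prefix: str = "s"
) -> dendropy.Tree:
    """Yule (pure-birth) tree with exactly ``n_species`` tips.

    Simulation starts from the root bifurcation (two lineages) and, after
    the n-th tip appears, runs one further exponential waiting time with
    all n lineages, so the expected root-to-tip depth is
    ``sum_{k=2..n} 1 / (k * birth_rate)``. The tree is ultrametric with
    strictly positive branch lengths and deterministic for a given seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active: list[tuple[dendropy.Node, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node, born = active.pop(int(rng.integers(k)))
        node.edge.length = t - born
        kids = (dendropy.Node(), dendropy.Node())
        for kid in kids:
            node.add_child(kid)
            active.append((kid, t))
    t += rng.exponential(1.0 / (n_species * birth_rate))
    width = max(4, len(str(n_species)))
    for i, (node, born) in enumerate(active):
        node.edge.length = t - born
        # binomial-style labels ("<prefix>gen sp0001") keep downstream
        # species-name validation quiet
        node.taxon = tns.new_taxon(f"{label_prefix}gen sp{i + 1:0{width}d}")
    return tree


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def simulate_lifeform(tree: dendropy.Tree, mk_rates, seed: int) -> dict[str, str]:
    """Two-state Markov lifeform evolution along the tree.

    State 1 is "epiphyte"; the root state is drawn from the stationary
    distribution ``q10/(q01+q10), q01/(q01+q10)``; transitions along each
    edge use the analytic two-state transition probabilities.
    """
    q01, q10 = mk_rates
    if q01 < 0 or q10 < 0 or (q01 + q10) == 0:
        raise ValueError("mk_rates must be nonnegative and not both zero")
    q = q01 + q10
    pi1 = q01 / q
    rng = np.random.default_rng(seed)
    state: dict = {}
    out: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            s = 1 if rng.random() < pi1 else 0
        else:
            t = nd.edge.length or 0.0
            parent = state[nd.parent_node]
            p1 = pi1 + ((1.0 if parent == 1 else 0.0) - pi1) * math.exp(-q * t)
            s = 1 if rng.random() < p1 else 0
        state[nd] = s
        if nd.is_leaf() and nd.taxon is not None:
            out[nd.taxon.label] = "epiphyte" if s == 1 else "terrestrial"
    return out


def simulate_phylo_noise(
    tree: dendropy.Tree, lambda_true: float, sigma2: float, seed: int, taxa=None
) -> tuple[list[str], np.ndarray]:
    """Multivariate normal noise with covariance sigma2 * C_lambda."""
    if taxa is None:
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = list(taxa)
    C = phylo_vcv(tree, taxa)
    V = sigma2 * lambda_transform(C, lambda_true)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"phylogenetic covariance not positive definite: {exc}")
    rng = np.random.default_rng(seed)
    eps = L @ rng.standard_normal(len(taxa))
    return taxa, eps


def simulate_log_range(
    tree: dendropy.Tree,
    labels: dict[str, str],
    alpha: float,
    beta_lifeform: float,
    lambda_true: float,
    sigma2: float,
    seed: int,
    taxa=None,
) -> tuple[list[str], np.ndarray]:
    """Log range size: alpha + beta * 1[epiphyte] + phylogenetic noise."""
    taxa, eps = simulate_phylo_noise(tree, lambda_true, sigma2, seed, taxa)
    ind = np.array([1.0 if labels[t] == "epiphyte" else 0.0 for t in taxa])
    return taxa, alpha + beta_lifeform * ind + eps


_HULL_FRACTION_CACHE: dict[int, float] = {}


def expected_hull_fraction(n: int, reps: int = 128) -> float:
    """Expected convex-hull area of n uniform points in a disc, as a
    fraction of the disc area (Monte-Carlo, cached; fixed internal seed —
    it is a calibration constant, not part of scenario randomness)."""
    if n < 3:
        raise ValueError("need at least 3 points")
    if n not in _HULL_FRACTION_CACHE:
        rng = np.random.default_rng(1234567 + n)
        total = 0.0
        for _ in range(reps):
            r = np.sqrt(rng.random(n))
            th = rng.random(n) * 2.0 * np.pi
            pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
            total += ConvexHull(pts).volume
        _HULL_FRACTION_CACHE[n] = total / reps / np.pi
    return _HULL_FRACTION_CACHE[n]


def make_toy_atlas(
    n_regions: int = 8,
    region_width_deg: float = 20.0,
    lat_half_deg: float = 15.0,
    lon_origin: float = -80.0,
    oceanic: tuple[str, ...] = ("R08",),
) -> tuple[RegionAtlas, list[RefPoint]]:
    """Rectangular toy botanical countries on the equatorial band.

    Region ``R0i`` spans ``lat_half_deg`` degrees either side of the
    equator and ``region_width_deg`` degrees of longitude; ISO code
    ``C0i`` maps one-to-one onto it. Each region has one "capital"
    reference point placed away from the zero/diagonal coordinate lines.
    """
    regions = {}
    centroids = {}
    iso_map = {}
    refs = []
    for i in range(n_regions):
        code = f"R{i + 1:02d}"
        lon_min = lon_origin + i * region_width_deg
        lon_max = lon_min + region_width_deg
        regions[code] = box(lon_min, -lat_half_deg, lon_max, lat_half_deg)
        centroids[code] = (0.0, (lon_min + lon_max) / 2.0)
        iso_map[f"C{i + 1:02d}"] = frozenset({code})
        refs.append(
            RefPoint(lat=11.53, lon=lon_min + 0.17 * region_width_deg, kind="capital")
        )
    atlas = RegionAtlas(
        regions=regions,
        centroids=centroids,
        iso_map=iso_map,
        oceanic_islands=frozenset(c for c in oceanic if c in regions),
    )
    return atlas, refs


def _region_iso(atlas: RegionAtlas, region: str) -> str | None:
    for iso, codes in atlas.iso_map.items():
        if region in codes:
            return iso
    return None


def simulate_occurrences(
    species_df: pd.DataFrame,
    violation_rates: dict | None,
    atlas: RegionAtlas,
    seed: int,
    *,
    ref_points=(),
    violation_counts: dict | None = None,
    clean_ref_margin_m: float = 2500.0,
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord], pd.DataFrame]:
    """Generate occurrence records with planted, labelled violations.

    ``species_df`` needs columns ``species``, ``native_region``,
    ``foreign_region``, ``eoo_target_km2``, ``n_geo``, ``n_nongeo``.
    Clean georeferenced records are drawn uniformly in a disc sized so the
    expected convex-hull area equals the EOO target; clean records avoid,
    by construction, every violation trigger (zero/equal coordinates,
    reference-point buffers, shared 3-decimal roundings and thinning-grid
    cells within a species). Violation counts per class are
    ``Binomial(n_geo, rate)`` unless exact per-species counts are supplied
    via ``violation_counts``.

    Returns (geo records, nongeo records, truth), where truth has one row
    per emitted record with its single role label ("clean" or a violation
    class).
    """
    rates = dict(violation_rates or {})
    rng = np.random.default_rng(seed)
    geo_records: list[OccurrenceRecord] = []
    nongeo_records: list[OccurrenceRecord] = []
    truth_rows = []
    gid = 0
    nid = 0
    refs = list(ref_points)

    def add_truth(rid, species, arm, label):
        truth_rows.append(
            {"record_id": rid, "species": species, "arm": arm, "label": label}
        )

    for row in species_df.itertuples(index=False):
        species = row.species
        native = row.native_region
        foreign = row.foreign_region
        n_geo = int(row.n_geo)
        n_nongeo = int(row.n_nongeo)
        target = float(row.eoo_target_km2)
        iso_native = _region_iso(atlas, native)
        iso_foreign = _region_iso(atlas, foreign)
        rect = atlas.regions[native]
        minx, miny, maxx, maxy = rect.bounds
        if not (miny < 0.0 < maxy):
            raise ValueError("toy regions must straddle the equator")

        frac = expected_hull_fraction(n_geo) if n_geo >= 3 else 1.0
        disc_km2 = target / frac
        r_lat = math.sqrt(disc_km2 / math.pi) / KM_PER_DEG
        pad = 0.05
        lat_lo, lat_hi = miny + r_lat + pad, maxy - r_lat - pad
        if lat_lo >= lat_hi:
            raise ValueError(f"{species}: EOO target too large for region {native}")
        clat = float(rng.uniform(lat_lo, lat_hi))
        coslat = math.cos(math.radians(clat))
        r_lon = r_lat / coslat
        lon_lo, lon_hi = minx + r_lon + pad, maxx - r_lon - pad
        if lon_lo >= lon_hi:
            raise ValueError(f"{species}: EOO target too large for region {native}")
        clon = float(rng.uniform(lon_lo, lon_hi))

        seen_round: set[tuple[float, float]] = set()
        seen_cell: set[tuple[int, int]] = set()
        clean_pts: list[tuple[float, float]] = []
        attempts = 0
        while len(clean_pts) < n_geo:
            attempts += 1
            if attempts > 200 * max(n_geo, 1):
                raise RuntimeError(f"{species}: cannot place clean points")
            rad = r_lat * math.sqrt(rng.random())
            th = rng.random() * 2.0 * math.pi
            lat = clat + rad * math.sin(th)
            lon = clon + rad * math.cos(th) / coslat
            if lat == 0.0 or lon == 0.0 or lat == lon:
                continue
            if any(
                haversine_m(lat, lon, p.lat, p.lon) <= clean_ref_margin_m for p in refs
            ):
                continue
            rkey = (round(lat, 3), round(lon, 3))
            ckey = grid_cell(lat, lon, 110.0)
            if rkey in seen_round or ckey in seen_cell:
                continue
            seen_round.add(rkey)
            seen_cell.add(ckey)
            clean_pts.append((lat, lon))

        for lat, lon in clean_pts:
            gid += 1
            rid = f"g{gid:06d}"
            geo_records.append(
                OccurrenceRecord(
                    record_id=rid, species=species, latitude=lat, longitude=lon,
                    country_code=iso_native, region_code=native,
                    basis="PreservedSpecimen",
                )
            )
            add_truth(rid, species, "geo", "clean")

        def n_for(cls: str) -> int:
            if violation_counts is not None and cls in violation_counts:
                return int(violation_counts[cls])
            rate = rates.get(cls, 0.0)
            return int(rng.binomial(n_geo, rate)) if rate > 0 else 0

        def emit_geo(cls, lat, lon, unc=None):
            nonlocal gid
            gid += 1
            rid = f"g{gid:06d}"
            geo_records.append(
                OccurrenceRecord(
                    record_id=rid, species=species, latitude=lat, longitude=lon,
                    coord_uncertainty_m=unc, country_code=iso_native,
                    region_code=native, basis="PreservedSpecimen",
                )
            )
            add_truth(rid, species, "geo", cls)

        for _ in range(n_for("duplicate_exact")):
            lat, lon = clean_pts[int(rng.integers(len(clean_pts)))]
            emit_geo("duplicate_exact", lat, lon)
        for _ in range(n_for("duplicate_3dp")):
            lat, lon = clean_pts[int(rng.integers(len(clean_pts)))]
            dl = round(lat, 3) + 1e-4
            dn = round(lon, 3) + 1e-4
            if dl == dn or dl == 0.0 or dn == 0.0:
                dn += 1e-4
            emit_geo("duplicate_3dp", dl, dn)
        for _ in range(n_for("zero_or_equal")):
            lon = float(rng.uniform(minx + pad, maxx - pad))
            while lon == 0.0:
                lon = float(rng.uniform(minx + pad, maxx - pad))
            emit_geo("zero_or_equal", 0.0, lon)
        for _ in range(n_for("low_precision")):
            rad = r_lat * math.sqrt(rng.random())
            th = rng.random() * 2.0 * math.pi
            emit_geo(
                "low_precision",
                clat + rad * math.sin(th),
                clon + rad * math.cos(th) / coslat,
                unc=float(rng.uniform(150_000.0, 500_000.0)),
            )
        for _ in range(n_for("foreign_region")):
            fminx, fminy, fmaxx, fmaxy = atlas.regions[foreign].bounds
            emit_geo(
                "foreign_region",
                float(rng.uniform(fminy + pad, fmaxy - pad)),
                float(rng.uniform(fminx + pad, fmaxx - pad)),
            )
        native_caps = [
            p for p in refs if minx <= p.lon <= maxx and miny <= p.lat <= maxy
        ]
        for _ in range(n_for("reference_point")):
            if not native_caps:
                break
            p = native_caps[int(rng.integers(len(native_caps)))]
            emit_geo("reference_point", p.lat, p.lon)

        # --- non-georeferenced arm ---
        clean_nongeo_meta = []
        for i in range(n_nongeo):
            nid += 1
            rid = f"n{nid:06d}"
            loc = f"{species} site {i + 1}"
            year = 1900 + i
            admin = f"prov{i + 1:02d}"
            nongeo_records.append(
                OccurrenceRecord(
                    record_id=rid, species=species, locality=loc, year=year,
                    admin_unit=admin, country_code=iso_native,
                    basis="PreservedSpecimen",
                )
            )
            clean_nongeo_meta.append((loc, year, admin))
            add_truth(rid, species, "nongeo", "clean")

        def n_for_nongeo(cls: str) -> int:
            if violation_counts is not None and cls in violation_counts:
                return int(violation_counts[cls])
            rate = rates.get(cls, 0.0)
            return int(rng.binomial(n_nongeo, rate)) if rate > 0 else 0

        def emit_nongeo(cls, loc, year, admin, cc):
            nonlocal nid
            nid += 1
            rid = f"n{nid:06d}"
            nongeo_records.append(
                OccurrenceRecord(
                    record_id=rid, species=species, locality=loc, year=year,
                    admin_unit=admin, country_code=cc, basis="PreservedSpecimen",
                )
            )
            add_truth(rid, species, "nongeo", cls)

        k = 0
        if clean_nongeo_meta:
            for _ in range(n_for_nongeo("nongeo_locality_dup")):
                k += 1
                base = clean_nongeo_meta[int(rng.integers(len(clean_nongeo_meta)))]
                mangled = "  " + base[0].upper().replace(" ", "   ") + " "
                emit_nongeo("nongeo_locality_dup", mangled, 1700 + k, f"dup{k:02d}",
                            iso_native)
            for _ in range(n_for_nongeo("nongeo_year_admin_dup")):
                k += 1
                base = clean_nongeo_meta[int(rng.integers(len(clean_nongeo_meta)))]
                emit_nongeo("nongeo_year_admin_dup", f"{species} duplicate event {k}",
                            base[1], base[2], iso_native)
        for _ in range(n_for_nongeo("nongeo_nonnative")):
            k += 1
            emit_nongeo("nongeo_nonnative", f"{species} foreign site {k}",
                        1600 + k, f"for{k:02d}", iso_foreign)

    truth = pd.DataFrame(truth_rows, columns=["record_id", "species", "arm", "label"])
    return geo_records, nongeo_records, truth


def polytomy_resolutions(
    tree: dendropy.Tree, n_trees: int, seed: int, *, collapse_frac: float = 0.01
) -> list[dendropy.Tree]:
    """Collapse short internal edges into polytomies, then re-resolve.

    Internal edges shorter than ``collapse_frac`` times the tree depth are
    collapsed (their length passed down to the children, preserving tip
    depths); each output tree is an independent random resolution of the
    resulting polytomies with new internal edges drawn uniformly in
    (0, collapse threshold). This mimics trees that differ only in the
    placement of weakly resolved taxa.
    """
    base = tree.clone(depth=1)
    thr = collapse_frac * tree_depth(base)
    for nd in list(base.postorder_internal_node_iter(exclude_seed_node=True)):
        if nd.edge.length is not None and nd.edge.length < thr:
            parent = nd.parent_node
            for ch in list(nd.child_nodes()):
                ch.edge.length = (ch.edge.length or 0.0) + nd.edge.length
                parent.add_child(ch)
            parent.remove_child(nd)
    out = []
    for i in range(n_trees):
        t = base.clone(depth=1)
        pyrng = random.Random(_child_seed(seed, 7000 + i))
        t.resolve_polytomies(rng=pyrng)
        nprng = np.random.default_rng(_child_seed(seed, 8000 + i))
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None and (nd.edge.length or 0.0) == 0.0:
                nd.edge.length = float(nprng.uniform(0.0, thr))
        out.append(t)
    return out


def _two_clade_tree(
    n: int, birth_rate: float, stem_length: float, seed: int
) -> dendropy.Tree:
    """Two Yule clades (tip prefixes 'a' and 'b'), each scaled to depth 1,
    joined by stem branches of ``stem_length``."""
    halves = (n // 2, n - n // 2)
    newicks = []
    for half, prefix, off in zip(halves, ("a", "b"), (0, 1)):
        t = simulate_tree(half, birth_rate, _child_seed(seed, 100 + off),
                          label_prefix=prefix)
        depth = tree_depth(t)
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length /= depth
        s = t.as_string(schema="newick", suppress_rooting=True).strip()
        newicks.append(s[:-1] if s.endswith(";") else s)
    data = f"({newicks[0]}:{stem_length},{newicks[1]}:{stem_length});"
    return dendropy.Tree.get(data=data, schema="newick", preserve_underscores=True)


@dataclass
class Scenario:
    """A fully generated scenario: inputs plus ground truth."""

    config: ScenarioConfig
    tree: dendropy.Tree
    trees: list[dendropy.Tree]
    taxa: list[str]
    lifeform: dict[str, str]
    log_range: np.ndarray
    checklist: list[ChecklistEntry]
    atlas: RegionAtlas
    ref_points: list[RefPoint]
    geo_records: list[OccurrenceRecord]
    nongeo_records: list[OccurrenceRecord]
    truth_records: pd.DataFrame
    truth_species: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit all input files plus ground truth; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "occurrences_geo": out / "occurrences_geo.csv",
            "occurrences_nongeo": out / "occurrences_nongeo.csv",
            "checklist": out / "checklist.csv",
            "trees": out / "trees.nwk",
            "regions": out / "regions.geojson",
            "ref_points": out / "ref_points.csv",
            "truth_records": out / "truth_records.csv",
            "truth_species": out / "truth_species.csv",
            "scenario": out / "scenario.json",
        }
        write_occurrences(self.geo_records, paths["occurrences_geo"])
        write_occurrences(self.nongeo_records, paths["occurrences_nongeo"])
        write_checklist(self.checklist, paths["checklist"])
        with paths["trees"].open("w") as fh:
            for t in self.trees:
                fh.write(t.as_string(schema="newick", suppress_rooting=True))
        self.atlas.to_geojson(paths["regions"])
        write_ref_points(self.ref_points, paths["ref_points"])
        self.truth_records.to_csv(paths["truth_records"], index=False)
        self.truth_species.to_csv(paths["truth_species"], index=False)
        cfg = asdict(self.config)
        with paths["scenario"].open("w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True)
        return paths


def scenario_defaults(name: str) -> ScenarioConfig:
    if name == "baseline":
        return ScenarioConfig(name="baseline")
    if name == "null_effect":
        return ScenarioConfig(name="null_effect", beta_lifeform=0.0)
    if name == "confounded_clades":
        # deep divergence between the two clades dwarfs the lifeform effect,
        # so ignoring phylogeny reverses the apparent sign of the effect
        return ScenarioConfig(
            name="confounded_clades", lambda_true=1.0, sigma2=0.1,
            stem_length=1000.0,
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def make_scenario(
    name: str, overrides: dict | None = None, seed: int = 0
) -> Scenario:
    """Generate a complete scenario with ground truth.

    ``baseline``: moderately clustered lifeform, positive lifeform effect.
    ``confounded_clades``: two deep clades; epiphytes are concentrated
    (0.9 vs 0.1) in the clade whose deep-branch Brownian displacement is
    negative, while the true lifeform effect is +ln(1.5) — ordinary
    regression then shows epiphytes with smaller ranges while the
    phylogenetic regression recovers the positive effect.
    ``null_effect``: no lifeform effect.
    """
    cfg = scenario_defaults(name)
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg = replace(cfg, seed=seed)

    s_tree = _child_seed(seed, 1)
    s_label = _child_seed(seed, 2)
    s_noise = _child_seed(seed, 3)
    s_check = _child_seed(seed, 4)
    s_occ = _child_seed(seed, 5)

    if cfg.name == "confounded_clades":
        tree = _two_clade_tree(cfg.n_species, cfg.birth_rate, cfg.stem_length, s_tree)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        taxa, eps = simulate_phylo_noise(tree, cfg.lambda_true, cfg.sigma2,
                                         s_noise, taxa)
        in_a = np.array([t.startswith("a") for t in taxa])
        mean_a = float(eps[in_a].mean())
        mean_b = float(eps[~in_a].mean())
        rich_is_a = mean_a < mean_b  # epiphytes concentrate in the low clade
        p_rich, p_poor = cfg.clade_epiphyte_probs
        rng_l = np.random.default_rng(s_label)
        lifeform = {}
        for t, a in zip(taxa, in_a):
            p = p_rich if (a == rich_is_a) else p_poor
            lifeform[t] = "epiphyte" if rng_l.random() < p else "terrestrial"
        ind = np.array([1.0 if lifeform[t] == "epiphyte" else 0.0 for t in taxa])
        y = cfg.alpha + cfg.beta_lifeform * ind + eps
    else:
        tree = simulate_tree(cfg.n_species, cfg.birth_rate, s_tree)
        lifeform = simulate_lifeform(tree, cfg.mk_rates, s_label)
        taxa, y = simulate_log_range(
            tree, lifeform, cfg.alpha, cfg.beta_lifeform,
            cfg.lambda_true, cfg.sigma2, s_noise,
        )

    trees = (
        polytomy_resolutions(tree, cfg.n_trees, _child_seed(seed, 6))
        if cfg.n_trees > 1
        else [tree]
    )

    atlas, ref_points = make_toy_atlas()
    codes = sorted(atlas.regions)
    rng_c = np.random.default_rng(s_check)

    # family = clade under each child of the root
    fam_of: dict[str, str] = {}
    for fi, child in enumerate(tree.seed_node.child_nodes()):
        for leaf in child.leaf_iter():
            fam_of[leaf.taxon.label] = f"F{fi + 1:02d}"

    checklist = []
    sp_rows = []
    for i, t in enumerate(taxa):
        if rng_c.random() < 0.06:
            n_reg = 5 + int(rng_c.integers(2))  # ineligible for count/EOO metrics
        else:
            n_reg = 1 + int(rng_c.integers(4))
        regions = list(rng_c.choice(codes, size=n_reg, replace=False))
        native = regions[0]
        others = [c for c in codes if c not in regions]
        foreign = str(others[int(rng_c.integers(len(others)))])
        checklist.append(
            ChecklistEntry(
                species=t, lifeform=lifeform[t], family=fam_of.get(t, "F00"),
                native_regions=frozenset(str(c) for c in regions),
            )
        )
        # cap keeps the sampling disc inside a toy region even for species
        # with few points (small expected-hull fraction => large disc)
        eoo_target = float(np.clip(math.exp(y[i]), 50.0, 1.5e5))
        # collection effort scales with range size, so the cleaned specimen
        # count acts as a range-size proxy the way herbarium records do
        effort = float(np.clip(math.exp(0.5 * (y[i] - cfg.alpha)), 0.2, 5.0))
        n_geo = 3 + int(rng_c.poisson(max(cfg.occ_mean * 0.6 - 3.0, 0.0) * effort))
        n_nongeo = 1 + int(rng_c.poisson(max(cfg.occ_mean * 0.4 - 1.0, 0.0) * effort))
        sp_rows.append(
            {
                "species": t, "lifeform": lifeform[t],
                "family": fam_of.get(t, "F00"),
                "native_region": str(native), "foreign_region": foreign,
                "n_regions": n_reg, "log_range": float(y[i]),
                "eoo_target_km2": eoo_target,
                "n_geo": n_geo, "n_nongeo": n_nongeo,
            }
        )
    species_df = pd.DataFrame(sp_rows)

    geo, nongeo, truth_records = simulate_occurrences(
        species_df, cfg.violation_rates, atlas, s_occ, ref_points=ref_points
    )
    truth_species = species_df.assign(
        specimen_count_true=lambda d: d.n_geo + d.n_nongeo
    )
    return Scenario(
        config=cfg, tree=tree, trees=trees, taxa=taxa, lifeform=lifeform,
        log_range=np.asarray(y, dtype=float), checklist=checklist, atlas=atlas,
        ref_points=ref_points, geo_records=geo, nongeo_records=nongeo,
        truth_records=truth_records, truth_species=truth_species,
    )


def make_rarity_table(
    n_epiphyte: int = 40,
    n_terrestrial: int = 40,
    prop_rare: tuple[float, float] = (0.5, 0.25),
    eoo_km2_max: float = 20_000.0,
    specimens_max: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Range table with exactly planted per-lifeform rarity proportions.

    ``prop_rare`` is (epiphyte, terrestrial); the same planted proportion
    is used for both the EOO and the specimen-count criterion. Returns
    (table, truth) where truth records the planted proportions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lifeform, n, prop in zip(
        ("epiphyte", "terrestrial"), (n_epiphyte, n_terrestrial), prop_rare
    ):
        n_rare = round(prop * n)
        for i in range(n):
            rare = i < n_rare
            eoo = (
                float(rng.uniform(0.05, 0.9)) * eoo_km2_max
                if rare
                else float(rng.uniform(1.5, 8.0)) * eoo_km2_max
            )
            count = (
                int(rng.integers(1, specimens_max + 1))
                if rare
                else int(rng.integers(specimens_max + 1, 12 * specimens_max))
            )
            rows.append(
                {
                    "species": f"{lifeform[0]}sp{i + 1:03d}",
                    "lifeform": lifeform,
                    "family": "F01",
                    "n_botanical_countries": 1,
                    "specimen_count": count,
                    "eoo_km2": eoo,
                    "eligible_le4": True,
                }
            )
    table = pd.DataFrame(rows)
    table["specimen_count"] = table["specimen_count"].astype("Int64")
    truth = {
        "epiphyte": round(prop_rare[0] * n_epiphyte) / n_epiphyte,
        "terrestrial": round(prop_rare[1] * n_terrestrial) / n_terrestrial,
    }
    return table, truth
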