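"""End-to-end orchestration: clean -> metrics -> regressions -> rarity.

Model–metric pairings follow the analysis design: the botanical-country
count is modelled with a quasi-Poisson GLM only (no PGLS for a
quasi-likelihood count model); specimen count and EOO are modelled with
log-OLS and with Pagel's-lambda PGLS, the latter run once per input tree
and aggregated across trees. Effect sizes are reported as percentage
differences of epiphytes relative to terrestrial species with Wald 95%
confidence intervals.

Sensitivity subsets mirror the study design: ``tropical_only`` keeps
species whose native-region centroid latitudes average inside the tropics;
``exclude_oceanic_islands`` drops species with any native oceanic-island
region (configurable to require all regions to be islands).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cleaning import CleaningConfig, clean_all, partition_records
from .io_formats import (
    ChecklistEntry,
    RegionAtlas,
    normalize_species_label,
    read_checklist,
    read_occurrences,
    read_ref_points,
    read_trees,
    write_range_table,
)
from .phylo_regression import (
    RegressionFit,
    aggregate_trees,
    effect_size_percent,
    ols_log,
    pgls_ml,
    quasipoisson_glm,
)
from .range_metrics import build_range_table
from .rarity import RarityThresholds, classify_rarity, rarity_proportions

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "subset_species",
    "run_analysis",
    "DEFAULT_MODELS",
    "TROPICS_LAT_DEG",
]

log = logging.getLogger(__name__)

#: Latitude of the tropics boundary (Tropic of Cancer/Capricorn), degrees.
TROPICS_LAT_DEG = 23.436

#: Which models are run for which range-size metric.
DEFAULT_MODELS: dict[str, tuple[str, ...]] = {
    "bc": ("quasipoisson",),
    "specimens": ("ols", "pgls"),
    "eoo": ("ols", "pgls"),
}

SUBSETS = ("all", "tropical_only", "exclude_oceanic_islands")


@dataclass
class AnalysisConfig:
    """Inputs, model plan and parameters of one pipeline run."""

    occurrences_geo: Path
    occurrences_nongeo: Path
    checklist: Path
    trees: Path
    regions: Path
    out_dir: Path
    ref_points: Path | None = None
    metrics: tuple[str, ...] = ("bc", "specimens", "eoo")
    models: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MODELS)
    )
    group_by: tuple[str, ...] = ()
    subset: str = "all"
    island_mode: str = "any"
    thresholds: RarityThresholds = field(default_factory=RarityThresholds)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}")
        for metric, models in self.models.items():
            if metric == "bc" and "pgls" in models:
                raise ValueError("PGLS is not performed for the botanical-country count")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Parse a flat ``key = value`` config file; paths are relative to it."""
        path = Path(path)
        base = path.parent
        kv: dict[str, str] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()

        def p(key, required=True):
            if key not in kv:
                if required:
                    raise ValueError(f"{path}: missing key {key!r}")
                return None
            return base / kv[key]

        thresholds = RarityThresholds(
            eoo_km2_max=float(kv.get("eoo_km2_max", 20_000.0)),
            specimens_max=int(kv.get("specimens_max", 5)),
        )
        cleaning = CleaningConfig(
            round_dp=int(kv.get("round_dp", 3)),
            grid_m=float(kv.get("grid_m", 110.0)),
            max_uncertainty_m=float(kv.get("max_uncertainty_m", 100_000.0)),
            ref_buffer_m=float(kv.get("ref_buffer_m", 1_000.0)),
            apply_native_filter=kv.get("apply_native_filter", "true").lower() != "false",
        )
        return cls(
            occurrences_geo=p("occurrences_geo"),
            occurrences_nongeo=p("occurrences_nongeo"),
            checklist=p("checklist"),
            trees=p("trees"),
            regions=p("regions"),
            ref_points=p("ref_points", required=False),
            out_dir=base / kv.get("out_dir", "results"),
            metrics=tuple(
                t.strip() for t in kv.get("metrics", "bc,specimens,eoo").split(",")
            ),
            group_by=tuple(
                t.strip() for t in kv.get("group_by", "").split(",") if t.strip()
            ),
            subset=kv.get("subset", "all"),
            island_mode=kv.get("island_mode", "any"),
            thresholds=thresholds,
            cleaning=cleaning,
        )


@dataclass
class AnalysisResult:
    range_table: pd.DataFrame
    cleaning_report: pd.DataFrame
    rarity: pd.DataFrame
    fits: pd.DataFrame
    manifest: dict
    paths: dict


def subset_species(
    checklist: Sequence[ChecklistEntry],
    atlas: RegionAtlas,
    mode: str,
    *,
    island_mode: str = "any",
    tropics_lat_deg: float = TROPICS_LAT_DEG,
) -> list[ChecklistEntry]:
    """Apply a sensitivity subset to the checklist.

    ``tropical_only`` keeps species whose native-region centroid latitudes
    average within the tropics (simple, unweighted mean).
    ``exclude_oceanic_islands`` drops species with any (``island_mode ==
    'any'``, default) or only (``'all'``) oceanic-island native regions.
    """
    if mode == "all":
        return list(checklist)
    out = []
    for e in checklist:
        if mode == "tropical_only":
            lats = []
            for c in e.native_regions:
                if c not in atlas.centroids:
                    raise ValueError(f"region {c} has no centroid in atlas")
                lats.append(atlas.centroids[c][0])
            if abs(float(np.mean(lats))) <= tropics_lat_deg:
                out.append(e)
        elif mode == "exclude_oceanic_islands":
            flags = [c in atlas.oceanic_islands for c in e.native_regions]
            drop = any(flags) if island_mode == "any" else all(flags)
            if not drop:
                out.append(e)
        else:
            raise ValueError(f"unknown subset mode {mode!r}")
    return out


def _metric_series(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Rows with the metric defined, plus the raw response column ``y_raw``."""
    if metric == "bc":
        d = table[["species", "lifeform", "family", "n_botanical_countries"]].copy()
        d["y_raw"] = d.pop("n_botanical_countries").astype(float)
        return d
    if metric == "specimens":
        d = table.loc[table["specimen_count"].notna(),
                      ["species", "lifeform", "family", "specimen_count"]].copy()
        d["y_raw"] = d.pop("specimen_count").astype(float)
        return d[d["y_raw"] > 0]
    if metric == "eoo":
        d = table.loc[table["eoo_km2"].notna(),
                      ["species", "lifeform", "family", "eoo_km2"]].copy()
        d["y_raw"] = d.pop("eoo_km2").astype(float)
        n_zero = int((d["y_raw"] <= 0).sum())
        if n_zero:
            log.info("eoo: excluding %d zero-area EOO values from log models", n_zero)
        return d[d["y_raw"] > 0]
    raise ValueError(f"unknown metric {metric!r}")


_COEF_NAMES = ("intercept", "epiphyte")


def _design(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = sub["y_raw"].to_numpy(dtype=float)
    x = (sub["lifeform"] == "epiphyte").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    return y, X


def _fit_row(metric, model, group, tree_index, fit: RegressionFit) -> dict:
    eff = effect_size_percent(fit, 1)
    return {
        "metric": metric,
        "model": model,
        "group": group,
        "tree_index": tree_index,
        "beta_lifeform": float(fit.beta[1]),
        "se": float(fit.se[1]),
        "percent": eff.percent,
        "ci_low": eff.ci_low,
        "ci_high": eff.ci_high,
        "lambda_hat": fit.lambda_hat if fit.lambda_hat is not None else np.nan,
        "phi": fit.dispersion_phi if fit.dispersion_phi is not None else np.nan,
        "n": fit.n_obs,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full pipeline and write its report bundle.

    Outputs in ``config.out_dir``: ``cleaning_report.csv``,
    ``range_table.csv``, ``rarity.csv``, ``fits.csv`` (per-tree PGLS rows
    plus ``tree_index = 'mean'`` aggregate rows, where ``se`` is the
    between-tree spread) and ``manifest.json`` (config echo, input
    checksums, version, record counts). Any stage error aborts with the
    stage name attached.
    """
    stage = "read_inputs"
    try:
        occ_geo = read_occurrences(config.occurrences_geo)
        occ_nongeo = read_occurrences(config.occurrences_nongeo)
        checklist_res = read_checklist(config.checklist)
        atlas = RegionAtlas.from_geojson(config.regions)
        trees = read_trees(config.trees)
        refs = read_ref_points(config.ref_points) if config.ref_points else []

        checklist = list(checklist_res.records)
        atlas.validate_checklist(checklist)

        stage = "subset"
        checklist = subset_species(
            checklist, atlas, config.subset, island_mode=config.island_mode
        )
        keep = {e.species for e in checklist}

        stage = "cleaning"
        geo_a, nongeo_a = partition_records(occ_geo.records)
        geo_b, nongeo_b = partition_records(occ_nongeo.records)
        clean_geo, clean_nongeo, report = clean_all(
            geo_a + geo_b, nongeo_a + nongeo_b, checklist, atlas, refs,
            config.cleaning,
        )

        stage = "range_metrics"
        table = build_range_table(checklist, clean_geo, clean_nongeo)

        stage = "rarity"
        table = classify_rarity(table, config.thresholds)
        rarity = rarity_proportions(
            table, ("lifeform",) + tuple(config.group_by)
        )

        stage = "regression"
        fit_rows = []
        # normalized species name -> verbatim tip label, per tree (Newick
        # writers commonly swap spaces and underscores)
        tip_maps = [
            {
                normalize_species_label(l.taxon.label): l.taxon.label
                for l in t.leaf_node_iter()
            }
            for t in trees
        ]
        for metric in config.metrics:
            data = _metric_series(table, metric)
            groups: list[tuple[str, pd.DataFrame]] = [("all", data)]
            for key in config.group_by:
                for val in sorted(data[key].dropna().unique()):
                    groups.append((f"{key}={val}", data[data[key] == val]))
            for model in config.models.get(metric, ()):
                for gname, sub in groups:
                    counts = sub["lifeform"].value_counts()
                    if (
                        len(sub) < 4
                        or counts.get("epiphyte", 0) < 2
                        or counts.get("terrestrial", 0) < 2
                    ):
                        log.info("skip %s/%s/%s: too few observations",
                                 metric, model, gname)
                        continue
                    if model == "quasipoisson":
                        y, X = _design(sub)
                        fit = quasipoisson_glm(y, X, coef_names=_COEF_NAMES)
                        fit_rows.append(_fit_row(metric, model, gname, "", fit))
                    elif model == "ols":
                        y, X = _design(sub)
                        fit = ols_log(y, X, coef_names=_COEF_NAMES)
                        fit_rows.append(_fit_row(metric, model, gname, "", fit))
                    elif model == "pgls":
                        per_tree = []
                        for ti, (t, tipmap) in enumerate(zip(trees, tip_maps)):
                            norm = sub["species"].map(normalize_species_label)
                            m = norm.isin(tipmap)
                            dropped = int((~m).sum())
                            if dropped:
                                log.info(
                                    "%s/pgls/%s tree %d: %d species not in tree",
                                    metric, gname, ti, dropped,
                                )
                            subt = sub[m]
                            counts_t = subt["lifeform"].value_counts()
                            if (
                                len(subt) < 4
                                or counts_t.get("epiphyte", 0) < 2
                                or counts_t.get("terrestrial", 0) < 2
                            ):
                                continue
                            y, X = _design(subt)
                            taxa = [
                                tipmap[normalize_species_label(s)]
                                for s in subt["species"]
                            ]
                            fit = pgls_ml(
                                np.log(y), X, t, taxa, coef_names=_COEF_NAMES,
                            )
                            per_tree.append(fit)
                            fit_rows.append(_fit_row(metric, model, gname, ti, fit))
                        if per_tree:
                            summ = aggregate_trees(per_tree)
                            agg = {
                                "metric": metric, "model": model, "group": gname,
                                "tree_index": "mean",
                                "beta_lifeform": float(summ.beta_mean[1]),
                                "se": float(summ.beta_spread[1]),
                                "percent": 100.0 * (np.exp(summ.beta_mean[1]) - 1.0),
                                "ci_low": np.nan, "ci_high": np.nan,
                                "lambda_hat": float(np.nanmean(summ.lambda_hats)),
                                "phi": np.nan,
                                "n": int(per_tree[0].n_obs),
                            }
                            fit_rows.append(agg)
                    else:
                        raise ValueError(f"unknown model {model!r}")
        fits = pd.DataFrame(fit_rows)

        stage = "write_outputs"
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cleaning_report": out / "cleaning_report.csv",
            "range_table": out / "range_table.csv",
            "rarity": out / "rarity.csv",
            "fits": out / "fits.csv",
            "manifest": out / "manifest.json",
        }
        report.to_frame().to_csv(paths["cleaning_report"], index=False)
        write_range_table(table, paths["range_table"])
        rarity.to_csv(paths["rarity"], index=False)
        fits.to_csv(paths["fits"], index=False)
        manifest = {
            "package": "epirange",
            "version": __version__,
            "subset": config.subset,
            "metrics": list(config.metrics),
            "group_by": list(config.group_by),
            "thresholds": {
                "eoo_km2_max": config.thresholds.eoo_km2_max,
                "specimens_max": config.thresholds.specimens_max,
            },
            "cleaning": {
                "round_dp": config.cleaning.round_dp,
                "grid_m": config.cleaning.grid_m,
                "max_uncertainty_m": config.cleaning.max_uncertainty_m,
                "ref_buffer_m": config.cleaning.ref_buffer_m,
                "apply_native_filter": config.cleaning.apply_native_filter,
            },
            "inputs": {
                "occurrences_geo": _sha256(config.occurrences_geo),
                "occurrences_nongeo": _sha256(config.occurrences_nongeo),
                "checklist": _sha256(config.checklist),
                "trees": _sha256(config.trees),
                "regions": _sha256(config.regions),
            },
            "counts": {
                "species": len(checklist),
                "species_in_occurrences_not_checklist": len(
                    table.attrs.get("unknown_species", [])
                ),
                "records_geo_in": len(geo_a) + len(geo_b),
                "records_nongeo_in": len(nongeo_a) + len(nongeo_b),
                "records_geo_clean": len(clean_geo),
                "records_nongeo_clean": len(clean_nongeo),
                "trees": len(trees),
            },
        }
        with paths["manifest"].open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return AnalysisResult(
        range_table=table,
        cleaning_report=report.to_frame(),
        rarity=rarity,
        fits=fits,
        manifest=manifest,
        paths=paths,
    )
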