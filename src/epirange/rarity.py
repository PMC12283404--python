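"""Rarity classification at fixed range-size thresholds.

A species is rare by extent of occurrence if EOO < 20,000 km^2 (the
IUCN Red List criterion B1 threshold for a threatened category, strict
inequality) and rare by abundance proxy if it has five or fewer cleaned
specimen records (inclusive). Species whose metric is undefined are
excluded from the relevant denominator, matching the convention of
quoting proportions "of species for which the metric was estimated".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["RarityThresholds", "classify_rarity", "rarity_proportions"]


@dataclass(frozen=True)
class RarityThresholds:
    """Rarity cutoffs: EOO strictly below ``eoo_km2_max`` km^2; specimen
    count at most ``specimens_max``."""

    eoo_km2_max: float = 20_000.0
    specimens_max: int = 5

    def __post_init__(self) -> None:
        if self.eoo_km2_max <= 0 or self.specimens_max <= 0:
            raise ValueError("thresholds must be positive")


def classify_rarity(
    table: pd.DataFrame, thr: RarityThresholds = RarityThresholds()
) -> pd.DataFrame:
    """Add ``rare_by_eoo`` and ``rare_by_specimens`` flags to a range table.

    Flags are nullable booleans: missing where the underlying metric is
    missing, so such species drop out of proportion denominators.
    """
    out = table.copy()
    eoo = pd.to_numeric(out["eoo_km2"], errors="raise")
    out["rare_by_eoo"] = pd.array(
        [pd.NA if pd.isna(v) else bool(v < thr.eoo_km2_max) for v in eoo],
        dtype="boolean",
    )
    cnt = out["specimen_count"]
    out["rare_by_specimens"] = pd.array(
        [pd.NA if pd.isna(v) else bool(v <= thr.specimens_max) for v in cnt],
        dtype="boolean",
    )
    return out


def rarity_proportions(
    table: pd.DataFrame, group_keys: Sequence[str] = ("lifeform",)
) -> pd.DataFrame:
    """Per-group counts and proportions of rare species.

    Denominators are the species with the relevant metric defined. Empty
    denominators yield missing proportions.
    """
    group_keys = list(group_keys)
    for k in group_keys:
        if k not in table.columns:
            raise ValueError(f"unknown group key {k!r}")
    if "rare_by_eoo" not in table.columns or "rare_by_specimens" not in table.columns:
        raise ValueError("table is not classified; run classify_rarity first")

    rows = []
    grouped = table.groupby(group_keys, dropna=False, sort=True, observed=True)
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        re = sub["rare_by_eoo"]
        rs = sub["rare_by_specimens"]
        n_eoo = int(re.notna().sum())
        n_rare_eoo = int((re == True).sum())  # noqa: E712 (boolean dtype with NA)
        n_spec = int(rs.notna().sum())
        n_rare_spec = int((rs == True).sum())  # noqa: E712
        rows.append(
            dict(zip(group_keys, key))
            | {
                "n_with_eoo": n_eoo,
                "n_rare_eoo": n_rare_eoo,
                "prop_rare_eoo": (n_rare_eoo / n_eoo) if n_eoo else pd.NA,
                "n_with_specimens": n_spec,
                "n_rare_specimens": n_rare_spec,
                "prop_rare_specimens": (n_rare_spec / n_spec) if n_spec else pd.NA,
            }
        )
    return pd.DataFrame(rows)
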