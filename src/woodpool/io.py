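"""CSV readers/writers and schema validation for the survey tables.

All tables are plain CSV with explicit headers.  Units: diameters cm,
lengths/heights m, areas ha (stands, plots) or m^2 (bark), lichen cover
cm^2.  Validation enforces the dead-wood class bounds row by row and
reports offending row numbers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import (
    DIAMETER_BOUNDS,
    DW_TYPES,
    STAND_TYPES,
    STUMP_MAX_HEIGHT_M,
    TREE_SPECIES,
)
from .synthetic import ObservationTable

STAND_COLUMNS = [
    "stand_id", "stand_type", "area_ha", "age_yr",
    "transect_length_m", "snag_plot_area_ha", "small_plot_area_ha",
]
ITEM_COLUMNS = [
    "item_id", "stand_id", "stand_type", "tree_species", "dw_type",
    "diameter_cm", "length_m", "bark_fraction",
]
OBS_COLUMNS = {
    "fungi": ["species", "item_id"],
    "lichens": ["species", "item_id", "cover_cm2"],
    "beetles": ["species", "sample_id", "item_id", "count"],
}
SAMPLE_COLUMNS = ["sample_id", "item_id", "bark_area_m2"]


class SchemaError(ValueError):
    """Raised when a table's columns or rows violate the schema."""


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise SchemaError(
            f"{name}: missing columns {missing or 'none'}, "
            f"unknown columns {unknown or 'none'}"
        )


def validate_stand_table(stands: pd.DataFrame) -> None:
    _check_columns(stands, STAND_COLUMNS, "stand table")
    bad = []
    for i, row in stands.iterrows():
        if row["stand_type"] not in STAND_TYPES:
            bad.append(f"row {i}: unknown stand_type {row['stand_type']!r}")
        if row["area_ha"] <= 0:
            bad.append(f"row {i}: area_ha must be > 0")
    if bad:
        raise SchemaError("stand table: " + "; ".join(bad[:20]))


def validate_item_table(items: pd.DataFrame) -> None:
    """Class-bound checks: FWD diameter in (1, 10) cm, others > 10 cm;
    stump height < 0.5 m, snag height > 0.5 m; bark fraction in [0, 1]."""
    _check_columns(items, ITEM_COLUMNS, "item table")
    bad = []
    for i, row in items.iterrows():
        dw = row["dw_type"]
        if dw not in DW_TYPES:
            bad.append(f"row {i}: unknown dw_type {dw!r}")
            continue
        if row["tree_species"] not in TREE_SPECIES:
            bad.append(f"row {i}: unknown tree_species {row['tree_species']!r}")
        d = row["diameter_cm"]
        lo, hi = DIAMETER_BOUNDS[dw]
        if d <= lo or (hi is not None and d >= hi):
            bad.append(
                f"row {i}: {dw} diameter {d} cm outside class bounds "
                f"({lo}, {hi if hi is not None else 'inf'})"
            )
        if row["length_m"] <= 0:
            bad.append(f"row {i}: length_m must be > 0")
        elif dw == "stump" and row["length_m"] >= STUMP_MAX_HEIGHT_M:
            bad.append(f"row {i}: stump height {row['length_m']} m must be < 0.5")
        elif dw == "snag" and row["length_m"] <= STUMP_MAX_HEIGHT_M:
            bad.append(f"row {i}: snag height {row['length_m']} m must be > 0.5")
        if not 0.0 <= row["bark_fraction"] <= 1.0:
            bad.append(f"row {i}: bark_fraction outside [0, 1]")
    if bad:
        raise SchemaError("item table: " + "; ".join(bad[:20]))


def read_stand_table(path: str | Path) -> pd.DataFrame:
    stands = pd.read_csv(path)
    validate_stand_table(stands)
    return stands


def read_item_table(path: str | Path) -> pd.DataFrame:
    items = pd.read_csv(path)
    validate_item_table(items)
    return items


def read_observation_table(
    path: str | Path, taxon: str, samples_path: str | Path | None = None
) -> ObservationTable:
    obs = pd.read_csv(path)
    _check_columns(obs, OBS_COLUMNS[taxon], f"{taxon} observation table")
    samples = None
    if taxon == "beetles":
        if samples_path is None:
            raise SchemaError("beetle observations require a samples table")
        samples = pd.read_csv(samples_path)
        _check_columns(samples, SAMPLE_COLUMNS, "beetle samples table")
        if (samples["bark_area_m2"] <= 0).any():
            raise SchemaError("beetle samples: bark_area_m2 must be > 0")
        if (obs["count"] < 0).any():
            raise SchemaError("beetle observations: counts must be >= 0")
    if taxon == "lichens" and (obs["cover_cm2"] < 0).any():
        raise SchemaError("lichen observations: cover_cm2 must be >= 0")
    return ObservationTable(taxon, obs, samples=samples)


def write_tables(
    out_dir: str | Path,
    stands: pd.DataFrame,
    items: pd.DataFrame,
    obs_tables: dict[str, ObservationTable],
) -> dict[str, Path]:
    """Write all tables as CSV under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["stands"] = out / "stands.csv"
    stands.to_csv(paths["stands"], index=False)
    paths["items"] = out / "items.csv"
    items.to_csv(paths["items"], index=False)
    for taxon, table in obs_tables.items():
        p = out / f"obs_{taxon}.csv"
        table.obs.to_csv(p, index=False)
        paths[f"obs_{taxon}"] = p
        if table.samples is not None:
            sp = out / f"samples_{taxon}.csv"
            table.samples.to_csv(sp, index=False)
            paths[f"samples_{taxon}"] = sp
    return paths


def read_all(
    stand_path: str | Path,
    item_path: str | Path,
    obs_paths: dict[str, str | Path],
    sample_paths: dict[str, str | Path] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, ObservationTable]]:
    """Read and validate the full table set for a pipeline run."""
    stands = read_stand_table(stand_path)
    items = read_item_table(item_path)
    unknown = set(items["stand_id"]) - set(stands["stand_id"])
    if unknown:
        raise SchemaError(f"item table references unknown stands: {sorted(unknown)[:5]}")
    sample_paths = sample_paths or {}
    obs = {
        taxon: read_observation_table(p, taxon, sample_paths.get(taxon))
        for taxon, p in obs_paths.items()
    }
    return stands, items, obs
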