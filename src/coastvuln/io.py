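"""Shared readers/writers, input validation, and run reporting.

All tabular exchange is CSV with explicit headers; climate grids are
NetCDF (one file per model/variable/layer/period); configuration is YAML.
Floats are written with a fixed repr so identical runs produce byte-identical
files. ``validate_bundle`` performs a schema and referential-integrity check
of every input table and reports *all* violations, not just the first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coastvuln.adaptive import ALL_METRICS
from coastvuln.grids import (
    ClimateField,
    SpeciesRange,
    read_climate_dir,
    read_ranges_csv,
    write_climate_dir,
    write_ranges_csv,
)

__all__ = [
    "InputBundle",
    "read_bundle",
    "read_table",
    "validate_bundle",
    "write_bundle",
    "write_report",
    "write_table",
]

FLOAT_FORMAT = "%.12g"

LANDINGS_COLUMNS = ["community", "port_group", "species", "year", "weight",
                    "revenue", "confidential", "category"]


@dataclass
class InputBundle:
    """The five pipeline inputs in memory."""

    climate: list[ClimateField]
    ranges: list[SpeciesRange]
    receipts: pd.DataFrame
    reliance: pd.DataFrame
    tracts: pd.DataFrame
    mapping: pd.DataFrame
    group_map: dict[str, dict[str, float]]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_bundle(bundle: InputBundle, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_climate_dir(bundle.climate, path / "climate")
    write_ranges_csv(bundle.ranges, path / "ranges.csv")
    write_table(bundle.receipts, path / "landings.csv")
    write_table(bundle.reliance, path / "reliance.csv")
    write_table(bundle.tracts, path / "tracts.csv")
    write_table(bundle.mapping, path / "tract_community.csv")
    with open(path / "group_map.yaml", "w") as fh:
        yaml.safe_dump(bundle.group_map, fh, sort_keys=True)


def read_bundle(path: str | Path) -> InputBundle:
    path = Path(path)
    climate = read_climate_dir(path / "climate")
    lon, lat = climate[0].lon, climate[0].lat
    group_map_path = path / "group_map.yaml"
    group_map = {}
    if group_map_path.exists():
        with open(group_map_path) as fh:
            group_map = yaml.safe_load(fh) or {}
    return InputBundle(
        climate=climate,
        ranges=read_ranges_csv(path / "ranges.csv", lon, lat),
        receipts=read_table(path / "landings.csv"),
        reliance=read_table(path / "reliance.csv"),
        tracts=read_table(path / "tracts.csv"),
        mapping=read_table(path / "tract_community.csv"),
        group_map=group_map,
    )


def validate_bundle(bundle: InputBundle) -> list[str]:
    """Schema, value-range, and referential-integrity check of all inputs.

    Returns the full list of violations (empty = valid).
    """
    v: list[str] = []
    receipts = bundle.receipts
    missing = [c for c in LANDINGS_COLUMNS if c not in receipts.columns]
    if missing:
        v.append(f"landings: missing columns {missing}")
    else:
        for i, row in receipts[receipts["weight"] < 0].iterrows():
            v.append(f"landings row {i}: negative weight {row['weight']}")
        for i, row in receipts[receipts["revenue"] < 0].iterrows():
            v.append(f"landings row {i}: negative revenue {row['revenue']}")
        multi_pg = (receipts.groupby("community")["port_group"].nunique() > 1)
        for comm in multi_pg[multi_pg].index:
            v.append(f"landings: community {comm} maps to multiple port groups")
        bad_cat = set(receipts["category"]) - {"normal", "other_misc",
                                               "unidentified_group"}
        if bad_cat:
            v.append(f"landings: unknown categories {sorted(bad_cat)}")

    rel = bundle.reliance
    if not {"community", "reliance"} <= set(rel.columns):
        v.append("reliance: needs columns community, reliance")
    else:
        if (rel["reliance"] < 0).any():
            v.append("reliance: negative values present")
        if "community" in receipts.columns:
            no_rel = set(receipts["community"]) - set(rel["community"])
            if no_rel:
                v.append(f"reliance: communities missing: {sorted(no_rel)}")

    tracts, mapping = bundle.tracts, bundle.mapping
    if "tract" not in tracts.columns:
        v.append("tracts: missing 'tract' column")
    missing_metrics = [m for m in ALL_METRICS if m not in tracts.columns]
    if missing_metrics:
        v.append(f"tracts: missing metrics {missing_metrics}")
    elif tracts[ALL_METRICS].isna().any().any():
        v.append("tracts: non-finite metric values present")
    if not {"tract", "community"} <= set(mapping.columns):
        v.append("tract mapping: needs columns tract, community")
    else:
        unmapped = set(mapping["tract"]) - set(tracts.get("tract", []))
        if unmapped:
            v.append(f"tract mapping: tracts without indicator rows: {sorted(unmapped)}")
        if "community" in receipts.columns:
            no_tract = set(receipts["community"]) - set(mapping["community"])
            if no_tract:
                v.append(f"tract mapping: communities without tracts: {sorted(no_tract)}")

    for r in bundle.ranges:
        if np.nanmax(r.probability) < 1e-12:
            v.append(f"ranges: species {r.species} has an empty probability grid")
    unid = set()
    if "category" in receipts.columns:
        unid = set(receipts.loc[receipts["category"] == "unidentified_group",
                                "species"])
    unmapped_groups = unid - set(bundle.group_map)
    if unmapped_groups:
        v.append(f"group map: unidentified groups without split rules: "
                 f"{sorted(unmapped_groups)}")
    return v


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records"))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(summary: dict, out_dir: str | Path) -> None:
    """Machine-readable JSON summary plus a short human-readable digest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(summary)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    lines = ["community vulnerability run summary", "=" * 36]
    for key in sorted(payload):
        val = payload[key]
        if isinstance(val, (int, float, str)) or val is None:
            lines.append(f"{key}: {val}")
        elif isinstance(val, list):
            lines.append(f"{key}: {len(val)} entries")
        else:
            lines.append(f"{key}: ...")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
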