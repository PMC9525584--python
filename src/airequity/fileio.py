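"""Readers and writers for the pipeline's canonical file formats.

Tract tables and weight mappings are plain CSV.  Gridded concentration
fields are long-format CSV (``row,col,value``) by default, with a NetCDF
option (dimensions ``row``/``col``, variable ``pm25``) read and written
through xarray's scipy backend.  Floats in region files are written with 17
significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from airequity.exposure import (
    TRACT_COLUMNS,
    WEIGHT_COLUMNS,
    ConcentrationField,
    validate_tracts,
)

__all__ = [
    "read_tracts",
    "write_tracts",
    "read_weights",
    "write_weights",
    "read_grid",
    "write_grid",
    "write_region_files",
    "read_region_files",
]

_FLOAT_FMT = "%.17g"


def read_tracts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str, "county_id": str},
                     float_precision="round_trip")
    for col in TRACT_COLUMNS[2:]:
        df[col] = df[col].astype(float)
    return validate_tracts(df[TRACT_COLUMNS])


def write_tracts(tracts: pd.DataFrame, path) -> None:
    validate_tracts(tracts)
    tracts[TRACT_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str, "row": int, "col": int},
                     float_precision="round_trip")
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weights file {path} missing columns: {missing}")
    df["weight"] = df["weight"].astype(float)
    return df[WEIGHT_COLUMNS]


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_grid(path, is_delta: bool = False) -> ConcentrationField:
    """Read a gridded field; dispatches on extension (.nc -> NetCDF, else CSV)."""
    path = Path(path)
    if path.suffix == ".nc":
        return _read_grid_netcdf(path, is_delta)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("row", "col", "value"):
        if col not in df.columns:
            raise ValueError(f"grid file {path} missing column {col!r}")
    nrow = int(df["row"].max()) + 1
    ncol = int(df["col"].max()) + 1
    if len(df) != nrow * ncol:
        raise ValueError(f"grid file {path} is not a dense {nrow}x{ncol} grid")
    arr = np.full((nrow, ncol), np.nan)
    arr[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["value"].to_numpy(float)
    return ConcentrationField(arr, is_delta=is_delta)


def write_grid(field: ConcentrationField, path) -> None:
    """Write a gridded field; dispatches on extension (.nc -> NetCDF, else CSV)."""
    path = Path(path)
    if path.suffix == ".nc":
        _write_grid_netcdf(field, path)
        return
    nrow, ncol = field.shape
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    pd.DataFrame(
        {"row": rows.ravel(), "col": cols.ravel(), "value": field.values.ravel()}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_grid_netcdf(path: Path, is_delta: bool) -> ConcentrationField:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        return ConcentrationField(
            ds["pm25"].transpose("row", "col").to_numpy(), is_delta=is_delta
        )


def _write_grid_netcdf(field: ConcentrationField, path: Path) -> None:
    import xarray as xr

    ds = xr.Dataset(
        {"pm25": (("row", "col"), field.values)},
        attrs={"units": "ug/m3"},
    )
    ds.to_netcdf(path, engine="scipy")


def write_region_files(region, directory, grid_format: str = "csv") -> dict:
    """Write a synthetic region as pipeline inputs plus a run-ready config.

    Returns the manifest: logical name -> path (relative to ``directory``),
    also stored as ``manifest.json``.
    """
    if grid_format not in ("csv", "netcdf"):
        raise ValueError("grid_format must be 'csv' or 'netcdf'")
    ext = "csv" if grid_format == "csv" else "nc"
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, str] = {
        "tracts": "tracts.csv",
        "weights": "weights.csv",
        "baseline": f"baseline_pm25.{ext}",
    }
    write_tracts(region.tracts, directory / manifest["tracts"])
    write_weights(region.weights, directory / manifest["weights"])
    write_grid(region.baseline_field, directory / manifest["baseline"])

    scenario_cfg = {}
    for name in sorted(region.scenario_deltas):
        fname = f"delta_{name}.{ext}"
        manifest[f"scenario:{name}"] = fname
        write_grid(region.scenario_deltas[name], directory / fname)
        scenario_cfg[name] = {
            "path": fname,
            "kind": "delta",
            "cost": float(region.scenario_costs[name]),
        }

    config = {
        "tracts": manifest["tracts"],
        "weights": manifest["weights"],
        "baseline": manifest["baseline"],
        "scenarios": scenario_cfg,
        "valuation": {"vsl": 9.7e6},
        "metadata": _jsonable(region.metadata),
    }
    manifest["config"] = "config.yaml"
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_region_files(directory):
    """Reconstruct a :class:`~airequity.synthetic.SyntheticRegion` from disk."""
    from airequity.synthetic import SyntheticRegion

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    with open(directory / manifest["config"]) as fh:
        config = yaml.safe_load(fh)
    deltas = {}
    costs = {}
    for name, scen in config["scenarios"].items():
        deltas[name] = read_grid(directory / scen["path"], is_delta=True)
        costs[name] = float(scen["cost"])
    return SyntheticRegion(
        tracts=read_tracts(directory / manifest["tracts"]),
        baseline_field=read_grid(directory / manifest["baseline"]),
        scenario_deltas=deltas,
        scenario_costs=costs,
        weights=read_weights(directory / manifest["weights"]),
        metadata=config.get("metadata", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
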