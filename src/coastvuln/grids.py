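"""Gridded containers: climate fields and species occurrence ranges.

Climate fields are monthly values on a regular lon-lat grid, one field per
(variable, layer, period, model); NetCDF is the on-disk format (one file per
field, dims ``time, lat, lon`` plus the domain mask). Species ranges are
static probability-of-occurrence grids with a benthic/pelagic habitat label,
stored as long-format CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from coastvuln.config import CLIMATE_VARIABLES, LAYERS, PERIODS

__all__ = [
    "ClimateField",
    "SpeciesRange",
    "read_climate_dir",
    "read_ranges_csv",
    "write_climate_dir",
    "write_ranges_csv",
]


@dataclass
class ClimateField:
    """One variable/layer/period/model grid of monthly values.

    values: (time, lat, lon) float array; mask: (lat, lon) bool array,
    True = inside the analysis domain. Values may be anything outside the
    mask; they must be finite inside it.
    """

    variable: str
    layer: str
    period: str
    model: str
    values: np.ndarray
    mask: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        if self.variable not in CLIMATE_VARIABLES:
            raise ValueError(f"unknown climate variable {self.variable!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (time, lat, lon)")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask geometry does not match values")
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ValueError("non-finite values inside the domain mask")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.model, self.variable, self.layer, self.period)

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "value": (("time", "lat", "lon"), self.values),
                "mask": (("lat", "lon"), self.mask.astype(np.int8)),
            },
            coords={
                "time": np.arange(self.values.shape[0]),
                "lat": self.lat,
                "lon": self.lon,
            },
            attrs={
                "variable": self.variable,
                "layer": self.layer,
                "period": self.period,
                "model": self.model,
            },
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ClimateField":
        return cls(
            variable=ds.attrs["variable"],
            layer=ds.attrs["layer"],
            period=ds.attrs["period"],
            model=ds.attrs["model"],
            values=ds["value"].values,
            mask=ds["mask"].values.astype(bool),
            lon=ds["lon"].values,
            lat=ds["lat"].values,
        )


@dataclass
class SpeciesRange:
    """Probability-of-occurrence grid for one species.

    habitat decides which layer's climate the species experiences:
    benthic -> bottom, pelagic -> surface.
    """

    species: str
    habitat: str
    probability: np.ndarray
    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self) -> None:
        if self.habitat not in ("benthic", "pelagic"):
            raise ValueError(f"habitat must be 'benthic' or 'pelagic', got {self.habitat!r}")
        self.probability = np.asarray(self.probability, dtype=float)
        if self.probability.ndim != 2:
            raise ValueError("probability must be a (lat, lon) grid")
        if np.nanmin(self.probability) < 0 or np.nanmax(self.probability) > 1:
            raise ValueError("occurrence probabilities must lie in [0, 1]")

    @property
    def layer(self) -> str:
        return "bottom" if self.habitat == "benthic" else "surface"


def _field_filename(f: ClimateField) -> str:
    return f"{f.model}_{f.variable}_{f.layer}_{f.period}.nc"


def write_climate_dir(fields: list[ClimateField], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in fields:
        f.to_dataset().to_netcdf(path / _field_filename(f), engine="scipy")


def read_climate_dir(path: str | Path) -> list[ClimateField]:
    path = Path(path)
    fields = []
    for nc in sorted(path.glob("*.nc")):
        with xr.open_dataset(nc, engine="scipy") as ds:
            fields.append(ClimateField.from_dataset(ds.load()))
    if not fields:
        raise FileNotFoundError(f"no climate NetCDF files under {path}")
    return fields


def write_ranges_csv(ranges: list[SpeciesRange], path: str | Path) -> None:
    """Long-format CSV: species, habitat, lon, lat, probability (cells > 0 only)."""
    rows = []
    for r in ranges:
        ii, jj = np.nonzero(r.probability > 0)
        rows.append(pd.DataFrame({
            "species": r.species,
            "habitat": r.habitat,
            "lat": r.lat[ii],
            "lon": r.lon[jj],
            "probability": r.probability[ii, jj],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_ranges_csv(path: str | Path, lon: np.ndarray, lat: np.ndarray) -> list[SpeciesRange]:
    """Rebuild range grids on the supplied lon/lat axes (the climate geometry)."""
    df = pd.read_csv(path)
    lon_idx = {round(float(x), 9): i for i, x in enumerate(lon)}
    lat_idx = {round(float(x), 9): i for i, x in enumerate(lat)}
    out = []
    for (species, habitat), sub in df.groupby(["species", "habitat"], sort=True):
        grid = np.zeros((lat.size, lon.size))
        for la, lo, p in zip(sub["lat"], sub["lon"], sub["probability"]):
            grid[lat_idx[round(float(la), 9)], lon_idx[round(float(lo), 9)]] = p
        out.append(SpeciesRange(species=str(species), habitat=str(habitat),
                                probability=grid, lon=lon, lat=lat))
    return out
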