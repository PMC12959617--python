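"""Habitat thermal exposure from weekly gridded water temperatures.

Two exposure metrics summarise the thermal regime over a species' geographic
range: the maximum habitat temperature (97.5th percentile across the range of
the 30-year climatological mean of the annual maximum weekly temperature) and
the habitat thermal variability (range mean of the per-gridcell, across-year
average of the within-year coefficient of variation of weekly temperature).
Temperatures are stored in Kelvin internally — the CV denominator must be an
absolute scale — and maxima are reported in °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "WeeklyTemperatureCube",
    "RangeMask",
    "ExposureSummary",
    "NoDataError",
    "climatological_annual_max",
    "max_habitat_temperature",
    "within_year_cv",
    "thermal_variability",
    "exposure_for_species",
]

KELVIN_OFFSET = 273.15

# a (cell, year) contributes only if at least this fraction of weeks is present
MIN_WEEK_FRACTION = 0.5


class NoDataError(ValueError):
    """A range mask intersects no non-missing gridcells."""


class DataIntegrityError(ValueError):
    """Physically impossible values (e.g. non-positive Kelvin temperatures)."""


@dataclass
class WeeklyTemperatureCube:
    """Weekly water temperatures on a rectangular grid, in Kelvin.

    ``values`` has dims (year, week, lat, lon).  53-week years must be folded
    into 52 by the producer (week 53 averaged into week 52) so the cube stays
    rectangular.
    """

    values: xr.DataArray
    realm_tag: str  # "freshwater" or "marine"

    def __post_init__(self) -> None:
        if tuple(self.values.dims) != ("year", "week", "lat", "lon"):
            raise ValueError("cube dims must be (year, week, lat, lon)")
        finite = self.values.values[np.isfinite(self.values.values)]
        if finite.size and finite.min() <= 0:
            raise DataIntegrityError("temperatures must be positive Kelvin")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.sizes["lat"], self.values.sizes["lon"]

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {"water_temp": self.values},
            attrs={"realm_tag": self.realm_tag, "units": "K"},
        )
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "WeeklyTemperatureCube":
        with xr.open_dataset(path, engine="scipy") as ds:
            da = ds["water_temp"].load()
            units = str(ds.attrs.get("units", da.attrs.get("units", "K")))
            realm = str(ds.attrs.get("realm_tag", "marine"))
        if units.lower() in ("degc", "celsius", "c", "degrees_celsius"):
            da = da + KELVIN_OFFSET
        return cls(values=da, realm_tag=realm)


@dataclass
class RangeMask:
    """Boolean occupancy of a species on the cube grid."""

    species: str
    cells: np.ndarray  # bool, shape (lat, lon)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)
        if not self.cells.any():
            raise ValueError(f"empty range mask for {self.species}")

    @property
    def member_cells(self) -> set[int]:
        return set(np.flatnonzero(self.cells.ravel()))

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


@dataclass(frozen=True)
class ExposureSummary:
    """Per-species habitat exposure metrics."""

    species: str
    max_habitat_temp: float  # °C
    thermal_variability: float  # dimensionless CV
    n_cells: int
    realm_tag: str


def _year_week_counts(values: np.ndarray) -> np.ndarray:
    """Present-week counts per (year, lat, lon)."""
    return np.isfinite(values).sum(axis=1)


def climatological_annual_max(cube: WeeklyTemperatureCube) -> xr.DataArray:
    """Mean over years of the annual maximum weekly temperature, in °C.

    Years where a cell reports fewer than half its weeks are dropped for that
    cell; cells with no usable year propagate as missing.
    """
    vals = cube.values.values  # (year, week, lat, lon)
    n_weeks = vals.shape[1]
    usable = _year_week_counts(vals) >= max(2, MIN_WEEK_FRACTION * n_weeks)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing cells
        annual_max = np.nanmax(np.where(np.isfinite(vals), vals, -np.inf), axis=1)
        annual_max = np.where(usable, annual_max, np.nan)
        clim = np.nanmean(annual_max, axis=0) - KELVIN_OFFSET
    return xr.DataArray(
        clim, coords={"lat": cube.values["lat"], "lon": cube.values["lon"]},
        dims=("lat", "lon"), name="climatological_annual_max_degC",
    )


def within_year_cv(cube: WeeklyTemperatureCube) -> xr.DataArray:
    """Across-year mean of the within-year CV of weekly temperature.

    CV is sd/mean on the Kelvin scale, per cell and year (sample sd, ddof=1);
    the yearly values are then averaged.  Insufficiently observed
    (cell, year) combinations are dropped as in the annual maximum.
    """
    vals = cube.values.values
    n_weeks = vals.shape[1]
    counts = _year_week_counts(vals)
    usable = counts >= max(2, MIN_WEEK_FRACTION * n_weeks)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing cells
        mean = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
        if np.any(usable & (mean <= 0)):
            raise DataIntegrityError("non-positive mean temperature on Kelvin scale")
        cv = np.where(usable, sd / mean, np.nan)
        cv_clim = np.nanmean(cv, axis=0)
    return xr.DataArray(
        cv_clim, coords={"lat": cube.values["lat"], "lon": cube.values["lon"]},
        dims=("lat", "lon"), name="within_year_cv",
    )


def max_habitat_temperature(
    layer: xr.DataArray, mask: RangeMask, percentile: float = 97.5
) -> float:
    """Percentile of a per-gridcell layer over a species' range.

    Uses the linear-interpolation quantile (numpy's default) so the 97.5th
    percentile is reproducible bit-for-bit.
    """
    vals = np.asarray(layer.values)[mask.cells]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NoDataError(f"range of {mask.species} has no non-missing cells")
    return float(np.percentile(vals, percentile, method="linear"))


def thermal_variability(cv_layer: xr.DataArray, mask: RangeMask) -> float:
    """Unweighted mean of the CV layer over a species' range."""
    vals = np.asarray(cv_layer.values)[mask.cells]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NoDataError(f"range of {mask.species} has no non-missing cells")
    return float(vals.mean())


def exposure_for_species(
    fresh_cube: WeeklyTemperatureCube | None,
    marine_cube: WeeklyTemperatureCube | None,
    masks: Mapping[str, RangeMask],
    realms: Mapping[str, str],
    percentile: float = 97.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Exposure summaries for every species with a usable mask.

    Freshwater species are summarised from the freshwater cube; marine and
    brackish species from the marine (sea-surface) cube.  Species without a
    mask, or whose realm's cube is absent, go to the skip report.

    Returns a DataFrame (species, realm, max_habitat_temp,
    thermal_variability, n_cells) and the list of skipped species.
    """
    layers: dict[str, tuple[xr.DataArray, xr.DataArray]] = {}
    if fresh_cube is not None:
        layers["freshwater"] = (
            climatological_annual_max(fresh_cube), within_year_cv(fresh_cube)
        )
    if marine_cube is not None:
        layers["marine"] = (
            climatological_annual_max(marine_cube), within_year_cv(marine_cube)
        )

    rows, skipped = [], []
    for species in sorted(realms):
        realm = realms[species]
        cube_key = "freshwater" if realm == "freshwater" else "marine"
        mask = masks.get(species)
        if mask is None or cube_key not in layers:
            skipped.append(species)
            continue
        max_layer, cv_layer = layers[cube_key]
        try:
            summary = ExposureSummary(
                species=species,
                max_habitat_temp=max_habitat_temperature(max_layer, mask, percentile),
                thermal_variability=thermal_variability(cv_layer, mask),
                n_cells=mask.n_cells,
                realm_tag=cube_key,
            )
        except NoDataError:
            skipped.append(species)
            continue
        rows.append(
            {
                "species": summary.species,
                "realm": realm,
                "max_habitat_temp": summary.max_habitat_temp,
                "thermal_variability": summary.thermal_variability,
                "n_cells": summary.n_cells,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["species", "realm", "max_habitat_temp", "thermal_variability", "n_cells"],
    )
    return frame, skipped
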