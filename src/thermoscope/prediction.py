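"""Global gridded predictions of heat tolerance, plasticity and safety margin.

A fitted realm model (model 3) is evaluated per gridcell using the cell's
climatological maximum weekly temperature and thermal variability.  Because
the cells are not tied to any particular species, the evaluation acclimation
temperature is anchored to the cell: the standardised acclimation value at
which the actual acclimation temperature would coincide with the cell's
maximum weekly temperature, derived from the empirical regression of actual
acclimation temperature on species maximum habitat temperature.  The ARR per
cell is the finite difference of predictions at the anchor and at the anchor
+1 °C.  Freshwater and marine layers are combined with freshwater priority,
and cells with high coefficient-propagated prediction uncertainty are
masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .models import ModelId, PhyloFit
from .plasticity import time_gained_pct, warming_tolerance

__all__ = [
    "AcclimationAnchor",
    "PredictionLayers",
    "fit_acclimation_anchor",
    "climatological_layers_for",
    "predict_layers",
    "apply_uncertainty_mask",
    "combine_realms",
]


def climatological_layers_for(cube) -> tuple[xr.DataArray, xr.DataArray]:
    """Exposure input layers of a cube: climatological annual max and CV."""
    from .exposure import climatological_annual_max, within_year_cv

    return climatological_annual_max(cube), within_year_cv(cube)

LAYER_NAMES = (
    "max_habitat_temp",
    "thermal_variability",
    "acclimation_std_anchor",
    "heat_tolerance",
    "arr",
    "warming_tolerance",
    "time_gained_pct",
    "prediction_sd",
)


@dataclass(frozen=True)
class AcclimationAnchor:
    """Empirical regression of actual acclimation temperature on habitat maxima.

    The anchor for a cell with maximum temperature T is the standardised
    acclimation value at which actual acclimation coincides with T:
    ``T − (intercept + slope·T)``.
    """

    intercept: float
    slope: float
    residual_sd: float
    n_species: int

    def anchor_std(self, max_temp):
        return np.asarray(max_temp, float) - (
            self.intercept + self.slope * np.asarray(max_temp, float)
        )


def fit_acclimation_anchor(
    records: pd.DataFrame, exposure: pd.DataFrame
) -> AcclimationAnchor:
    """OLS of actual acclimation temperature on species maximum habitat temp.

    ``records`` needs species and acclimation_temp columns; ``exposure``
    provides max_habitat_temp per species.  Requires at least 10 species.
    """
    merged = records.merge(
        exposure[["species", "max_habitat_temp"]], on="species", how="inner"
    ).dropna(subset=["acclimation_temp", "max_habitat_temp"])
    n_species = merged["species"].nunique()
    if n_species < 10:
        raise ValueError(f"anchor regression needs >= 10 species, got {n_species}")
    X = sm.add_constant(merged["max_habitat_temp"].to_numpy(float))
    res = sm.OLS(merged["acclimation_temp"].to_numpy(float), X).fit()
    return AcclimationAnchor(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(res.scale)),
        n_species=int(n_species),
    )


@dataclass
class PredictionLayers:
    """Per-gridcell prediction layers plus provenance metadata."""

    data: xr.Dataset  # variables per LAYER_NAMES + boolean "mask", "realm_tag"
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> xr.DataArray:
        return self.data[name]

    @property
    def mask(self) -> np.ndarray:
        return self.data["mask"].values.astype(bool)

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        ds["mask"] = ds["mask"].astype("int8")
        ds.attrs.update({k: str(v) for k, v in self.metadata.items()})
        ds.to_netcdf(path, engine="scipy")


def predict_layers(
    fit: PhyloFit,
    maxT_layer: xr.DataArray,
    cv_layer: xr.DataArray,
    realm_tag: str,
    anchor: AcclimationAnchor,
) -> PredictionLayers:
    """Evaluate a model-3 fit on co-registered exposure layers.

    Per cell: heat tolerance at the anchored acclimation; ARR as the
    +1 °C finite difference of predictions; warming tolerance; time gained
    (Eq-3 closed form of the ARR layer); and the prediction SD propagated
    from the coefficient covariance through the design row.  Cells where the
    anchor falls outside the fitted basis are still predicted (flagged as
    extrapolation in the metadata count).
    """
    if fit.model_id is not ModelId.MODEL3:
        raise ValueError("global prediction requires a model-3 fit")
    if maxT_layer.shape != cv_layer.shape or list(maxT_layer.dims) != list(cv_layer.dims):
        raise ValueError("max-temperature and CV layers are not co-registered")

    shape = maxT_layer.shape
    maxt = maxT_layer.values.ravel()
    cv = cv_layer.values.ravel()
    valid = np.isfinite(maxt) & np.isfinite(cv)
    anchor_std = anchor.anchor_std(maxt)

    def flat(values=np.nan):
        return np.full(maxt.shape, values, float)

    ht, arr, sd = flat(), flat(), flat()
    if valid.any():
        data = {
            "max_habitat_temp": maxt[valid],
            "thermal_variability": cv[valid],
            "acclimation_std": anchor_std[valid],
            "realm": np.full(valid.sum(), realm_tag, object),
        }
        ht[valid] = fit.predict(data)
        data_plus = dict(data, acclimation_std=anchor_std[valid] + 1.0)
        arr[valid] = fit.predict(data_plus) - ht[valid]
        sd[valid] = fit.predict_se(data)

    wt = warming_tolerance(ht, maxt)
    with np.errstate(divide="ignore", invalid="ignore"):
        tg = np.where(arr < 1, (1.0 / (1.0 - arr) - 1.0) * 100.0, np.nan)

    coords = maxT_layer.coords
    dims = maxT_layer.dims

    def wrap(v):
        return xr.DataArray(v.reshape(shape), coords=coords, dims=dims)

    ds = xr.Dataset(
        {
            "max_habitat_temp": wrap(maxt),
            "thermal_variability": wrap(cv),
            "acclimation_std_anchor": wrap(np.where(valid, anchor_std, np.nan)),
            "heat_tolerance": wrap(ht),
            "arr": wrap(arr),
            "warming_tolerance": wrap(wt),
            "time_gained_pct": wrap(tg),
            "prediction_sd": wrap(sd),
            "mask": wrap(np.zeros(maxt.shape)).astype(bool),
            "realm_tag": xr.DataArray(
                np.where(valid, realm_tag, "").reshape(shape), coords=coords, dims=dims
            ),
        }
    )
    return PredictionLayers(
        data=ds,
        metadata={
            "model_id": fit.model_id.value,
            "realm_tag": realm_tag,
            "anchor_intercept": anchor.intercept,
            "anchor_slope": anchor.slope,
            "n_valid_cells": int(valid.sum()),
        },
    )


def apply_uncertainty_mask(
    layers: PredictionLayers, sd_threshold: float | None = None,
    percentile: float = 90.0,
) -> PredictionLayers:
    """Suppress derived layers where the prediction SD is high.

    With no explicit threshold, cells above the given percentile of the SD
    layer are masked (default: worst 10%).  Masked cells carry no finite
    values in the derived layers; the threshold is recorded in metadata.
    """
    ds = layers.data.copy(deep=True)
    sd = ds["prediction_sd"].values
    finite = np.isfinite(sd)
    if sd_threshold is None:
        if not finite.any():
            raise ValueError("no finite prediction SDs to take a percentile of")
        sd_threshold = float(np.percentile(sd[finite], percentile))
    masked = finite & (sd > sd_threshold)
    ds["mask"] = (ds["mask"].dims, ds["mask"].values | masked)
    for name in ("heat_tolerance", "arr", "warming_tolerance", "time_gained_pct"):
        vals = ds[name].values
        vals[masked] = np.nan
        ds[name] = (ds[name].dims, vals)
    meta = dict(layers.metadata, sd_threshold=float(sd_threshold))
    return PredictionLayers(data=ds, metadata=meta)


def plot_layer(layers: PredictionLayers, name: str, path=None, cmap="viridis"):
    """Minimal rendering of one layer (masked cells transparent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.where(layers.mask, np.nan, layers[name].values)
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(values, origin="lower", cmap=cmap, aspect="auto")
    fig.colorbar(im, ax=ax, label=name)
    ax.set_xlabel("lon index")
    ax.set_ylabel("lat index")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def combine_realms(
    fresh: PredictionLayers, marine: PredictionLayers
) -> PredictionLayers:
    """Merge freshwater and marine layers into one global set.

    Cells with freshwater data take the freshwater values; remaining water
    cells take marine values (freshwater priority on overlap — coasts and
    estuaries); cells in neither stay missing.  Overlaps are counted in the
    metadata, and per-cell provenance is retained in ``realm_tag``.
    """
    if fresh.data.sizes != marine.data.sizes:
        raise ValueError("realm layers are on different grids")
    f_valid = np.isfinite(fresh.data["heat_tolerance"].values) | fresh.mask
    m_valid = np.isfinite(marine.data["heat_tolerance"].values) | marine.mask
    overlap = int((f_valid & m_valid).sum())

    ds = marine.data.copy(deep=True)
    for name in LAYER_NAMES:
        vals = ds[name].values.copy()
        fvals = fresh.data[name].values
        vals[f_valid] = fvals[f_valid]
        ds[name] = (ds[name].dims, vals)
    tag = ds["realm_tag"].values.astype(object).copy()
    tag[f_valid] = "freshwater"
    tag[m_valid & ~f_valid] = "marine"
    ds["realm_tag"] = (ds["realm_tag"].dims, tag)
    mask = marine.mask.copy()
    mask[f_valid] = fresh.mask[f_valid]
    ds["mask"] = (ds["mask"].dims, mask)
    meta = {
        "combined": True,
        "overlap_cells": overlap,
        "fresh": fresh.metadata,
        "marine": marine.metadata,
    }
    return PredictionLayers(data=ds, metadata=meta)
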