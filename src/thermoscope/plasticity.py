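"""Acclimation response ratios and the time bought by plasticity.

The acclimation response ratio (ARR) is the gain in heat tolerance per
degree of warm acclimation — the derivative of modelled heat tolerance with
respect to standardised acclimation temperature.  Combined with the warming
tolerance (heat tolerance minus maximum habitat temperature) and a warming
rate, it yields the time until overheating without plasticity (t₁) and with
plasticity (t₂); their relative difference, the time gained by plasticity,

    t₃ = (1/(1 − ARR) − 1) × 100 %,

is independent of the warming rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelId, PhyloFit

__all__ = [
    "PlasticityContext",
    "PlasticityResult",
    "arr_from_fit",
    "warming_tolerance",
    "overheating_times",
    "time_gained_pct",
    "species_metrics",
]


@dataclass(frozen=True)
class PlasticityContext:
    """Conditions at which the ARR derivative is evaluated.

    ``acclimation_std`` defaults to 0 (the species-level convention: the
    slope at each species' own mean acclimation temperature).  The warming
    rate (°C/yr) is only needed for t₁/t₂ and deliberately has no default.
    """

    thermal_variability: float
    realm: str = "marine"
    acclimation_std: float = 0.0
    warming_rate: float | None = None


@dataclass(frozen=True)
class PlasticityResult:
    arr: float
    warming_tolerance: float
    t1: float
    t2: float
    time_gained_pct: float
    already_overheated: bool = False


def arr_from_fit(fit: PhyloFit, ctx: PlasticityContext) -> float:
    """ARR as the analytic acclimation derivative of the fitted model.

    For the habitat models this is the linear acclimation coefficient plus
    the thermal-variability interaction times the context CV, plus the realm
    interaction contrast, plus the derivative of the stored orthogonal
    quadratic basis at the evaluation point (which is generally non-zero
    away from the basis centre).
    """
    if fit.model_id not in (ModelId.MODEL2, ModelId.MODEL3):
        raise ValueError("ARR extraction requires a model-2 or model-3 fit")
    coef = fit.coef["estimate"]
    if "acct" not in coef.index:
        raise ValueError("fit lacks acclimation terms")
    arr = coef["acct"] + coef["acct:tvar"] * ctx.thermal_variability
    realm_term = f"acct:realm[{ctx.realm}]"
    if realm_term in coef.index:
        arr += coef[realm_term]
    elif fit.model_id is ModelId.MODEL3 and ctx.realm != "marine":
        raise ValueError(f"unknown realm {ctx.realm!r} for model-3 fit")
    basis = fit.design.acct_basis
    if basis is not None:
        arr += coef["acct_q2"] * float(basis.derivative(ctx.acclimation_std))
    return float(arr)


def warming_tolerance(heat_tolerance, max_habitat_temp):
    """Thermal safety margin: heat tolerance − maximum habitat temperature.

    Negative values are meaningful: habitat maxima already exceed the
    (measured or modelled) tolerance.
    """
    return heat_tolerance - max_habitat_temp


def overheating_times(
    warming_tol: float, warming_rate: float, arr: float
) -> tuple[float, float, bool]:
    """Years until overheating without (t₁) and with (t₂) plasticity.

    t₁ = warming tolerance / warming rate; t₂ = t₁ / (1 − ARR).  A negative
    warming tolerance means the habitat maximum already exceeds tolerance:
    both times are 0 and the overheated flag is set.
    """
    if warming_rate <= 0:
        raise ValueError("warming_rate must be positive")
    if arr >= 1:
        raise ValueError("ARR >= 1 implies perfect compensation: infinite time")
    if warming_tol < 0:
        return 0.0, 0.0, True
    t1 = warming_tol / warming_rate
    return t1, t1 / (1.0 - arr), False


def time_gained_pct(arr):
    """Extra time until overheating afforded by plasticity, in percent.

    (1/(1 − ARR) − 1) × 100; equals (t₂/t₁ − 1) × 100 for any positive t₁,
    hence independent of the warming rate.
    """
    arr = np.asarray(arr, float)
    if np.any(arr >= 1):
        raise ValueError("ARR >= 1 implies unbounded time gain")
    out = (1.0 / (1.0 - arr) - 1.0) * 100.0
    return float(out) if out.ndim == 0 else out


def species_metrics(
    fit: PhyloFit,
    exposure: pd.DataFrame,
    warming_rate: float | None = None,
    acclimation_std: float = 0.0,
) -> pd.DataFrame:
    """Per-species ARR, warming tolerance and overheating times.

    ``exposure`` must carry species, realm, max_habitat_temp and
    thermal_variability.  Heat tolerance is the fixed-effect prediction of
    the fitted model at the species' exposure and the requested
    standardised acclimation temperature.
    """
    rows = []
    for _, r in exposure.iterrows():
        ctx = PlasticityContext(
            thermal_variability=r["thermal_variability"],
            realm=r["realm"] if r["realm"] in ("freshwater", "brackish") else "marine",
            acclimation_std=acclimation_std,
        )
        data = {
            "max_habitat_temp": [r["max_habitat_temp"]],
            "thermal_variability": [r["thermal_variability"]],
            "acclimation_std": [acclimation_std],
            "realm": [ctx.realm],
        }
        ht = float(fit.predict(data)[0])
        arr = arr_from_fit(fit, ctx)
        wt = warming_tolerance(ht, r["max_habitat_temp"])
        row = {
            "species": r["species"],
            "realm": r["realm"],
            "heat_tolerance": ht,
            "arr": arr,
            "warming_tolerance": wt,
            "time_gained_pct": time_gained_pct(arr) if arr < 1 else np.nan,
        }
        if warming_rate is not None:
            t1, t2, flag = overheating_times(wt, warming_rate, arr)
            row.update({"t1": t1, "t2": t2, "already_overheated": flag})
        rows.append(row)
    return pd.DataFrame(rows)
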