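"""Ingestion and harmonisation of heterogeneous upper-thermal-limit assays.

Upper thermal limits of fishes are measured either dynamically (CTmax: the
temperature is ramped from a start temperature at a fixed rate until loss of
function) or statically (LTmax: mortality after a fixed exposure at constant
temperature).  Because tolerated temperature falls with exposure duration,
endpoints from assays of different lengths are not directly comparable.  This
module computes the realised duration of each assay, estimates the slope of
heat tolerance against log-duration by a species-by-study bootstrap, and uses
that slope to standardise every endpoint to a common 1-hour exposure.  It
also centres acclimation temperatures within species (removing the
habitat–acclimation confound) and provides per-realm dataset accounting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Realm",
    "AssayType",
    "ToleranceRecord",
    "DurationSlope",
    "SchemaError",
    "InvalidMethodologyError",
    "read_tolerance_table",
    "assay_duration",
    "estimate_duration_slope",
    "standardise_to_one_hour",
    "centre_acclimation",
    "select_median_latitude",
    "dataset_summary",
    "harmonise_records",
    "records_to_frame",
]


class Realm(str, enum.Enum):
    """Habitat class of a species."""

    FRESHWATER = "freshwater"
    MARINE = "marine"
    BRACKISH = "brackish"


class AssayType(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"


class SchemaError(ValueError):
    """A required column cannot be resolved from the input table."""


class InvalidMethodologyError(ValueError):
    """Assay metadata is physically inconsistent (e.g. non-positive ramp)."""


class UnidentifiableSlopeError(ValueError):
    """All assay durations coincide; the log-duration slope has no support."""


@dataclass
class ToleranceRecord:
    """One thermal-limit measurement with its methodology metadata.

    ``endpoint_temp`` is the reported CT or LT value (°C).  Derived fields
    (``trial_duration`` for dynamic assays, ``acclimation_std``,
    ``heat_tolerance_std``) are filled by the harmonisation steps.
    """

    record_id: str
    species: str
    realm: Realm
    assay_type: AssayType
    endpoint_temp: float
    acclimation_temp: float
    start_temp: float | None = None
    ramp_rate: float | None = None  # °C / h
    trial_duration: float | None = None  # hours
    acclimation_duration: float | None = None  # days
    latitude: float | None = None
    study_id: str | None = None
    acclimation_std: float | None = None  # °C, filled by centre_acclimation
    heat_tolerance_std: float | None = None  # °C at 1 h, filled on harmonise

    def __post_init__(self) -> None:
        self.realm = Realm(self.realm)
        self.assay_type = AssayType(self.assay_type)

    @property
    def abs_latitude(self) -> float | None:
        return None if self.latitude is None else abs(self.latitude)


@dataclass(frozen=True)
class DurationSlope:
    """Fitted slope of heat tolerance against log assay duration.

    ``slope`` is in °C per log-unit of duration (hours); its sign is
    negative because tolerated temperature falls with exposure time.
    """

    slope: float
    slope_sd: float
    n_bootstrap: int
    log_base: str = "log10"  # or "natural"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.slope_sd < 0:
            raise ValueError("slope_sd must be non-negative")
        if self.log_base not in ("log10", "natural"):
            raise ValueError(f"unknown log base {self.log_base!r}")

    def log(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.log10(x) if self.log_base == "log10" else np.log(x)


# ---------------------------------------------------------------------------
# Reading and validation


_REQUIRED = (
    "record_id",
    "species",
    "realm",
    "assay_type",
    "endpoint_temp",
    "acclimation_temp",
)
_OPTIONAL = (
    "start_temp",
    "ramp_rate",
    "trial_duration",
    "acclimation_duration",
    "latitude",
    "study_id",
)
_NUMERIC = (
    "endpoint_temp",
    "acclimation_temp",
    "start_temp",
    "ramp_rate",
    "trial_duration",
    "acclimation_duration",
    "latitude",
)


def _validate_row(row: Mapping) -> tuple[ToleranceRecord | None, str | None]:
    """Return (record, None) or (None, reason)."""
    data: dict = {}
    for name in _REQUIRED + _OPTIONAL:
        value = row.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            if name in _REQUIRED:
                return None, f"missing {name}"
            data[name] = None
            continue
        if name in _NUMERIC:
            try:
                value = float(value)
            except (TypeError, ValueError):
                return None, f"unparseable numeric {name}={value!r}"
        data[name] = value
    try:
        data["realm"] = Realm(str(data["realm"]).strip().lower())
    except ValueError:
        return None, f"unknown realm {row.get('realm')!r}"
    try:
        data["assay_type"] = AssayType(str(data["assay_type"]).strip().lower())
    except ValueError:
        return None, f"unknown assay type {row.get('assay_type')!r}"
    data["record_id"] = str(data["record_id"])
    data["species"] = str(data["species"])
    if data["study_id"] is not None:
        data["study_id"] = str(data["study_id"])

    rec = ToleranceRecord(**data)
    if rec.assay_type is AssayType.DYNAMIC:
        has_ramp = rec.start_temp is not None and rec.ramp_rate is not None
        if not has_ramp and rec.trial_duration is None:
            return None, "dynamic assay without (start_temp, ramp_rate) or trial_duration"
        if has_ramp and rec.endpoint_temp <= rec.start_temp:
            return None, "dynamic endpoint_temp not above start_temp"
        if rec.ramp_rate is not None and rec.ramp_rate <= 0:
            return None, "non-positive ramp_rate"
    else:
        if rec.trial_duration is None:
            return None, "static assay without trial_duration"
    if rec.trial_duration is not None and rec.trial_duration <= 0:
        return None, "non-positive trial_duration"
    return rec, None


def read_tolerance_table(
    path, schema_config: Mapping[str, str] | None = None
) -> tuple[list[ToleranceRecord], pd.DataFrame]:
    """Read a CSV of tolerance records, validating each row.

    Parameters
    ----------
    path
        CSV file with one assay record per row.
    schema_config
        Mapping from schema field names to the file's column headers, e.g.
        ``{"endpoint_temp": "CTmax_C"}``.  Unmapped fields use their schema
        name directly.  Units are fixed: °C, hours, °C/h, decimal degrees.

    Returns
    -------
    (records, rejections)
        Validated records and a rejection report with columns
        ``row`` (0-based data row) and ``reason``.  Rows failing invariants
        are collected, never silently dropped.
    """
    frame = pd.read_csv(path)
    mapping = dict(schema_config or {})
    rename = {src: dst for dst, src in mapping.items() if src in frame.columns}
    frame = frame.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"required column(s) not resolvable: {', '.join(missing)}")

    records: list[ToleranceRecord] = []
    rejected: list[dict] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        rec, reason = _validate_row(row)
        if rec is None:
            rejected.append({"row": i, "record_id": row.get("record_id"), "reason": reason})
        else:
            records.append(rec)
    report = pd.DataFrame(rejected, columns=["row", "record_id", "reason"])
    return records, report


# ---------------------------------------------------------------------------
# Durations and standardisation


def assay_duration(record: ToleranceRecord) -> float:
    """Realised trial duration in hours.

    Static assays report their duration directly.  For dynamic assays the
    duration follows from the ramp: (endpoint − start) / ramp rate; an
    explicitly reported duration takes precedence because it reflects the
    realised trial.
    """
    if record.trial_duration is not None:
        if record.trial_duration <= 0:
            raise InvalidMethodologyError(
                f"{record.record_id}: non-positive trial duration"
            )
        return float(record.trial_duration)
    if record.assay_type is AssayType.STATIC:
        raise InvalidMethodologyError(f"{record.record_id}: static assay lacks duration")
    if record.start_temp is None or record.ramp_rate is None:
        raise InvalidMethodologyError(
            f"{record.record_id}: dynamic assay lacks both duration and ramp metadata"
        )
    if record.ramp_rate <= 0:
        raise InvalidMethodologyError(f"{record.record_id}: non-positive ramp rate")
    duration = (record.endpoint_temp - record.start_temp) / record.ramp_rate
    if duration <= 0:
        raise InvalidMethodologyError(
            f"{record.record_id}: endpoint at or below start temperature"
        )
    return float(duration)


def standardise_to_one_hour(
    endpoint_temp: float, duration: float, slope: DurationSlope | float,
    log_base: str = "log10",
) -> float:
    """Correct an endpoint to the 1-hour reference duration.

    Returns ``endpoint_temp − slope × log(duration / 1 h)``.  With a negative
    slope, endpoints from long trials are corrected upwards (the fish
    tolerated the temperature for longer than the reference hour) and short
    trials downwards.  Identity at duration = 1 h.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not isinstance(slope, DurationSlope):
        slope = DurationSlope(float(slope), 0.0, 1, log_base)
    return float(endpoint_temp - slope.slope * slope.log(duration))


def estimate_duration_slope(
    records: Sequence[ToleranceRecord],
    n_bootstrap: int = 50,
    rng_seed: int = 0,
    tree=None,
) -> DurationSlope:
    """Estimate the log-duration slope of heat tolerance by bootstrap.

    Each replicate keeps a single dynamic record per species-by-study group
    (so studies contributing many ramped trials do not dominate), pools these
    with all static records, and fits heat tolerance on log10(duration) with
    a species random intercept (plus a phylogenetic random intercept when a
    tree is supplied).  The returned slope is the mean across replicates and
    ``slope_sd`` its bootstrap SD.  Deterministic given ``rng_seed``.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    rng = np.random.default_rng(rng_seed)

    rows = []
    for rec in records:
        rows.append(
            (
                rec.species,
                rec.study_id or rec.species,
                rec.assay_type is AssayType.DYNAMIC,
                rec.endpoint_temp,
                assay_duration(rec),
            )
        )
    frame = pd.DataFrame(
        rows, columns=["species", "study", "dynamic", "endpoint", "duration"]
    )
    if frame["duration"].nunique() < 2:
        raise UnidentifiableSlopeError("all assay durations identical")
    frame["logdur"] = np.log10(frame["duration"])

    static = frame[~frame["dynamic"]]
    dynamic = frame[frame["dynamic"]]
    groups = list(dynamic.groupby(["species", "study"], sort=True).indices.values())

    from .models import fit_species_intercept_model  # local import: no cycle at runtime

    slopes = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        take = [g[rng.integers(len(g))] for g in groups]
        sub = pd.concat([dynamic.iloc[sorted(take)], static])
        slopes[b] = fit_species_intercept_model(
            y=sub["endpoint"].to_numpy(float),
            x=sub["logdur"].to_numpy(float),
            species=sub["species"].to_numpy(str),
            tree=tree,
        )
    return DurationSlope(
        slope=float(slopes.mean()),
        slope_sd=float(slopes.std(ddof=1)) if n_bootstrap > 1 else 0.0,
        n_bootstrap=n_bootstrap,
        log_base="log10",
    )


# ---------------------------------------------------------------------------
# Acclimation centring, latitude selection, accounting


def centre_acclimation(
    records: Sequence[ToleranceRecord],
) -> tuple[list[ToleranceRecord], list[str]]:
    """Centre acclimation temperature within species.

    ``acclimation_std = acclimation_temp − mean(acclimation_temp | species)``,
    removing the confound between habitat temperature and chosen acclimation
    level; the per-species mean of the standardised values is 0.  Returns new
    records (endpoints untouched) and the names of species flagged for having
    no acclimation data at all.
    """
    by_species: dict[str, list[float]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec.acclimation_temp)
    means = {sp: float(np.mean(v)) for sp, v in by_species.items()}
    flagged = sorted(sp for sp, v in by_species.items() if len(v) == 0)
    out = [
        replace(rec, acclimation_std=rec.acclimation_temp - means[rec.species])
        for rec in records
    ]
    return out, flagged


def select_median_latitude(records: Sequence[ToleranceRecord]) -> ToleranceRecord:
    """Pick the record at the median of the distinct collection latitudes.

    Even counts resolve to the lower of the two middle latitudes so the
    choice is deterministic.  Raises if no record carries a latitude.
    """
    with_lat = [r for r in records if r.latitude is not None]
    if not with_lat:
        raise ValueError("no record carries a latitude")
    distinct = sorted({r.latitude for r in with_lat})
    target = distinct[(len(distinct) - 1) // 2]
    for rec in with_lat:
        if rec.latitude == target:
            return rec
    raise AssertionError("unreachable")


def dataset_summary(records: Sequence[ToleranceRecord]) -> pd.DataFrame:
    """Per-realm and overall dataset accounting.

    Populations are species × distinct collection latitude; species without
    any latitude count as a single population.  Ranges are max − min within
    species, averaged over species (0 for singletons).
    """
    frame = records_to_frame(records)
    columns = [
        "records",
        "species",
        "populations",
        "pct_species_multi_population",
        "mean_acclimation_temps_per_species",
        "pct_species_multi_acclimation",
        "mean_range_acclimation_temp",
        "mean_range_latitude",
    ]

    def summarise(sub: pd.DataFrame) -> dict:
        if sub.empty:
            return dict.fromkeys(columns, 0.0) | {"records": 0, "species": 0, "populations": 0}
        by_sp = sub.groupby("species")
        n_lat = by_sp["latitude"].nunique(dropna=True).clip(lower=1)
        n_acc = by_sp["acclimation_temp"].nunique()
        rng_acc = by_sp["acclimation_temp"].agg(lambda s: s.max() - s.min())
        rng_lat = by_sp["latitude"].agg(
            lambda s: 0.0 if s.dropna().empty else s.max() - s.min()
        )
        return {
            "records": len(sub),
            "species": by_sp.ngroups,
            "populations": int(n_lat.sum()),
            "pct_species_multi_population": 100.0 * (n_lat > 1).mean(),
            "mean_acclimation_temps_per_species": float(n_acc.mean()),
            "pct_species_multi_acclimation": 100.0 * (n_acc > 1).mean(),
            "mean_range_acclimation_temp": float(rng_acc.mean()),
            "mean_range_latitude": float(rng_lat.mean()),
        }

    out = {"all": summarise(frame)}
    for realm in Realm:
        out[realm.value] = summarise(frame[frame["realm"] == realm.value])
    return pd.DataFrame(out).T[columns]


# ---------------------------------------------------------------------------
# Orchestration helpers


def harmonise_records(
    records: Sequence[ToleranceRecord], slope: DurationSlope
) -> list[ToleranceRecord]:
    """Fill duration-standardised tolerance and centred acclimation."""
    centred, _ = centre_acclimation(records)
    return [
        replace(
            rec,
            trial_duration=assay_duration(rec),
            heat_tolerance_std=standardise_to_one_hour(
                rec.endpoint_temp, assay_duration(rec), slope
            ),
        )
        for rec in centred
    ]


def records_to_frame(records: Iterable[ToleranceRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (realm/assay enums as strings)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "record_id": rec.record_id,
                "species": rec.species,
                "realm": rec.realm.value,
                "assay_type": rec.assay_type.value,
                "endpoint_temp": rec.endpoint_temp,
                "start_temp": rec.start_temp,
                "ramp_rate": rec.ramp_rate,
                "trial_duration": rec.trial_duration,
                "acclimation_temp": rec.acclimation_temp,
                "acclimation_std": rec.acclimation_std,
                "acclimation_duration": rec.acclimation_duration,
                "latitude": rec.latitude,
                "study_id": rec.study_id,
                "heat_tolerance_std": rec.heat_tolerance_std,
            }
        )
    cols = [
        "record_id", "species", "realm", "assay_type", "endpoint_temp",
        "start_temp", "ramp_rate", "trial_duration", "acclimation_temp",
        "acclimation_std", "acclimation_duration", "latitude", "study_id",
        "heat_tolerance_std",
    ]
    return pd.DataFrame(rows, columns=cols)
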