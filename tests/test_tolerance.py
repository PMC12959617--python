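"""Record ingestion, assay durations, 1-h standardisation, centring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoscope.simulate import simulate_duration_records
from thermoscope.tolerance import (
    AssayType,
    DurationSlope,
    InvalidMethodologyError,
    Realm,
    SchemaError,
    ToleranceRecord,
    UnidentifiableSlopeError,
    assay_duration,
    centre_acclimation,
    dataset_summary,
    estimate_duration_slope,
    read_tolerance_table,
    select_median_latitude,
    standardise_to_one_hour,
)


def make_record(**kwargs):
    base = dict(
        record_id="r1", species="sp1", realm=Realm.MARINE,
        assay_type=AssayType.STATIC, endpoint_temp=36.0,
        acclimation_temp=20.0, trial_duration=1.0,
    )
    base.update(kwargs)
    return ToleranceRecord(**base)


# ---------------------------------------------------------------------------
# Reading and validation


HEADER = (
    "record_id,species,realm,assay_type,endpoint_temp,start_temp,"
    "ramp_rate,trial_duration,acclimation_temp,latitude\n"
)


def test_empty_table_yields_empty_collections(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(HEADER)
    records, rejections = read_tolerance_table(path)
    assert records == []
    assert rejections.empty


def test_invalid_rows_are_rejected_with_reasons(tmp_path):
    rows = []
    for i in range(12):
        endpoint = "" if i in (3, 7) else "36.5"
        rows.append(f"r{i},sp{i % 4},marine,static,{endpoint},,,24,20,10\n")
    path = tmp_path / "records.csv"
    path.write_text(HEADER + "".join(rows))
    records, rejections = read_tolerance_table(path)
    assert len(records) == 10
    assert len(rejections) == 2
    assert set(rejections["row"]) == {3, 7}
    assert all("endpoint_temp" in r for r in rejections["reason"])


@pytest.mark.parametrize(
    "row, reason_fragment",
    [
        ("r1,sp1,estuarine,static,36,,,24,20,10", "unknown realm"),
        ("r1,sp1,marine,soak,36,,,24,20,10", "unknown assay type"),
        ("r1,sp1,marine,static,abc,,,24,20,10", "unparseable numeric"),
        ("r1,sp1,marine,dynamic,36,,,,20,10", "dynamic assay"),
        ("r1,sp1,marine,dynamic,34,36,18,,20,10", "not above start"),
        ("r1,sp1,marine,static,36,,,-2,20,10", "non-positive trial_duration"),
    ],
)
def test_rejection_reasons(tmp_path, row, reason_fragment):
    path = tmp_path / "one.csv"
    path.write_text(HEADER + row + "\n")
    records, rejections = read_tolerance_table(path)
    assert records == []
    assert reason_fragment in rejections["reason"].iloc[0]


def test_missing_required_column_is_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("record_id,species\nr1,sp1\n")
    with pytest.raises(SchemaError, match="realm"):
        read_tolerance_table(path)


def test_column_mapping_binds_foreign_headers(tmp_path):
    path = tmp_path / "mapped.csv"
    path.write_text(
        "id,taxon,habitat,protocol,CTmax_C,acc_C,dur_h\n"
        "x1,Gadus morhua,marine,static,24.5,10,24\n"
    )
    mapping = {
        "record_id": "id", "species": "taxon", "realm": "habitat",
        "assay_type": "protocol", "endpoint_temp": "CTmax_C",
        "acclimation_temp": "acc_C", "trial_duration": "dur_h",
    }
    records, rejections = read_tolerance_table(path, mapping)
    assert len(records) == 1 and rejections.empty
    assert records[0].species == "Gadus morhua"
    assert records[0].endpoint_temp == 24.5


# ---------------------------------------------------------------------------
# Durations


def test_dynamic_duration_from_ramp():
    rec = make_record(
        assay_type=AssayType.DYNAMIC, start_temp=25.0, endpoint_temp=34.0,
        ramp_rate=18.0, trial_duration=None,
    )
    assert assay_duration(rec) == pytest.approx(0.5)


def test_static_duration_passthrough():
    assert assay_duration(make_record(trial_duration=24.0)) == 24.0


def test_explicit_duration_preferred_over_ramp():
    rec = make_record(
        assay_type=AssayType.DYNAMIC, start_temp=25.0, endpoint_temp=34.0,
        ramp_rate=18.0, trial_duration=2.0,
    )
    assert assay_duration(rec) == 2.0


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(assay_type=AssayType.DYNAMIC, start_temp=36.0, endpoint_temp=34.0,
             ramp_rate=18.0, trial_duration=None),
        dict(assay_type=AssayType.DYNAMIC, start_temp=25.0, endpoint_temp=34.0,
             ramp_rate=-1.0, trial_duration=None),
        dict(assay_type=AssayType.STATIC, trial_duration=None),
    ],
)
def test_invalid_methodology_raises(kwargs):
    with pytest.raises(InvalidMethodologyError):
        assay_duration(make_record(**kwargs))


# ---------------------------------------------------------------------------
# Standardisation to 1 h


@pytest.mark.parametrize(
    "endpoint, duration, expected",
    [
        (38.0, 1.0, 38.0),
        (38.0, 10.0, 39.26),
        (40.0, 0.25, 40.0 + 1.26 * np.log10(0.25)),  # ≈ 39.24
    ],
)
def test_standardisation_arithmetic(endpoint, duration, expected):
    slope = DurationSlope(-1.26, 0.0147, 50, "log10")
    assert standardise_to_one_hour(endpoint, duration, slope) == pytest.approx(
        expected, abs=1e-9
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    slope=st.floats(-5, 5),
    endpoint=st.floats(0, 50),
    duration=st.floats(0.01, 1000),
)
def test_standardisation_identity_and_idempotence(slope, endpoint, duration):
    ds = DurationSlope(slope, 0.0, 1, "log10")
    # identity at the reference duration, for any slope
    assert standardise_to_one_hour(endpoint, 1.0, ds) == endpoint
    # correcting to 1 h then "re-correcting" from 1 h changes nothing
    once = standardise_to_one_hour(endpoint, duration, ds)
    assert standardise_to_one_hour(once, 1.0, ds) == once


def test_correction_direction_for_negative_slope():
    ds = DurationSlope(-1.26, 0.0, 1, "log10")
    durations = [0.1, 0.5, 1.0, 4.0, 24.0]
    corrected = [standardise_to_one_hour(38.0, d, ds) for d in durations]
    assert np.all(np.diff(corrected) > 0)


def test_natural_log_base():
    ds = DurationSlope(-1.26, 0.0, 1, "natural")
    assert standardise_to_one_hour(38.0, np.e, ds) == pytest.approx(39.26)


def test_non_positive_duration_rejected():
    with pytest.raises(ValueError):
        standardise_to_one_hour(38.0, 0.0, DurationSlope(-1.26, 0, 1))


# ---------------------------------------------------------------------------
# Slope estimation


def test_constant_tolerance_gives_null_slope():
    records = simulate_duration_records(
        n_species=100, true_slope=0.0, noise_sd=0.05, seed=1
    )
    fit = estimate_duration_slope(records, n_bootstrap=20, rng_seed=1)
    assert abs(fit.slope) < 0.05  # well within Monte-Carlo error of 0


def test_slope_estimation_deterministic_given_seed():
    records = simulate_duration_records(n_species=40, seed=2)
    a = estimate_duration_slope(records, n_bootstrap=10, rng_seed=9)
    b = estimate_duration_slope(records, n_bootstrap=10, rng_seed=9)
    assert a == b


def test_slope_estimation_parameter_errors():
    records = simulate_duration_records(n_species=10, seed=3)
    with pytest.raises(ValueError):
        estimate_duration_slope(records, n_bootstrap=0)
    same_duration = [
        r for r in records if r.assay_type is AssayType.STATIC
    ]
    for r in same_duration:
        r.trial_duration = 24.0
    with pytest.raises(UnidentifiableSlopeError):
        estimate_duration_slope(same_duration, n_bootstrap=5)


# ---------------------------------------------------------------------------
# Acclimation centring and latitude selection


def test_centre_acclimation_values_and_endpoints():
    records = [
        make_record(record_id=f"r{i}", acclimation_temp=t)
        for i, t in enumerate([15.0, 20.0, 25.0])
    ]
    centred, flagged = centre_acclimation(records)
    assert flagged == []
    assert [r.acclimation_std for r in centred] == [-5.0, 0.0, 5.0]
    assert all(r.endpoint_temp == 36.0 for r in centred)


def test_centring_is_per_species():
    records = [
        make_record(record_id="a1", species="A", acclimation_temp=10.0),
        make_record(record_id="a2", species="A", acclimation_temp=20.0),
        make_record(record_id="b1", species="B", acclimation_temp=30.0),
    ]
    centred, _ = centre_acclimation(records)
    by_sp = {}
    for r in centred:
        by_sp.setdefault(r.species, []).append(r.acclimation_std)
    for values in by_sp.values():
        assert np.mean(values) == pytest.approx(0.0, abs=1e-12)
    # cross-species mean need not vanish, but single records centre to 0
    assert centred[2].acclimation_std == 0.0


@pytest.mark.parametrize(
    "latitudes, expected",
    [
        ([10.0, 20.0, 30.0], 20.0),
        ([10.0, 20.0, 30.0, 40.0], 20.0),  # lower-middle tie-break
        ([33.0], 33.0),
    ],
)
def test_select_median_latitude(latitudes, expected):
    records = [
        make_record(record_id=f"r{i}", latitude=lat)
        for i, lat in enumerate(latitudes)
    ]
    assert select_median_latitude(records).latitude == expected


def test_select_median_latitude_requires_latitudes():
    with pytest.raises(ValueError):
        select_median_latitude([make_record(latitude=None)])


# ---------------------------------------------------------------------------
# Dataset accounting


def test_dataset_summary_hand_counted_fixture():
    records = []
    i = 0
    for sp in ["A", "B", "C"]:
        for lat in [10.0, 12.0]:
            for acc in [15.0, 25.0]:
                i += 1
                records.append(
                    make_record(
                        record_id=f"r{i}", species=sp, latitude=lat,
                        acclimation_temp=acc,
                    )
                )
    table = dataset_summary(records)
    row = table.loc["all"]
    assert row["records"] == 12
    assert row["species"] == 3
    assert row["populations"] == 6
    assert row["pct_species_multi_population"] == 100.0
    assert row["mean_acclimation_temps_per_species"] == 2.0
    assert row["pct_species_multi_acclimation"] == 100.0
    assert row["mean_range_acclimation_temp"] == 10.0
    assert row["mean_range_latitude"] == 2.0
    assert table.loc["marine", "records"] == 12
    assert table.loc["freshwater", "records"] == 0


def test_dataset_summary_empty_input():
    table = dataset_summary([])
    assert (table["records"] == 0).all()
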