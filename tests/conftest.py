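"""Shared fixtures: small synthetic studies and fits reused across tests."""

import warnings

import dendropy
import numpy as np
import pytest

import thermoscope as ts
from thermoscope.models import ModelId, ModelSpec, build_design, fit_mixed
from thermoscope.simulate import GridSpec, SimulationConfig
from thermoscope.tolerance import DurationSlope, harmonise_records, records_to_frame


@pytest.fixture(scope="session")
def small_bundle():
    """25-species world on a 10x8 grid, 3 years: fast but fully structured."""
    config = SimulationConfig(
        n_species=25, grid=GridSpec(n_lat=10, n_lon=8), years=3
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ts.make_bundle(config, seed=42)


@pytest.fixture(scope="session")
def medium_bundle():
    """60-species world on a 14x10 grid: enough signal for model checks."""
    config = SimulationConfig(
        n_species=60, grid=GridSpec(n_lat=14, n_lon=10), years=4
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ts.make_bundle(config, seed=7)


def model_table(bundle):
    slope = DurationSlope(bundle.truth.duration_slope_true, 0.0, 1, "log10")
    frame = records_to_frame(harmonise_records(bundle.records, slope))
    return frame.merge(
        bundle.exposure[["species", "max_habitat_temp", "thermal_variability"]],
        on="species",
    )


def fit_model(bundle, model_id):
    table = model_table(bundle)
    spec = ModelSpec(ModelId(model_id))
    y, X, design = build_design(table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_mixed(
            y, X, bundle.tree, table["species"].to_numpy(str), spec, design
        )
    return fit, table, X


@pytest.fixture(scope="session")
def model3_fit(medium_bundle):
    fit, table, X = fit_model(medium_bundle, "model3")
    return fit


@pytest.fixture(scope="session")
def model2_fit(medium_bundle):
    fit, table, X = fit_model(medium_bundle, "model2")
    return fit


@pytest.fixture(scope="session")
def cherry_tree():
    """((A,B),C): A and B share half their unit root-to-tip path."""
    return dendropy.Tree.get(
        data="((A:0.5,B:0.5):0.5,C:1.0);", schema="newick"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
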