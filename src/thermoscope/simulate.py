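"""Synthetic studies with known truth for every pipeline stage.

Generates a complete, internally consistent world: a Yule phylogeny scaled
to unit depth; freshwater and marine weekly temperature cubes (latitudinal
mean gradient, seasonal sinusoid whose amplitude grows poleward, realm
offsets, Gaussian weekly noise, Kelvin storage); contiguous latitudinal-band
range masks whose centres evolve by Brownian motion on the tree (so habitat
exposure is phylogenetically structured); and assay records drawn from the
realm heat-tolerance model — basal tolerance linear in the species' maximum
habitat temperature plus phylogenetic and species effects, plasticity with
thermal-variability and realm interactions and a negative quadratic
acclimation term, and a log-duration assay effect.  Every generating
parameter is recorded in :class:`SyntheticTruth` so each stage of the
analysis can be tested for parameter recovery without any downloaded data.

Default truth values sit near field-typical estimates for fishes (duration
slope −1.26 °C per log10 hour, ARR around 0.2, a basal-tolerance slope of
0.46 °C per °C habitat maximum, freshwater habitats ~3 °C hotter and more
seasonal than marine) so recovery tests double as plausibility checks.
"""

from __future__ import annotations

import dataclasses
import json
import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import xarray as xr

from .exposure import (
    KELVIN_OFFSET,
    RangeMask,
    WeeklyTemperatureCube,
    exposure_for_species,
)
from .tolerance import AssayType, Realm, ToleranceRecord, records_to_frame

__all__ = [
    "SyntheticTruth",
    "GridSpec",
    "SimulationConfig",
    "SyntheticBundle",
    "simulate_tree",
    "brownian_tip_values",
    "simulate_temperature_cubes",
    "simulate_ranges",
    "simulate_records",
    "simulate_duration_records",
    "make_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of a simulated study."""

    duration_slope_true: float = -1.26  # °C per log10 hour
    log_base: str = "log10"
    arr_base: float = 0.15  # ARR at zero CV, marine, centred acclimation
    arr_tvar_coef: float = 2.0  # ARR change per unit CV
    arr_realm_offsets: tuple[tuple[str, float], ...] = (
        ("marine", 0.0), ("freshwater", 0.06), ("brackish", 0.04),
    )
    quad_accT_coef: float = -0.01  # °C per (°C acclimation)², diminishing gains
    maxT_slope_true: float = 0.46  # °C tolerance per °C habitat maximum
    basal_intercept: float = 18.0  # °C at zero habitat maximum
    lambda_true: float = 0.9
    sigma_phylo: float = 2.0  # °C
    sigma_species: float = 1.0  # °C
    sigma_resid: float = 0.75  # °C
    realm_maxT_offset: float = 3.0  # °C, freshwater − marine habitat maxima
    realm_cv_offset: float = 0.006  # freshwater − marine within-year CV
    anchor_intercept: float = 5.0  # actual acclimation ~ a + b · maxT
    anchor_slope: float = 0.75
    anchor_resid_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.arr_base < 1:
            raise ValueError("arr_base must lie in [0, 1)")
        if self.quad_accT_coef > 0:
            raise ValueError("quadratic acclimation coefficient must be <= 0")
        for s in (self.sigma_phylo, self.sigma_species, self.sigma_resid):
            if s < 0:
                raise ValueError("sigmas must be non-negative")

    @property
    def realm_offsets(self) -> dict[str, float]:
        return dict(self.arr_realm_offsets)

    def arr_at(self, tvar: float, realm: str) -> float:
        return self.arr_base + self.arr_tvar_coef * tvar + self.realm_offsets[realm]


@dataclass(frozen=True)
class GridSpec:
    n_lat: int = 20
    n_lon: int = 20
    lat_min: float = -57.0
    lat_max: float = 57.0

    @property
    def lats(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return np.linspace(-171.0, 171.0, self.n_lon)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a synthetic bundle (defaults are the test-scale study)."""

    n_species: int = 300
    n_acclim_levels: int = 4
    acclim_spacing: float = 3.0  # °C between consecutive acclimation levels
    records_per_level: int = 1
    frac_dynamic: float = 0.7
    grid: GridSpec = field(default_factory=GridSpec)
    years: int = 10
    weeks: int = 52
    base_mean_c: float = 27.0  # annual-mean water temperature at the equator
    lat_falloff_c: float = 22.0  # mean drop from equator to |lat| = 60°
    amp_equator: float = 0.5  # seasonal amplitude at the equator, K
    amp_pole: float = 8.0  # seasonal amplitude at |lat| = 60°, K
    noise_weekly_sd: float = 0.3  # K
    range_breadth_deg: float = 9.0
    realm_probs: tuple[float, float, float] = (0.52, 0.37, 0.11)  # fresh, marine, brackish
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)


# ---------------------------------------------------------------------------
# Tree and Brownian traits


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Yule (pure-birth) tree on ``n_species`` tips, scaled to unit depth."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.model import birthdeath

    if n_species == 2:
        tree = dendropy.Tree.get(data="(sp1:1.0,sp2:1.0);", schema="newick")
        return tree
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng,
    )
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:0{width}d}"
    tree.calc_node_root_distances()
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree


def brownian_tip_values(
    tree: dendropy.Tree, seed: int, sigma: float = 1.0, lam: float = 1.0
) -> pd.Series:
    """Brownian trait values at the tips, optionally λ-scaled.

    λ < 1 mixes the Brownian value with an independent draw, matching a
    correlation matrix whose off-diagonals are multiplied by λ.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        length = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(length))
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    out = pd.Series(tips).sort_index()
    if lam < 1.0:
        iid = pd.Series(
            rng.standard_normal(len(out)), index=out.index
        )
        out = np.sqrt(lam) * out + np.sqrt(1.0 - lam) * iid
    return sigma * out


# ---------------------------------------------------------------------------
# Temperature cubes


def _seasonal_field(
    grid: GridSpec, years: int, weeks: int, amp_extra: float,
    mean_offset_c: float, noise_sd: float, config: SimulationConfig,
    rng: np.random.Generator,
) -> xr.DataArray:
    lats = grid.lats
    frac = np.abs(lats) / 60.0
    mean_k = KELVIN_OFFSET + config.base_mean_c - config.lat_falloff_c * frac**2
    mean_k = mean_k + mean_offset_c
    amp = config.amp_equator + (config.amp_pole - config.amp_equator) * frac + amp_extra
    week_angle = 2.0 * np.pi * (np.arange(weeks) + 0.5) / weeks
    # peak mid-year in the north, at year start/end in the south
    phase = np.where(lats >= 0, np.pi, 0.0)
    seasonal = amp[None, :] * np.cos(week_angle[:, None] + phase[None, :])  # (week, lat)
    base = mean_k[None, None, :, None] + seasonal[None, :, :, None]
    vals = np.broadcast_to(
        base, (years, weeks, grid.n_lat, grid.n_lon)
    ).astype(float).copy()
    if noise_sd > 0:
        vals += rng.normal(0.0, noise_sd, size=vals.shape)
    return xr.DataArray(
        vals,
        coords={
            "year": np.arange(years), "week": np.arange(1, weeks + 1),
            "lat": lats, "lon": grid.lons,
        },
        dims=("year", "week", "lat", "lon"),
    )


def simulate_temperature_cubes(
    config: SimulationConfig, seed: int
) -> tuple[WeeklyTemperatureCube, WeeklyTemperatureCube]:
    """Freshwater and marine weekly cubes (freshwater hotter, more seasonal).

    The noise-free annual maximum is the latitudinal mean plus the seasonal
    amplitude, in closed form; the freshwater cube adds the truth's realm
    mean offset and an amplitude increment sized to raise the within-year CV
    by roughly the truth's CV offset.
    """
    rng_f, rng_m = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    truth = config.truth
    # CV ≈ amplitude / (√2 · mean): invert for the amplitude increment
    mean_k = KELVIN_OFFSET + config.base_mean_c - config.lat_falloff_c * 0.25
    amp_extra = truth.realm_cv_offset * mean_k * np.sqrt(2.0)
    fresh = WeeklyTemperatureCube(
        values=_seasonal_field(
            config.grid, config.years, config.weeks, amp_extra,
            truth.realm_maxT_offset, config.noise_weekly_sd, config, rng_f,
        ),
        realm_tag="freshwater",
    )
    marine = WeeklyTemperatureCube(
        values=_seasonal_field(
            config.grid, config.years, config.weeks, 0.0, 0.0,
            config.noise_weekly_sd, config, rng_m,
        ),
        realm_tag="marine",
    )
    return fresh, marine


# ---------------------------------------------------------------------------
# Ranges


def simulate_ranges(
    config: SimulationConfig, tree: dendropy.Tree, seed: int
) -> tuple[dict[str, RangeMask], pd.Series]:
    """Latitudinal-band range masks with Brownian band centres.

    Band centres evolve on the tree so that closely related species occupy
    similar latitudes, making habitat exposure phylogenetically structured.
    Bands falling outside the grid are clipped (with a warning).
    Returns the masks and the band-centre latitude per species.
    """
    grid = config.grid
    z = brownian_tip_values(tree, seed, sigma=1.0)
    centres = (z * 35.0).clip(
        grid.lat_min + config.range_breadth_deg / 2,
        grid.lat_max - config.range_breadth_deg / 2,
    )
    if (np.abs(z * 35.0) > grid.lat_max).any():
        warnings.warn("some range bands were clipped to the grid", stacklevel=2)
    lats = grid.lats
    masks = {}
    for sp, centre in centres.items():
        rows = np.abs(lats - centre) <= config.range_breadth_deg / 2
        if not rows.any():
            rows[np.argmin(np.abs(lats - centre))] = True
        cells = np.zeros((grid.n_lat, grid.n_lon), bool)
        cells[rows, :] = True
        masks[sp] = RangeMask(species=sp, cells=cells, source="synthetic")
    return masks, centres


# ---------------------------------------------------------------------------
# Assay records


def simulate_records(
    tree: dendropy.Tree,
    exposure: pd.DataFrame,
    realms: dict[str, str],
    latitudes: pd.Series,
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[list[ToleranceRecord], pd.DataFrame]:
    """Assay records from the generating heat-tolerance model.

    Basal (1-h, centred-acclimation) tolerance per species is linear in its
    maximum habitat temperature plus a λ-scaled phylogenetic deviate and an
    iid species deviate.  Each record adds the plasticity terms, the
    log-duration effect, and residual noise.  Dynamic assays store start
    temperature and ramp rate such that the derived duration equals the
    simulated one; static assays report the duration directly.  Each species
    is sampled at two collection sites (band centre ± 1°), giving the
    population structure used by the sensitivity refits.

    Returns the records and a per-species truth table (basal tolerance,
    true ARR, mean acclimation temperature).
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss[0])
    species = exposure["species"].tolist()
    u_phylo = brownian_tip_values(
        tree, int(ss[1].generate_state(1)[0] % 2**31),
        sigma=truth.sigma_phylo, lam=truth.lambda_true,
    )
    u_species = pd.Series(
        np.random.default_rng(ss[2]).normal(0, truth.sigma_species, len(species)),
        index=species,
    )

    K = config.n_acclim_levels
    offsets = config.acclim_spacing * (np.arange(K) - (K - 1) / 2.0)
    ramp_choices = np.array([6.0, 12.0, 18.0, 30.0])
    static_durations = np.array([0.5, 1.0, 2.0, 6.0, 24.0])

    records: list[ToleranceRecord] = []
    truth_rows = []
    rid = 0
    for _, row in exposure.iterrows():
        sp = row["species"]
        realm = realms[sp]
        tvar = float(row["thermal_variability"])
        maxt = float(row["max_habitat_temp"])
        basal = (
            truth.basal_intercept + truth.maxT_slope_true * maxt
            + u_phylo[sp] + u_species[sp]
        )
        arr_i = truth.arr_at(tvar, realm)
        mean_acc = (
            truth.anchor_intercept + truth.anchor_slope * maxt
            + rng.normal(0, truth.anchor_resid_sd)
        )
        n_studies = 1 + int(rng.random() < 0.4)
        sites = [float(latitudes[sp]) - 1.0, float(latitudes[sp]) + 1.0]
        truth_rows.append(
            {"species": sp, "basal": basal, "arr_true": arr_i, "mean_acc": mean_acc}
        )
        for k, off in enumerate(offsets):
            acc = mean_acc + off
            for _ in range(config.records_per_level):
                dynamic = rng.random() < config.frac_dynamic
                if dynamic:
                    dur = float(np.exp(rng.normal(np.log(0.75), 0.5)))
                else:
                    dur = float(rng.choice(static_durations))
                ht_1h = basal + arr_i * off + truth.quad_accT_coef * off**2
                endpoint = (
                    ht_1h + truth.duration_slope_true * np.log10(dur)
                    + rng.normal(0, truth.sigma_resid)
                )
                rid += 1
                common = dict(
                    record_id=f"r{rid:05d}",
                    species=sp,
                    realm=Realm(realm),
                    endpoint_temp=float(endpoint),
                    acclimation_temp=float(acc),
                    acclimation_duration=14.0,
                    latitude=sites[k % 2],
                    study_id=f"{sp}-s{1 + rid % n_studies}",
                )
                if dynamic:
                    ramp = float(rng.choice(ramp_choices))
                    records.append(
                        ToleranceRecord(
                            assay_type=AssayType.DYNAMIC,
                            start_temp=float(endpoint - ramp * dur),
                            ramp_rate=ramp,
                            **common,
                        )
                    )
                else:
                    records.append(
                        ToleranceRecord(
                            assay_type=AssayType.STATIC,
                            trial_duration=dur,
                            **common,
                        )
                    )
    return records, pd.DataFrame(truth_rows)


def simulate_duration_records(
    n_species: int = 200,
    true_slope: float = -1.26,
    noise_sd: float = 0.5,
    n_dynamic_per_species: int = 3,
    n_static_per_species: int = 1,
    seed: int = 0,
) -> list[ToleranceRecord]:
    """Minimal records for duration-slope recovery: one acclimation level,
    species intercepts, endpoints linear in log10 duration with known slope."""
    rng = np.random.default_rng(seed)
    records: list[ToleranceRecord] = []
    static_durations = np.array([0.5, 1.0, 2.0, 6.0, 24.0, 96.0])
    rid = 0
    for i in range(n_species):
        sp = f"sp{i + 1:04d}"
        basal = rng.normal(35.0, 2.0)
        acc = rng.normal(20.0, 3.0)
        for _ in range(n_dynamic_per_species):
            dur = float(np.exp(rng.normal(np.log(0.75), 0.6)))
            endpoint = basal + true_slope * np.log10(dur) + rng.normal(0, noise_sd)
            ramp = float(rng.choice([6.0, 12.0, 18.0, 30.0]))
            rid += 1
            records.append(
                ToleranceRecord(
                    record_id=f"d{rid:05d}", species=sp, realm=Realm.MARINE,
                    assay_type=AssayType.DYNAMIC, endpoint_temp=float(endpoint),
                    acclimation_temp=float(acc),
                    start_temp=float(endpoint - ramp * dur), ramp_rate=ramp,
                    study_id=f"{sp}-s{1 + rid % 2}",
                )
            )
        for _ in range(n_static_per_species):
            dur = float(rng.choice(static_durations))
            endpoint = basal + true_slope * np.log10(dur) + rng.normal(0, noise_sd)
            rid += 1
            records.append(
                ToleranceRecord(
                    record_id=f"d{rid:05d}", species=sp, realm=Realm.MARINE,
                    assay_type=AssayType.STATIC, endpoint_temp=float(endpoint),
                    acclimation_temp=float(acc), trial_duration=dur,
                    study_id=f"{sp}-s1",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Bundles


@dataclass
class SyntheticBundle:
    """A complete synthetic study, loadable by every pipeline stage."""

    config: SimulationConfig
    truth: SyntheticTruth
    tree: dendropy.Tree
    fresh_cube: WeeklyTemperatureCube
    marine_cube: WeeklyTemperatureCube
    masks: dict[str, RangeMask]
    realms: dict[str, str]
    records: list[ToleranceRecord]
    exposure: pd.DataFrame
    species_truth: pd.DataFrame

    def write(self, out_dir) -> dict[str, str]:
        """Write the bundle in the pipeline's input formats; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": str(out / "records.csv"),
            "tree": str(out / "tree.nwk"),
            "fresh_cube": str(out / "fresh_temps.nc"),
            "marine_cube": str(out / "marine_temps.nc"),
            "masks": str(out / "range_masks.nc"),
            "truth": str(out / "truth.json"),
        }
        records_to_frame(self.records).to_csv(paths["records"], index=False)
        with open(paths["tree"], "w") as fh:
            fh.write(self.tree.as_string(schema="newick"))
        self.fresh_cube.to_netcdf(paths["fresh_cube"])
        self.marine_cube.to_netcdf(paths["marine_cube"])
        species = sorted(self.masks)
        grid = self.config.grid
        stack = np.stack([self.masks[sp].cells for sp in species]).astype("int8")
        xr.Dataset(
            {"member": (("species", "lat", "lon"), stack)},
            coords={"species": species, "lat": grid.lats, "lon": grid.lons},
        ).to_netcdf(paths["masks"], engine="scipy")
        truth_doc = dataclasses.asdict(self.truth)
        truth_doc["realms"] = self.realms
        with open(paths["truth"], "w") as fh:
            json.dump(truth_doc, fh, indent=1, sort_keys=True)
        return paths


def make_bundle(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Orchestrate all generators into one consistent study.

    Stage RNG streams are spawned from the bundle seed so each generator is
    independently reproducible; the realm contrast and plasticity structure
    the records encode are computed from the same exposure summaries the
    analysis pipeline will later recover.
    """
    config = config or SimulationConfig()
    truth = dataclasses.replace(config.truth, seed=seed)
    config = dataclasses.replace(config, truth=truth)
    ss = np.random.SeedSequence(seed).spawn(5)
    child = lambda i: int(ss[i].generate_state(1)[0] % 2**31)

    tree = simulate_tree(config.n_species, child(0))
    fresh_cube, marine_cube = simulate_temperature_cubes(config, child(1))
    masks, centres = simulate_ranges(config, tree, child(2))

    species = sorted(masks)
    rng = np.random.default_rng(ss[3])
    realm_draw = rng.choice(
        ["freshwater", "marine", "brackish"], size=len(species), p=config.realm_probs
    )
    realms = dict(zip(species, realm_draw))

    exposure, skipped = exposure_for_species(
        fresh_cube, marine_cube, masks, realms
    )
    if skipped:
        raise AssertionError(f"synthetic species unexpectedly skipped: {skipped}")
    records, species_truth = simulate_records(
        tree, exposure, realms, centres, truth, config, child(4)
    )
    return SyntheticBundle(
        config=config, truth=truth, tree=tree,
        fresh_cube=fresh_cube, marine_cube=marine_cube,
        masks=masks, realms=realms, records=records,
        exposure=exposure, species_truth=species_truth,
    )


def load_bundle(bundle_dir):
    """Read back a written bundle's inputs (records frame, tree, cubes, masks)."""
    from .tolerance import read_tolerance_table

    d = Path(bundle_dir)
    records, rejections = read_tolerance_table(d / "records.csv")
    tree = dendropy.Tree.get(path=str(d / "tree.nwk"), schema="newick")
    fresh = WeeklyTemperatureCube.from_netcdf(d / "fresh_temps.nc")
    marine = WeeklyTemperatureCube.from_netcdf(d / "marine_temps.nc")
    with xr.open_dataset(d / "range_masks.nc", engine="scipy") as ds:
        member = ds["member"].load()
    masks = {
        str(sp): RangeMask(species=str(sp), cells=member.sel(species=sp).values > 0)
        for sp in member["species"].values
    }
    with open(d / "truth.json") as fh:
        doc = json.load(fh)
    realms = doc.pop("realms")
    doc["arr_realm_offsets"] = tuple(
        (k, v) for k, v in doc["arr_realm_offsets"]
    )
    truth = SyntheticTruth(**doc)
    return {
        "records": records,
        "rejections": rejections,
        "tree": tree,
        "fresh_cube": fresh,
        "marine_cube": marine,
        "masks": masks,
        "realms": realms,
        "truth": truth,
    }
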