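"""Synthetic inputs with known ground truth for every pipeline stage.

Generates stratified CTD casts with a configurable internal-wave offset,
forward-modelled incubation endpoints, Poisson-sampled nanoSIMS ROI count
tables, and FISH field-of-view counts, so each stage (and the pipeline
end-to-end) is testable by parameter recovery without any external data.

All randomness flows from one seed: each stage draws from a substream
spawned deterministically from the scenario seed, so stages can be
regenerated independently and a fixed seed yields byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .depth_align import DepthProfile, StationRecord
from .single_cell import CellGeometry, biovolume, carbon_content, nitrogen_content
from .units import (
    C13_NATURAL_ABUNDANCE,
    DEFAULT_CN_RATIO,
    FMOL_PER_UMOL,
    N15_NATURAL_ABUNDANCE,
)

# fixed substream ids per stage (D21): stages regenerate independently
_STREAMS = {"casts": 1, "incubation": 2, "rois": 3, "fish": 4, "nutrients": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],)))


@dataclass
class PopulationSpec:
    """Ground-truth description of one simulated population."""

    name: str
    abundance: float  # cells L-1
    mean_cell_rate: float  # fmol N cell-1 d-1 (true mean)
    width_um: float
    length_um: float
    size_cv: float = 0.1
    rate_cv: float = 0.25
    n_cells: int = 20
    counts_per_plane: float = 2e4  # total (minor+major) ions per plane and pair
    planes_min: int = 20
    planes_max: int = 70


@dataclass
class ScenarioConfig:
    """Everything the generators need, with defaults sized like a stratified
    alpine-lake chemocline (chemocline 13.45-14.45 m, bulk N2 fixation of
    order 0.27 umol N L-1 d-1, single-cell rates 0.2-3.3 fmol N cell-1 d-1,
    20-70 planes per ROI)."""

    seed: int = 0
    # casts
    cast_offset_m: float = 0.3  # internal-wave vertical shift between casts
    depth_min_m: float = 12.0
    depth_max_m: float = 17.0
    grid_step_m: float = 0.02
    station_depths: tuple[float, ...] = (12.5, 13.0, 13.5, 13.7, 14.0, 14.5, 15.0, 15.5, 16.0, 16.5)
    sensor_noise_frac: float = 0.002  # of each parameter's dynamic range
    sigmoid_midpoint_m: float = 14.0
    sigmoid_width_m: float = 0.35
    # incubations
    incubation_depths: tuple[float, ...] = (13.7, 14.0, 15.5)
    true_n2_rates: tuple[float, ...] = (0.27, 0.14, 0.0)  # umol N L-1 d-1
    true_co2_rates: tuple[float, ...] = (3.7, 3.5, 1.2)  # umol C L-1 d-1
    n_replicates: int = 3
    time_d: float = 1.0
    pon_conc: float = 20.0  # umol N L-1
    at_pool_15n: float = 30.0
    at_pool_13c: float = 8.0
    at_na_15n: float = N15_NATURAL_ABUNDANCE
    at_na_13c: float = C13_NATURAL_ABUNDANCE
    measurement_cv: float = 0.002  # on endpoint atom%
    # single cells / populations
    cn_ratio: float = DEFAULT_CN_RATIO
    populations: tuple[PopulationSpec, ...] = ()
    # FISH
    n_fields: int = 40
    field_area_um2: float = 1.5e4
    filter_area_um2: float = 2.0e8
    volume_filtered_l: float = 0.01
    # nutrient profile / flux
    diffusivity_m2_s: float = 1.6e-6
    chemocline_top_m: float = 13.45
    chemocline_bottom_m: float = 14.45
    ammonium_deep_umol_l: float = 30.0

    def __post_init__(self) -> None:
        if not self.populations:
            self.populations = default_populations()
        if abs(self.cast_offset_m) > 1.0:
            raise ValueError("cast offset must be within +-1 m")

    @property
    def poc_conc(self) -> float:
        return self.pon_conc * self.cn_ratio

    def true_bulk_n2_from_populations(self) -> float:
        """Bulk rate implied by the population spec [umol N L-1 d-1]."""
        return sum(p.abundance * p.mean_cell_rate for p in self.populations) / FMOL_PER_UMOL


def default_populations() -> tuple[PopulationSpec, ...]:
    """Five populations; one dominant large-celled population carries ~80%
    of the true bulk fixation, the rest 10/5/3/2%."""
    return (
        PopulationSpec("popA_large", 6.566e7, 3.29, width_um=4.0, length_um=8.0, n_cells=25),
        PopulationSpec("popB", 3.0e7, 0.90, width_um=2.0, length_um=3.2, n_cells=20),
        PopulationSpec("popC", 2.7e7, 0.50, width_um=1.8, length_um=2.8, n_cells=18),
        PopulationSpec("popD", 2.7e7, 0.30, width_um=1.5, length_um=2.5, n_cells=16),
        PopulationSpec("popE", 2.348e7, 0.23, width_um=1.2, length_um=2.4, n_cells=15),
    )


# ---------------------------------------------------------------------------
# casts


def _fields(config: ScenarioConfig):
    """True physicochemical fields as functions of depth."""
    mid, w = config.sigmoid_midpoint_m, config.sigmoid_width_m

    def sig(z, m, s):
        return 1.0 / (1.0 + np.exp(-(np.asarray(z, float) - m) / s))

    return {
        "conductivity": lambda z: 120.0 + 80.0 * sig(z, mid, w),
        "temperature": lambda z: 16.0 - 10.0 * sig(z, mid - 0.1, w * 1.2),
        "pressure": lambda z: np.asarray(z, float) * 1.0,
        "turbidity": lambda z: 1.0
        + 12.0 * np.exp(-((np.asarray(z, float) - (mid - 0.2)) ** 2) / (2 * 0.3**2)),
    }


def make_casts(
    config: ScenarioConfig,
) -> tuple[DepthProfile, DepthProfile, list[StationRecord]]:
    """Downcast, upcast, and stationary upcast records.

    The upcast sees every water mass shifted ``cast_offset_m`` deeper: a
    station at nominal depth z measures the true field at z - offset, so a
    perfect alignment corrects depths by -offset.
    """
    rng = _rng(config.seed, "casts")
    z = np.round(
        np.arange(config.depth_min_m, config.depth_max_m + config.grid_step_m / 2, config.grid_step_m),
        6,
    )
    fields = _fields(config)
    spans = {p: float(np.ptp(f(z))) for p, f in fields.items()}

    def noisy(vals, p):
        return vals + rng.normal(0.0, config.sensor_noise_frac * spans[p], size=np.shape(vals))

    down = DepthProfile(depth=z, columns={p: noisy(f(z), p) for p, f in fields.items()})
    delta = config.cast_offset_m
    up = DepthProfile(depth=z, columns={p: noisy(f(z - delta), p) for p, f in fields.items()})
    stations = [
        StationRecord(
            nominal_depth=float(zs),
            parameter_means={p: float(noisy(f(zs - delta), p)) for p, f in fields.items()},
        )
        for zs in config.station_depths
    ]
    return down, up, stations


# ---------------------------------------------------------------------------
# incubations


def _endpoint_atpct(at_na: float, at_pool: float, rate: float, conc: float, time: float) -> float:
    """Two-pool mass balance: newly fixed material carries the pool label."""
    fixed = rate * time
    if fixed >= conc:
        raise ValueError("true rate * time must be below the biomass pool")
    return (at_na * (conc - fixed) + at_pool * fixed) / conc


def make_incubation(config: ScenarioConfig) -> pd.DataFrame:
    """Endpoint incubation table (long format) for N and C at each depth."""
    rng = _rng(config.seed, "incubation")
    rows = []
    for depth, n2, co2 in zip(config.incubation_depths, config.true_n2_rates, config.true_co2_rates):
        for element, rate, pool, na, conc in (
            ("N", n2, config.at_pool_15n, config.at_na_15n, config.pon_conc),
            ("C", co2, config.at_pool_13c, config.at_na_13c, config.poc_conc),
        ):
            true_end = _endpoint_atpct(na, pool, rate, conc, config.time_d)
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(1.0, config.measurement_cv) if config.measurement_cv > 0 else 1.0
                rows.append(
                    {
                        "depth_m": depth,
                        "replicate": f"r{rep}",
                        "element": element,
                        "at_sample": true_end * noise,
                        "at_na": na,
                        "at_pool": pool,
                        "biomass_conc_umol_L": conc,
                        "time_d": config.time_d,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nanoSIMS ROIs


def make_rois(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(roi_counts, geometry, truth) tables for all populations.

    Each cell draws a geometry (lognormal around the population spec) and a
    true rate; the rate implies a true heavy-isotope fraction by inverting
    the cell-rate equation through the cell's own N (or C) content; per-plane
    minor/major counts are independent Poisson variates at that fraction.
    """
    rng = _rng(config.seed, "rois")
    excess_n_medium = config.at_pool_15n - config.at_na_15n
    excess_c_medium = config.at_pool_13c - config.at_na_13c
    roi_rows, geom_rows, truth_rows = [], [], []
    for pop in config.populations:
        for i in range(pop.n_cells):
            cell_id = f"{pop.name}_{i:03d}"
            sigma = math.sqrt(math.log(1 + pop.size_cv**2))
            width = pop.width_um * rng.lognormal(-(sigma**2) / 2, sigma)
            length = pop.length_um * rng.lognormal(-(sigma**2) / 2, sigma)
            length = max(length, width * 1.0001)  # geometry requires width <= length
            geom = CellGeometry(width=width, length=length)
            bv = biovolume(geom)
            c_cell = carbon_content(bv)
            n_cell = nitrogen_content(c_cell, config.cn_ratio)

            rsigma = math.sqrt(math.log(1 + pop.rate_cv**2))
            rate_n = pop.mean_cell_rate * rng.lognormal(-(rsigma**2) / 2, rsigma)
            rate_c = rate_n * config.cn_ratio  # growth-consistent C uptake
            excess_n = rate_n * config.time_d / n_cell * excess_n_medium
            excess_c = rate_c * config.time_d / c_cell * excess_c_medium
            frac = {
                "N": (config.at_na_15n + excess_n) / 100.0,
                "C": (config.at_na_13c + excess_c) / 100.0,
            }
            n_planes = int(rng.integers(pop.planes_min, pop.planes_max + 1))
            for element, (minor_sp, major_sp) in (("N", ("15N", "14N")), ("C", ("13C", "12C"))):
                f = frac[element]
                if f >= 1.0:
                    raise ValueError("true fraction reached 1; lower rates or raise content")
                minor = rng.poisson(f * pop.counts_per_plane, size=n_planes)
                major = rng.poisson((1 - f) * pop.counts_per_plane, size=n_planes)
                for plane, (lo, hi) in enumerate(zip(minor, major)):
                    roi_rows.append(
                        {"cell_id": cell_id, "population": pop.name, "plane_index": plane,
                         "species": minor_sp, "counts": int(lo)}
                    )
                    roi_rows.append(
                        {"cell_id": cell_id, "population": pop.name, "plane_index": plane,
                         "species": major_sp, "counts": int(hi)}
                    )
            geom_rows.append(
                {"cell_id": cell_id, "population": pop.name,
                 "width_um": width, "length_um": length}
            )
            truth_rows.append(
                {"cell_id": cell_id, "population": pop.name, "true_rate_N_fmol_d": rate_n,
                 "true_rate_C_fmol_d": rate_c, "true_fraction_15N": frac["N"],
                 "true_fraction_13C": frac["C"], "biovolume_um3": bv,
                 "n_content_fmol": n_cell, "c_content_fmol": c_cell, "n_planes": n_planes}
            )
    return pd.DataFrame(roi_rows), pd.DataFrame(geom_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# FISH counts


def make_fish_counts(config: ScenarioConfig) -> pd.DataFrame:
    """Per-field labelled-cell counts, Poisson around the expected density."""
    rng = _rng(config.seed, "fish")
    ratio = config.field_area_um2 / config.filter_area_um2
    rows = []
    for pop in config.populations:
        lam = pop.abundance * config.volume_filtered_l * ratio
        counts = rng.poisson(lam, size=config.n_fields)
        for i, c in enumerate(counts):
            rows.append(
                {"population": pop.name, "field_index": i, "count": int(c),
                 "field_area_um2": config.field_area_um2,
                 "filter_area_um2": config.filter_area_um2,
                 "volume_L": config.volume_filtered_l,
                 "depth_m": config.incubation_depths[0]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nutrient profile


def make_nutrient_profile(config: ScenarioConfig) -> pd.DataFrame:
    """Aligned ammonium profile: depleted in the mixed layer, rising linearly
    below the chemocline to the deep-water value."""
    z = np.round(np.arange(config.depth_min_m, config.depth_max_m + 0.25, 0.25), 6)
    bottom = config.chemocline_bottom_m
    ramp_end = bottom + 1.5
    amm = np.where(
        z <= bottom,
        0.2,
        np.where(
            z >= ramp_end,
            config.ammonium_deep_umol_l,
            0.2 + (config.ammonium_deep_umol_l - 0.2) * (z - bottom) / (ramp_end - bottom),
        ),
    )
    return pd.DataFrame({"depth_m": z, "ammonium_umol_L": amm})


# ---------------------------------------------------------------------------
# full scenario


def write_scenario(config: ScenarioConfig, outdir: "str | Path") -> dict:
    """Write every pipeline input as CSV plus a ground_truth.json; returns truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    down, up, stations = make_casts(config)
    down.to_frame().to_csv(outdir / "downcast.csv", index=False)
    up.to_frame().to_csv(outdir / "upcast.csv", index=False)
    pd.DataFrame(
        [{"nominal_depth_m": s.nominal_depth, **s.parameter_means} for s in stations]
    ).to_csv(outdir / "stations.csv", index=False)
    make_incubation(config).to_csv(outdir / "incubations.csv", index=False)
    rois, geom, truth_cells = make_rois(config)
    rois.to_csv(outdir / "rois.csv", index=False)
    geom.to_csv(outdir / "geometry.csv", index=False)
    truth_cells.to_csv(outdir / "true_cells.csv", index=False)
    make_fish_counts(config).to_csv(outdir / "fish.csv", index=False)
    make_nutrient_profile(config).to_csv(outdir / "nutrients.csv", index=False)
    truth = {
        "seed": config.seed,
        "cast_offset_m": config.cast_offset_m,
        "true_n2_rates": dict(zip(map(str, config.incubation_depths), config.true_n2_rates)),
        "true_co2_rates": dict(zip(map(str, config.incubation_depths), config.true_co2_rates)),
        "bulk_n2_from_populations": config.true_bulk_n2_from_populations(),
        "populations": [
            {"name": p.name, "abundance_cells_L": p.abundance,
             "mean_cell_rate_fmol_N_d": p.mean_cell_rate,
             "share_pct": 100.0 * p.abundance * p.mean_cell_rate
             / (config.true_bulk_n2_from_populations() * FMOL_PER_UMOL)}
            for p in config.populations
        ],
        "at_excess_15N_medium": config.at_pool_15n - config.at_na_15n,
        "at_excess_13C_medium": config.at_pool_13c - config.at_na_13c,
        "time_d": config.time_d,
        "cn_ratio": config.cn_ratio,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def scenario_from_mapping(mapping: dict) -> ScenarioConfig:
    """Build a config from a flat key-value mapping (YAML scenario file)."""
    pops = mapping.pop("populations", None)
    cfg = ScenarioConfig(
        **{k: (tuple(v) if isinstance(v, list) else v) for k, v in mapping.items()}
    )
    if pops is not None:
        cfg.populations = tuple(PopulationSpec(**p) for p in pops)
    return cfg
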