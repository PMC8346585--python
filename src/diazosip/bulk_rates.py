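"""Bulk fixation rates from endpoint isotope incorporation.

rate = [(at%_sample - at%_NA) / (at%_pool - at%_NA)] * [biomass] / time

with the natural-abundance reference taken from the unincubated control
bottle and the pool enrichment from the labelled substrate (dissolved N2
via MIMS, or DIC via CRDS). The same form serves N (PON) and C (POC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .units import ML_PER_L, MOLAR_VOLUME_STP, PMOL_PER_MOL, PPM

logger = logging.getLogger(__name__)


@dataclass
class IncubationSample:
    """Endpoint measurements for one incubation bottle at one depth."""

    depth: float
    replicate: str
    element: str  # "N" or "C"
    at_sample: float  # atom% heavy isotope of PON/POC after incubation
    at_na: float  # atom% of the unincubated natural-abundance control
    at_pool: float  # atom% of the labelled substrate pool
    biomass_conc: float  # umol N (or C) per litre
    time: float  # days

    def __post_init__(self) -> None:
        for name in ("at_sample", "at_na", "at_pool"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] atom%")
        if self.biomass_conc <= 0:
            raise ValueError("biomass concentration must be positive")
        if self.time <= 0:
            raise ValueError("incubation time must be positive")
        if self.element not in ("N", "C"):
            raise ValueError("element must be 'N' or 'C'")


@dataclass
class BulkRate:
    """Replicate-aggregated volumetric fixation rate at one depth."""

    depth: float
    element: str
    rate: float  # umol L-1 d-1
    sd: float  # across replicates
    below_detection: bool
    detection_limit: float


class AtomExcess(NamedTuple):
    value: float
    clipped: bool


def atom_percent_excess(at_sample: float, at_reference: float) -> AtomExcess:
    """Enrichment above the reference, clipped at zero.

    A sample below its control cannot reflect real incorporation; negative
    differences clip to 0 and the ``clipped`` flag preserves the QC signal.
    """
    for v in (at_sample, at_reference):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"atom% value {v} outside [0, 100]")
    excess = at_sample - at_reference
    if excess < 0:
        logger.warning(
            "negative excess %.4g at%% (sample below reference) clipped to 0", excess
        )
        return AtomExcess(0.0, True)
    return AtomExcess(excess, False)


def bulk_rate(sample: IncubationSample) -> float:
    """Volumetric fixation rate [umol L-1 d-1] for one bottle."""
    if sample.at_pool <= sample.at_na:
        raise ValueError(
            f"pool enrichment {sample.at_pool} at% does not exceed the "
            f"natural-abundance reference {sample.at_na} at%: unlabelled bottle?"
        )
    excess = atom_percent_excess(sample.at_sample, sample.at_na).value
    return excess / (sample.at_pool - sample.at_na) * sample.biomass_conc / sample.time


def detection_limit(sample: IncubationSample, na_sd: float, multiplier: float = 3.0) -> float:
    """Rate equivalent of the minimum detectable excess.

    The minimum detectable excess is ``multiplier`` times the standard
    deviation of the natural-abundance atom% across control replicates;
    pushing it through the rate equation gives the limit of detection.
    """
    if na_sd < 0:
        raise ValueError("na_sd must be non-negative")
    return (
        multiplier * na_sd / (sample.at_pool - sample.at_na) * sample.biomass_conc / sample.time
    )


def censor_rate(
    rate: float,
    sample: IncubationSample,
    na_sd: float,
    multiplier: float = 3.0,
) -> BulkRate:
    """Censor a rate that fails the minimum-detectable-excess criterion.

    Censored rates are reported as 0 with ``below_detection`` set; the
    detection limit is always recorded so the censoring policy is explicit
    in the output.
    """
    lod = detection_limit(sample, na_sd, multiplier)
    excess = atom_percent_excess(sample.at_sample, sample.at_na).value
    censored = excess < multiplier * na_sd
    return BulkRate(
        depth=sample.depth,
        element=sample.element,
        rate=0.0 if censored else rate,
        sd=0.0,
        below_detection=censored,
        detection_limit=lod,
    )


def aggregate_replicates(rates: "np.ndarray | list[float]") -> tuple[float, float]:
    """Arithmetic mean and SD across replicate bottles (ddof=1; 0 for n=1)."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates to aggregate")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def autotrophic_n_demand(co2_rate: float, cn_ratio: float) -> float:
    """N required to sustain a measured autotrophic C fixation rate.

    demand [umol N L-1 d-1] = CO2 fixation rate [umol C L-1 d-1] / (C:N).
    """
    if cn_ratio <= 0:
        raise ValueError("C:N ratio must be positive")
    return co2_rate / cn_ratio


def fixation_fraction(n2_rate: float, n_demand: float, below_detection: bool = False) -> float:
    """Percent of the autotrophic N demand met by N2 fixation.

    Below-detection rates contribute 0%. Non-positive demand makes the
    fraction undefined (NaN, with a warning).
    """
    if n_demand <= 0:
        logger.warning("non-positive N demand: fixation fraction undefined")
        return math.nan
    if below_detection:
        return 0.0
    return 100.0 * n2_rate / n_demand


def mole_fraction_ppm(
    amount_pmol: float,
    gas_volume_ml: float,
    molar_volume: float = MOLAR_VOLUME_STP,
) -> float:
    """Mole fraction, in ppm, of an analyte dissolved out of a gas aliquot.

    Used for the labelled-gas contamination check: an analyte quantity in
    pmol recovered from a gas volume in mL, with total gas moles from the
    ideal molar volume (default 22.414 L mol-1 at 0 degC, 1 atm).
    """
    if gas_volume_ml <= 0:
        raise ValueError("gas volume must be positive")
    if molar_volume <= 0:
        raise ValueError("molar volume must be positive")
    moles_analyte = amount_pmol / PMOL_PER_MOL
    moles_gas = (gas_volume_ml / ML_PER_L) / molar_volume
    return PPM * moles_analyte / moles_gas


def bulk_rate_table(
    incubations: pd.DataFrame,
    lod_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Per-depth, per-element aggregated rates from a long incubation table.

    Expects columns: depth_m, replicate, element, at_sample, at_na, at_pool,
    biomass_conc_umol_L, time_d. The natural-abundance SD for the detection
    limit is the SD of ``at_na`` across replicates at each (depth, element);
    with a single control it falls back to 0 (nothing censored).
    """
    out = []
    for (depth, element), grp in incubations.groupby(["depth_m", "element"], sort=True):
        samples = [
            IncubationSample(
                depth=float(depth),
                replicate=str(r.replicate),
                element=str(element),
                at_sample=float(r.at_sample),
                at_na=float(r.at_na),
                at_pool=float(r.at_pool),
                biomass_conc=float(r.biomass_conc_umol_L),
                time=float(r.time_d),
            )
            for r in grp.itertuples()
        ]
        na_sd = float(np.std([s.at_na for s in samples], ddof=1)) if len(samples) > 1 else 0.0
        censored = [
            censor_rate(bulk_rate(s), s, na_sd, multiplier=lod_multiplier) for s in samples
        ]
        mean, sd = aggregate_replicates([c.rate for c in censored])
        below = all(c.below_detection for c in censored)
        out.append(
            {
                "depth_m": float(depth),
                "element": str(element),
                "rate": 0.0 if below else mean,
                "sd": sd,
                "below_detection": below,
                "detection_limit": max(c.detection_limit for c in censored),
            }
        )
    return pd.DataFrame(out)
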