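"""Steady-state diffusive ammonium flux into the chemocline and the N budget.

Fick's first law over a fixed gradient window gives an areal flux
[mmol m-2 d-1]; dividing by the chemocline thickness converts it to a
volumetric assimilation rate [umol L-1 d-1] under the assumption that the
layer is constantly mixed. The budget then partitions the autotrophic N
demand between N2 fixation and ammonium assimilation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import SECONDS_PER_DAY, UMOL_L_PER_MMOL_M3

logger = logging.getLogger(__name__)


@dataclass
class ConcentrationGradient:
    """Two bracketing samples defining a linear concentration gradient."""

    depth_upper: float  # m, shallower
    depth_lower: float  # m, deeper
    conc_upper: float  # umol L-1
    conc_lower: float  # umol L-1
    diffusivity: float  # m2 s-1 (turbulent)

    def __post_init__(self) -> None:
        if self.depth_lower <= self.depth_upper:
            raise ValueError("depth_lower must exceed depth_upper")
        if self.conc_upper < 0 or self.conc_lower < 0:
            raise ValueError("concentrations must be non-negative")
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")


@dataclass
class LayerBudget:
    """N-source budget for a mixed layer."""

    layer_top: float
    layer_bottom: float
    areal_flux: float  # mmol m-2 d-1
    volumetric_rate: float  # umol L-1 d-1
    n2_fixation: float  # umol L-1 d-1
    n_demand: float  # umol L-1 d-1
    fraction_fixation: float  # percent of demand
    fraction_ammonium: float  # percent of demand
    fraction_unexplained: float  # percent of demand


def fick_flux(gradient: ConcentrationGradient) -> float:
    """Areal flux [mmol m-2 d-1], positive when concentration increases downward.

    J = D * dC/dz with D converted to m2 d-1 and concentrations to mmol m-3
    (numerically equal to umol L-1); positive J is an upward flux into the
    layer above the gradient window.
    """
    d_day = gradient.diffusivity * SECONDS_PER_DAY
    dc = (gradient.conc_lower - gradient.conc_upper) * UMOL_L_PER_MMOL_M3  # mmol m-3
    dz = gradient.depth_lower - gradient.depth_upper
    return d_day * dc / dz


def volumetric_rate(areal_flux: float, layer_top: float, layer_bottom: float) -> float:
    """Spread an areal flux over a mixed layer: mmol m-2 d-1 / m = umol L-1 d-1."""
    thickness = layer_bottom - layer_top
    if thickness <= 0:
        raise ValueError("layer_bottom must exceed layer_top")
    return areal_flux / thickness


def steepest_segment(
    profile: pd.DataFrame,
    column: str,
    depth_col: str = "depth_m",
) -> tuple[float, float]:
    """Window (top, bottom) of the steepest gradient between consecutive samples.

    Optional helper when the gradient window is not fixed by configuration;
    scans consecutive sample pairs of the (depth-sorted) profile.
    """
    df = profile.dropna(subset=[depth_col, column]).sort_values(depth_col)
    if len(df) < 2:
        raise ValueError("need at least two samples to locate a gradient")
    z = df[depth_col].to_numpy(float)
    c = df[column].to_numpy(float)
    slopes = np.abs(np.diff(c) / np.diff(z))
    i = int(np.argmax(slopes))
    return float(z[i]), float(z[i + 1])


def n_source_budget(
    n_demand: float,
    n2_rate: float,
    ammonium_rate: float,
    layer_top: float = math.nan,
    layer_bottom: float = math.nan,
    areal_flux: float = math.nan,
) -> LayerBudget:
    """Partition the autotrophic N demand between fixation and ammonium.

    The ammonium contribution is capped at the demand left after fixation,
    so the two fractions never exceed 100% combined; any shortfall is
    reported as unexplained demand.
    """
    if n_demand <= 0:
        logger.warning("non-positive N demand: budget fractions undefined")
        return LayerBudget(
            layer_top=layer_top,
            layer_bottom=layer_bottom,
            areal_flux=areal_flux,
            volumetric_rate=ammonium_rate,
            n2_fixation=n2_rate,
            n_demand=n_demand,
            fraction_fixation=math.nan,
            fraction_ammonium=math.nan,
            fraction_unexplained=math.nan,
        )
    frac_fix = 100.0 * n2_rate / n_demand
    frac_amm = 100.0 * min(ammonium_rate, max(n_demand - n2_rate, 0.0)) / n_demand
    return LayerBudget(
        layer_top=layer_top,
        layer_bottom=layer_bottom,
        areal_flux=areal_flux,
        volumetric_rate=ammonium_rate,
        n2_fixation=n2_rate,
        n_demand=n_demand,
        fraction_fixation=frac_fix,
        fraction_ammonium=frac_amm,
        fraction_unexplained=max(100.0 - frac_fix - frac_amm, 0.0),
    )


def budget_from_profile(
    profile: pd.DataFrame,
    diffusivity_m2_s: float,
    window_top_m: float,
    window_bottom_m: float,
    layer_top_m: float,
    layer_bottom_m: float,
    n_demand: float,
    n2_rate: float = 0.0,
    column: str = "ammonium_umol_L",
    depth_col: str = "depth_m",
) -> LayerBudget:
    """Full budget from an aligned nutrient profile and a gradient window.

    Window endpoint concentrations are linearly interpolated from the
    profile (bottle sampling rarely lands exactly on the window bounds).
    """
    df = profile.dropna(subset=[depth_col, column]).sort_values(depth_col)
    z = df[depth_col].to_numpy(float)
    c = df[column].to_numpy(float)
    if not (z.min() <= window_top_m and window_bottom_m <= z.max()):
        raise ValueError("gradient window extends outside the profile")
    conc_upper = float(np.interp(window_top_m, z, c))
    conc_lower = float(np.interp(window_bottom_m, z, c))
    grad = ConcentrationGradient(
        depth_upper=window_top_m,
        depth_lower=window_bottom_m,
        conc_upper=conc_upper,
        conc_lower=conc_lower,
        diffusivity=diffusivity_m2_s,
    )
    flux = fick_flux(grad)
    rate = volumetric_rate(flux, layer_top_m, layer_bottom_m)
    return n_source_budget(
        n_demand=n_demand,
        n2_rate=n2_rate,
        ammonium_rate=rate,
        layer_top=layer_top_m,
        layer_bottom=layer_bottom_m,
        areal_flux=flux,
    )
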