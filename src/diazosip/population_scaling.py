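"""Scale single-cell activity to population and bulk level.

Field-of-view counts on membrane filters convert to volumetric abundances
with the standard epifluorescence formula; abundance times mean single-cell
rate gives the population rate, with standard errors propagated for the
product; population rates over the replicate-mean bulk rate give percent
contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bulk_rates import BulkRate
from .units import FMOL_PER_UMOL

logger = logging.getLogger(__name__)


@dataclass
class FishCountSet:
    """Labelled-cell counts over random fields of view for one population."""

    population: str
    counts: np.ndarray  # cells per field
    field_area: float  # um2
    filter_area: float  # um2, effective filtration area
    volume_filtered: float  # L

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size < 1:
            raise ValueError("need at least one field of view")
        if np.any(self.counts < 0) or np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be non-negative integers")
        if self.field_area <= 0 or self.filter_area <= 0:
            raise ValueError("areas must be positive")
        if self.volume_filtered <= 0:
            raise ValueError("filtered volume must be positive")


@dataclass
class PopulationSummary:
    """Abundance and mean single-cell rate for one population at one depth."""

    population: str
    depth: float
    abundance: float  # cells L-1
    abundance_se: float
    mean_cell_rate: float  # fmol N cell-1 d-1
    rate_se: float
    n_cells_analyzed: int

    def __post_init__(self) -> None:
        if self.abundance < 0 or self.abundance_se < 0 or self.rate_se < 0:
            raise ValueError("abundance and standard errors must be non-negative")
        if self.n_cells_analyzed < 1:
            raise ValueError("a rate requires at least one analyzed cell")


def cells_per_liter(counts: FishCountSet) -> tuple[float, float]:
    """Volumetric abundance [cells L-1] and its standard error.

    abundance = mean(count/field) * (filter area / field area) / volume;
    the SE of the mean count per field scales identically.
    """
    scale = (counts.filter_area / counts.field_area) / counts.volume_filtered
    mean = float(counts.counts.mean())
    n = counts.counts.size
    se = float(counts.counts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean * scale, se * scale


def population_rate(summary: PopulationSummary) -> tuple[float, float]:
    """Volumetric population rate [umol L-1 d-1] with propagated SE.

    R = abundance * mean cell rate / 1e9 (fmol -> umol). The SE uses the
    exact variance of a product of independent quantities,
    var = a^2 se_r^2 + r^2 se_a^2 + se_a^2 se_r^2, which reduces to the
    usual quadrature form R*sqrt((se_a/a)^2 + (se_r/r)^2) for small CVs.
    """
    a, r = summary.abundance, summary.mean_cell_rate
    se_a, se_r = summary.abundance_se, summary.rate_se
    rate = a * r / FMOL_PER_UMOL
    var = a**2 * se_r**2 + r**2 * se_a**2 + se_a**2 * se_r**2
    return rate, math.sqrt(var) / FMOL_PER_UMOL


def contribution(
    population_rates: "list[tuple[str, float, float]]",
    bulk: BulkRate,
) -> pd.DataFrame:
    """Percent of the bulk rate per population, plus the summed total.

    ``population_rates`` holds (population, rate, se) in umol L-1 d-1. The
    denominator is the replicate-mean bulk rate; its SD propagates into the
    total's SE in quadrature with the population SEs. A below-detection
    bulk rate makes contributions undefined.
    """
    if bulk.below_detection or bulk.rate <= 0:
        raise ValueError("bulk rate below detection: contributions undefined")
    b, sb = bulk.rate, bulk.sd
    rows = []
    for name, rate, se in population_rates:
        pct = 100.0 * rate / b
        # d(pct)/d(rate) = 100/b; d(pct)/d(b) = -100*rate/b^2
        pct_se = 100.0 * math.sqrt((se / b) ** 2 + (rate * sb / b**2) ** 2)
        rows.append({"population": name, "contribution_pct": pct, "contribution_se_pct": pct_se})
    total_rate = sum(r for _, r, _ in population_rates)
    total_var = sum(se**2 for _, _, se in population_rates)
    total_pct = 100.0 * total_rate / b
    total_se = 100.0 * math.sqrt(total_var / b**2 + (total_rate * sb / b**2) ** 2)
    rows.append(
        {"population": "TOTAL", "contribution_pct": total_pct, "contribution_se_pct": total_se}
    )
    return pd.DataFrame(rows)


def fish_table_to_countsets(df: pd.DataFrame) -> list[FishCountSet]:
    """Parse a long FISH table (population, field_index, count, areas, volume)."""
    sets = []
    for pop, grp in df.groupby("population", sort=True):
        sets.append(
            FishCountSet(
                population=str(pop),
                counts=grp.sort_values("field_index")["count"].to_numpy(),
                field_area=float(grp["field_area_um2"].iloc[0]),
                filter_area=float(grp["filter_area_um2"].iloc[0]),
                volume_filtered=float(grp["volume_L"].iloc[0]),
            )
        )
    return sets


def summarize_populations(
    fish: pd.DataFrame,
    cell_rates: pd.DataFrame,
    depth: float = math.nan,
    rate_column: str = "rate_N_fmol_d",
    require_qc: bool = True,
) -> list[PopulationSummary]:
    """Combine FISH abundances with per-cell rate tables.

    The mean single-cell rate is the arithmetic mean over QC-passing cells,
    deliberately including inactive (zero-rate) cells; SE = SD/sqrt(n).
    """
    summaries = []
    for counts in fish_table_to_countsets(fish):
        a, se_a = cells_per_liter(counts)
        sub = cell_rates[cell_rates["population"] == counts.population]
        if require_qc and "passed_qc" in sub.columns:
            sub = sub[sub["passed_qc"]]
        rates = sub[rate_column].dropna().to_numpy(float)
        if rates.size == 0:
            logger.warning("population %s has no QC-passing cells; skipped", counts.population)
            continue
        se_r = float(rates.std(ddof=1) / math.sqrt(rates.size)) if rates.size > 1 else 0.0
        summaries.append(
            PopulationSummary(
                population=counts.population,
                depth=depth,
                abundance=a,
                abundance_se=se_a,
                mean_cell_rate=float(rates.mean()),
                rate_se=se_r,
                n_cells_analyzed=int(rates.size),
            )
        )
    return summaries
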