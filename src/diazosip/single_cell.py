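"""Single-cell fixation rates from nanoSIMS region-of-interest ion counts.

Counts arrive drift-corrected, one row per acquisition plane and secondary
ion species. Planes are accumulated per cell, isotope fractions
minor/(minor+major) and their Poisson counting errors computed, cells
filtered at <5% relative ratio error, and cell-specific rates derived from

    rate = (at% excess_cell / at% excess_medium) * content_cell / time

with cellular N content obtained from biovolume via an allometric carbon
power law and a bulk C:N ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .units import CARBON_MOLAR_MASS, DEFAULT_CN_RATIO

logger = logging.getLogger(__name__)

#: QC threshold on the relative Poisson error of the minor/major ratio
POISSON_QC_THRESHOLD = 0.05

#: species labels expected in long-format ROI tables, per isotope pair
ISOTOPE_PAIRS = {"N": ("15N", "14N"), "C": ("13C", "12C")}


@dataclass
class RoiMeasurement:
    """Per-plane secondary-ion counts for one cell."""

    cell_id: str
    population: str
    planes: dict[str, np.ndarray] = field(default_factory=dict)  # species -> counts per plane

    def __post_init__(self) -> None:
        self.planes = {k: np.asarray(v) for k, v in self.planes.items()}
        lengths = {v.size for v in self.planes.values()}
        if not self.planes or 0 in lengths:
            raise ValueError("ROI must contain at least one plane per species")
        if len(lengths) != 1:
            raise ValueError("plane lists must have equal length across species")
        for sp, counts in self.planes.items():
            if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
                if np.any(counts != np.floor(counts)) or np.any(counts < 0):
                    raise ValueError(f"counts for {sp!r} must be non-negative integers")
                self.planes[sp] = counts.astype(np.int64)

    @property
    def n_planes(self) -> int:
        return next(iter(self.planes.values())).size


@dataclass
class CellGeometry:
    """Cell width (cross-section) and length in micrometres."""

    width: float
    length: float
    source: str = "image"  # "image" or "roi"

    def __post_init__(self) -> None:
        if not 0 < self.width <= self.length:
            raise ValueError("require 0 < width <= length")


def accumulate_planes(roi: RoiMeasurement) -> dict[str, int]:
    """Total counts per species across all planes of the ROI."""
    if roi.n_planes == 0:
        raise ValueError("empty plane list")
    return {sp: int(counts.sum()) for sp, counts in roi.planes.items()}


def isotope_fraction(minor_counts: float, major_counts: float) -> float:
    """Heavy-isotope fraction minor/(minor+major); NaN when no counts."""
    total = minor_counts + major_counts
    if total <= 0:
        logger.warning("zero total counts: isotope fraction undefined")
        return math.nan
    return minor_counts / total


def ratio_poisson_error(minor_counts: float, major_counts: float) -> float:
    """Relative Poisson error of the minor/major count ratio.

    sqrt(1/minor + 1/major) — the standard error propagation for a ratio of
    two independent Poisson totals. Zero minor counts make the error
    undefined (inf), which always fails QC.
    """
    if major_counts <= 0:
        raise ValueError("major counts must be positive")
    if minor_counts <= 0:
        return math.inf
    return math.sqrt(1.0 / minor_counts + 1.0 / major_counts)


def passes_qc(minor_counts: float, major_counts: float, threshold: float = POISSON_QC_THRESHOLD) -> bool:
    """Strictly-below-threshold test on the relative ratio error."""
    return ratio_poisson_error(minor_counts, major_counts) < threshold


def biovolume(geometry: CellGeometry) -> float:
    """Prolate-spheroid biovolume [um3]: (pi/6) * width^2 * length."""
    return math.pi / 6.0 * geometry.width**2 * geometry.length


def roi_geometry(width: float, length: float) -> CellGeometry:
    """Geometry from ROI equivalent-ellipse axes (minor = width, major = length)."""
    return CellGeometry(width=min(width, length), length=max(width, length), source="roi")


def carbon_content(bv: float) -> float:
    """Cellular carbon [fmol C] from biovolume via 0.433 * BV^0.863 pg C."""
    if bv < 0:
        raise ValueError("biovolume must be non-negative")
    pg_c = 0.433 * bv**0.863
    return pg_c * 1000.0 / CARBON_MOLAR_MASS


def nitrogen_content(c_cell: float, cn_ratio: float = DEFAULT_CN_RATIO) -> float:
    """Cellular nitrogen [fmol N] from carbon content and a bulk C:N ratio."""
    if cn_ratio <= 0:
        raise ValueError("C:N ratio must be positive")
    return c_cell / cn_ratio


def cell_rate(
    at_excess_cell: float,
    at_excess_medium: float,
    content: float,
    time: float,
) -> float:
    """Cell-specific fixation rate [fmol cell-1 d-1]."""
    if at_excess_medium <= 0:
        raise ValueError("medium excess enrichment must be positive")
    if time <= 0:
        raise ValueError("incubation time must be positive")
    if content <= 0:
        raise ValueError("cell content must be positive")
    return (at_excess_cell / at_excess_medium) * content / time


def convergence_check(
    cell_fractions: "np.ndarray | list[float]",
    threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Running-mean stability of isotope fractions across measured cells.

    Returns (cumulative means, relative change per added cell, adequate n).
    Adequate n is the smallest sample size after which the relative change
    of the running mean stays below ``threshold`` for every subsequent cell,
    in acquisition order; None when the series never stabilizes (or when
    fewer than two cells were measured, which is flagged insufficient).
    """
    arr = np.asarray(cell_fractions, dtype=float)
    if arr.size < 2:
        logger.warning("fewer than 2 cells: convergence cannot be assessed")
        return arr.copy(), np.array([]), None
    cum_mean = np.cumsum(arr) / np.arange(1, arr.size + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_change = np.abs(np.diff(cum_mean)) / np.abs(cum_mean[:-1])
    ok = rel_change < threshold  # ok[i]: adding cell i+2 moved the mean < threshold
    adequate = None
    for n in range(2, arr.size + 1):
        if np.all(ok[n - 2 :]):
            adequate = n
            break
    return cum_mean, rel_change, adequate


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    median_a: float
    median_b: float
    sufficient: bool


def fish_effect_compare(
    treated: "np.ndarray | list[float]",
    untreated: "np.ndarray | list[float]",
) -> GroupComparison:
    """Rank-based two-sample test for a hybridization effect on enrichment.

    Mann-Whitney U on the isotope fractions of treated vs untreated cells;
    groups with fewer than 3 cells are flagged insufficient (NaN p-value).
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(untreated, dtype=float)
    if a.size < 3 or b.size < 3:
        logger.warning("group with <3 cells: comparison flagged insufficient")
        return GroupComparison(math.nan, math.nan, float(np.median(a)) if a.size else math.nan,
                               float(np.median(b)) if b.size else math.nan, False)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        sufficient=True,
    )


def rois_from_table(df: pd.DataFrame) -> list[RoiMeasurement]:
    """Parse a long-format count table into ROI objects.

    Expected columns: cell_id, population, plane_index, species, counts.
    """
    rois = []
    for (cell_id, population), grp in df.groupby(["cell_id", "population"], sort=True):
        planes = {}
        for sp, sub in grp.groupby("species"):
            planes[str(sp)] = sub.sort_values("plane_index")["counts"].to_numpy()
        rois.append(RoiMeasurement(cell_id=str(cell_id), population=str(population), planes=planes))
    return rois


def _geometry_for(
    cell_id: str,
    population: str,
    geometry: pd.DataFrame,
) -> CellGeometry | None:
    """Per-cell geometry when present; otherwise the population median biovolume.

    Cluster-forming populations are sized from many imaged cells, so the
    population entries are reduced to the geometry of median biovolume.
    """
    if "cell_id" in geometry.columns:
        row = geometry[geometry["cell_id"].astype(str) == cell_id]
        if len(row) == 1:
            return CellGeometry(float(row.width_um.iloc[0]), float(row.length_um.iloc[0]))
    if "population" in geometry.columns:
        rows = geometry[geometry["population"].astype(str) == population]
        if len(rows):
            bv = math.pi / 6.0 * rows.width_um.to_numpy() ** 2 * rows.length_um.to_numpy()
            i = int(np.argsort(bv)[len(bv) // 2])  # row of median biovolume
            return CellGeometry(float(rows.width_um.iloc[i]), float(rows.length_um.iloc[i]))
    return None


def process_rois(
    roi_table: pd.DataFrame,
    geometry: pd.DataFrame,
    at_excess_15n_medium: float,
    at_excess_13c_medium: float,
    time_d: float,
    cn_ratio: float = DEFAULT_CN_RATIO,
    na_15n_atpct: float | None = None,
    na_13c_atpct: float | None = None,
    qc_threshold: float = POISSON_QC_THRESHOLD,
    enrichment_sigma: float = 3.0,
    fish_dilution_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-cell enrichment, QC, contents, and rates for a whole ROI table.

    Natural-abundance atom% references default to the count-weighted values
    measured on cells when not given. ``fish_dilution_factor`` is a
    multiplicative hook for hybridization isotope loss and defaults to 1
    (no correction). A cell is ``significantly_enriched`` when its excess
    exceeds ``enrichment_sigma`` times the propagated counting error of its
    atom% value.
    """
    from .units import C13_NATURAL_ABUNDANCE, N15_NATURAL_ABUNDANCE

    if na_15n_atpct is None:
        na_15n_atpct = N15_NATURAL_ABUNDANCE
    if na_13c_atpct is None:
        na_13c_atpct = C13_NATURAL_ABUNDANCE
    na = {"N": na_15n_atpct, "C": na_13c_atpct}
    medium = {"N": at_excess_15n_medium, "C": at_excess_13c_medium}

    rows = []
    for roi in rois_from_table(roi_table):
        totals = accumulate_planes(roi)
        geom = _geometry_for(roi.cell_id, roi.population, geometry)
        rec: dict[str, object] = {"cell_id": roi.cell_id, "population": roi.population,
                                  "n_planes": roi.n_planes}
        if geom is not None:
            bv = biovolume(geom)
            c_cell = carbon_content(bv)
            n_cell = nitrogen_content(c_cell, cn_ratio)
            rec.update(biovolume_um3=bv, c_content_fmol=c_cell, n_content_fmol=n_cell)
        else:
            logger.warning("no geometry for cell %s (%s)", roi.cell_id, roi.population)
            rec.update(biovolume_um3=math.nan, c_content_fmol=math.nan, n_content_fmol=math.nan)

        passed_all = True
        for element, (minor_sp, major_sp) in ISOTOPE_PAIRS.items():
            if minor_sp not in totals or major_sp not in totals:
                continue
            minor, major = totals[minor_sp], totals[major_sp]
            frac = isotope_fraction(minor, major)
            err = ratio_poisson_error(minor, major)
            ok = err < qc_threshold
            passed_all = passed_all and ok
            atpct = 100.0 * frac * fish_dilution_factor
            excess = max(atpct - na[element], 0.0)
            # counting error on the atom% value, for the enrichment call
            atpct_sigma = atpct * err
            significant = excess > enrichment_sigma * atpct_sigma
            content = rec["n_content_fmol"] if element == "N" else rec["c_content_fmol"]
            if geom is not None and medium[element] > 0:
                rate = cell_rate(excess, medium[element], float(content), time_d)
            else:
                rate = math.nan
            suffix = "15N" if element == "N" else "13C"
            rec[f"fraction_{suffix}"] = frac
            rec[f"at_excess_{suffix}"] = excess
            rec[f"poisson_error_{suffix}"] = err
            rec[f"significantly_enriched_{suffix}"] = significant
            rec[f"rate_{element}_fmol_d"] = rate
        rec["passed_qc"] = passed_all
        rows.append(rec)
    return pd.DataFrame(rows)
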