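"""Depth correction of upcast bottle samples against a continuous downcast.

Internal waves shift water masses vertically between the downcast and the
stationary upcast sampling stops. Samples are therefore reassigned to the
depth of the downcast row whose normalized physicochemical parameters best
match the station means: parameters are rescaled to a 0-100 percent scale,
and the corrected depth is the downcast row minimizing the summed absolute
percent differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: parameters used for matching unless the caller overrides them
DEFAULT_MATCH_PARAMS = ("conductivity", "temperature", "pressure")


@dataclass
class DepthProfile:
    """A continuous cast: strictly increasing depth grid plus parameter columns."""

    depth: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth must be strictly increasing")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for name, col in self.columns.items():
            if col.shape != self.depth.shape:
                raise ValueError(f"column {name!r} length != depth length")
            if np.any(~np.isfinite(col)):
                raise ValueError(f"column {name!r} contains missing values")

    def __len__(self) -> int:
        return self.depth.size

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, depth_col: str = "depth_m") -> "DepthProfile":
        """Build a profile from a dataframe, dropping rows with any missing value."""
        n0 = len(df)
        df = df.dropna().sort_values(depth_col)
        if len(df) < n0:
            logger.warning("dropped %d rows with missing values at ingest", n0 - len(df))
        cols = {c: df[c].to_numpy(float) for c in df.columns if c != depth_col}
        return cls(depth=df[depth_col].to_numpy(float), columns=cols)

    @classmethod
    def from_csv(cls, path, depth_col: str = "depth_m") -> "DepthProfile":
        return cls.from_frame(pd.read_csv(path), depth_col=depth_col)

    def to_frame(self, depth_col: str = "depth_m") -> pd.DataFrame:
        return pd.DataFrame({depth_col: self.depth, **self.columns})


@dataclass
class StationRecord:
    """Mean parameter values over one stationary upcast sampling window."""

    nominal_depth: float
    parameter_means: dict[str, float]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, depth_col: str = "nominal_depth_m") -> list["StationRecord"]:
        records = []
        for _, row in df.iterrows():
            means = {c: float(row[c]) for c in df.columns if c != depth_col and np.isfinite(row[c])}
            records.append(cls(nominal_depth=float(row[depth_col]), parameter_means=means))
        return records


def compute_ranges(
    downcast: DepthProfile,
    stations: Sequence[StationRecord],
    params: Iterable[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-parameter (min, max) over the union of downcast values and station means.

    Taking the union guarantees station values never clamp during
    normalization. Raises if the downcast and stations share no parameter.
    """
    station_params = set().union(*(s.parameter_means for s in stations)) if stations else set()
    shared = set(downcast.parameters) & station_params if stations else set(downcast.parameters)
    if params is not None:
        shared &= set(params)
    if not shared:
        raise ValueError("no shared parameters between downcast and stations")
    ranges: dict[str, tuple[float, float]] = {}
    for p in sorted(shared):
        vals = [downcast.columns[p]]
        vals.extend(
            np.atleast_1d(s.parameter_means[p]) for s in stations if p in s.parameter_means
        )
        allv = np.concatenate(vals)
        ranges[p] = (float(allv.min()), float(allv.max()))
    return ranges


def _normalize_values(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    out = 100.0 * (v - lo) / (hi - lo)
    n_clamped = int(np.sum((out < 0) | (out > 100)))
    if n_clamped:
        logger.warning("%d values outside range (%g, %g) clamped to 0/100", n_clamped, lo, hi)
    return np.clip(out, 0.0, 100.0)


def normalize(profile: DepthProfile, ranges: Mapping[str, tuple[float, float]]) -> DepthProfile:
    """Rescale each parameter to percent of its (min, max) range.

    Parameters with a degenerate range (max == min) carry no matching
    information and are excluded with a warning. Values outside the range
    clamp to 0/100 and are logged.
    """
    cols: dict[str, np.ndarray] = {}
    for p, col in profile.columns.items():
        if p not in ranges:
            continue
        lo, hi = ranges[p]
        if hi < lo:
            raise ValueError(f"range for {p!r} has max < min")
        if hi == lo:
            logger.warning("parameter %r has degenerate range; excluded from matching", p)
            continue
        cols[p] = _normalize_values(col, lo, hi)
    return DepthProfile(depth=profile.depth.copy(), columns=cols)


def normalize_station(
    station: StationRecord, ranges: Mapping[str, tuple[float, float]]
) -> StationRecord:
    """Normalize station means with the same ranges used for the downcast."""
    means: dict[str, float] = {}
    for p, v in station.parameter_means.items():
        if p not in ranges:
            continue
        lo, hi = ranges[p]
        if hi == lo:
            continue
        means[p] = float(_normalize_values(np.array([v]), lo, hi)[0])
    return StationRecord(nominal_depth=station.nominal_depth, parameter_means=means)


def match_depth(
    station: StationRecord,
    downcast_norm: DepthProfile,
    params: Iterable[str] | None = None,
) -> tuple[float, float]:
    """Corrected depth and match score for one normalized station.

    The score of a downcast row is the sum over shared parameters of the
    absolute difference between station percent and row percent; the
    corrected depth is the row with the lowest score, ties resolved to the
    shallowest depth.
    """
    if len(downcast_norm) == 0:
        raise ValueError("empty downcast profile")
    use = set(station.parameter_means) & set(downcast_norm.parameters)
    if params is not None:
        use &= set(params)
    missing = set(station.parameter_means) - set(downcast_norm.parameters)
    if missing:
        logger.warning(
            "station at %.2f m: parameters %s missing from downcast, ignored",
            station.nominal_depth,
            sorted(missing),
        )
    if not use:
        raise ValueError("station shares no parameters with downcast")
    score = np.zeros(len(downcast_norm))
    for p in sorted(use):
        score += np.abs(downcast_norm.columns[p] - station.parameter_means[p])
    idx = int(np.argmin(score))  # argmin takes the first minimum = shallowest row
    return float(downcast_norm.depth[idx]), float(score[idx])


def align_stations(
    stations: Sequence[StationRecord],
    downcast: DepthProfile,
    params: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Depth-correct every station against the downcast.

    Returns a table of (nominal_depth_m, corrected_depth_m, score), one row
    per station, and logs the applied shift for audit.
    """
    if params is None:
        params = [p for p in DEFAULT_MATCH_PARAMS if p in downcast.parameters]
    ranges = compute_ranges(downcast, stations, params=params)
    downcast_norm = normalize(downcast, ranges)
    rows = []
    for st in stations:
        st_norm = normalize_station(st, ranges)
        corrected, score = match_depth(st_norm, downcast_norm, params=params)
        logger.info(
            "station %.2f m -> %.2f m (shift %+.2f m, score %.3f)",
            st.nominal_depth,
            corrected,
            corrected - st.nominal_depth,
            score,
        )
        rows.append(
            {
                "nominal_depth_m": st.nominal_depth,
                "corrected_depth_m": corrected,
                "score": score,
            }
        )
    return pd.DataFrame(rows)
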