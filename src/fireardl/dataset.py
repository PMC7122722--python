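"""Monthly multivariate time-series container with transform provenance.

The analysis works on an aligned table of monthly fire and climate series:
area burned (ha), combined carbon emissions / biomass burned
(g cm^-2 month^-1), relative humidity (%), minimum and maximum temperature
(deg C), precipitation (mm), sunlight (h/month) and wind speed (m/s).
Every transform (natural log with an optional offset, differencing) is
recorded per variable so downstream stages can state exactly what scale a
coefficient lives on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical variable order used throughout the pipeline
CANONICAL_VARIABLES = [
    "area_burned",
    "cem",
    "rel_humidity",
    "t_min",
    "t_max",
    "precip",
    "sunlight",
    "wind",
]

#: variables that may legitimately be zero outside the fire season and
#: therefore get a +1 offset before the log transform by default
ZERO_INFLATED_VARIABLES = ("area_burned", "cem")

DEFAULT_WINDOW = ("2001-01", "2018-12")


@dataclass(frozen=True)
class TransformState:
    """Per-variable record of applied transforms."""

    log: bool = False
    log_offset: float = 0.0
    diff_order: int = 0

    def describe(self) -> str:
        parts = []
        if self.log:
            parts.append("log" if self.log_offset == 0 else f"log-offset({self.log_offset:g})")
        if self.diff_order:
            parts.append(f"differenced({self.diff_order})")
        return "+".join(parts) if parts else "raw"


@dataclass
class TimeSeriesDataset:
    """Aligned monthly series with transform bookkeeping.

    Invariants: all series share the (strictly increasing, gap-free)
    monthly index; no missing values survive alignment.
    """

    frame: pd.DataFrame  # PeriodIndex (freq='M') x variables
    transforms: dict[str, TransformState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.frame.index, pd.PeriodIndex):
            self.frame = self.frame.copy()
            self.frame.index = pd.PeriodIndex(self.frame.index, freq="M")
        for v in self.frame.columns:
            self.transforms.setdefault(v, TransformState())
        if self.frame.isna().any().any():
            raise ValueError("dataset contains missing values after alignment")
        idx = self.frame.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique()
            raise ValueError(f"duplicate months in index: {list(map(str, dups))}")
        if not idx.is_monotonic_increasing:
            raise ValueError("time index must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def variables(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def time_index(self) -> pd.PeriodIndex:
        return self.frame.index

    def series(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def with_frame(self, frame: pd.DataFrame, transforms=None) -> "TimeSeriesDataset":
        return TimeSeriesDataset(frame=frame, transforms=dict(transforms or self.transforms))


def load_timeseries(
    path,
    schema: dict[str, str] | None = None,
    window: tuple[str, str] | None = DEFAULT_WINDOW,
    date_column: str = "date",
) -> TimeSeriesDataset:
    """Read a monthly CSV into a :class:`TimeSeriesDataset`.

    Parameters
    ----------
    path : CSV with an ISO ``YYYY-MM`` date column plus numeric columns.
    schema : optional map ``canonical_name -> file_column`` for renamed
        headers; unmapped canonical names fall back to identical headers.
    window : inclusive ``(start, end)`` month strings; rows outside are
        dropped (pass ``None`` to keep everything).

    Rows with any missing mapped value are dropped (and logged); duplicate
    months and non-numeric cells are errors.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"empty table: {path}")
    schema = dict(schema or {})
    if date_column in raw.columns:
        date_col = date_column
    elif "date" in schema:
        date_col = schema.pop("date")
    else:
        raise ValueError(f"no date column {date_column!r} in {path}")

    try:
        months = pd.PeriodIndex(raw[date_col].astype(str), freq="M")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"date column {date_col!r} not parseable as year-month: {exc}") from exc

    colmap = {}
    for canon in CANONICAL_VARIABLES:
        src = schema.get(canon, canon)
        if src in raw.columns:
            colmap[canon] = src
    # also accept extra canonical-named schema entries beyond the defaults
    for canon, src in schema.items():
        if canon not in colmap and src in raw.columns:
            colmap[canon] = src
    if not colmap:
        raise ValueError("no recognised variable columns found")

    data = {}
    for canon, src in colmap.items():
        col = pd.to_numeric(raw[src], errors="coerce")
        bad = col.isna() & raw[src].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in column {src!r} at row {row} "
                f"(value {raw[src].iloc[row]!r})"
            )
        data[canon] = col

    frame = pd.DataFrame(data)
    frame.index = months
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique()
        raise ValueError(f"duplicate months: {list(map(str, dups))}")

    n0 = len(frame)
    missing = frame.isna().any(axis=1)
    if missing.any():
        logger.info("dropping %d rows with missing values", int(missing.sum()))
        frame = frame.loc[~missing]
    if window is not None:
        lo, hi = pd.Period(window[0], "M"), pd.Period(window[1], "M")
        outside = (frame.index < lo) | (frame.index > hi)
        if outside.any():
            logger.info("dropping %d rows outside window %s..%s", int(outside.sum()), lo, hi)
            frame = frame.loc[~outside]
    if frame.empty:
        raise ValueError("no rows remain after alignment")
    logger.info("loaded %d of %d rows from %s", len(frame), n0, path)
    frame = frame.sort_index()
    return TimeSeriesDataset(frame=frame)


def write_timeseries(ds: TimeSeriesDataset, path) -> None:
    """Write the dataset back out in the same CSV dialect (ISO YYYY-MM)."""
    out = ds.frame.copy()
    out.insert(0, "date", out.index.astype(str))
    out.to_csv(path, index=False, float_format="%.17g")


def log_transform(
    ds: TimeSeriesDataset,
    offsets: dict[str, float] | None = None,
    variables: list[str] | None = None,
) -> TimeSeriesDataset:
    """Apply natural logs (with per-variable nonnegative offsets).

    By default the zero-inflated fire variables (`area_burned`, `cem`)
    receive offset +1 so the no-fire winter months map to ln(1)=0; all
    other variables are logged without offset.  A nonpositive value with
    zero offset is an error naming the offending months.
    """
    offsets = dict(offsets or {})
    variables = variables if variables is not None else ds.variables
    frame = ds.frame.copy()
    transforms = dict(ds.transforms)
    for v in variables:
        st = transforms[v]
        if st.log:
            raise ValueError(f"variable {v!r} is already log-transformed")
        off = offsets.get(v, 1.0 if v in ZERO_INFLATED_VARIABLES else 0.0)
        if off < 0:
            raise ValueError(f"offset for {v!r} must be nonnegative")
        shifted = frame[v] + off
        if (shifted <= 0).any():
            months = frame.index[shifted <= 0]
            raise ValueError(
                f"log undefined for {v!r} with offset {off:g} in months: "
                f"{', '.join(map(str, months[:12]))}"
            )
        frame[v] = np.log(shifted.to_numpy(dtype=float))
        transforms[v] = replace(st, log=True, log_offset=off)
    return TimeSeriesDataset(frame=frame, transforms=transforms)


def drop_non_fire_season(ds: TimeSeriesDataset, months=(1, 11, 12)) -> TimeSeriesDataset:
    """Alternative to the log offset: drop winter (no-fire) months."""
    keep = ~ds.frame.index.month.isin(months)
    return TimeSeriesDataset(frame=ds.frame.loc[keep].copy(), transforms=dict(ds.transforms))


def difference(series: np.ndarray, order: int = 1) -> np.ndarray:
    """First or second difference; output is shorter by ``order``."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    x = np.asarray(series, dtype=float)
    if x.size <= order:
        raise ValueError(f"series of length {x.size} too short for order-{order} difference")
    return np.diff(x, n=order)
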