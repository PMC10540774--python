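"""Antecedent-discharge covariates for concentration rating models.

Every predictor used by the load and estuary models is assembled here from a
daily discharge record: decimal date, day of year, ``log(1+Q)``, a discounted
(exponentially weighted) moving average of transformed flow, long- and
short-term flow anomalies, and 20-day cumulative flow windows.

All flow-based covariates operate on a monotone transform of discharge;
``log1p`` is the default so that zero-flow days remain defined.  Plain ``log``
with a configurable offset is available for records with no zero-flow days.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import RangeError, ValidationError

__all__ = [
    "DischargeSeries",
    "AnomalyWindowSpec",
    "decimal_date",
    "discounted_moving_average",
    "long_term_flow_anomaly",
    "short_term_flow_anomaly",
    "cumulative_window",
    "build_covariates",
]


_TRANSFORMS = {
    "log1p": np.log1p,
    "log": np.log,
}


def _transform(values: np.ndarray, name: str, offset: float = 0.0) -> np.ndarray:
    if name not in _TRANSFORMS:
        raise ValidationError(f"unknown flow transform {name!r}; use 'log1p' or 'log'")
    if name == "log":
        return np.log(np.asarray(values, dtype=float) + offset)
    return np.log1p(np.asarray(values, dtype=float))


@dataclass
class DischargeSeries:
    """A gap-free daily mean discharge record for one gauge.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing calendar dates with a one-day step.
    flows : numpy.ndarray
        Mean daily discharge in cfs, one non-negative value per date.
    gauge_id : str
        Identifier of the gauge (free text).
    """

    dates: pd.DatetimeIndex
    flows: np.ndarray
    gauge_id: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.flows = np.asarray(self.flows, dtype=float)
        if len(self.dates) != len(self.flows):
            raise ValidationError("dates and flows must have equal length")
        if len(self.dates) == 0:
            raise ValidationError("empty discharge series")
        deltas = np.diff(self.dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            missing = self._missing_dates()
            raise ValidationError(
                f"discharge record has gaps; missing dates: {missing[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        if np.any(~np.isfinite(self.flows)) or np.any(self.flows < 0):
            raise ValidationError("flows must be finite and non-negative")

    def _missing_dates(self) -> list[str]:
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        return [d.strftime("%Y-%m-%d") for d in full.difference(self.dates)]

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "flow_cfs": self.flows})

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        date_col: str = "date",
        flow_col: str = "flow_cfs",
        gauge_id: str = "",
    ) -> "DischargeSeries":
        return cls(
            dates=pd.DatetimeIndex(pd.to_datetime(frame[date_col])),
            flows=frame[flow_col].to_numpy(dtype=float),
            gauge_id=gauge_id,
        )

    def index_of(self, date) -> int:
        date = pd.Timestamp(date)
        idx = (date - self.dates[0]).days
        if idx < 0 or idx >= len(self) or self.dates[idx] != date:
            raise RangeError(f"date {date.date()} outside discharge record")
        return int(idx)

    def flow_on(self, dates) -> np.ndarray:
        """Flows on the requested dates (all must be inside the record)."""
        idx = np.array([self.index_of(d) for d in pd.DatetimeIndex(dates)])
        return self.flows[idx]


def combine(a: DischargeSeries, b: DischargeSeries, gauge_id: str = "combined") -> DischargeSeries:
    """Sum two gauge records over their overlapping date span."""
    start = max(a.dates[0], b.dates[0])
    end = min(a.dates[-1], b.dates[-1])
    if start > end:
        raise RangeError("discharge records do not overlap")
    ia, ib = a.index_of(start), b.index_of(start)
    n = (end - start).days + 1
    return DischargeSeries(
        dates=pd.date_range(start, end, freq="D"),
        flows=a.flows[ia : ia + n] + b.flows[ib : ib + n],
        gauge_id=gauge_id,
    )


@dataclass
class AnomalyWindowSpec:
    """Window convention for the flow-anomaly covariate.

    ``ltfa`` contrasts mean transformed flow over the 365 days ending at (and
    including) day *t* with the mean over the entire record.  ``stfa``
    contrasts day *t* itself with the mean over the 30 days ending at *t* - 1
    (the current day is excluded so the contrast is clean).
    """

    kind: str = "ltfa"
    long_window: int = 365
    short_window: int = 30
    transform: str = "log1p"
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ltfa", "stfa"):
            raise ValidationError(f"anomaly kind must be 'ltfa' or 'stfa', got {self.kind!r}")
        if self.long_window <= 0 or self.short_window <= 0:
            raise ValidationError("anomaly windows must be positive")


def decimal_date(date):
    """Calendar date as decimal years: ``year + (day_of_year - 1) / days_in_year``.

    Jan 1 maps exactly onto the integer year; the divisor is the actual length
    of that year (365 or 366), so the mapping is continuous and monotone.
    Accepts a single date or any datetime array-like; returns float or ndarray.
    """
    if isinstance(date, (pd.Timestamp, _dt.date, _dt.datetime, str)):
        ts = pd.Timestamp(date)
        year_len = 366 if ts.is_leap_year else 365
        return ts.year + (ts.dayofyear - 1) / year_len
    idx = pd.DatetimeIndex(pd.to_datetime(date))
    year_len = np.where(idx.is_leap_year, 366, 365)
    return idx.year.to_numpy() + (idx.dayofyear.to_numpy() - 1) / year_len


def discounted_moving_average(values, d: float) -> np.ndarray:
    """Discounted moving average of a daily sequence from the record start.

    ``ma(t) = (x_t + d x_{t-1} + ... + d^{t-1} x_1) / (1 + d + ... + d^{t-1})``

    With ``d = 0`` this is the daily value itself; with ``d = 1`` it is the
    running mean of the record to date.  Evaluated by streaming recursion
    (a pair of first-order IIR filters), numerically equivalent to the direct
    weighted sum.
    """
    if not (0.0 <= d <= 1.0):
        raise ValidationError(f"discount factor d must lie in [0, 1], got {d}")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("empty sequence")
    num = lfilter([1.0], [1.0, -d], x)
    den = lfilter([1.0], [1.0, -d], np.ones_like(x))
    return num / den


def _trailing_mean(x: np.ndarray, window: int, include_current: bool) -> np.ndarray:
    """Mean over the trailing window at each position, truncated at the start."""
    s = pd.Series(x)
    if include_current:
        return s.rolling(window, min_periods=1).mean().to_numpy()
    shifted = s.shift(1)
    out = shifted.rolling(window, min_periods=1).mean().to_numpy()
    out[0] = x[0]  # no history on the first day; contrast defined as zero
    return out


def long_term_flow_anomaly(
    series: DischargeSeries,
    t=None,
    spec: AnomalyWindowSpec | None = None,
):
    """Long-term flow anomaly: trailing-year mean minus whole-record mean.

    Both means are of transformed (default ``log1p``) flow.  Days with fewer
    than a full year of history are computed over the available history; the
    vector form returns them alongside a warm-up flag, the scalar form (with
    ``t`` given) returns only the value.
    """
    spec = spec or AnomalyWindowSpec(kind="ltfa")
    x = _transform(series.flows, spec.transform, spec.log_offset)
    trail = _trailing_mean(x, spec.long_window, include_current=True)
    fa = trail - x.mean()
    warmup = np.arange(len(x)) < spec.long_window - 1
    if t is not None:
        return float(fa[series.index_of(t)])
    return fa, warmup


def short_term_flow_anomaly(
    series: DischargeSeries,
    t=None,
    spec: AnomalyWindowSpec | None = None,
):
    """Short-term flow anomaly: current day versus the preceding month.

    Transformed flow on day *t* minus the mean of transformed flow over the
    30 days before *t* (exclusive).  The first day of record has no history
    and is defined as zero, flagged as warm-up.
    """
    spec = spec or AnomalyWindowSpec(kind="stfa")
    x = _transform(series.flows, spec.transform, spec.log_offset)
    trail = _trailing_mean(x, spec.short_window, include_current=False)
    fa = x - trail
    warmup = np.arange(len(x)) < spec.short_window
    if t is not None:
        return float(fa[series.index_of(t)])
    return fa, warmup


def cumulative_window(values, t=None, window: int = 20, dates: pd.DatetimeIndex | None = None):
    """Sum of the trailing ``window`` daily values ending at and including *t*.

    Vector form (``t is None``) returns NaN for the first ``window - 1`` days;
    scalar form raises :class:`RangeError` when history is insufficient.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if isinstance(values, DischargeSeries):
        dates = values.dates
        x = values.flows.astype(float)
    else:
        x = np.asarray(values, dtype=float)
    out = pd.Series(x).rolling(window).sum().to_numpy()
    if t is None:
        return out
    if dates is None:
        idx = int(t)
    else:
        idx = int((pd.Timestamp(t) - dates[0]).days)
        if idx < 0 or idx >= len(x):
            raise RangeError(f"date {t} outside record")
    if idx < window - 1:
        raise RangeError(f"fewer than {window} days of history before position {idx}")
    return float(out[idx])


def build_covariates(
    series: DischargeSeries,
    spec: AnomalyWindowSpec | str = "ltfa",
    d: float = 0.95,
    lag_window: int = 20,
) -> pd.DataFrame:
    """Per-day design table of every rating-model predictor.

    Returns a DataFrame with one row per record day and columns ``date``,
    ``ddate``, ``yday``, ``log1pQ``, ``ma``, ``fa``, ``cum20_Q``, ``flow_cfs``
    and ``warmup``.  ``ma`` is the discounted moving average of transformed
    flow with discount ``d``; ``fa`` follows the window convention in
    ``spec``.  The first year of record is flagged as warm-up (moving average
    and anomaly windows are still spinning up) and is excluded from model
    fitting by default downstream.
    """
    if isinstance(spec, str):
        spec = AnomalyWindowSpec(kind=spec)
    x = _transform(series.flows, spec.transform, spec.log_offset)
    ma = discounted_moving_average(x, d)
    if spec.kind == "ltfa":
        fa, _ = long_term_flow_anomaly(series, spec=spec)
    else:
        fa, _ = short_term_flow_anomaly(series, spec=spec)
    n = len(series)
    warmup = np.arange(n) < spec.long_window
    return pd.DataFrame(
        {
            "date": series.dates,
            "ddate": decimal_date(series.dates),
            "yday": series.dates.dayofyear.to_numpy(),
            "log1pQ": np.log1p(series.flows),
            "ma": ma,
            "fa": fa,
            "cum20_Q": cumulative_window(series.flows, window=lag_window),
            "flow_cfs": series.flows,
            "warmup": warmup,
        }
    )
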