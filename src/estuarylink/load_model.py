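"""Concentration rating models and daily / annual / flow-normalized loads.

The rating model relates sparse discrete nutrient concentrations to a long
term trend (decimal date), season (day of year), transformed discharge
``log(1+Q)``, a discounted moving average of transformed flow, and a flow
anomaly, through a Gaussian additive model with a log link:

    log E[y] = a + f1(ddate) + f2(yday) + f3(log(1+Q)) + f4(ma) + f5(fa)

Fitted models predict a concentration for every day of the discharge record;
daily load is predicted concentration times discharge (cfs . mg/L -> kg/day).
Flow normalization removes discharge-driven variability by averaging each
day's prediction over every flow condition historically observed on that
calendar day.  Uncertainty on annual quantities comes from simulating the
multivariate-normal coefficient posterior of the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._gam import FittedAdditiveModel, ModelSpec, SmoothTerm, fit_gam
from .antecedent_covariates import DischargeSeries
from .errors import FitError, RangeError, ValidationError

__all__ = [
    "SampleSeries",
    "LoadSeries",
    "ModelSpec",
    "SmoothTerm",
    "FittedAdditiveModel",
    "CFS_MGL_TO_KG_PER_DAY",
    "default_rating_spec",
    "substitute_censored",
    "fit_concentration_model",
    "predict_daily_concentration",
    "concentration_to_load",
    "estimate_daily_loads",
    "lake_outlet_daily_load",
    "flow_normalize",
    "posterior_annual_intervals",
    "aggregate_annual",
]

#: kg/day delivered by 1 mg/L at 1 cfs: 28.316846592 L/ft^3 x 86400 s/day x 1e-6 kg/mg
CFS_MGL_TO_KG_PER_DAY = 28.316846592 * 86400 * 1e-6

_PARAMETERS = ("TP", "NO3", "NOx", "TKN", "chlorophyll_a", "DO")


@dataclass
class SampleSeries:
    """Discrete water-quality samples with left-censoring metadata.

    ``data`` holds one row per sample: ``date``, ``value`` (reported
    concentration; for censored rows this is the detection limit),
    ``censored`` (bool) and ``detection_limit`` (NaN when not applicable).
    ``truth`` optionally carries the generating functions of synthetic data
    so recovery tests can evaluate the true concentration on any day.
    """

    station_id: str
    parameter: str
    data: pd.DataFrame
    units: str = "mg/L"
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMETERS:
            raise ValidationError(f"unknown parameter {self.parameter!r}; one of {_PARAMETERS}")
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"])
        if "censored" not in df.columns:
            df["censored"] = False
        if "detection_limit" not in df.columns:
            df["detection_limit"] = np.nan
        df["censored"] = df["censored"].astype(bool)
        if (df["value"] <= 0).any():
            raise ValidationError("sample values must be positive")
        cens = df["censored"]
        if cens.any():
            if df.loc[cens, "detection_limit"].isna().any():
                raise ValidationError("censored samples must carry a detection limit")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class LoadSeries:
    """Daily and annual delivered and flow-normalized loads.

    ``daily`` / ``flow_normalized_daily``: columns ``date``, ``load_kg``
    (kg/day) plus optional ``lower90``/``upper90``.  ``annual`` /
    ``flow_normalized_annual``: columns ``year``, ``load_kg`` plus optional
    ``sd``, ``lower90``, ``upper90``.
    """

    daily: pd.DataFrame
    annual: pd.DataFrame | None = None
    flow_normalized_daily: pd.DataFrame | None = None
    flow_normalized_annual: pd.DataFrame | None = None
    parameter: str = ""
    station_id: str = ""


def default_rating_spec(
    smoothness_selection: str = "REML",
    trend_dim: int = 10,
    season_dim: int = 8,
    flow_dim: int = 10,
) -> ModelSpec:
    """The standard five-term rating model specification.

    Trend uses a curvature penalty; season is cyclic so day 1 joins day 366;
    the three flow-derived terms carry first-order penalties that shrink
    toward flat functions, restraining extrapolation at unsampled high flows.
    """
    return ModelSpec(
        response_family="gaussian_log_link",
        smoothness_selection=smoothness_selection,
        terms=[
            SmoothTerm("ddate", "thin_plate", trend_dim, penalty_order=2),
            SmoothTerm("yday", "cyclic_cubic", season_dim),
            SmoothTerm("log1pQ", "thin_plate", flow_dim, penalty_order=1),
            SmoothTerm("ma", "thin_plate", flow_dim, penalty_order=1),
            SmoothTerm("fa", "thin_plate", flow_dim, penalty_order=1),
        ],
    )


def substitute_censored(samples: SampleSeries) -> SampleSeries:
    """Replace censored values by one-half the detection limit.

    Censoring flags are preserved for audit; uncensored rows pass through
    unchanged.
    """
    df = samples.data.copy()
    cens = df["censored"].to_numpy()
    if cens.any() and df.loc[cens, "detection_limit"].isna().any():
        raise ValidationError("censored record missing a detection limit")
    df.loc[cens, "value"] = 0.5 * df.loc[cens, "detection_limit"]
    return replace(samples, data=df)


def _join_samples_to_covariates(
    samples: SampleSeries, covariates: pd.DataFrame, include_warmup: bool
) -> pd.DataFrame:
    cov = covariates if include_warmup else covariates[~covariates["warmup"]]
    merged = samples.data.merge(cov, on="date", how="inner")
    return merged


def fit_concentration_model(
    samples: SampleSeries,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    min_samples: int = 40,
    include_warmup: bool = False,
    optimizer_maxfev: int | None = None,
) -> FittedAdditiveModel:
    """Fit the concentration rating model to discrete samples.

    ``covariates`` is the full per-day design table from
    :func:`~estuarylink.antecedent_covariates.build_covariates`; sample dates
    are matched to its rows (warm-up days dropped unless ``include_warmup``).
    Predictions on days whose flow covariates fall outside the calibrated
    range are held flat at the range boundary.  Censored values should be
    substituted beforehand.
    """
    spec = spec or default_rating_spec()
    merged = _join_samples_to_covariates(samples, covariates, include_warmup)
    n = len(merged)
    if n < min_samples:
        raise FitError(
            f"only {n} usable samples after matching covariates; need >= {min_samples}"
        )
    return fit_gam(
        merged["value"].to_numpy(dtype=float),
        merged,
        spec,
        optimizer_maxfev=optimizer_maxfev,
    )


def predict_daily_concentration(
    model: FittedAdditiveModel, covariates: pd.DataFrame
) -> pd.Series:
    """Predicted concentration (response scale) per covariate row."""
    conc = model.predict_response(covariates)
    return pd.Series(conc, index=pd.DatetimeIndex(covariates["date"]), name="conc")


def concentration_to_load(conc, flow_cfs):
    """Convert concentration (mg/L) and discharge (cfs) to load (kg/day)."""
    conc = np.asarray(conc, dtype=float)
    flow = np.asarray(flow_cfs, dtype=float)
    if np.any(conc < 0) or np.any(flow < 0):
        raise ValidationError("concentration and flow must be non-negative")
    out = conc * flow * CFS_MGL_TO_KG_PER_DAY
    return float(out) if out.ndim == 0 else out


def estimate_daily_loads(
    model: FittedAdditiveModel,
    covariates: pd.DataFrame,
    discharge: DischargeSeries,
) -> pd.DataFrame:
    """Daily delivered load: predicted concentration times daily discharge."""
    conc = predict_daily_concentration(model, covariates)
    flows = discharge.flow_on(covariates["date"])
    return pd.DataFrame(
        {
            "date": pd.DatetimeIndex(covariates["date"]),
            "conc_mgl": conc.to_numpy(),
            "load_kg": concentration_to_load(conc.to_numpy(), flows),
        }
    )


def lake_outlet_daily_load(
    conc_daily: pd.Series, dam_release: DischargeSeries
) -> pd.DataFrame:
    """Daily load at a reservoir outlet: outlet concentration x dam release.

    Used where rating-model covariates are built from tributary inflow while
    the mass actually delivered downstream passes through the dam.  The
    concentration series must cover exactly dates inside the release record.
    """
    dates = pd.DatetimeIndex(conc_daily.index)
    try:
        flows = dam_release.flow_on(dates)
    except RangeError as exc:
        raise RangeError(f"concentration dates not all inside release record: {exc}") from exc
    return pd.DataFrame(
        {
            "date": dates,
            "conc_mgl": conc_daily.to_numpy(),
            "load_kg": concentration_to_load(conc_daily.to_numpy(), flows),
        }
    )


_TIME_TERMS = ("ddate", "yday")


def _split_terms(model: FittedAdditiveModel):
    time_terms = [t for t in model.term_names if t in _TIME_TERMS]
    flow_terms = [t for t in model.term_names if t not in _TIME_TERMS]
    return time_terms, flow_terms


def _yday_key(dates: pd.DatetimeIndex) -> np.ndarray:
    """Calendar-day grouping key; Feb 29 pools with Feb 28."""
    month = dates.month.to_numpy()
    day = dates.day.to_numpy()
    day = np.where((month == 2) & (day == 29), 28, day)
    return month * 100 + day


def flow_normalize(
    model: FittedAdditiveModel,
    covariates: pd.DataFrame,
    load_flow: DischargeSeries | None = None,
    normalize_load_flow: bool = True,
) -> pd.DataFrame:
    """Flow-normalized daily concentration and load.

    For each day *t*, the flow-based covariate tuples observed on the same
    calendar day in every year of the record are substituted in turn (with the
    trend and season terms held at day *t*), and the predictions are averaged.
    By default each historical tuple's own discharge also multiplies its
    predicted concentration, so the load is normalized over the full joint
    flow distribution; ``normalize_load_flow=False`` instead multiplies the
    flow-normalized concentration by day *t*'s own discharge.

    ``load_flow`` supplies the discharge used for the mass conversion when it
    differs from the series behind the covariates (reservoir outlets); it
    defaults to the ``flow_cfs`` column of ``covariates``.
    """
    dates = pd.DatetimeIndex(covariates["date"])
    n = len(covariates)
    time_terms, flow_terms = _split_terms(model)
    eta_time = model.coefficients[0] + model.partial_linear(covariates, time_terms)
    eta_flow = model.partial_linear(covariates, flow_terms)
    if load_flow is not None:
        flows = load_flow.flow_on(dates)
    else:
        flows = covariates["flow_cfs"].to_numpy(dtype=float)

    keys = _yday_key(dates)
    fn_conc = np.empty(n)
    fn_load = np.empty(n)
    frame = pd.DataFrame({"key": keys, "ef": eta_flow, "q": flows})
    by_key_conc = frame.groupby("key")["ef"].apply(lambda s: np.exp(s.to_numpy()).mean())
    by_key_load = frame.groupby("key").apply(
        lambda g: float(np.mean(np.exp(g["ef"].to_numpy()) * g["q"].to_numpy())),
        include_groups=False,
    )
    fn_conc = np.exp(eta_time) * by_key_conc.loc[keys].to_numpy()
    if normalize_load_flow:
        fn_load = np.exp(eta_time) * by_key_load.loc[keys].to_numpy() * CFS_MGL_TO_KG_PER_DAY
    else:
        fn_load = fn_conc * flows * CFS_MGL_TO_KG_PER_DAY
    return pd.DataFrame({"date": dates, "fn_conc_mgl": fn_conc, "fn_load_kg": fn_load})


def aggregate_annual(daily: pd.DataFrame, column: str = "load_kg") -> pd.DataFrame:
    """Sum a daily series to calendar-year totals, keeping complete years only.

    Partial years (fewer days than the calendar year holds) are excluded and
    listed in the result's ``attrs['partial_years']``.
    """
    dates = pd.DatetimeIndex(daily["date"])
    years = dates.year
    out = (
        pd.DataFrame({"year": years, column: daily[column].to_numpy()})
        .groupby("year", as_index=False)
        .agg(total=(column, "sum"), n_days=(column, "size"))
    )
    year_len = np.where(
        pd.to_datetime(out["year"].astype(str) + "-12-31").dt.dayofyear == 366, 366, 365
    )
    complete = out["n_days"].to_numpy() == year_len
    result = out.loc[complete, ["year", "total"]].rename(columns={"total": column})
    result = result.reset_index(drop=True)
    result.attrs["partial_years"] = out.loc[~complete, "year"].tolist()
    return result


def posterior_annual_intervals(
    model: FittedAdditiveModel,
    covariates: pd.DataFrame,
    target: str = "annual_load",
    load_flow: DischargeSeries | None = None,
    n_draws: int = 1000,
    level: float = 0.90,
    seed: int | None = None,
) -> pd.DataFrame:
    """Credible intervals on annual (or flow-normalized annual) loads.

    Coefficient vectors are drawn from the multivariate-normal posterior of
    the fitted model; the target is recomputed per draw and summarized by its
    posterior mean, standard deviation and central ``level`` interval.  The
    plug-in estimate from the point coefficients is reported alongside.

    ``target`` is ``"annual_load"`` or ``"fn_annual_load"``.
    """
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    if target not in ("annual_load", "fn_annual_load"):
        raise ValidationError(f"unknown target {target!r}")
    dates = pd.DatetimeIndex(covariates["date"])
    if load_flow is not None:
        flows = load_flow.flow_on(dates)
    else:
        flows = covariates["flow_cfs"].to_numpy(dtype=float)

    X = model.design_matrix(covariates)
    draws = model.posterior_coefficient_draws(n_draws, seed=seed)  # (n_draws, p)

    def _annual_sum(daily_matrix: np.ndarray) -> pd.DataFrame:
        frame = pd.DataFrame(daily_matrix)
        frame["year"] = dates.year
        agg = frame.groupby("year").sum()
        return agg

    if target == "annual_load":
        eta = X @ draws.T  # (n_days, n_draws)
        daily = np.exp(eta) * (flows * CFS_MGL_TO_KG_PER_DAY)[:, None]
        plug_daily = np.exp(X @ model.coefficients) * flows * CFS_MGL_TO_KG_PER_DAY
    else:
        time_terms, flow_terms = _split_terms(model)
        cols_time = [0] + [
            j
            for name in time_terms
            for j in range(model._term_slices[name].start, model._term_slices[name].stop)
        ]
        cols_flow = [
            j
            for name in flow_terms
            for j in range(model._term_slices[name].start, model._term_slices[name].stop)
        ]
        eta_t = X[:, cols_time] @ draws[:, cols_time].T  # (n_days, n_draws)
        eta_f = X[:, cols_flow] @ draws[:, cols_flow].T
        keys = _yday_key(dates)
        qexp = np.exp(eta_f) * flows[:, None]
        key_frame = pd.DataFrame(qexp)
        key_frame["key"] = keys
        group_mean = key_frame.groupby("key").mean()  # (n_keys, n_draws)
        daily = np.exp(eta_t) * group_mean.loc[keys].to_numpy() * CFS_MGL_TO_KG_PER_DAY
        # plug-in
        pt = X[:, cols_time] @ model.coefficients[cols_time]
        pf = X[:, cols_flow] @ model.coefficients[cols_flow]
        pqe = pd.DataFrame({"key": keys, "v": np.exp(pf) * flows})
        gm = pqe.groupby("key")["v"].mean()
        plug_daily = np.exp(pt) * gm.loc[keys].to_numpy() * CFS_MGL_TO_KG_PER_DAY

    annual = _annual_sum(daily)
    plug = pd.DataFrame({"v": plug_daily})
    plug["year"] = dates.year
    plug_annual = plug.groupby("year")["v"].sum()

    # keep complete calendar years only, consistent with aggregate_annual
    counts = pd.Series(1, index=dates).groupby(dates.year).sum()
    year_len = pd.Series(
        np.where(pd.to_datetime(counts.index.astype(str) + "-12-31").dayofyear == 366, 366, 365),
        index=counts.index,
    )
    complete_years = counts.index[counts == year_len]
    annual = annual.loc[annual.index.isin(complete_years)]

    alpha = (1.0 - level) / 2.0
    vals = annual.to_numpy()
    out = pd.DataFrame(
        {
            "year": annual.index.to_numpy(),
            "load_kg": plug_annual.loc[annual.index].to_numpy(),
            "posterior_mean": vals.mean(axis=1),
            "sd": vals.std(axis=1, ddof=1),
            "lower90": np.quantile(vals, alpha, axis=1),
            "upper90": np.quantile(vals, 1.0 - alpha, axis=1),
        }
    )
    return out.reset_index(drop=True)
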