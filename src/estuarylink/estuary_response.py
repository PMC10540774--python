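"""Estuary water-quality response to inflow and watershed nutrient loads.

Stage two of the pipeline asks whether seasonally adjusted freshwater inflow,
and flow-normalized nutrient loads beyond it, explain variation in estuary
constituents.  For each constituent a nested set of Gamma (log link) additive
models is fit on identical rows:

    Temporal:    log E[y] = a + f1(ddate) + f2(yday)
    Flow:        ... + f3(adjusted 20-day inflow)
    Flow+Load:   ... + f4(20-day flow-normalized load)  [one or two smooths]

and the set is compared with small-sample-corrected AIC and Akaike weights
(model probabilities).  Because 20-day inflow and loads are tightly coupled
to season and to each other, inflow enters as the residual of a seasonal fit
to log cumulative inflow, and loads enter flow-normalized, so the load smooth
captures management-driven rather than runoff-driven variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gam import FittedAdditiveModel, ModelSpec, SmoothTerm, fit_gam
from .antecedent_covariates import (
    DischargeSeries,
    combine,
    cumulative_window,
    decimal_date,
)
from .errors import ValidationError

__all__ = [
    "ModelComparison",
    "MODEL_SETS",
    "seasonally_adjust_inflow",
    "assemble_design",
    "estuary_model_spec",
    "fit_estuary_model",
    "aicc",
    "model_probabilities",
    "compare_models",
]

#: nested model sets per constituent: label -> smooth-term covariate names.
#: TKN has no load model (no organic-nitrogen load series exists); TP and NOx
#: include only their matching load; chlorophyll-a and DO include both.
MODEL_SETS = {
    "TP": [
        ("Temporal", ["ddate", "yday"]),
        ("Flow", ["ddate", "yday", "adj_cum20_inflow"]),
        ("Flow+Load", ["ddate", "yday", "adj_cum20_inflow", "cum20_fn_load_TP"]),
    ],
    "NOx": [
        ("Temporal", ["ddate", "yday"]),
        ("Flow", ["ddate", "yday", "adj_cum20_inflow"]),
        ("Flow+Load", ["ddate", "yday", "adj_cum20_inflow", "cum20_fn_load_NO3"]),
    ],
    "chlorophyll_a": [
        ("Temporal", ["ddate", "yday"]),
        ("Flow", ["ddate", "yday", "adj_cum20_inflow"]),
        (
            "Flow+Load",
            ["ddate", "yday", "adj_cum20_inflow", "cum20_fn_load_TP", "cum20_fn_load_NO3"],
        ),
    ],
    "DO": [
        ("Temporal", ["ddate", "yday"]),
        ("Flow", ["ddate", "yday", "adj_cum20_inflow"]),
        (
            "Flow+Load",
            ["ddate", "yday", "adj_cum20_inflow", "cum20_fn_load_TP", "cum20_fn_load_NO3"],
        ),
    ],
    "TKN": [
        ("Temporal", ["ddate", "yday"]),
        ("Flow", ["ddate", "yday", "adj_cum20_inflow"]),
    ],
}


@dataclass
class ModelComparison:
    """Ordered comparison of a nested model set for one constituent."""

    models: pd.DataFrame  # columns: label, aicc, weight, edof
    best_label: str
    parameter: str = ""

    def __post_init__(self) -> None:
        w = self.models["weight"].to_numpy()
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("model probabilities must sum to 1")


def seasonally_adjust_inflow(
    cum_inflow: pd.Series, basis_dim: int = 8, smoothness_selection: str = "REML"
) -> pd.Series:
    """Residuals of a cyclic seasonal fit to log-transformed cumulative inflow.

    ``cum_inflow`` maps date to 20-day cumulative inflow (cfs-days).  The
    series is log1p transformed (cumulative inflow can touch zero on fully
    dry windows), regressed on day of year with a cyclic cubic smooth, and
    the residuals returned: a mean-zero series with the seasonal cycle
    removed, isolating anomalous wetness.
    """
    cum_inflow = cum_inflow.dropna()
    if len(cum_inflow) < 366:
        raise ValidationError("need at least one full year of cumulative inflow")
    dates = pd.DatetimeIndex(cum_inflow.index)
    y = np.log1p(cum_inflow.to_numpy(dtype=float))
    table = pd.DataFrame({"yday": dates.dayofyear.to_numpy(dtype=float)})
    spec = ModelSpec(
        response_family="gaussian_identity",
        smoothness_selection=smoothness_selection,
        terms=[SmoothTerm("yday", "cyclic_cubic", basis_dim)],
    )
    model = fit_gam(y, table, spec)
    resid = y - model.predict_response(table)
    return pd.Series(resid, index=dates, name="adj_cum20_inflow")


def assemble_design(
    estuary_samples,
    inflow,
    fn_loads: dict | None = None,
    lag_window: int = 20,
) -> pd.DataFrame:
    """Per-sample design rows for the estuary model set.

    Parameters
    ----------
    estuary_samples : SampleSeries
        Constituent samples (positive values; Gamma support).
    inflow : DischargeSeries or pair of DischargeSeries
        Combined freshwater inflow; a pair is summed over its common span.
    fn_loads : dict, optional
        ``{"NO3": frame, "TP": frame}`` daily flow-normalized load frames
        (columns ``date`` and ``fn_load_kg`` or ``load_kg``).

    Rows whose lag window is not fully covered are dropped; the count is
    recorded in ``attrs['n_dropped']``.
    """
    if isinstance(inflow, (tuple, list)):
        if len(inflow) != 2:
            raise ValidationError("inflow pair must contain exactly two series")
        inflow = combine(inflow[0], inflow[1])

    cum = pd.Series(
        cumulative_window(inflow.flows, window=lag_window), index=inflow.dates
    )
    adj = seasonally_adjust_inflow(cum.dropna())

    frame = estuary_samples.data.copy()
    dates = pd.DatetimeIndex(frame["date"])
    design = pd.DataFrame(
        {
            "date": dates,
            "ddate": decimal_date(dates),
            "yday": dates.dayofyear.to_numpy(dtype=float),
            "response": frame["value"].to_numpy(dtype=float),
        }
    )
    design["adj_cum20_inflow"] = adj.reindex(dates).to_numpy()

    for param, daily in (fn_loads or {}).items():
        col = "fn_load_kg" if "fn_load_kg" in daily.columns else "load_kg"
        cum_load = pd.Series(
            cumulative_window(daily[col].to_numpy(), window=lag_window),
            index=pd.DatetimeIndex(daily["date"]),
        )
        design[f"cum20_fn_load_{param}"] = cum_load.reindex(dates).to_numpy()

    covariate_cols = [c for c in design.columns if c not in ("date", "response")]
    complete = design[covariate_cols].notna().all(axis=1)
    out = design.loc[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~complete).sum())
    if (out["response"] <= 0).any():
        raise ValidationError("estuary responses must be positive (Gamma support)")
    return out


def estuary_model_spec(
    term_names: list,
    smoothness_selection: str = "REML",
    trend_dim: int = 10,
    season_dim: int = 8,
    covariate_dim: int = 10,
) -> ModelSpec:
    terms = []
    for name in term_names:
        if name == "yday":
            terms.append(SmoothTerm("yday", "cyclic_cubic", season_dim))
        elif name == "ddate":
            terms.append(SmoothTerm("ddate", "thin_plate", trend_dim, penalty_order=2))
        else:
            terms.append(SmoothTerm(name, "thin_plate", covariate_dim, penalty_order=2))
    return ModelSpec(
        response_family="gamma_log_link",
        smoothness_selection=smoothness_selection,
        terms=terms,
    )


def fit_estuary_model(
    design: pd.DataFrame,
    formula,
    parameter: str | None = None,
    smoothness_selection: str = "REML",
    optimizer_maxfev: int | None = None,
) -> FittedAdditiveModel:
    """Fit one Gamma (log link) estuary model.

    ``formula`` is either a model label from :data:`MODEL_SETS` (requires
    ``parameter``) or an explicit list of design-column names.
    """
    if isinstance(formula, str):
        if parameter is None:
            raise ValidationError("parameter required when formula is a label")
        labels = dict(MODEL_SETS[parameter])
        if formula not in labels:
            raise ValidationError(
                f"model {formula!r} not defined for {parameter}; options {list(labels)}"
            )
        term_names = labels[formula]
    else:
        term_names = list(formula)
    missing = [c for c in term_names if c not in design.columns]
    if missing:
        raise ValidationError(f"design lacks columns {missing}")
    spec = estuary_model_spec(term_names, smoothness_selection=smoothness_selection)
    return fit_gam(
        design["response"].to_numpy(dtype=float),
        design,
        spec,
        optimizer_maxfev=optimizer_maxfev,
    )


def aicc(model: FittedAdditiveModel) -> float:
    """Small-sample-corrected AIC with k = effective dof + 1 (scale parameter).

    ``AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1)``.
    """
    k = model.effective_dof + 1.0
    n = model.n_obs
    if n - k - 1 <= 0:
        raise ValidationError(f"AICc undefined: n={n} too small for k={k:.1f}")
    aic = -2.0 * model.loglik + 2.0 * k
    return float(aic + 2.0 * k * (k + 1.0) / (n - k - 1.0))


def model_probabilities(aicc_values) -> np.ndarray:
    """Akaike weights from AICc values, computed stably via max-subtraction.

    ``w_i = exp(-(AICc_i - min AICc)/2) / sum_j exp(-(AICc_j - min AICc)/2)``.
    Infinite AICc values receive zero weight.
    """
    a = np.asarray(aicc_values, dtype=float)
    if len(a) < 2 or not np.isfinite(a).any():
        raise ValidationError("need at least two AICc values, at least one finite")
    delta = a - np.nanmin(a[np.isfinite(a)])
    with np.errstate(over="ignore"):
        raw = np.where(np.isfinite(delta), np.exp(-0.5 * delta), 0.0)
    return raw / raw.sum()


def compare_models(
    design: pd.DataFrame,
    parameter: str,
    smoothness_selection: str = "REML",
    optimizer_maxfev: int | None = None,
    tie_tol: float = 0.5,
) -> ModelComparison:
    """Fit the nested model set for one constituent and weigh the models.

    All models are fit on identical rows: rows missing any covariate used by
    any model in the set are removed first, so the information criteria are
    comparable.

    When an added smooth is penalized to (near) zero the richer model
    collapses onto the simpler one and the AICc values effectively tie; the
    flagged best model is then the simplest of the tied set (models within
    ``tie_tol`` AICc of the minimum), far below any evidential threshold for
    preferring the extra term.  All tied models keep their near-equal
    weights in the table.
    """
    if parameter not in MODEL_SETS:
        raise ValidationError(f"no model set defined for parameter {parameter!r}")
    model_set = MODEL_SETS[parameter]
    needed = sorted({c for _, cols in model_set for c in cols})
    missing = [c for c in needed if c not in design.columns]
    if missing:
        raise ValidationError(
            f"design lacks columns {missing} required by the {parameter} model set"
        )
    common = design.dropna(subset=needed).reset_index(drop=True)
    if len(common) < len(design):
        raise ValidationError(
            "rows differ across models; rebuild the design with complete covariates"
        )

    rows = []
    for label, term_names in model_set:
        model = fit_estuary_model(
            common,
            term_names,
            smoothness_selection=smoothness_selection,
            optimizer_maxfev=optimizer_maxfev,
        )
        rows.append({"label": label, "aicc": aicc(model), "edof": model.effective_dof})
    table = pd.DataFrame(rows)
    table["weight"] = model_probabilities(table["aicc"].to_numpy())
    tied = table.index[table["aicc"] - table["aicc"].min() < tie_tol]
    best = table.loc[tied[0], "label"]  # model sets are ordered simple -> complex
    return ModelComparison(models=table, best_label=str(best), parameter=parameter)
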