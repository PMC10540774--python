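"""Goodness-of-fit metrics and repeated k-fold cross-validation.

Metrics follow the conventions standard in hydrologic model evaluation:
Nash-Sutcliffe efficiency (1 = perfect, 0 = no better than the observed
mean), Pearson sample correlation, and percent bias with positive values
indicating underprediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gam import ModelSpec
from .errors import UndefinedMetricError, ValidationError
from .load_model import (
    SampleSeries,
    _join_samples_to_covariates,
    concentration_to_load,
    default_rating_spec,
    fit_concentration_model,
)

__all__ = ["CVConfig", "CVResult", "nse", "pbias", "pearson_r", "repeated_kfold_cv"]


def _check_pair(obs, sim, min_len=2):
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise ValidationError("obs and sim must have equal length")
    if len(obs) < min_len:
        raise UndefinedMetricError(f"need at least {min_len} pairs")
    return obs, sim


def nse(obs, sim) -> float:
    """Nash-Sutcliffe efficiency: ``1 - sum((obs-sim)^2) / sum((obs-mean)^2)``."""
    obs, sim = _check_pair(obs, sim)
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise UndefinedMetricError("NSE undefined for constant observations")
    return float(1.0 - np.sum((obs - sim) ** 2) / denom)


def pbias(obs, sim) -> float:
    """Percent bias: ``100 * sum(obs - sim) / sum(obs)``; positive = underprediction."""
    obs, sim = _check_pair(obs, sim, min_len=1)
    total = np.sum(obs)
    if total == 0:
        raise UndefinedMetricError("PBIAS undefined when observations sum to zero")
    return float(100.0 * np.sum(obs - sim) / total)


def pearson_r(obs, sim) -> float:
    """Pearson sample correlation coefficient."""
    obs, sim = _check_pair(obs, sim)
    if np.std(obs) == 0 or np.std(sim) == 0:
        raise UndefinedMetricError("correlation undefined for constant input")
    return float(np.corrcoef(obs, sim)[0, 1])


@dataclass
class CVConfig:
    """Repeated k-fold cross-validation settings."""

    k: int = 5
    repeats: int = 10
    seed: int = 0
    target: str = "concentration"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.target not in ("concentration", "daily_load"):
            raise ValidationError("target must be 'concentration' or 'daily_load'")


@dataclass
class CVResult:
    """Per-fold metrics, their medians, and empirical tail probabilities.

    ``per_fold`` has one row per (repeat, fold) with columns ``nse``, ``r``,
    ``pbias`` (NaN where a fold was too small or degenerate to evaluate).
    ``tail_probabilities`` adds, for each metric value, the two-sided tail
    mass ``min(F(x), 1 - F(x))`` of its own empirical distribution.
    """

    per_fold: pd.DataFrame
    medians: dict
    tail_probabilities: pd.DataFrame


def _tail_prob(values: np.ndarray) -> np.ndarray:
    finite = np.isfinite(values)
    out = np.full(len(values), np.nan)
    if finite.sum() == 0:
        return out
    x = values[finite]
    order = np.argsort(np.argsort(x))
    cdf = (order + 1) / len(x)
    out[finite] = np.minimum(cdf, 1.0 - cdf)
    return out


def repeated_kfold_cv(
    samples: SampleSeries,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    cv: CVConfig | None = None,
    min_samples: int = 30,
    optimizer_maxfev: int | None = None,
) -> CVResult:
    """Repeated k-fold cross-validation of the concentration rating model.

    For each repeat, sample dates are randomly partitioned into ``k`` folds
    (seeded); the model is refit on each k-1 fold training set and evaluated
    on the held-out fold.  Metrics are computed on the concentration scale by
    default; ``target='daily_load'`` evaluates on predicted-versus-observed
    daily loads (concentration times that day's discharge).

    Folds whose metrics are undefined (too small, constant observations) are
    reported with NaN rather than dropped silently.
    """
    spec = spec or default_rating_spec()
    cv = cv or CVConfig()
    merged = _join_samples_to_covariates(samples, covariates, include_warmup=False)
    n = len(merged)
    if n < cv.k * 2:
        raise ValidationError(f"{n} samples cannot populate {cv.k} folds")

    rng = np.random.default_rng(cv.seed)
    rows = []
    for rep in range(cv.repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, cv.k)
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, test_idx)
            train = merged.iloc[train_idx]
            test = merged.iloc[test_idx]
            train_samples = SampleSeries(
                station_id=samples.station_id,
                parameter=samples.parameter,
                data=train[["date", "value", "censored", "detection_limit"]],
                units=samples.units,
            )
            model = fit_concentration_model(
                train_samples,
                covariates,
                spec=spec,
                min_samples=min(min_samples, len(train)),
                optimizer_maxfev=optimizer_maxfev,
            )
            pred = model.predict_response(test)
            obs = test["value"].to_numpy(dtype=float)
            if cv.target == "daily_load":
                flows = test["flow_cfs"].to_numpy(dtype=float)
                pred = concentration_to_load(pred, flows)
                obs = concentration_to_load(obs, flows)
            try:
                row = {
                    "repeat": rep,
                    "fold": fold_id,
                    "nse": nse(obs, pred),
                    "r": pearson_r(obs, pred),
                    "pbias": pbias(obs, pred),
                }
            except UndefinedMetricError:
                row = {"repeat": rep, "fold": fold_id, "nse": np.nan, "r": np.nan, "pbias": np.nan}
            rows.append(row)

    per_fold = pd.DataFrame(rows)
    medians = {m: float(np.nanmedian(per_fold[m])) for m in ("nse", "r", "pbias")}
    tails = per_fold.copy()
    for m in ("nse", "r", "pbias"):
        tails[f"{m}_tail"] = _tail_prob(per_fold[m].to_numpy())
    return CVResult(per_fold=per_fold, medians=medians, tail_probabilities=tails)
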