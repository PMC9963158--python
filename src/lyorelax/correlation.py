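"""Correlation of relaxation time with crystallization time, and prediction.

Across freeze-drying processes of one formulation stored at one temperature,
the composite relaxation time tau_beta tracks molecular mobility and hence
the time to crystallization.  This module fits the ordinary-least-squares
line ``t_cryst = intercept + slope * tau_beta``, reports r-squared and the
Kendall rank agreement between the two orderings, and predicts the
crystallization time of a new process from its tau_beta with a standard
new-observation prediction interval.

Only processes of the same formulation at the same storage temperature are
comparable; pooling across formulations is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationModel",
    "Prediction",
    "linear_correlation",
    "rank_agreement",
    "predict_crystallization_time",
    "correlate_table",
]


@dataclass
class CorrelationModel:
    """Fitted tau_beta -> crystallization-time line with diagnostics and the
    sufficient statistics needed for prediction intervals."""

    slope: float  # hours of crystallization time per hour of tau_beta
    intercept: float  # hours
    r2: float
    n: int
    kendall_tau: float
    residual_sd: float  # hours, sqrt(RSS / (n - 2)); 0 if n == 2
    x_mean: float
    s_xx: float
    x_min: float
    x_max: float
    formulation: str = ""
    temperature: float | None = None


@dataclass
class Prediction:
    point: float  # hours
    lower: float
    upper: float
    extrapolated: bool


def _as_xy(pairs):
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (tau_beta, cryst_time)")
    if np.any(~np.isfinite(arr)):
        raise ValueError("pairs contain missing or non-finite values")
    return arr[:, 0], arr[:, 1]


def linear_correlation(
    pairs,
    *,
    formulation: str = "",
    temperature: float | None = None,
    formulations=None,
) -> CorrelationModel:
    """OLS fit of crystallization time on tau_beta.

    ``pairs`` is a sequence of ``(tau_beta_hours, cryst_time_hours)``.
    Requires ``n >= 2`` and a non-constant predictor; a warning is emitted
    for ``n < 4`` where a linear correlation is not statistically robust.
    If per-pair ``formulations`` labels are given, they must all agree:
    only different processes of the same formulation are comparable.
    """
    if formulations is not None:
        labels = set(formulations)
        if len(labels) > 1:
            raise ValueError(
                f"cannot pool pairs across formulations {sorted(labels)}; "
                "only processes of one formulation are comparable"
            )
        if not formulation and labels:
            formulation = next(iter(labels))
    x, y = _as_xy(pairs)
    n = x.size
    if n < 2:
        raise ValueError("need at least two (tau_beta, cryst_time) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all tau_beta values are equal")
    if n < 4:
        warnings.warn(
            f"linear correlation fitted on only {n} points; not statistically robust",
            stacklevel=2,
        )
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    residual_sd = float(np.sqrt(rss / (n - 2))) if n > 2 else 0.0
    tau = rank_agreement(pairs) if np.ptp(y) > 0 or np.ptp(x) > 0 else np.nan
    return CorrelationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n=n,
        kendall_tau=tau,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        s_xx=float(np.sum((x - x.mean()) ** 2)),
        x_min=float(x.min()),
        x_max=float(x.max()),
        formulation=formulation,
        temperature=temperature,
    )


def rank_agreement(pairs) -> float:
    """Kendall tau-b between the tau_beta ordering and the crystallization
    ordering.  +1 means the relaxation times predict the crystallization
    order perfectly."""
    x, y = _as_xy(pairs)
    if x.size < 2:
        raise ValueError("need at least two pairs for rank agreement")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("rank agreement undefined: all pairs tied")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def predict_crystallization_time(
    model: CorrelationModel, tau_beta: float, *, confidence: float = 0.95
) -> Prediction:
    """Predict the crystallization time (hours) of a new process.

    The interval is the standard OLS new-observation prediction interval
    ``point +/- t * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)``.  Predictions
    outside twice the fitted tau_beta range are flagged as extrapolated.
    For a perfect fit (zero residual) the interval has zero width; with
    ``n < 3`` residual degrees of freedom are absent and the interval is
    undefined (NaN bounds).
    """
    if not np.isfinite(model.slope):
        raise ValueError("model is not fitted")
    point = model.intercept + model.slope * tau_beta
    span = model.x_max - model.x_min
    lo_ok = model.x_min - 0.5 * span if span > 0 else model.x_min
    hi_ok = model.x_max + 0.5 * span if span > 0 else model.x_max
    extrapolated = not (lo_ok <= tau_beta <= hi_ok)
    if model.residual_sd == 0.0:
        return Prediction(point=float(point), lower=float(point), upper=float(point), extrapolated=extrapolated)
    if model.n < 3:
        return Prediction(point=float(point), lower=np.nan, upper=np.nan, extrapolated=extrapolated)
    se = model.residual_sd * np.sqrt(
        1.0 + 1.0 / model.n + (tau_beta - model.x_mean) ** 2 / model.s_xx
    )
    tq = stats.t.ppf(0.5 + confidence / 2.0, model.n - 2)
    return Prediction(
        point=float(point),
        lower=float(point - tq * se),
        upper=float(point + tq * se),
        extrapolated=extrapolated,
    )


def correlate_table(
    results: pd.DataFrame,
    *,
    tau_col: str = "tau_beta_h",
    time_col: str = "cryst_time_h",
    formulation_col: str = "formulation",
    temperature_col: str = "temperature_C",
) -> dict[tuple[str, float], CorrelationModel]:
    """Fit one model per (formulation, storage temperature) group of a
    results table.  A table spanning several formulations is fitted per
    group, never pooled; calling :func:`linear_correlation` directly with a
    mixed-formulation table is the user's error and this helper guards it."""
    required = {tau_col, time_col, formulation_col, temperature_col}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns: {sorted(missing)}")
    models: dict[tuple[str, float], CorrelationModel] = {}
    for (form, temp), grp in results.groupby([formulation_col, temperature_col]):
        grp = grp.dropna(subset=[tau_col, time_col])
        if len(grp) < 2:
            continue
        models[(form, float(temp))] = linear_correlation(
            np.column_stack([grp[tau_col], grp[time_col]]),
            formulation=str(form),
            temperature=float(temp),
        )
    return models
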