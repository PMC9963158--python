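"""Ingestion, trimming and constrained MSE fitting of IMC power-time records.

A TAM-style isothermal microcalorimetry measurement of a freeze-dried cake
yields a decaying exothermic power record over 12 h.  The record is fitted
with the MSE relaxation power model (see :mod:`lyorelax.mse`) under the hard
constraints ``tau0 > tau1`` and ``0 < beta <= 1``; the amplitude
``delta_h_r_inf`` is not a free parameter but fixed from DSC-derived Tg and
delta_cp.  The constraints are built into the optimisation by
reparameterisation, never checked post hoc:

    tau1 = exp(u1),   tau0 = tau1 + exp(u2),   beta = 1 / (1 + exp(-u3))

so any unconstrained ``(u1, u2, u3)`` maps to an admissible parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .mse import MSEParams, ThermalContext, power_uW_per_g, tau_beta

__all__ = ["PowerTimeSeries", "MSEFit", "preprocess", "fit_mse", "fit_report", "DEFAULT_START"]

#: conventional fit starting point
DEFAULT_START = MSEParams(tau0=2.0, tau1=1.0, beta=0.1)

_MIN_POINTS = 10


@dataclass
class PowerTimeSeries:
    """A mass-normalised IMC power record.

    ``times`` are hours since the start of the measurement-position record,
    strictly increasing; ``powers`` are exothermic-positive uW/g.
    """

    times: np.ndarray
    powers: np.ndarray
    sample_mass_g: float | None = None
    temperature: float | None = None
    sample_id: str = ""
    process_label: str = ""
    formulation_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.times.shape != self.powers.shape or self.times.ndim != 1:
            raise ValueError("times and powers must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class MSEFit:
    """Result of a constrained MSE fit: parameters, the fixed thermal context,
    the derived composite relaxation time and fit diagnostics."""

    params: MSEParams | None
    ctx: ThermalContext
    tau_beta: float | None
    rss: float
    r2_fit: float
    n_points: int
    converged: bool
    start_params: MSEParams
    tau_beta_convention: str = "kww"
    message: str = ""
    series_meta: dict = field(default_factory=dict)


def preprocess(series: PowerTimeSeries, trim_start: float = 0.0, duration: float = 12.0) -> PowerTimeSeries:
    """Restrict a record to ``trim_start <= t <= duration`` (hours).

    The time origin is preserved (no re-zeroing); an empty selection is an
    error.  ``trim_start`` defaults to 0 — the nominal procedure fits the
    whole 12 h record — but an initial equilibration transient can be cut.
    """
    if trim_start < 0:
        raise ValueError("trim_start must be >= 0")
    if duration <= trim_start:
        raise ValueError("duration must exceed trim_start")
    mask = (series.times >= trim_start) & (series.times <= duration)
    if not np.any(mask):
        raise ValueError("no data points remain after trimming")
    return replace(series, times=series.times[mask], powers=series.powers[mask])


def _pack(params: MSEParams) -> np.ndarray:
    beta = min(max(params.beta, 1e-9), 1.0 - 1e-12)
    return np.array(
        [
            np.log(params.tau1),
            np.log(params.tau0 - params.tau1),
            np.log(beta / (1.0 - beta)),
        ]
    )


def _unpack(u: np.ndarray) -> MSEParams:
    tau1 = float(np.exp(u[0]))
    tau0 = tau1 + float(np.exp(u[1]))
    beta = float(1.0 / (1.0 + np.exp(-u[2])))
    return MSEParams(tau0=tau0, tau1=tau1, beta=beta)


def fit_mse(
    series: PowerTimeSeries,
    ctx: ThermalContext,
    starts: MSEParams = DEFAULT_START,
    *,
    tau_beta_convention: str = "kww",
    free_amplitude: bool = False,
    ftol: float = 1e-10,
    max_nfev: int = 5000,
) -> MSEFit:
    """Constrained least-squares fit of the MSE power model to a record.

    ``delta_h_r_inf`` comes from ``ctx`` and stays fixed unless
    ``free_amplitude`` is set (a sensitivity-analysis option).  The fit is
    deterministic for identical inputs.  Non-convergence — including a record
    with no relaxation signal — is reported on the returned :class:`MSEFit`
    rather than raised.
    """
    n = len(series)
    n_free = 4 if free_amplitude else 3
    if n < max(_MIN_POINTS, n_free + 1):
        raise ValueError(f"need at least {max(_MIN_POINTS, n_free + 1)} points to fit, got {n}")

    t = series.times
    p_obs = series.powers
    scale = float(np.max(np.abs(p_obs))) if n else 0.0
    if scale <= 0 or not np.isfinite(scale):
        return MSEFit(
            params=None, ctx=ctx, tau_beta=None, rss=float(np.sum(p_obs**2)),
            r2_fit=0.0, n_points=n, converged=False, start_params=starts,
            tau_beta_convention=tau_beta_convention,
            message="no relaxation signal (record is zero or non-finite)",
        )

    if free_amplitude:
        u0 = np.concatenate([_pack(starts), [np.log(max(ctx.delta_h_r_inf, 1e-6))]])

        def residuals(u):
            return power_uW_per_g(t, _unpack(u[:3]), float(np.exp(u[3]))) - p_obs
    else:
        u0 = _pack(starts)

        def residuals(u):
            return power_uW_per_g(t, _unpack(u), ctx) - p_obs

    result = least_squares(
        residuals, u0, method="lm", ftol=ftol, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev
    )
    params = _unpack(result.x[:3])
    rss = float(np.sum(result.fun**2))
    tss = float(np.sum((p_obs - p_obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    converged = bool(result.status > 0 and np.all(np.isfinite(result.x)))
    fitted_ctx = ctx
    if free_amplitude and converged:
        fitted_ctx = ThermalContext(
            temperature=ctx.temperature, tg=ctx.tg, delta_cp=ctx.delta_cp,
            delta_h_r_inf=float(np.exp(result.x[3])),
        )
    return MSEFit(
        params=params if converged else None,
        ctx=fitted_ctx,
        tau_beta=tau_beta(params, tau_beta_convention) if converged else None,
        rss=rss,
        r2_fit=r2,
        n_points=n,
        converged=converged,
        start_params=starts,
        tau_beta_convention=tau_beta_convention,
        message=result.message,
        series_meta={
            "sample_id": series.sample_id,
            "process": series.process_label,
            "formulation": series.formulation_label,
            "temperature_C": series.temperature,
        },
    )


def fit_report(fits: "MSEFit | list[MSEFit]") -> pd.DataFrame:
    """Tabulate one row per fit: sample metadata, fitted parameters, tau_beta,
    the fixed amplitude, and diagnostics.  Non-converged fits keep their
    metadata but carry NaN parameter cells."""
    if isinstance(fits, MSEFit):
        fits = [fits]
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "sample_id": f.series_meta.get("sample_id", ""),
                "process": f.series_meta.get("process", ""),
                "formulation": f.series_meta.get("formulation", ""),
                "temperature_C": f.series_meta.get("temperature_C"),
                "tau0_h": p.tau0 if p else np.nan,
                "tau1_h": p.tau1 if p else np.nan,
                "beta": p.beta if p else np.nan,
                "tau_beta_h": f.tau_beta if f.tau_beta is not None else np.nan,
                "tau_beta_convention": f.tau_beta_convention,
                "delta_h_r_inf_J_per_g": f.ctx.delta_h_r_inf,
                "rss": f.rss,
                "r2_fit": f.r2_fit,
                "n_points": f.n_points,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
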