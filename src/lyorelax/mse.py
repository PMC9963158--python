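"""Modified stretched-exponential (MSE) enthalpy-relaxation model.

An amorphous glass stored below its glass transition temperature Tg slowly
relaxes toward the supercooled-liquid enthalpy.  The fraction of relaxation
enthalpy still unrecovered after time ``t`` is described here by the
Pikal/Kawakami modification of the Kohlrausch-Williams-Watts (KWW)
stretched exponential,

    Phi(t) = exp[ -(t / tau0) * (1 + t / tau1)**(beta - 1) ],

with two time constants ``tau0 > tau1 > 0`` (hours) and a stretch exponent
``0 < beta <= 1``.  An isothermal microcalorimeter measures the heat released
by this process; the exothermic, mass-normalised power is the exact time
derivative

    P(t) = -277.8 * dHr_inf * dPhi/dt
         = 277.8 * (dHr_inf / tau0) * (1 + beta*t/tau1)
           * (1 + t/tau1)**(beta - 2) * Phi(t)        [uW/g]

where ``dHr_inf = (Tg - T) * delta_cp`` (J/g) is the maximum recoverable
relaxation enthalpy at storage temperature ``T`` and 277.8 converts J/(g*h)
to uW/g.  All time arguments are in hours.

The single-number mobility summary is the composite relaxation time
``tau_beta``; see :func:`tau_beta` for the convention used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POWER_CONVERSION_UW_PER_JGH",
    "MSEParams",
    "ThermalContext",
    "delta_h_r_inf",
    "relaxation_survival",
    "power_uW_per_g",
    "tau_beta",
]

#: conversion factor from J/(g*h) to uW/g (1e6 / 3600, printed as 277.8)
POWER_CONVERSION_UW_PER_JGH = 277.8


@dataclass(frozen=True)
class MSEParams:
    """Parameters of the MSE relaxation function.

    Attributes
    ----------
    tau0, tau1 : float
        Time constants in hours; ``tau0 > tau1 > 0`` is required.
    beta : float
        Stretch exponent, ``0 < beta <= 1``.
    """

    tau0: float
    tau1: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau0) and np.isfinite(self.tau1) and np.isfinite(self.beta)):
            raise ValueError("MSE parameters must be finite")
        if not self.tau1 > 0:
            raise ValueError(f"tau1 must be positive, got {self.tau1}")
        if not self.tau0 > self.tau1:
            raise ValueError(f"tau0 must exceed tau1, got tau0={self.tau0}, tau1={self.tau1}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")

    def scaled(self, factor: float) -> "MSEParams":
        """Return parameters with both time constants and beta multiplied by ``factor``
        (beta clipped into its admissible interval); handy for perturbed fit starts."""
        return MSEParams(
            tau0=self.tau0 * factor,
            tau1=self.tau1 * factor,
            beta=min(1.0, self.beta * factor),
        )


@dataclass(frozen=True)
class ThermalContext:
    """Thermal state of a sample: storage temperature, glass transition and
    the derived relaxation-enthalpy amplitude.

    ``delta_h_r_inf`` (J/g) is computed as ``(tg - temperature) * delta_cp``
    when not given explicitly.  Samples at or above Tg carry no recoverable
    relaxation enthalpy and are rejected.
    """

    temperature: float
    tg: float
    delta_cp: float
    delta_h_r_inf: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.delta_h_r_inf is None:
            object.__setattr__(
                self, "delta_h_r_inf", delta_h_r_inf(self.temperature, self.tg, self.delta_cp)
            )
        if self.delta_h_r_inf < 0:
            raise ValueError("delta_h_r_inf must be non-negative")


def delta_h_r_inf(temperature: float, tg: float, delta_cp: float) -> float:
    """Maximum recoverable relaxation enthalpy ``(Tg - T) * delta_cp`` in J/g.

    Parameters
    ----------
    temperature : float
        Storage/measurement temperature in degC; must not exceed ``tg``.
    tg : float
        Glass transition temperature in degC.
    delta_cp : float
        Heat-capacity step at Tg in J/(g*K); must be positive.
    """
    if not delta_cp > 0:
        raise ValueError(f"delta_cp must be positive, got {delta_cp}")
    if temperature > tg:
        raise ValueError(
            f"temperature {temperature} degC is above Tg {tg} degC; "
            "the relaxation model applies only below the glass transition"
        )
    return (tg - temperature) * delta_cp


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def relaxation_survival(t, params: MSEParams):
    """MSE survival function Phi(t): the fraction of relaxation enthalpy not
    yet released after ``t`` hours.  Phi(0) = 1 and Phi decreases strictly
    to zero.  Accepts scalars or arrays (hours)."""
    t = _check_times(t)
    x = t / params.tau1
    exponent = (t / params.tau0) * np.power(1.0 + x, params.beta - 1.0)
    out = np.exp(-exponent)
    return float(out) if out.ndim == 0 else out


def power_uW_per_g(t, params: MSEParams, ctx) -> "np.ndarray | float":
    """Exothermic relaxation power P(t) in uW/g at time ``t`` hours.

    ``ctx`` is a :class:`ThermalContext` or directly the amplitude
    ``delta_h_r_inf`` in J/g.  P is the exact negative derivative of
    ``delta_h_r_inf * Phi`` scaled by the J/(g*h) -> uW/g constant, so the
    full integral of P recovers the relaxation enthalpy.
    """
    dh = ctx.delta_h_r_inf if isinstance(ctx, ThermalContext) else float(ctx)
    if dh < 0:
        raise ValueError("delta_h_r_inf must be non-negative")
    t = _check_times(t)
    x = t / params.tau1
    phi = np.exp(-(t / params.tau0) * np.power(1.0 + x, params.beta - 1.0))
    out = (
        POWER_CONVERSION_UW_PER_JGH
        * (dh / params.tau0)
        * (1.0 + params.beta * x)
        * np.power(1.0 + x, params.beta - 2.0)
        * phi
    )
    return float(out) if out.ndim == 0 else out


def tau_beta(params: MSEParams, convention: str = "kww") -> float:
    """Composite relaxation time tau_beta in hours.

    The long-time limit of the MSE exponent is ``(t/tau0)*(t/tau1)**(beta-1)
    = t**beta / (tau0 * tau1**(beta-1))``, i.e. a KWW decay whose ``tau**beta``
    equals ``tau0 * tau1**(beta-1)``.  That composite is far better determined
    by the data than tau0, tau1 or beta individually (which are strongly
    correlated in the fit), so it is the default summary:

    - ``"kww"`` (default): ``tau0 * tau1**(beta - 1)``
    - ``"tau0_beta"``:     ``tau0**beta``
    """
    if convention == "kww":
        return params.tau0 * params.tau1 ** (params.beta - 1.0)
    if convention == "tau0_beta":
        return params.tau0**params.beta
    raise ValueError(f"unknown tau_beta convention {convention!r}")
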