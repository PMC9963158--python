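"""Feature extraction from deconvolved DSC curves.

Modulated DSC separates a thermogram into reversing and total (plus
non-reversing) heat-flow components.  Here the reversing curve supplies the
glass transition (Tg) and the heat-capacity step delta_cp that parameterise
the relaxation amplitude, and the total curve supplies the crystallization
exotherm (onset temperature, peak temperature, enthalpy).  Curves arrive
already deconvolved; signals follow the endothermic-up convention, so the
cp increase at Tg is a step up and crystallization is a downward peak.

Conventions (standard thermal-analysis practice):

- Tg midpoint: half-height between linear pre- and post-transition
  baselines; Tg onset: intersection of the pre-transition baseline with the
  tangent at the steepest slope.
- delta_cp: baseline-to-baseline step height divided by the heating rate.
- Peak onset: intersection of the local linear baseline with the
  leading-edge tangent at the steepest slope.
- Enthalpy: baseline-subtracted peak area divided by the heating rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "DSCThermogram",
    "DSCFeatures",
    "extract_glass_transition",
    "extract_crystallization_event",
    "extract_features",
]


@dataclass
class DSCThermogram:
    """A deconvolved thermogram: strictly increasing temperature grid (degC),
    reversing and total heat-flow signals (W/g, endo-up), heating rate (K/min)."""

    temperatures: np.ndarray
    reversing_signal: np.ndarray
    total_signal: np.ndarray
    heating_rate: float = 2.0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.reversing_signal = np.asarray(self.reversing_signal, dtype=float)
        self.total_signal = np.asarray(self.total_signal, dtype=float)
        if not (self.temperatures.shape == self.reversing_signal.shape == self.total_signal.shape):
            raise ValueError("temperature and signal arrays must have equal shape")
        if self.temperatures.size > 1 and not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not self.heating_rate > 0:
            raise ValueError("heating_rate must be positive")


@dataclass
class DSCFeatures:
    """Scalar features of one thermogram.  A fully crystalline (or
    peak-free) sample has ``cryst_enthalpy = 0`` and ``None`` onsets."""

    tg_midpoint: float | None = None
    tg_onset: float | None = None
    delta_cp: float | None = None
    cryst_onset: float | None = None
    cryst_peak_T: float | None = None
    cryst_enthalpy: float = 0.0
    crystalline_flag: bool = False


def _noise_sigma(signal: np.ndarray) -> float:
    d = np.diff(signal)
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0) if d.size else 0.0


def _smooth(signal: np.ndarray, dT: float, width_K: float = 1.0) -> np.ndarray:
    win = max(5, int(round(width_K / dT)) | 1)
    if win >= signal.size:
        win = (signal.size - 1) | 1
    return savgol_filter(signal, win, polyorder=2)


def _linfit(T: np.ndarray, y: np.ndarray, lo: float, hi: float, what: str):
    mask = (T >= lo) & (T <= hi)
    if mask.sum() < 5:
        raise ValueError(f"not enough points ({mask.sum()}) for the {what} baseline in [{lo:.1f}, {hi:.1f}] degC")
    return np.polyfit(T[mask], y[mask], 1)


def extract_glass_transition(
    thermogram: DSCThermogram,
    *,
    baseline_window_K: float = 15.0,
    baseline_offset_K: float = 5.0,
    min_step_sigma: float = 5.0,
):
    """Locate the glass transition on the reversing curve.

    Returns ``(tg_onset, tg_midpoint, delta_cp)`` with temperatures in degC
    and ``delta_cp`` in J/(g*K).  Raises ``ValueError`` ("no glass transition
    found") when no step rises above ``min_step_sigma`` times the noise.
    """
    T = thermogram.temperatures
    if T.size < 25:
        raise ValueError("thermogram too short for glass-transition analysis")
    dT = float(np.median(np.diff(T)))
    s = thermogram.reversing_signal
    sigma = _noise_sigma(s)
    s_sm = _smooth(s, dT)
    deriv = np.gradient(s_sm, T)

    i_star = int(np.argmax(deriv))
    d_max = deriv[i_star]
    # transition region: contiguous run around the steepest slope
    above = deriv > 0.25 * d_max
    lo_i = i_star
    while lo_i > 0 and above[lo_i - 1]:
        lo_i -= 1
    hi_i = i_star
    while hi_i < T.size - 1 and above[hi_i + 1]:
        hi_i += 1
    T_lo, T_hi = T[lo_i] - 1.0, T[hi_i] + 1.0

    try:
        pre = _linfit(T, s, T_lo - baseline_offset_K - baseline_window_K, T_lo - baseline_offset_K, "pre-Tg")
        post = _linfit(T, s, T_hi + baseline_offset_K, T_hi + baseline_offset_K + baseline_window_K, "post-Tg")
    except ValueError as exc:
        # a noise-located "transition" at the edge of the window means there
        # is no real step in range
        raise ValueError(f"no glass transition found ({exc})") from exc

    mid_region = slice(max(lo_i - 1, 0), min(hi_i + 2, T.size))
    Tm = T[mid_region]
    frac = (s_sm[mid_region] - np.polyval(pre, Tm)) / np.maximum(
        np.polyval(post, Tm) - np.polyval(pre, Tm), 1e-30
    )
    step_mid = np.polyval(post, T[i_star]) - np.polyval(pre, T[i_star])
    if not np.isfinite(step_mid) or step_mid < min_step_sigma * max(sigma, 1e-30):
        raise ValueError("no glass transition found (step height below noise threshold)")

    # half-height crossing, linearly interpolated
    crossings = np.where(np.diff(np.sign(frac - 0.5)) > 0)[0]
    if crossings.size == 0:
        raise ValueError("no glass transition found (no half-height crossing)")
    j = crossings[0]
    tg_mid = float(
        Tm[j] + (0.5 - frac[j]) / (frac[j + 1] - frac[j]) * (Tm[j + 1] - Tm[j])
    )

    step_at_mid = float(np.polyval(post, tg_mid) - np.polyval(pre, tg_mid))
    delta_cp = step_at_mid / (thermogram.heating_rate / 60.0)

    # onset: pre baseline vs tangent at steepest slope
    y_star = s_sm[i_star]
    tg_onset = float((y_star - d_max * T[i_star] - pre[1]) / (pre[0] - d_max))
    return tg_onset, tg_mid, delta_cp


def extract_crystallization_event(
    thermogram: DSCThermogram,
    *,
    prominence_sigma: float = 5.0,
    extent_sigma: float = 2.0,
):
    """Locate the crystallization exotherm on the total curve.

    Returns ``(cryst_onset, cryst_peak_T, cryst_enthalpy)``; onset and peak
    are degC, enthalpy is positive J/g.  An absent peak yields
    ``(None, None, 0.0)``.  With several exotherms the lowest-temperature
    one is analysed and a warning is emitted.
    """
    T = thermogram.temperatures
    dT = float(np.median(np.diff(T)))
    s = thermogram.total_signal
    sigma = _noise_sigma(s)
    s_sm = _smooth(s, dT)
    # exotherm points down in endo-up convention
    y = -s_sm
    min_width = max(3, int(round(0.5 / dT)))
    prom_floor = max(prominence_sigma * sigma, 1e-9 * max(float(np.ptp(s)), 1.0))
    peaks, props = find_peaks(y, prominence=prom_floor, width=min_width)
    if peaks.size == 0:
        return None, None, 0.0
    if peaks.size > 1:
        warnings.warn(
            f"{peaks.size} exothermic peaks detected; analysing the lowest-temperature one",
            stacklevel=2,
        )
    order = np.argsort(T[peaks])
    peaks, prominences = peaks[order], props["prominences"][order]
    apex = int(peaks[0])

    # peak extent: walk out until the deviation from the local trend is small
    height = prominences[0]
    left = apex
    while left > 0 and y[left - 1] > y[apex] - height + extent_sigma * max(sigma, 1e-12 * height):
        left -= 1
    right = apex
    while right < T.size - 1 and y[right + 1] > y[apex] - height + extent_sigma * max(sigma, 1e-12 * height):
        right += 1
    pad = max(3, int(round(2.0 / dT)))
    bl_lo = max(left - pad, 0)
    bl_hi = min(right + pad, T.size - 1)
    base_T = np.concatenate([T[bl_lo:left + 1], T[right:bl_hi + 1]])
    base_y = np.concatenate([s[bl_lo:left + 1], s[right:bl_hi + 1]])
    base = np.polyfit(base_T, base_y, 1)

    seg = slice(left, right + 1)
    excess = np.polyval(base, T[seg]) - s[seg]  # positive over the exotherm
    area = float(np.trapezoid(np.clip(excess, 0.0, None), T[seg]))  # (W/g)*K
    enthalpy = area / (thermogram.heating_rate / 60.0)  # J/g

    # onset: leading-edge tangent at the steepest (most exothermic) slope
    deriv = np.gradient(s_sm, T)
    lead = slice(left, apex + 1)
    i_rel = int(np.argmin(deriv[lead]))
    i_tan = left + i_rel
    d_tan = deriv[i_tan]
    y_tan = s_sm[i_tan]
    onset = float((y_tan - d_tan * T[i_tan] - base[1]) / (base[0] - d_tan))
    peak_T = float(T[apex])
    return onset, peak_T, enthalpy


def extract_features(thermogram: DSCThermogram) -> DSCFeatures:
    """Run both extractions and assemble a :class:`DSCFeatures` row."""
    tg_onset, tg_mid, dcp = extract_glass_transition(thermogram)
    onset, peak_T, enthalpy = extract_crystallization_event(thermogram)
    return DSCFeatures(
        tg_midpoint=tg_mid,
        tg_onset=tg_onset,
        delta_cp=dcp,
        cryst_onset=onset,
        cryst_peak_T=peak_T,
        cryst_enthalpy=enthalpy,
        crystalline_flag=enthalpy == 0.0,
    )
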