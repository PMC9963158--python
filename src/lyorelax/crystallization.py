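"""Crystallization-time determination.

Two experimental routes yield a crystallization time for a freeze-dried
sample:

- **Fast path (IMC):** fast-crystallizing samples stay in the calorimeter
  until an exothermic crystallization peak appears on top of the decayed
  relaxation signal; the time of the peak maximum is the crystallization
  time.  Pooled vials can produce double peaks a few days apart.
- **Slow path (storage DSC):** slow samples are stored and aliquots are
  measured weekly by DSC.  As the cake crystallizes in storage, the
  above-Tg crystallization exotherm shrinks (and its onset drops); the
  crystallization time is defined as the interpolated time at which the
  exotherm enthalpy falls below a fraction ``theta`` of its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .dsc import DSCFeatures
from .imc import PowerTimeSeries, fit_mse, preprocess
from .mse import ThermalContext, power_uW_per_g

__all__ = [
    "ExothermPeak",
    "StorageRecord",
    "detect_exotherm_peaks",
    "imc_crystallization_time",
    "storage_crystallization_time",
]

#: uW*h/g -> J/g
_UWH_TO_J = 3600.0 / 1e6


@dataclass
class ExothermPeak:
    """One detected crystallization exotherm in an IMC record."""

    time_of_maximum: float  # hours
    height: float  # uW/g above the relaxation baseline
    prominence: float  # uW/g
    area: float  # J/g
    confirmed: bool = False  # set by the user after DSC/XRD confirmation


@dataclass
class StorageRecord:
    """Weekly DSC-feature trajectory of one stored sample."""

    sample_id: str
    storage_temperature: float
    weekly_times: np.ndarray  # days, strictly increasing
    weekly_features: list[DSCFeatures] = field(default_factory=list)
    cryst_time: float | None = None  # days
    status: str = "amorphous"

    def __post_init__(self) -> None:
        self.weekly_times = np.asarray(self.weekly_times, dtype=float)
        if self.weekly_times.size > 1 and not np.all(np.diff(self.weekly_times) > 0):
            raise ValueError("weekly_times must be strictly increasing")
        if len(self.weekly_features) != self.weekly_times.size:
            raise ValueError("one feature set per time point required")


def _asym_gauss(t, center, height, w_left, w_right):
    w = np.where(t < center, w_left, w_right)
    return height * np.exp(-0.5 * ((t - center) / w) ** 2)


def _refine_peak(t, r, i_apex, width_h):
    """Refine a peak by fitting a two-sided Gaussian plus a local linear
    background around the apex; returns the fitted (centre, height, w_left,
    w_right) or ``None`` if the fit is unusable.

    The raw argmax is quantised to the sampling grid and wanders under noise
    because the signal is flat near its maximum; a local shape fit uses the
    whole peak flank instead.  The linear background absorbs instrument
    drift, which would otherwise pull the fitted centre toward the peak's
    wider side."""
    lo = np.searchsorted(t, t[i_apex] - 3.0 * width_h)
    hi = np.searchsorted(t, t[i_apex] + 3.0 * width_h)
    tt, rr = t[lo:hi], r[lo:hi]
    if tt.size < 10:
        return None
    t_ref = float(t[i_apex])
    h0 = max(float(r[i_apex]), 1e-12)
    x0 = np.array([t_ref, h0, max(width_h, 1e-3), max(width_h, 1e-3), 0.0, 0.0])

    def resid(x):
        return (
            _asym_gauss(tt, x[0], x[1], abs(x[2]) + 1e-6, abs(x[3]) + 1e-6)
            + x[4]
            + x[5] * (tt - t_ref)
            - rr
        )

    try:
        res = least_squares(resid, x0, method="lm", max_nfev=2000)
    except Exception:
        return None
    center, height, wl, wr = res.x[0], res.x[1], abs(res.x[2]) + 1e-6, abs(res.x[3]) + 1e-6
    if not np.isfinite(center) or not (tt[0] <= center <= tt[-1]) or height <= 0:
        return None
    return float(center), float(height), float(wl), float(wr)


def detect_exotherm_peaks(
    series: PowerTimeSeries,
    ctx: ThermalContext | None = None,
    *,
    baseline_fit_hours: float = 12.0,
    smooth_window_s: float = 900.0,
    prominence_sigma: float = 5.0,
    min_width_h: float = 0.5,
    refine: bool = True,
) -> list[ExothermPeak]:
    """Detect crystallization exotherms in a (possibly multi-day) IMC record.

    The MSE relaxation model is refit on the first ``baseline_fit_hours`` of
    the record (where the relaxation decay dominates) and subtracted; peaks
    are then sought in the smoothed residual with a prominence threshold of
    ``prominence_sigma`` times a robust (median-absolute-deviation) white
    noise estimate.  Peak times are refined by a local two-sided-Gaussian
    fit so they are not limited to the sampling grid.
    """
    t = series.times
    if t.size < 100 or t[-1] - t[0] < baseline_fit_hours:
        raise ValueError(
            f"record too short for exotherm detection (need >= {baseline_fit_hours} h and >= 100 points)"
        )
    p = series.powers

    # relaxation baseline from the early, peak-free segment
    head = preprocess(series, 0.0, baseline_fit_hours)
    if ctx is None:
        ctx = ThermalContext(temperature=25.0, tg=60.0, delta_cp=0.5)
        fit = fit_mse(head, ctx, free_amplitude=True)
    else:
        fit = fit_mse(head, ctx)
    if fit.converged and fit.params is not None:
        baseline = power_uW_per_g(t, fit.params, fit.ctx)
    else:  # no usable relaxation signal; fall back to a median level
        baseline = np.full_like(p, float(np.median(p[: head.times.size])))
    residual = p - baseline

    sigma = 1.4826 * float(np.median(np.abs(np.diff(residual)))) / np.sqrt(2.0)
    dt_h = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_window_s / 3600.0 / dt_h)))
    r_sm = uniform_filter1d(residual, size=win)

    floor = 1e-6 * max(float(np.max(np.abs(p))), 1e-30)
    threshold = max(prominence_sigma * sigma, floor)
    idx, props = find_peaks(
        r_sm, prominence=threshold, width=max(1, int(round(min_width_h / dt_h)))
    )
    # refine left to right, subtracting each fitted peak's shape so the tail
    # of an earlier exotherm does not bias the centre of a later one; the
    # refinement uses the raw residual (the smoothed one has correlated
    # noise and a slightly distorted apex)
    order = np.argsort(t[idx])
    r_work = residual.copy()
    peaks: list[ExothermPeak] = []
    for k in order:
        i = int(idx[k])
        w_samples = props["widths"][k]
        width_h = max(w_samples * dt_h / 2.355, dt_h)  # FWHM -> sigma-like
        t_max = float(t[i])
        area = None
        if refine:
            fit_local = _refine_peak(t, r_work, i, width_h)
            if fit_local is not None:
                t_max, height, wl, wr = fit_local
                r_work = r_work - _asym_gauss(t, t_max, height, wl, wr)
                # analytic area of the fitted shape, immune to neighbouring peaks
                area = height * np.sqrt(np.pi / 2.0) * (wl + wr) * _UWH_TO_J
        if area is None:
            lo = int(props["left_bases"][k])
            hi = int(props["right_bases"][k])
            area = float(
                np.trapezoid(np.clip(residual[lo : hi + 1], 0.0, None), t[lo : hi + 1])
            ) * _UWH_TO_J
        peaks.append(
            ExothermPeak(
                time_of_maximum=t_max,
                height=float(r_sm[i]),
                prominence=float(props["prominences"][k]),
                area=area,
            )
        )
    peaks.sort(key=lambda pk: pk.time_of_maximum)
    return peaks


def imc_crystallization_time(peaks: list[ExothermPeak], policy: str = "first") -> float | None:
    """Reduce a list of exotherms to a single crystallization time (hours).

    Policies: ``"first"`` (default — the first vial to crystallize),
    ``"largest-area"``, ``"mean-of-maxima"``.  An empty list yields ``None``.
    """
    if not peaks:
        return None
    if policy == "first":
        return peaks[0].time_of_maximum
    if policy == "largest-area":
        return max(peaks, key=lambda p: p.area).time_of_maximum
    if policy == "mean-of-maxima":
        return float(np.mean([p.time_of_maximum for p in peaks]))
    raise ValueError(f"unknown peak policy {policy!r}")


def storage_crystallization_time(
    record: StorageRecord,
    rule: str = "enthalpy-fraction",
    *,
    theta: float = 0.5,
    onset_drop_K: float = 5.0,
) -> float | None:
    """Crystallization time (in the units of ``weekly_times``) from a weekly
    DSC trajectory.

    ``"enthalpy-fraction"`` (default): first time the above-Tg exotherm
    enthalpy falls below ``theta`` times its initial value, linearly
    interpolated between adjacent measurements; the enthalpy tracks the
    remaining amorphous fraction directly.  ``"onset-drop"``: first time the
    exotherm onset temperature has dropped by ``onset_drop_K`` kelvin from
    its initial value.  Returns ``None`` if the threshold is never crossed
    (still amorphous).
    """
    if record.weekly_times.size < 2:
        raise ValueError("need at least two weekly measurements")
    times = record.weekly_times

    if rule == "enthalpy-fraction":
        values = np.array([f.cryst_enthalpy for f in record.weekly_features], dtype=float)
        if not np.isfinite(values[0]):
            raise ValueError("missing initial (week-0) crystallization enthalpy")
        if values[0] == 0.0:
            return 0.0  # already crystalline at the start of storage
        target = theta * values[0]
        crossing = values < target
    elif rule == "onset-drop":
        onsets = np.array(
            [np.nan if f.cryst_onset is None else f.cryst_onset for f in record.weekly_features],
            dtype=float,
        )
        if not np.isfinite(onsets[0]):
            raise ValueError("missing initial (week-0) crystallization onset")
        values = onsets
        target = onsets[0] - onset_drop_K
        crossing = values < target
    else:
        raise ValueError(f"unknown storage rule {rule!r}")

    below = np.where(crossing)[0]
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(times[0])
    v0, v1 = values[j - 1], values[j]
    frac = (v0 - target) / (v0 - v1)
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))
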