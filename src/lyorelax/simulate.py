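"""Synthetic calorimetry data with known ground truth.

No public raw IMC/DSC records exist for this kind of study, so every
pipeline stage is exercised against synthetic data that emulates the
experimental design: five freeze-drying processes differing only in their
freezing step (random nucleation RN, annealed AN1.5/AN3.0, controlled
nucleation CN, quench cooling QN), one formulation, storage at 25 and
40 degC.

The generator produces

- 12-h IMC relaxation records sampled every 2 s for the first hour and
  every 10 s thereafter (60 s for multi-day records), with white noise and
  linear drift;
- extended IMC records carrying crystallization exotherms (two-sided
  Gaussians; optionally doubled with a 2-5 day offset, as pooled vials
  produce);
- deconvolved DSC thermograms (sigmoidal cp step at Tg on the reversing
  curve, downward crystallization exotherm on the total curve);
- weekly storage trajectories in which the above-Tg exotherm enthalpy
  decays as a logistic function of storage time centred on the true
  crystallization time;
- whole studies whose true crystallization times follow the linear law
  ``t_c = a + b * tau_beta + noise``.

All randomness derives from one integer seed through a documented
splitting scheme (CRC32 of the record's role and labels mixed into a
``SeedSequence``), so studies are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crystallization import StorageRecord
from .dsc import DSCFeatures, DSCThermogram
from .imc import PowerTimeSeries
from .mse import MSEParams, power_uW_per_g, tau_beta

__all__ = [
    "ProcessCondition",
    "ExothermShape",
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "rng_for",
    "sample_grid",
    "generate_imc_curve",
    "generate_dsc_thermogram",
    "generate_storage_trajectory",
    "generate_study",
]


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Child generator for one record: the study seed plus a CRC32 of the
    stringified keys, combined in a ``SeedSequence``."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


@dataclass(frozen=True)
class ProcessCondition:
    """True state of one freeze-drying process variant."""

    name: str
    mse: MSEParams
    tg: float  # degC
    delta_cp: float = 0.5  # J/(g*K)


@dataclass(frozen=True)
class ExothermShape:
    """Two-sided Gaussian crystallization exotherm in an IMC record: a fast
    rise and a slower fall around the maximum.

    The default height makes the peak area ~45 J/g — the crystallization
    enthalpy the DSC exotherm carries — so the IMC and DSC pictures of the
    same event are energetically consistent:
    45 J/g * (1e6/3600) / (sqrt(pi/2) * (6 + 18) h) ~ 415 uW/g.
    """

    height_uW_per_g: float = 415.0
    rise_h: float = 6.0
    fall_h: float = 18.0


def _default_processes() -> tuple[ProcessCondition, ...]:
    # tau1 = 1 h so tau_beta == tau0; CN relaxes fastest, QN slowest,
    # spanning the realistic 1-5 h range at 40 degC
    beta = 0.15
    return (
        ProcessCondition("CN", MSEParams(1.2, 1.0, beta), tg=49.0),
        ProcessCondition("AN1.5", MSEParams(2.0, 1.0, beta), tg=60.1),
        ProcessCondition("RN", MSEParams(2.6, 1.0, beta), tg=60.2),
        ProcessCondition("AN3.0", MSEParams(3.3, 1.0, beta), tg=60.2),
        ProcessCondition("QN", MSEParams(4.8, 1.0, beta), tg=72.0),
    )


@dataclass
class SyntheticStudyConfig:
    """Study design and noise model for the synthetic generator.

    The crystallization law ``t_c = cryst_intercept_h +
    cryst_slope_h_per_h * tau_beta + N(0, cryst_noise_sd_h)`` uses a slope
    of 601.35 h of crystallization time per hour of relaxation time; the
    noise standard deviation of 36 h reflects the few-day crystallization
    scatter between individual vials.
    """

    processes: tuple[ProcessCondition, ...] = field(default_factory=_default_processes)
    formulation: str = "sucrose_protein_2mg"
    storage_temperatures: tuple[float, ...] = (25.0, 40.0)
    fast_path_temperatures: tuple[float, ...] = (40.0,)
    #: tau_beta multiplier per storage temperature (mobility slows below 40 degC)
    temperature_tau_factor: dict = field(default_factory=lambda: {40.0: 1.0, 25.0: 2.5})
    cryst_intercept_h: float = 0.0
    cryst_slope_h_per_h: float = 601.35
    cryst_noise_sd_h: float = 36.0
    exotherm: ExothermShape = field(default_factory=ExothermShape)
    pooled_vial_double_peak: bool = False
    double_peak_offset_d: tuple[float, float] = (2.0, 5.0)
    cn_early_transient: bool = False
    moisture_factors: dict | None = None
    # IMC acquisition and noise
    imc_noise_sd_uW: float = 1.0
    imc_drift_uW_per_h: float = 0.02
    sampling_first_hour_s: float = 2.0
    sampling_rest_s: float = 10.0
    sampling_long_s: float = 60.0
    long_record_threshold_h: float = 24.0
    # DSC shape
    dsc_grid_step_K: float = 0.1
    dsc_heating_rate_K_min: float = 2.0
    tg_width_K: float = 3.0  # 10-90% width of the cp step
    cryst_onset_C: float = 85.0
    cryst_onset_total_drop_K: float = 15.0
    cryst_enthalpy_J_per_g: float = 45.0
    cryst_peak_sigma_K: float = 2.0
    dsc_snr: float = 50.0
    # storage
    weekly_interval_d: float = 7.0
    storage_transition_width_d: float = 1.0  # logistic scale of the amorphous-fraction decay
    seed: int = 0

    def process(self, name: str) -> ProcessCondition:
        for p in self.processes:
            if p.name == name:
                return p
        raise KeyError(f"unknown process {name!r}")


def sample_grid(config: SyntheticStudyConfig, duration_h: float) -> np.ndarray:
    """Acquisition time grid in hours: 2 s steps for the first hour, then
    10 s (or a coarser long-record interval beyond one day's duration)."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    first = np.arange(0.0, min(3600.0, duration_h * 3600.0), config.sampling_first_hour_s)
    if duration_h <= 1.0:
        return first / 3600.0
    rest_step = (
        config.sampling_rest_s
        if duration_h <= config.long_record_threshold_h
        else config.sampling_long_s
    )
    rest = np.arange(3600.0, duration_h * 3600.0, rest_step)
    return np.concatenate([first, rest]) / 3600.0


def _asym_gauss(t, center, height, w_left, w_right):
    w = np.where(t < center, w_left, w_right)
    return height * np.exp(-0.5 * ((t - center) / w) ** 2)


def generate_imc_curve(
    config: SyntheticStudyConfig,
    process: "str | ProcessCondition",
    *,
    temperature: float = 40.0,
    duration_h: float = 12.0,
    cryst_times_h: "list[float] | None" = None,
    params: MSEParams | None = None,
    seed: int | None = None,
):
    """One IMC record for a process, with optional crystallization exotherms.

    Returns ``(PowerTimeSeries, truth)`` where ``truth`` records the
    generating parameters, the true tau_beta and the exotherm centres.
    With all noise terms zero and no exotherm the record equals the MSE
    power model exactly on the sampling grid.
    """
    proc = config.process(process) if isinstance(process, str) else process
    if params is None:
        params = proc.mse
    if temperature >= proc.tg:
        raise ValueError(f"storage temperature {temperature} degC is above Tg {proc.tg} degC")
    dh = (proc.tg - temperature) * proc.delta_cp
    if cryst_times_h:
        beyond = [tc for tc in cryst_times_h if tc > duration_h]
        if beyond:
            raise ValueError(
                f"exotherm time(s) {beyond} h fall beyond the {duration_h} h record"
            )
    rng = rng_for(config.seed if seed is None else seed, "imc", proc.name, temperature, duration_h)

    t = sample_grid(config, duration_h)
    p = power_uW_per_g(t, params, dh)
    for tc in cryst_times_h or []:
        p = p + _asym_gauss(
            t, tc, config.exotherm.height_uW_per_g, config.exotherm.rise_h, config.exotherm.fall_h
        )
    if config.cn_early_transient and proc.name == "CN":
        p = p + 20.0 * np.exp(-0.5 * ((t - 0.58) / 0.15) ** 2)
        p = p - 5.0 * np.exp(-0.5 * ((t - 84.0) / 24.0) ** 2)
    p = p + config.imc_drift_uW_per_h * t
    if config.imc_noise_sd_uW > 0:
        p = p + rng.normal(0.0, config.imc_noise_sd_uW, size=t.shape)

    series = PowerTimeSeries(
        times=t,
        powers=p,
        temperature=temperature,
        sample_id=f"{proc.name}@{temperature:g}C",
        process_label=proc.name,
        formulation_label=config.formulation,
    )
    truth = {
        "process": proc.name,
        "temperature_C": temperature,
        "params": params,
        "tau_beta_h": tau_beta(params),
        "delta_h_r_inf_J_per_g": dh,
        "tg_C": proc.tg,
        "delta_cp_J_per_gK": proc.delta_cp,
        "cryst_times_h": list(cryst_times_h or []),
    }
    return series, truth


def generate_dsc_thermogram(
    config: SyntheticStudyConfig,
    *,
    crystallized_fraction: float = 0.0,
    tg: float = 60.2,
    delta_cp: float = 0.5,
    onset_C: float | None = None,
    enthalpy_J_per_g: float | None = None,
    heating_rate: float | None = None,
    seed: int | None = None,
):
    """One deconvolved thermogram with ground truth.

    The total-curve exotherm enthalpy scales with ``1 -
    crystallized_fraction``; a fully crystallized sample shows no exotherm.
    The Gaussian peak is placed so that its tangent-method onset equals
    ``onset_C`` exactly (onset = centre - 2 sigma for a Gaussian).
    """
    if not 0.0 <= crystallized_fraction <= 1.0:
        raise ValueError("crystallized_fraction must lie in [0, 1]")
    rate = config.dsc_heating_rate_K_min if heating_rate is None else heating_rate
    onset = config.cryst_onset_C if onset_C is None else onset_C
    e0 = config.cryst_enthalpy_J_per_g if enthalpy_J_per_g is None else enthalpy_J_per_g
    rng = rng_for(
        config.seed if seed is None else seed, "dsc", tg, crystallized_fraction, onset, rate
    )

    lo = tg - 40.0
    hi = max(onset + 30.0, tg + 40.0)
    T = np.arange(lo, hi, config.dsc_grid_step_K)
    if not (T[0] + 25.0 < tg < T[-1] - 25.0):
        raise ValueError(f"Tg {tg} degC outside the generated temperature window")

    rate_K_s = rate / 60.0
    step = delta_cp * rate_K_s  # W/g
    w = config.tg_width_K / np.log(81.0)  # logistic scale from the 10-90% width
    sigmoid = 1.0 / (1.0 + np.exp(-(T - tg) / w))
    baseline = 0.02 + 1e-4 * (T - T[0])
    reversing = baseline + step * sigmoid

    total = reversing.copy()
    e_eff = e0 * (1.0 - crystallized_fraction)
    sig = config.cryst_peak_sigma_K
    mu = onset + 2.0 * sig
    if e_eff > 0:
        peak_height = e_eff * rate_K_s / (sig * np.sqrt(2.0 * np.pi))  # W/g
        total = total - peak_height * np.exp(-0.5 * ((T - mu) / sig) ** 2)

    noise_sd = step / config.dsc_snr if config.dsc_snr > 0 else 0.0
    if noise_sd > 0:
        reversing = reversing + rng.normal(0.0, noise_sd, size=T.shape)
        total = total + rng.normal(0.0, noise_sd, size=T.shape)

    thermo = DSCThermogram(
        temperatures=T, reversing_signal=reversing, total_signal=total, heating_rate=rate
    )
    truth = {
        "tg_C": tg,
        "delta_cp_J_per_gK": delta_cp,
        "cryst_onset_C": onset if e_eff > 0 else None,
        "cryst_peak_T_C": mu if e_eff > 0 else None,
        "cryst_enthalpy_J_per_g": e_eff,
        "crystallized_fraction": crystallized_fraction,
    }
    return thermo, truth


def generate_storage_trajectory(
    config: SyntheticStudyConfig,
    process: "str | ProcessCondition",
    *,
    temperature: float = 25.0,
    cryst_time_d: float = 60.0,
    n_weeks: int | None = None,
    enthalpy_rel_noise: float = 0.02,
    seed: int | None = None,
):
    """Weekly DSC-feature trajectory of one stored sample.

    The amorphous fraction decays logistically around the true
    crystallization time ``cryst_time_d``; the exotherm enthalpy follows it
    and the exotherm onset drifts down proportionally.  Returns
    ``(StorageRecord, truth)``.
    """
    proc = config.process(process) if isinstance(process, str) else process
    if n_weeks is None:
        n_weeks = int(np.ceil(cryst_time_d / config.weekly_interval_d)) + 4
    rng = rng_for(
        config.seed if seed is None else seed, "storage", proc.name, temperature, cryst_time_d
    )
    times = np.arange(n_weeks + 1) * config.weekly_interval_d
    w = config.storage_transition_width_d
    amorphous = 1.0 / (1.0 + np.exp((times - cryst_time_d) / w))
    e0 = config.cryst_enthalpy_J_per_g
    enthalpies = e0 * amorphous * (1.0 + rng.normal(0.0, enthalpy_rel_noise, size=times.shape))
    enthalpies = np.clip(enthalpies, 0.0, None)
    onsets = config.cryst_onset_C - config.cryst_onset_total_drop_K * (1.0 - amorphous)
    features = [
        DSCFeatures(
            tg_midpoint=proc.tg,
            tg_onset=proc.tg - 2.0,
            delta_cp=proc.delta_cp,
            cryst_onset=float(onsets[i]) if enthalpies[i] > 0 else None,
            cryst_peak_T=float(onsets[i] + 2 * config.cryst_peak_sigma_K)
            if enthalpies[i] > 0
            else None,
            cryst_enthalpy=float(enthalpies[i]),
            crystalline_flag=enthalpies[i] == 0.0,
        )
        for i in range(times.size)
    ]
    record = StorageRecord(
        sample_id=f"{proc.name}@{temperature:g}C",
        storage_temperature=temperature,
        weekly_times=times,
        weekly_features=features,
    )
    truth = {
        "process": proc.name,
        "temperature_C": temperature,
        "cryst_time_d": cryst_time_d,
        "enthalpy_week0_J_per_g": e0,
    }
    return record, truth


@dataclass
class SyntheticStudy:
    """A full multi-process study: IMC records and storage trajectories per
    (process, temperature) plus a truth table sufficient to recompute every
    expected pipeline output."""

    config: SyntheticStudyConfig
    imc_records: dict
    storage_records: dict
    truth: pd.DataFrame


def generate_study(config: SyntheticStudyConfig, seed: int | None = None) -> SyntheticStudy:
    """Generate the whole study.

    For each process and storage temperature a true crystallization time is
    drawn from the linear law on the (temperature-scaled) true tau_beta.
    Fast-path temperatures get an extended IMC record containing the
    exotherm; slow-path temperatures get the plain 12-h relaxation record
    plus a weekly DSC trajectory whose enthalpy decay encodes the true
    time.
    """
    seed = config.seed if seed is None else seed
    imc_records: dict = {}
    storage_records: dict = {}
    rows = []
    for temp in config.storage_temperatures:
        factor = config.temperature_tau_factor.get(temp, 1.0)
        fast = temp in config.fast_path_temperatures
        for proc in config.processes:
            moisture = (config.moisture_factors or {}).get(proc.name, 1.0)
            params_t = MSEParams(
                tau0=proc.mse.tau0 * factor * moisture, tau1=proc.mse.tau1, beta=proc.mse.beta
            )
            tb_true = tau_beta(params_t)
            rng = rng_for(seed, "law", proc.name, temp)
            t_c = (
                config.cryst_intercept_h
                + config.cryst_slope_h_per_h * tb_true
                + rng.normal(0.0, config.cryst_noise_sd_h)
            )
            t_c = max(t_c, 48.0)
            cryst_times = None
            duration = 12.0
            if fast:
                cryst_times = [t_c]
                if config.pooled_vial_double_peak:
                    off = rng.uniform(*config.double_peak_offset_d) * 24.0
                    cryst_times.append(t_c + off)
                duration = max(cryst_times) * 1.15 + 48.0
            series, _ = generate_imc_curve(
                config,
                proc,
                temperature=temp,
                duration_h=duration,
                cryst_times_h=cryst_times,
                params=params_t,
                seed=seed,
            )
            imc_records[(proc.name, temp)] = series
            record, _ = generate_storage_trajectory(
                config, proc, temperature=temp, cryst_time_d=t_c / 24.0, seed=seed
            )
            storage_records[(proc.name, temp)] = record
            rows.append(
                {
                    "process": proc.name,
                    "formulation": config.formulation,
                    "temperature_C": temp,
                    "path": "imc" if fast else "storage",
                    "tau0_true_h": params_t.tau0,
                    "tau1_true_h": params_t.tau1,
                    "beta_true": params_t.beta,
                    "tau_beta_true_h": tb_true,
                    "tg_C": proc.tg,
                    "delta_cp_J_per_gK": proc.delta_cp,
                    "cryst_time_true_h": t_c,
                }
            )
    truth = pd.DataFrame(rows)
    return SyntheticStudy(
        config=replace(config, seed=seed),
        imc_records=imc_records,
        storage_records=storage_records,
        truth=truth,
    )
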