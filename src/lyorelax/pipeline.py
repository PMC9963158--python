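"""End-to-end orchestration: relaxation fits -> crystallization times ->
correlation models, on an in-memory synthetic study or a directory of CSVs.

Per-sample failures (a record that does not fit, a missing Tg) are collected
and reported; the remaining samples are still processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .correlation import CorrelationModel, correlate_table
from .crystallization import detect_exotherm_peaks, imc_crystallization_time, storage_crystallization_time
from .imc import DEFAULT_START, MSEParams, fit_mse, fit_report, preprocess
from .io import read_power_timeseries, read_weekly_features, write_json, write_table
from .mse import ThermalContext
from .simulate import SyntheticStudy

__all__ = ["PipelineOptions", "PipelineResult", "run_pipeline", "save_study", "load_study_dir"]


@dataclass
class PipelineOptions:
    """Stage options with their documented defaults."""

    trim_start_h: float = 0.0
    fit_duration_h: float = 12.0
    starts: MSEParams = field(default_factory=lambda: DEFAULT_START)
    tau_beta_convention: str = "kww"
    peak_policy: str = "first"
    storage_rule: str = "enthalpy-fraction"
    theta: float = 0.5


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    results: pd.DataFrame  # one row per sample: tau_beta_h, cryst_time_h, path
    models: dict  # (formulation, temperature) -> CorrelationModel
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and bool(self.models)


def run_pipeline(study, options: PipelineOptions | None = None) -> PipelineResult:
    """Run the whole analysis chain on a :class:`SyntheticStudy` or on a
    directory previously written by :func:`save_study`."""
    if not isinstance(study, SyntheticStudy):
        study = load_study_dir(study)
    opts = options or PipelineOptions()
    fits = []
    rows = []
    errors = []
    meta = study.truth.set_index(["process", "temperature_C"])
    for (proc, temp), series in study.imc_records.items():
        info = meta.loc[(proc, temp)]
        try:
            if pd.isna(info["tg_C"]):
                raise ValueError("missing Tg")
            ctx = ThermalContext(
                temperature=temp, tg=float(info["tg_C"]), delta_cp=float(info["delta_cp_J_per_gK"])
            )
            head = preprocess(series, opts.trim_start_h, opts.fit_duration_h)
            fit = fit_mse(head, ctx, opts.starts, tau_beta_convention=opts.tau_beta_convention)
            fits.append(fit)
            if info["path"] == "imc":
                peaks = detect_exotherm_peaks(series, ctx)
                t_c = imc_crystallization_time(peaks, opts.peak_policy)
            else:
                record = study.storage_records[(proc, temp)]
                t_c_days = storage_crystallization_time(record, opts.storage_rule, theta=opts.theta)
                t_c = None if t_c_days is None else t_c_days * 24.0
            rows.append(
                {
                    "process": proc,
                    "formulation": info["formulation"],
                    "temperature_C": temp,
                    "path": info["path"],
                    "tau_beta_h": fit.tau_beta,
                    "cryst_time_h": t_c,
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # error isolation: keep processing other samples
            errors.append({"process": proc, "temperature_C": temp, "error": str(exc)})
    results = pd.DataFrame(rows)
    models: dict = {}
    if len(results):
        usable = results.dropna(subset=["tau_beta_h", "cryst_time_h"])
        if len(usable):
            models = correlate_table(usable)
    return PipelineResult(fits=fit_report(fits), results=results, models=models, errors=errors)


def _slug(proc: str, temp: float) -> str:
    return f"{proc.replace('.', 'p')}_{temp:g}C".replace("/", "-")


def save_study(study: SyntheticStudy, out_dir) -> Path:
    """Write a study to disk in the CSV dialects the readers accept:
    ``truth.csv``, one ``imc_*.csv`` per record and one ``storage_*.csv``
    per trajectory, plus a provenance JSON echoing the configuration."""
    from .io import write_power_timeseries, write_weekly_features

    out = Path(out_dir)
    (out / "imc").mkdir(parents=True, exist_ok=True)
    (out / "storage").mkdir(parents=True, exist_ok=True)
    write_table(study.truth, out / "truth.csv")
    for (proc, temp), series in study.imc_records.items():
        write_power_timeseries(series, out / "imc" / f"{_slug(proc, temp)}.csv", time_unit="s")
    for (proc, temp), record in study.storage_records.items():
        write_weekly_features(record, out / "storage" / f"{_slug(proc, temp)}.csv")
    write_json({"n_records": len(study.imc_records)}, out / "study.json",
               seed=study.config.seed, config=study.config)
    return out


def load_study_dir(path) -> SyntheticStudy:
    """Reload a study written by :func:`save_study`."""
    from .simulate import SyntheticStudyConfig

    path = Path(path)
    truth = pd.read_csv(path / "truth.csv")
    imc_records = {}
    storage_records = {}
    for _, row in truth.iterrows():
        proc, temp = row["process"], float(row["temperature_C"])
        slug = _slug(proc, temp)
        imc_records[(proc, temp)] = read_power_timeseries(
            path / "imc" / f"{slug}.csv",
            time_unit="s",
            temperature=temp,
            sample_id=f"{proc}@{temp:g}C",
            process_label=proc,
            formulation_label=row["formulation"],
        )
        storage_csv = path / "storage" / f"{slug}.csv"
        if storage_csv.exists():
            storage_records[(proc, temp)] = read_weekly_features(
                storage_csv, sample_id=f"{proc}@{temp:g}C", storage_temperature=temp
            )
    return SyntheticStudy(
        config=SyntheticStudyConfig(), imc_records=imc_records,
        storage_records=storage_records, truth=truth,
    )
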