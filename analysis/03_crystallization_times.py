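#!/usr/bin/env python
"""Determine each sample's crystallization time.

Fast-path samples (40 degC): detect the crystallization exotherm in the
long IMC record and take the time of its maximum.  Slow-path samples
(25 degC): find when the weekly DSC exotherm enthalpy drops below half its
initial value (linearly interpolated).  Writes
results/crystallization_times.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lyorelax.crystallization import (
    detect_exotherm_peaks,
    imc_crystallization_time,
    storage_crystallization_time,
)
from lyorelax.io import write_table
from lyorelax.mse import ThermalContext
from lyorelax.pipeline import load_study_dir


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--out", type=Path, default=Path("results/crystallization_times.csv"))
    parser.add_argument("--policy", default="first", help="peak policy for double exotherms")
    parser.add_argument("--theta", type=float, default=0.5, help="enthalpy-fraction threshold")
    args = parser.parse_args()

    study = load_study_dir(args.study)
    meta = study.truth.set_index(["process", "temperature_C"])
    rows = []
    for (proc, temp), series in study.imc_records.items():
        info = meta.loc[(proc, temp)]
        if info["path"] == "imc":
            ctx = ThermalContext(temperature=temp, tg=float(info["tg_C"]),
                                 delta_cp=float(info["delta_cp_J_per_gK"]))
            peaks = detect_exotherm_peaks(series, ctx)
            t_c = imc_crystallization_time(peaks, args.policy)
            n_peaks = len(peaks)
        else:
            record = study.storage_records[(proc, temp)]
            t_c_days = storage_crystallization_time(record, theta=args.theta)
            t_c = None if t_c_days is None else t_c_days * 24.0
            n_peaks = None
        rows.append({
            "process": proc,
            "formulation": info["formulation"],
            "temperature_C": temp,
            "path": info["path"],
            "n_exotherms": n_peaks,
            "cryst_time_h": t_c,
            "cryst_time_d": None if t_c is None else t_c / 24.0,
        })
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_table(table, args.out)
    print(f"crystallization times for {len(table)} samples -> {args.out}")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
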