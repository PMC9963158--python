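#!/usr/bin/env python
"""Correlate relaxation time with crystallization time and predict.

Joins the fit table with the crystallization times, fits one OLS line per
(formulation, storage temperature) group, reports r-squared, the slope
(hours of crystallization time gained per hour of tau_beta) and the Kendall
rank agreement, then demonstrates prediction for a hypothetical new process
in the middle of the tau_beta range.  Writes results/correlation.csv and
results/models.json.
"""

import argparse
from pathlib import Path

import pandas as pd

from lyorelax.correlation import correlate_table, predict_crystallization_time
from lyorelax.io import write_json, write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
    parser.add_argument("--times", type=Path, default=Path("results/crystallization_times.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    fits = pd.read_csv(args.fits)
    times = pd.read_csv(args.times)
    joined = fits.merge(times, on=["process", "formulation", "temperature_C"])
    usable = joined.dropna(subset=["tau_beta_h", "cryst_time_h"])
    models = correlate_table(usable)

    rows = []
    for (form, temp), model in models.items():
        mid_tau = 0.5 * (model.x_min + model.x_max)
        pred = predict_crystallization_time(model, mid_tau)
        rows.append({
            "formulation": form,
            "temperature_C": temp,
            "n": model.n,
            "slope_h_per_h": model.slope,
            "intercept_h": model.intercept,
            "r2": model.r2,
            "kendall_tau": model.kendall_tau,
            "example_tau_beta_h": mid_tau,
            "predicted_cryst_time_h": pred.point,
            "prediction_lower_h": pred.lower,
            "prediction_upper_h": pred.upper,
        })
        print(
            f"{form} @ {temp:g} degC (n={model.n}): "
            f"r2={model.r2:.4f}, slope={model.slope:.1f} h per h of tau_beta, "
            f"Kendall tau={model.kendall_tau:.2f}"
        )
        print(
            f"  a new process with tau_beta = {mid_tau:.2f} h is predicted to "
            f"crystallize after {pred.point / 24:.1f} d "
            f"[{pred.lower / 24:.1f}, {pred.upper / 24:.1f}] d"
        )
    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame(rows), args.out_dir / "correlation.csv")
    write_json(
        {f"{form}@{temp:g}C": model for (form, temp), model in models.items()},
        args.out_dir / "models.json",
    )


if __name__ == "__main__":
    main()
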