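"""Preprocessing and constrained MSE fitting of IMC records."""

import numpy as np
import pytest

from lyorelax.imc import DEFAULT_START, MSEParams, PowerTimeSeries, fit_mse, fit_report, preprocess
from lyorelax.mse import ThermalContext, power_uW_per_g, tau_beta
from lyorelax.simulate import SyntheticStudyConfig, sample_grid
from conftest import random_valid_params

TRUE = MSEParams(2.0, 1.0, 0.1)
CTX = ThermalContext(temperature=25.0, tg=60.21, delta_cp=0.5)  # dHr_inf = 17.605 J/g


def make_series(params=TRUE, noise_sd=0.0, seed=0, dh=None):
    grid = sample_grid(SyntheticStudyConfig(), 12.0)
    dh = CTX.delta_h_r_inf if dh is None else dh
    p = power_uW_per_g(grid, params, dh)
    if noise_sd:
        p = p + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    return PowerTimeSeries(times=grid, powers=p)


class TestSeriesAndPreprocess:
    def test_acquisition_scheme_point_count(self):
        # 2 s steps for 1 h then 10 s steps for 11 h: 1800 + 3960 points
        assert len(make_series()) == 5760

    def test_identity_trim(self):
        s = make_series()
        out = preprocess(s, 0.0, 12.0)
        np.testing.assert_array_equal(out.times, s.times)

    def test_trim_removes_early_points_without_rezeroing(self):
        out = preprocess(make_series(), 0.1, 12.0)
        assert out.times[0] >= 0.1
        assert out.times[0] == pytest.approx(0.1, abs=2 / 3600)  # origin preserved

    def test_empty_trim_errors(self):
        with pytest.raises(ValueError):
            preprocess(make_series(), 20.0, 24.0)
        with pytest.raises(ValueError):
            preprocess(make_series(), 5.0, 4.0)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PowerTimeSeries(times=[0.0, 1.0, 1.0], powers=[1.0, 2.0, 3.0])


class TestFit:
    def test_noiseless_recovery_from_perturbed_start(self):
        # generate at the conventional start values, initialise at 1.5x each
        fit = fit_mse(make_series(), CTX, starts=TRUE.scaled(1.5))
        assert fit.converged
        assert fit.params.tau0 == pytest.approx(TRUE.tau0, rel=1e-3)
        assert fit.params.tau1 == pytest.approx(TRUE.tau1, rel=1e-3)
        assert fit.params.beta == pytest.approx(TRUE.beta, rel=1e-3)
        assert fit.tau_beta == pytest.approx(tau_beta(TRUE), rel=1e-3)

    def test_noiseless_self_consistency_random_truths(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            truth = random_valid_params(rng, beta_min=0.08)
            fit = fit_mse(make_series(params=truth), CTX, starts=DEFAULT_START)
            assert fit.converged
            assert fit.tau_beta == pytest.approx(tau_beta(truth), rel=1e-3)

    def test_noisy_recovery_median_tau_beta_error(self):
        # 1% of P(0) white noise, 20 seeds: median tau_beta error < 5%
        p0 = power_uW_per_g(0.0, TRUE, CTX.delta_h_r_inf)
        errs = []
        for seed in range(20):
            fit = fit_mse(make_series(noise_sd=0.01 * p0, seed=seed), CTX)
            errs.append(abs(fit.tau_beta - tau_beta(TRUE)) / tau_beta(TRUE))
        assert np.median(errs) < 0.05

    def test_noise_degrades_recovery_monotonically(self):
        p0 = power_uW_per_g(0.0, TRUE, CTX.delta_h_r_inf)
        medians = []
        for level in (0.005, 0.01, 0.02):
            errs = [
                abs(fit_mse(make_series(noise_sd=level * p0, seed=s), CTX).tau_beta - tau_beta(TRUE))
                for s in range(10)
            ]
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_zero_record_flags_non_convergence(self):
        s = PowerTimeSeries(times=np.linspace(0, 12, 100), powers=np.zeros(100))
        fit = fit_mse(s, CTX)
        assert not fit.converged
        assert fit.params is None and fit.tau_beta is None

    def test_determinism(self):
        f1 = fit_mse(make_series(noise_sd=1.0, seed=3), CTX)
        f2 = fit_mse(make_series(noise_sd=1.0, seed=3), CTX)
        assert (f1.params.tau0, f1.params.tau1, f1.params.beta) == (
            f2.params.tau0, f2.params.tau1, f2.params.beta,
        )

    def test_constraints_hold_on_adversarial_inputs(self):
        # the reparameterisation cannot leave the admissible region
        t = np.linspace(0.01, 12, 200)
        rng = np.random.default_rng(9)
        for powers in (
            rng.normal(5, 2, t.size),  # pure noise
            np.linspace(1, 50, t.size),  # increasing ramp
            np.exp(-t / 0.01) * 1e4 + 1,  # near-singular decay
        ):
            fit = fit_mse(PowerTimeSeries(times=t, powers=powers), CTX)
            if fit.params is not None:
                assert fit.params.tau0 > fit.params.tau1 > 0
                assert 0 < fit.params.beta <= 1

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            fit_mse(PowerTimeSeries(times=np.linspace(0, 1, 5), powers=np.ones(5)), CTX)


class TestFitReport:
    def test_converged_and_failed_rows(self):
        good = fit_mse(make_series(), CTX)
        bad = fit_mse(PowerTimeSeries(times=np.linspace(0, 12, 100), powers=np.zeros(100)), CTX)
        table = fit_report([good, bad])
        assert list(table["converged"]) == [True, False]
        assert np.isnan(table.loc[1, "tau0_h"])
        assert table.loc[0, "tau_beta_h"] == pytest.approx(good.tau_beta)

    def test_roundtrip_through_csv_preserves_12_digits(self, tmp_path):
        from lyorelax.io import write_table
        import pandas as pd

        table = fit_report(fit_mse(make_series(noise_sd=0.5, seed=1), CTX))
        path = tmp_path / "fits.csv"
        write_table(table, path)
        back = pd.read_csv(path)
        for col in ("tau0_h", "tau1_h", "beta", "tau_beta_h"):
            assert back.loc[0, col] == pytest.approx(table.loc[0, col], rel=1e-11)
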