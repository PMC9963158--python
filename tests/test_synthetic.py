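"""The synthetic-data generator: determinism, noise-off identities and
round-trip fidelity against the extraction stages."""

import numpy as np
import pandas as pd
import pytest

from lyorelax.dsc import extract_crystallization_event, extract_glass_transition
from lyorelax.mse import power_uW_per_g
from lyorelax.simulate import (
    SyntheticStudyConfig,
    generate_dsc_thermogram,
    generate_imc_curve,
    generate_storage_trajectory,
    generate_study,
    sample_grid,
)


class TestIMCGeneration:
    def test_noise_off_identity_with_power_model(self, quiet_config):
        series, truth = generate_imc_curve(quiet_config, "RN", duration_h=12.0)
        expected = power_uW_per_g(series.times, truth["params"], truth["delta_h_r_inf_J_per_g"])
        np.testing.assert_array_equal(series.powers, expected)

    def test_default_12h_scheme_has_5760_samples(self, default_config):
        assert sample_grid(default_config, 12.0).size == 5760

    def test_seeded_runs_are_bit_identical(self, default_config):
        s1, _ = generate_imc_curve(default_config, "QN", duration_h=12.0, seed=11)
        s2, _ = generate_imc_curve(default_config, "QN", duration_h=12.0, seed=11)
        np.testing.assert_array_equal(s1.powers, s2.powers)
        s3, _ = generate_imc_curve(default_config, "QN", duration_h=12.0, seed=12)
        assert not np.array_equal(s1.powers, s3.powers)

    def test_exotherm_beyond_record_errors(self, default_config):
        with pytest.raises(ValueError, match="beyond"):
            generate_imc_curve(default_config, "RN", duration_h=12.0, cryst_times_h=[120.0])

    def test_storage_above_tg_rejected(self, default_config):
        with pytest.raises(ValueError, match="above Tg"):
            generate_imc_curve(default_config, "CN", temperature=55.0)

    def test_long_records_switch_to_coarse_sampling(self, default_config):
        grid = sample_grid(default_config, 48.0)
        assert np.max(np.diff(grid)) == pytest.approx(60.0 / 3600.0)


class TestDSCGeneration:
    def test_fully_crystallized_sample_has_no_exotherm(self, default_config):
        thermo, truth = generate_dsc_thermogram(default_config, crystallized_fraction=1.0, seed=1)
        assert truth["cryst_enthalpy_J_per_g"] == 0.0
        assert extract_crystallization_event(thermo)[2] == 0.0

    def test_roundtrip_enthalpy_recovery(self, default_config):
        thermo, _ = generate_dsc_thermogram(
            default_config, crystallized_fraction=0.0, enthalpy_J_per_g=45.0, seed=2
        )
        assert extract_crystallization_event(thermo)[2] == pytest.approx(45.0, rel=0.02)

    def test_roundtrip_tg_recovery_for_fast_nucleated_sample(self, default_config):
        thermo, _ = generate_dsc_thermogram(default_config, tg=48.98, seed=3)
        _, mid, _ = extract_glass_transition(thermo)
        assert mid == pytest.approx(48.98, abs=0.2)

    def test_invalid_fraction_rejected(self, default_config):
        with pytest.raises(ValueError):
            generate_dsc_thermogram(default_config, crystallized_fraction=1.2)


class TestStudyGeneration:
    def test_same_seed_identical_truth_tables(self, default_config):
        t1 = generate_study(default_config, seed=5).truth
        t2 = generate_study(default_config, seed=5).truth
        pd.testing.assert_frame_equal(t1, t2)

    def test_default_tau_beta_ordering_cn_shortest_qn_longest(self, quiet_config):
        truth = generate_study(quiet_config, seed=1).truth
        at40 = truth[truth.temperature_C == 40.0].set_index("process")["tau_beta_true_h"]
        assert at40.idxmin() == "CN" and at40.idxmax() == "QN"

    def test_crystallization_law_in_truth_table(self, quiet_config):
        truth = generate_study(quiet_config, seed=2).truth
        cfg = quiet_config
        expected = cfg.cryst_intercept_h + cfg.cryst_slope_h_per_h * truth["tau_beta_true_h"]
        np.testing.assert_allclose(truth["cryst_time_true_h"], expected)

    def test_fast_and_slow_paths_assigned_by_temperature(self, quiet_config):
        truth = generate_study(quiet_config, seed=3).truth
        assert set(truth.loc[truth.temperature_C == 40.0, "path"]) == {"imc"}
        assert set(truth.loc[truth.temperature_C == 25.0, "path"]) == {"storage"}

    def test_moisture_factor_shifts_tau_and_time_proportionally(self, quiet_config):
        from dataclasses import replace

        wet = replace(quiet_config, moisture_factors={"RN": 1.3})
        dry_truth = generate_study(quiet_config, seed=4).truth.set_index(["process", "temperature_C"])
        wet_truth = generate_study(wet, seed=4).truth.set_index(["process", "temperature_C"])
        ratio_tau = (
            wet_truth.loc[("RN", 40.0), "tau_beta_true_h"]
            / dry_truth.loc[("RN", 40.0), "tau_beta_true_h"]
        )
        ratio_tc = (
            wet_truth.loc[("RN", 40.0), "cryst_time_true_h"]
            / dry_truth.loc[("RN", 40.0), "cryst_time_true_h"]
        )
        assert ratio_tau == pytest.approx(1.3)
        assert ratio_tc == pytest.approx(1.3)  # zero intercept: strict proportionality


class TestStorageTrajectoryGeneration:
    def test_enthalpy_halves_at_true_crystallization_time(self):
        cfg = SyntheticStudyConfig()
        record, truth = generate_storage_trajectory(
            cfg, "RN", cryst_time_d=35.0, enthalpy_rel_noise=0.0, seed=6
        )
        e = np.array([f.cryst_enthalpy for f in record.weekly_features])
        # logistic amorphous fraction: enthalpy before >> after the truth
        before = record.weekly_times < 28.0
        after = record.weekly_times > 42.0
        assert e[before].min() > 0.9 * truth["enthalpy_week0_J_per_g"]
        assert e[after].max() < 0.1 * truth["enthalpy_week0_J_per_g"]

    def test_onset_drifts_down_as_sample_crystallizes(self):
        record, _ = generate_storage_trajectory(
            SyntheticStudyConfig(), "RN", cryst_time_d=21.0, seed=7
        )
        onsets = [f.cryst_onset for f in record.weekly_features if f.cryst_onset is not None]
        assert onsets[-1] < onsets[0]
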