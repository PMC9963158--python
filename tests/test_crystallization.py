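"""Crystallization-time determination from IMC exotherms and storage DSC."""

import numpy as np
import pytest

from lyorelax.crystallization import (
    ExothermPeak,
    StorageRecord,
    detect_exotherm_peaks,
    imc_crystallization_time,
    storage_crystallization_time,
)
from lyorelax.dsc import DSCFeatures
from lyorelax.mse import ThermalContext
from lyorelax.simulate import SyntheticStudyConfig, generate_imc_curve

CFG = SyntheticStudyConfig()
CTX40 = ThermalContext(temperature=40.0, tg=72.0, delta_cp=0.5)


def features_from(enthalpies, onsets=None):
    onsets = onsets or [85.0] * len(enthalpies)
    return [
        DSCFeatures(cryst_enthalpy=float(e), cryst_onset=o if e > 0 else None)
        for e, o in zip(enthalpies, onsets)
    ]


class TestExothermDetection:
    def test_single_exotherm_recovered_within_one_interval(self):
        series, _ = generate_imc_curve(CFG, "RN", duration_h=160.0, cryst_times_h=[120.0], seed=5)
        interval = np.max(np.diff(series.times))
        peaks = detect_exotherm_peaks(series, ThermalContext(40.0, 60.2, 0.5))
        assert len(peaks) == 1
        assert abs(peaks[0].time_of_maximum - 120.0) < interval

    def test_pooled_vial_double_peak_times(self):
        # two exotherms 2.5 days apart, as pooled vials produce
        t1, t2 = 18.3 * 24.0, 20.8 * 24.0
        series, _ = generate_imc_curve(CFG, "QN", duration_h=560.0, cryst_times_h=[t1, t2], seed=6)
        interval = np.max(np.diff(series.times))
        peaks = detect_exotherm_peaks(series, CTX40)
        assert len(peaks) == 2
        assert abs(peaks[0].time_of_maximum - t1) < interval
        assert abs(peaks[1].time_of_maximum - t2) < interval

    def test_pure_relaxation_decay_yields_no_peaks(self):
        series, _ = generate_imc_curve(CFG, "RN", duration_h=48.0, seed=7)
        assert detect_exotherm_peaks(series, ThermalContext(40.0, 60.2, 0.5)) == []

    def test_short_record_errors(self):
        series, _ = generate_imc_curve(CFG, "RN", duration_h=2.0, seed=1)
        with pytest.raises(ValueError, match="too short"):
            detect_exotherm_peaks(series, CTX40)

    def test_detection_recall_and_precision_over_seeds(self):
        # default peak height is far above 10x the noise sd: every planted
        # exotherm must be found and nothing else
        hits, extras = 0, 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            tc = float(rng.uniform(60.0, 140.0))
            series, _ = generate_imc_curve(
                CFG, "RN", duration_h=170.0, cryst_times_h=[tc], seed=seed
            )
            peaks = detect_exotherm_peaks(series, ThermalContext(40.0, 60.2, 0.5))
            hits += any(abs(p.time_of_maximum - tc) < 1.0 for p in peaks)
            extras += len(peaks) - 1
        assert hits == 15 and extras == 0

    def test_earlier_truth_gives_earlier_estimate(self):
        times = []
        for tc in (80.0, 100.0, 120.0):
            series, _ = generate_imc_curve(CFG, "RN", duration_h=170.0, cryst_times_h=[tc], seed=2)
            peaks = detect_exotherm_peaks(series, ThermalContext(40.0, 60.2, 0.5))
            times.append(imc_crystallization_time(peaks))
        assert times[0] < times[1] < times[2]


class TestPeakPolicy:
    def test_single_peak(self):
        assert imc_crystallization_time([ExothermPeak(500.0, 10, 10, 5)]) == 500.0

    def test_policies_on_double_peak(self):
        peaks = [ExothermPeak(29.0 * 24, 10, 10, 5.0), ExothermPeak(32.3 * 24, 12, 12, 9.0)]
        assert imc_crystallization_time(peaks, "first") == 29.0 * 24
        assert imc_crystallization_time(peaks, "largest-area") == 32.3 * 24
        assert imc_crystallization_time(peaks, "mean-of-maxima") == pytest.approx(30.65 * 24)

    def test_empty_list_is_none(self):
        assert imc_crystallization_time([]) is None

    def test_unknown_policy_errors(self):
        with pytest.raises(ValueError):
            imc_crystallization_time([ExothermPeak(1, 1, 1, 1)], "median")


class TestStorageRule:
    def test_half_enthalpy_crossing_interpolated(self):
        record = StorageRecord(
            "s", 25.0, weekly_times=[0, 1, 2, 3], weekly_features=features_from([50, 50, 24, 0])
        )
        t = storage_crystallization_time(record, theta=0.5)
        assert t == pytest.approx(1 + 25 / 26)  # crossing between weeks 1 and 2

    def test_constant_enthalpy_still_amorphous(self):
        record = StorageRecord(
            "s", 25.0, weekly_times=[0, 7, 14], weekly_features=features_from([50, 50, 49])
        )
        assert storage_crystallization_time(record) is None

    def test_zero_from_start_is_already_crystalline(self):
        record = StorageRecord(
            "s", 25.0, weekly_times=[0, 7], weekly_features=features_from([0, 0])
        )
        assert storage_crystallization_time(record) == 0.0

    def test_invariant_to_uniform_enthalpy_scaling(self):
        e = [40, 38, 30, 10, 1]
        t1 = storage_crystallization_time(
            StorageRecord("a", 25.0, [0, 7, 14, 21, 28], features_from(e))
        )
        t2 = storage_crystallization_time(
            StorageRecord("b", 25.0, [0, 7, 14, 21, 28], features_from([3 * x for x in e]))
        )
        assert t1 == pytest.approx(t2)

    def test_monotone_in_true_crystallization_time(self):
        from lyorelax.simulate import generate_storage_trajectory

        derived = []
        for tc in (30.0, 50.0, 70.0):
            record, _ = generate_storage_trajectory(CFG, "RN", cryst_time_d=tc, seed=4)
            derived.append(storage_crystallization_time(record))
        assert derived[0] < derived[1] < derived[2]
        # logistic decay centred on the truth: crossing lands near it
        for tc, est in zip((30.0, 50.0, 70.0), derived):
            assert est == pytest.approx(tc, abs=2.0)

    def test_onset_drop_rule(self):
        record = StorageRecord(
            "s",
            25.0,
            weekly_times=[0, 7, 14],
            weekly_features=features_from([50, 40, 30], onsets=[85.0, 83.0, 78.0]),
        )
        t = storage_crystallization_time(record, "onset-drop", onset_drop_K=5.0)
        assert 7.0 < t <= 14.0

    def test_requires_two_measurements(self):
        record = StorageRecord("s", 25.0, weekly_times=[0], weekly_features=features_from([50]))
        with pytest.raises(ValueError):
            storage_crystallization_time(record)
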