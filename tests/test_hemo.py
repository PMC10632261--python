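"""Compression-cycle detection, per-cycle values, CPP and baseline summary."""

import numpy as np
import pandas as pd
import pytest

import cprkit as ck
from cprkit.hemo import (
    baseline_summary,
    detect_cycles,
    extract_cycle_values,
    extract_cycles,
    per_minute_hemo,
)
from cprkit.simulate import HemodynamicRecording


def make_hemo(ap, fs=125.0, cvp=None, t0=0.0):
    n = len(ap)
    return HemodynamicRecording(
        time=t0 + np.arange(n) / fs, ap=np.asarray(ap, float),
        cvp=np.zeros(n) if cvp is None else np.asarray(cvp, float),
        sample_rate=fs,
    )


def match_to_truth(cycles, truth_cycles, half_period=0.29):
    det_t = cycles["t_max_compression"].to_numpy()
    tru_t = truth_cycles["t_max_compression"].to_numpy()
    idx = np.abs(tru_t[None, :] - det_t[:, None]).argmin(axis=1)
    ok = np.abs(det_t - tru_t[idx]) < half_period
    return idx, ok


class TestDetection:
    def test_flatline_yields_no_cycles(self):
        rec = make_hemo(np.full(125 * 30, 40.0))
        assert len(detect_cycles(rec)) == 0

    def test_102_cycles_in_60s_of_ccc(self, ccc_subject):
        _, _, hemo, _, _ = ccc_subject
        cycles = extract_cycles(hemo, 102.0)
        assert (cycles["t_max_compression"] < 60.0).sum() == 102

    def test_sinusoid_peaks_within_one_sample_of_analytic(self):
        fs, f = 125.0, 102.0 / 60.0
        t = np.arange(int(60 * fs)) / fs
        phase = 0.4
        ap = 60 + 50 * np.sin(2 * np.pi * f * t - phase)
        rec = make_hemo(ap, fs)
        cycles = detect_cycles(rec, 102.0)
        t_peaks = rec.time[cycles["i_peak"].to_numpy()]
        # analytic maxima at (pi/2 + phase + 2 pi k) / (2 pi f)
        k = np.round((2 * np.pi * f * t_peaks - phase - np.pi / 2) / (2 * np.pi))
        t_true = (np.pi / 2 + phase + 2 * np.pi * k) / (2 * np.pi * f)
        assert np.max(np.abs(t_peaks - t_true)) <= 1.0 / fs + 1e-9

    def test_no_cycles_inside_302_pauses(self, t302_noise_free):
        cfg, _, hemo, _, truth = t302_noise_free
        cycles = extract_cycles(hemo, 102.0)
        block = cfg.compressions_per_cycle * cfg.compression_period
        phases = cycles["t_max_compression"] % cfg.cycle_period
        assert np.all(phases < block + cfg.compression_period)

    def test_ccc_minute_counts_within_rate_bounds(self, ccc_subject, t302_subject):
        _, _, hemo_c, _, _ = ccc_subject
        _, _, hemo_t, _, _ = t302_subject
        pm_c = per_minute_hemo(extract_cycles(hemo_c, 102.0))
        pm_t = per_minute_hemo(extract_cycles(hemo_t, 102.0))
        assert pm_c["n_cycles"].iloc[:-1].isin([101, 102, 103]).all()
        assert (pm_t["n_cycles"] < pm_c["n_cycles"]).all()


class TestCycleValues:
    def test_cpp_identity_every_cycle(self, ccc_subject):
        _, _, hemo, _, _ = ccc_subject
        cycles = extract_cycles(hemo, 102.0)
        np.testing.assert_array_equal(
            cycles["cpp"], cycles["ap_end_decomp"] - cycles["cvp_end_decomp"]
        )

    def test_identical_channels_give_zero_cpp(self):
        fs, f = 125.0, 1.7
        t = np.arange(int(30 * fs)) / fs
        wave = 60 + 50 * np.sin(2 * np.pi * f * t)
        rec = make_hemo(wave, fs, cvp=wave.copy())
        cycles = extract_cycle_values(rec, detect_cycles(rec, 102.0))
        assert len(cycles) > 0
        np.testing.assert_allclose(cycles["cpp"], 0.0, atol=1e-12)

    def test_end_decomp_arithmetic(self):
        row = pd.Series({"ap_end_decomp": 20.0, "cvp_end_decomp": 5.0})
        assert row["ap_end_decomp"] - row["cvp_end_decomp"] == 15.0

    def test_noise_free_values_match_truth(self, ccc_noise_free):
        _, _, hemo, _, truth = ccc_noise_free
        cycles = extract_cycles(hemo, 102.0)
        idx, ok = match_to_truth(cycles, truth.true_cycle_values)
        assert ok.mean() > 0.999
        tc = truth.true_cycle_values
        for col, tol in [("max_ap", 0.2), ("min_ap", 0.2), ("max_cvp", 0.2),
                         ("min_cvp", 0.2), ("cpp", 0.2)]:
            d = cycles[col].to_numpy()[ok] - tc[col].to_numpy()[idx][ok]
            assert np.abs(d).max() < tol, col

    def test_noisy_values_within_tolerance(self, ccc_subject):
        _, _, hemo, _, truth = ccc_subject
        cycles = extract_cycles(hemo, 102.0)
        idx, ok = match_to_truth(cycles, truth.true_cycle_values)
        tc = truth.true_cycle_values
        for col in ["max_ap", "min_ap", "max_cvp", "min_cvp", "cpp"]:
            d = cycles[col].to_numpy()[ok] - tc[col].to_numpy()[idx][ok]
            assert abs(np.mean(d)) < 1.5, col


class TestPerMinute:
    def test_full_run_twenty_records(self, ccc_subject):
        _, _, hemo, _, _ = ccc_subject
        pm = per_minute_hemo(extract_cycles(hemo, 102.0))
        assert len(pm) == 20

    def test_single_cycle_minute(self):
        cycles = pd.DataFrame([{
            "t_max_compression": 70.0, "max_ap": 100.0, "min_ap": -2.0,
            "max_cvp": 120.0, "min_cvp": 1.0, "cpp": 12.0,
        }])
        pm = per_minute_hemo(cycles, duration_min=3)
        assert pm.loc[2, "mean_max_ap"] == 100.0
        assert pm.loc[2, "n_cycles"] == 1
        assert np.isnan(pm.loc[1, "mean_max_ap"])

    def test_binning_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        n = 200
        cycles = pd.DataFrame({
            "t_max_compression": rng.uniform(0, 600, n),
            "max_ap": rng.normal(120, 10, n), "min_ap": rng.normal(-4, 2, n),
            "max_cvp": rng.normal(150, 10, n), "min_cvp": rng.normal(2, 2, n),
            "cpp": rng.normal(10, 3, n),
        })
        pm = per_minute_hemo(cycles, duration_min=10)
        for m in range(1, 11):
            sel = cycles[(cycles["t_max_compression"] >= 60 * (m - 1))
                         & (cycles["t_max_compression"] < 60 * m)]
            if len(sel):
                assert pm.loc[m, "mean_cpp"] == pytest.approx(sel["cpp"].mean())
                assert pm.loc[m, "n_cycles"] == len(sel)


class TestBaseline:
    def test_constant_pressures_recovered(self):
        fs = 125.0
        n = int(360 * fs)
        rec = make_hemo(np.full(n, 90.0), fs, cvp=np.full(n, 7.0), t0=-360.0)
        bs = baseline_summary(rec, arrest_time=0.0)
        assert bs["map"] == pytest.approx(90.0)
        assert bs["cvp"] == pytest.approx(7.0)

    def test_pulse_train_heart_rate(self, ccc_noise_free):
        cfg, _, hemo, _, truth = ccc_noise_free
        bs = baseline_summary(hemo, arrest_time=-cfg.untreated_vf_duration * 60)
        assert bs["hr"] == pytest.approx(truth.baseline["hr"], abs=1.0)
        assert bs["map"] == pytest.approx(truth.baseline["map"], abs=0.5)
        assert bs["cvp"] == pytest.approx(truth.baseline["cvp"], abs=0.5)

    def test_short_window_rejected(self):
        fs = 125.0
        rec = make_hemo(np.full(int(100 * fs), 90.0), fs, t0=-100.0)
        with pytest.raises(ValueError):
            baseline_summary(rec, arrest_time=0.0)

    def test_passthrough_values(self):
        fs = 125.0
        n = int(360 * fs)
        rec = make_hemo(np.full(n, 90.0), fs, t0=-360.0)
        bs = baseline_summary(rec, 0.0, last_values={"vti": 280.0},
                              baseline_abg={"ph": 7.5})
        assert bs["vti"] == 280.0 and bs["ph"] == 7.5
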