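"""Breath segmentation and per-breath/per-minute feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cprkit as ck
from cprkit.breaths import (
    DetectionParams,
    compute_breath_features,
    detect_breaths,
    extract_breath_features,
    per_minute_means,
)
from cprkit.simulate import VentilationRecording


def make_recording(flow, fs=256.0, paw=None, co2=None):
    n = len(flow)
    t = np.arange(n) / fs
    return VentilationRecording(
        time=t, flow=np.asarray(flow, float),
        paw=np.zeros(n) if paw is None else np.asarray(paw, float),
        co2=np.zeros(n) if co2 is None else np.asarray(co2, float),
        sample_rate=fs,
    )


class TestDetection:
    def test_all_zero_flow_gives_no_breaths(self):
        rec = make_recording(np.zeros(256 * 10))
        assert detect_breaths(rec) == []

    def test_constant_flow_gives_no_breaths(self):
        rec = make_recording(np.full(256 * 10, 20.0))
        assert detect_breaths(rec) == []

    def test_non_uniform_grid_rejected(self):
        rec = make_recording(np.zeros(2560))
        rec.time[100] += 0.01
        with pytest.raises(ValueError, match="non-uniform"):
            detect_breaths(rec)

    def test_noise_free_ccc_onsets_within_one_sample(self, ccc_noise_free):
        _, vent, _, _, truth = ccc_noise_free
        windows = detect_breaths(vent)
        assert len(windows) == len(truth.breath_onsets)
        onsets = vent.time[[w[0] for w in windows]]
        assert np.max(np.abs(onsets - truth.breath_onsets)) <= 1.0 / vent.sample_rate + 1e-12

    def test_breath_count_per_minute_with_default_artifact(self, ccc_subject):
        _, vent, _, _, _ = ccc_subject
        feats = extract_breath_features(vent)
        mins = per_minute_means(feats)
        assert mins["n_breaths"].tolist() == [10] * 20


class TestFeatures:
    def test_rectangular_pulse_arithmetic(self):
        # 30 l/min for 0.5 s = 500 ml/s * 0.5 s = 250 ml
        fs = 256.0
        n = int(2 * fs)
        flow = np.zeros(n)
        i0, i1 = 100, 100 + int(0.5 * fs)
        flow[i0 : i1 + 1] = 30.0
        rec = make_recording(flow, fs)
        f = compute_breath_features(rec, (i0, i1, n - 1))
        assert f["pif"] == pytest.approx(30.0)
        assert f["vti"] == pytest.approx(250.0, rel=1e-6)
        assert f["ti"] == pytest.approx(0.5, abs=1e-9)

    def test_half_sine_matches_closed_form_integral(self):
        fs, peak, dur = 256.0, 60.0, 0.435
        n = int(2 * fs)
        flow = np.zeros(n)
        i0 = 50
        i1 = i0 + int(round(dur * fs))
        tt = (np.arange(i0, i1 + 1) - i0) / fs
        flow[i0 : i1 + 1] = peak * np.sin(np.pi * tt / dur)
        rec = make_recording(flow, fs)
        f = compute_breath_features(rec, (i0, i1, n - 1))
        expected = (2 / np.pi) * peak * dur / 0.06  # l/min * s -> ml
        assert f["vti"] == pytest.approx(expected, rel=0.01)

    def test_noise_free_pip_recovers_group_mean(self, ccc_noise_free):
        _, vent, _, _, truth = ccc_noise_free
        feats = extract_breath_features(vent)
        np.testing.assert_allclose(feats["pip"], 58.6, atol=0.05)

    def test_window_outside_recording_rejected(self):
        rec = make_recording(np.zeros(100))
        with pytest.raises(ValueError):
            compute_breath_features(rec, (50, 90, 150))


class TestPerMinute:
    def test_full_run_yields_twenty_records(self, ccc_subject):
        _, vent, _, _, _ = ccc_subject
        mins = per_minute_means(extract_breath_features(vent))
        assert len(mins) == 20
        assert list(mins.index) == list(range(1, 21))

    def test_single_breath_minute_equals_that_breath(self):
        feats = pd.DataFrame([
            {"onset": 125.0, "pif": 40.0, "vti": 200.0, "pip": 30.0,
             "ti": 0.4, "peco2": 35.0},
        ])
        mins = per_minute_means(feats, duration_min=5)
        assert mins.loc[3, "mean_pif"] == 40.0
        assert mins.loc[3, "mv"] == 200.0
        assert mins.loc[3, "n_breaths"] == 1
        # all other minutes missing, not zero
        assert mins.drop(index=3)["mean_pif"].isna().all()

    @given(st.lists(
        st.tuples(st.floats(0, 1199), st.floats(1, 100), st.floats(1, 500)),
        min_size=1, max_size=60,
    ))
    def test_binning_matches_bruteforce_oracle(self, rows):
        feats = pd.DataFrame([
            {"onset": o, "pif": p, "vti": v, "pip": 1.0, "ti": 0.4, "peco2": 1.0}
            for o, p, v in rows
        ])
        mins = per_minute_means(feats, duration_min=20)
        for m in range(1, 21):
            sel = [r for r in rows if int(r[0] // 60) + 1 == m]
            if sel:
                assert mins.loc[m, "mean_pif"] == pytest.approx(
                    np.mean([r[1] for r in sel]))
                assert mins.loc[m, "mv"] == pytest.approx(
                    np.sum([r[2] for r in sel]))
            else:
                assert np.isnan(mins.loc[m, "mean_pif"])

    def test_volume_conservation(self, t302_subject):
        _, vent, _, _, _ = t302_subject
        feats = extract_breath_features(vent)
        mins = per_minute_means(feats)
        assert mins["mv"].sum() == pytest.approx(feats["vti"].sum(), rel=1e-9)

    def test_pre_cpr_breaths_excluded(self):
        feats = pd.DataFrame([
            {"onset": -5.0, "pif": 1, "vti": 1, "pip": 1, "ti": 1, "peco2": 1},
            {"onset": 10.0, "pif": 2, "vti": 2, "pip": 2, "ti": 2, "peco2": 2},
        ])
        mins = per_minute_means(feats, duration_min=2)
        assert mins.loc[1, "n_breaths"] == 1


class TestMechanism:
    def test_minute_volume_follows_rate_at_equal_vti(self, ccc_subject, t302_subject):
        """Equal tidal volumes at 10 vs ~6 breaths/min produce the minute-
        volume difference through rate alone."""
        _, vent_c, _, _, _ = ccc_subject
        _, vent_t, _, _, _ = t302_subject
        fc = extract_breath_features(vent_c)
        ft = extract_breath_features(vent_t)
        mc = per_minute_means(fc)
        mt = per_minute_means(ft)
        # stationary CCC: mv ~ mean vti x 10 within 5%
        assert mc["mv"].mean() == pytest.approx(fc["vti"].mean() * 10, rel=0.05)
        ratio = mc["mv"].mean() / mt["mv"].mean()
        rate_ratio = mc["n_breaths"].mean() / mt["n_breaths"].mean()
        assert ratio == pytest.approx(rate_ratio, rel=0.06)
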