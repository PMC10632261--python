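"""File dialects: recording CSVs, ground-truth sidecars, result tables.

Channel units are fixed in the column names — flow in l/min, airway
pressure in cmH2O, vascular pressure in mmHg, CO2 in mmHg — because the
source tables mix units.  One directory per subject holds ventilation.csv,
hemodynamics.csv, abg.csv and truth.json (the sidecar, with the config
echoed into it).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig, GeneratorParams
from .simulate import (
    ABGSeries,
    HemodynamicRecording,
    SubjectData,
    SubjectTruth,
    VentilationRecording,
)

VENT_COLUMNS = ["time_s", "flow_lpm", "paw_cmh2o", "co2_mmhg"]
HEMO_COLUMNS = ["time_s", "ap_mmhg", "cvp_mmhg"]
ABG_COLUMNS = ["time_min", "pao2_mmhg", "paco2_mmhg", "ph", "lactate_mmol_l"]


def write_ventilation_csv(path, rec: VentilationRecording) -> None:
    # time needs full precision to preserve the uniform grid; channels are
    # physiological signals where 1e-5 resolution is far below noise
    pd.DataFrame({
        "time_s": np.round(rec.time, 9), "flow_lpm": np.round(rec.flow, 5),
        "paw_cmh2o": np.round(rec.paw, 5), "co2_mmhg": np.round(rec.co2, 5),
    }).to_csv(path, index=False)


def read_ventilation_csv(path) -> VentilationRecording:
    df = pd.read_csv(path)
    missing = set(VENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ventilation CSV missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return VentilationRecording(
        time=t, flow=df["flow_lpm"].to_numpy(float),
        paw=df["paw_cmh2o"].to_numpy(float), co2=df["co2_mmhg"].to_numpy(float),
        sample_rate=round(fs, 6),
    )


def write_hemodynamic_csv(path, rec: HemodynamicRecording) -> None:
    pd.DataFrame({
        "time_s": np.round(rec.time, 9), "ap_mmhg": np.round(rec.ap, 5),
        "cvp_mmhg": np.round(rec.cvp, 5),
    }).to_csv(path, index=False)


def read_hemodynamic_csv(path) -> HemodynamicRecording:
    df = pd.read_csv(path)
    missing = set(HEMO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hemodynamic CSV missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return HemodynamicRecording(
        time=t, ap=df["ap_mmhg"].to_numpy(float),
        cvp=df["cvp_mmhg"].to_numpy(float), sample_rate=round(fs, 6),
    )


def write_abg_csv(path, abg: ABGSeries) -> None:
    pd.DataFrame({
        "time_min": abg.sample_times, "pao2_mmhg": abg.pao2,
        "paco2_mmhg": abg.paco2, "ph": abg.ph, "lactate_mmol_l": abg.lactate,
    }).to_csv(path, index=False, float_format="%.6g")


def read_abg_csv(path) -> ABGSeries:
    df = pd.read_csv(path)
    missing = set(ABG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ABG CSV missing columns {sorted(missing)}")
    return ABGSeries(
        sample_times=df["time_min"].to_numpy(float),
        pao2=df["pao2_mmhg"].to_numpy(float),
        paco2=df["paco2_mmhg"].to_numpy(float),
        ph=df["ph"].to_numpy(float),
        lactate=df["lactate_mmol_l"].to_numpy(float),
    )


def write_truth_sidecar(path, subject: SubjectData) -> None:
    truth = subject.truth
    payload = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "weight_kg": subject.weight,
        "sex": subject.sex,
        "config": subject.config.to_dict(),
        "generator_params": subject.params.to_dict(),
        "breath_onsets_s": truth.breath_onsets.tolist(),
        "true_breath_features": truth.true_breath_features.to_dict(orient="list"),
        "compression_times_s": truth.compression_times.tolist(),
        "decompression_end_times_s": truth.decompression_end_times.tolist(),
        "true_cycle_values": truth.true_cycle_values.to_dict(orient="list"),
        "true_trends": {k: v.tolist() for k, v in truth.true_trends.items()},
        "baseline": truth.baseline,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_subject_dir(outdir, subject: SubjectData) -> Path:
    """Write one subject's recordings + sidecar into ``outdir/subject_id``."""
    d = Path(outdir) / subject.subject_id
    d.mkdir(parents=True, exist_ok=True)
    write_ventilation_csv(d / "ventilation.csv", subject.vent)
    write_hemodynamic_csv(d / "hemodynamics.csv", subject.hemo)
    write_abg_csv(d / "abg.csv", subject.abg)
    write_truth_sidecar(d / "truth.json", subject)
    return d


def validate_recording(path, kind: str = "ventilation") -> list[str]:
    """Dialect/grid checks on a recording CSV; returns violation strings
    (empty = clean) and never raises on content problems."""
    violations: list[str] = []
    expected = {"ventilation": VENT_COLUMNS, "hemodynamics": HEMO_COLUMNS,
                "abg": ABG_COLUMNS}[kind]
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        return [f"unreadable: {exc}"]
    missing = set(expected) - set(df.columns)
    if missing:
        violations.append(f"schema: missing columns {sorted(missing)}")
        return violations
    tcol = expected[0]
    t = df[tcol].to_numpy(float)
    if len(t) > 2 and kind != "abg":
        dt = np.diff(t)
        if np.any(dt <= 0):
            violations.append("grid: time not strictly increasing")
        elif np.ptp(dt) > 1e-6:
            violations.append("grid: non-uniform sample spacing")
        else:
            fs = 1.0 / np.median(dt)
            nominal = {"ventilation": 256.0, "hemodynamics": 125.0}[kind]
            if abs(fs - nominal) > 0.01 * nominal:
                violations.append(
                    f"rate: sample rate {fs:.3f} Hz differs from nominal {nominal} Hz"
                )
    for col in expected[1:]:
        if not np.all(np.isfinite(df[col].to_numpy(float))):
            violations.append(f"values: non-finite entries in {col}")
    if kind == "ventilation" and "co2_mmhg" in df.columns:
        if (df["co2_mmhg"] < -1e-9).any():
            violations.append("values: negative CO2")
    return violations


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
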