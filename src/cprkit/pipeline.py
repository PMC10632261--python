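"""End-to-end pipeline: simulate -> extract -> longitudinal statistics.

``run_pipeline`` drives the whole chain from a :class:`PipelineConfig`
(YAML-serializable) and emits, per run:

* one directory per subject (ventilation.csv, hemodynamics.csv, abg.csv,
  truth.json) plus per-breath / per-cycle / per-minute extraction tables,
* a group-comparison report CSV (one row per parameter: group means with
  95% CIs, difference CI, p, AIC-selected or configured covariance),
* a per-time-point estimates CSV with the group x time interaction p,
* a run manifest with config hash and per-file checksums (timestamps are
  informational and excluded from reproducibility comparisons).

The timebase convention is t = 0 at CPR start; pre-arrest baseline samples
carry negative times.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breaths import DetectionParams, extract_breath_features, per_minute_means
from .config import ExperimentConfig
from .hemo import CycleDetectionParams, extract_cycles, per_minute_hemo
from .io import file_checksum, write_subject_dir
from .lmm import fit_lmm, select_covariance
from .simulate import SubjectData, simulate_cohort

log = logging.getLogger(__name__)

VENT_PARAMETERS = ["pif", "vti", "ti", "mv", "peco2", "pip"]
HEMO_PARAMETERS = ["cpp", "max_ap", "min_ap", "max_cvp", "min_cvp"]
ABG_PARAMETERS = ["pao2", "paco2", "lactate", "ph"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    out_dir: str = "cprkit_run"
    n_per_group: int = 8
    seed: int = 0
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cycles: CycleDetectionParams = field(default_factory=CycleDetectionParams)
    covariance: str = "ante1"
    select_covariance_by_aic: bool = False
    covariance_candidates: tuple = ("ante1", "cs", "ar1", "diag")
    df_method: str = "satterthwaite"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["experiment"] = self.experiment.to_dict()
        d["covariance_candidates"] = list(self.covariance_candidates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "experiment" in d:
            d["experiment"] = ExperimentConfig.from_dict(d["experiment"])
        if "detection" in d and isinstance(d["detection"], dict):
            d["detection"] = DetectionParams(**d["detection"])
        if "cycles" in d and isinstance(d["cycles"], dict):
            d["cycles"] = CycleDetectionParams(**d["cycles"])
        if "covariance_candidates" in d:
            d["covariance_candidates"] = tuple(d["covariance_candidates"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        level excluded, so relocated runs compare equal)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict[str, str]
    version: str
    created: str

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    def same_outputs(self, other: "RunManifest") -> bool:
        """Reproducibility comparison: config and checksums, not timestamps."""
        return (self.config_hash == other.config_hash
                and self.checksums == other.checksums)


# ---------------------------------------------------------------------------
# extraction helpers


def extract_subject_tables(
    subject: SubjectData,
    detection: DetectionParams | None = None,
    cycles_params: CycleDetectionParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-breath, per-cycle and per-minute tables for one subject."""
    cfg = subject.config
    n_min = int(round(cfg.cpr_duration))
    breaths = extract_breath_features(subject.vent, detection)
    vent_minutes = per_minute_means(breaths, cpr_start=0.0, duration_min=n_min)
    cyc = extract_cycles(
        subject.hemo, cfg.compression_rate, cycles_params, cpr_start=0.0
    )
    hemo_minutes = per_minute_hemo(cyc, cpr_start=0.0, duration_min=n_min)
    return {
        "breaths": breaths, "vent_minutes": vent_minutes,
        "cycles": cyc, "hemo_minutes": hemo_minutes,
    }


def build_longitudinal(
    subjects: list[SubjectData],
    tables: list[dict[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Long-format subject x time x parameter dataset for the mixed models.

    Per-minute ventilation and hemodynamic parameters use minute indices
    1..20; ABG parameters use the 5-min sampling grid (time index 1..4 for
    minutes 5, 10, 15, 20)."""
    rows = []
    for subj, tab in zip(subjects, tables):
        vm, hm = tab["vent_minutes"], tab["hemo_minutes"]
        for minute in vm.index:
            for p, col in zip(
                VENT_PARAMETERS,
                ["mean_pif", "mean_vti", "mean_ti", "mv", "mean_peco2", "mean_pip"],
            ):
                rows.append((subj.subject_id, subj.group, int(minute), p,
                             float(vm.loc[minute, col])))
        for minute in hm.index:
            for p, col in zip(
                HEMO_PARAMETERS,
                ["mean_cpp", "mean_max_ap", "mean_min_ap", "mean_max_cvp", "mean_min_cvp"],
            ):
                rows.append((subj.subject_id, subj.group, int(minute), p,
                             float(hm.loc[minute, col])))
        abg = subj.abg
        cpr = abg.sample_times > 0
        for k, tmin in enumerate(abg.sample_times[cpr]):
            for p, arr in zip(
                ABG_PARAMETERS, (abg.pao2, abg.paco2, abg.lactate, abg.ph)
            ):
                rows.append((subj.subject_id, subj.group, k + 1, p,
                             float(arr[cpr][k])))
    df = pd.DataFrame(rows, columns=["subject", "group", "time", "parameter", "value"])
    return df.dropna(subset=["value"]).reset_index(drop=True)


def group_comparison_report(
    data: pd.DataFrame,
    parameters: list[str] | None = None,
    structure: str = "ante1",
    select_by_aic: bool = False,
    candidates=("ante1", "cs", "ar1", "diag"),
    df_method: str = "satterthwaite",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-parameter mixed-model comparison (report table) plus per-time
    estimates with the interaction p (timecourse table)."""
    if parameters is None:
        parameters = sorted(data["parameter"].unique())
    report_rows, time_rows = [], []
    for p in parameters:
        sub = data[data["parameter"] == p]
        if sub.empty:
            continue
        try:
            if select_by_aic:
                ranked = select_covariance(sub, None, candidates, df_method)
                fit = ranked.iloc[0]["fit"]
            else:
                fit = fit_lmm(sub, None, structure=structure, df_method=df_method)
        except Exception as exc:
            raise PipelineError("stats", f"mixed model failed for {p!r}: {exc}")
        fit.parameter = p
        report_rows.append(fit.summary_row())
        cm = fit.cell_means.copy()
        cm.insert(0, "parameter", p)
        cm["interaction_p"] = fit.interaction_p
        time_rows.append(cm)
    return pd.DataFrame(report_rows), pd.concat(time_rows, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> extract -> stats, writing all artifacts under
    ``config.out_dir`` and returning the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    try:
        subjects = simulate_cohort(
            config.n_per_group, config.experiment, seed=config.seed
        )
        for s in subjects:
            d = write_subject_dir(out / "subjects", s)
            for f in sorted(d.iterdir()):
                checksums[str(f.relative_to(out))] = file_checksum(f)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc))

    try:
        tables = []
        for s in subjects:
            tab = extract_subject_tables(s, config.detection, config.cycles)
            d = out / "subjects" / s.subject_id
            tab["breaths"].to_csv(d / "breaths.csv", index=False)
            tab["vent_minutes"].to_csv(d / "vent_minutes.csv")
            tab["cycles"].to_csv(d / "cycles.csv", index=False)
            tab["hemo_minutes"].to_csv(d / "hemo_minutes.csv")
            for name in ("breaths.csv", "vent_minutes.csv", "cycles.csv",
                         "hemo_minutes.csv"):
                checksums[str((d / name).relative_to(out))] = file_checksum(d / name)
            tables.append(tab)
        long_df = build_longitudinal(subjects, tables)
        long_df.to_csv(out / "longitudinal.csv", index=False)
        checksums["longitudinal.csv"] = file_checksum(out / "longitudinal.csv")
        meta = pd.DataFrame(
            [(s.subject_id, s.group, s.weight, s.sex) for s in subjects],
            columns=["subject", "group", "weight_kg", "sex"],
        )
        meta.to_csv(out / "subjects.csv", index=False)
        checksums["subjects.csv"] = file_checksum(out / "subjects.csv")
    except Exception as exc:
        raise PipelineError("extract", str(exc))

    report, timecourse = group_comparison_report(
        long_df,
        structure=config.covariance,
        select_by_aic=config.select_covariance_by_aic,
        candidates=config.covariance_candidates,
        df_method=config.df_method,
    )
    report.to_csv(out / "report_groups.csv", index=False)
    timecourse.to_csv(out / "report_timecourse.csv", index=False)
    checksums["report_groups.csv"] = file_checksum(out / "report_groups.csv")
    checksums["report_timecourse.csv"] = file_checksum(out / "report_timecourse.csv")

    manifest = RunManifest(
        config_hash=config.config_hash(),
        checksums=checksums,
        version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest.to_json(out / "manifest.json")
    config.to_yaml(out / "config.yaml")
    return manifest
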