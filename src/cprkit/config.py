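"""Experiment and generator configuration.

The :class:`ExperimentConfig` captures the CPR protocol schedule (compression
rate, ventilation mode, phase durations, sampling rates) while
:class:`GeneratorParams` carries the physiological magnitudes the synthetic
generator draws from (group-level means, per-minute trends, noise and
compression-artifact amplitudes).  Defaults reproduce the two study arms:

* **CCC** — continuous compressions at 102/min with one manual ventilation
  every 6 s (10 breaths/min), asynchronous to compressions.
* **30:2** — cycles of 30 compressions followed by a 3.2 s pause during which
  2 ventilations are delivered (~6 breaths/min effective).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Any


class CPRMode(str, enum.Enum):
    """Ventilation mode during CPR."""

    CCC = "ccc"
    THIRTY_TWO = "302"

    @classmethod
    def parse(cls, value: "str | CPRMode") -> "CPRMode":
        if isinstance(value, CPRMode):
            return value
        v = str(value).strip().lower().replace(":", "")
        if v in ("ccc", "continuous"):
            return cls.CCC
        if v in ("302", "30_2", "thirty_two", "30-2"):
            return cls.THIRTY_TWO
        raise ValueError(f"unknown CPR mode: {value!r}")


@dataclass
class ExperimentConfig:
    """Protocol schedule and acquisition settings for one subject.

    Durations of the untreated arrest and CPR phases are in minutes; event
    spacings (ventilation interval, pause length) in seconds.  ``seed`` feeds
    every random draw of the generator, so identical configs produce
    bit-identical recordings.
    """

    cpr_mode: CPRMode = CPRMode.CCC
    compression_rate: float = 102.0      # compressions/min
    ccc_vent_interval: float = 6.0       # s between breaths in CCC
    pause_duration: float = 3.2          # s ventilation pause in 30:2
    compressions_per_cycle: int = 30     # compressions per 30:2 cycle
    breaths_per_pause: int = 2
    untreated_vf_duration: float = 3.0   # min of untreated VF before CPR
    cpr_duration: float = 20.0           # min of CPR
    abg_interval: float = 5.0            # min between arterial blood gases
    vent_sample_rate: float = 256.0      # Hz
    hemo_sample_rate: float = 125.0      # Hz
    subject_weight: float = 33.0         # kg
    target_vt_per_kg: float = 8.0        # ml/kg intended tidal volume
    seed: int = 0

    def __post_init__(self) -> None:
        self.cpr_mode = CPRMode.parse(self.cpr_mode)
        positive = (
            "compression_rate", "ccc_vent_interval", "pause_duration",
            "untreated_vf_duration", "cpr_duration", "abg_interval",
            "vent_sample_rate", "hemo_sample_rate", "subject_weight",
            "target_vt_per_kg",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("compressions_per_cycle", "breaths_per_pause"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name} must be a positive integer")

    # -- convenience, all in seconds ------------------------------------
    @property
    def cpr_duration_s(self) -> float:
        return self.cpr_duration * 60.0

    @property
    def compression_period(self) -> float:
        return 60.0 / self.compression_rate

    @property
    def cycle_period(self) -> float:
        """Length of one 30:2 compression+pause block in seconds."""
        return self.compressions_per_cycle * self.compression_period + self.pause_duration

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cpr_mode"] = self.cpr_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# Group-level means for the two arms.  Ventilation magnitudes and the
# hemodynamic envelope are overridable; defaults are the study-arm point
# estimates, with per-minute linear trends that preserve the 20-min mean.
_MODE_DEFAULTS: dict[CPRMode, dict[str, float]] = {
    CPRMode.CCC: dict(
        pip_mean=58.6, peco2_mean=28.6, peco2_slope=0.6,
        vti_mean=221.5, ti_mean=0.435,
        cpp_mean=10.0, cpp_slope=0.6,
        max_ap_mean=132.4, max_ap_slope=3.0,
        min_ap_mean=-4.8,
        max_cvp_mean=169.5, max_cvp_slope=1.5,
        min_cvp_mean=1.3,
        baseline_hr=100.0, baseline_map=91.7, baseline_cvp=7.0,
        abg_pao2_mean=141.7, abg_paco2_mean=50.2, abg_paco2_slope=-0.9,
        abg_lactate_mean=5.6, abg_lactate_slope=-0.25,
        abg_ph_mean=7.28, abg_ph_slope=0.006,
        baseline_pao2=181.9, baseline_paco2=38.0,
        baseline_lactate=1.2, baseline_ph=7.5,
    ),
    CPRMode.THIRTY_TWO: dict(
        pip_mean=35.1, peco2_mean=39.4, peco2_slope=-0.4,
        vti_mean=221.4, ti_mean=0.419,
        cpp_mean=15.2, cpp_slope=0.7,
        max_ap_mean=108.7, max_ap_slope=2.5,
        min_ap_mean=-3.2,
        max_cvp_mean=146.4, max_cvp_slope=2.5,
        min_cvp_mean=5.0,
        baseline_hr=95.0, baseline_map=81.8, baseline_cvp=3.0,
        abg_pao2_mean=156.0, abg_paco2_mean=61.1, abg_paco2_slope=-1.0,
        abg_lactate_mean=5.4, abg_lactate_slope=-0.25,
        abg_ph_mean=7.22, abg_ph_slope=0.006,
        baseline_pao2=183.8, baseline_paco2=40.9,
        baseline_lactate=1.2, baseline_ph=7.48,
    ),
}


@dataclass
class GeneratorParams:
    """Physiological magnitudes driving the synthetic waveforms.

    ``*_slope`` values are the per-minute decay rates of the corresponding
    per-minute generating means; a positive slope means the parameter
    *declines* over the 20 min of CPR while its overall mean is preserved
    (mean + slope * (midpoint - minute)).  ABG slopes follow the same sign
    convention, so positive ``abg_ph_slope`` means pH falls over time while
    negative ``abg_paco2_slope`` / ``abg_lactate_slope`` mean those rise.

    Noise standard deviations are additive Gaussian per channel; artifact
    amplitudes shape the deterministic compression oscillation superimposed
    on the airway channels.  Setting ``noise_free()`` zeroes both, leaving
    the clean generating waveforms for oracle tests.
    """

    # ventilation magnitudes
    pip_mean: float = 58.6          # cmH2O, peak inspiratory pressure
    peco2_mean: float = 28.6        # mmHg, peak expired CO2 (20-min mean)
    peco2_slope: float = 0.6        # mmHg/min decline (negative = rise)
    vti_mean: float = 221.5         # ml inspiratory tidal volume
    ti_mean: float = 0.435          # s inspiration duration
    paw_baseline: float = 2.0       # cmH2O airway pressure between breaths
    exp_time_constant: float = 0.4  # s passive expiration decay
    # hemodynamic magnitudes (mmHg; slopes mmHg/min)
    cpp_mean: float = 10.0
    cpp_slope: float = 0.6
    max_ap_mean: float = 132.4
    max_ap_slope: float = 3.0
    min_ap_mean: float = -4.8
    max_cvp_mean: float = 169.5
    max_cvp_slope: float = 1.5
    min_cvp_mean: float = 1.3
    # pre-arrest baseline
    baseline_hr: float = 100.0      # beats/min
    baseline_map: float = 91.7      # mmHg
    baseline_cvp: float = 7.0       # mmHg
    baseline_pulse_pressure: float = 55.0
    # arterial blood gases
    abg_pao2_mean: float = 141.7
    abg_paco2_mean: float = 50.2
    abg_paco2_slope: float = -0.9
    abg_lactate_mean: float = 5.6
    abg_lactate_slope: float = -0.25
    abg_ph_mean: float = 7.28
    abg_ph_slope: float = 0.006
    baseline_pao2: float = 181.9
    baseline_paco2: float = 38.0
    baseline_lactate: float = 1.2
    baseline_ph: float = 7.5
    # breath-to-breath / cycle-to-cycle within-subject jitter
    breath_cv: float = 0.04         # CV of per-breath pip/peco2/vti/ti
    cycle_cv: float = 0.05          # CV of per-cycle maxAP/maxCVP
    cycle_sd: float = 1.0           # mmHg additive jitter on near-zero values
    # compression artifact amplitudes (deterministic oscillation)
    flow_artifact_amp: float = 3.0  # l/min on the flow channel
    paw_artifact_amp: float = 12.0  # cmH2O between breaths
    paw_ripple_amp: float = 8.0     # cmH2O ripple within an overlapped breath
    co2_artifact_frac: float = 0.15  # fractional downward CO2 dips
    # measurement noise (additive Gaussian SD per channel)
    flow_noise_sd: float = 0.5      # l/min
    paw_noise_sd: float = 0.5       # cmH2O
    co2_noise_sd: float = 0.25      # mmHg
    ap_noise_sd: float = 1.0        # mmHg
    cvp_noise_sd: float = 1.0       # mmHg

    @classmethod
    def for_mode(cls, mode: "CPRMode | str", **overrides: float) -> "GeneratorParams":
        """Default magnitudes for one study arm, with optional overrides."""
        mode = CPRMode.parse(mode)
        kwargs = dict(_MODE_DEFAULTS[mode])
        kwargs.update(overrides)
        return cls(**kwargs)

    def noise_free(self) -> "GeneratorParams":
        """Copy with all measurement noise and compression artifact removed."""
        return dataclasses.replace(
            self,
            flow_artifact_amp=0.0, paw_artifact_amp=0.0, paw_ripple_amp=0.0,
            co2_artifact_frac=0.0, flow_noise_sd=0.0, paw_noise_sd=0.0,
            co2_noise_sd=0.0, ap_noise_sd=0.0, cvp_noise_sd=0.0,
            breath_cv=0.0, cycle_cv=0.0, cycle_sd=0.0,
        )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
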