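"""Protocol-faithful synthetic CPR recordings with ground-truth sidecars.

The generator emulates the two-arm porcine CPR experiment: mechanical chest
compressions at 102/min, manual bag ventilations either asynchronous every
6 s (CCC) or two breaths inside each 3.2 s pause after 30 compressions
(30:2), arterial/central-venous pressure at 125 Hz, pneumotachograph
ventilation channels at 256 Hz and arterial blood gases every 5 min.  The
waveforms are phenomenological: each breath is a half-sine inspiratory flow
pulse with passive exponential expiration, airway pressure is an elastic
half-sine plus a compression-frequency oscillation when the breath overlaps
active compressions, CO2 shows an expiratory upstroke to a per-minute peak
level, and each compression/decompression cycle is a piecewise-cosine
pressure excursion through its compression peak, decompression trough and
end-decompression plateau.

Every generating value (per-breath PIF/Vti/PIP/Ti/PECO2, per-cycle pressure
extrema and CPP, per-minute trend means) is recorded in a
:class:`SubjectTruth` sidecar, which downstream extraction modules are
tested against.  Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import CPRMode, ExperimentConfig, GeneratorParams

GROUP_LABELS = {CPRMode.CCC: "CCC", CPRMode.THIRTY_TWO: "30:2"}

# between-subject jitter applied by simulate_cohort (documented defaults):
# bag ventilation is feedback-guided, hence low variability; hemodynamic
# magnitudes during arrest vary widely between animals.
VENT_JITTER_CV = 0.05
HEMO_JITTER_CV = 0.20
HEMO_JITTER_SD = 1.5        # mmHg, additive on near-zero pressures
ABG_JITTER_CV = 0.05
PH_JITTER_SD = 0.03
WEIGHT_MEAN_KG = 33.5
WEIGHT_SD_KG = 3.0

_CO2_UPSTROKE_S = 0.8       # s to reach the expiratory CO2 plateau
_MAX_EXPIRATION_S = 8.0     # cap on the modelled expiratory flow tail
_PHASE_PEAK = 0.30          # compression-cycle phase of maximum compression
_PHASE_TROUGH = 0.75        # phase of maximum decompression
_PHASE_PLATEAU = 0.90       # start of the end-decompression plateau


@dataclass
class VentilationRecording:
    """Uniform 256 Hz ventilation trace: flow (l/min, inspiration positive),
    airway pressure (cmH2O) and exhaled CO2 (mmHg)."""

    time: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    co2: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.flow) == len(self.paw) == len(self.co2) == n):
            raise ValueError("channel lengths differ")


@dataclass
class HemodynamicRecording:
    """Uniform 125 Hz arterial + central venous pressure trace (mmHg).

    Covers the 5-min pre-arrest baseline, the untreated VF phase and the
    CPR phase; t = 0 at CPR start, pre-arrest times are negative.
    """

    time: np.ndarray
    ap: np.ndarray
    cvp: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if not (len(self.ap) == len(self.cvp) == len(self.time)):
            raise ValueError("channel lengths differ")


@dataclass
class ABGSeries:
    """Arterial blood gases; times in minutes relative to CPR start, the
    pre-arrest baseline sample carries a negative time."""

    sample_times: np.ndarray
    pao2: np.ndarray
    paco2: np.ndarray
    ph: np.ndarray
    lactate: np.ndarray


@dataclass
class SubjectTruth:
    """Generating values for one simulated subject (the extraction oracle)."""

    breath_onsets: np.ndarray
    true_breath_features: pd.DataFrame   # onset, pif, vti, pip, ti, peco2
    compression_times: np.ndarray        # instants of maximum compression
    decompression_end_times: np.ndarray
    true_cycle_values: pd.DataFrame      # t_peak, max/min AP & CVP, ends, cpp
    true_trends: dict[str, np.ndarray]   # per-minute generating means
    baseline: dict[str, float]           # pre-arrest truth (hr, map, cvp, ...)


@dataclass
class SubjectData:
    """One simulated subject with metadata and all recordings."""

    subject_id: str
    group: str
    weight: float
    sex: str
    config: ExperimentConfig
    params: GeneratorParams
    vent: VentilationRecording
    hemo: HemodynamicRecording
    abg: ABGSeries
    truth: SubjectTruth


# ---------------------------------------------------------------------------
# schedules


def breath_onset_schedule(config: ExperimentConfig) -> np.ndarray:
    """Breath onset times (s from CPR start) implied by the protocol."""
    dur = config.cpr_duration_s
    if config.cpr_mode is CPRMode.CCC:
        # first breath half an interval in: asynchronous to compressions and
        # clear of minute boundaries
        return np.arange(config.ccc_vent_interval / 2.0, dur, config.ccc_vent_interval)
    onsets = []
    block = config.compressions_per_cycle * config.compression_period
    spacing = (config.pause_duration - 0.4) / config.breaths_per_pause
    k = 0
    while True:
        pause_start = k * config.cycle_period + block
        if pause_start + config.pause_duration > dur:
            break
        for j in range(config.breaths_per_pause):
            onsets.append(pause_start + 0.2 + j * spacing)
        k += 1
    return np.asarray(onsets)


def compression_start_times(config: ExperimentConfig) -> np.ndarray:
    """Start times (s) of every compression cycle during CPR."""
    dur = config.cpr_duration_s
    tc = config.compression_period
    if config.cpr_mode is CPRMode.CCC:
        return np.arange(0.0, dur, tc)
    starts = []
    k = 0
    while k * config.cycle_period < dur:
        base = k * config.cycle_period
        for j in range(config.compressions_per_cycle):
            s = base + j * tc
            if s < dur:
                starts.append(s)
        k += 1
    return np.asarray(starts)


def active_compression_gate(t: np.ndarray, config: ExperimentConfig) -> np.ndarray:
    """1.0 where compressions are active at CPR-relative time ``t``, else 0."""
    gate = (t >= 0) & (t < config.cpr_duration_s)
    if config.cpr_mode is CPRMode.THIRTY_TWO:
        block = config.compressions_per_cycle * config.compression_period
        gate = gate & ((t % config.cycle_period) < block)
    return gate.astype(float)


def _trend(mean: float, slope: float, n_minutes: int) -> np.ndarray:
    """Mean-preserving linear per-minute trend; positive slope = decline."""
    m = np.arange(1, n_minutes + 1, dtype=float)
    return mean + slope * ((n_minutes + 1) / 2.0 - m)


def _jitter(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return values.copy()
    z = np.clip(rng.standard_normal(values.shape), -3.0, 3.0)
    return values * (1.0 + cv * z)


# ---------------------------------------------------------------------------
# single-subject simulation


def simulate_subject(
    config: ExperimentConfig, params: GeneratorParams | None = None
) -> tuple[VentilationRecording, HemodynamicRecording, ABGSeries, SubjectTruth]:
    """Simulate one subject's recordings plus the ground-truth sidecar."""
    if params is None:
        params = GeneratorParams.for_mode(config.cpr_mode)
    rng = np.random.default_rng(config.seed)
    n_min = int(round(config.cpr_duration))

    trends = {
        "pip": _trend(params.pip_mean, 0.0, n_min),
        "peco2": _trend(params.peco2_mean, params.peco2_slope, n_min),
        "vti": _trend(params.vti_mean, 0.0, n_min),
        "ti": _trend(params.ti_mean, 0.0, n_min),
        "cpp": _trend(params.cpp_mean, params.cpp_slope, n_min),
        "max_ap": _trend(params.max_ap_mean, params.max_ap_slope, n_min),
        "min_ap": _trend(params.min_ap_mean, 0.0, n_min),
        "max_cvp": _trend(params.max_cvp_mean, params.max_cvp_slope, n_min),
        "min_cvp": _trend(params.min_cvp_mean, 0.0, n_min),
    }

    vent, breath_truth = _simulate_ventilation(config, params, trends, rng)
    hemo, comp_times, decomp_times, cycle_truth = _simulate_hemodynamics(
        config, params, trends, rng
    )
    abg = _simulate_abg(config, params, rng)

    truth = SubjectTruth(
        breath_onsets=breath_truth["onset"].to_numpy(),
        true_breath_features=breath_truth,
        compression_times=comp_times,
        decompression_end_times=decomp_times,
        true_cycle_values=cycle_truth,
        true_trends=trends,
        baseline={
            "hr": params.baseline_hr,
            "map": params.baseline_map,
            "cvp": params.baseline_cvp,
        },
    )
    return vent, hemo, abg, truth


def _simulate_ventilation(config, params, trends, rng):
    fs = config.vent_sample_rate
    dur = config.cpr_duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    f_c = config.compression_rate / 60.0

    gate = active_compression_gate(t, config)
    osc = np.sin(2 * np.pi * f_c * t)
    posc = np.maximum(osc, 0.0)

    flow = params.flow_artifact_amp * osc * gate
    paw = params.paw_baseline + params.paw_artifact_amp * posc * gate
    co2 = np.zeros(n)

    onsets = breath_onset_schedule(config)
    n_breaths = len(onsets)
    minute_idx = np.minimum((onsets // 60.0).astype(int), len(trends["pip"]) - 1)
    ti_b = _jitter(rng, trends["ti"][minute_idx], params.breath_cv)
    vti_b = _jitter(rng, trends["vti"][minute_idx], params.breath_cv)
    pip_b = _jitter(rng, trends["pip"][minute_idx], params.breath_cv)
    peco2_b = _jitter(rng, trends["peco2"][minute_idx], params.breath_cv)

    rows = []
    for b in range(n_breaths):
        o, ti, vti, pip, peco2 = onsets[b], ti_b[b], vti_b[b], pip_b[b], peco2_b[b]
        i0 = int(np.ceil(o * fs))
        i1 = min(int(np.floor((o + ti) * fs)), n - 1)
        nxt = onsets[b + 1] if b + 1 < n_breaths else dur
        i2 = min(int(np.floor(nxt * fs)) - 1, n - 1)

        # inspiratory half-sine; peak in l/min from the closed-form integral
        peak_lpm = (np.pi / 2.0) * (vti / ti) * 0.06  # ml/s -> l/min
        tt = t[i0 : i1 + 1]
        flow[i0 : i1 + 1] += peak_lpm * np.sin(np.pi * (tt - o) / ti)

        # passive exponential expiration, volume-balanced
        te = o + ti
        j0, j1 = i1 + 1, min(i2, i1 + int(_MAX_EXPIRATION_S * fs))
        if j1 >= j0:
            ttx = t[j0 : j1 + 1]
            flow[j0 : j1 + 1] += (
                -(vti / params.exp_time_constant)
                * np.exp(-(ttx - te) / params.exp_time_constant)
                * 0.06
            )

        # airway pressure: elastic half-sine plus compression ripple where the
        # breath overlaps active compressions, normalized so the noise-free
        # maximum equals the drawn per-breath PIP exactly
        raw = (pip - params.paw_baseline) * np.sin(np.pi * (tt - o) / ti)
        raw = raw + params.paw_ripple_amp * posc[i0 : i1 + 1] * gate[i0 : i1 + 1]
        peak = raw.max()
        if peak > 0:
            raw *= (pip - params.paw_baseline) / peak
        paw[i0 : i1 + 1] = params.paw_baseline + raw

        # expiratory CO2 upstroke to the per-breath peak level, with downward
        # compression dips clipped at the plateau (peak value preserved)
        if i2 >= i1 + 1:
            ttx = t[i1 + 1 : i2 + 1]
            shape = np.minimum(1.0, (ttx - te) / _CO2_UPSTROKE_S)
            dip = params.co2_artifact_frac * gate[i1 + 1 : i2 + 1] * np.abs(
                osc[i1 + 1 : i2 + 1]
            )
            seg = peco2 * np.clip(shape - dip, 0.0, None)
            co2[i1 + 1 : i2 + 1] = seg
            true_peco2 = float(seg.max())
        else:
            true_peco2 = 0.0

        insp = np.maximum(flow[i0 : i1 + 1], 0.0)
        true_vti = float(np.trapezoid(insp, t[i0 : i1 + 1]) / 0.06)
        true_pif = float(insp.max())
        rows.append((o, true_pif, true_vti, pip, ti, true_peco2))

    breath_truth = pd.DataFrame(
        rows, columns=["onset", "pif", "vti", "pip", "ti", "peco2"]
    )

    if params.flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, params.flow_noise_sd, n)
    if params.paw_noise_sd > 0:
        paw = paw + rng.normal(0.0, params.paw_noise_sd, n)
    if params.co2_noise_sd > 0:
        co2 = np.clip(co2 + rng.normal(0.0, params.co2_noise_sd, n), 0.0, None)

    rec = VentilationRecording(time=t, flow=flow, paw=paw, co2=co2, sample_rate=fs)
    return rec, breath_truth


def _cosine_segment(phi, p0, p1, v0, v1):
    """Cosine-eased interpolation from (p0, v0) to (p1, v1) over phase phi."""
    u = np.clip((phi - p0) / (p1 - p0), 0.0, 1.0)
    return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * u))


def _simulate_hemodynamics(config, params, trends, rng):
    fs = config.hemo_sample_rate
    vf_s = config.untreated_vf_duration * 60.0
    t_start = -(300.0 + vf_s)
    dur = config.cpr_duration_s
    n = int(round((dur - t_start) * fs))
    t = t_start + np.arange(n) / fs

    ap = np.zeros(n)
    cvp = np.zeros(n)

    # --- pre-arrest baseline: pulsatile AP around the configured MAP -------
    base = t < -vf_s
    tb = t[base]
    pulse = np.maximum(np.sin(2 * np.pi * (params.baseline_hr / 60.0) * (tb - t_start)), 0.0) ** 2
    ap[base] = params.baseline_map + params.baseline_pulse_pressure * (pulse - pulse.mean())
    resp = 0.8 * np.sin(2 * np.pi * 0.25 * (tb - t_start))
    cvp[base] = params.baseline_cvp + (resp - resp.mean())

    # --- untreated VF: pulseless decay -------------------------------------
    vf = (t >= -vf_s) & (t < 0)
    tv = t[vf]
    ap[vf] = 12.0 + 18.0 * np.exp(-(tv + vf_s) / 40.0)
    cvp[vf] = 8.0 + 0.3 * np.sin(2 * np.pi * 0.25 * tv)

    # --- CPR: piecewise-cosine compression cycles ---------------------------
    tc = config.compression_period
    starts = compression_start_times(config)
    n_min = len(trends["cpp"])
    minute_idx = np.minimum((starts // 60.0).astype(int), n_min - 1)

    max_ap_c = _jitter(rng, trends["max_ap"][minute_idx], params.cycle_cv)
    max_cvp_c = _jitter(rng, trends["max_cvp"][minute_idx], params.cycle_cv)
    zsd = params.cycle_sd
    min_ap_c = trends["min_ap"][minute_idx] + (
        rng.normal(0.0, zsd, len(starts)) if zsd > 0 else 0.0
    )
    min_cvp_c = trends["min_cvp"][minute_idx] + (
        rng.normal(0.0, zsd, len(starts)) if zsd > 0 else 0.0
    )
    cpp_c = trends["cpp"][minute_idx] + (
        rng.normal(0.0, zsd, len(starts)) if zsd > 0 else 0.0
    )
    cvp_end_c = min_cvp_c + 2.0
    ap_end_c = cvp_end_c + cpp_c

    i_cpr0 = int(np.searchsorted(t, 0.0))
    rows = []
    for k, s in enumerate(starts):
        i0 = int(np.searchsorted(t, s))
        i1 = min(int(np.searchsorted(t, s + tc)), n)
        if i1 <= i0:
            continue
        phi = (t[i0:i1] - s) / tc
        for arr, vmax, vmin, vend in (
            (ap, max_ap_c[k], min_ap_c[k], ap_end_c[k]),
            (cvp, max_cvp_c[k], min_cvp_c[k], cvp_end_c[k]),
        ):
            seg = np.empty(i1 - i0)
            m1 = phi < _PHASE_PEAK
            m2 = (phi >= _PHASE_PEAK) & (phi < _PHASE_TROUGH)
            m3 = (phi >= _PHASE_TROUGH) & (phi < _PHASE_PLATEAU)
            m4 = phi >= _PHASE_PLATEAU
            seg[m1] = _cosine_segment(phi[m1], 0.0, _PHASE_PEAK, vend, vmax)
            seg[m2] = _cosine_segment(phi[m2], _PHASE_PEAK, _PHASE_TROUGH, vmax, vmin)
            seg[m3] = _cosine_segment(phi[m3], _PHASE_TROUGH, _PHASE_PLATEAU, vmin, vend)
            seg[m4] = vend
            arr[i0:i1] = seg
        rows.append(
            (
                s + _PHASE_PEAK * tc,
                s + 0.95 * tc,
                max_ap_c[k],
                min_ap_c[k],
                max_cvp_c[k],
                min_cvp_c[k],
                ap_end_c[k],
                cvp_end_c[k],
                cpp_c[k],
            )
        )

    # fill 30:2 pauses (and any CPR tail) with a passive decay from the last
    # end-decompression level
    covered = np.zeros(n, dtype=bool)
    covered[: i_cpr0] = True
    for s in starts:
        i0 = int(np.searchsorted(t, s))
        i1 = min(int(np.searchsorted(t, s + tc)), n)
        covered[i0:i1] = True
    gaps = np.flatnonzero(~covered)
    if len(gaps):
        splits = np.split(gaps, np.flatnonzero(np.diff(gaps) > 1) + 1)
        for g in splits:
            i_prev = g[0] - 1
            a0 = ap[i_prev] if i_prev >= 0 else 15.0
            c0 = cvp[i_prev] if i_prev >= 0 else 5.0
            tg = t[g] - t[g[0]]
            ap[g] = 10.0 + (a0 - 10.0) * np.exp(-tg / 2.0)
            cvp[g] = 4.0 + (c0 - 4.0) * np.exp(-tg / 2.0)

    cycle_truth = pd.DataFrame(
        rows,
        columns=[
            "t_max_compression", "t_end_decompression",
            "max_ap", "min_ap", "max_cvp", "min_cvp",
            "ap_end_decomp", "cvp_end_decomp", "cpp",
        ],
    )

    if params.ap_noise_sd > 0:
        ap = ap + rng.normal(0.0, params.ap_noise_sd, n)
    if params.cvp_noise_sd > 0:
        cvp = cvp + rng.normal(0.0, params.cvp_noise_sd, n)

    rec = HemodynamicRecording(time=t, ap=ap, cvp=cvp, sample_rate=fs)
    return (
        rec,
        cycle_truth["t_max_compression"].to_numpy(),
        cycle_truth["t_end_decompression"].to_numpy(),
        cycle_truth,
    )


def _simulate_abg(config, params, rng):
    times = [-config.untreated_vf_duration]
    tt = config.abg_interval
    while tt <= config.cpr_duration + 1e-9:
        times.append(tt)
        tt += config.abg_interval
    times = np.asarray(times, dtype=float)
    cpr = times > 0
    # short protocols may end before the first scheduled CPR sample
    mid = times[cpr].mean() if cpr.any() else 0.0

    def series(mean, slope, baseline, noise_sd):
        out = np.empty(len(times))
        out[~cpr] = baseline
        out[cpr] = mean + slope * (mid - times[cpr])
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, len(times))
        return out

    pao2 = np.clip(series(params.abg_pao2_mean, 0.0, params.baseline_pao2, 8.0), 1.0, None)
    paco2 = np.clip(
        series(params.abg_paco2_mean, params.abg_paco2_slope, params.baseline_paco2, 2.0),
        1.0, None,
    )
    lactate = np.clip(
        series(params.abg_lactate_mean, params.abg_lactate_slope, params.baseline_lactate, 0.3),
        0.1, None,
    )
    ph = np.clip(
        series(params.abg_ph_mean, params.abg_ph_slope, params.baseline_ph, 0.02),
        6.51, 7.79,
    )
    return ABGSeries(sample_times=times, pao2=pao2, paco2=paco2, ph=ph, lactate=lactate)


# ---------------------------------------------------------------------------
# cohort simulation


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Reproducible per-subject seed: SeedSequence(master, spawn_key=(g, i))."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, subject_index))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_per_group: int,
    base_config: ExperimentConfig | None = None,
    seed: int = 0,
    param_overrides: dict[str, float] | None = None,
) -> list[SubjectData]:
    """Simulate a two-arm cohort with between-subject variation.

    Per-subject seeds derive from the master seed via
    ``SeedSequence(master, spawn_key=(group, index))``; weight is
    truncated-normal around 33.5 kg, ventilation trend magnitudes get 5% CV
    multiplicative jitter and hemodynamic magnitudes 20% CV (additive 1.5 mmHg
    on near-zero pressures).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if base_config is None:
        base_config = ExperimentConfig()
    subjects: list[SubjectData] = []
    for g_idx, mode in enumerate((CPRMode.CCC, CPRMode.THIRTY_TWO)):
        label = GROUP_LABELS[mode]
        for i in range(n_per_group):
            ss = np.random.SeedSequence(seed, spawn_key=(g_idx, i))
            rng = np.random.default_rng(ss)
            sseed = subject_seed(seed, g_idx, i)
            weight = float(
                np.clip(rng.normal(WEIGHT_MEAN_KG, WEIGHT_SD_KG), 26.0, 42.0)
            )
            sex = "F" if rng.random() < 7.0 / 16.0 else "M"
            params = GeneratorParams.for_mode(mode, **(param_overrides or {}))

            def mult(value, cv):
                return float(value * (1.0 + cv * np.clip(rng.standard_normal(), -2.5, 2.5)))

            params = dataclasses.replace(
                params,
                pip_mean=mult(params.pip_mean, VENT_JITTER_CV),
                peco2_mean=mult(params.peco2_mean, VENT_JITTER_CV),
                vti_mean=mult(params.vti_mean, VENT_JITTER_CV),
                ti_mean=mult(params.ti_mean, VENT_JITTER_CV),
                cpp_mean=mult(params.cpp_mean, HEMO_JITTER_CV),
                max_ap_mean=mult(params.max_ap_mean, HEMO_JITTER_CV),
                max_cvp_mean=mult(params.max_cvp_mean, HEMO_JITTER_CV),
                min_ap_mean=float(params.min_ap_mean + rng.normal(0.0, HEMO_JITTER_SD)),
                min_cvp_mean=float(params.min_cvp_mean + rng.normal(0.0, HEMO_JITTER_SD)),
                baseline_map=mult(params.baseline_map, 0.10),
                baseline_hr=mult(params.baseline_hr, 0.08),
                abg_pao2_mean=mult(params.abg_pao2_mean, ABG_JITTER_CV),
                abg_paco2_mean=mult(params.abg_paco2_mean, ABG_JITTER_CV),
                abg_lactate_mean=mult(params.abg_lactate_mean, ABG_JITTER_CV),
                abg_ph_mean=float(params.abg_ph_mean + rng.normal(0.0, PH_JITTER_SD)),
            )
            config = dataclasses.replace(
                base_config, cpr_mode=mode, subject_weight=weight, seed=sseed
            )
            vent, hemo, abg, truth = simulate_subject(config, params)
            subjects.append(
                SubjectData(
                    subject_id=f"{'ccc' if mode is CPRMode.CCC else 't302'}_{i + 1:02d}",
                    group=label,
                    weight=weight,
                    sex=sex,
                    config=config,
                    params=params,
                    vent=vent,
                    hemo=hemo,
                    abg=abg,
                    truth=truth,
                )
            )
    return subjects
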