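"""Compression-cycle detection and per-cycle hemodynamics at 125 Hz.

Compression peaks are found on a lightly smoothed arterial-pressure signal
with a minimum peak spacing of 0.7x the nominal compression period; the
decompression trough is the minimum between consecutive peaks.  For each
cycle the per-channel extrema (maxAP/maxCVP at maximum compression,
minAP/minCVP at maximum decompression) are read off the raw channels, and
coronary perfusion pressure is

    CPP = AP(end of decompression) - CVP(end of decompression),

with "end of decompression" operationalized as the last sample before the
next compression upstroke (upstroke = smoothed AP derivative exceeding a
fraction of the cycle's peak derivative).  ``end_decomp_at_trough=True``
switches to sampling both channels at the decompression trough instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import HemodynamicRecording

log = logging.getLogger(__name__)


@dataclass
class CycleDetectionParams:
    smooth_hz: float = 10.0
    min_prominence: float = 10.0       # mmHg
    min_spacing_factor: float = 0.7    # x nominal compression period
    upstroke_frac: float = 0.25        # fraction of peak derivative
    end_decomp_guard_s: float = 0.02   # margin before the detected upstroke
    end_decomp_cap_periods: float = 1.05  # cap i_end at this many periods
    end_decomp_at_trough: bool = False


def _smooth(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff >= fs / 2:
        return np.asarray(x, dtype=float)
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_cycles(
    rec: HemodynamicRecording,
    compression_rate_hint: float = 102.0,
    params: CycleDetectionParams | None = None,
) -> pd.DataFrame:
    """Detect compression cycles on the CPR-phase arterial pressure.

    Returns one row per detected compression peak with index columns
    ``i_up`` (upstroke start), ``i_peak``, ``i_trough`` and ``i_end`` (last
    sample before the next upstroke; -1 when truncated by the recording
    edge).  A flatline trace yields an empty frame.  No cycles are emitted
    inside 30:2 ventilation pauses because no compression peaks exist there.
    """
    if params is None:
        params = CycleDetectionParams()
    fs = rec.sample_rate
    ap = np.asarray(rec.ap, dtype=float)
    cols = ["i_up", "i_peak", "i_trough", "i_end"]
    if len(ap) < 8 or np.ptp(ap) == 0.0:
        return pd.DataFrame(columns=cols, dtype=int)

    sm = _smooth(ap, fs, params.smooth_hz)
    period = 60.0 / compression_rate_hint
    distance = max(1, int(round(params.min_spacing_factor * period * fs)))
    peaks, _ = signal.find_peaks(sm, distance=distance, prominence=params.min_prominence)
    if len(peaks) == 0:
        return pd.DataFrame(columns=cols, dtype=int)

    deriv = np.gradient(sm) * fs
    max_back = int(round(period * fs))
    rows = []
    for j, p in enumerate(peaks):
        lo = max(0, p - max_back)
        dseg = deriv[lo:p]
        if len(dseg) == 0:
            continue
        thr = params.upstroke_frac * max(dseg.max(), 1e-9)
        rising = np.flatnonzero(dseg >= thr)
        if len(rising) == 0:
            continue
        # start of the contiguous rising run that ends at the peak
        runs = np.split(rising, np.flatnonzero(np.diff(rising) > 1) + 1)
        i_up = lo + runs[-1][0]
        hi = peaks[j + 1] if j + 1 < len(peaks) else len(ap)
        i_trough = p + int(np.argmin(ap[p:hi])) if hi > p else p
        rows.append((i_up, p, i_trough))

    out = []
    guard = int(round(params.end_decomp_guard_s * fs))
    cap = int(round(params.end_decomp_cap_periods * period * fs))
    for j, (i_up, p, i_tr) in enumerate(rows):
        if j + 1 < len(rows):
            i_end = min(rows[j + 1][0] - 1 - guard, i_up + cap)
        else:
            i_end = i_up + cap if i_up + cap < len(ap) else -1
        out.append((i_up, p, i_tr, i_end))
    return pd.DataFrame(out, columns=cols, dtype=int)


def extract_cycle_values(
    rec: HemodynamicRecording,
    cycles: pd.DataFrame,
    params: CycleDetectionParams | None = None,
) -> pd.DataFrame:
    """Per-cycle pressures and CPP for detected cycle windows.

    Cycles truncated by the recording edge (no end-of-decompression sample)
    are dropped with a logged count.  For every emitted cycle the identity
    ``cpp = ap_end_decomp - cvp_end_decomp`` holds exactly.
    """
    if params is None:
        params = CycleDetectionParams()
    ap = np.asarray(rec.ap, dtype=float)
    cvp = np.asarray(rec.cvp, dtype=float)
    t = np.asarray(rec.time, dtype=float)
    rows = []
    dropped = 0
    for rec_i in cycles.itertuples(index=False):
        i_up, i_peak, i_tr, i_end = rec_i.i_up, rec_i.i_peak, rec_i.i_trough, rec_i.i_end
        if i_end < 0 or i_end <= i_tr:
            dropped += 1
            continue
        # compression half-cycle: upstroke -> trough; per-channel extrema
        max_ap = float(ap[i_up : i_tr + 1].max())
        max_cvp = float(cvp[i_up : i_tr + 1].max())
        # decompression: trough -> end
        min_ap = float(ap[i_tr : i_end + 1].min())
        min_cvp = float(cvp[i_tr : i_end + 1].min())
        if params.end_decomp_at_trough:
            ap_end = float(ap[i_tr])
            cvp_end = float(cvp[i_tr])
            t_end = float(t[i_tr])
        else:
            ap_end = float(ap[i_end])
            cvp_end = float(cvp[i_end])
            t_end = float(t[i_end])
        i_max = i_up + int(np.argmax(ap[i_up : i_tr + 1]))
        rows.append(
            {
                "t_max_compression": float(t[i_max]),
                "t_max_decompression": float(t[i_tr + int(np.argmin(ap[i_tr : i_end + 1]))]),
                "t_end_decompression": t_end,
                "max_ap": max_ap,
                "min_ap": min_ap,
                "max_cvp": max_cvp,
                "min_cvp": min_cvp,
                "ap_end_decomp": ap_end,
                "cvp_end_decomp": cvp_end,
                "cpp": ap_end - cvp_end,
            }
        )
    if dropped:
        log.info("dropped %d cycles truncated by the recording edge", dropped)
    return pd.DataFrame(
        rows,
        columns=[
            "t_max_compression", "t_max_decompression", "t_end_decompression",
            "max_ap", "min_ap", "max_cvp", "min_cvp",
            "ap_end_decomp", "cvp_end_decomp", "cpp",
        ],
    )


def extract_cycles(
    rec: HemodynamicRecording,
    compression_rate_hint: float = 102.0,
    params: CycleDetectionParams | None = None,
    cpr_start: float = 0.0,
) -> pd.DataFrame:
    """Detect and fill compression cycles on the CPR phase (t >= cpr_start)."""
    i0 = int(np.searchsorted(rec.time, cpr_start))
    sub = HemodynamicRecording(
        time=rec.time[i0:], ap=rec.ap[i0:], cvp=rec.cvp[i0:], sample_rate=rec.sample_rate
    )
    windows = detect_cycles(sub, compression_rate_hint, params)
    return extract_cycle_values(sub, windows, params)


def per_minute_hemo(
    cycles: pd.DataFrame, cpr_start: float = 0.0, duration_min: int = 20
) -> pd.DataFrame:
    """Per-minute means of the per-cycle values, binned by the time of
    maximum compression; empty minutes carry NaN."""
    idx = pd.RangeIndex(1, duration_min + 1, name="minute")
    cols = [
        "mean_max_ap", "mean_min_ap", "mean_max_cvp", "mean_min_cvp",
        "mean_cpp", "n_cycles",
    ]
    if len(cycles) == 0:
        out = pd.DataFrame(index=idx, columns=cols, dtype=float)
        out["n_cycles"] = 0
        return out
    minute = np.floor((cycles["t_max_compression"] - cpr_start) / 60.0).astype(int) + 1
    keep = (minute >= 1) & (minute <= duration_min)
    g = cycles[keep].groupby(minute[keep])
    out = pd.DataFrame(index=idx, columns=cols, dtype=float)
    for src, dst in zip(
        ["max_ap", "min_ap", "max_cvp", "min_cvp", "cpp"],
        ["mean_max_ap", "mean_min_ap", "mean_max_cvp", "mean_min_cvp", "mean_cpp"],
    ):
        out[dst] = g[src].mean()
    out["n_cycles"] = g.size().reindex(idx).fillna(0).astype(int)
    return out


def baseline_summary(
    rec: HemodynamicRecording,
    arrest_time: float,
    last_values: dict[str, float] | None = None,
    baseline_abg: dict[str, float] | None = None,
    window_s: float = 300.0,
) -> dict[str, float]:
    """Baseline summary from the ``window_s`` of recording directly before
    arrest induction: MAP and CVP as means over the window, HR from
    arterial pulse detection.  Monitor values and the baseline ABG are
    passed through unchanged.
    """
    t = np.asarray(rec.time, dtype=float)
    i1 = int(np.searchsorted(t, arrest_time))
    i0 = int(np.searchsorted(t, arrest_time - window_s))
    if t[i0] > arrest_time - window_s + 1.0 / rec.sample_rate:
        raise ValueError("less than the required pre-arrest window available")
    ap = np.asarray(rec.ap[i0:i1], dtype=float)
    cvp = np.asarray(rec.cvp[i0:i1], dtype=float)
    sm = _smooth(ap, rec.sample_rate, 10.0)
    peaks, _ = signal.find_peaks(
        sm, distance=int(0.3 * rec.sample_rate), prominence=max(5.0, 0.2 * np.ptp(sm))
    ) if np.ptp(sm) > 0 else (np.array([], dtype=int), {})
    hr = len(peaks) * 60.0 / window_s
    out = {"hr": hr, "map": float(ap.mean()), "cvp": float(cvp.mean())}
    for src in (last_values, baseline_abg):
        if src:
            out.update({k: float(v) for k, v in src.items()})
    return out
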