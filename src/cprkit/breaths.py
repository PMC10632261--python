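"""Per-breath segmentation and ventilation features from 256 Hz recordings.

Individual ventilations are segmented on a low-pass-filtered flow signal:
the cutoff sits above the breath band (a ~0.4 s inspiration concentrates
below ~1.2 Hz) but attenuates the 1.7 Hz chest-compression oscillation, so
a simple supra-threshold rule separates manual bag breaths from compression
artifact.  Per-breath features are then read off the *raw* channels:

* PIF — maximum inspiratory flow (l/min)
* Vti — trapezoidal integral of positive inspiratory flow (ml)
* PIP — maximum airway pressure over the whole breath window (cmH2O)
* Ti  — inspiration duration (s)
* PECO2 — peak exhaled CO2 in the expiration window, a proxy for EtCO2
  (the compression artifact corrupts the end-tidal plateau, the peak is
  robust to it)

Per-minute means (plus minute volume = sum of Vti) feed the longitudinal
mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import VentilationRecording

log = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass
class DetectionParams:
    """Breath-segmentation thresholds.

    ``lowpass_hz`` must lie above the breath band and below the compression
    frequency content; ``flow_threshold`` is the supra-threshold rule on the
    filtered flow and ``min_insp_s`` the minimum supra-threshold duration for
    a candidate inspiration.
    """

    lowpass_hz: float = 1.4
    filter_order: int = 4
    flow_threshold: float = 5.0     # l/min
    min_insp_s: float = 0.05
    onset_backtrack_s: float = 0.3
    onset_eps: float = 0.5          # l/min, raw-flow level defining onset
    max_breath_s: float = 10.0
    peco2_window_s: float = 5.0
    co2_smooth_hz: float = 0.0      # 0 = peak of the raw CO2 curve
    pip_whole_breath: bool = True   # search PIP over the whole breath window


def _check_uniform_grid(time: np.ndarray, tol: float = 1e-9) -> float:
    dt = np.diff(time)
    if len(dt) == 0:
        raise ValueError("recording too short")
    if np.any(np.abs(dt - dt[0]) > tol + 1e-6 * dt[0]):
        raise ValueError("non-uniform time grid")
    return float(dt[0])


def detect_breaths(
    rec: VentilationRecording, params: DetectionParams | None = None
) -> list[tuple[int, int, int]]:
    """Segment breaths; returns (onset, end_of_inspiration, end_of_breath)
    index triplets, time-ordered and non-overlapping.

    An empty or constant flow trace yields an empty list.
    """
    if params is None:
        params = DetectionParams()
    _check_uniform_grid(rec.time)
    fs = rec.sample_rate
    flow = np.asarray(rec.flow, dtype=float)
    if len(flow) < 8 or np.ptp(flow) == 0.0:
        return []

    sos = signal.butter(
        params.filter_order, params.lowpass_hz, btype="low", fs=fs, output="sos"
    )
    filt = signal.sosfiltfilt(sos, flow)

    above = filt > params.flow_threshold
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(flow)]
    min_len = max(1, int(round(params.min_insp_s * fs)))

    windows: list[tuple[int, int, int]] = []
    back = int(round(params.onset_backtrack_s * fs))
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        # refine onset on the raw flow: the filtered pulse is widened by the
        # filter, so locate the eps-crossing of the raw signal near the
        # filtered threshold crossing (walking whichever way is needed).
        # The eps level adapts to the local artifact floor so the walk stops
        # at the inspiratory upstroke, not inside the compression oscillation.
        w0, w1 = max(0, s - int(0.8 * fs)), max(0, s - int(0.1 * fs))
        if w1 > w0:
            seg = flow[w0:w1]
            floor = 1.4826 * np.median(np.abs(seg - np.median(seg)))
        else:
            floor = 0.0
        eps = float(np.clip(2.0 * floor, params.onset_eps, params.flow_threshold))
        j = s
        lo = max(0, s - back)
        hi_j = min(len(flow) - 1, s + back)
        if flow[j] > eps:
            while j > lo and flow[j - 1] > eps:
                j -= 1
        else:
            while j < hi_j and flow[j] <= eps:
                j += 1
        if windows and j <= windows[-1][1]:
            j = windows[-1][1] + 1
        # end of inspiration: first non-positive raw sample after the
        # inspiratory peak (filtered peak marks the pulse centre)
        pk = s + int(np.argmax(filt[s:e])) if e > s else s
        k = max(pk, j + 1)
        while k < len(flow) - 1 and flow[k] > 0.0:
            k += 1
        windows.append((j, k, k))  # breath end fixed up below

    out: list[tuple[int, int, int]] = []
    cap = int(round(params.max_breath_s * fs))
    for i, (j, k, _) in enumerate(windows):
        nxt = windows[i + 1][0] - 1 if i + 1 < len(windows) else len(flow) - 1
        out.append((j, k, min(nxt, j + cap)))
    return out


def compute_breath_features(
    rec: VentilationRecording,
    window: tuple[int, int, int],
    params: DetectionParams | None = None,
) -> dict[str, float]:
    """Features for one detected breath window.

    Returns a dict with keys onset, pif, vti, pip, ti, peco2.
    """
    if params is None:
        params = DetectionParams()
    i0, i1, i2 = window
    n = len(rec.time)
    if not (0 <= i0 <= i1 <= i2 < n):
        raise ValueError(f"window {window} outside recording of length {n}")
    fs = rec.sample_rate

    insp_flow = np.maximum(rec.flow[i0 : i1 + 1], 0.0)
    pif = float(insp_flow.max()) if len(insp_flow) else 0.0
    # l/min -> ml/s is /60*1000; trapezoid over seconds gives ml
    vti = float(np.trapezoid(insp_flow, rec.time[i0 : i1 + 1]) / 0.06)
    ti = float(rec.time[i1] - rec.time[i0])

    pip_hi = i2 if params.pip_whole_breath else i1
    pip = float(rec.paw[i0 : pip_hi + 1].max())

    j1 = min(i2, i1 + int(round(params.peco2_window_s * fs)))
    if j1 > i1:
        seg = np.asarray(rec.co2[i1 : j1 + 1], dtype=float)
        if params.co2_smooth_hz and params.co2_smooth_hz < fs / 2:
            sos = signal.butter(2, params.co2_smooth_hz, btype="low", fs=fs, output="sos")
            seg = signal.sosfiltfilt(sos, seg)
        peco2 = float(max(seg.max(), 0.0))
    else:
        peco2 = 0.0
    return {
        "onset": float(rec.time[i0]),
        "pif": pif,
        "vti": vti,
        "pip": pip,
        "ti": ti,
        "peco2": peco2,
    }


def extract_breath_features(
    rec: VentilationRecording, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Detect all breaths and tabulate per-breath features."""
    windows = detect_breaths(rec, params)
    rows = [compute_breath_features(rec, w, params) for w in windows]
    return pd.DataFrame(rows, columns=["onset", "pif", "vti", "pip", "ti", "peco2"])


def per_minute_means(
    features: pd.DataFrame, cpr_start: float = 0.0, duration_min: int = 20
) -> pd.DataFrame:
    """Per-minute means of each breath feature plus minute volume.

    A breath belongs to minute ``floor((onset - cpr_start)/60) + 1`` (its
    onset minute).  Minutes without breaths carry NaN, never zero; minute
    volume is the sum of Vti of the minute's breaths.  Breaths with onsets
    before ``cpr_start`` are excluded with a warning.
    """
    idx = pd.RangeIndex(1, duration_min + 1, name="minute")
    cols = ["mean_pif", "mean_vti", "mean_pip", "mean_ti", "mean_peco2", "mv", "n_breaths"]
    if len(features) == 0:
        out = pd.DataFrame(index=idx, columns=cols, dtype=float)
        out["n_breaths"] = 0
        return out
    feats = features.sort_values("onset")
    early = feats["onset"] < cpr_start
    if early.any():
        log.warning("excluding %d breaths before CPR start", int(early.sum()))
        feats = feats[~early]
    minute = np.floor((feats["onset"] - cpr_start) / 60.0).astype(int) + 1
    feats = feats[minute <= duration_min]
    minute = minute[minute <= duration_min]
    g = feats.groupby(minute)
    out = pd.DataFrame(index=idx, columns=cols, dtype=float)
    for feat, col in zip(
        ["pif", "vti", "pip", "ti", "peco2"],
        ["mean_pif", "mean_vti", "mean_pip", "mean_ti", "mean_peco2"],
    ):
        out[col] = g[feat].mean()
    out["mv"] = g["vti"].sum()
    out["n_breaths"] = g.size().reindex(idx).fillna(0).astype(int)
    return out
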