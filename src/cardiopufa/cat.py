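"""Calcium-transient analysis for spontaneously beating monolayers.

Beat detection on the low-pass-filtered fluorescence signal, per-beat
CaT APD90 (time from transient onset to 90% return toward baseline), the
Fridericia rate correction APDc = APD / RR^(1/3) with RR in seconds, and
monolayer summaries averaging the first ten complete beats per condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import minimum_filter1d

from .synth import CaTRecord


@dataclass
class BeatTable:
    onsets_s: np.ndarray
    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    rr_s: np.ndarray          # forward interval; last beat reuses the previous

    def __len__(self):
        return self.onsets_s.size

    @property
    def frequency_hz(self) -> np.ndarray:
        return 1.0 / self.rr_s


def _lowpass(sig: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return sig
    sos = sps.butter(4, cutoff_hz, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, sig)


def detect_beats(record: CaTRecord, threshold_frac: float = 0.2,
                 refractory_s: float = 0.4, lowpass_hz: float = 100.0,
                 baseline_window_s: float = 2.5) -> BeatTable:
    """Onsets where the filtered signal crosses baseline + threshold*amplitude
    upward, separated by at least the refractory period.

    Baseline is a rolling minimum of the filtered signal; amplitude is the
    global (max - baseline) excursion.  A record with no beats yields an
    empty table, not an error.
    """
    t, x = record.time_s, record.signal
    if t.size < 2 or (t[-1] - t[0]) < 2.0 * refractory_s:
        raise ValueError("record shorter than two refractory periods")
    fs = record.fs_hz
    xf = _lowpass(x, fs, lowpass_hz)
    # the rolling-minimum window must cover at least one full beat period,
    # otherwise the baseline rides up on the decaying transient tail
    win = max(int(round(baseline_window_s * fs)), 3)
    baseline = minimum_filter1d(xf, size=win, mode="nearest")
    amp = float(np.max(xf - baseline))
    empty = BeatTable(*(np.empty(0),) * 4)
    if amp <= 0:
        return empty
    thresh = baseline + threshold_frac * amp
    rearm = baseline + 0.5 * threshold_frac * amp
    onsets, peaks_t, peaks_a = [], [], []
    last = -np.inf
    armed = True
    # upward threshold crossings with hysteresis: re-arm only after the
    # signal falls back to half the threshold level
    for i in range(1, t.size):
        if armed and xf[i] > thresh[i] and xf[i - 1] <= thresh[i - 1]:
            if t[i] - last >= refractory_s:
                onsets.append(t[i])
                last = t[i]
            armed = False
        elif not armed and xf[i] < rearm[i]:
            armed = True
    if not onsets:
        return empty
    onsets = np.asarray(onsets)
    # per-beat peaks between consecutive onsets
    bounds = np.append(onsets, t[-1])
    for k in range(onsets.size):
        sel = (t >= bounds[k]) & (t < bounds[k + 1])
        seg = xf[sel]
        j = int(np.argmax(seg))
        peaks_t.append(t[sel][j])
        peaks_a.append(seg[j] - baseline[sel][j])
    rr = np.diff(onsets)
    if rr.size == 0:
        rr_full = np.array([np.nan])
    else:
        rr_full = np.append(rr, rr[-1])
    return BeatTable(onsets, np.asarray(peaks_t), np.asarray(peaks_a), rr_full)


def cat_apd90(record: CaTRecord, beats: BeatTable,
              return_frac: float = 0.10, lowpass_hz: float = 100.0,
              baseline_window_s: float = 2.5) -> np.ndarray:
    """Per-beat CaT APD90 in ms.

    Measured from the beat onset to the first decay-phase crossing of
    baseline + return_frac*(peak - baseline), with linear interpolation.
    Beats truncated by the end of the record are dropped.
    """
    t, x = record.time_s, record.signal
    xf = _lowpass(x, record.fs_hz, lowpass_hz)
    win = max(int(round(baseline_window_s * record.fs_hz)), 3)
    baseline = minimum_filter1d(xf, size=win, mode="nearest")
    out = []
    for k in range(len(beats)):
        on = beats.onsets_s[k]
        end = (beats.onsets_s[k + 1] if k + 1 < len(beats) else t[-1])
        sel = (t >= on) & (t <= end)
        ts, seg, base = t[sel], xf[sel], baseline[sel]
        if seg.size < 3:
            continue
        j_peak = int(np.argmax(seg - base))
        level = base + return_frac * (seg[j_peak] - base[j_peak])
        below = np.nonzero(seg[j_peak:] < level[j_peak:])[0]
        if below.size == 0:
            continue  # truncated: no return to baseline inside the record
        j = j_peak + below[0]
        f = (seg[j - 1] - level[j - 1]) / ((seg[j - 1] - level[j - 1])
                                           - (seg[j] - level[j]))
        t_cross = ts[j - 1] + f * (ts[j] - ts[j - 1])
        out.append((t_cross - on) * 1000.0)
    return np.asarray(out)


def fridericia(apd90_ms, rr_s):
    """Rate-corrected duration APDc = APD / RR^(1/3), RR in seconds."""
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    return np.asarray(apd90_ms, dtype=float) / np.cbrt(rr)


def analyze_record(record: CaTRecord, **detect_kw) -> pd.DataFrame:
    """Beat table + APD90 + APD90c for one record."""
    beats = detect_beats(record, **detect_kw)
    apd = cat_apd90(record, beats)
    n = apd.size
    rr = beats.rr_s[:n]
    return pd.DataFrame({
        "onset_s": beats.onsets_s[:n],
        "rr_s": rr,
        "frequency_hz": 1.0 / rr,
        "apd90_ms": apd,
        "apd90c_ms": fridericia(apd, rr),
    })


def summarize_condition(records_by_monolayer: dict, condition: str,
                        n_beats: int = 10) -> pd.DataFrame:
    """Monolayer means of APD90c over the first ``n_beats`` complete beats.

    Accepts a mapping monolayer-id -> CaTRecord (or an already-analyzed
    per-beat DataFrame).  Monolayers with fewer complete beats use what is
    available and are flagged.
    """
    rows = []
    for mid, rec in records_by_monolayer.items():
        df = rec if isinstance(rec, pd.DataFrame) else analyze_record(rec)
        take = df.head(n_beats)
        rows.append(dict(condition=condition, monolayer=mid,
                         n_beats=len(take),
                         short=len(take) < n_beats,
                         apd90c_ms=take.apd90c_ms.mean(),
                         apd90_ms=take.apd90_ms.mean(),
                         rr_s=take.rr_s.mean()))
    return pd.DataFrame(rows)


def condition_stats(per_monolayer: pd.DataFrame) -> pd.Series:
    """Across-monolayer mean +/- SEM of the monolayer APD90c means."""
    vals = per_monolayer.apd90c_ms.to_numpy()
    n = vals.size
    sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    return pd.Series({"mean_apd90c_ms": vals.mean(), "sem_apd90c_ms": sem,
                      "n_monolayers": n})


def paired_deltas(ctrl: pd.DataFrame, treated: pd.DataFrame) -> pd.DataFrame:
    """Per-monolayer treated - control APD90c differences."""
    m = ctrl.merge(treated, on="monolayer", suffixes=("_ctrl", "_treated"))
    m["delta_apd90c_ms"] = m.apd90c_ms_treated - m.apd90c_ms_ctrl
    return m[["monolayer", "apd90c_ms_ctrl", "apd90c_ms_treated",
              "delta_apd90c_ms"]]
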