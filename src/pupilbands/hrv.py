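"""HRV preprocessing: beat annotations -> clean 8 Hz tachogram signal.

Stages, in order: RR intervals from beat times, Tukey boxplot outlier
removal, linear interpolation onto a uniform grid, and a zero-phase 1 Hz
low-pass to isolate the LF/HF region of interest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import RRSeries, SampledSignal

DEFAULT_FS = 8.0
DEFAULT_LOWPASS_HZ = 1.0


def rr_from_peaks(beat_times) -> RRSeries:
    """RR intervals (ms) from strictly increasing beat times (s)."""
    bt = np.asarray(beat_times, dtype=float)
    if bt.size < 3:
        raise ValueError("need at least 3 beats")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return RRSeries(bt, np.diff(bt) * 1000.0)


def boxplot_outlier_filter(x, k: float = 1.5):
    """Tukey fences: drop values outside [Q1 - k*IQR, Q3 + k*IQR].

    Returns ``(kept values, removed index array)``.  A zero-IQR series flags
    nothing (all points sit at the quartiles), so constant segments survive.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for a boxplot fence")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    removed = np.nonzero((x < lo) | (x > hi))[0]
    if removed.size == x.size:
        raise ValueError("boxplot filter removed every value")
    kept = np.delete(x, removed)
    return kept, removed


def uniform_resample_linear(times, values, fs: float = DEFAULT_FS,
                            ) -> SampledSignal:
    """Linear interpolation of an irregular tachogram onto a uniform grid.

    Grid spans [times[0], times[-1]]; output length floor(span*fs) + 1.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("need >= 2 (time, value) pairs")
    span = t[-1] - t[0]
    n = int(np.floor(span * fs)) + 1
    if n < 2:
        raise ValueError(f"span {span:.3f} s too short for fs={fs}")
    grid = t[0] + np.arange(n) / fs
    return SampledSignal(np.interp(grid, t, v), fs=fs, t0=t[0])


def lowpass(signal: SampledSignal, cutoff: float, order: int = 4,
            ) -> SampledSignal:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    if not cutoff < signal.fs / 2:
        raise ValueError(f"cutoff {cutoff} must be below Nyquist {signal.fs / 2}")
    sos = sps.butter(order, cutoff, btype="low", fs=signal.fs, output="sos")
    y = sps.sosfiltfilt(sos, signal.values)
    return SampledSignal(y, signal.fs, signal.t0, signal.valid_mask.copy())


def preprocess_rr(rr: RRSeries, fs: float = DEFAULT_FS,
                  lowpass_hz: float = DEFAULT_LOWPASS_HZ,
                  fence_k: float = 1.5) -> tuple[SampledSignal, dict]:
    """Full HRV chain; returns the clean signal and a cleaning report."""
    kept, removed = boxplot_outlier_filter(rr.intervals, k=fence_k)
    times = np.delete(rr.tachogram_times, removed)
    if kept.size < 2:
        raise ValueError("fewer than 2 intervals survive outlier removal")
    sig = uniform_resample_linear(times, kept, fs=fs)
    sig = lowpass(sig, lowpass_hz)
    report = {
        "n_beats": len(rr),
        "n_intervals": rr.intervals.size,
        "n_outliers_removed": int(removed.size),
        "fs": fs,
        "n_samples": len(sig),
    }
    return sig, report


# ---------------------------------------------------------------------------
# plain-text I/O

def read_beats_csv(path: str | Path) -> RRSeries:
    """Beat annotations (column ``beat_time_s``) or intervals (``rr_ms``)."""
    df = pd.read_csv(path)
    if "beat_time_s" in df.columns:
        return rr_from_peaks(df["beat_time_s"].to_numpy())
    if "rr_ms" in df.columns:
        rr_ms = df["rr_ms"].to_numpy(dtype=float)
        beat_times = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
        return RRSeries(beat_times, rr_ms)
    raise ValueError(f"{path}: expected a beat_time_s or rr_ms column")


def write_hrv_csv(sig: SampledSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": sig.times, "rr_ms": sig.values}).to_csv(
        path, index=False, float_format="%.6f")
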