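"""Pulse detection, inter-beat intervals, and windowed heart rate.

Systolic peaks are detected as prominence-thresholded local maxima with a
physiological refractory distance (0.25 s, a 240 bpm ceiling); the
prominence threshold adapts to the record as half the typical rolling
signal SD.  IBIs are taken peak-to-peak (peaks are the most robust landmark
in wrist PPG, where the diastolic peak and dicrotic notch are often
undetectable) and screened to 250-2000 ms before HRV analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal

from .io import PPGRecord

__all__ = [
    "PulseSeries",
    "HRSeries",
    "InsufficientBeatsError",
    "detect_pulses",
    "heart_rate_series",
]

MIN_IBI_MS = 250.0
MAX_IBI_MS = 2000.0


class InsufficientBeatsError(ValueError):
    """Too few pulses detected to analyse the record."""


@dataclasses.dataclass
class PulseSeries:
    """Detected systolic peaks, pulse onsets, and the derived IBI series."""

    peak_indices: np.ndarray
    onset_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        self.onset_indices = np.asarray(self.onset_indices, dtype=np.int64)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.peak_indices.size)

    @property
    def ibis_ms(self) -> np.ndarray:
        """Peak-to-peak intervals in ms (unscreened)."""
        return np.diff(self.peak_indices) / self.fs * 1000.0

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs

    def valid_ibis_ms(self, lo: float = MIN_IBI_MS, hi: float = MAX_IBI_MS,
                      with_times: bool = False):
        """IBIs inside the physiological screen, optionally with end times (s)."""
        ibis = self.ibis_ms
        keep = (ibis >= lo) & (ibis <= hi)
        if with_times:
            return ibis[keep], self.peak_times_s[1:][keep]
        return ibis[keep]


@dataclasses.dataclass
class HRSeries:
    """Per-window heart rate (non-overlapping windows, trailing partial dropped)."""

    bpm: np.ndarray
    window_s: float = 10.0

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)

    @property
    def valid_bpm(self) -> np.ndarray:
        """Rates surviving the validity screen (20 < bpm < 250, window non-empty)."""
        b = self.bpm
        return b[(b > 20) & (b < 250)]


def detect_pulses(record: PPGRecord, min_distance_s: float = 0.25,
                  prominence_factor: float = 0.5,
                  rolling_window_s: float = 2.0) -> PulseSeries:
    """Detect one systolic peak per cardiac cycle and its preceding onset."""
    if record.stage != "repaired":
        raise ValueError(f"expected a repaired record, got stage={record.stage!r}")
    if record.duration_s < 10:
        raise ValueError("record shorter than 10 s")
    x = record.samples
    fs = record.fs
    win = max(3, int(round(rolling_window_s * fs)))
    rolling_sd = pd.Series(x).rolling(win, min_periods=win // 2, center=True).std()
    prominence = prominence_factor * float(np.nanmedian(rolling_sd))
    if not prominence > 0:
        raise InsufficientBeatsError("flat signal: no pulses detectable")
    peaks, _ = signal.find_peaks(x, distance=max(1, int(round(min_distance_s * fs))),
                                 prominence=prominence)
    if peaks.size < 3:
        raise InsufficientBeatsError(f"only {peaks.size} peaks found")
    # onset k = local minimum between peak k-1 and peak k (record start for k=0)
    onsets = np.empty(peaks.size, dtype=np.int64)
    prev = 0
    for k, p in enumerate(peaks):
        seg = x[prev:p]
        onsets[k] = prev + (int(np.argmin(seg)) if seg.size else 0)
        prev = p
    return PulseSeries(peak_indices=peaks, onset_indices=onsets, fs=fs)


def heart_rate_series(pulses: PulseSeries, record_length: int,
                      window_s: float = 10.0) -> HRSeries:
    """Heart rate per non-overlapping window: peak count x (60 / window_s).

    Windows with zero peaks are flagged invalid (bpm 0, excluded by the
    validity screen); the trailing partial window is discarded.
    """
    fs = pulses.fs
    n_windows = int(record_length / fs // window_s)
    if n_windows < 1:
        raise ValueError("record does not cover one full window")
    edges = (np.arange(n_windows + 1) * window_s * fs).astype(np.int64)
    counts, _ = np.histogram(pulses.peak_indices, bins=edges)
    return HRSeries(bpm=counts * (60.0 / window_s), window_s=window_s)
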