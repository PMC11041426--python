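"""Pulse-waveform geometry features.

Each detected pulse (onset -> systolic peak -> next onset) yields 14
geometric quantities: rise/fall times RT and FT, rising/falling edge
magnitudes RP and FN, the edge slopes (RP/RT, FN/FT), the areas under the
rising and falling edges (AUR, A_FE) and the whole pulse (A_Pulse) after
subtracting the chord joining the two onsets, the area ratio
A_ratio = AUR/A_FE, the pulse duration, and the ratios RT/FT, RP/FN and
Rslope/Fslope.  Eight summary statistics over pulses per quantity give the
112-entry block.  Wrist PPG typically lacks a usable dicrotic notch, so no
diastolic-peak quantities are attempted.
"""

from __future__ import annotations

import numpy as np

from ..beats import PulseSeries
from ..io import PPGRecord
from ._stats import stats8
from .hrv import InsufficientDataError

__all__ = ["pulse_geometry", "waveform_features", "hr_features", "cwt_features"]

MIN_VALID_PULSES = 10


def pulse_geometry(pulses: PulseSeries, record: PPGRecord) -> np.ndarray:
    """Per-pulse (n_valid, 14) geometry matrix in catalogue quantity order."""
    x = record.samples
    fs = record.fs
    rows = []
    for k in range(pulses.count - 1):
        on0 = pulses.onset_indices[k]
        pk = pulses.peak_indices[k]
        on1 = pulses.onset_indices[k + 1]
        if not (on0 < pk < on1) or on1 >= x.size:
            continue
        rt = (pk - on0) / fs
        ft = (on1 - pk) / fs
        rp = x[pk] - x[on0]
        fn = x[pk] - x[on1]
        if rp <= 0 or fn <= 0:
            continue
        seg = x[on0:on1 + 1]
        chord = np.linspace(seg[0], seg[-1], seg.size)
        y = seg - chord
        i_pk = pk - on0
        aur = float(np.trapezoid(y[: i_pk + 1], dx=1.0 / fs))
        auf = float(np.trapezoid(y[i_pk:], dx=1.0 / fs))
        if aur <= 0 or auf <= 0:
            continue
        rslope, fslope = rp / rt, fn / ft
        rows.append([rt, ft, rp, fn, rslope, fslope, aur, auf, aur + auf,
                     aur / auf, rt + ft, rt / ft, rp / fn, rslope / fslope])
    return np.asarray(rows, dtype=float)


def waveform_features(pulses: PulseSeries, record: PPGRecord) -> np.ndarray:
    """112 values: stats8 over pulses for each of the 14 geometry quantities."""
    geom = pulse_geometry(pulses, record)
    if geom.shape[0] < MIN_VALID_PULSES:
        raise InsufficientDataError(
            f"only {geom.shape[0]} valid pulses (< {MIN_VALID_PULSES})")
    return np.concatenate([stats8(geom[:, q]) for q in range(geom.shape[1])])


def hr_features(bpm_valid: np.ndarray) -> np.ndarray:
    """10 statistics of the windowed heart-rate series (valid windows only)."""
    from scipy import stats as sps

    b = np.asarray(bpm_valid, dtype=float)
    if b.size < 3:
        raise InsufficientDataError(f"need >= 3 valid HR windows, got {b.size}")
    q75, q25 = np.percentile(b, [75, 25])
    sd = b.std()
    return np.array([
        b.mean(), sd, np.median(b), q75 - q25, b.min(), b.max(),
        b.max() - b.min(),
        sps.skew(b) if sd > 0 else 0.0,
        sps.kurtosis(b) if sd > 0 else 0.0,
        sd / b.mean() if b.mean() != 0 else 0.0,
    ])


def cwt_features(record: PPGRecord, n_scales: int = 32,
                 f_lo: float = 0.3, f_hi: float = 4.0) -> np.ndarray:
    """Mean, SD, max of |CWT| with the Mexican-hat wavelet.

    Scales are 32 logarithmic steps whose pseudo-frequencies span the
    pass band (0.3-4 Hz).
    """
    import pywt

    if record.stage != "repaired":
        raise ValueError(f"expected a repaired record, got stage={record.stage!r}")
    fc = pywt.central_frequency("mexh")
    freqs = np.geomspace(f_lo, f_hi, n_scales)
    scales = fc * record.fs / freqs
    coefs, _ = pywt.cwt(record.samples, scales, "mexh",
                        sampling_period=1.0 / record.fs)
    mag = np.abs(coefs)
    return np.array([mag.mean(), mag.std(), mag.max()])
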