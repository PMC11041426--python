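"""Frame-level energy measures: Kaiser-Teager energy and log energy.

Both operate on non-overlapping 5-second frames of the cleaned signal.
The Kaiser-Teager operator KTE(i) = x(i)^2 - x(i+1) x(i-1) gives an
instantaneous amplitude-frequency energy; ten statistics are computed per
frame and averaged across frames.  The log energy of a frame is
E_log = sum_i log(x(i)^2 + eps) with eps = 1e-12 (so an all-zero frame
contributes a finite floor value); its across-frame sequence yields ten
statistics plus the seven Yule-Walker AR(7) coefficients.
"""

from __future__ import annotations

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from ..io import PPGRecord
from ._stats import stats10
from .hrv import InsufficientDataError

__all__ = ["frame_signal", "teager_kaiser", "kte_features",
           "log_energy_sequence", "log_energy_features", "LOG_EPS"]

FRAME_S = 5.0
LOG_EPS = 1e-12
AR_ORDER_LOG = 7


def frame_signal(x: np.ndarray, fs: float, frame_s: float = FRAME_S) -> np.ndarray:
    """(n_frames, frame_len) view of non-overlapping frames; tail discarded."""
    frame_len = int(round(frame_s * fs))
    if frame_len < 3:
        raise ValueError("frame shorter than 3 samples")
    n = (x.size // frame_len) * frame_len
    return x[:n].reshape(-1, frame_len)


def teager_kaiser(x: np.ndarray) -> np.ndarray:
    """KTE over the interior samples: x_i^2 - x_{i+1} x_{i-1}."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    return x[1:-1] ** 2 - x[2:] * x[:-2]


def kte_features(record: PPGRecord, frame_s: float = FRAME_S) -> np.ndarray:
    """10 KTE statistics (incl. KTE_skew), each averaged across frames."""
    frames = frame_signal(record.samples, record.fs, frame_s)
    if frames.shape[0] < 2:
        raise InsufficientDataError("need >= 2 complete frames for KTE features")
    per_frame = np.vstack([stats10(teager_kaiser(f)) for f in frames])
    return per_frame.mean(axis=0)


def log_energy_sequence(x: np.ndarray, fs: float,
                        frame_s: float = FRAME_S) -> np.ndarray:
    """E_log per frame: sum(log(x^2 + eps))."""
    frames = frame_signal(x, fs, frame_s)
    return np.log(frames**2 + LOG_EPS).sum(axis=1)


def log_energy_features(record: PPGRecord, frame_s: float = FRAME_S) -> np.ndarray:
    """17 values: 10 statistics of the E_log sequence (incl. LOG_std) plus
    the 7 Yule-Walker AR coefficients of order 7 (convention
    x_t = a_1 x_{t-1} + ... + e_t)."""
    e = log_energy_sequence(record.samples, record.fs, frame_s)
    if e.size < 10:
        raise InsufficientDataError(
            f"need >= 10 frames for log-energy features, got {e.size}")
    st = stats10(e)
    if e.std() > 0:
        rho, _ = yule_walker(e - e.mean(), order=AR_ORDER_LOG, method="mle")
    else:
        rho = np.zeros(AR_ORDER_LOG)  # constant sequence carries no AR structure
    return np.concatenate([st, rho])
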