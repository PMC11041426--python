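"""Shared summary-statistic helpers for feature blocks.

Conventions for degenerate inputs: skewness/kurtosis of a constant series
are 0; coefficient of variation with zero mean is 0.  Kurtosis is excess
kurtosis (normal -> 0); both moments are the biased (population) versions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

STAT8 = ("mean", "sd", "median", "iqr", "min", "max", "skew", "kurt")
STAT10 = STAT8 + ("rms", "cv")


def _skew(v: np.ndarray) -> float:
    return float(sps.skew(v)) if np.std(v) > 0 else 0.0


def _kurt(v: np.ndarray) -> float:
    return float(sps.kurtosis(v)) if np.std(v) > 0 else 0.0


def stats8(v: np.ndarray) -> np.ndarray:
    """mean, SD, median, IQR, min, max, skewness, excess kurtosis."""
    v = np.asarray(v, dtype=float)
    q75, q25 = np.percentile(v, [75, 25])
    return np.array([
        v.mean(), v.std(), np.median(v), q75 - q25, v.min(), v.max(),
        _skew(v), _kurt(v),
    ])


def stats10(v: np.ndarray) -> np.ndarray:
    """stats8 plus RMS and coefficient of variation (SD/mean, 0 if mean=0)."""
    v = np.asarray(v, dtype=float)
    rms = float(np.sqrt(np.mean(v**2)))
    m = v.mean()
    cv = float(v.std() / m) if m != 0 else 0.0
    return np.concatenate([stats8(v), [rms, cv]])
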