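"""Sample entropy and multiscale entropy (MSE).

SampEn(m, r) = -ln(A/B), where B counts pairs of length-m templates whose
Chebyshev distance is <= r (self-matches excluded) and A counts the same
pairs extended to length m+1.  Both counts use the N-m templates that admit
an (m+1)-extension.  Pair counting goes through a k-d tree, which makes
full-record (N ~ 15000) evaluation fast; tests check it against a direct
O(N^2) template counter.

MSE evaluates SampEn on coarse-grained (non-overlapping block-mean)
versions of the signal; the tolerance r is fixed from the SD of the
original scale-1 series, following the original MSE formulation (a
per-scale r is available as an option).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from ..beats import PulseSeries
from ..io import PPGRecord
from .catalog import MSE_SCALES

__all__ = [
    "SampEnParams",
    "DegenerateSeriesError",
    "sample_entropy",
    "coarse_grain",
    "mse_curve",
    "mse_features",
    "MIN_PULSES_FOR_MSE",
]

MIN_PULSES_FOR_MSE = 240      # pulse-count gate for a trustworthy MSE block
MIN_COARSE_LENGTH = 100       # shortest coarse-grained series worth analysing


class DegenerateSeriesError(ValueError):
    """Zero-variance series: the tolerance r = 0.1*SD collapses to zero."""


@dataclasses.dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension m, tolerance r, and series length N.

    r defaults to 0.1 x SD of the series (the convention used throughout
    this package; note many references use 0.2 x SD).
    """

    m: int = 2
    r: float | None = None
    r_factor: float = 0.1

    def resolve_r(self, series: np.ndarray) -> float:
        if self.r is not None:
            return float(self.r)
        return self.r_factor * float(np.std(series))


def _template_pairs(x: np.ndarray, m: int, r: float, n_templates: int) -> int:
    """Number of unordered template pairs (i<j) with Chebyshev distance <= r."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tree = cKDTree(np.ascontiguousarray(emb))
    total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
    return int((total - n_templates) // 2)


def sample_entropy(series: np.ndarray, params: SampEnParams | None = None) -> float:
    """SampEn of a 1-D series; capped at ln(n_pairs) when no m+1 match exists."""
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    m = params.m
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need N > m+1 = {m + 1}, got N = {n}")
    if np.std(x) == 0:
        raise DegenerateSeriesError("constant series has undefined SampEn")
    r = params.resolve_r(x)
    if not r > 0:
        raise DegenerateSeriesError("tolerance r must be positive")
    n_templates = n - m  # templates that admit an (m+1)-extension
    b = _template_pairs(x, m, r, n_templates)
    a = _template_pairs(x, m + 1, r, n_templates)
    if b == 0:
        # no matches at length m either; maximal irregularity at this N
        return float(np.log(n_templates * (n_templates - 1) / 2))
    if a == 0:
        # documented cap: -ln of the smallest resolvable conditional probability
        return float(np.log(n_templates * (n_templates - 1) / 2))
    return float(-np.log(a / b))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length tau; output length floor(N/tau)."""
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if x.size < tau:
        raise ValueError(f"series of length {x.size} shorter than tau={tau}")
    n = (x.size // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def mse_curve(series: np.ndarray, scales=MSE_SCALES, m: int = 2,
              r_factor: float = 0.1, per_scale_r: bool = False) -> np.ndarray:
    """SampEn of the coarse-grained series at each timescale factor."""
    x = np.asarray(series, dtype=float)
    r1 = r_factor * float(np.std(x))
    out = np.empty(len(scales))
    for i, tau in enumerate(scales):
        cg = coarse_grain(x, int(tau))
        if cg.size < MIN_COARSE_LENGTH:
            raise ValueError(
                f"coarse-grained series too short at tau={tau} ({cg.size} points)")
        params = SampEnParams(m=m, r=None if per_scale_r else r1, r_factor=r_factor)
        out[i] = sample_entropy(cg, params)
    return out


def mse_features(record: PPGRecord, pulses: PulseSeries, m: int = 2,
                 r_factor: float = 0.1, per_scale_r: bool = False) -> np.ndarray:
    """The 20-entry MSE block over timescale factors 8-14.

    Composition: the 7 per-scale entropies, the 6 adjacent-scale sums
    (including MSE_sum_13_14), the 6 adjacent-scale means, and the grand
    mean over scales 8-14.  Records with fewer than 240 pulses return an
    all-NaN block (recorded as missing rather than unreliable numbers).
    """
    if pulses.count < MIN_PULSES_FOR_MSE:
        return np.full(20, np.nan)
    try:
        curve = mse_curve(record.samples, MSE_SCALES, m=m, r_factor=r_factor,
                          per_scale_r=per_scale_r)
    except ValueError:
        return np.full(20, np.nan)
    sums = curve[:-1] + curve[1:]
    return np.concatenate([curve, sums, sums / 2.0, [curve.mean()]])
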