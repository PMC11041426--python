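"""Heart-rate-variability features: time domain, spectral, nonlinear.

The IBI (NN) series is analysed over a single 5-minute frame.  Spectral
features come from an evenly resampled 4 Hz tachogram via either a Welch
periodogram or a Yule-Walker autoregressive (order 16) spectrum, with the
standard VLF (0.0033-0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
bands.  Nonlinear measures cover the Poincare geometry, entropies, detrended
fluctuation analysis, fractal dimensions and a correlation-dimension
estimate.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps_signal
from scipy import stats as sps
from statsmodels.regression.linear_model import yule_walker

from .entropy import SampEnParams, sample_entropy

__all__ = [
    "InsufficientDataError",
    "hrv_time_features",
    "hrv_frequency_features",
    "hrv_nonlinear_features",
    "BANDS",
]

BANDS = {"vlf": (0.0033, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}
TACHOGRAM_FS = 4.0
AR_ORDER_HRV = 16


class InsufficientDataError(ValueError):
    """Too few IBIs (or too short a tachogram) for the requested features."""


# ---------------------------------------------------------------- time domain

def _triangular_index_and_tinn(nn: np.ndarray) -> tuple[float, float]:
    """HRV triangular index and TINN from the 1/128 s histogram."""
    binw = 1000.0 / 128.0  # ms
    lo = np.floor(nn.min() / binw) * binw
    n_bins = max(1, int(np.ceil((nn.max() - lo) / binw)) + 1)
    edges = lo + np.arange(n_bins + 1) * binw
    hist, _ = np.histogram(nn, bins=edges)
    peak = hist.max()
    hti = nn.size / peak if peak > 0 else 0.0
    # TINN: least-squares triangular fit over the histogram, baseline N..M
    centers = edges[:-1] + binw / 2
    kmax = int(np.argmax(hist))
    best, best_nm = np.inf, (centers[0], centers[-1])
    for i in range(0, kmax + 1):
        for j in range(kmax, n_bins):
            if i == j:
                continue
            tri = np.zeros(n_bins)
            left = slice(i, kmax + 1)
            if kmax > i:
                tri[left] = peak * (centers[left] - centers[i]) / (centers[kmax] - centers[i])
            else:
                tri[kmax] = peak
            right = slice(kmax, j + 1)
            if j > kmax:
                tri[right] = peak * (centers[j] - centers[right]) / (centers[j] - centers[kmax])
            tri[kmax] = peak
            err = float(np.sum((hist - tri) ** 2))
            if err < best:
                best, best_nm = err, (centers[i], centers[j])
    tinn = best_nm[1] - best_nm[0]
    return float(hti), float(tinn)


def hrv_time_features(ibis_ms: np.ndarray) -> np.ndarray:
    """The 31 time-domain statistics of the NN series (ms).

    Includes the standard NN summary statistics, RMSSD, SDSD (defined here
    as the SD of the *absolute* successive differences), pNN20/pNN50 and
    their counts, NN-derived heart-rate statistics, the HRV triangular
    index and TINN.
    """
    nn = np.asarray(ibis_ms, dtype=float)
    if nn.size < 10:
        raise InsufficientDataError(f"need >= 10 IBIs, got {nn.size}")
    d = np.diff(nn)
    ad = np.abs(d)
    hr = 60000.0 / nn
    q75, q25 = np.percentile(nn, [75, 25])
    adq75, adq25 = np.percentile(ad, [75, 25])
    rmssd = float(np.sqrt(np.mean(d**2)))
    hti, tinn = _triangular_index_and_tinn(nn)
    mean_nn = nn.mean()
    vals = [
        mean_nn, np.median(nn), nn.std(), q75 - q25, nn.min(), nn.max(),
        nn.max() - nn.min(), np.mean(np.abs(nn - mean_nn)),
        np.percentile(nn, 10), np.percentile(nn, 90),
        sps.skew(nn) if nn.std() > 0 else 0.0,
        sps.kurtosis(nn) if nn.std() > 0 else 0.0,
        nn.std() / mean_nn,
        rmssd, ad.std(), rmssd / mean_nn,
        np.sum(ad > 20.0), 100.0 * np.mean(ad > 20.0),
        np.sum(ad > 50.0), 100.0 * np.mean(ad > 50.0),
        ad.mean(), np.median(ad), adq75 - adq25, ad.max(),
        hr.mean(), np.median(hr), hr.min(), hr.max(), hr.std(),
        hti, tinn,
    ]
    return np.asarray(vals, dtype=float)


# ------------------------------------------------------------- spectral domain

def resample_tachogram(ibis_ms: np.ndarray, times_s: np.ndarray | None = None,
                       fs: float = TACHOGRAM_FS) -> tuple[np.ndarray, float]:
    """Linear-interpolate the IBI series onto an even fs grid (values in ms)."""
    nn = np.asarray(ibis_ms, dtype=float)
    if times_s is None:
        times_s = np.cumsum(nn) / 1000.0
    t = np.asarray(times_s, dtype=float)
    span = t[-1] - t[0]
    if span < 2.0 / BANDS["hf"][0]:
        raise InsufficientDataError(
            f"tachogram spans {span:.1f} s, shorter than two HF cycles")
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return np.interp(grid, t, nn), fs


def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(256, x.size)
    return sps_signal.welch(x - x.mean(), fs=fs, nperseg=nperseg,
                            noverlap=nperseg // 2)


def _ar_psd(x: np.ndarray, fs: float, order: int = AR_ORDER_HRV,
            n_freqs: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Yule-Walker AR spectrum evaluated on a dense grid."""
    xc = x - x.mean()
    rho, sigma = yule_walker(xc, order=order, method="mle")
    freqs = np.linspace(0, fs / 2, n_freqs)
    _, h = sps_signal.freqz(b=[1.0], a=np.concatenate([[1.0], -rho]),
                            worN=freqs, fs=fs)
    psd = (sigma**2 / fs) * np.abs(h) ** 2 * 2.0  # one-sided
    return freqs, psd


def _band_features(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    powers, peaks = {}, {}
    for band, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        if sel.sum() >= 2:
            powers[band] = float(np.trapezoid(psd[sel], freqs[sel]))
        else:
            powers[band] = float(psd[sel].sum() * (freqs[1] - freqs[0])) if sel.any() else 0.0
        peaks[band] = float(freqs[sel][np.argmax(psd[sel])]) if sel.any() else 0.0
    total = float(np.trapezoid(psd[freqs <= BANDS["hf"][1]],
                               freqs[freqs <= BANDS["hf"][1]]))
    total = max(total, 1e-24)
    lf_hf = powers["lf"] / powers["hf"] if powers["hf"] > 0 else 0.0
    lfhf_sum = max(powers["lf"] + powers["hf"], 1e-24)
    return np.array([
        total, powers["vlf"], powers["lf"], powers["hf"], lf_hf,
        powers["vlf"] / total, powers["lf"] / total, powers["hf"] / total,
        powers["lf"] / lfhf_sum, powers["hf"] / lfhf_sum,
        peaks["vlf"], peaks["lf"], peaks["hf"],
    ])


def hrv_frequency_features(ibis_ms: np.ndarray, method: str = "welch",
                           times_s: np.ndarray | None = None) -> np.ndarray:
    """13 spectral features of the tachogram for one PSD estimator.

    total power (VLF..HF), absolute VLF/LF/HF powers, LF/HF, relative
    powers (fraction of total), LF/HF normalized powers (fraction of
    LF+HF), and per-band peak frequencies.
    """
    x, fs = resample_tachogram(ibis_ms, times_s)
    if method == "welch":
        freqs, psd = _welch_psd(x, fs)
    elif method == "ar":
        freqs, psd = _ar_psd(x, fs)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return _band_features(freqs, psd)


# ------------------------------------------------------------------ nonlinear

def _dfa(x: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis exponent over the given box sizes."""
    y = np.cumsum(x - x.mean())
    flucts = []
    for n in scales:
        n = int(n)
        n_boxes = y.size // n
        if n_boxes < 2:
            continue
        segs = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box linear detrend
        tc = t - t.mean()
        beta = segs @ tc / (tc @ tc)
        resid = segs - segs.mean(axis=1, keepdims=True) - np.outer(beta, tc)
        flucts.append((n, np.sqrt(np.mean(resid**2))))
    if len(flucts) < 2:
        return np.nan
    ns, fs_ = zip(*flucts)
    fs_ = np.maximum(fs_, 1e-12)
    return float(np.polyfit(np.log(ns), np.log(fs_), 1)[0])


def _higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    n = x.size
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            d = np.abs(np.diff(x[idx])).sum()
            lengths.append(d * (n - 1) / (((idx.size - 1) * k) * k))
        if lengths:
            lk.append(np.mean(lengths))
            ks.append(k)
    lk = np.maximum(lk, 1e-12)
    return float(np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lk), 1)[0])


def _petrosian_fd(x: np.ndarray) -> float:
    n = x.size
    d = np.diff(x)
    n_delta = int(np.sum(d[1:] * d[:-1] < 0))
    if n_delta == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def _correlation_dimension(x: np.ndarray, m: int = 2) -> float:
    """Grassberger-Procaccia slope estimate at embedding dimension m."""
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    if emb.shape[0] > 600:          # cap pairwise work; subsample evenly
        emb = emb[:: emb.shape[0] // 600 + 1]
    d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    iu = np.triu_indices(d.shape[0], k=1)
    dist = d[iu]
    dist = dist[dist > 0]
    if dist.size < 10:
        return np.nan
    radii = np.percentile(dist, [5, 10, 20, 30, 40, 50])
    radii = np.unique(radii[radii > 0])
    if radii.size < 2:
        return np.nan
    c = np.array([np.mean(dist <= r) for r in radii])
    return float(np.polyfit(np.log(radii), np.log(np.maximum(c, 1e-12)), 1)[0])


def hrv_nonlinear_features(ibis_ms: np.ndarray) -> np.ndarray:
    """14 nonlinear HRV measures.

    Poincare SD1/SD2 (with ratio, ellipse area, CSI, CVI, modified CSI),
    approximate and sample entropy of the NN series, DFA alpha1/alpha2
    (NaN below 50 IBIs), Higuchi and Petrosian fractal dimensions, and a
    correlation-dimension estimate.
    """
    nn = np.asarray(ibis_ms, dtype=float)
    if nn.size < 10:
        raise InsufficientDataError(f"need >= 10 IBIs, got {nn.size}")
    d = np.diff(nn)
    # SD1 = RMSSD / sqrt(2) exactly (no mean subtraction): the convention
    # under which the Poincare identity holds for any IBI series
    sd1 = float(np.sqrt(np.mean(d**2) / 2.0))
    sdnn = float(nn.std())
    sd2 = float(np.sqrt(max(2 * sdnn**2 - sd1**2, 0.0)))
    t_, l_ = 4 * sd1, 4 * sd2
    csi = l_ / t_ if t_ > 0 else 0.0
    cvi = float(np.log10(l_ * t_)) if l_ * t_ > 0 else 0.0
    csi_mod = l_**2 / t_ if t_ > 0 else 0.0
    if nn.std() > 0:
        apen = _approximate_entropy(nn)
        sampen_nn = sample_entropy(nn, SampEnParams(m=2, r_factor=0.1))
    else:
        apen = 0.0
        sampen_nn = 0.0
    alpha1 = _dfa(nn, np.arange(4, 17)) if nn.size >= 50 else np.nan
    hi = min(64, nn.size // 4)
    alpha2 = _dfa(nn, np.unique(np.geomspace(16, hi, 8).astype(int))) \
        if nn.size >= 64 and hi > 16 else np.nan
    if nn.std() > 0:
        hfd = _higuchi_fd(nn)
        pfd = _petrosian_fd(nn)
        cdim = _correlation_dimension(nn)
    else:
        hfd, pfd, cdim = 0.0, 1.0, 0.0
    return np.array([
        sd1, sd2, sd1 / sd2 if sd2 > 0 else 0.0,
        np.pi * sd1 * sd2, csi, cvi, csi_mod,
        apen, sampen_nn, alpha1, alpha2, hfd, pfd, cdim,
    ])


def _approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.1) -> float:
    r = r_factor * float(np.std(x))

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        c = np.mean(d <= r, axis=1)  # self-matches included (ApEn convention)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)
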