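"""The frozen 248-entry feature catalogue.

The catalogue is the single source of truth for feature identifiers,
ordering and family membership: F1-F71 HRV (time / Welch / AR / nonlinear),
F72-F81 heart rate, F82-F84 continuous wavelet transform, F85-F196 pulse
waveform geometry (14 quantities x 8 statistics), F197-F206 Kaiser-Teager
energy, F207-F223 log energy (10 statistics + 7 Yule-Walker AR
coefficients), F224 sample entropy, F225-F244 multiscale entropy, plus the
four demographic covariates.  Block boundaries and the named features
(Welch_hf_rel, A_FE_mean, KTE_skew, LOG_std, MSE_sum_13_14, ...) are fixed;
individual definitions inside a block are the package's canonical choices.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from ._stats import STAT8, STAT10

__all__ = ["CatalogEntry", "FeatureCatalog", "FeatureVector", "FEATURE_CATALOG"]

HRV_TIME_NAMES = (
    "nn_mean", "nn_median", "sdnn", "nn_iqr", "nn_min", "nn_max", "nn_range",
    "nn_mad", "nn_p10", "nn_p90", "nn_skew", "nn_kurt", "cvnn",
    "rmssd", "sdsd", "cvsd",
    "nn20", "pnn20", "nn50", "pnn50",
    "sd_abs_mean", "sd_abs_median", "sd_abs_iqr", "sd_abs_max",
    "hr_nn_mean", "hr_nn_median", "hr_nn_min", "hr_nn_max", "hr_nn_sd",
    "hti", "tinn",
)  # 31

SPECTRAL_NAMES = (
    "total_power", "vlf", "lf", "hf", "lf_hf",
    "vlf_rel", "lf_rel", "hf_rel", "lf_norm", "hf_norm",
    "vlf_peak", "lf_peak", "hf_peak",
)  # 13 per PSD estimator

HRV_NONLINEAR_NAMES = (
    "sd1", "sd2", "sd1_sd2", "ellipse_area", "csi", "cvi", "csi_modified",
    "apen_nn", "sampen_nn", "dfa_alpha1", "dfa_alpha2",
    "higuchi_fd", "petrosian_fd", "corr_dim",
)  # 14

HR_NAMES = ("HR_mean", "HR_sd", "HR_median", "HR_iqr", "HR_min", "HR_max",
            "HR_range", "HR_skew", "HR_kurt", "HR_cv")  # 10

CWT_NAMES = ("CWT_mean", "CWT_sd", "CWT_max")  # 3

WAVEFORM_QUANTITIES = (
    "RT", "FT", "RP", "FN", "Rslope", "Fslope",
    "AUR", "A_FE", "A_Pulse", "A_ratio", "PD",
    "RT_FT", "RP_FN", "Rslope_Fslope",
)  # 14; x STAT8 -> 112

MSE_SCALES = tuple(range(8, 15))  # timescale factors 8..14

DEMOGRAPHIC_NAMES = ("Age", "Gender", "BMI", "Family_history")


@dataclasses.dataclass(frozen=True)
class CatalogEntry:
    feature_id: str      # "F1".."F244" or a demographic name
    family: str
    name: str            # human-readable / Table-style name


def _build_entries() -> tuple[CatalogEntry, ...]:
    entries: list[CatalogEntry] = []
    k = 1

    def add(family: str, name: str) -> None:
        nonlocal k
        entries.append(CatalogEntry(f"F{k}", family, name))
        k += 1

    for nm in HRV_TIME_NAMES:
        add("hrv_time", nm)
    for nm in SPECTRAL_NAMES:
        add("hrv_welch", f"Welch_{nm}")
    for nm in SPECTRAL_NAMES:
        add("hrv_ar", f"AR_{nm}")
    for nm in HRV_NONLINEAR_NAMES:
        add("hrv_nonlinear", nm)
    for nm in HR_NAMES:
        add("hr", nm)
    for nm in CWT_NAMES:
        add("cwt", nm)
    for q in WAVEFORM_QUANTITIES:
        for s in STAT8:
            add("waveform", f"{q}_{'sd' if s == 'sd' else s}")
    for s in STAT10:
        add("kte", f"KTE_{'std' if s == 'sd' else s}")
    for s in STAT10:
        add("log_energy", f"LOG_{'std' if s == 'sd' else s}")
    for i in range(1, 8):
        add("log_energy", f"LOG_ar{i}")
    add("sampen", "SampEn")
    for tau in MSE_SCALES:
        add("mse", f"MSE_{tau}")
    for tau in MSE_SCALES[:-1]:
        add("mse", f"MSE_sum_{tau}_{tau + 1}")
    for tau in MSE_SCALES[:-1]:
        add("mse", f"MSE_mean_{tau}_{tau + 1}")
    add("mse", "MSE_mean_8_14")
    for nm in DEMOGRAPHIC_NAMES:
        entries.append(CatalogEntry(nm, "demographic", nm))
    return tuple(entries)


class FeatureCatalog:
    """Ordered, immutable schema for the 248-entry feature vector."""

    def __init__(self) -> None:
        self.entries = _build_entries()
        self.ids = tuple(e.feature_id for e in self.entries)
        self.names = tuple(e.name for e in self.entries)
        self.families = tuple(e.family for e in self.entries)
        if len(self.ids) != len(set(self.ids)):
            raise AssertionError("duplicate feature ids in catalogue")
        self._index = {fid: i for i, fid in enumerate(self.ids)}
        self._name_index = {nm: i for i, nm in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.entries)

    def index(self, feature_id: str) -> int:
        return self._index[feature_id]

    def id_of(self, name: str) -> str:
        """Feature id for a human-readable name (e.g. 'Welch_hf_rel' -> 'F39')."""
        return self.ids[self._name_index[name]]

    def family_slice(self, family: str) -> np.ndarray:
        return np.array([i for i, f in enumerate(self.families) if f == family])

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for f in self.families:
            sizes[f] = sizes.get(f, 0) + 1
        return sizes

    def to_json(self) -> str:
        return json.dumps([dataclasses.asdict(e) for e in self.entries], indent=1)


FEATURE_CATALOG = FeatureCatalog()
assert len(FEATURE_CATALOG) == 248


@dataclasses.dataclass
class FeatureVector:
    """One measurement's 248 values in catalogue order.

    NaN is permitted only in the multiscale-entropy block (records with
    fewer than 240 pulses); everything else must be finite.
    """

    values: np.ndarray
    catalog: FeatureCatalog = dataclasses.field(default_factory=lambda: FEATURE_CATALOG)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.catalog),):
            raise ValueError(
                f"expected {len(self.catalog)} values, got {self.values.shape}")
        bad = ~np.isfinite(self.values)
        mse = np.zeros(len(self.catalog), dtype=bool)
        mse[self.catalog.family_slice("mse")] = True
        if np.any(bad & ~mse) or np.any(np.isinf(self.values)):
            raise ValueError("non-finite value outside the MSE block")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.catalog.ids))

    def __getitem__(self, feature_id: str) -> float:
        return float(self.values[self.catalog.index(feature_id)])
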