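"""Assemble the full 248-entry feature vector for one measurement."""

from __future__ import annotations

import warnings

import numpy as np

from ..beats import PulseSeries, heart_rate_series
from ..io import Demographics, PPGRecord
from .catalog import FEATURE_CATALOG, FeatureCatalog, FeatureVector
from .energy import kte_features, log_energy_features
from .entropy import SampEnParams, mse_features, sample_entropy
from .hrv import (hrv_frequency_features, hrv_nonlinear_features,
                  hrv_time_features)
from .waveform import cwt_features, hr_features, waveform_features

__all__ = ["extract_all", "HRV_FRAME_S"]

HRV_FRAME_S = 300.0  # HRV is analysed over one 5-minute frame


def extract_all(record: PPGRecord, pulses: PulseSeries,
                demographics: Demographics,
                catalog: FeatureCatalog = FEATURE_CATALOG) -> FeatureVector:
    """Compute every catalogue feature from a repaired record and its pulses.

    HRV blocks use the first 5 minutes of the record (shorter records are
    analysed whole, with a warning).  The MSE block is NaN when fewer than
    240 pulses are available.
    """
    if record.stage != "repaired":
        raise ValueError(f"expected a repaired record, got stage={record.stage!r}")
    if record.duration_s < HRV_FRAME_S:
        warnings.warn(
            f"record is {record.duration_s:.0f} s (< {HRV_FRAME_S:.0f} s); "
            "HRV computed on the full record", stacklevel=2)
    frame_end = int(min(record.duration_s, HRV_FRAME_S) * record.fs)
    in_frame = pulses.peak_indices < frame_end
    frame_pulses = PulseSeries(
        peak_indices=pulses.peak_indices[in_frame],
        onset_indices=pulses.onset_indices[in_frame], fs=pulses.fs)
    ibis, ibi_times = frame_pulses.valid_ibis_ms(with_times=True)

    hr = heart_rate_series(pulses, record.samples.size)

    blocks = [
        hrv_time_features(ibis),
        hrv_frequency_features(ibis, "welch", times_s=ibi_times),
        hrv_frequency_features(ibis, "ar", times_s=ibi_times),
        hrv_nonlinear_features(ibis),
        hr_features(hr.valid_bpm),
        cwt_features(record),
        waveform_features(pulses, record),
        kte_features(record),
        log_energy_features(record),
        [sample_entropy(record.samples, SampEnParams(m=2, r_factor=0.1))],
        mse_features(record, pulses),
        demographics.encoded(),
    ]
    values = np.concatenate([np.asarray(b, dtype=float) for b in blocks])
    return FeatureVector(values=values, catalog=catalog)
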