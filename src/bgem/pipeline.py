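"""End-to-end convenience: signals -> cleaned records -> feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beats import detect_pulses
from .features import FEATURE_CATALOG, extract_all
from .io import Demographics, PPGRecord
from .preprocess import preprocess
from .synthetic import Cohort

__all__ = ["extract_record_features", "cohort_feature_table"]


def extract_record_features(record: PPGRecord, demographics: Demographics):
    """Preprocess a raw record, detect pulses, and extract the 248 features."""
    clean = preprocess(record)
    pulses = detect_pulses(clean)
    return extract_all(clean, pulses, demographics)


def cohort_feature_table(cohort: Cohort, progress: bool = False
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix (rows = subjects, columns = catalogue ids) and labels."""
    rows = []
    for i, state in enumerate(cohort.subjects):
        record, _, _ = cohort.record(i)
        fv = extract_record_features(record, state.demographics)
        rows.append(fv.values)
        if progress and (i + 1) % 50 == 0:
            print(f"  extracted {i + 1}/{cohort.n} subjects")
    X = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_CATALOG.ids),
                     index=[s.subject_id for s in cohort.subjects])
    return X, cohort.labels
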