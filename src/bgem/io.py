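"""Reading and writing PPG signals and feature tables.

Raw wrist-PPG comes off the device either as little-endian signed 16-bit
binary or as one-value-per-line numeric text.  Binary codes are mapped to
real amplitudes by ``code / 2**15`` (a linear, odd-symmetric DAC); every
downstream feature is invariant to affine amplitude rescaling after
band-pass filtering, so any linear DAC convention is equivalent.

Feature tables are plain CSV with a fixed header defined by the feature
catalogue; missing values (e.g. the multiscale-entropy block on records
with too few pulses) are serialized as empty fields.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PPGRecord",
    "Demographics",
    "FormatError",
    "EmptyInputError",
    "SchemaError",
    "read_raw_ppg",
    "dac_convert",
    "write_feature_table",
    "read_feature_table",
]

_STAGES = ("raw", "filtered", "repaired")


class FormatError(ValueError):
    """Malformed on-disk signal data (e.g. odd-length int16 binary)."""


class EmptyInputError(ValueError):
    """A signal file with no samples."""


class SchemaError(ValueError):
    """Feature-table rows inconsistent with the declared catalogue."""


@dataclasses.dataclass
class PPGRecord:
    """A uniformly sampled single-channel PPG signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued amplitudes (arbitrary units after DAC).
    fs : float
        Sampling rate in Hz (wrist devices targeted here run at 50 Hz).
    stage : {"raw", "filtered", "repaired"}
        Provenance flag; stages only ever advance raw -> filtered -> repaired.
    subject_id : str
        Opaque subject/measurement identifier.
    t0 : float or None
        Optional acquisition timestamp (seconds since epoch).
    """

    samples: np.ndarray
    fs: float = 50.0
    stage: str = "raw"
    subject_id: str = ""
    t0: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise EmptyInputError("PPGRecord requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}, got {self.stage!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def advance(self, samples: np.ndarray, stage: str) -> "PPGRecord":
        """Return a new record at a later processing stage."""
        if _STAGES.index(stage) != _STAGES.index(self.stage) + 1:
            raise ValueError(f"illegal stage transition {self.stage!r} -> {stage!r}")
        return PPGRecord(samples=np.asarray(samples, dtype=float), fs=self.fs,
                         stage=stage, subject_id=self.subject_id, t0=self.t0)


@dataclasses.dataclass(frozen=True)
class Demographics:
    """Per-subject covariates added to the feature vector.

    age in years, gender in {"male", "female"}, bmi in kg/m^2,
    family_history of diabetes in {"yes", "no"}.
    """

    age: float
    gender: str
    bmi: float
    family_history: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.bmi > 0:
            raise ValueError("bmi must be positive")
        if self.gender not in ("male", "female"):
            raise ValueError("gender must be 'male' or 'female'")
        if self.family_history not in ("yes", "no"):
            raise ValueError("family_history must be 'yes' or 'no'")

    def encoded(self) -> tuple[float, float, float, float]:
        """(age, gender, bmi, family_history) with female=0/male=1, no=0/yes=1."""
        return (float(self.age), 1.0 if self.gender == "male" else 0.0,
                float(self.bmi), 1.0 if self.family_history == "yes" else 0.0)


def dac_convert(codes: np.ndarray) -> np.ndarray:
    """Map signed 16-bit integer codes to real amplitudes in [-1, 1)."""
    return np.asarray(codes, dtype=np.int32) / 2.0**15


def read_raw_ppg(path: str | Path, fs: float = 50.0,
                 encoding: str = "int16-binary", subject_id: str = "") -> PPGRecord:
    """Read a raw PPG signal from disk.

    ``encoding="int16-binary"`` expects little-endian signed 16-bit codes and
    applies the DAC mapping; ``encoding="numeric-text"`` expects one numeric
    value per line (or whitespace/comma separated) passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if encoding == "int16-binary":
        raw = path.read_bytes()
        if len(raw) == 0:
            raise EmptyInputError(f"{path} is empty")
        if len(raw) % 2 != 0:
            raise FormatError(f"{path}: byte length {len(raw)} not a multiple of 2")
        codes = np.frombuffer(raw, dtype="<i2")
        samples = dac_convert(codes)
    elif encoding == "numeric-text":
        text = path.read_text()
        tokens = text.replace(",", " ").split()
        if not tokens:
            raise EmptyInputError(f"{path} contains no values")
        try:
            samples = np.array([float(t) for t in tokens])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric token in text signal") from exc
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return PPGRecord(samples=samples, fs=fs, stage="raw",
                     subject_id=subject_id or path.stem)


def write_raw_ppg(record: PPGRecord, path: str | Path,
                  encoding: str = "numeric-text") -> None:
    """Write a signal to disk (text: one value per line; binary: int16 codes)."""
    path = Path(path)
    if encoding == "numeric-text":
        path.write_text("\n".join(f"{v:.9g}" for v in record.samples) + "\n")
    elif encoding == "int16-binary":
        codes = np.clip(np.round(record.samples * 2.0**15), -32768, 32767)
        path.write_bytes(codes.astype("<i2").tobytes())
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def write_feature_table(rows: Iterable[tuple[str, Sequence[float], float]],
                        path: str | Path, feature_names: Sequence[str]) -> None:
    """Write (subject_id, feature values, label) rows as CSV.

    Header is ``subject_id,<feature names...>,label``; NaN feature values are
    serialized as empty fields so missing blocks round-trip as missing.
    """
    rows = list(rows)
    n = len(feature_names)
    for sid, values, _label in rows:
        if len(values) != n:
            raise SchemaError(
                f"row {sid!r} has {len(values)} values, catalogue declares {n}")
    df = pd.DataFrame(
        [[sid, *np.asarray(values, dtype=float), label] for sid, values, label in rows],
        columns=["subject_id", *feature_names, "label"],
    )
    df.to_csv(path, index=False, na_rep="")


def read_feature_table(path: str | Path,
                       feature_names: Sequence[str] | None = None,
                       ) -> list[tuple[str, np.ndarray, float]]:
    """Read a feature-table CSV back into (subject_id, values, label) rows."""
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "subject_id" or df.columns[-1] != "label":
        raise SchemaError(f"{path}: expected subject_id,<features...>,label header")
    names = list(df.columns[1:-1])
    if feature_names is not None and names != list(feature_names):
        raise SchemaError(f"{path}: header does not match the declared catalogue")
    out = []
    for _, row in df.iterrows():
        out.append((str(row.iloc[0]),
                    row.iloc[1:-1].to_numpy(dtype=float),
                    float(row.iloc[-1])))
    return out
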