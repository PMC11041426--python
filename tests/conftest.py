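import numpy as np
import pytest

from bgem import SyntheticConfig, simulate_cohort
from bgem.io import Demographics
from bgem.synthetic import EffectSpec, SubjectState, simulate_ppg


DEMO = Demographics(age=45.0, gender="female", bmi=23.0, family_history="no")


def make_subject(seed=3, hr_bpm=72.0, hf_frac=0.35, rise_s=0.15, decay_s=0.11,
                 corr_noise_sd=0.02, gain=1.0):
    return SubjectState(subject_id="T", label=0, glucose=5.5, demographics=DEMO,
                        hr_bpm=hr_bpm, hf_frac=hf_frac, rise_s=rise_s,
                        decay_s=decay_s, corr_noise_sd=corr_noise_sd,
                        gain=gain, seed=seed)


@pytest.fixture(scope="session")
def demographics():
    return DEMO


@pytest.fixture(scope="session")
def default_record():
    """One default-condition 5-min raw record with its ground truth."""
    cfg = SyntheticConfig()
    record, peaks, ibis = simulate_ppg(cfg, make_subject(seed=11))
    return cfg, record, peaks, ibis


@pytest.fixture(scope="session")
def clean_record(default_record):
    from bgem.preprocess import preprocess

    _, record, _, _ = default_record
    return preprocess(record)


@pytest.fixture(scope="session")
def clean_pulses(clean_record):
    from bgem.beats import detect_pulses

    return detect_pulses(clean_record)


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic pulse train: no noise, jitter, modulation or artifacts."""
    return SyntheticConfig(noise_sd=0.0, artifact_rate_per_min=0.0,
                           ibi_jitter_ms=0.0, mod_depth_ms=0.0, resp_amp=0.0,
                           amp_jitter=0.0, rise_jitter_s=0.0)


@pytest.fixture(scope="session")
def strong_cohort_features():
    """The end-to-end study cohort: n=400, strong effect spec, fixed seed.

    Built once per session (a few minutes); feature matrix plus labels.
    """
    from bgem.pipeline import cohort_feature_table

    cfg = SyntheticConfig(n_subjects=400, prevalence=0.5,
                          effect=EffectSpec.strong(), seed=20)
    cohort = simulate_cohort(cfg)
    X, y = cohort_feature_table(cohort)
    return X, y
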