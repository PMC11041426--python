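import warnings

import numpy as np
import pytest

from bgem.beats import PulseSeries, detect_pulses
from bgem.features import FEATURE_CATALOG, extract_all
from bgem.features._stats import stats8
from bgem.features.energy import (kte_features, log_energy_features,
                                  log_energy_sequence, teager_kaiser)
from bgem.features.entropy import mse_features
from bgem.features.waveform import cwt_features, hr_features, pulse_geometry
from bgem.io import PPGRecord
from bgem.preprocess import preprocess
from bgem.synthetic import SyntheticConfig, simulate_ppg
from statsmodels.regression.linear_model import yule_walker
from tests.conftest import make_subject

FS = 50.0


class TestCatalog:
    def test_frozen_block_sizes(self):
        sizes = FEATURE_CATALOG.family_sizes()
        assert sizes == {"hrv_time": 31, "hrv_welch": 13, "hrv_ar": 13,
                         "hrv_nonlinear": 14, "hr": 10, "cwt": 3,
                         "waveform": 112, "kte": 10, "log_energy": 17,
                         "sampen": 1, "mse": 20, "demographic": 4}
        assert len(FEATURE_CATALOG) == 248

    def test_block_index_ranges(self):
        # family boundaries must match the frozen index layout
        assert FEATURE_CATALOG.ids[0] == "F1"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F71")] == "hrv_nonlinear"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F72")] == "hr"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F82")] == "cwt"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F85")] == "waveform"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F197")] == "kte"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F207")] == "log_energy"
        assert FEATURE_CATALOG.ids[FEATURE_CATALOG.index("F224")] == "F224"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F224")] == "sampen"
        assert FEATURE_CATALOG.families[FEATURE_CATALOG.index("F225")] == "mse"
        assert FEATURE_CATALOG.names[FEATURE_CATALOG.index("F244")] == "MSE_mean_8_14"
        # the named features used downstream resolve correctly
        for nm in ("Welch_hf_rel", "AR_hf_rel", "A_FE_mean", "A_ratio_mean",
                   "A_ratio_max", "A_Pulse_iqr", "KTE_skew", "LOG_std",
                   "MSE_sum_13_14"):
            assert FEATURE_CATALOG.id_of(nm).startswith("F")


class TestKTE:
    def test_arithmetic_ramp_gives_slope_squared(self):
        assert teager_kaiser(np.array([1., 2., 3., 4., 5.])).tolist() == [1., 1., 1.]
        assert np.allclose(teager_kaiser(np.arange(0, 30, 3.0)), 9.0)

    def test_constant_signal_gives_zero_stats(self):
        rec = PPGRecord(np.ones(int(20 * FS)), fs=FS, stage="repaired")
        v = kte_features(rec)
        np.testing.assert_allclose(v, 0.0)

    def test_sinusoid_closed_form(self):
        a, om = 1.7, 0.4
        x = a * np.sin(om * np.arange(int(20 * FS)))
        rec = PPGRecord(x, fs=FS, stage="repaired")
        v = kte_features(rec)
        expected = a**2 * np.sin(om) ** 2
        assert v[0] == pytest.approx(expected, rel=0.02)  # per-frame mean KTE


class TestLogEnergy:
    def test_identical_frames_have_zero_std(self):
        frame = np.sin(np.arange(int(5 * FS)))
        rec = PPGRecord(np.tile(frame, 12), fs=FS, stage="repaired")
        v = log_energy_features(rec)
        assert v[1] == pytest.approx(0.0, abs=1e-9)  # LOG_std

    def test_white_noise_ar_coefficients_small(self):
        # 60 frames of independent noise -> E_log sequence ~ IID
        x = np.random.default_rng(12).standard_normal(int(60 * 5 * FS))
        rec = PPGRecord(x, fs=FS, stage="repaired")
        v = log_energy_features(rec)
        assert np.all(np.abs(v[10:]) < 0.2)

    def test_ar1_structure_recovered(self):
        # E_log sequence generated by an AR(1) with coefficient 0.8
        rng = np.random.default_rng(8)
        n = 200
        e = np.zeros(n)
        innov = rng.standard_normal(n)
        for i in range(1, n):
            e[i] = 0.8 * e[i - 1] + innov[i]
        rho, _ = yule_walker(e - e.mean(), order=7, method="mle")
        assert abs(rho[0] - 0.8) < 0.15

    def test_all_zero_frames_hit_epsilon_floor_not_minus_inf(self):
        seq = log_energy_sequence(np.zeros(int(10 * FS)), FS)
        assert np.all(np.isfinite(seq))


class TestCWT:
    def _rec(self, x):
        return PPGRecord(np.asarray(x, float), fs=FS, stage="repaired")

    def test_zero_signal_gives_zeros(self):
        np.testing.assert_allclose(cwt_features(self._rec(np.zeros(1000))), 0.0)

    def test_linearity_in_amplitude(self):
        x = np.random.default_rng(0).standard_normal(2000)
        v1 = cwt_features(self._rec(x))
        v2 = cwt_features(self._rec(2 * x))
        assert v2[0] == pytest.approx(2 * v1[0], rel=1e-9)   # mean
        assert v2[2] == pytest.approx(2 * v1[2], rel=1e-9)   # max

    def test_max_response_at_matching_scale(self):
        import pywt

        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        fc = pywt.central_frequency("mexh")
        freqs = np.geomspace(0.3, 4.0, 32)
        scales = fc * FS / freqs
        coefs, _ = pywt.cwt(x, scales, "mexh", sampling_period=1 / FS)
        power = np.abs(coefs[:, 500:-500]).mean(axis=1)
        best = freqs[np.argmax(power)]
        near_1hz = freqs[np.argmin(np.abs(freqs - 1.0))]
        assert best == pytest.approx(near_1hz)


class TestWaveform:
    def _sawtooth_pulses(self, n=15, rt=0.2, ft=0.6):
        """Back-to-back triangular pulses: rise rt to 1, fall ft to 0."""
        period = rt + ft
        fs = FS
        t = np.arange(0, n * period + 1 / fs, 1 / fs)
        x = np.zeros_like(t)
        peaks, onsets = [], []
        for k in range(n):
            t0 = k * period
            onsets.append(int(round(t0 * fs)))
            peaks.append(int(round((t0 + rt) * fs)))
            up = (t - t0) / rt
            x = np.maximum(x, np.where((t >= t0) & (t <= t0 + rt), up, 0))
            down = 1 - (t - t0 - rt) / ft
            x = np.maximum(x, np.where((t > t0 + rt) & (t <= t0 + period), down, 0))
        rec = PPGRecord(x, fs=fs, stage="repaired")
        pulses = PulseSeries(peak_indices=np.array(peaks),
                             onset_indices=np.array(onsets), fs=fs)
        return rec, pulses

    def test_sawtooth_hand_computed_geometry(self):
        rec, pulses = self._sawtooth_pulses()
        geom = pulse_geometry(pulses, rec)
        row = geom[1]  # interior pulse
        # triangle areas by hand: AUR = 1/2*0.2*1, AUF = 1/2*0.6*1
        assert row[0] == pytest.approx(0.2)            # RT
        assert row[1] == pytest.approx(0.6)            # FT
        assert row[2] == pytest.approx(1.0)            # RP
        assert row[3] == pytest.approx(1.0)            # FN
        assert row[4] == pytest.approx(5.0)            # Rslope
        assert row[5] == pytest.approx(1 / 0.6)        # Fslope
        assert row[6] == pytest.approx(0.1)            # AUR
        assert row[7] == pytest.approx(0.3)            # AUF (A_FE)
        assert row[8] == pytest.approx(0.4)            # Apulse
        assert row[9] == pytest.approx(1 / 3)          # A_ratio

    def test_symmetric_triangles_have_unit_ratios(self):
        rec, pulses = self._sawtooth_pulses(rt=0.4, ft=0.4)
        geom = pulse_geometry(pulses, rec)
        np.testing.assert_allclose(geom[:, 9], 1.0, rtol=0.05)   # A_ratio
        np.testing.assert_allclose(geom[:, 11], 1.0, rtol=0.05)  # RT/FT
        np.testing.assert_allclose(geom[:, 13], 1.0, rtol=0.05)  # slope ratio

    def test_amplitude_homogeneity(self):
        rec, pulses = self._sawtooth_pulses()
        g1 = pulse_geometry(pulses, rec)
        rec2 = PPGRecord(2 * rec.samples, fs=FS, stage="repaired")
        g2 = pulse_geometry(pulses, rec2)
        for q in (2, 3, 6, 7, 8):        # RP, FN, AUR, AUF, Apulse scale
            np.testing.assert_allclose(g2[:, q], 2 * g1[:, q], rtol=1e-9)
        for q in (0, 1, 9, 11, 12, 13):  # RT, FT and ratios do not
            np.testing.assert_allclose(g2[:, q], g1[:, q], rtol=1e-9)


class TestHRStats:
    def test_constant_series(self):
        v = hr_features(np.full(10, 72.0))
        assert v[0] == 72 and v[1] == 0 and v[9] == 0

    def test_three_window_example(self):
        v = hr_features(np.array([60.0, 66.0, 72.0]))
        assert v[0] == pytest.approx(66.0)
        assert v[6] == pytest.approx(12.0)  # range

    def test_moments_match_brute_force(self):
        rng = np.random.default_rng(2)
        b = 70 + 5 * rng.standard_normal(30)
        v = hr_features(b)
        m = b.mean()
        sk = np.mean((b - m) ** 3) / b.std() ** 3
        ku = np.mean((b - m) ** 4) / b.std() ** 4 - 3
        assert v[7] == pytest.approx(sk, abs=1e-9)
        assert v[8] == pytest.approx(ku, abs=1e-9)


class TestExtractAll:
    def test_full_record_yields_248_finite_features(self, clean_record,
                                                    clean_pulses, demographics):
        fv = extract_all(clean_record, clean_pulses, demographics)
        assert fv.values.size == 248
        assert np.isfinite(fv.values).all()

    def test_determinism_bit_for_bit(self, clean_record, clean_pulses,
                                     demographics):
        a = extract_all(clean_record, clean_pulses, demographics)
        b = extract_all(clean_record, clean_pulses, demographics)
        np.testing.assert_array_equal(a.values, b.values)

    def test_short_record_missing_mse_block_only(self, demographics):
        # ~200 pulses (< 240): the MSE block is NA, everything else present
        cfg = SyntheticConfig(duration_s=170.0)
        record, _, _ = simulate_ppg(cfg, make_subject(seed=5, hr_bpm=70))
        clean = preprocess(record)
        pulses = detect_pulses(clean)
        assert pulses.count < 240
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = extract_all(clean, pulses, demographics)
        nan_idx = np.flatnonzero(np.isnan(fv.values))
        assert len(nan_idx) == 20
        assert set(FEATURE_CATALOG.families[i] for i in nan_idx) == {"mse"}

    def test_mse_gate_at_240_pulses(self, clean_record, clean_pulses):
        few = PulseSeries(peak_indices=clean_pulses.peak_indices[:200],
                          onset_indices=clean_pulses.onset_indices[:200],
                          fs=FS)
        assert np.isnan(mse_features(clean_record, few)).all()
        assert np.isfinite(mse_features(clean_record, clean_pulses)).all()

    def test_amplitude_scaling_invariants_end_to_end(self, default_record,
                                                     demographics):
        _, record, _, _ = default_record
        fv1 = _extract_raw(record, demographics)
        rec3 = PPGRecord(3.0 * record.samples, fs=record.fs)
        fv3 = _extract_raw(rec3, demographics)
        C = FEATURE_CATALOG
        for nm in ("RP_mean", "AUR_mean", "A_FE_mean", "A_Pulse_iqr",
                   "CWT_mean", "CWT_max"):
            assert fv3[C.id_of(nm)] == pytest.approx(3 * fv1[C.id_of(nm)],
                                                     rel=1e-6)
        for nm in ("RT_mean", "A_ratio_mean", "RT_FT_mean", "SampEn",
                   "MSE_8", "Welch_hf_rel", "nn_mean", "HR_mean"):
            assert fv3[C.id_of(nm)] == pytest.approx(fv1[C.id_of(nm)],
                                                     rel=1e-6)


def _extract_raw(record, demographics):
    clean = preprocess(record)
    pulses = detect_pulses(clean)
    return extract_all(clean, pulses, demographics)


def test_stats8_matches_direct_moments():
    v = np.random.default_rng(1).normal(size=100)
    s = stats8(v)
    assert s[0] == pytest.approx(v.mean())
    assert s[3] == pytest.approx(np.percentile(v, 75) - np.percentile(v, 25))
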