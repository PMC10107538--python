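import numpy as np
import pytest

from neoseize.data_io import EEGRecording
from neoseize.qeeg_features import (
    BandScheme,
    InsufficientDataError,
    amplitude_moments,
    connectivity,
    detect_ibis,
    extract_features,
    fractal_dimension,
    higuchi_fd,
    range_eeg,
    spectral_powers,
)

from tests.conftest import LABELS8, make_recording


class TestSpectralPowers:
    def test_sine_parseval(self, sine_epoch):
        out = spectral_powers(sine_epoch)
        # 10 µV sine: variance A²/2 = 50 µV², all inside the delta band
        assert out["spectral_power_delta"] == pytest.approx(50.0, rel=0.02)
        assert out["spectral_relative_power_delta"] >= 0.99

    def test_zero_signal_flagged(self):
        rec = make_recording(np.zeros((8, 256 * 120)), fs=256.0)
        out = spectral_powers(rec)
        assert out["spectral_power_delta"] == 0.0
        assert np.isnan(out["spectral_flatness_delta"])
        assert np.isnan(out["spectral_edge_frequency"])

    def test_white_noise_flatness_and_sef(self, noise_epoch):
        out = spectral_powers(noise_epoch)
        for band in ("delta", "theta", "alpha", "beta"):
            assert out[f"spectral_flatness_{band}"] >= 0.9
        assert 26.5 <= out["spectral_edge_frequency"] <= 28.5

    def test_relative_powers_sum_to_one(self, noise_epoch):
        out = spectral_powers(noise_epoch)
        total = sum(out[f"spectral_relative_power_{b}"] for b in ("delta", "theta", "alpha", "beta"))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_masked_raises(self, sine_epoch):
        rec = EEGRecording(
            sine_epoch.channel_labels, sine_epoch.fs, sine_epoch.data,
            artifact_intervals=[(0.0, sine_epoch.duration_s)],
        )
        with pytest.raises(InsufficientDataError):
            spectral_powers(rec)

    def test_parseval_consistency_noise(self, noise_epoch):
        from scipy import signal as sps

        out = spectral_powers(noise_epoch)
        band_sum = sum(out[f"spectral_power_{b}"] for b in ("delta", "theta", "alpha", "beta"))
        sos = sps.butter(8, [1.0, 30.0], btype="bandpass", fs=noise_epoch.fs, output="sos")
        var = sps.sosfiltfilt(sos, noise_epoch.data, axis=-1).var()
        assert band_sum == pytest.approx(var, rel=0.10)


class TestRangeEEG:
    def test_sine_margins(self):
        fs = 256.0
        t = np.arange(0, 120, 1 / fs)
        x = 10.0 * np.sin(2 * np.pi * 5.0 * t)
        rec = make_recording(np.tile(x, (8, 1)), fs=fs)
        out = range_eeg(rec)
        for key in ("reeg_lower", "reeg_median", "reeg_upper"):
            assert out[key] == pytest.approx(20.0, rel=0.05)
        assert out["reeg_asymmetry"] == pytest.approx(0.0, abs=1e-6)

    def test_right_triple_asymmetry(self):
        fs = 256.0
        t = np.arange(0, 120, 1 / fs)
        x = 10.0 * np.sin(2 * np.pi * 5.0 * t)
        data = np.tile(x, (8, 1))
        data[4:] *= 3.0  # right-hemisphere channels
        out = range_eeg(make_recording(data, fs=fs))
        assert out["reeg_asymmetry"] == pytest.approx(0.5, abs=0.01)

    def test_zero_signal(self):
        rec = make_recording(np.zeros((8, 256 * 60)), fs=256.0)
        out = range_eeg(rec)
        assert out["reeg_median"] == 0.0
        assert np.isnan(out["reeg_asymmetry"])

    def test_too_few_windows_raise(self):
        rec = make_recording(np.zeros((8, 256 * 5)), fs=256.0)
        with pytest.raises(InsufficientDataError):
            range_eeg(rec)


class TestDetectIBIs:
    def test_constructed_burst_suppression(self, rng):
        fs = 250.0
        parts = []
        for _ in range(10):
            parts.append(rng.normal(0, 50, int(5 * fs)))
            parts.append(rng.normal(0, 1, int(20 * fs)))
        x = np.concatenate(parts)
        rec = make_recording(np.tile(x, (8, 1)), fs=fs)
        ann = detect_ibis(rec)
        assert ann.percentage == pytest.approx(80.0, abs=5.0)
        assert ann.median_s == pytest.approx(20.0, abs=1.0)
        assert ann.count == 10
        assert ann.max_s >= ann.median_s

    def test_continuous_activity(self, rng):
        rec = make_recording(rng.normal(0, 50, (8, int(120 * 250))), fs=250.0)
        ann = detect_ibis(rec)
        assert ann.percentage == 0.0
        assert ann.count == 0

    def test_fully_suppressed(self, rng):
        rec = make_recording(rng.normal(0, 1, (8, int(120 * 250))), fs=250.0)
        ann = detect_ibis(rec)
        assert ann.percentage == pytest.approx(100.0, abs=0.5)
        assert ann.count == 1
        assert ann.max_s == pytest.approx(120.0, abs=0.5)

    def test_intervals_disjoint_and_long_enough(self, rng):
        fs = 250.0
        parts = []
        for _ in range(6):
            parts.append(rng.normal(0, 40, int(rng.integers(3, 8) * fs)))
            parts.append(rng.normal(0, 1, int(rng.integers(7, 30) * fs)))
        rec = make_recording(np.tile(np.concatenate(parts), (8, 1)), fs=fs)
        ann = detect_ibis(rec)
        prev_end = -1.0
        for s, e in ann.intervals:
            assert e - s >= 6.0
            assert s > prev_end
            prev_end = e
        assert 0.0 <= ann.percentage <= 100.0


class TestAmplitudeMoments:
    def test_gaussian_kurtosis(self, rng):
        # one hour at 256 Hz as in the study epoch
        rec = make_recording(rng.normal(0, 10, (2, int(3600 * 256 / 8))), fs=256.0,
                             labels=["F3", "C3"])
        _, kurt = amplitude_moments(rec, (4.0, 7.0))
        assert kurt == pytest.approx(3.0, abs=0.2)

    def test_symmetric_signal_zero_skew(self, rng):
        # wide band keeps the effective sample count high enough for a tight
        # bound on the sample-skewness magnitude
        rec = make_recording(rng.normal(0, 10, (2, 256 * 300)), fs=256.0, labels=["F3", "C3"])
        skew, _ = amplitude_moments(rec, (13.0, 30.0))
        assert skew == pytest.approx(0.0, abs=0.1)

    def test_spikes_raise_kurtosis(self, rng):
        base = rng.normal(0, 10, (2, 256 * 300))
        rec = make_recording(base, fs=256.0, labels=["F3", "C3"])
        spiked = base.copy()
        spikes = rng.choice(spiked.shape[1], 40, replace=False)
        spiked[:, spikes] += 300.0
        rec_s = make_recording(spiked, fs=256.0, labels=["F3", "C3"])
        band = (13.0, 30.0)
        assert amplitude_moments(rec_s, band)[1] > amplitude_moments(rec, band)[1]

    def test_constant_signal_flagged(self):
        rec = make_recording(np.zeros((2, 256 * 120)), fs=256.0, labels=["F3", "C3"])
        skew, kurt = amplitude_moments(rec, (1.0, 4.0))
        assert np.isnan(skew) and np.isnan(kurt)


class TestFractalDimension:
    def test_ramp_is_one(self):
        assert higuchi_fd(np.linspace(0.0, 1.0, 512)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_is_two(self, rng):
        fds = [higuchi_fd(rng.normal(size=512)) for _ in range(20)]
        assert np.median(fds) == pytest.approx(2.0, abs=0.1)

    def test_white_noise_matches_curve_length_oracle(self, rng):
        # brute-force oracle: recompute the Higuchi curve lengths directly
        x = rng.normal(size=512)

        def oracle(x, k_max=6):
            n = len(x)
            logs = []
            for k in range(1, k_max + 1):
                lmk = []
                for m in range(k):
                    idx = np.arange(m, n, k)
                    if len(idx) < 2:
                        continue
                    lm = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / ((len(idx) - 1) * k) / k
                    lmk.append(lm)
                logs.append(np.log(np.mean(lmk)))
            kk = np.log(1.0 / np.arange(1, k_max + 1))
            return np.polyfit(kk, logs, 1)[0]

        assert higuchi_fd(x) == pytest.approx(oracle(x), abs=1e-9)

    def test_sine_is_smooth(self):
        fs = 256.0
        t = np.arange(0, 120, 1 / fs)
        rec = make_recording(np.tile(np.sin(2 * np.pi * 5 * t) * 10, (8, 1)), fs=fs)
        assert fractal_dimension(rec) < 1.3

    def test_constant_flagged(self):
        rec = make_recording(np.zeros((8, 256 * 120)), fs=256.0)
        assert np.isnan(fractal_dimension(rec))


class TestConnectivity:
    def test_identical_hemispheres(self, rng):
        half = rng.normal(0, 10, (4, 256 * 120))
        rec = make_recording(np.vstack([half, half]), fs=256.0)
        out = connectivity(rec)
        for band in ("delta", "theta", "alpha", "beta"):
            assert out[f"bsi_{band}"] == pytest.approx(0.0, abs=1e-12)
            assert out[f"coherence_mean_{band}"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_hemispheres_null(self, rng):
        rec = make_recording(rng.normal(0, 10, (8, 256 * 600)), fs=256.0)
        out = connectivity(rec)
        assert out["bsi_delta"] <= 0.15
        assert out["coherence_mean_delta"] <= 0.2

    def test_quadruple_power_bsi(self, rng):
        half = rng.normal(0, 10, (4, 256 * 120))
        rec = make_recording(np.vstack([half, 2.0 * half]), fs=256.0)
        out = connectivity(rec)
        assert out["bsi_delta"] == pytest.approx(0.6, abs=1e-9)

    def test_single_hemisphere_flagged(self, rng):
        rec = make_recording(rng.normal(size=(2, 256 * 60)), fs=256.0, labels=["F3", "C3"])
        out = connectivity(rec)
        assert np.isnan(out["bsi_delta"])


class TestExtractFeatures:
    def test_weighted_block_zero_when_continuous(self, rng):
        rec = make_recording(rng.normal(0, 50, (8, int(120 * 250))), fs=250.0)
        vec = extract_features(rec)
        assert vec.values["ibi_percentage"] == 0.0
        weighted = [v for k, v in vec.values.items() if k.startswith("w_")]
        assert all(v == 0.0 or np.isnan(v) for v in weighted)

    def test_weighted_block_is_scaled_copy(self, rng):
        fs = 250.0
        parts = []
        for _ in range(10):
            parts.append(rng.normal(0, 50, int(10 * fs)))
            parts.append(rng.normal(0, 1, int(10 * fs)))
        rec = make_recording(np.tile(np.concatenate(parts), (8, 1)), fs=fs)
        vec = extract_features(rec)
        w = vec.values["ibi_percentage"] / 100.0
        assert 0.0 < w < 1.0
        for key in ("spectral_power_delta", "reeg_median", "fractal_dimension"):
            assert vec.values[f"w_{key}"] == pytest.approx(vec.values[key] * w)

    def test_class_direction(self):
        from neoseize.synthetic_data import GeneratorParams, generate_eeg

        p = GeneratorParams()
        rec_non = generate_eeg(p.eeg_non_seizure, duration_s=120, fs=250.0, rng=7)
        rec_sz = generate_eeg(p.eeg_seizure, duration_s=120, fs=250.0, rng=7)
        f_non = extract_features(rec_non).values
        f_sz = extract_features(rec_sz).values
        assert f_sz["spectral_power_delta"] < f_non["spectral_power_delta"]
        assert f_sz["ibi_percentage"] > f_non["ibi_percentage"]

    def test_adjusters_attached(self, rng):
        rec = make_recording(rng.normal(0, 30, (8, int(120 * 250))), fs=250.0)
        vec = extract_features(rec, asm_before_epoch=True, hypothermia_at_epoch=False)
        assert vec.values["asm_before_epoch"] == 1.0
        assert vec.values["hypothermia_at_epoch"] == 0.0

    def test_identical_code_path_two_channels(self, rng):
        rec = make_recording(rng.normal(0, 30, (2, int(120 * 250))), fs=250.0,
                             labels=["F3-C3", "F4-C4"])
        vec = extract_features(rec)
        assert np.isfinite(vec.values["bsi_delta"])
        assert np.isfinite(vec.values["coherence_mean_delta"])


@pytest.mark.parametrize("gain", [0.5, 2.0, 10.0])
def test_scale_equivariance(rng, gain):
    fs = 250.0
    parts = []
    for _ in range(5):
        parts.append(rng.normal(0, 40, int(8 * fs)))
        parts.append(rng.normal(0, 2, int(10 * fs)))
    base = np.tile(np.concatenate(parts), (8, 1))
    base[4:] *= 1.5  # break symmetry so BSI is non-trivial
    rec = make_recording(base, fs=fs)
    rec_g = make_recording(base * gain, fs=fs)

    sp, sp_g = spectral_powers(rec), spectral_powers(rec_g)
    assert sp_g["spectral_power_delta"] == pytest.approx(gain**2 * sp["spectral_power_delta"], rel=1e-6)
    re, re_g = range_eeg(rec), range_eeg(rec_g)
    assert re_g["reeg_median"] == pytest.approx(gain * re["reeg_median"], rel=1e-6)
    # invariants
    for key in ("spectral_relative_power_delta", "spectral_flatness_beta", "spectral_edge_frequency"):
        assert sp_g[key] == pytest.approx(sp[key], rel=1e-6)
    assert re_g["reeg_asymmetry"] == pytest.approx(re["reeg_asymmetry"], rel=1e-6)
    cn, cn_g = connectivity(rec), connectivity(rec_g)
    assert cn_g["bsi_delta"] == pytest.approx(cn["bsi_delta"], rel=1e-6)
    assert cn_g["coherence_mean_delta"] == pytest.approx(cn["coherence_mean_delta"], rel=1e-6)
    assert fractal_dimension(rec_g) == pytest.approx(fractal_dimension(rec), rel=1e-6)
    sk, ku = amplitude_moments(rec, (1.0, 4.0))
    sk_g, ku_g = amplitude_moments(rec_g, (1.0, 4.0))
    assert sk_g == pytest.approx(sk, rel=1e-6)
    assert ku_g == pytest.approx(ku, rel=1e-6)


def test_channel_permutation_invariance(rng):
    data = rng.normal(0, 20, (8, int(120 * 250)))
    rec = make_recording(data, fs=250.0)
    # permute within hemispheres (left block 0-3, right block 4-7)
    perm = [2, 0, 3, 1, 7, 5, 4, 6]
    labels_p = [LABELS8[i] for i in perm]
    rec_p = make_recording(data[perm], fs=250.0, labels=labels_p)
    a, b = spectral_powers(rec), spectral_powers(rec_p)
    for k in a:
        assert a[k] == pytest.approx(b[k], rel=1e-9, nan_ok=True)
    ca, cb = connectivity(rec), connectivity(rec_p)
    for band in ("delta", "beta"):
        assert ca[f"bsi_{band}"] == pytest.approx(cb[f"bsi_{band}"], rel=1e-9)


def test_mask_invariance(rng):
    fs = 250.0
    parts = []
    for _ in range(8):
        parts.append(rng.normal(0, 40, int(6 * fs)))
        parts.append(rng.normal(0, 2, int(9 * fs)))
    clean = np.tile(np.concatenate(parts), (8, 1))
    rec_clean = make_recording(clean, fs=fs)
    corrupted = clean.copy()
    i, j = int(37 * fs), int(49 * fs)
    corrupted[:, i:j] += rng.normal(0, 500, (8, j - i))
    rec_masked = EEGRecording(list(LABELS8), fs, corrupted, artifact_intervals=[(37.0, 49.0)])

    sp_c, sp_m = spectral_powers(rec_clean), spectral_powers(rec_masked)
    assert sp_m["spectral_power_delta"] == pytest.approx(sp_c["spectral_power_delta"], rel=0.05)
    re_c, re_m = range_eeg(rec_clean), range_eeg(rec_masked)
    assert re_m["reeg_median"] == pytest.approx(re_c["reeg_median"], rel=0.05)


def test_band_scheme_validation():
    with pytest.raises(ValueError):
        BandScheme(delta=(4.0, 1.0)).validate(250.0)
    with pytest.raises(ValueError):
        BandScheme(beta=(13.0, 200.0)).validate(250.0)
    BandScheme().validate(250.0)
    # the alternative published band footnote is constructible
    BandScheme(delta=(0.5, 3.0), theta=(4.0, 7.0), alpha=(8.0, 12.0)).validate(250.0)
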