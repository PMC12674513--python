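"""Audio preprocessing, SNR quality control, features and verification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethobuzz import bioacoustics as ba
from ethobuzz.synth import BuzzElementPlan, gen_buzz_recording, gen_type_recordings


def _tone(freq_hz, rate=22000, dur_s=2.0, amp=0.3):
    t = np.arange(int(rate * dur_s)) / rate
    return ba.Recording(amp * np.sin(2 * np.pi * freq_hz * t), rate, f"tone{freq_hz}")


# ---------------------------------------------------------------------------
# SNR


def test_snr_identity_when_segment_equals_flanks():
    rng = np.random.default_rng(0)
    block = rng.normal(0, 0.1, 22000)
    rec = ba.Recording(np.tile(block, 3), 22000, "flat")
    assert ba.compute_snr(rec, 1.0, 2.0) == pytest.approx(1.0, abs=1e-12)


def test_snr_linear_in_segment_amplitude():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 0.1, 3 * 22000)
    x[22000: 2 * 22000] *= 3.0
    rec = ba.Recording(np.tile(rng.normal(0, 0.1, 22000), 3), 22000, "x")
    rec.samples[22000: 2 * 22000] *= 3.0
    assert ba.compute_snr(rec, 1.0, 2.0) == pytest.approx(3.0, abs=1e-12)


@given(st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=40, deadline=None)
def test_snr_invariant_to_global_scaling(k):
    rng = np.random.default_rng(2)
    x = rng.normal(0, 0.05, 3 * 8000)
    rec = ba.Recording(x, 8000, "s")
    scaled = ba.Recording(k * x, 8000, "s")
    a = ba.compute_snr(rec, 1.0, 2.0)
    b = ba.compute_snr(scaled, 1.0, 2.0)
    assert b == pytest.approx(a, rel=1e-9)


def test_snr_at_file_edge_warns_and_silent_flanks_error():
    rng = np.random.default_rng(3)
    rec = ba.Recording(rng.normal(0, 0.1, 2 * 8000), 8000, "e")
    with pytest.warns(UserWarning, match="flank"):
        ba.compute_snr(rec, 0.0, 1.0)  # no pre-flank available
    silent = ba.Recording(np.concatenate([np.zeros(8000), rng.normal(0, 0.1, 8000),
                                          np.zeros(8000)]), 8000, "z")
    with pytest.raises(ValueError, match="flank"):
        ba.compute_snr(silent, 1.0, 2.0)


def test_filter_by_snr_boundary_and_idempotence():
    ann = pd.DataFrame(dict(recording_id="r", onset_s=[0, 1, 2], offset_s=[0.5, 1.5, 2.5],
                            sound_type="pulse_buzzing", snr=[1.4, 1.5, 2.0]))
    kept, report = ba.filter_by_snr(ann)
    assert sorted(kept.snr) == [1.5, 2.0]
    assert report["n_removed"] == 1
    again, report2 = ba.filter_by_snr(kept)
    assert len(again) == len(kept) and report2["n_removed"] == 0
    none_kept, rep = ba.filter_by_snr(ann[ann.snr < 1.5])
    assert len(none_kept) == 0 and rep["n_kept"] == 0


def test_constructed_snr_set_matches_hand_count():
    # elements at RMS ratios ~1, ~3 and ~8 over the same noise floor
    elements = [
        BuzzElementPlan(1.0, 0.4, "pulse_buzzing", 250.0, level=0.0),  # noise-only
        BuzzElementPlan(3.0, 0.4, "pulse_buzzing", 250.0, level=0.06),
        BuzzElementPlan(5.0, 0.4, "pulse_buzzing", 250.0, level=0.16),
    ]
    rec, ann, truth = gen_buzz_recording(elements, seed=4, noise_level=0.02, total_s=7.0)
    ann = ba.annotate_snr(ann, {rec.recording_id: rec})
    kept, report = ba.filter_by_snr(ann, 1.5)
    assert len(kept) == 2 and report["n_removed"] == 1
    # measured SNR close to the construction target
    assert ann.snr.iloc[2] == pytest.approx(truth["expected_snr"][2], rel=0.1)


# ---------------------------------------------------------------------------
# preprocessing


def test_preprocess_resamples_stereo_to_22k_mono():
    rate = 44100
    rng = np.random.default_rng(5)
    stereo = rng.normal(0, 0.1, size=(rate * 6, 2))
    rec = ba.Recording(stereo, rate, "st")
    out = ba.preprocess(rec, noise_span=(0.0, 5.0))
    assert out.rate_hz == 22000
    assert out.samples.ndim == 1
    assert abs(out.duration_s - rec.duration_s) <= 1.0 / 22000


def test_highpass_attenuates_stopband():
    low, high = _tone(50.0), _tone(500.0)
    y_low = ba.highpass(low.samples, 22000)
    y_high = ba.highpass(high.samples, 22000)
    att_low = np.sqrt(np.mean(y_low**2)) / np.sqrt(np.mean(low.samples**2))
    att_high = np.sqrt(np.mean(y_high**2)) / np.sqrt(np.mean(high.samples**2))
    assert att_low < 0.2 and att_high > 0.9


def test_spectral_subtraction_reduces_stationary_noise():
    rng = np.random.default_rng(6)
    rec = ba.Recording(rng.normal(0, 0.1, 22000 * 8), 22000, "n")
    out = ba.preprocess(rec, noise_span=(0.0, 5.0))
    assert np.sqrt(np.mean(out.samples**2)) < 0.5 * np.sqrt(np.mean(rec.samples**2))


def test_preprocess_requires_recording_longer_than_noise_span():
    rec = ba.Recording(np.zeros(22000), 22000, "short")
    with pytest.raises(ValueError, match="shorter"):
        ba.preprocess(rec, noise_span=(0.0, 5.0))


# ---------------------------------------------------------------------------
# spectro-temporal features


def test_pure_tone_features_and_noise_entropy():
    tone = _tone(440.0)
    f = ba.extract_features(tone, 0.25, 1.75)
    bin_width = 22000 / 512  # one FFT bin
    assert f.entropy < 0.3  # pure tone: near 0
    assert abs(f.mean_freq_khz * 1000 - 440.0) < bin_width
    assert abs(f.dominant_freq_khz * 1000 - 440.0) < bin_width
    noise = ba.Recording(np.random.default_rng(7).normal(0, 0.2, 44000), 22000, "n")
    fn = ba.extract_features(noise, 0.25, 1.75)
    assert fn.entropy > 0.9  # noise: near 1


def test_harmonic_stack_second_harmonic_and_hnr_monotone():
    el = [BuzzElementPlan(0.5, 0.6, "x", 200.0, n_harmonics=5, level=0.3)]
    hnrs = []
    for noise in (0.002, 0.02, 0.1):
        rec, _, _ = gen_buzz_recording(el, seed=8, noise_level=noise, total_s=2.0)
        f = ba.extract_features(rec, 0.5, 1.1)
        hnrs.append(f.hnr_db)
        if noise == 0.002:
            assert f.f1_freq_khz == pytest.approx(0.4, abs=0.05)  # 2 x 200 Hz
    assert hnrs[0] > hnrs[1] > hnrs[2]  # more noise, lower HNR


def test_silent_span_flagged_undefined():
    rec = ba.Recording(np.zeros(22000), 22000, "s")
    f = ba.extract_features(rec, 0.1, 0.6)
    assert not f.defined and np.isnan(f.entropy)


# ---------------------------------------------------------------------------
# MFCC


@pytest.mark.parametrize("dur", [0.05, 0.2, 1.0])
def test_mfcc_length_always_108(dur):
    rec = _tone(300.0)
    v = ba.mfcc_features(rec, 0.2, 0.2 + dur)
    assert v.shape == (108,)


def test_mfcc_too_short_span_errors():
    rec = _tone(300.0)
    with pytest.raises(ValueError, match="short"):
        ba.mfcc_features(rec, 0.0, 5 / 22000)


def test_mfcc_stationary_signal_has_similar_windows():
    rec = _tone(300.0)
    v = ba.mfcc_features(rec, 0.2, 1.2).reshape(9, 12)
    spread = np.abs(v - v.mean(axis=0)).max()
    assert spread < 0.1 * np.abs(v).max()


def test_mfcc_separates_fundamentals():
    specs = {
        "pulse_buzzing": dict(kind="random", fundamental_hz=450.0, duration_s=0.15,
                              ioi_range_s=(0.5, 1.5)),
        "continuous_buzzing": dict(kind="random", fundamental_hz=150.0, duration_s=0.15,
                                   ioi_range_s=(0.5, 1.5)),
    }
    recs, ann = gen_type_recordings(specs, n_per_type=12, seed=9)
    X, y = [], []
    for _, row in ann.iterrows():
        X.append(ba.mfcc_features(recs[row.recording_id], row.onset_s, row.offset_s))
        y.append(row.sound_type)
    X, y = np.array(X), np.array(y)
    a, b = X[y == "pulse_buzzing"], X[y == "continuous_buzzing"]
    within = np.linalg.norm(a - a.mean(0), axis=1).mean()
    between = np.linalg.norm(a.mean(0) - b.mean(0))
    assert between > within


# ---------------------------------------------------------------------------
# verification


@pytest.fixture(scope="module")
def two_class_features():
    specs = {
        "pulse_buzzing": dict(kind="random", fundamental_hz=450.0, duration_s=0.12,
                              ioi_range_s=(0.4, 1.2), f0_jitter_hz=30.0),
        "continuous_buzzing": dict(kind="random", fundamental_hz=150.0, duration_s=0.3,
                                   ioi_range_s=(0.6, 1.5), f0_jitter_hz=15.0),
    }
    recs, ann = gen_type_recordings(specs, n_per_type=40, seed=10)
    X, y = [], []
    for _, row in ann.iterrows():
        X.append(ba.mfcc_features(recs[row.recording_id], row.onset_s, row.offset_s))
        y.append(row.sound_type)
    return np.array(X), np.array(y)


def test_verify_labels_separable_classes(two_class_features):
    X, y = two_class_features
    res = ba.verify_labels(X, y, train_fraction=0.2, seed=0)
    assert res.test_accuracy > 0.95
    assert res.train_reverse_accuracy == pytest.approx(1.0)
    assert res.ci_low <= res.test_accuracy <= res.ci_high
    assert res.confusion.to_numpy().sum() == res.n_test


def test_verify_labels_permuted_is_chance(two_class_features):
    X, y = two_class_features
    rng = np.random.default_rng(1)
    res = ba.verify_labels(X, rng.permutation(y), train_fraction=0.2, seed=0)
    assert abs(res.test_accuracy - 0.5) < 0.2


def test_verify_labels_small_class_errors(two_class_features):
    X, y = two_class_features
    y2 = y.copy()
    y2[:1] = "fanning"
    with pytest.raises(ValueError, match="fewer than 2"):
        ba.verify_labels(X, y2, seed=0)
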