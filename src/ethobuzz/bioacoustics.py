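"""Defensive-buzz audio processing, quality control and verification.

Pipeline for annotated mono WAV recordings of buzzing bees: preprocessing
(downsampling to 22 kHz mono, spectral noise subtraction against a captured
noise profile with a 30 dB reduction depth, 70 Hz Butterworth high-pass),
signal-to-noise quality control of annotated segments (segment RMS divided
by the mean RMS of equal-length flanking segments, threshold 1.5),
spectro-temporal feature extraction (duration, spectral entropy, mean and
dominant frequency, second-harmonic frequency, harmonic-to-noise ratio),
MFCC representation (nine equal-length windows x 12 mel coefficients = 108
values per call) and random-forest verification of the manual sound-type
labels.

The mel filterbank / cepstrum step is implemented here on top of scipy's
FFT and DCT primitives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import dct, rfft, rfftfreq
from scipy.io import wavfile
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from statsmodels.stats.proportion import proportion_confint

SOUND_TYPES = ("pulse_buzzing", "continuous_buzzing", "fanning", "flying")

#: Target rate after preprocessing (Hz).
TARGET_RATE_HZ = 22000

ANNOTATION_COLUMNS = ("recording_id", "onset_s", "offset_s", "sound_type")


@dataclass
class Recording:
    """A mono waveform held as float64 in [-1, 1]."""

    samples: np.ndarray
    rate_hz: int
    recording_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:  # (n, channels) -> mono mean
            self.samples = self.samples.mean(axis=1)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    def slice(self, onset_s: float, offset_s: float) -> np.ndarray:
        i = int(round(onset_s * self.rate_hz))
        j = int(round(offset_s * self.rate_hz))
        return self.samples[max(i, 0): max(j, 0)]


def read_wav(path, recording_id: str | None = None) -> Recording:
    """Read a PCM/float WAV file, scaling integer formats to [-1, 1]."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Recording(data, int(rate), recording_id or str(path))


def write_wav(path, rec: Recording) -> None:
    """Write a Recording as 16-bit PCM WAV."""
    x = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(path, rec.rate_hz, (x * 32767.0).astype(np.int16))


def read_annotations(path) -> pd.DataFrame:
    """Read an annotation CSV (recording_id, onset_s, offset_s, sound_type)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing annotation column(s): {', '.join(missing)}")
    if not (df["offset_s"] > df["onset_s"]).all():
        bad = df.index[~(df["offset_s"] > df["onset_s"])].tolist()
        raise ValueError(f"offset_s must exceed onset_s (rows {bad})")
    return df


# ---------------------------------------------------------------------------
# preprocessing


def _resample(x: np.ndarray, rate: int, target: int) -> np.ndarray:
    if rate == target:
        return x
    frac = Fraction(target, rate).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def spectral_subtract(
    x: np.ndarray,
    rate_hz: int,
    noise_span: tuple[float, float],
    reduction_db: float = 30.0,
    nperseg: int = 512,
) -> np.ndarray:
    """Magnitude-domain spectral subtraction of a noise-profile spectrum.

    The mean magnitude spectrum over ``noise_span`` is subtracted from every
    STFT frame, flooring each bin at ``reduction_db`` below its original
    magnitude (the maximum reduction depth); phases are kept.
    """
    noverlap = nperseg * 3 // 4
    f, t, Z = signal.stft(x, fs=rate_hz, nperseg=nperseg, noverlap=noverlap)
    frame_times = t
    in_noise = (frame_times >= noise_span[0]) & (frame_times < noise_span[1])
    if not in_noise.any():
        raise ValueError("noise span contains no STFT frames")
    noise_mag = np.abs(Z[:, in_noise]).mean(axis=1, keepdims=True)
    mag = np.abs(Z)
    floor = mag * 10.0 ** (-reduction_db / 20.0)
    mag_sub = np.maximum(mag - noise_mag, floor)
    Z_out = mag_sub * np.exp(1j * np.angle(Z))
    _, y = signal.istft(Z_out, fs=rate_hz, nperseg=nperseg, noverlap=noverlap)
    if len(y) >= len(x):
        return y[: len(x)]
    return np.pad(y, (0, len(x) - len(y)))


def highpass(x: np.ndarray, rate_hz: int, cutoff_hz: float = 70.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass."""
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def preprocess(
    rec: Recording,
    noise_span: tuple[float, float] = (0.0, 5.0),
    target_rate_hz: int = TARGET_RATE_HZ,
    reduction_db: float = 30.0,
    highpass_hz: float = 70.0,
    nperseg: int = 512,
) -> Recording:
    """Standard preprocessing: 22 kHz mono, noise subtraction, 70 Hz HP.

    ``noise_span`` designates the captured noise profile (default the first
    five seconds); the recording must be longer than the span.
    """
    if rec.duration_s <= (noise_span[1] - noise_span[0]):
        raise ValueError(
            f"recording ({rec.duration_s:.2f}s) shorter than noise span "
            f"({noise_span[1] - noise_span[0]:.2f}s)"
        )
    x = _resample(rec.samples, rec.rate_hz, target_rate_hz)
    x = spectral_subtract(x, target_rate_hz, noise_span, reduction_db, nperseg)
    x = highpass(x, target_rate_hz, highpass_hz)
    return Recording(x, target_rate_hz, rec.recording_id)


# ---------------------------------------------------------------------------
# SNR quality control


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0


def compute_snr(rec: Recording, onset_s: float, offset_s: float) -> float:
    """Segment RMS over the mean RMS of equal-length flanking segments.

    The two flanks immediately precede and follow the annotated span, each
    of the span's own duration.  A value of 1 means the signal has the same
    amplitude as the background.  Flanks truncated by the file edge are
    used as available (with a warning); if neither flank contains samples,
    or the flanks are pure silence, the ratio is undefined and an error is
    raised.
    """
    if not offset_s > onset_s:
        raise ValueError("offset_s must exceed onset_s")
    dur = offset_s - onset_s
    seg = rec.slice(onset_s, offset_s)
    if not len(seg):
        raise ValueError("annotated span contains no samples")
    pre = rec.slice(max(onset_s - dur, 0.0), onset_s)
    post = rec.slice(offset_s, min(offset_s + dur, rec.duration_s))
    n_full = len(seg)
    if len(pre) < n_full or len(post) < n_full:
        warnings.warn(
            "flanking window truncated at the file edge; SNR computed on the "
            "available flank samples",
            stacklevel=2,
        )
    flanks = [f for f in (pre, post) if len(f)]
    if not flanks:
        raise ValueError("no flanking samples available around the annotation")
    flank_amp = float(np.mean([_rms(f) for f in flanks]))
    if flank_amp == 0.0:
        raise ValueError("zero-amplitude flanks: SNR undefined")
    return _rms(seg) / flank_amp


def annotate_snr(
    annotations: pd.DataFrame, recordings: dict[str, Recording]
) -> pd.DataFrame:
    """Attach an ``snr`` column by computing it for every annotation row."""
    out = annotations.copy()
    snrs = []
    for _, row in out.iterrows():
        rec = recordings[row["recording_id"]]
        snrs.append(compute_snr(rec, row["onset_s"], row["offset_s"]))
    out["snr"] = snrs
    return out


def filter_by_snr(
    annotations: pd.DataFrame, threshold: float = 1.5
) -> tuple[pd.DataFrame, dict]:
    """Keep annotations with snr >= threshold (boundary kept).

    Returns ``(kept, report)`` where the report counts kept/removed rows
    overall and per sound type.  Idempotent.
    """
    if "snr" not in annotations.columns:
        raise ValueError("annotations lack an 'snr' column; run annotate_snr first")
    keep = annotations["snr"] >= threshold
    kept = annotations[keep].reset_index(drop=True)
    removed = annotations[~keep]
    report = {
        "threshold": threshold,
        "n_input": int(len(annotations)),
        "n_kept": int(len(kept)),
        "n_removed": int(len(removed)),
        "removed_by_type": removed.groupby("sound_type").size().to_dict()
        if len(removed)
        else {},
    }
    return kept, report


# ---------------------------------------------------------------------------
# features


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate_hz: int, fmin_hz: float = 20.0, fmax_hz: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    fmax_hz = fmax_hz or rate_hz / 2.0
    mels = np.linspace(_hz_to_mel(fmin_hz), _hz_to_mel(fmax_hz), n_mels + 2)
    edges_hz = _mel_to_hz(mels)
    freqs = rfftfreq(n_fft, d=1.0 / rate_hz)
    fb = np.zeros((n_mels, len(freqs)))
    for i in range(n_mels):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mfcc_features(
    rec: Recording,
    onset_s: float,
    offset_s: float,
    n_windows: int = 9,
    n_mels: int = 12,
) -> np.ndarray:
    """Fixed-length MFCC vector: ``n_windows`` x ``n_mels`` = 108 values.

    The annotated span is cut into ``n_windows`` equal-length windows; per
    window a Hann-weighted magnitude spectrum feeds a 12-filter mel bank,
    whose log energies are DCT-II transformed into 12 coefficients.  The
    windows are concatenated in order, so the vector length is constant
    regardless of the span duration.
    """
    seg = rec.slice(onset_s, offset_s)
    if len(seg) < n_windows:
        raise ValueError(
            f"annotated span too short ({len(seg)} samples) for {n_windows} windows"
        )
    win_len = len(seg) // n_windows
    n_fft = max(64, int(2 ** np.ceil(np.log2(win_len))))
    fb = mel_filterbank(n_mels, n_fft, rec.rate_hz)
    out = np.empty(n_windows * n_mels)
    taper = np.hanning(win_len)
    for w in range(n_windows):
        chunk = seg[w * win_len: (w + 1) * win_len] * taper
        spec = np.abs(rfft(chunk, n=n_fft))
        energies = fb @ (spec**2)
        loge = np.log(energies + 1e-12)
        out[w * n_mels: (w + 1) * n_mels] = dct(loge, type=2, norm="ortho")
    return out


@dataclass
class AcousticFeatures:
    """Six spectro-temporal metrics of one annotated sound."""

    duration_s: float
    entropy: float  # normalised spectral entropy, 0 (pure tone) .. 1 (noise)
    mean_freq_khz: float  # energy-weighted spectral centroid
    dominant_freq_khz: float  # mean per-frame peak frequency
    f1_freq_khz: float  # second-harmonic frequency (peak nearest 2 * f0)
    hnr_db: float  # harmonic-to-noise ratio
    defined: bool = True
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "entropy": self.entropy,
            "mean_freq_khz": self.mean_freq_khz,
            "dominant_freq_khz": self.dominant_freq_khz,
            "f1_freq_khz": self.f1_freq_khz,
            "hnr_db": self.hnr_db,
        }


def _estimate_f0(seg: np.ndarray, rate_hz: int, fmin: float = 50.0, fmax: float = 2000.0):
    """Fundamental frequency and normalised autocorrelation peak height."""
    x = seg - seg.mean()
    n = len(x)
    r = signal.correlate(x, x, mode="full")[n - 1:]
    if r[0] <= 0:
        return np.nan, 0.0
    r = r / r[0]
    lag_min = max(2, int(rate_hz / fmax))
    lag_max = min(n - 1, int(rate_hz / fmin))
    if lag_max <= lag_min:
        return np.nan, 0.0
    k = lag_min + int(np.argmax(r[lag_min:lag_max]))
    return rate_hz / k, float(np.clip(r[k], 0.0, 1.0 - 1e-9))


def extract_features(
    rec: Recording,
    onset_s: float,
    offset_s: float,
    nperseg: int = 512,
    window: str = "blackmanharris",
) -> AcousticFeatures:
    """Extract the six spectro-temporal metrics for an annotated span.

    Spectra use a 512-point FFT with a Blackman-Harris window and 75 %
    overlap (shorter spans shrink the segment length so that at least two
    frames exist).  A silent span yields ``defined=False`` with NaNs.
    """
    seg = rec.slice(onset_s, offset_s)
    duration = offset_s - onset_s
    if len(seg) < 8 or _rms(seg) == 0.0:
        return AcousticFeatures(duration, *([np.nan] * 5), defined=False, note="silent or empty span")
    nperseg = int(min(nperseg, max(8, len(seg) // 2)))
    noverlap = nperseg * 3 // 4
    f, t, S = signal.spectrogram(
        seg, fs=rec.rate_hz, window=window, nperseg=nperseg, noverlap=noverlap,
        mode="psd",
    )
    if S.shape[1] < 2 or S.sum() == 0:
        return AcousticFeatures(duration, *([np.nan] * 5), defined=False, note="too few frames")
    mean_spec = S.mean(axis=1)
    p = mean_spec / mean_spec.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-(p[p > 0] * np.log(p[p > 0])).sum() / np.log(len(p)))
    mean_freq = float((f * p).sum())
    dom_freq = float(f[np.argmax(S, axis=0)].mean())
    f0, r_peak = _estimate_f0(seg, rec.rate_hz)
    if np.isfinite(f0):
        # second harmonic: local spectral peak nearest 2 * f0
        peaks, _ = signal.find_peaks(mean_spec)
        if len(peaks):
            f1 = float(f[peaks[np.argmin(np.abs(f[peaks] - 2.0 * f0))]])
        else:
            f1 = 2.0 * f0
        hnr = float(10.0 * np.log10(r_peak / (1.0 - r_peak))) if r_peak > 0 else -np.inf
    else:
        f1, hnr = np.nan, np.nan
    return AcousticFeatures(
        duration_s=duration,
        entropy=ent,
        mean_freq_khz=mean_freq / 1000.0,
        dominant_freq_khz=dom_freq / 1000.0,
        f1_freq_khz=f1 / 1000.0,
        hnr_db=hnr,
    )


def features_table(
    annotations: pd.DataFrame, recordings: dict[str, Recording]
) -> pd.DataFrame:
    """Spectro-temporal metrics + MFCC vector for every annotation."""
    rows = []
    for _, ann in annotations.iterrows():
        rec = recordings[ann["recording_id"]]
        feats = extract_features(rec, ann["onset_s"], ann["offset_s"])
        mfcc = mfcc_features(rec, ann["onset_s"], ann["offset_s"])
        row = {**ann.to_dict(), **feats.as_dict(), "defined": feats.defined}
        row.update({f"mfcc_{k:03d}": v for k, v in enumerate(mfcc)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label verification


@dataclass
class VerificationResult:
    """Random-forest check of the manual sound-type labels."""

    test_accuracy: float
    ci_low: float
    ci_high: float
    train_reverse_accuracy: float
    confusion: pd.DataFrame
    n_train: int
    n_test: int
    classes: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> str:
        return (
            f"Label verification: test accuracy {self.test_accuracy:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}; n_test={self.n_test}); "
            f"reverse prediction on the {self.n_train} training calls: "
            f"{self.train_reverse_accuracy:.3f}\n" + self.confusion.to_string()
        )


def verify_labels(
    features: np.ndarray,
    labels,
    train_fraction: float = 0.2,
    seed: int | None = None,
    balance: bool = False,
    n_estimators: int = 500,
) -> VerificationResult:
    """Train a random forest on a split of the calls and score the rest.

    ``train_fraction`` defaults to 0.2 (a 20/80 train/test split).  With
    ``balance=True`` classes are first sub-sampled to the size of the
    smallest class.  Reports test accuracy with an exact binomial 95 % CI,
    the confusion matrix, and the reverse prediction accuracy on the
    training set (a diagnostic that should approach 1 on separable data).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"class(es) with fewer than 2 members: {small}")
    rng = np.random.default_rng(seed)
    if balance:
        m = counts.min()
        keep = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=m, replace=False) for c in classes]
        )
        X, y = X[keep], y[keep]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, stratify=y,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(rng.integers(0, 2**31 - 1))
    )
    clf.fit(X_tr, y_tr)
    pred_te = clf.predict(X_te)
    acc = float(np.mean(pred_te == y_te))
    lo, hi = proportion_confint(int((pred_te == y_te).sum()), len(y_te), method="beta")
    rev = float(np.mean(clf.predict(X_tr) == y_tr))
    cm = pd.DataFrame(
        confusion_matrix(y_te, pred_te, labels=classes), index=classes, columns=classes
    )
    return VerificationResult(
        test_accuracy=acc,
        ci_low=float(lo),
        ci_high=float(hi),
        train_reverse_accuracy=rev,
        confusion=cm,
        n_train=len(y_tr),
        n_test=len(y_te),
        classes=tuple(classes),
    )
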