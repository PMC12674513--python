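"""Inter-onset-interval rhythm analysis (the isochrony test).

Workflow: measure inter-onset intervals (IOIs) between the initiations of
successive annotated sound elements of one recording; discard IOIs above
the pooled 95th-percentile threshold (outliers unlikely to belong to one
behavioural sequence); form the ratio r = I_n / (I_n + I_{n+1}) for
adjacent IOI pairs whose three bounding sounds share one sound type
("symmetric" pairs); categorise each ratio against small-integer rhythms
(1:1 at r = 1/2, 2:1 at r = 2/3, 1:2 at r = 1/3, band edges at +/-0.25 on
the interval-ratio scale); and compare the observed ratio distribution to
a per-recording uniform resampling null with a two-sample KS test.

Isochronous sequences put essentially all ratios in the on-integer 1:1
band [4/9, 5/9] (printed 0.44-0.55), which a uniform null does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

#: On/off band edges expressed as exact interval-ratio fractions.
#: For a k:1 rhythm the on band spans interval ratios (k - 0.25):1 to
#: (k + 0.25):1 and the off bands extend a further 0.25 on either side.
def _band(num: float, den: float) -> float:
    """r for the interval ratio num:den."""
    return num / (num + den)


#: Category bands as (name, low, high, closed_low, closed_high); on-integer
#: bands are closed, ties at an on/off edge go to the on-integer band.
CATEGORY_BANDS = (
    ("on_1_2", _band(1, 2.25), _band(1, 1.75), True, True),        # [0.3077, 0.3636]
    ("off_1_2_low", _band(1, 2.5), _band(1, 2.25), True, False),   # [0.2857, 0.3077)
    ("off_1_2_high", _band(1, 1.75), _band(1, 1.5), False, False),  # (0.3636, 0.4)
    ("on_1_1", _band(1, 1.25), _band(1.25, 1), True, True),        # [0.4444, 0.5556]
    ("off_1_1_low", _band(1, 1.5), _band(1, 1.25), True, False),   # [0.4, 0.4444)
    ("off_1_1_high", _band(1.25, 1), _band(1.5, 1), False, True),  # (0.5556, 0.6]
    ("on_2_1", _band(1.75, 1), _band(2.25, 1), True, True),        # [0.6364, 0.6923]
    ("off_2_1_low", _band(1.5, 1), _band(1.75, 1), False, False),  # (0.6, 0.6364)
    ("off_2_1_high", _band(2.25, 1), _band(2.5, 1), False, True),  # (0.6923, 0.7143]
)

CATEGORIES = tuple(name for name, *_ in CATEGORY_BANDS) + ("other",)


@dataclass
class IOISequence:
    """Onsets and inter-onset intervals of one recording.

    ``types[k]`` is the sound type of the k-th onset, so IOI ``k`` spans
    sounds ``k`` and ``k+1``.  ``kept`` marks IOIs surviving thresholding.
    """

    recording_id: str
    onsets_s: np.ndarray
    types: np.ndarray
    iois_s: np.ndarray = field(init=False)
    kept: np.ndarray = field(init=False)

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.types = np.asarray(self.types, dtype=object)
        self.iois_s = np.diff(self.onsets_s)
        self.kept = np.ones(len(self.iois_s), dtype=bool)


def compute_iois(annotations: pd.DataFrame) -> list[IOISequence]:
    """Build one IOI sequence per recording from onset annotations.

    Onsets are sorted internally, so input order does not matter.
    Duplicate onset times would give zero IOIs and are rejected with a
    diagnostic.  A recording with a single annotation yields an empty IOI
    list.
    """
    out = []
    for rec_id, grp in annotations.groupby("recording_id", sort=False):
        grp = grp.sort_values("onset_s", kind="stable")
        onsets = grp["onset_s"].to_numpy(float)
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            k = int(np.nonzero(np.diff(onsets) <= 0)[0][0])
            raise ValueError(
                f"recording {rec_id!r}: duplicate onset time at {onsets[k]:.6g} s "
                "gives a zero inter-onset interval"
            )
        out.append(IOISequence(str(rec_id), onsets, grp["sound_type"].to_numpy(object)))
    return out


def threshold_iois(
    sequences: list[IOISequence], quantile: float = 0.95
) -> tuple[list[IOISequence], float]:
    """Drop IOIs above the pooled ``quantile`` (default 95th percentile).

    The threshold is one value computed on the IOIs pooled over all
    recordings; IOIs strictly above it are marked not-kept.  Idempotent:
    re-thresholding the kept IOIs removes nothing further.
    """
    pool = np.concatenate([s.iois_s[s.kept] for s in sequences]) if sequences else np.array([])
    if pool.size == 0:
        raise ValueError("no IOIs to threshold")
    if pool.size < 20:
        warnings.warn(
            f"only {pool.size} pooled IOIs; the {quantile:.0%} quantile is unstable",
            stacklevel=2,
        )
    thr = float(np.quantile(pool, quantile))
    out = []
    for s in sequences:
        s2 = IOISequence(s.recording_id, s.onsets_s, s.types)
        s2.kept = s.kept & (s2.iois_s <= thr)
        out.append(s2)
    return out, thr


def interval_ratio(i_n: float, i_next: float) -> float:
    """Rhythm ratio r = I_n / (I_n + I_{n+1}), in (0, 1).

    Equal intervals give 0.5; r for the reversed pair is 1 - r.
    """
    if not (i_n > 0 and i_next > 0):
        raise ValueError("intervals must be positive")
    return i_n / (i_n + i_next)


def categorize(r: float) -> str:
    """Small-integer rhythm category of a ratio.

    On-integer bands are closed intervals; ratios not covered by any 1:2,
    1:1 or 2:1 band are ``other``.  r must lie strictly inside (0, 1).
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"ratio {r} outside (0, 1)")
    for name, lo, hi, clo, chi in CATEGORY_BANDS:
        if (r > lo or (clo and r == lo)) and (r < hi or (chi and r == hi)):
            return name
    return "other"


def symmetric_pairs(
    sequences: list[IOISequence], sound_type: str | None = None
) -> pd.DataFrame:
    """Adjacent IOI pairs whose three bounding sounds share one type.

    Pairs are taken between IOIs adjacent in the original sequence; a pair
    is dropped if either IOI was removed by thresholding (removals break
    the sequence rather than splicing it).  Returns one row per kept pair
    with the ratio and its category.
    """
    rows = []
    for s in sequences:
        for k in range(len(s.iois_s) - 1):
            if not (s.kept[k] and s.kept[k + 1]):
                continue
            t0, t1, t2 = s.types[k], s.types[k + 1], s.types[k + 2]
            if not (t0 == t1 == t2):
                continue
            if sound_type is not None and t0 != sound_type:
                continue
            r = interval_ratio(s.iois_s[k], s.iois_s[k + 1])
            rows.append(
                dict(
                    recording_id=s.recording_id,
                    sound_type=t0,
                    rank=k,
                    i_n=s.iois_s[k],
                    i_next=s.iois_s[k + 1],
                    r=r,
                    category=categorize(r),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["recording_id", "sound_type", "rank", "i_n", "i_next", "r", "category"],
    )


def generate_null(
    sequences: list[IOISequence], seed: int | np.random.Generator
) -> list[IOISequence]:
    """Uniform-resampling null with the observed per-recording structure.

    For each recording the observed IOIs are replaced by the same number of
    draws from a uniform distribution on that recording's [min, max] IOI
    range; onsets are rebuilt by accumulation and sound types are carried
    over, so thresholding and symmetric pairing apply identically.
    Recordings with a degenerate range (min == max) or fewer than two IOIs
    are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for s in sequences:
        if len(s.iois_s) < 2:
            warnings.warn(
                f"recording {s.recording_id!r} has fewer than 2 IOIs; skipped in null",
                stacklevel=2,
            )
            continue
        lo, hi = float(s.iois_s.min()), float(s.iois_s.max())
        if not hi > lo:
            warnings.warn(
                f"recording {s.recording_id!r} has a degenerate IOI range; skipped in null",
                stacklevel=2,
            )
            continue
        iois = rng.uniform(lo, hi, size=len(s.iois_s))
        onsets = np.concatenate([[s.onsets_s[0]], s.onsets_s[0] + np.cumsum(iois)])
        out.append(IOISequence(s.recording_id + "::null", onsets, s.types.copy()))
    return out


@dataclass
class KSResult:
    statistic: float
    p: float
    low_power: bool = False


def ks_compare(observed_ratios, null_ratios, min_n: int = 5) -> KSResult:
    """Two-sample KS test of the observed vs null ratio distributions."""
    obs = np.asarray(observed_ratios, float)
    nul = np.asarray(null_ratios, float)
    if len(obs) == 0 or len(nul) == 0:
        raise ValueError("both ratio samples must be non-empty")
    stat, p = stats.ks_2samp(obs, nul)
    return KSResult(float(stat), float(p), low_power=min(len(obs), len(nul)) < min_n)


@dataclass
class RhythmResult:
    """End-to-end isochrony analysis of one sound type."""

    sound_type: str | None
    ioi_threshold_s: float
    observed: pd.DataFrame  # ratio table (symmetric pairs)
    null: pd.DataFrame
    ks: KSResult
    category_fractions: pd.Series
    alpha: float = 0.05

    @property
    def is_rhythmic(self) -> bool:
        """Observed ratios deviate from the uniform null at ``alpha``."""
        return bool(self.ks.p < self.alpha)

    def summary(self) -> str:
        on11 = self.category_fractions.get("on_1_1", 0.0)
        return (
            f"Rhythm analysis ({self.sound_type or 'all types'}): "
            f"{len(self.observed)} observed ratio pairs, IOI threshold "
            f"{self.ioi_threshold_s:.3g} s; KS D = {self.ks.statistic:.3f}, "
            f"p = {self.ks.p:.3g}; on-integer 1:1 fraction = {on11:.3f}"
        )


def analyze_rhythm(
    annotations: pd.DataFrame,
    sound_type: str | None = None,
    seed: int | np.random.Generator = 0,
    quantile: float = 0.95,
    per_recording: bool = False,
) -> "RhythmResult | list[RhythmResult]":
    """Full pipeline: IOIs -> threshold -> symmetric pairs -> null -> KS.

    The null sequences are thresholded at their own pooled quantile so that
    observed and null ratios are computed by identical rules.  With
    ``per_recording=True`` a result per recording is returned instead of
    one pooled-per-type result.
    """
    sequences = compute_iois(annotations)
    if per_recording:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = []
        for s in sequences:
            sub = annotations[annotations["recording_id"] == s.recording_id]
            out.append(analyze_rhythm(sub, sound_type, rng, quantile, per_recording=False))
        return out
    filtered, thr = threshold_iois(sequences, quantile)
    observed = symmetric_pairs(filtered, sound_type)
    null_seq = generate_null(sequences, seed)
    null_filtered, _ = threshold_iois(null_seq, quantile)
    null = symmetric_pairs(null_filtered, sound_type)
    ks = ks_compare(observed["r"], null["r"])
    frac = (
        observed["category"].value_counts(normalize=True).reindex(CATEGORIES, fill_value=0.0)
        if len(observed)
        else pd.Series(0.0, index=CATEGORIES)
    )
    return RhythmResult(
        sound_type=sound_type,
        ioi_threshold_s=thr,
        observed=observed,
        null=null,
        ks=ks,
        category_fractions=frac,
    )
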