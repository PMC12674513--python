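"""Synthetic data with known ground truth for every pipeline stage.

Emulates the statistical structure of colony-defence trials without any
video or audio of real bees: phase-structured Bernoulli occurrence with
Gamma bout durations and inside/outside location preferences per behaviour;
log-linear coupled occurrence for association tests; stimulus-dependent
occurrence shifts for the microcolony design; Gamma-noise velocity tracks;
onset sequences that are isochronous (with jitter), uniform-random or
2:1-alternating; and harmonic buzz waveforms over Gaussian background
noise with controllable per-element SNR.

All generators take an explicit seed (or Generator) and are deterministic:
the same seed and spec reproduce byte-identical tables and waveforms.
Ground-truth parameter records are returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioacoustics import Recording
from .events import DEFAULT_ANALYSIS_BEHAVIOURS, PhaseScheme, default_phase_scheme


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# behaviour events


@dataclass
class BehaviourGenSpec:
    """Ground-truth parameters for a behaviour-event table.

    ``occurrence[behaviour][phase]`` is the per-bee Bernoulli probability of
    performing the behaviour at all during the phase.  Given occurrence,
    the number of bouts is 1 + Poisson(bout_rate_per_min * phase minutes)
    and bout durations are Gamma(shape, scale) seconds, placed uniformly in
    the phase without within-behaviour overlap.  ``p_outside`` is the
    probability a bout is located outside the brood area.
    """

    n_colonies: int = 4
    n_bees_per_colony: int = 20
    include_queen: bool = True
    scheme: PhaseScheme = field(default_factory=lambda: default_phase_scheme("part1"))
    occurrence: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    duration_shape: Mapping[str, float] = field(default_factory=dict)
    duration_scale: Mapping[str, float] = field(default_factory=dict)
    bout_rate_per_min: Mapping[str, float] = field(default_factory=dict)
    p_outside: Mapping[str, float] = field(default_factory=dict)
    #: multiplicative odds shift on occurrence per (stimulus, behaviour, phase)
    stimulus_effects: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        for beh, per_phase in self.occurrence.items():
            for ph, p in per_phase.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"occurrence[{beh}][{ph}] = {p} outside [0, 1]")


def default_behaviour_spec() -> BehaviourGenSpec:
    """Demo spec loosely mimicking the whole-colony response pattern.

    Near-universal post-disturbance abdominal pumping, acute-phase
    continuous buzzing, rare leg raising, a delayed pulse-buzzing/grooming
    peak.  Purely a demonstration parameterisation.
    """
    occ = {
        "patrolling":        {"BD": 0.00, "AR": 0.90, "DR": 0.60, "R": 0.20},
        "continuous_buzzing": {"BD": 0.02, "AR": 0.90, "DR": 0.15, "R": 0.05},
        "abdominal_pumping": {"BD": 0.00, "AR": 0.90, "DR": 0.70, "R": 0.40},
        "grooming":          {"BD": 0.40, "AR": 0.10, "DR": 0.70, "R": 0.60},
        "flying_climbing":   {"BD": 0.02, "AR": 0.30, "DR": 0.20, "R": 0.05},
        "leg_raising":       {"BD": 0.00, "AR": 0.25, "DR": 0.05, "R": 0.01},
        "perching":          {"BD": 0.05, "AR": 0.50, "DR": 0.45, "R": 0.15},
        "pulse_buzzing":     {"BD": 0.00, "AR": 0.25, "DR": 0.55, "R": 0.25},
    }
    return BehaviourGenSpec(
        occurrence=occ,
        duration_shape={b: 2.0 for b in occ},
        duration_scale={b: 3.0 for b in occ},
        bout_rate_per_min={b: 1.0 for b in occ},
        p_outside={
            "patrolling": 0.4, "continuous_buzzing": 0.2, "abdominal_pumping": 0.3,
            "grooming": 0.25, "flying_climbing": 0.85, "leg_raising": 0.75,
            "perching": 0.3, "pulse_buzzing": 0.25,
        },
    )


def _place_bouts(rng, phase, durations):
    """Place bouts of the given durations uniformly in a phase without
    overlap; durations are capped if the packing is infeasible."""
    total = phase.length_s
    durations = np.asarray(durations, float)
    if durations.sum() > 0.9 * total:
        durations = durations * (0.9 * total / durations.sum())
    free = total - durations.sum()
    gaps = rng.dirichlet(np.ones(len(durations) + 1)) * free
    starts, cursor = [], phase.start_s
    for g, d in zip(gaps[:-1], durations):
        cursor += g
        starts.append(cursor)
        cursor += d
    return np.array(starts), durations


def gen_behaviour_events(
    spec: BehaviourGenSpec,
    seed,
    stimulus: str = "mechanical_disturbance",
    day: int = 1,
    trial_prefix: str = "T",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate an event table, its roster and the ground-truth record.

    One trial per colony.  Returns ``(events, roster, truth)``; the truth
    dict carries the spec parameters and the per-bee occurrence draws, and
    suffices to recompute expected pipeline outputs without re-reading the
    generated table.
    """
    rng = _rng(seed)
    events, roster, draws = [], [], []
    effects = spec.stimulus_effects.get(stimulus, {})
    for c in range(spec.n_colonies):
        colony = f"C{c + 1}"
        trial = f"{trial_prefix}{c + 1}"
        bees = [(f"{colony}-w{i + 1}", "worker") for i in range(spec.n_bees_per_colony)]
        if spec.include_queen:
            bees.append((f"{colony}-q", "queen"))
        for bee, caste in bees:
            roster.append(
                dict(trial_id=trial, colony_id=colony, bee_id=bee, caste=caste,
                     excluded=False, stimulus=stimulus, day=day)
            )
            for beh, per_phase in spec.occurrence.items():
                for ph in spec.scheme.phases:
                    p = per_phase.get(ph.label, 0.0)
                    shift = effects.get(beh, {}).get(ph.label, 1.0)
                    if shift != 1.0 and 0.0 < p < 1.0:
                        odds = p / (1.0 - p) * shift
                        p = odds / (1.0 + odds)
                    occurred = bool(rng.random() < p)
                    draws.append(
                        dict(trial_id=trial, bee_id=bee, behaviour=beh,
                             phase=ph.label, p=p, occurred=occurred)
                    )
                    if not occurred:
                        continue
                    mins = ph.length_s / 60.0
                    n_bouts = 1 + rng.poisson(spec.bout_rate_per_min.get(beh, 1.0) * mins)
                    durs = rng.gamma(
                        spec.duration_shape.get(beh, 2.0),
                        spec.duration_scale.get(beh, 3.0),
                        size=n_bouts,
                    )
                    starts, durs = _place_bouts(rng, ph, durs)
                    for s, d in zip(starts, durs):
                        loc = "outside" if rng.random() < spec.p_outside.get(beh, 0.5) else "inside"
                        events.append(
                            dict(trial_id=trial, colony_id=colony, bee_id=bee,
                                 caste=caste, behaviour=beh, start_s=float(s),
                                 stop_s=float(s + d), location=loc)
                        )
    events_df = pd.DataFrame(
        events,
        columns=["trial_id", "colony_id", "bee_id", "caste", "behaviour",
                 "start_s", "stop_s", "location"],
    )
    roster_df = pd.DataFrame(roster)
    truth = {
        "spec": spec,
        "stimulus": stimulus,
        "day": day,
        "occurrence_draws": pd.DataFrame(draws),
    }
    return events_df, roster_df, truth


def gen_coupled_behaviours(
    n_bees: int,
    marginals: Mapping[str, float],
    coupling: Mapping[tuple[str, str], float] | None,
    seed,
    phase: str = "AR",
    trial_id: str = "T1",
) -> pd.DataFrame:
    """Bee-level joint occurrence from a log-linear pairwise model.

    ``log P(x) = sum_i a_i x_i + sum_{i<j} b_ij x_i x_j - log Z`` with
    ``a_i = logit(marginal_i)`` so that zero coupling reduces exactly to
    independent Bernoulli draws at the requested marginals.  Returns a
    summary-shaped table (one row per bee per behaviour with an
    ``occurred`` flag and matching dummy durations) directly consumable by
    the association analyses.
    """
    rng = _rng(seed)
    behaviours = list(marginals)
    k = len(behaviours)
    coupling = dict(coupling or {})
    for (a, b), v in list(coupling.items()):
        if coupling.get((b, a), v) != v:
            raise ValueError("coupling matrix must be symmetric")
        coupling[(b, a)] = v
    alphas = {}
    for b, p in marginals.items():
        if not 0.0 < p < 1.0:
            raise ValueError(f"marginal for {b!r} must be in (0, 1)")
        alphas[b] = np.log(p / (1.0 - p))
    states = np.array(np.meshgrid(*[[0, 1]] * k, indexing="ij")).reshape(k, -1).T
    logw = states @ np.array([alphas[b] for b in behaviours])
    for i in range(k):
        for j in range(i + 1, k):
            beta = coupling.get((behaviours[i], behaviours[j]), 0.0)
            logw = logw + beta * states[:, i] * states[:, j]
    logw -= logw.max()
    w = np.exp(logw)
    if not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("non-normalizable coupling")
    probs = w / w.sum()
    idx = rng.choice(len(states), size=n_bees, p=probs)
    rows = []
    for bee, st in enumerate(states[idx]):
        for b, x in zip(behaviours, st):
            dur = float(rng.gamma(2.0, 3.0)) if x else 0.0
            rows.append(
                dict(trial_id=trial_id, colony_id="C1", bee_id=f"b{bee + 1}",
                     caste="worker", phase=phase, behaviour=b, occurred=bool(x),
                     n_bouts=int(x), total_duration_s=dur,
                     duration_inside_s=dur, duration_outside_s=0.0,
                     duration_per_min=dur)
            )
    return pd.DataFrame(rows)


def gen_velocity(
    n_workers: int,
    scheme: PhaseScheme,
    phase_mean_mm_s: Mapping[str, float],
    seed,
    shape: float = 4.0,
    include_queen: bool = True,
    queen_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-bee per-phase mean velocities, Gamma-distributed around the
    phase means (queens scaled by ``queen_factor``)."""
    rng = _rng(seed)
    rows = []
    bees = [(f"w{i + 1}", "worker", 1.0) for i in range(n_workers)]
    if include_queen:
        bees.append(("q", "queen", queen_factor))
    for bee, caste, fac in bees:
        for ph in scheme.phases:
            mean = phase_mean_mm_s.get(ph.label, 1.0) * fac
            rows.append(
                dict(bee_id=bee, caste=caste, phase=ph.label,
                     velocity=float(rng.gamma(shape, mean / shape)))
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# onsets and audio


def gen_onsets(
    kind: str,
    seed,
    n_onsets: int = 100,
    period_s: float = 0.5,
    jitter_sd_s: float = 0.0,
    ioi_range_s: tuple[float, float] = (0.2, 2.0),
    alternating_ratio: float = 2.0,
    base_ioi_s: float = 0.5,
    start_s: float = 0.0,
) -> np.ndarray:
    """Onset times for one synthetic sequence.

    ``isochronous``: onsets at k * period + N(0, jitter); draws that would
    produce a non-increasing onset are redrawn.  ``random``: IOIs uniform
    on ``ioi_range_s``.  ``alternating``: IOIs alternate base and
    ratio * base (exact small-integer rhythm).
    """
    rng = _rng(seed)
    if kind == "isochronous":
        if period_s <= 0 or jitter_sd_s < 0:
            raise ValueError("period must be positive and jitter non-negative")
        onsets = [start_s]
        for k in range(1, n_onsets):
            while True:
                t = start_s + k * period_s + rng.normal(0.0, jitter_sd_s)
                if t > onsets[-1]:
                    break
                if jitter_sd_s == 0:
                    raise ValueError("zero period")
            onsets.append(t)
        return np.array(onsets)
    if kind == "random":
        lo, hi = ioi_range_s
        if not 0 < lo < hi:
            raise ValueError("ioi_range_s must satisfy 0 < lo < hi")
        iois = rng.uniform(lo, hi, size=n_onsets - 1)
        return start_s + np.concatenate([[0.0], np.cumsum(iois)])
    if kind == "alternating":
        iois = np.where(
            np.arange(n_onsets - 1) % 2 == 0, base_ioi_s, alternating_ratio * base_ioi_s
        )
        return start_s + np.concatenate([[0.0], np.cumsum(iois)])
    raise ValueError(f"unknown onset process {kind!r}")


def gen_pulse_train_onsets(
    seed,
    n_onsets: int = 100,
    period_s: float = 0.5,
    jitter_frac: float = 0.05,
    train_len_range: tuple[int, int] = (15, 25),
    gap_range_s: tuple[float, float] = (2.0, 8.0),
    start_s: float = 0.0,
) -> np.ndarray:
    """Pulse-train onsets: isochronous trains separated by long pauses.

    Emulates the bout structure of pulse-buzzing recordings: series of
    evenly spaced pulses (period with Gaussian onset jitter of
    ``jitter_frac * period``) of 15-25 pulses each, separated by silent
    gaps drawn uniformly on ``gap_range_s``, until ``n_onsets`` onsets have
    been produced.  The gaps are what the pooled IOI-quantile threshold of
    the rhythm analysis removes.
    """
    rng = _rng(seed)
    onsets: list[float] = []
    t = start_s
    remaining = n_onsets
    while remaining > 0:
        k = min(int(rng.integers(train_len_range[0], train_len_range[1] + 1)), remaining)
        train = gen_onsets(
            "isochronous", rng, n_onsets=k, period_s=period_s,
            jitter_sd_s=jitter_frac * period_s, start_s=t,
        )
        onsets.extend(train)
        remaining -= k
        t = train[-1] + rng.uniform(*gap_range_s)
    return np.array(onsets)


@dataclass
class BuzzElementPlan:
    """One planned sound element of a synthetic recording."""

    onset_s: float
    duration_s: float
    sound_type: str
    fundamental_hz: float
    n_harmonics: int = 4
    rolloff: float = 0.6  # amplitude factor per successive harmonic
    level: float = 0.2  # RMS target of the element waveform


def gen_buzz_recording(
    elements: Sequence[BuzzElementPlan],
    seed,
    rate_hz: int = 22000,
    noise_level: float = 0.02,
    recording_id: str = "synth",
    total_s: float | None = None,
) -> tuple[Recording, pd.DataFrame, dict]:
    """Background Gaussian noise plus harmonic-stack elements.

    Each element is a sum of ``n_harmonics`` sinusoids at multiples of the
    fundamental with geometric ``rolloff``, scaled to RMS ``level`` and
    ramped with a 10 ms Hann fade at both edges; the expected segment SNR
    is approximately ``sqrt(level**2 + noise_level**2) / noise_level``.
    If the mix would clip, amplitudes are rescaled with a warning.
    Returns the recording, its annotation table and a ground-truth dict.
    """
    import warnings as _warnings

    rng = _rng(seed)
    if total_s is None:
        total_s = max(e.onset_s + e.duration_s for e in elements) + 1.0
    n = int(round(total_s * rate_hz))
    x = rng.normal(0.0, noise_level, size=n)
    ann = []
    for e in elements:
        i = int(round(e.onset_s * rate_hz))
        m = int(round(e.duration_s * rate_hz))
        if e.fundamental_hz * e.n_harmonics > rate_hz / 2:
            raise ValueError("harmonic stack exceeds the Nyquist frequency")
        t = np.arange(m) / rate_hz
        amps = e.rolloff ** np.arange(e.n_harmonics)
        wave = np.zeros(m)
        for h, a in enumerate(amps, start=1):
            wave += a * np.sin(2 * np.pi * e.fundamental_hz * h * t)
        wave *= e.level / np.sqrt(np.mean(wave**2))
        ramp = min(int(0.01 * rate_hz), m // 4)
        if ramp > 0:
            env = np.ones(m)
            fade = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[:ramp] = fade
            env[-ramp:] = fade[::-1]
            wave *= env
        x[i: i + m] += wave[: max(0, n - i)]
        ann.append(
            dict(recording_id=recording_id, onset_s=e.onset_s,
                 offset_s=e.onset_s + e.duration_s, sound_type=e.sound_type)
        )
    peak = np.abs(x).max()
    if peak > 1.0:
        _warnings.warn("synthetic mix would clip; amplitudes rescaled", stacklevel=2)
        x /= peak * 1.01
    rec = Recording(x, rate_hz, recording_id)
    truth = {
        "elements": list(elements),
        "noise_level": noise_level,
        "rate_hz": rate_hz,
        "expected_snr": [
            float(np.sqrt(e.level**2 + noise_level**2) / noise_level) for e in elements
        ],
    }
    return rec, pd.DataFrame(ann), truth


def gen_type_recordings(
    type_specs: Mapping[str, dict],
    n_per_type: int,
    seed,
    rate_hz: int = 22000,
    noise_level: float = 0.02,
) -> tuple[dict[str, Recording], pd.DataFrame]:
    """One recording per sound type with ``n_per_type`` elements each.

    ``type_specs[sound_type]`` may set fundamental_hz, duration_s, level,
    n_harmonics, rolloff and the onset process parameters (kind, period_s,
    jitter_sd_s, ioi_range_s).  Convenience wrapper used by the classifier
    and rhythm test benches.
    """
    rng = _rng(seed)
    recordings: dict[str, Recording] = {}
    anns = []
    for st, cfg in type_specs.items():
        dur = cfg.get("duration_s", 0.15)
        kind = cfg.get("kind", "random")
        onsets = gen_onsets(
            kind,
            rng,
            n_onsets=n_per_type,
            period_s=cfg.get("period_s", 0.5),
            jitter_sd_s=cfg.get("jitter_sd_s", 0.0),
            ioi_range_s=cfg.get("ioi_range_s", (0.3, 2.0)),
        )
        onsets = onsets + 0.5  # room for the leading flank
        f0 = cfg.get("fundamental_hz", 200.0)
        jitter_f = cfg.get("f0_jitter_hz", 0.0)
        elements = [
            BuzzElementPlan(
                onset_s=float(t),
                duration_s=dur,
                sound_type=st,
                fundamental_hz=f0 + (rng.uniform(-jitter_f, jitter_f) if jitter_f else 0.0),
                n_harmonics=cfg.get("n_harmonics", 4),
                rolloff=cfg.get("rolloff", 0.6),
                level=cfg.get("level", 0.2),
            )
            for t in onsets
        ]
        rec, ann, _ = gen_buzz_recording(
            elements, rng, rate_hz=rate_hz, noise_level=noise_level,
            recording_id=f"rec_{st}",
        )
        recordings[rec.recording_id] = rec
        anns.append(ann)
    return recordings, pd.concat(anns, ignore_index=True)
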