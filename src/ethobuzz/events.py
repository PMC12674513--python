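"""Behavioural event tables — the shared data model for colony-defence trials.

A trial observes every bee of a (micro)colony around a disturbance applied at
time 0 s.  Each scored bout of one of the nine ethogram behaviours is a row:
who (trial, colony, bee, caste), what (behaviour), when (start/stop seconds,
negative before the disturbance) and where (inside or outside the brood area).
Times are half-open intervals ``[start_s, stop_s)`` so every instant belongs
to exactly one phase when the trial is cut into named phases.

The module reads/writes BORIS-export-like CSV tables through a configurable
:class:`Dialect`, validates them row by row, and clips bouts to a
:class:`PhaseScheme` so durations can be attributed to phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: The nine ethogram behaviours (canonical labels).
BEHAVIOURS = (
    "abdominal_pumping",
    "continuous_buzzing",
    "fanning",
    "flying_climbing",
    "grooming",
    "leg_raising",
    "patrolling",
    "perching",
    "pulse_buzzing",
)

#: Behaviours included in analyses by default.  "fanning" is parsed and stored
#: but excluded because it was scored too rarely to analyse; pass
#: ``behaviours=BEHAVIOURS`` to re-include it.
DEFAULT_ANALYSIS_BEHAVIOURS = tuple(b for b in BEHAVIOURS if b != "fanning")

CASTES = ("worker", "queen")
LOCATIONS = ("inside", "outside", "unknown")
STIMULI = ("mechanical_disturbance", "intruder_breath", "foreign_object", "none")

#: Canonical column order of a normalised event table.
EVENT_COLUMNS = (
    "trial_id",
    "colony_id",
    "bee_id",
    "caste",
    "behaviour",
    "start_s",
    "stop_s",
    "location",
)


class EventTableError(ValueError):
    """A structural problem with an event table (e.g. a missing column)."""


class EventValidationError(EventTableError):
    """Row-level validation failures; ``diagnostics`` lists (row, message)."""

    def __init__(self, diagnostics: Sequence[tuple[int, str]]):
        self.diagnostics = list(diagnostics)
        lines = "; ".join(f"row {i}: {m}" for i, m in self.diagnostics[:10])
        more = "" if len(self.diagnostics) <= 10 else f" (+{len(self.diagnostics) - 10} more)"
        super().__init__(f"{len(self.diagnostics)} invalid event row(s): {lines}{more}")


def _canon_label(label: str) -> str:
    """Normalise a free-text behaviour/caste/location label."""
    return "_".join(str(label).strip().lower().replace("-", " ").replace("_", " ").split())


@dataclass(frozen=True)
class Dialect:
    """Column/label mapping for one CSV export flavour.

    ``columns`` maps canonical names to source column names; ``extra_columns``
    are passed through unchanged (trial metadata such as stimulus/day/test).
    Label maps are applied after whitespace/case normalisation.
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in EVENT_COLUMNS}
    )
    behaviour_labels: Mapping[str, str] = field(default_factory=dict)
    caste_labels: Mapping[str, str] = field(default_factory=dict)
    location_labels: Mapping[str, str] = field(default_factory=dict)
    extra_columns: tuple[str, ...] = ()

    @classmethod
    def from_config(cls, path: str) -> "Dialect":
        """Load a dialect from a YAML/JSON config file."""
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            columns={**{c: c for c in EVENT_COLUMNS}, **cfg.get("columns", {})},
            behaviour_labels=cfg.get("behaviour_labels", {}),
            caste_labels=cfg.get("caste_labels", {}),
            location_labels=cfg.get("location_labels", {}),
            extra_columns=tuple(cfg.get("extra_columns", ())),
        )


DEFAULT_DIALECT = Dialect()


@dataclass(frozen=True)
class Phase:
    """One named, half-open phase ``[start_s, end_s)`` of a trial."""

    label: str
    start_s: float
    end_s: float

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseScheme:
    """An ordered, contiguous partition of the observation window into phases.

    Phases are disjoint half-open intervals whose union is the whole window
    ``[-pre_s, post_s)``; every time point maps to exactly one phase.
    """

    phases: tuple[Phase, ...]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("a PhaseScheme needs at least one phase")
        for ph in self.phases:
            if not ph.end_s > ph.start_s:
                raise ValueError(f"phase {ph.label!r} has non-positive length")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start_s != a.end_s:
                raise ValueError(
                    f"phases {a.label!r} and {b.label!r} are not contiguous"
                )
        if len({ph.label for ph in self.phases}) != len(self.phases):
            raise ValueError("phase labels must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(ph.label for ph in self.phases)

    @property
    def window(self) -> tuple[float, float]:
        return (self.phases[0].start_s, self.phases[-1].end_s)

    @property
    def total_s(self) -> float:
        return self.window[1] - self.window[0]

    def length_s(self, label: str) -> float:
        return self[label].length_s

    def __getitem__(self, label: str) -> Phase:
        for ph in self.phases:
            if ph.label == label:
                return ph
        raise KeyError(label)

    def phase_of(self, t_s: float) -> str | None:
        """Phase label containing time ``t_s``, or None outside the window."""
        for ph in self.phases:
            if ph.start_s <= t_s < ph.end_s:
                return ph.label
        return None


def default_phase_scheme(part: str) -> PhaseScheme:
    """Default phase schemes for the two experiment designs.

    ``part1`` is the 10-minute whole-colony design: before disturbance
    BD [-120, 0), acute response AR [0, 60), delayed response DR [60, 240)
    and recovery R [240, 480).  ``part2`` is the 3-minute microcolony design:
    BD [-60, 0), AD1 [0, 60), AD2 [60, 120).
    """
    if part == "part1":
        return PhaseScheme(
            (
                Phase("BD", -120.0, 0.0),
                Phase("AR", 0.0, 60.0),
                Phase("DR", 60.0, 240.0),
                Phase("R", 240.0, 480.0),
            )
        )
    if part == "part2":
        return PhaseScheme(
            (
                Phase("BD", -60.0, 0.0),
                Phase("AD1", 0.0, 60.0),
                Phase("AD2", 60.0, 120.0),
            )
        )
    raise ValueError(f"unknown part {part!r}; expected 'part1' or 'part2'")


@dataclass(frozen=True)
class TrialDesign:
    """Stimulus and observation-window metadata for one trial."""

    stimulus: str = "mechanical_disturbance"
    day: int = 1
    pre_s: float = 120.0
    post_s: float = 480.0

    def __post_init__(self):
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}; one of {STIMULI}")
        if not (self.pre_s > 0 and self.post_s > 0):
            raise ValueError("pre_s and post_s must be positive")


def _map_label(raw: str, overrides: Mapping[str, str], allowed: tuple[str, ...]):
    canon = _canon_label(raw)
    canon = _canon_label(overrides.get(raw, overrides.get(canon, canon)))
    return canon if canon in allowed else None


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical event table; raise :class:`EventValidationError`.

    Checks: stop_s > start_s, known behaviour/caste/location labels, and that
    bouts of one (trial, bee, behaviour) do not overlap in time.  Returns the
    input (sorted by trial, bee, behaviour, start) on success.
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"missing required column(s): {', '.join(missing)}")
    diags: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        if not np.isfinite(row["start_s"]) or not np.isfinite(row["stop_s"]):
            diags.append((idx, "non-numeric start/stop time"))
            continue
        if not row["stop_s"] > row["start_s"]:
            diags.append(
                (idx, f"stop_s ({row['stop_s']}) must exceed start_s ({row['start_s']})")
            )
        if row["behaviour"] not in BEHAVIOURS:
            diags.append(
                (
                    idx,
                    f"unknown behaviour {row['behaviour']!r}; accepted labels: "
                    + ", ".join(BEHAVIOURS),
                )
            )
        if row["caste"] not in CASTES:
            diags.append((idx, f"unknown caste {row['caste']!r}; accepted: {CASTES}"))
        if row["location"] not in LOCATIONS:
            diags.append(
                (idx, f"unknown location {row['location']!r}; accepted: {LOCATIONS}")
            )
    if diags:
        raise EventValidationError(diags)
    out = df.sort_values(["trial_id", "bee_id", "behaviour", "start_s"], kind="stable")
    # within one (trial, bee, behaviour) bouts must not overlap
    for (trial, bee, beh), grp in out.groupby(["trial_id", "bee_id", "behaviour"]):
        starts = grp["start_s"].to_numpy()
        stops = grp["stop_s"].to_numpy()
        bad = np.nonzero(starts[1:] < stops[:-1])[0]
        if bad.size:
            diags.append(
                (
                    grp.index[bad[0] + 1],
                    f"overlapping bouts of {beh!r} for bee {bee!r} in trial {trial!r}",
                )
            )
    if diags:
        raise EventValidationError(diags)
    return out.reset_index(drop=True)


def read_events(path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read and validate an event CSV, returning a canonical event table.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    dialect : Dialect, optional
        Column/label mapping; defaults to canonical column names.

    Raises
    ------
    EventTableError
        If a mapped column is missing.
    EventValidationError
        With row-level diagnostics for degenerate bouts or unknown labels.
    """
    dialect = dialect or DEFAULT_DIALECT
    raw = pd.read_csv(path)
    cols = {}
    for canon in EVENT_COLUMNS:
        src = dialect.columns.get(canon, canon)
        if src not in raw.columns:
            raise EventTableError(f"missing required column: {src!r} (for {canon!r})")
        cols[canon] = raw[src]
    df = pd.DataFrame(cols)
    for extra in dialect.extra_columns:
        if extra in raw.columns:
            df[extra] = raw[extra]
    df["start_s"] = pd.to_numeric(df["start_s"], errors="coerce")
    df["stop_s"] = pd.to_numeric(df["stop_s"], errors="coerce")
    diags: list[tuple[int, str]] = []
    for col, overrides, allowed in (
        ("behaviour", dialect.behaviour_labels, BEHAVIOURS),
        ("caste", dialect.caste_labels, CASTES),
        ("location", dialect.location_labels, LOCATIONS),
    ):
        mapped = []
        for idx, raw_label in df[col].items():
            m = _map_label(raw_label, overrides, allowed)
            if m is None:
                diags.append(
                    (
                        idx,
                        f"unknown {col} label {raw_label!r}; accepted labels: "
                        + ", ".join(allowed),
                    )
                )
                mapped.append(str(raw_label))
            else:
                mapped.append(m)
        df[col] = mapped
    if diags:
        raise EventValidationError(diags)
    return validate_events(df)


def write_events(df: pd.DataFrame, path) -> None:
    """Write a canonical event table as CSV (canonical columns first)."""
    extras = [c for c in df.columns if c not in EVENT_COLUMNS]
    df[list(EVENT_COLUMNS) + extras].to_csv(path, index=False)


def clip_events_to_phases(events: pd.DataFrame, scheme: PhaseScheme) -> pd.DataFrame:
    """Split each bout at phase boundaries and attribute fragments to phases.

    Returns one row per (event, phase) overlap with ``start_s``/``stop_s``
    replaced by the fragment bounds plus ``phase`` and ``duration_s`` columns
    and an ``event_index`` pointing back to the source row.  Fragment
    durations sum to the original bout duration, up to any part of the bout
    outside the observation window (truncated with a warning).
    """
    lo, hi = scheme.window
    outside = (events["stop_s"] <= lo) | (events["start_s"] >= hi)
    clipped_any = outside.any() or (
        (events["start_s"] < lo) | (events["stop_s"] > hi)
    ).any()
    if clipped_any:
        warnings.warn(
            "some events extend outside the observation window and were truncated",
            stacklevel=2,
        )
    pieces = []
    for ph in scheme.phases:
        s = events["start_s"].clip(lower=ph.start_s)
        e = events["stop_s"].clip(upper=ph.end_s)
        keep = e > s
        if not keep.any():
            continue
        frag = events.loc[keep].copy()
        frag["start_s"] = s[keep]
        frag["stop_s"] = e[keep]
        frag["phase"] = ph.label
        frag["duration_s"] = frag["stop_s"] - frag["start_s"]
        frag["event_index"] = frag.index
        pieces.append(frag)
    if not pieces:
        out = events.iloc[0:0].copy()
        out["phase"] = pd.Series(dtype=str)
        out["duration_s"] = pd.Series(dtype=float)
        out["event_index"] = pd.Series(dtype=int)
        return out
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# velocity tracks

VELOCITY_COLUMNS = ("bee_id", "caste", "time_s", "velocity_mm_s")


def read_velocity(path) -> pd.DataFrame:
    """Read a velocity table (bee_id, caste, time_s, velocity_mm_s)."""
    df = pd.read_csv(path)
    missing = [c for c in VELOCITY_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"missing required column(s): {', '.join(missing)}")
    if (df["velocity_mm_s"] < 0).any():
        raise EventValidationError(
            [(int(i), "negative velocity") for i in df.index[df["velocity_mm_s"] < 0]]
        )
    for bee, grp in df.groupby("bee_id"):
        t = grp["time_s"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise EventValidationError(
                [(int(grp.index[0]), f"times not strictly increasing for bee {bee!r}")]
            )
    return df


def bin_velocity(velocity: pd.DataFrame, scheme: PhaseScheme) -> pd.DataFrame:
    """Mean velocity per bee per phase (samples outside the window dropped)."""
    df = velocity.copy()
    df["phase"] = [scheme.phase_of(t) for t in df["time_s"]]
    df = df.dropna(subset=["phase"])
    out = (
        df.groupby(["bee_id", "caste", "phase"], as_index=False)["velocity_mm_s"]
        .mean()
        .rename(columns={"velocity_mm_s": "velocity"})
    )
    return out
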