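"""Per-phase behaviour metrics and phase-effect models.

Builds the bee x phase x behaviour summary table (occurrence, bout counts,
durations, per-location durations), participation rates split by caste,
inside/outside location-preference t-tests, marginal regression models for
phase effects on occurrence (binomial), duration and velocity (Gamma,
log link), and Fisher exact tests for the rare leg-raising behaviour.

The phase-effect models are marginal GEE fits with an exchangeable working
correlation within the grouping unit (the bee), standing in for the
random-intercept mixed models of the original analysis contract; candidate
fixed effects (day, caste) are retained by backward elimination on QIC, and
all pairwise phase contrasts are Wald tests on the fitted coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .events import DEFAULT_ANALYSIS_BEHAVIOURS, PhaseScheme, clip_events_to_phases

ROSTER_COLUMNS = ("trial_id", "colony_id", "bee_id", "caste")


class UnknownSubjectError(ValueError):
    """An event references a bee that is not on the trial roster."""


def summarize(
    events: pd.DataFrame,
    scheme: PhaseScheme,
    roster: pd.DataFrame,
    behaviours: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Summarise events into one row per (bee, phase, behaviour).

    Parameters
    ----------
    events : DataFrame
        Validated canonical event table.
    scheme : PhaseScheme
        Phase partition of the observation window.
    roster : DataFrame
        One row per (trial_id, bee_id) with colony_id and caste; an optional
        boolean ``excluded`` column drops bees that could not be followed
        (they disappear from all denominators).  Extra columns (stimulus,
        day, test, ...) are carried through to the summary rows.
    behaviours : tuple of str, optional
        Behaviour set to summarise; defaults to the eight analysis
        behaviours (fanning excluded).

    Returns
    -------
    DataFrame
        Columns: roster keys and metadata, phase, behaviour, occurred,
        n_bouts, total_duration_s, duration_inside_s, duration_outside_s,
        duration_per_min.  Rows with occurred=False are present for every
        roster bee.
    """
    behaviours = tuple(behaviours or DEFAULT_ANALYSIS_BEHAVIOURS)
    roster = roster.copy()
    if "excluded" in roster.columns:
        roster = roster[~roster["excluded"].astype(bool)].drop(columns=["excluded"])
    roster_keys = set(zip(roster["trial_id"], roster["bee_id"]))
    ev_keys = set(zip(events["trial_id"], events["bee_id"]))
    unknown = ev_keys - roster_keys
    if unknown:
        raise UnknownSubjectError(
            f"events reference bees not on the roster: {sorted(unknown)[:5]}"
        )

    ev = events[events["behaviour"].isin(behaviours)]
    clipped = clip_events_to_phases(ev, scheme)
    if len(clipped):
        clipped = clipped.assign(
            dur_in=np.where(clipped["location"] == "inside", clipped["duration_s"], 0.0),
            dur_out=np.where(clipped["location"] == "outside", clipped["duration_s"], 0.0),
        )
        agg = (
            clipped.groupby(["trial_id", "bee_id", "phase", "behaviour"])
            .agg(
                n_bouts=("duration_s", "size"),
                total_duration_s=("duration_s", "sum"),
                duration_inside_s=("dur_in", "sum"),
                duration_outside_s=("dur_out", "sum"),
            )
            .reset_index()
        )
    else:
        agg = pd.DataFrame(
            columns=[
                "trial_id",
                "bee_id",
                "phase",
                "behaviour",
                "n_bouts",
                "total_duration_s",
                "duration_inside_s",
                "duration_outside_s",
            ]
        )

    full = roster.merge(pd.DataFrame({"phase": list(scheme.labels)}), how="cross").merge(
        pd.DataFrame({"behaviour": list(behaviours)}), how="cross"
    )
    out = full.merge(agg, on=["trial_id", "bee_id", "phase", "behaviour"], how="left")
    for c in ("n_bouts", "total_duration_s", "duration_inside_s", "duration_outside_s"):
        out[c] = out[c].fillna(0.0)
    out["n_bouts"] = out["n_bouts"].astype(int)
    out["occurred"] = out["total_duration_s"] > 0
    phase_len = out["phase"].map({l: scheme.length_s(l) for l in scheme.labels})
    out["duration_per_min"] = out["total_duration_s"] * 60.0 / phase_len
    return out


@dataclass(frozen=True)
class ParticipationRate:
    """Worker participation proportion and queen trial counts."""

    behaviour: str
    phases: tuple[str, ...]
    worker_performed: int
    worker_total: int
    queen_trials_performed: int
    queen_trials_total: int

    @property
    def worker_proportion(self) -> float:
        if self.worker_total == 0:
            raise ValueError("empty worker roster")
        return self.worker_performed / self.worker_total


def participation_rate(
    summaries: pd.DataFrame,
    behaviour: str,
    phases: tuple[str, ...] | None = None,
) -> ParticipationRate:
    """Proportion of bees performing ``behaviour`` in any of ``phases``.

    Workers are counted per (trial, bee); queens are reported as
    trials-with-occurrence out of trials with a queen.  ``phases`` defaults
    to all post-disturbance phases (every phase after the first).
    """
    all_phases = list(dict.fromkeys(summaries["phase"]))
    phases = tuple(phases or all_phases[1:])
    sub = summaries[(summaries["behaviour"] == behaviour) & summaries["phase"].isin(phases)]
    if sub.empty:
        raise ValueError(f"no summary rows for {behaviour!r} in phases {phases}")
    per_bee = sub.groupby(["trial_id", "bee_id", "caste"])["occurred"].any().reset_index()
    workers = per_bee[per_bee["caste"] == "worker"]
    if workers.empty:
        raise ValueError("empty worker roster")
    queens = per_bee[per_bee["caste"] == "queen"]
    q_trials = queens.groupby("trial_id")["occurred"].any()
    return ParticipationRate(
        behaviour=behaviour,
        phases=phases,
        worker_performed=int(workers["occurred"].sum()),
        worker_total=len(workers),
        queen_trials_performed=int(q_trials.sum()),
        queen_trials_total=len(q_trials),
    )


@dataclass(frozen=True)
class LocationTest:
    """One-sample t-test of outside-minus-inside duration differences."""

    behaviour: str
    phase: str
    n: int
    mean_d_s: float
    t: float
    p: float
    testable: bool
    note: str = ""


def location_preference_test(
    summaries: pd.DataFrame, behaviour: str, phase: str
) -> LocationTest:
    """Test whether a behaviour is performed mainly inside or outside.

    For each bee that performed the behaviour in the phase, d_s =
    duration_outside_s - duration_inside_s (unknown-location time is
    excluded, not imputed).  A one-sample t-test of d against 0 is run;
    positive mean means an outside preference.  With fewer than two
    performers, or zero variance, the result is flagged untestable.
    """
    sub = summaries[
        (summaries["behaviour"] == behaviour)
        & (summaries["phase"] == phase)
        & (summaries["total_duration_s"] > 0)
    ]
    d = (sub["duration_outside_s"] - sub["duration_inside_s"]).to_numpy(float)
    n = len(d)
    if n < 2:
        return LocationTest(behaviour, phase, n, float(d.mean()) if n else np.nan,
                            np.nan, np.nan, False, "fewer than 2 performing bees")
    if np.allclose(d, d[0]):
        return LocationTest(behaviour, phase, n, float(d.mean()), np.nan, np.nan,
                            False, "zero variance (constant differences)")
    t, p = stats.ttest_1samp(d, 0.0)
    return LocationTest(behaviour, phase, n, float(d.mean()), float(t), float(p), True)


def leg_raising_exact_tests(
    summaries: pd.DataFrame, behaviour: str = "leg_raising"
) -> pd.DataFrame:
    """Pairwise Fisher exact tests of occurrence between phases.

    For every phase pair, the 2x2 table (performed / not performed in each
    phase) is tested with a two-sided Fisher exact test; p-values are
    Bonferroni-adjusted (multiplied by the number of pairs, capped at 1).
    Phases with an empty roster are skipped and reported with a note.
    """
    sub = summaries[summaries["behaviour"] == behaviour]
    counts = sub.groupby("phase", sort=False).agg(
        performed=("occurred", "sum"), total=("occurred", "size")
    )
    phases = [p for p in counts.index if counts.loc[p, "total"] > 0]
    skipped = [p for p in counts.index if counts.loc[p, "total"] == 0]
    pairs = [(a, b) for i, a in enumerate(phases) for b in phases[i + 1 :]]
    rows = []
    m = len(pairs)
    for a, b in pairs:
        ka, na = int(counts.loc[a, "performed"]), int(counts.loc[a, "total"])
        kb, nb = int(counts.loc[b, "performed"]), int(counts.loc[b, "total"])
        odds, p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]])
        rows.append(
            dict(
                phase_a=a,
                phase_b=b,
                performed_a=ka,
                total_a=na,
                performed_b=kb,
                total_b=nb,
                odds_ratio=odds,
                p_raw=p,
                p_bonferroni=min(1.0, m * p),
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["skipped_phases"] = skipped
    out.attrs["n_comparisons"] = m
    return out


# ---------------------------------------------------------------------------
# phase-effect models


@dataclass
class PhaseEffectResult:
    """Fitted phase-effect model: coefficients and pairwise phase contrasts.

    ``contrasts`` holds one row per unordered phase pair with the Wald
    estimate (difference on the linear-predictor scale), its SE, z, p and a
    significance flag at ``alpha``; inestimable contrasts (e.g. a phase with
    all-zero occurrence) are flagged via ``estimable=False``.
    """

    response: str
    family: str
    formula: str
    n_obs: int
    group_col: str
    coefficients: pd.DataFrame
    contrasts: pd.DataFrame
    retained_terms: tuple[str, ...]
    dropped_terms: tuple[str, ...]
    converged: bool
    fallback: str | None = None
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"Phase-effect model ({self.response}, {self.family})",
            f"  formula: {self.formula}   n = {self.n_obs}, groups = {self.group_col}",
            f"  retained: {', '.join(self.retained_terms)}"
            + (f"; dropped: {', '.join(self.dropped_terms)}" if self.dropped_terms else ""),
        ]
        if self.fallback:
            lines.append(f"  note: fitted with fallback '{self.fallback}'")
        lines.append(self.coefficients.to_string(index=False))
        lines.append("Pairwise phase contrasts:")
        lines.append(self.contrasts.to_string(index=False))
        return "\n".join(lines)


def _fit_gee(formula, data, family, group_col):
    """Fit with the documented retry chain: exchangeable GEE, then
    independence GEE, then a plain GLM.  Returns (results, fallback_tag)."""
    attempts = [
        ("exchangeable", lambda: smf.gee(
            formula, groups=group_col, data=data, family=family,
            cov_struct=sm.cov_struct.Exchangeable()).fit(maxiter=100)),
        ("independence", lambda: smf.gee(
            formula, groups=group_col, data=data, family=family,
            cov_struct=sm.cov_struct.Independence()).fit(maxiter=100)),
        ("glm", lambda: smf.glm(formula, data=data, family=family).fit()),
    ]
    last_err = None
    for tag, fit in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit()
            if np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)):
                return res, (None if tag == "exchangeable" else tag)
        except Exception as err:  # noqa: BLE001 - any numerical failure triggers retry
            last_err = err
    raise RuntimeError(f"all model fits failed: {last_err}")


def _qic(res) -> float:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = res.qic()
        return float(q[0]) if isinstance(q, tuple) else float(q)
    except Exception:  # GLM fallback: use AIC
        try:
            return float(res.aic)
        except Exception:
            return np.inf


def phase_effect_model(
    data: pd.DataFrame,
    response: str = "occurrence",
    behaviour: str | None = None,
    group_col: str = "bee_id",
    candidate_fixed: tuple[str, ...] = (),
    always_fixed: tuple[str, ...] = (),
    alpha: float = 0.05,
    phase_order: tuple[str, ...] | None = None,
) -> PhaseEffectResult:
    """Fit the phase-effect regression for occurrence, duration or velocity.

    ``response`` selects the column and family: ``occurrence`` models the
    per-bee occurrence flag with a binomial family; ``duration`` models
    duration_per_min with a Gamma/log family on bees that performed the
    behaviour (occurred rows only); ``velocity`` models a ``velocity``
    column with Gamma/log.  ``candidate_fixed`` terms (e.g. day, caste) are
    kept only if they lower QIC under backward elimination; phase and
    ``always_fixed`` terms are always retained.
    """
    df = data.copy()
    if behaviour is not None:
        df = df[df["behaviour"] == behaviour]
    if response == "occurrence":
        df["_y"] = df["occurred"].astype(int)
        family = sm.families.Binomial()
        fam_name = "binomial"
    elif response == "duration":
        df = df[df["occurred"]]
        df["_y"] = df["duration_per_min"].astype(float)
        family = sm.families.Gamma(link=sm.families.links.Log())
        fam_name = "gamma_log"
    elif response == "velocity":
        df["_y"] = df["velocity"].astype(float)
        if (df["_y"] <= 0).any():
            # Gamma support is strictly positive; zero velocities are nudged to
            # half the smallest positive value and the handling is recorded.
            floor = df.loc[df["_y"] > 0, "_y"].min() / 2.0
            df.loc[df["_y"] <= 0, "_y"] = floor
        family = sm.families.Gamma(link=sm.families.links.Log())
        fam_name = "gamma_log"
    else:
        raise ValueError(f"unknown response {response!r}")
    if df.empty:
        raise ValueError("no rows to fit (after occurred-filtering?)")

    order = list(phase_order or dict.fromkeys(df["phase"]))
    order = [p for p in order if p in set(df["phase"])]
    df["phase"] = pd.Categorical(df["phase"], categories=order)

    base_terms = ["C(phase)"] + [t for t in always_fixed if df[t].nunique() > 1]
    candidates = [t for t in candidate_fixed if t in df.columns and df[t].nunique() > 1]

    def formula_for(terms):
        return "_y ~ " + " + ".join(terms)

    terms = base_terms + candidates
    res, fallback = _fit_gee(formula_for(terms), df, family, group_col)
    # backward elimination on the candidates only
    improved = True
    while improved and any(t in terms for t in candidates):
        improved = False
        best_q = _qic(res)
        for t in [t for t in terms if t in candidates]:
            trial_terms = [x for x in terms if x != t]
            try:
                trial_res, trial_fb = _fit_gee(formula_for(trial_terms), df, family, group_col)
            except RuntimeError:
                continue
            q = _qic(trial_res)
            if q < best_q:
                res, fallback, terms, best_q = trial_res, trial_fb, trial_terms, q
                improved = True
                break

    coef = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "p": res.pvalues.to_numpy(),
        }
    )

    # all pairwise phase contrasts (Wald)
    names = list(res.params.index)
    col_of = {p: names.index(f"C(phase)[T.{p}]") for p in order[1:] if f"C(phase)[T.{p}]" in names}
    rows = []
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            L = np.zeros(len(names))
            if a in col_of:
                L[col_of[a]] += 1.0
            if b in col_of:
                L[col_of[b]] -= 1.0
            tt = res.t_test(L)
            est = float(np.squeeze(tt.effect))
            se = float(np.squeeze(tt.sd))
            p = float(np.squeeze(tt.pvalue))
            estimable = bool(np.isfinite(est) and np.isfinite(se) and se < 100.0)
            rows.append(
                dict(
                    phase_a=a,
                    phase_b=b,
                    estimate=est,
                    se=se,
                    z=est / se if se > 0 else np.nan,
                    p=p,
                    significant=bool(estimable and p < alpha),
                    estimable=estimable,
                )
            )
    contrasts = pd.DataFrame(rows)
    return PhaseEffectResult(
        response=response,
        family=fam_name,
        formula=formula_for(terms),
        n_obs=len(df),
        group_col=group_col,
        coefficients=coef,
        contrasts=contrasts,
        retained_terms=tuple(terms),
        dropped_terms=tuple(t for t in candidates if t not in terms),
        converged=bool(getattr(res, "converged", True)),
        fallback=fallback,
        alpha=alpha,
    )
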