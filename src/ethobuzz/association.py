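"""Within-bee behaviour associations.

Quantifies how behaviours combine in individual bees: conditional
co-occurrence within a phase (P(X|Y) vs P(X), chi-square on the bee-level
2x2 table), carry-over across phases (Y in an earlier phase, X in a later
one), Spearman correlations between time investments, and the behavioural
"suite" analysis that compares observed counts of behaviour combinations
against the expectation under independence.

A bee "performed" a behaviour in a phase when its occurrence flag is set
(any positive duration); bout counts play no role here.  No multiple-testing
correction is applied across the co-occurrence matrix.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .events import DEFAULT_ANALYSIS_BEHAVIOURS


def _flags(summaries: pd.DataFrame, phase: str, behaviours) -> pd.DataFrame:
    """Bee-level occurrence flags: index (trial_id, bee_id), one bool column
    per behaviour."""
    sub = summaries[(summaries["phase"] == phase) & summaries["behaviour"].isin(behaviours)]
    tbl = sub.pivot_table(
        index=["trial_id", "bee_id"],
        columns="behaviour",
        values="occurred",
        aggfunc="any",
        fill_value=False,
    )
    return tbl.reindex(columns=list(behaviours), fill_value=False).astype(bool)


def _cooccurrence_cells(
    fx: pd.DataFrame, fy: pd.DataFrame, phase_x: str, phase_y: str,
    alpha: float, correction: bool,
) -> pd.DataFrame:
    idx = fx.index.intersection(fy.index)
    fx, fy = fx.loc[idx], fy.loc[idx]
    n = len(idx)
    rows = []
    for y in fy.columns:
        for x in fx.columns:
            if x == y and phase_x == phase_y:
                continue
            cell = dict(behaviour_x=x, behaviour_y=y, phase_x=phase_x, phase_y=phase_y, n=n)
            if n == 0:
                rows.append({**cell, "excluded": True, "reason": "no bees"})
                continue
            xv, yv = fx[x].to_numpy(), fy[y].to_numpy()
            n_y = int(yv.sum())
            p_x = float(xv.mean())
            p_y = float(yv.mean())
            if n_y == 0 or xv.sum() == 0:
                rows.append({**cell, "p_x": p_x, "p_y": p_y, "excluded": True,
                             "reason": "behaviour not performed at all"})
                continue
            p_joint = float((xv & yv).mean())
            p_x_given_y = p_joint * n / n_y
            if p_x in (0.0, 1.0) or p_y in (0.0, 1.0):
                # degenerate marginal: no contingency to test
                rows.append({**cell, "p_x": p_x, "p_y": p_y, "p_joint": p_joint,
                             "p_x_given_y": p_x_given_y, "chi2": 0.0, "p_value": 1.0,
                             "significant": False, "excluded": False,
                             "reason": "degenerate marginal"})
                continue
            table = np.array(
                [
                    [(xv & yv).sum(), (xv & ~yv).sum()],
                    [(~xv & yv).sum(), (~xv & ~yv).sum()],
                ]
            )
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
            rows.append({**cell, "p_x": p_x, "p_y": p_y, "p_joint": p_joint,
                         "p_x_given_y": p_x_given_y, "chi2": float(chi2),
                         "p_value": float(p), "significant": bool(p < alpha),
                         "excluded": False, "reason": ""})
    return pd.DataFrame(rows)


def cooccurrence_within(
    summaries: pd.DataFrame,
    phase: str,
    behaviours: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Conditional co-occurrence of behaviour pairs within one phase.

    For every ordered pair (x, y), x != y, reports P(X), P(Y), the joint,
    P(X|Y) and a chi-square test (no continuity correction by default) of
    x-occurrence split by y-occurrence.  Cells where either behaviour was
    not performed at all are excluded with a reason.
    """
    behaviours = tuple(behaviours or DEFAULT_ANALYSIS_BEHAVIOURS)
    f = _flags(summaries, phase, behaviours)
    return _cooccurrence_cells(f, f, phase, phase, alpha, correction)


def cooccurrence_cross(
    summaries: pd.DataFrame,
    phase_from: str,
    phase_to: str,
    behaviours: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Carry-over co-occurrence: Y in ``phase_from``, X in ``phase_to``."""
    behaviours = tuple(behaviours or DEFAULT_ANALYSIS_BEHAVIOURS)
    fy = _flags(summaries, phase_from, behaviours)
    fx = _flags(summaries, phase_to, behaviours)
    return _cooccurrence_cells(fx, fy, phase_to, phase_from, alpha, correction)


def duration_correlation(
    summaries: pd.DataFrame,
    phase_x: str,
    phase_y: str | None = None,
    behaviours: tuple[str, ...] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlation between time investments in two behaviours.

    Within one phase (``phase_y`` omitted) unordered pairs x < y are tested;
    across phases all ordered pairs are tested, x measured in ``phase_x``
    and y in ``phase_y``.  Only bees with positive duration of both
    behaviours enter; cells with fewer than ``min_n`` such bees, or with
    constant durations, are excluded/flagged.
    """
    behaviours = tuple(behaviours or DEFAULT_ANALYSIS_BEHAVIOURS)
    cross = phase_y is not None and phase_y != phase_x
    phase_y = phase_y or phase_x

    def durations(phase):
        sub = summaries[
            (summaries["phase"] == phase) & summaries["behaviour"].isin(behaviours)
        ]
        return sub.pivot_table(
            index=["trial_id", "bee_id"],
            columns="behaviour",
            values="total_duration_s",
            aggfunc="sum",
            fill_value=0.0,
        ).reindex(columns=list(behaviours), fill_value=0.0)

    dx, dy = durations(phase_x), durations(phase_y)
    idx = dx.index.intersection(dy.index)
    dx, dy = dx.loc[idx], dy.loc[idx]
    if cross:
        pairs = list(product(behaviours, behaviours))
    else:
        pairs = list(combinations(behaviours, 2))
    rows = []
    for x, y in pairs:
        both = (dx[x] > 0) & (dy[y] > 0)
        n = int(both.sum())
        cell = dict(behaviour_x=x, behaviour_y=y, phase_x=phase_x, phase_y=phase_y, n=n)
        if n < min_n:
            rows.append({**cell, "excluded": True, "reason": f"fewer than {min_n} bees"})
            continue
        a = dx.loc[both, x].to_numpy()
        b = dy.loc[both, y].to_numpy()
        if np.allclose(a, a[0]) or np.allclose(b, b[0]):
            rows.append({**cell, "excluded": True, "reason": "constant durations"})
            continue
        rho, p = stats.spearmanr(a, b)
        rows.append({**cell, "rho": float(rho), "p_value": float(p),
                     "excluded": False, "reason": ""})
    return pd.DataFrame(rows)


def suite_venn(
    summaries: pd.DataFrame,
    panel: tuple[str, str, str, str],
    phases: tuple[str, ...] | None = None,
    castes: tuple[str, ...] = ("worker",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs independence-expected counts of behaviour combinations.

    The unit is one individual trial (one bee in one trial).  For a panel of
    four behaviours, counts the trials in which exactly each of the 16
    subsets was performed (in any of ``phases``, default post-disturbance)
    and the count expected were the behaviours independent with the same
    marginal frequencies.  Also returns the k-of-panel distribution: the
    fraction of trials in which at least / exactly k panel behaviours were
    performed.

    Returns ``(subsets, k_of_n)``; observed and expected subset counts both
    sum to the number of trials.
    """
    panel = tuple(panel)
    vocab = set(summaries["behaviour"])
    missing = [b for b in panel if b not in vocab]
    if missing:
        raise ValueError(f"panel behaviours absent from summaries: {missing}")
    all_phases = list(dict.fromkeys(summaries["phase"]))
    phases = tuple(phases or all_phases[1:])
    sub = summaries[
        summaries["phase"].isin(phases)
        & summaries["behaviour"].isin(panel)
        & summaries["caste"].isin(castes)
    ]
    flags = (
        sub.groupby(["trial_id", "bee_id", "behaviour"])["occurred"]
        .any()
        .unstack("behaviour")
        .reindex(columns=list(panel), fill_value=False)
        .fillna(False)
        .astype(bool)
    )
    n = len(flags)
    marginals = flags.mean(axis=0) if n else pd.Series(0.0, index=list(panel))
    rows = []
    for mask in product([False, True], repeat=len(panel)):
        members = tuple(b for b, m in zip(panel, mask) if m)
        observed = int((flags.to_numpy() == np.array(mask)).all(axis=1).sum()) if n else 0
        expected = n * float(
            np.prod([marginals[b] if m else 1 - marginals[b] for b, m in zip(panel, mask)])
        )
        rows.append(
            dict(
                behaviour_set="+".join(members) if members else "(none)",
                k=sum(mask),
                observed=observed,
                expected_independent=expected,
                **{f"has_{b}": m for b, m in zip(panel, mask)},
            )
        )
    subsets = pd.DataFrame(rows)
    k_counts = flags.sum(axis=1) if n else pd.Series(dtype=int)
    k_rows = []
    for k in range(len(panel) + 1):
        k_rows.append(
            dict(
                k=k,
                fraction_exactly=float((k_counts == k).mean()) if n else np.nan,
                fraction_at_least=float((k_counts >= k).mean()) if n else np.nan,
            )
        )
    return subsets, pd.DataFrame(k_rows)
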