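"""Behaviour co-occurrence, duration correlations and suite analysis."""

import numpy as np
import pandas as pd
import pytest

from ethobuzz.association import (
    cooccurrence_cross,
    cooccurrence_within,
    duration_correlation,
    suite_venn,
)
from ethobuzz.synth import gen_coupled_behaviours


def _summaries_from_flags(flags, phase="AR", durations=None):
    """Summary rows from a bee x behaviour boolean DataFrame."""
    rows = []
    for bee, row in flags.iterrows():
        for beh, x in row.items():
            dur = durations.loc[bee, beh] if durations is not None else (7.0 if x else 0.0)
            rows.append(dict(trial_id="T1", colony_id="C1", bee_id=bee, caste="worker",
                             phase=phase, behaviour=beh, occurred=bool(dur > 0),
                             n_bouts=int(dur > 0), total_duration_s=float(dur),
                             duration_inside_s=float(dur), duration_outside_s=0.0,
                             duration_per_min=float(dur)))
    return pd.DataFrame(rows)


def test_perfectly_coupled_pair_detected():
    rng = np.random.default_rng(0)
    x = rng.random(40) < 0.5
    flags = pd.DataFrame({"perching": x, "pulse_buzzing": x},
                         index=[f"b{i}" for i in range(40)])
    cells = cooccurrence_within(_summaries_from_flags(flags), "AR",
                                behaviours=("perching", "pulse_buzzing"))
    cell = cells[(cells.behaviour_x == "perching") & (cells.behaviour_y == "pulse_buzzing")].iloc[0]
    assert cell.p_x_given_y == pytest.approx(1.0)
    assert cell.p_x == pytest.approx(x.mean())
    assert cell.p_value < 0.001


def test_universal_behaviour_is_degenerate_not_tested():
    flags = pd.DataFrame({"grooming": [True] * 20,
                          "perching": [True] * 10 + [False] * 10},
                         index=[f"b{i}" for i in range(20)])
    cells = cooccurrence_within(_summaries_from_flags(flags), "AR",
                                behaviours=("grooming", "perching"))
    cell = cells[(cells.behaviour_x == "grooming")].iloc[0]
    assert cell.p_x_given_y == pytest.approx(1.0) == pytest.approx(cell.p_x)
    assert cell.chi2 == pytest.approx(0.0) and not cell.significant


def test_unperformed_behaviour_excluded():
    flags = pd.DataFrame({"grooming": [True, False], "fanning": [False, False]},
                         index=["b1", "b2"])
    cells = cooccurrence_within(_summaries_from_flags(flags), "AR",
                                behaviours=("grooming", "fanning"))
    assert cells[cells.behaviour_y == "fanning"].excluded.all()


def test_bayes_consistency_on_testable_cells():
    """P(x|y) P(y) = P(y|x) P(x) = joint on every testable cell."""
    s = gen_coupled_behaviours(
        120,
        {"patrolling": 0.5, "grooming": 0.6, "perching": 0.3, "pulse_buzzing": 0.4},
        {("patrolling", "grooming"): 1.2},
        seed=2,
    )
    cells = cooccurrence_within(
        s, "AR", behaviours=("patrolling", "grooming", "perching", "pulse_buzzing")
    )
    ok = cells[~cells.excluded].set_index(["behaviour_x", "behaviour_y"])
    for (x, y), row in ok.iterrows():
        mirror = ok.loc[(y, x)]
        assert row.p_x_given_y * row.p_y == pytest.approx(row.p_joint, abs=1e-12)
        assert mirror.p_joint == pytest.approx(row.p_joint, abs=1e-12)


def test_cross_phase_persistence_and_empty_from_phase():
    bees = [f"b{i}" for i in range(30)]
    rng = np.random.default_rng(3)
    ar = pd.DataFrame({"perching": rng.random(30) < 0.5,
                       "grooming": rng.random(30) < 0.5}, index=bees)
    dr = pd.DataFrame({"perching": ar["perching"],  # everyone persists
                       "grooming": rng.random(30) < 0.5}, index=bees)
    s = pd.concat([_summaries_from_flags(ar, "AR"), _summaries_from_flags(dr, "DR")])
    cells = cooccurrence_cross(s, "AR", "DR", behaviours=("perching", "grooming"))
    cell = cells[(cells.behaviour_x == "perching") & (cells.behaviour_y == "perching")].iloc[0]
    assert cell.p_x_given_y == pytest.approx(1.0)
    assert cell.significant
    # a from-phase with no activity excludes every cell
    bd = pd.DataFrame({"perching": [False] * 30, "grooming": [False] * 30}, index=bees)
    s2 = pd.concat([_summaries_from_flags(bd, "BD"), _summaries_from_flags(dr, "DR")])
    cells2 = cooccurrence_cross(s2, "BD", "DR", behaviours=("perching", "grooming"))
    assert cells2.excluded.all()


def test_independent_behaviours_significant_at_alpha():
    """Type-I: independent occurrence -> ~5% significant cells."""
    reps = 300
    hits = 0
    for i in range(reps):
        s = gen_coupled_behaviours(
            200, {"patrolling": 0.5, "grooming": 0.5}, None, seed=10_000 + i
        )
        cells = cooccurrence_within(s, "AR", behaviours=("patrolling", "grooming"))
        cell = cells[(cells.behaviour_x == "patrolling")].iloc[0]
        hits += bool(cell.significant)
    from scipy import stats
    lo, hi = stats.binom.ppf([0.025, 0.975], reps, 0.05)
    assert lo <= hits <= hi


# ---------------------------------------------------------------------------
# duration correlations


def test_duration_correlation_monotone_transforms():
    bees = [f"b{i}" for i in range(10)]
    x = np.arange(1.0, 11.0)
    flags = pd.DataFrame(True, index=bees, columns=["patrolling", "grooming", "perching"])
    durs = pd.DataFrame({"patrolling": x, "grooming": 2 * x, "perching": 30.0 - x},
                        index=bees)
    s = _summaries_from_flags(flags, durations=durs)
    cells = duration_correlation(s, "AR", behaviours=("patrolling", "grooming", "perching"))
    c = cells.set_index(["behaviour_x", "behaviour_y"])
    assert c.loc[("patrolling", "grooming"), "rho"] == pytest.approx(1.0)
    assert c.loc[("patrolling", "perching"), "rho"] == pytest.approx(-1.0)


def test_duration_correlation_exclusions():
    bees = ["b1", "b2", "b3", "b4"]
    flags = pd.DataFrame(True, index=bees, columns=["patrolling", "grooming", "perching"])
    durs = pd.DataFrame({"patrolling": [1.0, 2.0, 3.0, 4.0],
                         "grooming": [5.0, 5.0, 5.0, 5.0],   # constant
                         "perching": [1.0, 0.0, 0.0, 0.0]},  # a single performer
                        index=bees)
    s = _summaries_from_flags(flags, durations=durs)
    cells = duration_correlation(s, "AR", behaviours=("patrolling", "grooming", "perching"))
    c = cells.set_index(["behaviour_x", "behaviour_y"])
    assert c.loc[("patrolling", "grooming"), "excluded"]  # constant flagged
    assert c.loc[("patrolling", "perching"), "excluded"]  # n < 3
    assert "fewer" in c.loc[("patrolling", "perching"), "reason"]


def test_independent_durations_rho_small():
    rng = np.random.default_rng(8)
    bees = [f"b{i}" for i in range(30)]
    flags = pd.DataFrame(True, index=bees, columns=["patrolling", "grooming"])
    rhos = []
    for i in range(50):
        durs = pd.DataFrame({"patrolling": rng.uniform(1, 10, 30),
                             "grooming": rng.uniform(1, 10, 30)}, index=bees)
        s = _summaries_from_flags(flags, durations=durs)
        cells = duration_correlation(s, "AR", behaviours=("patrolling", "grooming"))
        rhos.append(cells.iloc[0].rho)
    assert abs(np.mean(rhos)) < 0.1
    assert np.mean(np.abs(rhos) > 0.5) < 0.05


# ---------------------------------------------------------------------------
# suite (Venn) analysis

PANEL = ("patrolling", "continuous_buzzing", "abdominal_pumping", "grooming")


def test_suite_venn_saturated_panel():
    bees = [f"b{i}" for i in range(12)]
    flags = pd.DataFrame(True, index=bees, columns=list(PANEL))
    s = _summaries_from_flags(flags)
    s = pd.concat([s, _summaries_from_flags(pd.DataFrame(False, index=bees, columns=list(PANEL)), "BD")])
    subsets, kofn = suite_venn(s, PANEL, phases=("AR",))
    full = subsets[subsets.k == 4].iloc[0]
    assert full.observed == 12 and full.expected_independent == pytest.approx(12.0)
    assert kofn.set_index("k").loc[4, "fraction_at_least"] == 1.0


def test_suite_venn_expected_counts_sum_to_n_and_product_rule():
    s = gen_coupled_behaviours(64, {b: 0.5 for b in PANEL}, None, seed=4)
    subsets, _ = suite_venn(s, PANEL, phases=("AR",))
    n = subsets.observed.sum()
    assert n == 64
    assert subsets.expected_independent.sum() == pytest.approx(64.0)
    # with marginals exactly 0.5 the full-set expectation would be n/16;
    # here expectations use the realised marginals, so just check the formula
    m = [subsets[subsets[f"has_{b}"]].observed.sum() / n for b in PANEL]
    full = subsets[subsets.k == 4].iloc[0]
    assert full.expected_independent == pytest.approx(n * np.prod(m))


def test_suite_venn_independence_observed_close_to_expected():
    s = gen_coupled_behaviours(400, {b: p for b, p in zip(PANEL, (0.95, 0.94, 0.92, 0.95))},
                               None, seed=5)
    subsets, kofn = suite_venn(s, PANEL, phases=("AR",))
    # the dominant cell (all four) should be within a multinomial-ish band
    full = subsets[subsets.k == 4].iloc[0]
    sd = np.sqrt(full.expected_independent * (1 - full.expected_independent / 400))
    assert abs(full.observed - full.expected_independent) < 4 * sd + 1
    assert kofn.set_index("k").loc[3, "fraction_at_least"] > 0.9


def test_suite_venn_unknown_panel_behaviour_raises(demo_summaries):
    with pytest.raises(ValueError, match="absent"):
        suite_venn(demo_summaries, ("patrolling", "grooming", "perching", "nonsense"))
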