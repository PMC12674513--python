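"""Stimulus comparison via grand-mean normalisation (microcolony design).

Occurrence probabilities per behaviour are averaged over (stimulus, bin,
day, colony, test) cells, referenced against the mechanical-disturbance
grand mean of the same (behaviour, bin, colony), normalised as
``log((mean + eps) / (grand mean + eps))`` with eps = 1e-5 (natural log),
and analysed with an ordinary linear model ``log_ratio ~ stimulus * bin``
with per-cell contrasts against the mechanical-disturbance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

#: Epsilon guard of the normalisation formula.
EPSILON = 1e-5

REFERENCE_STIMULUS = "mechanical_disturbance"


def mean_probabilities(
    summaries: pd.DataFrame,
    keys: tuple[str, ...] = ("behaviour", "stimulus", "phase", "day", "colony_id", "test"),
) -> pd.DataFrame:
    """Mean bee-level occurrence probability per key combination.

    ``keys`` defaults to (behaviour, stimulus, bin, day, colony, test);
    keys absent from the summaries (e.g. no ``test`` column) are dropped.
    Empty key groups are simply absent rows.
    """
    present = [k for k in keys if k in summaries.columns]
    required = {"behaviour", "stimulus", "phase"}
    if not required.issubset(present):
        raise ValueError(f"summaries must carry columns {sorted(required)}")
    out = (
        summaries.groupby(present, as_index=False, observed=True)["occurred"]
        .mean()
        .rename(columns={"occurred": "mean_p"})
    )
    return out


def grand_mean_reference(
    table: pd.DataFrame, reference_stimulus: str = REFERENCE_STIMULUS
) -> pd.DataFrame:
    """Grand mean of the reference stimulus per (behaviour, bin, colony)."""
    ref = table[table["stimulus"] == reference_stimulus]
    if ref.empty:
        raise ValueError(f"no rows for reference stimulus {reference_stimulus!r}")
    missing = set(table["colony_id"]) - set(ref["colony_id"])
    if missing:
        raise ValueError(
            "colony lacking any reference-stimulus trial: " + ", ".join(map(str, sorted(missing)))
        )
    return (
        ref.groupby(["behaviour", "phase", "colony_id"], as_index=False)["mean_p"]
        .mean()
        .rename(columns={"mean_p": "grand_mean_p"})
    )


def normalize(
    table: pd.DataFrame, reference: pd.DataFrame, epsilon: float = EPSILON
) -> pd.DataFrame:
    """Attach ``log_ratio = log((mean_p + eps)/(grand_mean_p + eps))``.

    Natural log; the epsilon guard keeps the ratio finite for zero
    probabilities (log(eps/eps) = 0).  Reference-stimulus rows are
    normalised against their own grand mean (hence centred near zero).
    """
    out = table.merge(reference, on=["behaviour", "phase", "colony_id"], how="left")
    if out["grand_mean_p"].isna().any():
        bad = out.loc[out["grand_mean_p"].isna(), ["behaviour", "phase", "colony_id"]]
        raise ValueError(f"reference incomplete for rows:\n{bad.drop_duplicates()}")
    out["epsilon"] = epsilon
    out["log_ratio"] = np.log((out["mean_p"] + epsilon) / (out["grand_mean_p"] + epsilon))
    return out


@dataclass
class StimulusModelResult:
    """OLS fit of log-ratio on stimulus x bin with per-cell contrasts."""

    formula: str
    n_obs: int
    coefficients: pd.DataFrame
    contrasts: pd.DataFrame  # per (stimulus, bin) cell vs baseline at same bin
    anova: pd.DataFrame
    rank_deficient: bool
    dropped_note: str = ""
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"Stimulus x bin linear model: {self.formula}   n = {self.n_obs}",
            self.coefficients.to_string(index=False),
            "Cell contrasts vs baseline stimulus:",
            self.contrasts.to_string(index=False),
        ]
        if self.rank_deficient:
            lines.append(f"NOTE: rank-deficient design. {self.dropped_note}")
        return "\n".join(lines)


def stimulus_bin_model(
    normalized: pd.DataFrame,
    baseline: str = REFERENCE_STIMULUS,
    alpha: float = 0.05,
) -> StimulusModelResult:
    """Fit ``log_ratio ~ C(stimulus) * C(phase)`` and test cells vs baseline.

    Requires at least two stimuli and two bins.  For every non-baseline
    stimulus and bin, the contrast is the model-implied cell-mean difference
    to the baseline stimulus at the same bin (the per-panel asterisks).
    """
    df = normalized.copy()
    stimuli = list(dict.fromkeys(df["stimulus"]))
    bins = list(dict.fromkeys(df["phase"]))
    if len(stimuli) < 2 or len(bins) < 2:
        raise ValueError("need at least two stimuli and two bins")
    if baseline not in stimuli:
        raise ValueError(f"baseline stimulus {baseline!r} absent")
    stimuli = [baseline] + [s for s in stimuli if s != baseline]
    df["stimulus"] = pd.Categorical(df["stimulus"], categories=stimuli)
    df["phase"] = pd.Categorical(df["phase"], categories=bins)
    formula = "log_ratio ~ C(stimulus) * C(phase)"
    model = smf.ols(formula, data=df)
    res = model.fit()
    rank_deficient = np.linalg.matrix_rank(model.exog) < model.exog.shape[1]
    note = ""
    if rank_deficient:
        note = "some stimulus x bin cells are empty; their terms are not estimable"
    coef = pd.DataFrame(
        {"term": res.params.index, "estimate": res.params.to_numpy(),
         "se": res.bse.to_numpy(), "p": res.pvalues.to_numpy()}
    )
    try:
        anova = sm.stats.anova_lm(res, typ=2)
    except Exception:
        anova = pd.DataFrame()
    design_info = model.data.design_info
    rows = []
    for s in stimuli[1:]:
        for b in bins:
            X1 = np.asarray(
                build_design_matrices([design_info], pd.DataFrame({"stimulus": [s], "phase": [b]}))[0]
            )
            X0 = np.asarray(
                build_design_matrices(
                    [design_info], pd.DataFrame({"stimulus": [baseline], "phase": [b]})
                )[0]
            )
            tt = res.t_test(X1 - X0)
            est = float(np.squeeze(tt.effect))
            se = float(np.squeeze(tt.sd))
            p = float(np.squeeze(tt.pvalue))
            rows.append(
                dict(stimulus=s, bin=b, estimate=est, se=se, p=p,
                     significant=bool(np.isfinite(p) and p < alpha))
            )
    return StimulusModelResult(
        formula=formula,
        n_obs=len(df),
        coefficients=coef,
        contrasts=pd.DataFrame(rows),
        anova=anova,
        rank_deficient=bool(rank_deficient),
        dropped_note=note,
        alpha=alpha,
    )
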