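"""Trial- and participant-level exclusion cascade.

The cascade runs in a fixed order on a shrinking trial set, and each stage's
exclusion fraction is reported relative to the set it actually saw:

1. error trials (an error in *either* sub-task), fraction of all trials;
2. RT outliers — RT1 or RT2 beyond mean ± 3 SD of the participant × condition
   cell — fraction of correct trials (single pass, no re-iteration);
3. grouped/reversed responses — inter-response interval < 100 ms, including
   negative intervals — fraction of the remaining trials.

Because stage 2 statistics are computed on post-error trials, permuting the
stages changes the reported percentages; the order here is enforced by
:func:`run_cascade`.

Participant screening (error rate over 25%, grouped-response or
unmoved-marker percentage more than 3 SD above the sample mean) flags
participants with reasons; it never silently drops them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionReport",
    "exclude_errors",
    "exclude_rt_outliers",
    "exclude_grouped",
    "screen_participants",
    "run_cascade",
]

GROUPED_IRI_MS = 100.0
ERROR_RATE_SCREEN = 0.25


@dataclass
class ExclusionReport:
    """Per-stage exclusion percentages and participant flags."""

    pct_errors: float
    pct_rt_outliers: float
    pct_grouped: float
    n_degenerate_markers: int
    participants_flagged: list = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return {
            "pct_errors": self.pct_errors,
            "pct_rt_outliers": self.pct_rt_outliers,
            "pct_grouped": self.pct_grouped,
            "n_degenerate_markers": self.n_degenerate_markers,
            "participants_flagged": [list(t) for t in self.participants_flagged],
            "n_input": self.n_input,
            "n_output": self.n_output,
        }


def _rts(trials: pd.DataFrame):
    return trials["t_R1"] - trials["t_S1"], trials["t_R2"] - trials["t_S2"]


def exclude_errors(trials: pd.DataFrame):
    """Remove trials with an error in either sub-task.

    Returns ``(kept, pct_removed)`` with the percentage relative to the
    input table.
    """
    bad = ~(trials["correct1"].astype(bool) & trials["correct2"].astype(bool))
    pct = 100.0 * bad.mean() if len(trials) else 0.0
    return trials.loc[~bad].copy(), float(pct)


def _condition_cols(trials: pd.DataFrame, condition_cols=None):
    if condition_cols is not None:
        return list(condition_cols)
    cols = ["soa"]
    if "difficulty" in trials.columns:
        cols.append("difficulty")
    return cols


def exclude_rt_outliers(trials: pd.DataFrame, condition_cols=None):
    """Remove trials whose RT1 *or* RT2 deviates more than 3 SD from the
    participant × condition cell mean (sample SD, single pass).

    Cells with fewer than 2 trials cannot define an SD and are skipped with
    a warning.  Returns ``(kept, pct_removed)`` relative to the input
    (i.e. to correct trials when run in cascade order).
    """
    if len(trials) == 0:
        return trials.copy(), 0.0
    cols = ["participant"] + _condition_cols(trials, condition_cols)
    rt1, rt2 = _rts(trials)
    work = trials.assign(_rt1=rt1, _rt2=rt2)
    keep = pd.Series(True, index=work.index)
    for _, cell in work.groupby(cols, sort=False):
        if len(cell) < 2:
            warnings.warn(
                "participant/condition cell with < 2 trials skipped in RT "
                "outlier screening",
                stacklevel=2,
            )
            continue
        for col in ("_rt1", "_rt2"):
            m, s = cell[col].mean(), cell[col].std(ddof=1)
            keep.loc[cell.index[(cell[col] - m).abs() > 3.0 * s]] = False
    pct = 100.0 * (~keep).mean()
    return trials.loc[keep].copy(), float(pct)


def exclude_grouped(trials: pd.DataFrame):
    """Remove trials with inter-response interval (t_R2 - t_R1) < 100 ms.

    The signed interval is used, so reversed responses (R2 before R1) are
    removed too; the 100 ms boundary itself is retained (strict <).
    """
    if len(trials) == 0:
        return trials.copy(), 0.0
    iri = trials["t_R2"] - trials["t_R1"]
    bad = iri < GROUPED_IRI_MS
    pct = 100.0 * bad.mean()
    return trials.loc[~bad].copy(), float(pct)


def _unmoved_mask(trials: pd.DataFrame) -> pd.Series:
    """Trials where all four markers sit at the initial central pixel."""
    centre = trials["timeline_px"] / 2.0
    return (
        (trials["iS1_px"] == centre)
        & (trials["iS2_px"] == centre)
        & (trials["iR1_px"] == centre)
        & (trials["iR2_px"] == centre)
    )


def _degenerate_mask(trials: pd.DataFrame) -> pd.Series:
    """Trials where all four markers coincide (any position)."""
    return (
        (trials["iS1_px"] == trials["iS2_px"])
        & (trials["iS1_px"] == trials["iR1_px"])
        & (trials["iS1_px"] == trials["iR2_px"])
    )


def screen_participants(trials: pd.DataFrame) -> list:
    """Flag participants violating the recruitment-replacement rules.

    Rules (computed on the raw, unfiltered table):

    * error rate in either sub-task strictly over 25%;
    * percentage of grouped responses (|IRI| < 100 ms) more than 3 SD above
      the sample mean of per-participant percentages;
    * percentage of unmoved-marker trials more than 3 SD above the sample
      mean.

    Returns a list of ``(participant, reason, value_pct)`` tuples.
    """
    flags = []
    err = ~(trials["correct1"].astype(bool) & trials["correct2"].astype(bool))
    iri = trials["t_R2"] - trials["t_R1"]
    per = pd.DataFrame(
        {
            "error": err.groupby(trials["participant"]).mean() * 100.0,
            "grouped": (iri.abs() < GROUPED_IRI_MS)
            .groupby(trials["participant"])
            .mean()
            * 100.0,
            "unmoved": _unmoved_mask(trials).groupby(trials["participant"]).mean()
            * 100.0,
        }
    )
    for pid, v in per["error"].items():
        if v > 100.0 * ERROR_RATE_SCREEN:
            flags.append((pid, "error_rate", float(v)))
    for reason in ("grouped", "unmoved"):
        col = per[reason]
        m, s = col.mean(), col.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            continue
        for pid, v in col.items():
            if v > m + 3.0 * s:
                flags.append((pid, f"{reason}_pct", float(v)))
    return flags


def run_cascade(trials: pd.DataFrame, condition_cols=None):
    """Apply the full exclusion cascade in order and report each stage.

    Returns ``(clean_trials, ExclusionReport)``.  Participant screening is
    reported (flags with reasons) but flagged participants are not dropped;
    replacement is a recruitment decision, not a data transform.
    """
    n_in = len(trials)
    flags = screen_participants(trials) if n_in else []
    kept, pct_err = exclude_errors(trials)
    kept, pct_out = exclude_rt_outliers(kept, condition_cols)
    kept, pct_grp = exclude_grouped(kept)
    report = ExclusionReport(
        pct_errors=pct_err,
        pct_rt_outliers=pct_out,
        pct_grouped=pct_grp,
        n_degenerate_markers=int(_degenerate_mask(kept).sum()) if len(kept) else 0,
        participants_flagged=flags,
        n_input=n_in,
        n_output=len(kept),
    )
    return kept, report
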