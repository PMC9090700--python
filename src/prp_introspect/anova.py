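"""Mean-level awareness test: SOA × Task repeated-measures ANOVA on iRTs.

The behavioural PRP signature is a large SOA effect on RT2 and none on RT1.
Awareness of that cost is therefore defined as a *larger SOA effect on iRT2
than on iRT1*: the SOA × Task interaction must be significant (p < .05) and
the introspective SOA effect (short − long) on Task 2 must exceed the one on
Task 1.  A non-significant interaction, or one driven by Task 1, is an
introspective blind spot.

Only the shortest and longest SOA levels enter the test.  With two-level
factors sphericity is trivially satisfied (Greenhouse–Geisser ε = 1); a
generic ε estimator is provided for the three-SOA variant.  Cell error bars
use within-subject (Cousineau–Morey) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .timeline import add_irt_columns

__all__ = [
    "AnovaResult",
    "cell_means",
    "rm_anova",
    "within_subject_se",
    "greenhouse_geisser_epsilon",
]

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Interaction test of the SOA × Task ANOVA plus the awareness verdict.

    ``eta_p2`` is the partial eta-squared F·df1/(F·df1 + df2);
    ``gg_epsilon`` is 1 for two-level factors.  ``soa_effect_task1`` /
    ``soa_effect_task2`` are the mean short−long iRT differences (ms).
    ``table`` holds the full ANOVA table (all three effects).
    """

    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    gg_epsilon: float
    verdict: str
    soa_effect_task1: float
    soa_effect_task2: float
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "eta_p2": self.eta_p2,
            "gg_epsilon": self.gg_epsilon,
            "verdict": self.verdict,
            "soa_effect_task1": self.soa_effect_task1,
            "soa_effect_task2": self.soa_effect_task2,
        }


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta-squared from an F statistic: F·df1 / (F·df1 + df2)."""
    return F * df1 / (F * df1 + df2)


def cell_means(
    trials: pd.DataFrame,
    soa_levels=None,
    task1_source: str = "introspective",
) -> pd.DataFrame:
    """Per-participant mean iRT for each SOA (shortest/longest) × Task cell.

    Returns a tidy frame with columns ``participant, soa, task, irt``
    (unweighted within-cell means).  ``task1_source='objective'`` substitutes
    the objective RT1 for iRT1 — the variant needed when S1/R1 markers are
    fixed in place and only Task 2 is recreated.  Participants missing any
    cell are dropped with a warning.
    """
    if task1_source not in ("introspective", "objective"):
        raise ValueError("task1_source must be 'introspective' or 'objective'")
    work = add_irt_columns(trials)
    if soa_levels is None:
        soa_levels = (work["soa"].min(), work["soa"].max())
    work = work[work["soa"].isin(soa_levels)].copy()
    if task1_source == "objective":
        work["iRT1"] = work["t_R1"] - work["t_S1"]
    long = work.melt(
        id_vars=["participant", "soa"],
        value_vars=["iRT1", "iRT2"],
        var_name="task",
        value_name="irt",
    )
    long["task"] = long["task"].map({"iRT1": "T1", "iRT2": "T2"})
    cells = (
        long.groupby(["participant", "soa", "task"], as_index=False)["irt"].mean()
    )
    n_cells = cells.groupby("participant")["irt"].count()
    incomplete = n_cells[n_cells < 2 * len(soa_levels)].index
    if len(incomplete):
        warnings.warn(
            f"dropping participants with missing cells: {sorted(incomplete)}",
            stacklevel=2,
        )
        cells = cells[~cells["participant"].isin(incomplete)]
    return cells


def rm_anova(cells: pd.DataFrame) -> AnovaResult:
    """Two-way within-subjects ANOVA (SOA × Task) on the cell-mean table.

    The interaction row carries the awareness test.  Raises on fewer than
    two participants.
    """
    n_sub = cells["participant"].nunique()
    if n_sub < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 participants")
    fit = AnovaRM(
        data=cells,
        depvar="irt",
        subject="participant",
        within=["soa", "task"],
    ).fit()
    tab = fit.anova_table
    inter = tab.loc["soa:task"]
    F = float(inter["F Value"])
    df1, df2 = float(inter["Num DF"]), float(inter["Den DF"])
    p = float(inter["Pr > F"])

    soa_sorted = sorted(cells["soa"].unique())
    short, long_ = soa_sorted[0], soa_sorted[-1]
    pivot = cells.pivot_table(index="participant", columns=["soa", "task"], values="irt")
    eff1 = float((pivot[(short, "T1")] - pivot[(long_, "T1")]).mean())
    eff2 = float((pivot[(short, "T2")] - pivot[(long_, "T2")]).mean())

    verdict = "awareness" if (p < ALPHA and eff2 > eff1) else "blind_spot"
    return AnovaResult(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        eta_p2=partial_eta_squared(F, df1, df2),
        gg_epsilon=1.0,  # both factors have 2 levels
        verdict=verdict,
        soa_effect_task1=eff1,
        soa_effect_task2=eff2,
        table=tab,
    )


def greenhouse_geisser_epsilon(wide: np.ndarray) -> float:
    """Greenhouse–Geisser ε for a one-way within-subject factor.

    ``wide`` is participants × levels.  ε = 1 for two levels; lower bound
    1/(k−1).  Used for the optional three-SOA analysis variant.
    """
    wide = np.asarray(wide, dtype=float)
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need at least 2 levels")
    if k == 2:
        return 1.0
    S = np.cov(wide, rowvar=False, ddof=1)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    return float(num / den)


def within_subject_se(cells: pd.DataFrame, value: str = "irt") -> pd.DataFrame:
    """Cousineau–Morey within-subject standard error per design cell.

    Each observation is recentred by its participant's mean (plus the grand
    mean); the per-cell SD/√n is then inflated by √(J/(J−1)) where J is the
    number of within-subject cells.
    """
    cell_cols = [c for c in cells.columns if c not in ("participant", value)]
    work = cells.copy()
    part_mean = work.groupby("participant")[value].transform("mean")
    work["_norm"] = work[value] - part_mean + work[value].mean()
    J = work.groupby(cell_cols).ngroups
    morey = np.sqrt(J / (J - 1.0)) if J > 1 else 1.0
    out = (
        work.groupby(cell_cols)["_norm"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"]) * morey
    out["mean"] = work.groupby(cell_cols)[value].mean().to_numpy()
    return out.drop(columns="sd")
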