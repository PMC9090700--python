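"""Mixed-effects modelling of single-trial introspective inaccuracy.

The headline inferential stage: what predicts how inaccurately a trial is
recreated?  The dependent variable is sqrt(∆rad); the fixed effects are

* Modality order — VA coded against the AV baseline (between-subjects);
* SOA — the long level coded against the 50 ms baseline (two-level factor);
* sqrt(central gap) — the square-rooted absolute time between the two
  central events S2 and R1;

plus all two-way interactions.  Square-root transforms of the two
continuous variables give residuals much closer to normal than raw values.
The random-effects structure lets intercepts and sqrt(central-gap) slopes
(with their correlation — three covariance parameters) vary over
participant × SOA groups, so SOA-specific individual differences are
absorbed before the fixed effects are assessed.

Model fitting is REML for the reported estimates; model selection uses ML
likelihood-ratio tests comparing the model with and without each fixed
term (χ² = 2·Δloglik, df 1), and the whole random structure is tested
against an ordinary least-squares fit (df 3).  Reported p-values for the
fixed-effect estimates are Wald z (asymptotic); at trial-level sample sizes
these coincide with finite-sample df corrections to reporting precision.

Vincentized summaries (per-participant central-gap quantile bins, averaged
across participants, Morey within-subject errors) provide the matching
descriptive picture on untransformed variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .anova import within_subject_se

__all__ = [
    "LmeSpec",
    "ModelFit",
    "prepare_lme_frame",
    "fit_lme",
    "lrt_model_selection",
    "vincentize",
    "FULL_FIXED_TERMS",
]

#: Fixed-effect terms of the full model (main effects + two-way interactions).
FULL_FIXED_TERMS = (
    "order_va",
    "soa_long",
    "sqrt_gap",
    "order_va:soa_long",
    "order_va:sqrt_gap",
    "soa_long:sqrt_gap",
)

#: Human-readable names for reporting, in Table-style order.
TERM_LABELS = {
    "Intercept": "Intercept",
    "order_va": "Modality order",
    "soa_long": "SOA",
    "sqrt_gap": "Central gap",
    "order_va:soa_long": "Modality order x SOA",
    "order_va:sqrt_gap": "Modality order x Central gap",
    "soa_long:sqrt_gap": "SOA x Central gap",
}


@dataclass
class LmeSpec:
    """Model specification: fixed terms and random structure."""

    fixed_terms: tuple = FULL_FIXED_TERMS
    re_formula: str = "~sqrt_gap"
    groups: str = "grp"


@dataclass
class ModelFit:
    """Fixed-effect estimates and diagnostics of one mixed-model fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    loglike: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    reml: bool
    lrt: pd.DataFrame | None = None
    random_lrt: dict | None = None
    result: object = field(repr=False, default=None)

    def summary_table(self) -> pd.DataFrame:
        """Table-style frame: estimate, SE, 95% CI, p per fixed term."""
        rows = []
        for term in self.params.index:
            rows.append(
                {
                    "term": TERM_LABELS.get(term, term),
                    "estimate": self.params[term],
                    "se": self.bse[term],
                    "ci_low": self.conf_int.loc[term, 0],
                    "ci_high": self.conf_int.loc[term, 1],
                    "p": self.pvalues[term],
                }
            )
        return pd.DataFrame(rows)


def prepare_lme_frame(radians: pd.DataFrame, soa_levels=None) -> pd.DataFrame:
    """Build the modelling frame from a radian-annotated trial table.

    Keeps the shortest/longest SOA and non-degenerate trials; adds the
    coded predictors ``order_va`` (VA=1, AV=0), ``soa_long`` (long=1),
    ``sqrt_gap``, the transformed dependent ``sqrt_drad``, and the
    participant × SOA grouping label ``grp``.
    """
    work = radians.copy()
    if soa_levels is None:
        soa_levels = (work["soa"].min(), work["soa"].max())
    work = work[work["soa"].isin(soa_levels)]
    if "degenerate" in work.columns:
        work = work[~work["degenerate"].astype(bool)]
    work = work.dropna(subset=["delta_rad", "central_gap"])
    out = work.copy()
    out["order_va"] = (out["modality_order"] == "VA").astype(float)
    out["soa_long"] = (out["soa"] == max(soa_levels)).astype(float)
    out["sqrt_gap"] = np.sqrt(out["central_gap"])
    out["sqrt_drad"] = np.sqrt(out["delta_rad"])
    out["grp"] = (
        out["participant"].astype(str) + ":" + out["soa"].astype(int).astype(str)
    )
    return out


def _formula(terms) -> str:
    return "sqrt_drad ~ " + " + ".join(terms) if terms else "sqrt_drad ~ 1"


def _active_terms(frame: pd.DataFrame, terms) -> tuple:
    """Drop fixed terms whose design column is constant (e.g. modality
    order in a single-order dataset), which would make the design singular."""
    active = []
    for term in terms:
        col = np.ones(len(frame))
        for part in term.split(":"):
            col = col * frame[part].to_numpy()
        if np.ptp(col) > 0:
            active.append(term)
        else:
            warnings.warn(f"dropping constant fixed term {term!r}", stacklevel=3)
    return tuple(active)


def _is_singular(result, tol: float = 1e-8) -> bool:
    cov = np.asarray(result.cov_re)
    if cov.size == 0:
        return False
    eig = np.linalg.eigvalsh(cov)
    return bool(eig.min() < tol * max(eig.max(), 1.0))


def _fit_mixed(frame: pd.DataFrame, terms, spec: LmeSpec, reml: bool):
    model = smf.mixedlm(
        _formula(terms), data=frame, groups=frame[spec.groups],
        re_formula=spec.re_formula,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
        if not result.converged:
            result = model.fit(reml=reml, method="powell", maxiter=2000)
    return result


def fit_lme(
    radians: pd.DataFrame,
    spec: LmeSpec | None = None,
    reml: bool = True,
    prepared: bool = False,
) -> ModelFit:
    """Fit the mixed model of sqrt(∆rad) on the coded predictors.

    ``radians`` is a trial table with radian columns (or an already
    prepared frame if ``prepared=True``).  If the estimated random-effects
    covariance comes out singular, the model is refitted with independent
    (diagonal) intercept and slope components and a warning is issued.
    """
    spec = spec or LmeSpec()
    frame = radians if prepared else prepare_lme_frame(radians)
    terms = _active_terms(frame, spec.fixed_terms)
    spec = LmeSpec(fixed_terms=terms, re_formula=spec.re_formula, groups=spec.groups)
    result = _fit_mixed(frame, spec.fixed_terms, spec, reml)
    singular = _is_singular(result)
    if singular:
        warnings.warn(
            "singular random-effects covariance; refitting with independent "
            "intercept and slope",
            stacklevel=2,
        )
        model = smf.mixedlm(
            _formula(spec.fixed_terms),
            data=frame,
            groups=frame[spec.groups],
            vc_formula={"gap_slope": "0 + sqrt_gap"},
            re_formula="~1",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=reml, method=["lbfgs", "powell"])
    fe = result.fe_params
    bse = result.bse.loc[fe.index]
    ci = pd.DataFrame(
        {0: fe - 1.96 * bse, 1: fe + 1.96 * bse}, index=fe.index
    )
    return ModelFit(
        params=fe,
        bse=bse,
        pvalues=result.pvalues.loc[fe.index],
        conf_int=ci,
        loglike=float(result.llf),
        converged=bool(result.converged),
        singular=singular,
        n_obs=int(result.nobs),
        n_groups=frame[spec.groups].nunique(),
        reml=reml,
        result=result,
    )


def lrt_model_selection(
    radians: pd.DataFrame, spec: LmeSpec | None = None, prepared: bool = False
) -> pd.DataFrame:
    """Likelihood-ratio model selection over the fixed terms.

    For each fixed term the full ML fit is compared with the ML fit without
    that term (χ² = 2·Δloglik, df 1).  A final row tests the whole random
    structure against an OLS fit with the same fixed effects (df 3: two
    variances and a covariance).
    """
    from scipy import stats

    spec = spec or LmeSpec()
    frame = radians if prepared else prepare_lme_frame(radians)
    spec = LmeSpec(
        fixed_terms=_active_terms(frame, spec.fixed_terms),
        re_formula=spec.re_formula,
        groups=spec.groups,
    )
    full = _fit_mixed(frame, spec.fixed_terms, spec, reml=False)
    rows = []
    for term in spec.fixed_terms:
        reduced_terms = tuple(t for t in spec.fixed_terms if t != term)
        reduced = _fit_mixed(frame, reduced_terms, spec, reml=False)
        chisq = max(0.0, 2.0 * (full.llf - reduced.llf))
        rows.append(
            {
                "term": TERM_LABELS.get(term, term),
                "chisq": chisq,
                "df": 1,
                "p": float(stats.chi2.sf(chisq, 1)),
            }
        )
    ols = sm.OLS.from_formula(_formula(spec.fixed_terms), data=frame).fit()
    chisq_re = max(0.0, 2.0 * (full.llf - ols.llf))
    rows.append(
        {
            "term": "Random structure",
            "chisq": chisq_re,
            "df": 3,
            "p": float(stats.chi2.sf(chisq_re, 3)),
        }
    )
    return pd.DataFrame(rows)


def vincentize(
    radians: pd.DataFrame,
    n_bins: int = 5,
    by=("modality_order", "soa"),
    prepared: bool = False,
) -> pd.DataFrame:
    """Vincentized ∆rad against central gap.

    Within each participant × panel cell (panel = modality order × SOA),
    trials are sorted by central gap and split into ``n_bins`` equal-count
    bins (remainders spread over the leading bins); raw ∆rad and gap are
    averaged per bin, then across participants, with Morey within-subject
    SEs per panel.
    """
    frame = radians if prepared else prepare_lme_frame(radians)
    by = list(by)
    per_part = []
    for keys, cell in frame.groupby(["participant"] + by, sort=True):
        cell = cell.sort_values("central_gap")
        chunks = np.array_split(np.arange(len(cell)), n_bins)
        for b, idx in enumerate(chunks):
            if len(idx) == 0:
                continue
            sub = cell.iloc[idx]
            rec = dict(zip(["participant"] + by, keys))
            rec.update(
                vincentile=b + 1,
                delta_rad=sub["delta_rad"].mean(),
                central_gap=sub["central_gap"].mean(),
            )
            per_part.append(rec)
    per_part = pd.DataFrame(per_part)
    out_rows = []
    for panel_keys, panel in per_part.groupby(by, sort=True):
        se = within_subject_se(
            panel[["participant", "vincentile", "delta_rad"]], value="delta_rad"
        )
        gaps = panel.groupby("vincentile")["central_gap"].mean()
        for _, r in se.iterrows():
            rec = dict(zip(by, panel_keys if isinstance(panel_keys, tuple) else (panel_keys,)))
            rec.update(
                vincentile=int(r["vincentile"]),
                mean_central_gap=float(gaps.loc[r["vincentile"]]),
                mean_delta_rad=float(r["mean"]),
                se=float(r["se"]),
                n_participants=int(r["n"]),
            )
            out_rows.append(rec)
    return pd.DataFrame(out_rows)
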