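"""Repeatability statistics and the trial x donor-type model layer.

Repeatability of a fermentation parameter is expressed as the coefficient
of variation across fermentation trials,

    CV_RF = 100 * sigma / mean,

with sigma the unbiased (n-1 denominator) sample standard deviation of
the per-trial values. CV_RFT and CV_RFA are computed within donor type
(fasted heifers / lactating cows); for the overall CV_RFALL two
estimators are reported, because pooling trial means across donor types
that differ systematically inflates the SD: (i) the plain CV over all
trial means, and (ii) the pooled within-type SD over the grand mean.

Donor-type comparisons use a fixed-effects linear model

    Y_ij = mu + alpha_i + beta_j + (alpha beta)_ij + eps_ij

(alpha: fermentation trial, beta: donor type) with backward reduction of
non-significant terms, plus a Welch t-test for the unbalanced two-group
comparison. When every trial is run with a single donor type — the usual
study layout — the trial factor is confounded with donor type and the
model is automatically reduced to the donor effect, with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import ValidationError

__all__ = [
    "unbiased_sd",
    "cv_rf",
    "sem",
    "welch_test",
    "WelchResult",
    "ModelFit",
    "fit_trial_donor_model",
    "repeatability_report",
    "relative_difference",
]


def unbiased_sd(values: Sequence[float]) -> float:
    """Sample standard deviation with the n-1 denominator."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValidationError(f"unbiased SD needs n >= 2, got n = {x.size}")
    return float(np.std(x, ddof=1))


def cv_rf(values: Sequence[float]) -> float:
    """Repeatability coefficient of variation, percent: 100 * sd / mean."""
    x = np.asarray(list(values), dtype=float)
    m = x.mean()
    if m == 0:
        raise ValidationError("CV undefined: mean of values is 0")
    return 100.0 * unbiased_sd(x) / m


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean, sd / sqrt(n)."""
    x = np.asarray(list(values), dtype=float)
    return unbiased_sd(x) / np.sqrt(x.size)


def relative_difference(a: float, b: float) -> float:
    """Percent by which ``a`` exceeds ``b``: 100 * (a - b) / b."""
    if b == 0:
        raise ValidationError("relative difference undefined for reference 0")
    return 100.0 * (a - b) / b


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test (Welch-Satterthwaite degrees of freedom).

    Degenerate case: zero variance in both groups with equal means is a
    perfect non-difference and returns t = 0, p = 1 by convention.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch test needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        return WelchResult(t=float("inf"), df=float(a.size + b.size - 2), p=0.0)
    with warnings.catch_warnings():
        # near-identical groups trigger scipy's catastrophic-cancellation note
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


@dataclass
class ModelFit:
    """Outcome of the trial x donor fixed-effects analysis for one response."""

    response: str
    term_p: Dict[str, float]          # p-values from the fullest estimable model
    reduced_terms: List[str]          # terms retained after backward reduction
    donor_p: Optional[float]          # p for the donor effect (final model holding it)
    interaction_p: Optional[float]    # None when inestimable
    split_trial_p: Optional[Dict[str, float]]  # per-donor trial effect when split
    welch: Optional[WelchResult]
    warnings: List[str] = field(default_factory=list)


_TRIAL = "C(trial_id)"
_DONOR = "C(donor_type)"
_INTER = "C(trial_id):C(donor_type)"


def _anova_p(model, term: str) -> Optional[float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    if term not in tab.index:
        return None
    p = tab.loc[term, "PR(>F)"]
    return None if np.isnan(p) else float(p)


def fit_trial_donor_model(
    table: pd.DataFrame,
    alpha: float = 0.05,
    response: str = "value",
) -> ModelFit:
    """Fit and reduce the trial x donor fixed-effects model for one parameter.

    Parameters
    ----------
    table
        Long-format frame with columns ``trial_id``, ``donor_type`` and
        ``value`` (one row per trial mean, or per bottle when bottles are
        retained as replicates).
    alpha
        Significance level for term retention and interaction splitting.
    """
    df = table.rename(columns={response: "value"}) if response != "value" else table
    df = df[["trial_id", "donor_type", "value"]].copy()
    donors = df["donor_type"].unique()
    if donors.size < 2:
        raise ValidationError("trial x donor model needs both donor types present")
    notes: List[str] = []

    cells = df.groupby(["trial_id", "donor_type"], observed=True).size()
    nested = (df.groupby("trial_id")["donor_type"].nunique() == 1).all()
    replicated = (cells > 1).any()

    term_p: Dict[str, float] = {}
    interaction_p: Optional[float] = None
    split_trial_p: Optional[Dict[str, float]] = None
    donor_p: Optional[float] = None
    reduced: List[str] = []

    if nested:
        # Trial is confounded with donor type: alpha_i and (alpha beta)_ij are
        # not separable from beta_j. Reduce to the donor effect.
        notes.append(
            "trial factor nested in donor type: full model rank deficient; "
            "reduced to donor effect"
        )
        m = smf.ols("value ~ C(donor_type)", data=df).fit()
        donor_p = _anova_p(m, _DONOR)
        term_p[_DONOR] = donor_p
        reduced = [_DONOR] if donor_p is not None and donor_p < alpha else []
    else:
        if replicated:
            full = smf.ols("value ~ C(trial_id) * C(donor_type)", data=df).fit()
            interaction_p = _anova_p(full, _INTER) if full.df_resid > 0 else None
        if interaction_p is not None:
            term_p[_INTER] = interaction_p
        if interaction_p is not None and interaction_p < alpha:
            # significant interaction: split by donor type and re-test trial
            split_trial_p = {}
            for d, sub in df.groupby("donor_type", observed=True):
                if sub["trial_id"].nunique() > 1:
                    ms = smf.ols("value ~ C(trial_id)", data=sub).fit()
                    p = _anova_p(ms, _TRIAL)
                    if p is not None:
                        split_trial_p[str(d)] = p
            reduced = [_TRIAL, _DONOR, _INTER]
            m_add = smf.ols("value ~ C(trial_id) + C(donor_type)", data=df).fit()
            donor_p = _anova_p(m_add, _DONOR)
            term_p[_DONOR] = donor_p
            tp = _anova_p(m_add, _TRIAL)
            if tp is not None:
                term_p[_TRIAL] = tp
        else:
            if interaction_p is not None:
                notes.append("interaction not significant: dropped")
            m = smf.ols("value ~ C(trial_id) + C(donor_type)", data=df).fit()
            p_trial = _anova_p(m, _TRIAL)
            p_donor = _anova_p(m, _DONOR)
            if p_trial is not None:
                term_p[_TRIAL] = p_trial
            if p_donor is not None:
                term_p[_DONOR] = p_donor
            # backward reduction: drop non-significant terms
            keep_trial = p_trial is not None and p_trial < alpha
            if not keep_trial:
                m = smf.ols("value ~ C(donor_type)", data=df).fit()
                p_donor = _anova_p(m, _DONOR)
            donor_p = p_donor
            reduced = [t for t, ok in ((_TRIAL, keep_trial),) if ok]
            if donor_p is not None and donor_p < alpha:
                reduced.append(_DONOR)

    groups = [g["value"].to_numpy() for _, g in df.groupby("donor_type", observed=True)]
    welch = welch_test(groups[0], groups[1]) if all(len(g) >= 2 for g in groups) else None

    return ModelFit(
        response=response,
        term_p=term_p,
        reduced_terms=reduced,
        donor_p=donor_p,
        interaction_p=interaction_p,
        split_trial_p=split_trial_p,
        welch=welch,
        warnings=notes,
    )


def repeatability_report(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter repeatability table across fermentation trials.

    Parameters
    ----------
    per_trial
        Long-format frame with columns ``parameter``, ``trial_id``,
        ``donor_type``, ``value`` (one row per trial and parameter).

    Returns
    -------
    DataFrame with one row per parameter: per-donor n, mean, sd, SEM and
    CV_RF, plus two overall estimators — ``cv_all_pooled_means`` (CV over
    all trial means) and ``cv_all_within`` (pooled within-type SD over the
    grand mean).
    """
    rows = []
    for param, sub in per_trial.groupby("parameter", observed=True, sort=False):
        row: Dict[str, float] = {"parameter": param}
        sds, dfs = [], []
        for donor in ("RF_T", "RF_A"):
            vals = sub.loc[sub["donor_type"] == donor, "value"].to_numpy(dtype=float)
            key = donor.split("_")[1].lower()
            row[f"n_{key}"] = vals.size
            if vals.size:
                row[f"mean_{key}"] = vals.mean()
            if vals.size >= 2:
                sd = unbiased_sd(vals)
                row[f"sd_{key}"] = sd
                row[f"sem_{key}"] = sd / np.sqrt(vals.size)
                row[f"cv_{key}"] = 100.0 * sd / vals.mean() if vals.mean() != 0 else np.nan
                sds.append(sd)
                dfs.append(vals.size - 1)
        allv = sub["value"].to_numpy(dtype=float)
        if allv.size >= 2 and allv.mean() != 0:
            row["cv_all_pooled_means"] = cv_rf(allv)
            if sds:
                pooled_sd = np.sqrt(
                    sum(d * s**2 for s, d in zip(sds, dfs)) / sum(dfs)
                )
                row["cv_all_within"] = 100.0 * pooled_sd / allv.mean()
        rows.append(row)
    return pd.DataFrame(rows)
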