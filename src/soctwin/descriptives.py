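"""Descriptive statistics for twin cohorts.

Per-sex means and sample SDs with a sex-difference test whose standard
errors are clustered on twin pair (co-twins are not independent
observations), Cronbach's alpha for item-level internal consistency, and
Pearson trait correlations optionally adjusted for sex by within-sex
mean-centering (equivalent to partialling out a sex indicator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgs_association import _clustered_ols
from .synthetic_data import TwinCohort

import statsmodels.api as sm


@dataclass
class DescriptivesRow:
    """Per-sex summary of one trait with a clustered sex-difference test."""

    trait: str
    n_men: int
    mean_men: float
    sd_men: float
    n_women: int
    mean_women: float
    sd_women: float
    sex_difference_p: float
    cronbach_alpha: float | None = None


def describe_by_sex(cohort: TwinCohort, trait: str) -> DescriptivesRow:
    """Per-sex n/mean/SD and the pair-clustered sex-difference p-value.

    The p-value comes from regressing the trait on a female indicator with
    standard errors clustered on pair_id (t reference with clusters - 1
    degrees of freedom).  SDs use the n-1 denominator.
    """
    df = cohort.data[["sex", "pair_id", trait]].dropna(subset=[trait])
    if not len(df):
        raise ValueError(f"trait {trait!r} has no non-missing values")
    per = {}
    for sex in ("M", "F"):
        vals = df.loc[df["sex"] == sex, trait]
        if len(vals) < 2:
            raise ValueError(
                f"trait {trait!r}: need at least 2 non-missing values for "
                f"sex {sex}, found {len(vals)}")
        per[sex] = (len(vals), float(vals.mean()), float(vals.std(ddof=1)))
    female = (df["sex"] == "F").astype(float).to_numpy()
    X = sm.add_constant(female)
    res, _ = _clustered_ols(df[trait].to_numpy(float), X,
                            df["pair_id"].to_numpy())
    return DescriptivesRow(trait, *per["M"], *per["F"],
                           sex_difference_p=float(res.pvalues[1]))


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum of item variances / variance
    of the item sum), with n-1 variances.

    Negative values are possible for negatively correlated items and are
    returned as-is.  Raises when the total score has zero variance.
    """
    X = np.asarray(item_matrix, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an individuals x items matrix with >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if np.isnan(X).any():
        X = X[~np.isnan(X).any(axis=1)]  # listwise deletion
        if X.shape[0] < 3:
            raise ValueError("fewer than 3 complete rows after deletion")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def trait_correlations(cohort: TwinCohort, traits: list[str] | None = None,
                       adjust_for_sex: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlations of trait values across individuals.

    With ``adjust_for_sex`` the correlations are computed on within-sex
    mean-centered values.  Rows with a missing value in any requested trait
    are dropped listwise.  A constant trait raises.
    """
    traits = list(traits) if traits is not None else list(cohort.traits)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    df = cohort.data[["sex"] + traits].dropna(subset=traits)
    vals = df[traits].to_numpy(float)
    for j, t in enumerate(traits):
        if np.ptp(vals[:, j]) == 0:
            raise ValueError(f"trait {t!r} is constant; correlation undefined")
    if adjust_for_sex:
        for sex in ("M", "F"):
            mask = (df["sex"] == sex).to_numpy()
            if mask.any():
                vals[mask] -= vals[mask].mean(axis=0)
    corr = np.corrcoef(vals.T)
    return pd.DataFrame(corr, index=traits, columns=traits)


def table1(cohort: TwinCohort, traits: list[str] | None = None) -> pd.DataFrame:
    """Descriptives table: one row per trait, per-sex n/mean/SD and the
    clustered sex-difference p-value."""
    traits = list(traits) if traits is not None else list(cohort.traits)
    rows = []
    for t in traits:
        r = describe_by_sex(cohort, t)
        rows.append({"trait": t, "n_men": r.n_men, "mean_men": r.mean_men,
                     "sd_men": r.sd_men, "n_women": r.n_women,
                     "mean_women": r.mean_women, "sd_women": r.sd_women,
                     "p_sexdiff": r.sex_difference_p})
    return pd.DataFrame(rows)
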