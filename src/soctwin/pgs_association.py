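"""Polygenic-score association with pair-clustered inference.

Each polygenic score is standardized and regressed on the trait by OLS,
so the slope is the trait change per 1 SD of the score.  Because co-twins
are not independent, the slope variance uses the cluster-sandwich
estimator with the standard small-sample factor G/(G-1) * (N-1)/(N-k)
and t(G-1) reference distribution (the convention of Stata's cluster
option); with singleton clusters this reduces exactly to the HC1
heteroskedasticity-robust estimator.  The per-score R-squared is the
simple regression R-squared (the squared trait-score correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass
class PGSAssociation:
    """Standardized-score regression result for one score and stratum."""

    score: str
    stratum: str  # "men", "women" or "pooled"
    beta: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    r2: float
    n: int
    n_clusters: int
    interaction_p: float | None = None  # pooled models only


def standardize_score(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample SD (n-1 denominator) 1."""
    x = np.asarray(values, float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("standardization requires at least 2 distinct values")
    return (x - x.mean()) / x.std(ddof=1)


def _clustered_ols(y: np.ndarray, X: np.ndarray, clusters: np.ndarray):
    """OLS with Stata-style cluster-robust covariance and t(G-1) inference."""
    _, n_clusters = np.unique(clusters, return_inverse=False), len(set(clusters))
    if n_clusters < 2:
        raise ValueError("cluster-robust inference requires at least 2 clusters")
    model = sm.OLS(y, X)
    return model.fit(cov_type="cluster",
                     cov_kwds={"groups": clusters, "use_correction": True},
                     use_t=True), n_clusters


def pgs_regression_clustered(trait: np.ndarray, score: np.ndarray,
                             clusters: np.ndarray, score_name: str = "pgs",
                             stratum: str = "pooled",
                             standardize: bool = True) -> PGSAssociation:
    """Regress a trait on a (standardized) polygenic score with pair-clustered
    standard errors.

    The slope is in trait units per 1 SD of the score; the 95% CI uses the
    t distribution with (clusters - 1) degrees of freedom.
    """
    y = np.asarray(trait, float)
    s = np.asarray(score, float)
    clusters = np.asarray(clusters)
    if not len(y) == len(s) == len(clusters):
        raise ValueError("trait, score and cluster ids must have equal length")
    ok = ~(np.isnan(y) | np.isnan(s))
    y, s, clusters = y[ok], s[ok], clusters[ok]
    if standardize:
        s = standardize_score(s)
    elif np.ptp(s) == 0:
        raise ValueError("score is constant")
    X = sm.add_constant(s)
    res, n_clusters = _clustered_ols(y, X, clusters)
    lo, hi = res.conf_int()[1]
    r = np.corrcoef(y, s)[0, 1]
    return PGSAssociation(score_name, stratum, float(res.params[1]),
                          float(lo), float(hi), float(res.bse[1]),
                          float(res.pvalues[1]), float(r * r),
                          len(y), n_clusters)


def sex_interaction_test(trait: np.ndarray, score: np.ndarray,
                         sex: np.ndarray, clusters: np.ndarray,
                         standardize: bool = True) -> float:
    """Clustered Wald p-value of the sex-by-score interaction.

    Fits the pooled regression trait ~ sex + score + sex:score with
    pair-clustered standard errors and returns the interaction p-value.
    """
    y = np.asarray(trait, float)
    s = np.asarray(score, float)
    sex = np.asarray(sex)
    clusters = np.asarray(clusters)
    ok = ~(np.isnan(y) | np.isnan(s))
    y, s, sex, clusters = y[ok], s[ok], sex[ok], clusters[ok]
    levels = np.unique(sex)
    if len(levels) < 2:
        raise ValueError("sex interaction requires both sexes present")
    if standardize:
        s = standardize_score(s)
    female = (sex == levels[1]).astype(float)
    X = np.column_stack([np.ones_like(y), female, s, female * s])
    res, _ = _clustered_ols(y, X, clusters)
    return float(res.pvalues[3])


def pgs_table(cohort, trait: str, scores: list[str] | None = None,
              stratify_sex: bool = True):
    """Per-score association table (one row per score and stratum).

    Scores are standardized within the analysis stratum.  Pooled rows
    carry the sex-interaction p-value.
    """
    import pandas as pd
    scores = list(scores) if scores is not None else list(cohort.pgs_scores)
    df = cohort.data
    rows = []
    for score in scores:
        strata = [("men", df["sex"] == "M"), ("women", df["sex"] == "F")] \
            if stratify_sex else []
        strata.append(("pooled", df["sex"].notna()))
        for label, mask in strata:
            sub = df[mask]
            assoc = pgs_regression_clustered(
                sub[trait].to_numpy(), sub[score].to_numpy(),
                sub["pair_id"].to_numpy(), score_name=score, stratum=label)
            if label == "pooled":
                assoc.interaction_p = sex_interaction_test(
                    df[trait].to_numpy(), df[score].to_numpy(),
                    df["sex"].to_numpy(), df["pair_id"].to_numpy())
            rows.append(assoc)
    return pd.DataFrame([{
        "score": a.score, "sex": a.stratum, "beta": a.beta,
        "LL": a.ci_low, "UL": a.ci_high, "R2": a.r2, "p": a.p,
        "interaction_p": a.interaction_p, "n": a.n,
    } for a in rows])
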