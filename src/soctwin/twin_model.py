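"""Univariate twin structural models and their likelihood.

The classical twin design decomposes trait variance into additive genetic
(A), shared-environment (C), dominance (D) and unique-environment (E)
sources using the expected cross-twin correlations of the latent factors
(A: 1 in MZ / 0.5 in DZ; D: 1 / 0.25; C: 1 / 1; E: 0).  Models are
parameterized on raw path coefficients whose squares enter the variances,
which keeps every variance component nonnegative without bound
constraints.  The data likelihood treats each complete pair as one draw
from a bivariate normal with a group-specific mean vector and the
model-implied 2x2 covariance; it is evaluated from per-group sufficient
statistics (pair count, mean vector, scatter matrix), which is exactly
equal to the per-pair density summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import TwinCohort

_LOG_2PI = float(np.log(2.0 * np.pi))

COMPONENT_SETS = {"ACE": ("A", "C", "E"), "ADE": ("A", "D", "E"),
                  "AE": ("A", "E"), "E": ("E",)}


class IdentificationError(ValueError):
    """The requested model is not identified on the available groups."""


# --------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components are free and how sex enters.

    components: "ACE", "ADE", "AE" or "E" (E is always present; C and D
    cannot be free simultaneously in twins reared together).
    sex: "pooled" (one parameter set, opposite-sex DZ pairs pooled with DZ),
    "stratified" (independent parameter sets per sex; opposite-sex pairs
    excluded), or "sexlim" (per-sex parameter sets joined through the
    opposite-sex DZ group, whose cross-twin genetic covariance is
    0.5*rg*a_m*a_f with the cross-sex genetic correlation rg free or fixed).
    """

    components: str = "AE"
    sex: str = "pooled"
    rg: float = 1.0
    rg_free: bool = False

    def __post_init__(self) -> None:
        if self.components not in COMPONENT_SETS:
            raise ValueError(f"unknown component set {self.components!r}")
        if self.sex not in ("pooled", "stratified", "sexlim"):
            raise ValueError(f"unknown sex handling {self.sex!r}")
        if self.rg_free and self.sex != "sexlim":
            raise ValueError("rg is only free in sex-limitation models")

    @property
    def free(self) -> tuple[str, ...]:
        return COMPONENT_SETS[self.components]

    @property
    def strata(self) -> tuple[str, ...]:
        return ("pooled",) if self.sex == "pooled" else ("M", "F")

    @property
    def n_parameters(self) -> int:
        per = 1 + len(self.free)  # mean + one path per free component
        n = per * len(self.strata)
        if self.sex == "sexlim" and self.rg_free:
            n += 1
        return n

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        """Parse strings like "AE", "ACE:stratified", "AE:sexlim(rg=free)"."""
        parts = text.split(":")
        comp = parts[0].strip()
        if len(parts) == 1:
            return cls(comp)
        suffix = parts[1].strip()
        if suffix == "stratified":
            return cls(comp, sex="stratified")
        if suffix.startswith("sexlim"):
            rg_free = "rg=free" in suffix
            rg = 1.0
            if not rg_free and "rg=" in suffix:
                rg = float(suffix.split("rg=")[1].rstrip(")"))
            return cls(comp, sex="sexlim", rg=rg, rg_free=rg_free)
        raise ValueError(f"cannot parse model string {text!r}")


@dataclass
class VarianceComponents:
    """Fitted path coefficients and standardized variance proportions.

    ``paths[stratum]`` maps component letter to its raw path coefficient;
    ``proportions(stratum)`` returns the standardized a², c², d², e²
    (squared paths over total variance), which sum to one by construction.
    """

    paths: dict[str, dict[str, float]]
    rg: float = 1.0

    def total_variance(self, stratum: str = "pooled") -> float:
        return float(sum(v * v for v in self.paths[stratum].values()))

    def proportions(self, stratum: str = "pooled") -> dict[str, float]:
        tot = self.total_variance(stratum)
        out = {}
        for comp in ("A", "C", "D", "E"):
            path = self.paths[stratum].get(comp, 0.0)
            out[comp.lower() + "2"] = (path * path) / tot if tot > 0 else np.nan
        return out


@dataclass
class UnivariateFit:
    """Result of a maximum-likelihood univariate twin-model fit."""

    model: ModelSpec | str
    trait: str
    minus2LL: float
    n_parameters: int
    n_pairs: int
    components: VarianceComponents | None = None
    means: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    # internal handles reused by profile CIs
    _stats: dict = field(default_factory=dict, repr=False)
    _params: np.ndarray | None = field(default=None, repr=False)


# --------------------------------------------------------------------------
# expected covariance structure

_KA = {"MZ": 1.0, "DZss": 0.5}
_KD = {"MZ": 1.0, "DZss": 0.25}


def expected_pair_covariance(components: VarianceComponents,
                             group: tuple[str, str | None]) -> np.ndarray:
    """Model-implied 2x2 covariance of a twin pair for one group.

    ``group`` is (zygosity, stratum) as produced by
    :meth:`TwinCohort.pair_arrays`; for the opposite-sex group the male
    member is row/column 0 and the cross-twin covariance is
    0.5*rg*a_m*a_f + c_m*c_f.
    """
    zyg, stratum = group
    if zyg == "DZos":
        pm = components.paths.get("M") or components.paths["pooled"]
        pf = components.paths.get("F") or components.paths["pooled"]
        vm = sum(v * v for v in pm.values())
        vf = sum(v * v for v in pf.values())
        cov = (0.5 * components.rg * pm.get("A", 0.0) * pf.get("A", 0.0)
               + pm.get("C", 0.0) * pf.get("C", 0.0)
               + 0.25 * pm.get("D", 0.0) * pf.get("D", 0.0))
        return np.array([[vm, cov], [cov, vf]])
    p = components.paths.get(stratum or "pooled") or components.paths["pooled"]
    a2 = p.get("A", 0.0) ** 2
    c2 = p.get("C", 0.0) ** 2
    d2 = p.get("D", 0.0) ** 2
    e2 = p.get("E", 0.0) ** 2
    total = a2 + c2 + d2 + e2
    cov = _KA[zyg] * a2 + c2 + _KD[zyg] * d2
    return np.array([[total, cov], [cov, total]])


# --------------------------------------------------------------------------
# sufficient statistics and likelihood


@dataclass
class GroupStats:
    """Pair count, sample mean vector and ML scatter matrix of one group."""

    n: int
    mean: np.ndarray  # (2,)
    scatter: np.ndarray  # (2,2), ML covariance about the sample mean


def group_statistics(cohort: TwinCohort, trait: str,
                     min_pairs: int = 1) -> dict[tuple[str, str | None], GroupStats]:
    """Complete-pair sufficient statistics by (zygosity, sex) group."""
    stats = {}
    for key, arr in cohort.pair_arrays(trait).items():
        n = arr.shape[0]
        if n < min_pairs:
            continue
        mean = arr.mean(axis=0)
        dev = arr - mean
        stats[key] = GroupStats(n, mean, dev.T @ dev / n)
    return stats


def neg2_loglik_stats(stats: dict, mu: dict, sigma: dict) -> float:
    """-2 log-likelihood from sufficient statistics.

    ``mu[key]`` is the 2-vector mean and ``sigma[key]`` the 2x2 covariance
    implied for each group; exactly equals the per-pair bivariate-normal
    density summation.  A non-positive-definite implied covariance yields
    +inf (rejected by the optimizer) rather than an exception.
    """
    total = 0.0
    for key, st in stats.items():
        S = sigma[key]
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        if det <= 0 or S[0, 0] <= 0:
            return np.inf
        inv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        d = st.mean - mu[key]
        quad = float(np.einsum("ij,ij->", inv, st.scatter) + d @ inv @ d)
        total += st.n * (2.0 * _LOG_2PI + float(np.log(det)) + quad)
    return total


def implied_moments(model: ModelSpec, params: np.ndarray,
                    groups: list[tuple[str, str | None]]) -> tuple[dict, dict]:
    """Group mean vectors and covariance matrices at a parameter vector."""
    comps, means = unpack_parameters(model, params)
    mu, sigma = {}, {}
    for key in groups:
        zyg, stratum = key
        if zyg == "DZos":
            m = np.array([means.get("M", means.get("pooled")),
                          means.get("F", means.get("pooled"))])
        else:
            m_val = means.get(stratum or "pooled", means.get("pooled"))
            m = np.array([m_val, m_val])
        mu[key] = m
        sigma[key] = expected_pair_covariance(comps, key)
    return mu, sigma


def unpack_parameters(model: ModelSpec,
                      params: np.ndarray) -> tuple[VarianceComponents, dict]:
    """Split a flat parameter vector into paths per stratum and means.

    Layout per stratum: [mean, path_1, ..., path_m] in the order of
    ``model.free``; a trailing rg parameter when the sex-limitation model
    frees it.
    """
    free = model.free
    per = 1 + len(free)
    paths, means = {}, {}
    for i, stratum in enumerate(model.strata):
        block = params[i * per:(i + 1) * per]
        means[stratum] = float(block[0])
        paths[stratum] = {comp: float(b) for comp, b in zip(free, block[1:])}
    rg = model.rg
    if model.sex == "sexlim" and model.rg_free:
        rg = float(params[-1])
    return VarianceComponents(paths, rg=rg), means


def neg2_loglik(model: ModelSpec, params: np.ndarray, cohort: TwinCohort,
                trait: str) -> float:
    """-2 log-likelihood of a parameter vector on a cohort's complete pairs."""
    stats = group_statistics(cohort, trait)
    stats = select_groups(model, stats)
    mu, sigma = implied_moments(model, params, list(stats))
    return neg2_loglik_stats(stats, mu, sigma)


def select_groups(model: ModelSpec, stats: dict) -> dict:
    """Restrict/merge sufficient statistics to the groups a model uses.

    Pooled models merge the sexes within zygosity and treat opposite-sex
    pairs as DZ; stratified models drop the opposite-sex group; the
    sex-limitation model keeps all five groups.
    """
    if model.sex == "stratified":
        return {k: v for k, v in stats.items() if k[0] != "DZos"}
    if model.sex == "sexlim":
        return dict(stats)
    merged: dict[tuple[str, str | None], GroupStats] = {}
    buckets: dict[str, list[GroupStats]] = {"MZ": [], "DZss": []}
    for (zyg, _sex), st in stats.items():
        buckets["MZ" if zyg == "MZ" else "DZss"].append(st)
    for zyg, parts in buckets.items():
        if not parts:
            continue
        n = sum(p.n for p in parts)
        mean = sum(p.n * p.mean for p in parts) / n
        scat = np.zeros((2, 2))
        for p in parts:
            d = p.mean - mean
            scat += p.n * (p.scatter + np.outer(d, d))
        merged[(zyg, "pooled")] = GroupStats(n, mean, scat / n)
    return merged


# --------------------------------------------------------------------------
# saturated reference model


def saturated_model(cohort: TwinCohort, trait: str,
                    stratify_sex: bool = False) -> UnivariateFit:
    """ML fit with free means per group and birth order and free per-group
    covariance matrices — the reference model for assumption testing.

    The ML estimates are the per-cell sample means and the ML (denominator
    n) covariance matrix of each group; groups with fewer than two pairs or
    a singular sample covariance are dropped with a warning.
    """
    raw = group_statistics(cohort, trait)
    if stratify_sex:
        # same data as stratified structured fits: opposite-sex pairs excluded
        raw = {k: v for k, v in raw.items() if k[0] != "DZos"}
    if not stratify_sex:
        # keep zygosity groups separate (MZ / DZss / DZos) but merge sexes
        merged: dict = {}
        for zyg in ("MZ", "DZss", "DZos"):
            parts = [(k, v) for k, v in raw.items() if k[0] == zyg]
            if not parts:
                continue
            if zyg == "DZos":
                merged[(zyg, None)] = parts[0][1]
                continue
            n = sum(v.n for _, v in parts)
            mean = sum(v.n * v.mean for _, v in parts) / n
            scat = np.zeros((2, 2))
            for _, v in parts:
                d = v.mean - mean
                scat += v.n * (v.scatter + np.outer(d, d))
            merged[(zyg, None)] = GroupStats(n, mean, scat / n)
        raw = merged
    m2ll = 0.0
    n_par = 0
    n_pairs = 0
    means, covs = {}, {}
    flags = []
    for key, st in sorted(raw.items(), key=str):
        det = np.linalg.det(st.scatter)
        if st.n < 2 or det <= 0:
            warnings.warn(f"saturated model: dropping degenerate group {key}")
            flags.append(f"dropped:{key}")
            continue
        # ML at the sample moments: quadratic term reduces to tr(I) = 2
        m2ll += st.n * (2.0 * _LOG_2PI + float(np.log(det)) + 2.0)
        n_par += 5  # two means + three covariance elements
        n_pairs += st.n
        means[key] = st.mean.copy()
        covs[key] = st.scatter.copy()
    fit = UnivariateFit("saturated", trait, m2ll, n_par, n_pairs,
                        means={"per_group": means, "cov": covs}, flags=flags)
    fit._stats = {"groups": raw}
    return fit
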