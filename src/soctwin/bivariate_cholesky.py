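"""Bivariate AE twin model via Cholesky decomposition.

Two traits per twin give a 4-variate normal per pair, ordered
(trait1 twin1, trait2 twin1, trait1 twin2, trait2 twin2).  Additive
genetic and unique-environment (co)variation are parameterized by
lower-triangular path matrices A and E: within-person blocks are
A·Aᵀ + E·Eᵀ and cross-twin blocks k·A·Aᵀ with k = 1 (MZ) or 0.5 (DZ).
From the fitted paths follow the genetic correlation rA, the
unique-environment correlation rE, and the decomposition of the
phenotypic correlation r = rA·√(h1²·h2²) + rE·√(e1²·e2²) into the
fractions contributed by genes and by unique environment.  Shared
environment and dominance are omitted (AE structure), the configuration
retained by the univariate model-selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .synthetic_data import TwinCohort

_LOG_2PI = float(np.log(2.0 * np.pi))
_K_CROSS = {"MZ": 1.0, "DZss": 0.5, "DZos": 0.5}


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in a component)."""


# --------------------------------------------------------------------------
# types


@dataclass
class CholeskyPaths:
    """Lower-triangular A and E path matrices (2x2) for one stratum."""

    A: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        self.E = np.asarray(self.E, float)

    @classmethod
    def from_vector(cls, v) -> "CholeskyPaths":
        a11, a21, a22, e11, e21, e22 = v
        return cls(np.array([[a11, 0.0], [a21, a22]]),
                   np.array([[e11, 0.0], [e21, e22]]))

    @property
    def genetic_covariance(self) -> np.ndarray:
        return self.A @ self.A.T

    @property
    def environment_covariance(self) -> np.ndarray:
        return self.E @ self.E.T

    @property
    def total_covariance(self) -> np.ndarray:
        return self.genetic_covariance + self.environment_covariance


@dataclass
class BivariateDecomposition:
    """Derived correlations and explained fractions for one stratum.

    fracA and fracE sum to 1 when defined and may individually exceed 1
    (or be negative) when the genetic and environmental contributions to
    the phenotypic correlation have opposite signs; they are not clamped.
    """

    r: float
    rA: float
    rE: float
    fracA: float
    fracE: float
    h2: tuple[float, float]
    e2: tuple[float, float]
    r_ci: tuple[float, float] | None = None
    rA_ci: tuple[float, float] | None = None
    rE_ci: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class BivariateFit:
    """ML fit of the bivariate AE Cholesky model."""

    trait1: str
    trait2: str
    stratum: str
    paths: CholeskyPaths
    means: tuple[float, float]
    decomposition: BivariateDecomposition
    minus2LL: float
    n_pairs: int
    converged: bool = True


# --------------------------------------------------------------------------
# expected covariance


def expected_quad_covariance(paths: CholeskyPaths, group: str) -> np.ndarray:
    """Model-implied 4x4 pair covariance for one zygosity group."""
    within = paths.total_covariance
    cross = _K_CROSS[group] * paths.genetic_covariance
    return np.block([[within, cross], [cross, within]])


# --------------------------------------------------------------------------
# derived quantities


def genetic_correlation_from_paths(a11: float, a21: float, a22: float) -> float:
    """rA from the lower-triangular A paths: A-covariance over the geometric
    mean of the A-variances."""
    va1 = a11 * a11
    va2 = a21 * a21 + a22 * a22
    if va1 <= 0 or va2 <= 0:
        raise UndefinedCorrelationError(
            "genetic correlation undefined: a trait has zero genetic variance")
    return float(a11 * a21 / (abs(a11) * np.sqrt(va2)))


def decompose_trait_correlation(h2_1: float, h2_2: float, e2_1: float,
                                e2_2: float, rA: float, rE: float,
                                tol: float = 0.02):
    """Reassemble r = rA·√(h1²h2²) + rE·√(e1²e2²) and the explained fractions.

    Accepts standardized components that sum to 1 within ``tol`` per trait
    (printed two-decimal table values qualify).  Returns (r, fracA, fracE);
    when r = 0 the fractions are undefined and returned as NaN with a
    warning.
    """
    for label, h2, e2 in (("trait1", h2_1, e2_1), ("trait2", h2_2, e2_2)):
        if abs(h2 + e2 - 1.0) > tol:
            raise ValueError(
                f"{label}: standardized components sum to {h2 + e2}, not 1")
    if not (-1.0 <= rA <= 1.0 and -1.0 <= rE <= 1.0):
        raise ValueError("rA and rE must lie in [-1, 1]")
    gen = rA * np.sqrt(h2_1 * h2_2)
    env = rE * np.sqrt(e2_1 * e2_2)
    r = gen + env
    if r == 0.0:
        warnings.warn("phenotypic correlation is zero; explained fractions "
                      "are undefined")
        return 0.0, float("nan"), float("nan")
    fracA = gen / r
    return float(r), float(fracA), float(1.0 - fracA)


def shared_variance_fraction(rA: float) -> float:
    """Fraction of one trait's additive-genetic variance shared with the
    other: rA² (an even function of rA)."""
    if not -1.0 <= rA <= 1.0:
        raise ValueError("rA must lie in [-1, 1]")
    return float(rA * rA)


def shared_variance_percent(rA: float) -> int:
    """rA² as an integer-rounded percentage (report-layer convention)."""
    return int(round(100.0 * shared_variance_fraction(rA)))


# --------------------------------------------------------------------------
# sufficient statistics and likelihood


@dataclass
class QuadStats:
    n: int
    mean: np.ndarray  # (4,)
    scatter: np.ndarray  # (4,4)


def quad_statistics(cohort: TwinCohort, trait1: str, trait2: str,
                    stratify_sex: bool = False) -> dict[str, dict[str, QuadStats]]:
    """Per-stratum, per-zygosity sufficient statistics of the pair 4-vector.

    Pooled mode merges the sexes and treats opposite-sex DZ pairs as DZ;
    stratified mode returns separate "M"/"F" strata without the
    opposite-sex group.
    """
    wide = cohort.pair_table([trait1, trait2])
    cols = [f"{trait1}_1", f"{trait2}_1", f"{trait1}_2", f"{trait2}_2"]

    def stats_of(sub) -> QuadStats | None:
        if len(sub) < 2:
            return None
        arr = sub[cols].to_numpy(float)
        mean = arr.mean(axis=0)
        dev = arr - mean
        return QuadStats(arr.shape[0], mean, dev.T @ dev / arr.shape[0])

    out: dict[str, dict[str, QuadStats]] = {}
    if stratify_sex:
        for sex, label in (("M", "M"), ("F", "F")):
            stratum = {}
            for zyg in ("MZ", "DZss"):
                st = stats_of(wide[(wide["zygosity"] == zyg)
                                   & (wide["sex_1"] == sex)])
                if st is not None:
                    stratum[zyg] = st
            out[label] = stratum
    else:
        stratum = {}
        st = stats_of(wide[wide["zygosity"] == "MZ"])
        if st is not None:
            stratum["MZ"] = st
        st = stats_of(wide[wide["zygosity"].isin(["DZss", "DZos"])])
        if st is not None:
            stratum["DZss"] = st
        out["pooled"] = stratum
    return out


_INFEASIBLE = 1e12  # finite stand-in for +inf keeps quasi-Newton gradients clean


def _neg2_loglik_quad(stats: dict[str, QuadStats], mu: np.ndarray,
                      paths: CholeskyPaths) -> float:
    total = 0.0
    for zyg, st in stats.items():
        S = expected_quad_covariance(paths, zyg)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        inv = np.linalg.inv(S)
        d = st.mean - mu
        quad = float(np.einsum("ij,ij->", inv, st.scatter) + d @ inv @ d)
        total += st.n * (4.0 * _LOG_2PI + logdet + quad)
    return total


# --------------------------------------------------------------------------
# fitting


def _fit_stratum(stats: dict[str, QuadStats], trait1: str, trait2: str,
                 stratum: str, ci: bool = True,
                 level: float = 0.95) -> BivariateFit:
    if "MZ" not in stats or "DZss" not in stats:
        raise ValueError(
            f"stratum {stratum!r}: bivariate AE fit needs both MZ and DZ "
            "complete pairs for both traits")

    def objective(x: np.ndarray) -> float:
        mu = np.array([x[0], x[1], x[0], x[1]])
        val = _neg2_loglik_quad(stats, mu, CholeskyPaths.from_vector(x[2:]))
        return val if np.isfinite(val) else _INFEASIBLE

    # moment-based starts: split the phenotypic covariance between A and E
    n_tot = sum(st.n for st in stats.values())
    mean = sum(st.n * st.mean for st in stats.values()) / n_tot
    pheno = np.zeros((2, 2))
    for st in stats.values():
        d = (st.mean - mean).reshape(2, 2).mean(axis=0)
        within = 0.5 * (st.scatter[:2, :2] + st.scatter[2:, 2:])
        pheno += st.n * (within + np.outer(d, d))
    pheno /= n_tot
    mu0 = 0.5 * (mean[:2] + mean[2:])

    starts = []
    for wa in (0.5, 0.8, 0.2):
        try:
            La = np.linalg.cholesky(wa * pheno + 1e-8 * np.eye(2))
            Le = np.linalg.cholesky((1 - wa) * pheno + 1e-8 * np.eye(2))
        except np.linalg.LinAlgError:
            continue
        starts.append(np.concatenate([
            mu0, [La[0, 0], La[1, 0], La[1, 1], Le[0, 0], Le[1, 0], Le[1, 1]]]))
    results = []
    eps = 1e-10
    bounds = [(None, None)] * 2 + [(eps, None), (None, None), (None, None),
                                   (eps, None), (None, None), (None, None)]
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-13, "gtol": 1e-8,
                                         "maxiter": 2000})
        if np.isfinite(res.fun) and res.fun < _INFEASIBLE:
            results.append(res)
    if not results:
        raise RuntimeError(f"bivariate fit failed for stratum {stratum!r}")
    best = min(results, key=lambda r: r.fun)
    x = best.x.copy()
    x[4] = abs(x[4])  # a22, e22 sign convention
    x[7] = abs(x[7])
    paths = CholeskyPaths.from_vector(x[2:])
    decomp = _decomposition_from_paths(paths)
    fit_out = BivariateFit(trait1, trait2, stratum, paths,
                           (float(x[0]), float(x[1])), decomp,
                           float(best.fun), n_tot, bool(best.success))
    if ci:
        decomp.rA_ci = _profile_corr_ci(stats, x, best.fun, "A", level)
        decomp.rE_ci = _profile_corr_ci(stats, x, best.fun, "E", level)
        decomp.r_ci = _wald_r_ci(stats, x, level)
    return fit_out


def _decomposition_from_paths(paths: CholeskyPaths) -> BivariateDecomposition:
    VA, VE = paths.genetic_covariance, paths.environment_covariance
    V = VA + VE
    flags = []
    h2 = (VA[0, 0] / V[0, 0], VA[1, 1] / V[1, 1])
    e2 = (VE[0, 0] / V[0, 0], VE[1, 1] / V[1, 1])
    r = V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])

    def corr(M, label):
        denom = np.sqrt(M[0, 0] * M[1, 1])
        if denom <= 0:
            flags.append(f"zero-{label}-variance")
            return float("nan")
        return float(M[0, 1] / denom)

    rA = corr(VA, "A")
    rE = corr(VE, "E")
    gen = rA * np.sqrt(h2[0] * h2[1]) if np.isfinite(rA) else 0.0
    if r != 0 and np.isfinite(r):
        fracA = gen / r
        fracE = 1.0 - fracA
    else:
        flags.append("zero-phenotypic-correlation")
        fracA = fracE = float("nan")
    return BivariateDecomposition(float(r), rA, rE, float(fracA), float(fracE),
                                  tuple(map(float, h2)), tuple(map(float, e2)),
                                  flags=flags)


def _constrained_objective(stats, which: str, r_fixed: float):
    """Objective over [mu1, mu2, s1, s2, p11, p21, p22] with the chosen
    component's correlation fixed: its path block is rebuilt from the two
    component SDs (s1, s2 > 0) and the fixed correlation."""

    def make_paths(x: np.ndarray) -> CholeskyPaths:
        s1, s2 = abs(x[2]), abs(x[3])
        block = np.array([[s1, 0.0],
                          [r_fixed * s2, s2 * np.sqrt(max(0.0, 1 - r_fixed**2))]])
        other = np.array([[x[4], 0.0], [x[5], x[6]]])
        return (CholeskyPaths(block, other) if which == "A"
                else CholeskyPaths(other, block))

    def objective(x: np.ndarray) -> float:
        mu = np.array([x[0], x[1], x[0], x[1]])
        val = _neg2_loglik_quad(stats, mu, make_paths(x))
        return val if np.isfinite(val) else _INFEASIBLE

    return objective


def _profile_corr_ci(stats, x_hat: np.ndarray, m2ll: float, which: str,
                     level: float, tol: float = 1e-3) -> tuple[float, float]:
    """Profile-likelihood CI for rA or rE by bisection on the correlation.

    Each profiled point re-minimizes the remaining seven parameters by
    L-BFGS-B, warm-started from the neighbouring solution, so the
    bisection stays cheap.
    """
    paths = CholeskyPaths.from_vector(x_hat[2:])
    M = (paths.genetic_covariance if which == "A"
         else paths.environment_covariance)
    denom = np.sqrt(M[0, 0] * M[1, 1])
    if denom <= 0:
        return (float("nan"), float("nan"))
    point = float(np.clip(M[0, 1] / denom, -1.0, 1.0))
    other = (paths.E if which == "A" else paths.A)
    x_mle = np.array([x_hat[0], x_hat[1],
                      max(np.sqrt(M[0, 0]), 1e-6),
                      max(np.sqrt(M[1, 1]), 1e-6),
                      other[0, 0], other[1, 0], other[1, 1]])
    warm = {"x": x_mle.copy()}
    cutoff = m2ll + float(sps.chi2.ppf(level, 1))
    bounds = [(None, None)] * 2 + [(1e-8, None)] * 2 + \
        [(1e-8, None), (None, None), (None, None)]
    opts = {"ftol": 1e-11, "gtol": 1e-6, "maxiter": 300}

    def prof(r0: float) -> float:
        obj = _constrained_objective(stats, which, r0)
        res = optimize.minimize(obj, warm["x"], method="L-BFGS-B",
                                bounds=bounds, options=opts)
        best = float(res.fun)
        # the warm start can sit in a bad basin after a jump; retry from
        # the MLE-based start before declaring the point outside the region
        if not np.isfinite(best) or best > cutoff:
            res2 = optimize.minimize(obj, x_mle, method="L-BFGS-B",
                                     bounds=bounds, options=opts)
            if np.isfinite(res2.fun) and res2.fun < best:
                res, best = res2, float(res2.fun)
        if np.isfinite(best) and best <= cutoff + 10.0:
            warm["x"] = res.x
        return best

    def bound(outside: float, inside: float) -> float:
        lo, hi = outside, inside
        if prof(outside) <= cutoff:
            return outside
        for _ in range(40):
            if abs(hi - lo) < tol:
                break
            mid = 0.5 * (lo + hi)
            if prof(mid) > cutoff:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    low = bound(-1.0 + 1e-6, point)
    warm["x"] = x_mle.copy()
    high = bound(1.0 - 1e-6, point)
    low = -1.0 if low <= -1.0 + 1e-5 else low
    high = 1.0 if high >= 1.0 - 1e-5 else high
    return (float(min(low, point)), float(max(high, point)))


def _wald_r_ci(stats, x_hat: np.ndarray, level: float) -> tuple[float, float]:
    """Delta-method CI for the phenotypic correlation implied by the fit.

    Uses the numerical Hessian of the -2lnL at the MLE (parameter
    covariance = 2·H⁻¹) and the numerical gradient of r."""

    def objective(x: np.ndarray) -> float:
        mu = np.array([x[0], x[1], x[0], x[1]])
        return _neg2_loglik_quad(stats, mu, CholeskyPaths.from_vector(x[2:]))

    def r_of(x: np.ndarray) -> float:
        V = CholeskyPaths.from_vector(x[2:]).total_covariance
        return float(V[0, 1] / np.sqrt(V[0, 0] * V[1, 1]))

    n = len(x_hat)
    h = 1e-4 * np.maximum(np.abs(x_hat), 1.0)
    H = np.zeros((n, n))
    f0 = objective(x_hat)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = objective(x_hat + ei + ej)
            fpm = objective(x_hat + ei - ej)
            fmp = objective(x_hat - ei + ej)
            fmm = objective(x_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return (float("nan"), float("nan"))
    grad = np.zeros(n)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        grad[i] = (r_of(x_hat + ei) - r_of(x_hat - ei)) / (2 * h[i])
    var = float(grad @ cov @ grad)
    if var < 0:
        return (float("nan"), float("nan"))
    z = float(sps.norm.ppf(0.5 + level / 2))
    r0 = r_of(x_hat)
    return (max(-1.0, r0 - z * np.sqrt(var)), min(1.0, r0 + z * np.sqrt(var)))


def fit_bivariate(cohort: TwinCohort, trait1: str, trait2: str,
                  stratify_sex: bool = False, ci: bool = True,
                  level: float = 0.95) -> dict[str, BivariateFit]:
    """ML fit of the bivariate AE Cholesky model.

    Returns one :class:`BivariateFit` per stratum ("pooled", or "M"/"F"
    when stratified).  Profile-likelihood CIs are computed for rA and rE;
    the phenotypic-correlation CI is delta-method based.
    """
    all_stats = quad_statistics(cohort, trait1, trait2, stratify_sex)
    out = {}
    for stratum, stats in all_stats.items():
        out[stratum] = _fit_stratum(stats, trait1, trait2, stratum,
                                    ci=ci, level=level)
    return out
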