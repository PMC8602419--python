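"""Maximum-likelihood estimation, model selection and confidence intervals.

Fitting minimizes the -2 log-likelihood over raw path coefficients by
quasi-Newton (L-BFGS-B) iteration from three fixed deterministic starting
points (equal split, A-heavy, E-heavy), so repeated fits of the same data
are identical.  Model selection follows the usual twin-study sequence:
fit ACE and ADE, keep the one with the lower -2lnL, then test the
parsimonious AE model against it and against the saturated reference by
likelihood-ratio chi-square tests.  Likelihood-ratio p-values for variance
components are reported against the plain chi-square reference; because a
variance component sits on the boundary of its parameter space under the
null, the 50:50 chi-square-mixture p-value is attached alongside for
single-df comparisons.  Confidence intervals for standardized proportions
are profile-likelihood based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .synthetic_data import TwinCohort
from .twin_model import (
    _LOG_2PI,
    GroupStats,
    IdentificationError,
    ModelSpec,
    UnivariateFit,
    group_statistics,
    implied_moments,
    neg2_loglik_stats,
    saturated_model,
    select_groups,
    unpack_parameters,
)

#: deterministic variance-share starting points (share of the heavy
#: component; the remainder is split equally among the others)
_START_SHARES = (None, ("A", 0.7), ("E", 0.7))
_START_RG = (0.5, 0.9, 0.1)


class ConvergenceError(RuntimeError):
    """All optimizer restarts failed to converge."""

    def __init__(self, message: str, best: float = np.nan):
        super().__init__(message)
        self.best_objective = best


# --------------------------------------------------------------------------
# fitting


def _check_identified(model: ModelSpec, stats: dict) -> None:
    if len(model.free) == 1:  # E-only needs any data
        if not stats:
            raise IdentificationError("no complete pairs available")
        return
    strata = model.strata if model.sex == "stratified" else (None,)
    for stratum in strata:
        def has(zygs):
            return any(k[0] in zygs and st.n >= 2
                       and (stratum is None or k[1] == stratum)
                       for k, st in stats.items())
        mz = has(("MZ",))
        dz = has(("DZss", "DZos"))
        if not (mz and dz):
            where = f" for sex {stratum}" if stratum else ""
            raise IdentificationError(
                f"separating {'/'.join(model.free[:-1])} from E requires both "
                f"MZ and DZ pairs{where} (MZ present: {mz}, DZ present: {dz})")


def _data_scale(stats: dict) -> tuple[float, float]:
    """Pooled mean and variance of all individuals in the statistics."""
    n_tot = sum(2 * st.n for st in stats.values())
    mean = sum(st.n * st.mean.sum() for st in stats.values()) / n_tot
    var = 0.0
    for st in stats.values():
        d = st.mean - mean
        var += st.n * (np.trace(st.scatter) + d @ d)
    return mean, var / n_tot


def _start_vector(model: ModelSpec, stats: dict, heavy) -> np.ndarray:
    free = model.free
    params = []
    for stratum in model.strata:
        sub = {k: v for k, v in stats.items()
               if model.sex == "pooled" or k[1] in (stratum, None)}
        m0, v0 = _data_scale(sub if sub else stats)
        shares = {c: 1.0 / len(free) for c in free}
        if heavy is not None and heavy[0] in shares and len(free) > 1:
            comp, w = heavy
            rest = (1.0 - w) / (len(free) - 1)
            shares = {c: (w if c == comp else rest) for c in free}
        params.append(m0)
        params.extend(np.sqrt(shares[c] * v0) for c in free)
    return np.array(params, float)


def fit(model: ModelSpec, cohort: TwinCohort, trait: str) -> UnivariateFit:
    """Fit a univariate twin model by maximum likelihood.

    Uses complete pairs only (singletons are removed from the likelihood,
    matching the cohort-filtering convention).  Raises
    :class:`IdentificationError` before optimization when the available
    zygosity groups cannot separate the requested components, and
    :class:`ConvergenceError` when no restart converges.
    """
    if isinstance(model, str):
        model = ModelSpec.from_string(model)
    stats = select_groups(model, group_statistics(cohort, trait))
    _check_identified(model, stats)
    keys = list(stats)

    def objective(params: np.ndarray) -> float:
        mu, sigma = implied_moments(model, params, keys)
        return neg2_loglik_stats(stats, mu, sigma)

    n_base = (1 + len(model.free)) * len(model.strata)
    results = []
    for heavy, rg0 in zip(_START_SHARES, _START_RG):
        x0 = _start_vector(model, stats, heavy)
        bounds = [(None, None)] * n_base
        if model.sex == "sexlim" and model.rg_free:
            x0 = np.append(x0, rg0)
            bounds.append((0.0, 1.0))
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-7,
                                         "maxiter": 1000})
        if np.isfinite(res.fun):
            results.append(res)
    if not results:
        raise ConvergenceError(f"no restart converged for {model} on {trait!r}")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    flags = []
    if len(results) > 1 and results[1].fun - best.fun > 1e-4:
        flags.append("restart-instability")
    if not best.success:
        flags.append("optimizer-warning")

    params = best.x.copy()
    # canonicalize path signs (components are squares; report paths >= 0)
    per = 1 + len(model.free)
    for i in range(len(model.strata)):
        params[i * per + 1:(i + 1) * per] = np.abs(params[i * per + 1:(i + 1) * per])
    comps, means = unpack_parameters(model, params)
    n_pairs = sum(st.n for st in stats.values())
    out = UnivariateFit(model, trait, float(best.fun), model.n_parameters,
                        n_pairs, components=comps, means=means,
                        converged=bool(best.success), flags=flags)
    out._stats = {"groups": stats}
    out._params = params
    return out


# --------------------------------------------------------------------------
# likelihood-ratio comparison


@dataclass
class ModelComparison:
    """Likelihood-ratio test of a nested against a full model."""

    full: UnivariateFit
    nested: UnivariateFit
    chi2: float
    df: int
    p: float
    p_mixture: float | None = None  # 50:50 chi-bar-square, single-df only
    label: str = ""


def _component_names(fit_obj: UnivariateFit) -> set[str] | None:
    if isinstance(fit_obj.model, ModelSpec):
        return set(fit_obj.model.free)
    return None  # saturated: superset of everything


def compare(full: UnivariateFit, nested: UnivariateFit,
            label: str = "") -> ModelComparison:
    """Chi-square difference test of nested against full.

    Requires the nested model's free components to be a subset of the
    full model's (the saturated model encloses every structured model)
    and the two fits to use the same pairs.
    """
    f_comp, n_comp = _component_names(full), _component_names(nested)
    if f_comp is not None and n_comp is not None and not n_comp <= f_comp:
        raise ValueError(
            f"models are not nested: {sorted(n_comp)} is not a subset "
            f"of {sorted(f_comp)}")
    if n_comp is None and f_comp is not None:
        raise ValueError("the saturated model cannot be the nested model")
    if full.n_pairs != nested.n_pairs:
        raise ValueError("fits use different numbers of pairs")
    df = full.n_parameters - nested.n_parameters
    if df < 0:
        raise ValueError("nested model has more parameters than the full model")
    chi2 = max(0.0, nested.minus2LL - full.minus2LL)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 <= 1e-8 else 0.0)
    p_mix = None
    if df == 1:
        p_mix = 0.5 * float(sps.chi2.sf(chi2, 1)) + (0.5 if chi2 == 0 else 0.0)
    return ModelComparison(full, nested, chi2, df, p, p_mix, label)


# --------------------------------------------------------------------------
# model-selection sequence


@dataclass
class SelectionResult:
    """Fits and likelihood-ratio tests of the model-selection sequence."""

    fits: dict[str, UnivariateFit]
    comparisons: list[ModelComparison]
    chosen_full: str  # "ACE" or "ADE"
    flags: list[str] = field(default_factory=list)

    def report(self):
        import pandas as pd
        rows = []
        for comp in self.comparisons:
            full_name = (comp.full.model.components
                         if isinstance(comp.full.model, ModelSpec)
                         else str(comp.full.model))
            nested_name = (comp.nested.model.components
                           if isinstance(comp.nested.model, ModelSpec)
                           else str(comp.nested.model))
            rows.append({
                "comparison": comp.label or f"{nested_name} vs {full_name}",
                "minus2LL_full": comp.full.minus2LL,
                "minus2LL_nested": comp.nested.minus2LL,
                "chi2": comp.chi2, "df": comp.df, "p": comp.p,
            })
        return pd.DataFrame(rows)


def selection_sequence(cohort: TwinCohort, trait: str,
                       stratify_sex: bool = False) -> SelectionResult:
    """Run the standard selection sequence for one trait.

    Fits the saturated, ACE and ADE models; keeps whichever of ACE/ADE has
    the lower -2lnL (exact tie resolved to ACE and flagged); then tests AE
    against the retained full model and against the saturated reference.
    """
    mode = "stratified" if stratify_sex else "pooled"
    sat = saturated_model(cohort, trait, stratify_sex=stratify_sex)
    fits = {"saturated": sat}
    for name in ("ACE", "ADE", "AE"):
        fits[name] = fit(ModelSpec(name, sex=mode), cohort, trait)
    flags = []
    if fits["ACE"].minus2LL <= fits["ADE"].minus2LL:
        chosen = "ACE"
        if fits["ACE"].minus2LL == fits["ADE"].minus2LL:
            flags.append("ACE/ADE tie; ACE retained")
    else:
        chosen = "ADE"
    comparisons = [
        compare(fits[chosen], fits["AE"], label=f"AE vs {chosen}"),
        compare(sat, fits["AE"], label="AE vs saturated"),
    ]
    return SelectionResult(fits, comparisons, chosen, flags)


# --------------------------------------------------------------------------
# multiple testing


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha/k."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / k


# --------------------------------------------------------------------------
# profile-likelihood confidence intervals


@dataclass
class ProfileCI:
    """Profile-likelihood interval for a standardized proportion."""

    low: float
    high: float
    level: float
    flags: list[str] = field(default_factory=list)


def _ae_profile_closed_form(stats_items: list, p: float) -> float:
    """Exact profiled -2lnL of an AE model at fixed a-squared proportion p.

    For fixed p the implied pair correlation is p (MZ) or p/2 (DZ); the
    free mean and total variance then have closed-form ML solutions through
    the exchangeable-correlation GLS identities, so no inner optimization
    is needed.
    """
    if not 0.0 <= p < 1.0:
        return np.inf
    rho = {"MZ": p, "DZss": 0.5 * p, "DZos": 0.5 * p}
    num = den = 0.0
    for key, st in stats_items:
        r = rho[key[0]]
        num += st.n * st.mean.sum() / (1.0 + r)
        den += 2.0 * st.n / (1.0 + r)
    mu = num / den
    q_total = 0.0
    n_total = 0
    logdet = 0.0
    for key, st in stats_items:
        r = rho[key[0]]
        inv = np.array([[1.0, -r], [-r, 1.0]]) / (1.0 - r * r)
        d = st.mean - mu
        q_total += st.n * (np.einsum("ij,ij->", inv, st.scatter) + d @ inv @ d)
        n_total += st.n
        logdet += st.n * np.log(1.0 - r * r)
    v = q_total / (2.0 * n_total)
    if v <= 0:
        return np.inf
    return (n_total * (2.0 * _LOG_2PI + 2.0 * np.log(v))
            + logdet + q_total / v)


def _profile_objective(fit_obj: UnivariateFit, component: str,
                       stratum: str):
    """Profiled -2lnL as a function of one standardized proportion.

    AE models profile in closed form (per stratum; stratified AE
    likelihoods factorize over the sexes, so the other sex contributes its
    unconstrained minimum).  Other models re-minimize numerically over the
    remaining free parameters with the target proportion fixed.
    """
    model: ModelSpec = fit_obj.model
    stats = fit_obj._stats["groups"]
    comp_letter = component[0].upper()
    if model.components == "AE" and model.sex in ("pooled", "stratified"):
        mine = [(k, v) for k, v in stats.items()
                if model.sex == "pooled" or k[1] == stratum]
        mine_keys = {k for k, _ in mine}
        others = [(k, v) for k, v in stats.items() if k not in mine_keys]
        const = 0.0
        if others:
            # unconstrained minimum of the other stratum's factorized block
            res = optimize.minimize_scalar(
                lambda p: _ae_profile_closed_form(others, p),
                bounds=(0.0, 1.0 - 1e-9), method="bounded",
                options={"xatol": 1e-10})
            const = float(res.fun)

        if comp_letter == "A":
            return lambda p: _ae_profile_closed_form(mine, p) + const
        return lambda p: _ae_profile_closed_form(mine, 1.0 - p) + const

    # general numeric path
    free = model.free
    per = 1 + len(free)
    strata = list(model.strata)
    s_idx = strata.index(stratum if stratum in strata else "pooled")
    c_idx = free.index(comp_letter)
    others_idx = [i for i in range(len(free)) if i != c_idx]
    keys = list(stats)

    def prof(p: float) -> float:
        if not 0.0 <= p <= 1.0:
            return np.inf

        def reduced_objective(x: np.ndarray) -> float:
            # x: per-stratum blocks; target stratum block = [mean, v, (theta)]
            params = np.empty(len(strata) * per
                              + (1 if model.sex == "sexlim" and model.rg_free
                                 else 0))
            xi = 0
            for i in range(len(strata)):
                base = i * per
                if i == s_idx:
                    mean, v = x[xi], abs(x[xi + 1])
                    xi += 2
                    if len(others_idx) == 2:
                        theta = min(max(x[xi], 0.0), 1.0)
                        xi += 1
                        shares = {c_idx: p,
                                  others_idx[0]: theta * (1 - p),
                                  others_idx[1]: (1 - theta) * (1 - p)}
                    else:
                        shares = {c_idx: p, others_idx[0]: 1 - p}
                    params[base] = mean
                    for j in range(len(free)):
                        params[base + 1 + j] = np.sqrt(shares[j] * v)
                else:
                    params[base:base + per] = x[xi:xi + per]
                    xi += per
            if model.sex == "sexlim" and model.rg_free:
                params[-1] = min(max(x[-1], 0.0), 1.0)
            mu, sigma = implied_moments(model, params, keys)
            return neg2_loglik_stats(stats, mu, sigma)

        # start from the fitted solution
        x0 = []
        fitted = fit_obj._params
        for i in range(len(strata)):
            base = i * per
            if i == s_idx:
                v_hat = float(np.sum(fitted[base + 1:base + per] ** 2))
                x0.extend([fitted[base], max(v_hat, 1e-8)])
                if len(others_idx) == 2:
                    o1 = fitted[base + 1 + others_idx[0]] ** 2
                    o2 = fitted[base + 1 + others_idx[1]] ** 2
                    x0.append(o1 / (o1 + o2) if o1 + o2 > 0 else 0.5)
            else:
                x0.extend(fitted[base:base + per])
        if model.sex == "sexlim" and model.rg_free:
            x0.append(fitted[-1])
        res = optimize.minimize(reduced_objective, np.array(x0),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-9,
                                         "maxiter": 4000})
        return float(res.fun)

    return prof


def profile_ci(fit_obj: UnivariateFit, component: str = "a2",
               stratum: str | None = None, level: float = 0.95,
               tol: float = 1e-5) -> ProfileCI:
    """Profile-likelihood CI for a standardized variance proportion.

    The interval is the set of proportion values whose profiled -2lnL lies
    within the chi-square(1) quantile of the fit's minimum, found by
    bisection on each side and clipped to [0, 1]; estimates pinned at a
    boundary yield a one-sided interval with a flag.
    """
    model = fit_obj.model
    if not isinstance(model, ModelSpec):
        raise ValueError("profile CIs require a structured-model fit")
    stratum = stratum or model.strata[0]
    point = fit_obj.components.proportions(stratum)[component]
    prof = _profile_objective(fit_obj, component, stratum)
    flags: list[str] = []

    # reference the exact profile minimum where it is cheap to locate
    base = min(fit_obj.minus2LL, prof(point))
    if model.components == "AE" and model.sex in ("pooled", "stratified"):
        res = optimize.minimize_scalar(prof, bounds=(0.0, 1.0 - 1e-9),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if res.fun < base:
            base, point = float(res.fun), float(res.x)
    cutoff = base + float(sps.chi2.ppf(level, 1))

    def bound(lo: float, hi: float) -> float:
        """Bisect for prof == cutoff; lo is outside the region, hi inside."""
        for _ in range(200):
            if abs(hi - lo) < tol:
                break
            mid = 0.5 * (lo + hi)
            if prof(mid) > cutoff:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if point <= tol or prof(0.0) <= cutoff:
        low = 0.0
        if point <= tol:
            flags.append("boundary-low")
    else:
        low = bound(0.0, point)
    if point >= 1.0 - tol or prof(1.0 - 1e-12) <= cutoff:
        high = 1.0
        if point >= 1.0 - tol:
            flags.append("boundary-high")
    else:
        high = bound(1.0, point)
    low, high = max(0.0, min(low, point)), min(1.0, max(high, point))
    ci = ProfileCI(low, high, level, flags)
    fit_obj.ci[(stratum, component)] = ci
    return ci
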