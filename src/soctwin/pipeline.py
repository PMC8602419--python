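"""End-to-end pipeline: simulate/load -> descriptives -> univariate ->
bivariate Cholesky -> polygenic scores, from a single configuration.

Writes five tables (descriptives, univariate variance components,
bivariate correlation decomposition, PGS associations, and the model-fit
comparisons) in two forms: a human-readable CSV rounded at conventional
reporting precision (proportions and correlations to 2 decimals, p-values
to 4 or "<0.001") and a full-precision machine-readable twin with the
``_raw`` suffix.  A log records the seed, pair counts and singletons
removed, so a run is reproducible from its log alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bivariate_cholesky import fit_bivariate
from .descriptives import table1, trait_correlations
from .estimation import bonferroni_threshold, fit, profile_ci, selection_sequence
from .pgs_association import pgs_table
from .synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    TraitSpec,
    TwinCohort,
    attach_pgs,
    complete_pairs,
    simulate_cohort,
)
from .twin_model import ModelSpec


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` / ``simulate`` must be given.
    """

    out_dir: str
    seed: int = 0
    input_path: str | None = None
    simulate: SimulationConfig | None = None
    pgs: dict = field(default_factory=dict)  # name -> {trait, r2}
    traits: list[str] | None = None
    soc_trait: str = "soc"
    stratify_sex: bool = True
    ci: str = "profile"  # or "none"
    alpha: float = 0.05
    n_tests: int | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ConfigurationError(
                "exactly one of input_path / simulate must be provided")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            traits = {}
            for name, spec in s.pop("traits").items():
                if "a2" in spec:  # symmetric shorthand
                    traits[name] = TraitSpec.symmetric(
                        spec.get("mean", 0.0), spec.get("sd", 1.0),
                        spec["a2"], spec.get("c2", 0.0), spec.get("d2", 0.0))
                else:
                    traits[name] = TraitSpec.by_sex(
                        spec["mean_m"], spec["sd_m"], spec["a2_m"],
                        spec["mean_f"], spec["sd_f"], spec["a2_f"])
            for key in ("rA", "rE"):
                if key in s:
                    s[key] = np.asarray(s[key], float)
            sim = SimulationConfig(traits=traits, seed=raw.get("seed", 0), **s)
        bonf = raw.get("bonferroni", {})
        return cls(out_dir=raw["out_dir"], seed=raw.get("seed", 0),
                   input_path=raw.get("input"), simulate=sim,
                   pgs=raw.get("pgs", {}), traits=raw.get("traits"),
                   soc_trait=raw.get("soc_trait", "soc"),
                   stratify_sex=raw.get("stratify_sex", True),
                   ci=raw.get("ci", "profile"),
                   alpha=bonf.get("alpha", 0.05),
                   n_tests=bonf.get("n_tests"))


# --------------------------------------------------------------------------
# rendering helpers


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.4f}"


def _round_table(df: pd.DataFrame, ndigits: int = 2,
                 p_cols: tuple = ()) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in p_cols:
            out[col] = out[col].map(_fmt_p)
        elif pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(ndigits)
    return out


def _write(df: pd.DataFrame, out_dir: Path, name: str,
           p_cols: tuple = ()) -> None:
    df.to_csv(out_dir / f"{name}_raw.csv", index=False)
    _round_table(df, p_cols=p_cols).to_csv(out_dir / f"{name}.csv", index=False)


# --------------------------------------------------------------------------
# stages


def _univariate_table(cohort, traits, stratify_sex, with_ci) -> pd.DataFrame:
    rows = []
    mode = "stratified" if stratify_sex else "pooled"
    for trait in traits:
        f = fit(ModelSpec("AE", sex=mode), cohort, trait)
        for stratum in f.model.strata:
            props = f.components.proportions(stratum)
            row = {"trait": trait, "sex": stratum,
                   "a2": props["a2"], "e2": props["e2"],
                   "n_pairs": f.n_pairs}
            if with_ci:
                for comp in ("a2", "e2"):
                    ci = profile_ci(f, comp, stratum=stratum)
                    row[f"{comp}_LL"], row[f"{comp}_UL"] = ci.low, ci.high
                    if ci.flags:
                        row.setdefault("flags", "")
                        row["flags"] = (row.get("flags", "") +
                                        ";".join(f"{comp}:{fl}" for fl in ci.flags))
            rows.append(row)
    cols = ["trait", "sex", "a2", "a2_LL", "a2_UL", "e2", "e2_LL", "e2_UL",
            "n_pairs", "flags"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


def _bivariate_table(cohort, soc_trait, traits, stratify_sex,
                     with_ci) -> pd.DataFrame:
    rows = []
    for trait in traits:
        if trait == soc_trait:
            continue
        fits = fit_bivariate(cohort, soc_trait, trait,
                             stratify_sex=stratify_sex, ci=with_ci)
        for stratum, f in fits.items():
            d = f.decomposition
            row = {"trait": trait, "sex": stratum, "r": d.r,
                   "rA": d.rA, "fracA": d.fracA,
                   "rE": d.rE, "fracE": d.fracE,
                   "flags": ";".join(d.flags)}
            if with_ci:
                for label, ci in (("r", d.r_ci), ("rA", d.rA_ci),
                                  ("rE", d.rE_ci)):
                    if ci is not None:
                        row[f"{label}_LL"], row[f"{label}_UL"] = ci
            rows.append(row)
    cols = ["trait", "sex", "r", "r_LL", "r_UL", "rA", "rA_LL", "rA_UL",
            "fracA", "rE", "rE_LL", "rE_UL", "fracE", "flags"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report tables.

    Returns a dict of the in-memory tables plus the log record.  Stage
    failures abort with the stage name; tables already written are kept.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "soctwin_version": __version__,
                 "stages": {}}
    stage = "load"
    tables: dict = {}
    try:
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            for i, (name, spec) in enumerate(sorted(config.pgs.items())):
                cohort = attach_pgs(cohort, spec["trait"], spec["r2"],
                                    seed=config.seed + 1000 + i, name=name)
            cohort.to_csv(out_dir / "cohort.csv")
        else:
            cohort = TwinCohort.from_csv(config.input_path)
        traits = list(config.traits or cohort.traits)
        n_total = len(cohort)
        analysis_cohort, n_removed = complete_pairs(cohort, traits)
        log["stages"]["load"] = {
            "individuals": n_total, "complete_pairs": analysis_cohort.n_pairs,
            "individuals_removed_incomplete": n_removed,
        }

        stage = "descriptives"
        t1 = table1(cohort, traits)  # descriptives use every individual
        _write(t1, out_dir, "table1", p_cols=("p_sexdiff",))
        corr = trait_correlations(cohort, traits, adjust_for_sex=True)
        corr.round(4).to_csv(out_dir / "trait_correlations.csv")
        tables["table1"] = t1
        log["stages"]["descriptives"] = {"n_traits": len(traits)}

        stage = "modelfit"
        fit_rows = []
        for trait in traits:
            sel = selection_sequence(analysis_cohort, trait,
                                     stratify_sex=config.stratify_sex)
            rep = sel.report()
            rep.insert(0, "trait", trait)
            rep["chosen_full"] = sel.chosen_full
            fit_rows.append(rep)
        modelfit = pd.concat(fit_rows, ignore_index=True)
        n_tests = config.n_tests or len(traits)
        modelfit["bonferroni_threshold"] = round(
            bonferroni_threshold(config.alpha, n_tests), 4)
        _write(modelfit, out_dir, "modelfit", p_cols=("p",))
        tables["modelfit"] = modelfit
        log["stages"]["modelfit"] = {"n_tests": n_tests}

        stage = "univariate"
        with_ci = config.ci == "profile"
        t2 = _univariate_table(analysis_cohort, traits,
                               config.stratify_sex, with_ci)
        _write(t2, out_dir, "table2")
        tables["table2"] = t2
        log["stages"]["univariate"] = {"n_pairs": analysis_cohort.n_pairs}

        stage = "bivariate"
        t3 = _bivariate_table(analysis_cohort, config.soc_trait, traits,
                              config.stratify_sex, with_ci)
        _write(t3, out_dir, "table3")
        tables["table3"] = t3
        log["stages"]["bivariate"] = {"n_pairs": analysis_cohort.n_pairs}

        if cohort.pgs_scores:
            stage = "pgs"
            t4 = pgs_table(cohort, config.soc_trait,
                           stratify_sex=config.stratify_sex)
            _write(t4, out_dir, "table4", p_cols=("p", "interaction_p"))
            tables["table4"] = t4
            log["stages"]["pgs"] = {"n_scores": len(cohort.pgs_scores)}
    except Exception as err:
        log["failed_stage"] = stage
        log["error"] = str(err)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    tables["log"] = log
    return tables
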