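"""ML fitting, model selection, Bonferroni, profile confidence intervals."""

import numpy as np
import pytest
from scipy import integrate, stats as sps

from soctwin.estimation import (
    ModelComparison,
    ProfileCI,
    _ae_profile_closed_form,
    bonferroni_threshold,
    compare,
    fit,
    profile_ci,
    selection_sequence,
)
from soctwin.synthetic_data import SimulationConfig, TraitSpec, simulate_cohort
from soctwin.twin_model import IdentificationError, ModelSpec, group_statistics
from tests.conftest import ae_config


class TestFit:
    def test_ae_recovery_large_n(self):
        """AE fits at 4000+4000 pairs land within 0.03 of a2 = 0.5; the
        mean bias over 20 seeds is below 0.01 (generator ground truth)."""
        errs = []
        for seed in range(20):
            c = simulate_cohort(ae_config(4000, 4000, 0, a2=0.5, seed=seed))
            f = fit(ModelSpec("AE"), c, "y")
            err = f.components.proportions()["a2"] - 0.5
            assert abs(err) < 0.03
            errs.append(err)
        assert abs(np.mean(errs)) < 0.01

    def test_e_model_closed_form(self, small_cohort):
        f = fit(ModelSpec("E"), small_cohort, "y")
        vals = np.concatenate([
            v.ravel() for v in small_cohort.pair_arrays("y").values()])
        assert f.components.paths["pooled"]["E"] ** 2 == \
            pytest.approx(vals.var(), abs=1e-6)
        assert f.means["pooled"] == pytest.approx(vals.mean(), abs=1e-6)

    def test_mz_only_not_identified(self):
        c = simulate_cohort(ae_config(100, 0, 0, a2=0.5, seed=1))
        with pytest.raises(IdentificationError, match="MZ and DZ"):
            fit(ModelSpec("AE"), c, "y")

    def test_deterministic_under_pair_reordering(self, small_cohort):
        f0 = fit(ModelSpec("AE"), small_cohort, "y")
        shuffled = small_cohort.data.sample(frac=1, random_state=9)
        c2 = type(small_cohort)(shuffled.reset_index(drop=True), ("y",))
        f1 = fit(ModelSpec("AE"), c2, "y")
        assert f1.minus2LL == pytest.approx(f0.minus2LL, abs=1e-8)
        assert f1.components.proportions()["a2"] == \
            pytest.approx(f0.components.proportions()["a2"], abs=1e-8)

    def test_stratified_fit_recovers_sex_specific_heritability(self):
        spec = TraitSpec.by_sex(0, 1, 0.3, 0, 1, 0.6)
        cfg = SimulationConfig(4000, 4000, 0, {"y": spec}, seed=21)
        c = simulate_cohort(cfg)
        f = fit(ModelSpec("AE", sex="stratified"), c, "y")
        assert f.components.proportions("M")["a2"] == pytest.approx(0.3, abs=0.05)
        assert f.components.proportions("F")["a2"] == pytest.approx(0.6, abs=0.05)

    def test_sexlim_recovers_low_rg(self):
        """With cross-sex genetic correlation 0.4 in the generator, the
        sex-limitation fit estimates rg well below 1."""
        spec = TraitSpec.symmetric(0, 1, 0.6)
        cfg = SimulationConfig(3000, 3000, 3000, {"y": spec}, rg=0.4, seed=22)
        c = simulate_cohort(cfg)
        f = fit(ModelSpec("AE", sex="sexlim", rg_free=True), c, "y")
        assert f.components.rg == pytest.approx(0.4, abs=0.12)


class TestCompare:
    def test_identical_models(self, small_cohort):
        f = fit(ModelSpec("AE"), small_cohort, "y")
        cmp = compare(f, f)
        assert (cmp.chi2, cmp.df, cmp.p) == (0.0, 0, 1.0)

    def test_chi2_quantile(self, small_cohort):
        full = fit(ModelSpec("ACE"), small_cohort, "y")
        nested = fit(ModelSpec("AE"), small_cohort, "y")
        cmp = compare(full, nested)
        assert cmp.df == 1
        # plain-chi2 bookkeeping against a brute-force CDF integration
        dens = lambda x: sps.chi2.pdf(x, 1)
        brute, _ = integrate.quad(dens, cmp.chi2, np.inf)
        assert cmp.p == pytest.approx(brute, abs=1e-8)
        assert cmp.p_mixture == pytest.approx(0.5 * cmp.p, abs=1e-12)
        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self, small_cohort):
        ace = fit(ModelSpec("ACE"), small_cohort, "y")
        ade = fit(ModelSpec("ADE"), small_cohort, "y")
        with pytest.raises(ValueError, match="not nested|not a subset"):
            compare(ace, ade)

    def test_boundary_rejection_rate_below_nominal(self):
        """Testing AE (true) against ACE at alpha=0.05 rejects well below
        5% because c2 sits on the boundary (chi-bar-square mixture)."""
        n_rej = 0
        n_rep = 100
        for rep in range(n_rep):
            c = simulate_cohort(ae_config(300, 300, 0, a2=0.5,
                                          seed=300_000 + rep))
            full = fit(ModelSpec("ACE"), c, "y")
            nested = fit(ModelSpec("AE"), c, "y")
            n_rej += compare(full, nested).p < 0.05
        assert n_rej / n_rep < 0.05 + 0.04  # recorded: expected ~2.6%


class TestSelectionSequence:
    def test_ae_not_rejected_under_ae_truth(self):
        ok = 0
        n_rep = 100
        for rep in range(n_rep):
            c = simulate_cohort(ae_config(500, 500, 0, a2=0.5,
                                          seed=400_000 + rep))
            sel = selection_sequence(c, "y")
            ok += sel.comparisons[0].p > 0.05
        assert ok / n_rep >= 0.90

    def test_c_loaded_data_prefers_ace(self):
        cfg = SimulationConfig(10_000, 10_000, 0,
                               {"y": TraitSpec.symmetric(0, 1, 0.4, c2=0.3)},
                               seed=17)
        c = simulate_cohort(cfg)
        sel = selection_sequence(c, "y")
        assert sel.chosen_full == "ACE"
        assert sel.fits["ACE"].minus2LL < sel.fits["ADE"].minus2LL

    def test_report_rows_match_comparisons(self, small_cohort):
        sel = selection_sequence(small_cohort, "y")
        assert len(sel.report()) == len(sel.comparisons) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_nesting_monotonicity(self, seed):
        """-2lnL ordering saturated <= ACE/ADE <= AE <= E on random data."""
        rng = np.random.default_rng(seed)
        a2 = rng.uniform(0.1, 0.7)
        c = simulate_cohort(ae_config(150, 120, 80, a2=a2, seed=seed))
        sel = selection_sequence(c, "y")
        e = fit(ModelSpec("E"), c, "y")
        sat = sel.fits["saturated"].minus2LL
        tol = 1e-5
        assert sat <= sel.fits["ACE"].minus2LL + tol
        assert sat <= sel.fits["ADE"].minus2LL + tol
        assert sel.fits["ACE"].minus2LL <= sel.fits["AE"].minus2LL + tol
        assert sel.fits["ADE"].minus2LL <= sel.fits["AE"].minus2LL + tol
        assert sel.fits["AE"].minus2LL <= e.minus2LL + tol


class TestBonferroni:
    def test_paper_value(self):
        assert round(bonferroni_threshold(0.05, 11), 4) == 0.0045

    def test_identity_and_simple_division(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 5) == pytest.approx(0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestProfileCI:
    def test_contains_point_estimate(self, small_cohort):
        f = fit(ModelSpec("AE"), small_cohort, "y")
        ci = profile_ci(f, "a2")
        point = f.components.proportions()["a2"]
        assert ci.low <= point <= ci.high

    def test_matches_wald_in_quadratic_regime(self):
        """At large n the profile objective is quadratic, so the profile CI
        equals the Wald interval computed from the numerical curvature of
        the closed-form profile (oracle)."""
        c = simulate_cohort(ae_config(10_000, 10_000, 0, a2=0.5, seed=31))
        f = fit(ModelSpec("AE"), c, "y")
        ci = profile_ci(f, "a2")
        stats_items = list(f._stats["groups"].items())
        p_hat = f.components.proportions()["a2"]
        h = 1e-4
        prof = lambda p: _ae_profile_closed_form(stats_items, p)
        curv = (prof(p_hat + h) - 2 * prof(p_hat) + prof(p_hat - h)) / h**2
        se = np.sqrt(2.0 / curv)
        assert ci.low == pytest.approx(p_hat - 1.96 * se, abs=2e-3)
        assert ci.high == pytest.approx(p_hat + 1.96 * se, abs=2e-3)

    def test_zero_heritability_boundary(self):
        c = simulate_cohort(ae_config(1000, 1000, 0, a2=0.0, seed=32))
        f = fit(ModelSpec("AE"), c, "y")
        ci = profile_ci(f, "a2")
        assert ci.low == 0.0

    def test_numeric_profile_path_is_consistent(self, small_cohort):
        """The re-optimizing profile of an ACE fit attains the fit's own
        -2lnL at the MLE proportion, never dips below it, and the CI
        endpoints sit on the chi-square(1) cutoff."""
        from soctwin.estimation import _profile_objective

        ace = fit(ModelSpec("ACE"), small_cohort, "y")
        prof = _profile_objective(ace, "a2", "pooled")
        p_hat = ace.components.proportions()["a2"]
        assert prof(p_hat) == pytest.approx(ace.minus2LL, abs=1e-4)
        for p in (max(p_hat - 0.15, 0.01), min(p_hat + 0.15, 0.99)):
            assert prof(p) >= ace.minus2LL - 1e-6
        ci = profile_ci(ace, "a2")
        cutoff = ace.minus2LL + sps.chi2.ppf(0.95, 1)
        for endpoint in (ci.low, ci.high):
            if 0.0 < endpoint < 1.0:
                assert prof(endpoint) == pytest.approx(cutoff, abs=0.02)

    def test_e2_interval_mirrors_a2(self, small_cohort):
        f = fit(ModelSpec("AE"), small_cohort, "y")
        a = profile_ci(f, "a2")
        e = profile_ci(f, "e2")
        assert e.low == pytest.approx(1 - a.high, abs=1e-4)
        assert e.high == pytest.approx(1 - a.low, abs=1e-4)
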