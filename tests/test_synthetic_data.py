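"""Generator calibration, cohort invariants and filtering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soctwin.synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    TraitSpec,
    TwinCohort,
    attach_pgs,
    complete_pairs,
    simulate_cohort,
)
from tests.conftest import ae_config


class TestSimulateCohort:
    def test_seed_determinism(self):
        cfg = dict(n_mz_pairs=50, n_dzss_pairs=40, n_dzos_pairs=30,
                   traits={"y": TraitSpec.symmetric(10, 2, 0.4, c2=0.2)},
                   n_singletons=11, seed=7)
        a = simulate_cohort(SimulationConfig(**cfg))
        b = simulate_cohort(SimulationConfig(**cfg))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_pure_additive_mz_identical(self):
        """With a2 = 1 the trait is fully genetic, so MZ co-twins coincide."""
        c = simulate_cohort(ae_config(100, 50, a2=1.0, seed=1))
        arr = c.pair_arrays("y")
        for sex in ("M", "F"):
            mz = arr[("MZ", sex)]
            assert np.allclose(mz[:, 0], mz[:, 1])
            assert np.corrcoef(mz.T)[0, 1] == pytest.approx(1.0)

    def test_pure_environment_independent(self):
        c = simulate_cohort(ae_config(5000, 5000, 5000, a2=0.0, seed=2))
        for arr in c.pair_arrays("y").values():
            assert abs(np.corrcoef(arr.T)[0, 1]) < 0.05

    def test_cross_twin_correlations_match_closed_form(self):
        """a2=0.6/e2=0.4 at 20k pairs per group: MZ r = 0.60, DZ r = 0.30.

        The expected values come from an independent direct Monte-Carlo
        draw of the latent A/E construction, which agrees with the
        closed-form cross-twin correlations a2 (MZ) and a2/2 (DZ).
        """
        rng = np.random.default_rng(99)
        a, e = np.sqrt(0.6), np.sqrt(0.4)
        # independent oracle: draw the latent factors directly
        g = rng.standard_normal(400_000)
        y1 = a * g + e * rng.standard_normal(400_000)
        y2 = a * g + e * rng.standard_normal(400_000)
        assert np.corrcoef(y1, y2)[0, 1] == pytest.approx(0.60, abs=0.01)
        gs = rng.standard_normal((400_000, 3))
        h1 = a * (np.sqrt(0.5) * gs[:, 0] + np.sqrt(0.5) * gs[:, 1]) \
            + e * rng.standard_normal(400_000)
        h2 = a * (np.sqrt(0.5) * gs[:, 0] + np.sqrt(0.5) * gs[:, 2]) \
            + e * rng.standard_normal(400_000)
        assert np.corrcoef(h1, h2)[0, 1] == pytest.approx(0.30, abs=0.01)

        c = simulate_cohort(ae_config(20_000, 20_000, a2=0.6, seed=3))
        arr = c.pair_arrays("y")
        mz = np.vstack([arr[("MZ", "M")], arr[("MZ", "F")]])
        dz = np.vstack([arr[("DZss", "M")], arr[("DZss", "F")]])
        assert np.corrcoef(mz.T)[0, 1] == pytest.approx(0.60, abs=0.01)
        assert np.corrcoef(dz.T)[0, 1] == pytest.approx(0.30, abs=0.01)

    @pytest.mark.parametrize("a2,c2,d2,rg", [
        (0.4, 0.3, 0.0, 1.0),
        (0.3, 0.0, 0.3, 1.0),
        (0.6, 0.0, 0.0, 0.5),
    ])
    def test_moment_matching_with_c_d_and_rg(self, a2, c2, d2, rg):
        """Cross-twin covariances match a2+c2+d2 (MZ), a2/2+c2+d2/4 (DZss)
        and 0.5*rg*a_m*a_f + c2 (DZos) within 3 Monte-Carlo SEs."""
        n = 30_000
        cfg = SimulationConfig(n, n, n,
                               {"y": TraitSpec.symmetric(0, 1, a2, c2, d2)},
                               rg=rg, seed=11)
        c = simulate_cohort(cfg)
        arr = c.pair_arrays("y")
        expected = {"MZ": a2 + c2 + d2, "DZss": 0.5 * a2 + c2 + 0.25 * d2,
                    "DZos": 0.5 * rg * a2 + c2 + 0.25 * d2}
        se = 3.0 / np.sqrt(n)
        for (zyg, _sex), vals in arr.items():
            cov = np.cov(vals.T)[0, 1]
            assert cov == pytest.approx(expected[zyg], abs=3 * se), zyg

    def test_marginal_calibration_by_sex(self):
        spec = TraitSpec.by_sex(64.1, 10.0, 0.3, 61.7, 10.6, 0.5)
        cfg = SimulationConfig(30_000, 0, 0, {"y": spec}, seed=4)
        d = simulate_cohort(cfg).data
        for sex, mean, sd in (("M", 64.1, 10.0), ("F", 61.7, 10.6)):
            sub = d[d.sex == sex]["y"]
            assert sub.mean() == pytest.approx(mean, abs=0.2)
            assert sub.std() == pytest.approx(sd, abs=0.15)

    def test_group_sizes_and_singletons(self):
        c = simulate_cohort(SimulationConfig(
            10, 8, 6, {"y": TraitSpec.symmetric(0, 1, 0.5)},
            n_singletons=5, seed=5))
        d = c.data
        sizes = d.groupby("pair_id").size()
        assert (sizes == 1).sum() == 5
        assert c.n_pairs == 24
        assert len(d) == 2 * 24 + 5

    @given(st.integers(2, 30), st.integers(2, 30), st.integers(0, 30),
           st.floats(0.0, 1.0), st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_cohort_invariants_hold(self, n_mz, n_dz, n_os, a2, seed):
        cohort = simulate_cohort(ae_config(n_mz, n_dz, n_os, a2=a2, seed=seed))
        cohort.validate()  # raises on violation
        assert cohort.n_pairs == n_mz + n_dz + n_os


class TestConfigValidation:
    def test_negative_proportion_names_trait_and_sex(self):
        spec = TraitSpec({"M": 0, "F": 0}, {"M": 1, "F": 1},
                         {"M": -0.1, "F": 0.5}, e2={"M": 1.1, "F": 0.5})
        with pytest.raises(ConfigurationError, match="'y'.*sex M|sex M"):
            SimulationConfig(10, 10, 0, {"y": spec})

    def test_proportions_must_sum_to_one(self):
        spec = TraitSpec({"M": 0, "F": 0}, {"M": 1, "F": 1},
                         {"M": 0.5, "F": 0.5}, e2={"M": 0.4, "F": 0.5})
        with pytest.raises(ConfigurationError, match="sum"):
            SimulationConfig(10, 10, 0, {"y": spec})

    def test_c_and_d_together_rejected(self):
        with pytest.raises(ConfigurationError, match="C and D"):
            SimulationConfig(10, 10, 0,
                             {"y": TraitSpec.symmetric(0, 1, 0.4, 0.2, 0.2)})

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(0, 0, 0, {"y": TraitSpec.symmetric(0, 1, 0.5)})

    def test_bad_factor_correlation_matrix(self):
        with pytest.raises(ConfigurationError, match="rA"):
            SimulationConfig(10, 10, 0,
                             {"a": TraitSpec.symmetric(0, 1, 0.5),
                              "b": TraitSpec.symmetric(0, 1, 0.5)},
                             rA=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestAttachPgs:
    def test_zero_r2_gives_independent_score(self):
        c = simulate_cohort(ae_config(10_000, 10_000, a2=0.5, seed=6))
        c = attach_pgs(c, "y", 0.0, seed=1)
        d = c.data
        r2 = np.corrcoef(d["y"], d["pgs_y"])[0, 1] ** 2
        assert r2 < 0.005

    def test_r2_recovered_at_large_n(self):
        c = simulate_cohort(ae_config(12_500, 12_500, a2=0.5, seed=7))
        c = attach_pgs(c, "y", 0.05, seed=2)
        d = c.data  # 50k individuals
        r2 = np.corrcoef(d["y"], d["pgs_y"])[0, 1] ** 2
        assert 0.04 <= r2 <= 0.06

    def test_mz_cotwin_scores_identical(self):
        c = simulate_cohort(ae_config(200, 200, a2=0.5, seed=8))
        c = attach_pgs(c, "y", 0.05, seed=3)
        wide = c.pair_table(["pgs_y"])
        mz = wide[wide.zygosity == "MZ"]
        assert np.allclose(mz["pgs_y_1"], mz["pgs_y_2"])
        dz = wide[wide.zygosity == "DZss"]
        r = np.corrcoef(dz["pgs_y_1"], dz["pgs_y_2"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.15)

    def test_r2_beyond_heritability_rejected(self):
        c = simulate_cohort(ae_config(100, 100, a2=0.3, seed=9))
        with pytest.raises(ConfigurationError, match="herit|additive"):
            attach_pgs(c, "y", 0.4, seed=4)

    def test_existing_columns_untouched(self):
        c = simulate_cohort(ae_config(100, 100, a2=0.5, seed=10))
        before = c.data.copy()
        c2 = attach_pgs(c, "y", 0.05, seed=5)
        pd.testing.assert_frame_equal(c2.data[before.columns], before)
        assert c2.pgs_scores == ("pgs_y",)


class TestCompletePairs:
    def _cohort(self, rows):
        return TwinCohort(pd.DataFrame(rows, columns=[
            "pair_id", "member", "zygosity", "sex", "y"]), ("y",))

    def test_incomplete_pair_dropped(self):
        c = self._cohort([
            ("p1", 1, "MZ", "M", 1.0), ("p1", 2, "MZ", "M", 2.0),
            ("p2", 1, "DZss", "F", 0.5), ("p2", 2, "DZss", "F", 0.7),
            ("p3", 1, "MZ", "F", 0.1),
        ])
        out, removed = complete_pairs(c)
        assert out.n_pairs == 2 and removed == 1

    def test_missing_trait_value_drops_pair(self):
        c = self._cohort([
            ("p1", 1, "MZ", "M", 1.0), ("p1", 2, "MZ", "M", np.nan),
            ("p2", 1, "MZ", "F", 0.5), ("p2", 2, "MZ", "F", 0.7),
        ])
        out, removed = complete_pairs(c, traits=["y"])
        assert out.n_pairs == 1 and removed == 2

    def test_complete_cohort_identity(self):
        c = self._cohort([
            ("p1", 1, "MZ", "M", 1.0), ("p1", 2, "MZ", "M", 2.0)])
        out, removed = complete_pairs(c)
        assert removed == 0
        pd.testing.assert_frame_equal(out.data, c.data)

    def test_all_singletons_empty_result(self):
        c = self._cohort([("p1", 1, "MZ", "M", 1.0),
                          ("p2", 1, "DZss", "F", 0.2),
                          ("p3", 2, "DZos", "F", 0.4)])
        out, removed = complete_pairs(c)
        assert len(out) == 0 and removed == 3


class TestCohortIO:
    def test_csv_roundtrip(self):
        c = simulate_cohort(ae_config(20, 15, 10, a2=0.5, seed=12))
        c = attach_pgs(c, "y", 0.1, seed=1)
        buf = io.StringIO()
        c.to_csv(buf)
        buf.seek(0)
        back = TwinCohort.from_csv(buf)
        assert back.traits == ("y",)
        assert back.pgs_scores == ("pgs_y",)
        visible = [col for col in c.data.columns if not col.startswith("_")]
        pd.testing.assert_frame_equal(back.data, c.data[visible],
                                      check_exact=False, rtol=1e-12)

    def test_invalid_table_rejected(self):
        df = pd.DataFrame({"pair_id": ["p", "p"], "member": [1, 1],
                           "zygosity": ["MZ", "MZ"], "sex": ["M", "M"],
                           "y": [0.0, 1.0]})
        with pytest.raises(Exception, match="member"):
            TwinCohort(df, ("y",))

    def test_discordant_sex_mz_rejected(self):
        df = pd.DataFrame({"pair_id": ["p", "p"], "member": [1, 2],
                           "zygosity": ["MZ", "MZ"], "sex": ["M", "F"],
                           "y": [0.0, 1.0]})
        with pytest.raises(Exception, match="sex"):
            TwinCohort(df, ("y",))
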