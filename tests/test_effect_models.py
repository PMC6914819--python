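import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import metabotraj as mt
from metabotraj.effect_models import ModelError, per_cell_scheme

from oracles import anova_oracle, bh_oracle, make_balanced_design, pooled_t_oracle


class TestFitFactorial:
    def test_pure_background_contrast_gives_full_r2(self):
        design = make_balanced_design(5)
        y = np.where(design.table["background"] == "C57", 1.0, -1.0)
        fit = mt.fit_factorial(y, design)
        assert fit.loc["background", "percent_variance"] == pytest.approx(100.0)
        others = fit.drop(["background", "residual"])["percent_variance"]
        assert np.allclose(others, 0.0, atol=1e-8)

    @pytest.mark.parametrize("n_per_cell", [2, 3, 5])
    def test_matches_group_mean_oracle(self, n_per_cell):
        rng = np.random.default_rng(n_per_cell)
        design = make_balanced_design(n_per_cell)
        y = rng.normal(size=design.n_samples)
        y += 0.4 * (design.table["stage"] == "LATE").to_numpy()
        fit = mt.fit_factorial(y, design)
        orc = anova_oracle(y, design.table)
        assert np.allclose(fit["sum_sq"], orc["sum_sq"], rtol=1e-9)
        assert np.allclose(fit["F"].fillna(-1), orc["F"].fillna(-1), rtol=1e-9)
        assert np.allclose(fit["p"].fillna(-1), orc["p"].fillna(-1), rtol=1e-9)

    def test_partition_identity_and_sum_to_100(self):
        rng = np.random.default_rng(0)
        design = make_balanced_design(4)
        y = rng.normal(size=design.n_samples)
        fit = mt.fit_factorial(y, design)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        assert fit["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-8)
        assert fit["percent_variance"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        design = make_balanced_design(3)
        y = rng.normal(size=design.n_samples)
        fit1 = mt.fit_factorial(y, design)
        perm = rng.permutation(design.n_samples)
        tbl = design.table.iloc[perm].reset_index(drop=True)
        fit2 = mt.fit_factorial(y[perm], mt.StudyDesign(tbl))
        pd.testing.assert_frame_equal(fit1, fit2)

    def test_zero_total_ss_reports_residual_100(self):
        design = make_balanced_design(2)
        fit = mt.fit_factorial(np.full(design.n_samples, 3.0), design)
        assert fit.loc["residual", "percent_variance"] == 100.0
        assert (fit.drop("residual")["sum_sq"] == 0).all()

    def test_empty_cell_is_error(self):
        design = make_balanced_design(2)
        keep = ~(
            (design.table["background"] == "C57")
            & (design.table["genotype"] == "NTG")
            & (design.table["stage"] == "PRE")
        ).to_numpy()
        sub = mt.StudyDesign(design.table.loc[keep].reset_index(drop=True))
        with pytest.raises(ModelError, match="empty design cell"):
            mt.fit_factorial(np.zeros(keep.sum()), sub)

    def test_unbalanced_falls_back_to_type_ii_with_warning(self):
        rng = np.random.default_rng(2)
        design = make_balanced_design(3)
        drop_one = np.ones(design.n_samples, bool)
        drop_one[0] = False
        sub = mt.StudyDesign(design.table.loc[drop_one].reset_index(drop=True))
        y = rng.normal(size=sub.n_samples)
        with pytest.warns(UserWarning, match="unbalanced"):
            fit = mt.fit_factorial(y, sub)
        assert set(fit.index) == {*mt.TERMS, "residual"}
        assert (fit["sum_sq"] >= 0).all()


class TestBHAdjust:
    def test_textbook_example(self):
        out = mt.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged_and_all_ones(self):
        assert mt.bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(mt.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_missing_excluded_then_reinserted(self):
        out = mt.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_oracle(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            mt.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_definition(self, ps):
        p = np.asarray(ps)
        out = mt.bh_adjust(p)
        assert np.allclose(out, bh_oracle(p))
        assert np.all(out >= p - 1e-12)  # adjustment never shrinks a p-value
        # monotone non-decreasing in rank
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestEffectTable:
    def test_single_metabolite_fdr_equals_p(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        one = logged.with_values(logged.values.iloc[:, [0]], "log10")
        et = mt.effect_table(one)
        rows = et.table[et.table["term"] != "residual"]
        assert np.allclose(rows["p_fdr"], rows["p"], equal_nan=True)

    def test_duplicated_metabolite_columns_identical_rows(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        dup = logged.values.iloc[:, [0, 0]].copy()
        dup.columns = ["a", "b"]
        et = mt.effect_table(logged.with_values(dup, "log10"))
        a = et.table[et.table["feature"] == "a"].drop(columns="feature").reset_index(drop=True)
        b = et.table[et.table["feature"] == "b"].drop(columns="feature").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_background_signals_flagged(self):
        cfg = mt.SimulationConfig(
            n_metabolites=60, segments=("lumbar",), drift_spec={}, seed=13,
            effect_spec={f"m{i:03d}": {"background": 0.5} for i in (1, 2, 3, 4, 5)},
        )
        raw, design, _ = mt.simulate_study(cfg)
        logged = mt.log_transform(raw.with_values(raw.values, "normalized")
                                  .subset_samples(design.is_study()))
        et = mt.effect_table(logged)
        hits = set(et.table.query("term == 'background' and significant")["feature"])
        assert {f"m{i:03d}" for i in (1, 2, 3, 4, 5)} <= hits
        assert len(hits) <= 7  # at most a stray false flag or two

    def test_failed_metabolite_flagged_not_fatal(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        vals = logged.values.iloc[:, :3].copy()
        vals.iloc[0, 1] = np.nan  # incomplete -> per-feature failure
        et = mt.effect_table(logged.with_values(vals, "log10"))
        bad = et.table[et.table["feature"] == vals.columns[1]]
        assert (~bad["ok"]).all()
        good = et.table[et.table["feature"] != vals.columns[1]]
        assert good["ok"].all()


class TestTwoGroupTests:
    def test_identical_groups_t_zero_p_one(self):
        design = make_balanced_design(3)
        vals = pd.DataFrame(
            np.tile(np.arange(3.0), 12)[:, None] + 1.0,
            index=pd.Index(design.sample_ids), columns=["m1"],
        )
        m = mt.MetaboliteMatrix(vals, design, "log10")
        tt = mt.two_group_tests(m)
        assert np.allclose(tt.table["t"], 0.0)
        assert np.allclose(tt.table["p"], 1.0)

    def test_matches_pooled_variance_formula(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        tt = mt.two_group_tests(logged)
        meta = logged.design.table
        met = logged.metabolite_ids[0]
        v = logged.values[met].to_numpy()
        sel = (meta["background"] == "C57") & (meta["stage"] == "PRE")
        a = v[(sel & (meta["genotype"] == "NTG")).to_numpy()]
        b = v[(sel & (meta["genotype"] == "G93A")).to_numpy()]
        t_exp, p_exp = pooled_t_oracle(a, b)
        row = tt.table.query("feature == @met and contrast == 'C57-PRE:NTG_vs_G93A'").iloc[0]
        assert row["t"] == pytest.approx(t_exp, abs=1e-12)
        assert row["p"] == pytest.approx(p_exp, abs=1e-12)

    def test_per_cell_scheme_has_six_contrasts(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        tt = mt.two_group_tests(logged)
        assert tt.table["contrast"].nunique() == 6
        assert len(per_cell_scheme()) == 6

    def test_pooled_scheme_backgrounds(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        scheme = {"C57_vs_129S": ({"background": "C57"}, {"background": "129S"})}
        tt = mt.two_group_tests(logged, scheme=scheme)
        row = tt.table.iloc[0]
        assert row["n_a"] == 30 and row["n_b"] == 30

    def test_small_group_flagged_untestable(self):
        design = make_balanced_design(1)  # n = 1 per cell
        vals = pd.DataFrame(
            np.arange(12.0)[:, None], index=pd.Index(design.sample_ids), columns=["m1"]
        )
        tt = mt.two_group_tests(mt.MetaboliteMatrix(vals, design, "log10"))
        assert (~tt.table["testable"]).all()
        assert tt.table["p"].isna().all()

    def test_tier_flags_consistent_with_p_values(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        tt = mt.two_group_tests(logged).table
        assert ((tt["sig_fdr20"]) == ((tt["p"] <= 0.05) & (tt["p_fdr"] < 0.20))).all()
        assert ((tt["sig_fdr5"]) == ((tt["p"] <= 0.05) & (tt["p_fdr"] < 0.05))).all()
        assert (tt.loc[tt["sig_fdr5"], "sig_fdr20"]).all()

    def test_welch_flag_changes_statistic(self, lumbar_scaled):
        logged = lumbar_scaled[1]
        t1 = mt.two_group_tests(logged).table["p"]
        t2 = mt.two_group_tests(logged, welch=True).table["p"]
        assert not np.allclose(t1, t2)
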