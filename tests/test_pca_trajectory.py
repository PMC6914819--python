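import numpy as np
import pandas as pd
import pytest

import metabotraj as mt
from metabotraj.pca_trajectory import PCAError

from oracles import make_balanced_design, pca_eigen_oracle


def _scaled(X, design=None):
    design = design or make_balanced_design(X.shape[0] // 12)
    X = np.asarray(X, dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    frame = pd.DataFrame(X, index=pd.Index(design.sample_ids),
                         columns=[f"m{j}" for j in range(X.shape[1])])
    return mt.MetaboliteMatrix(frame, design, "scaled")


class TestFitPCA:
    def test_perfectly_correlated_pair_loads_on_pc1_only(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        model = mt.fit_pca(_scaled(np.column_stack([x, 2 * x + 1])))
        assert model.explained_fraction[0] == pytest.approx(1.0)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(1)
        m = _scaled(rng.normal(size=(24, 10)), make_balanced_design(2))
        model = mt.fit_pca(m)  # K = min(n-1, p) = 10 = rank
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, m.values.to_numpy(), atol=1e-8)
        assert model.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        m = _scaled(rng.normal(size=(24, 6)), make_balanced_design(2))
        model = mt.fit_pca(m)
        frac, V = pca_eigen_oracle(m.values.to_numpy())
        assert np.allclose(model.explained_fraction, frac, atol=1e-10)
        for k in range(model.K):  # loadings agree up to sign
            dot = abs(np.dot(model.loadings.to_numpy()[:, k], V[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_loadings_and_score_identity(self, lumbar_scaled):
        scaled = lumbar_scaled[2]
        model = mt.fit_pca(scaled, K=8)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(8), atol=1e-8)
        X = scaled.values.to_numpy()
        assert np.allclose(model.scores.to_numpy(), (X - X.mean(0)) @ L, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        m = _scaled(rng.normal(size=(12, 4)))
        m1 = mt.fit_pca(m)
        m2 = mt.fit_pca(m)
        pd.testing.assert_frame_equal(m1.loadings, m2.loadings)
        for k in range(m1.K):
            col = m1.loadings.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_missing_values_rejected(self):
        m = _scaled(np.random.default_rng(4).normal(size=(12, 3)))
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        with pytest.raises(PCAError, match="missing"):
            mt.fit_pca(mt.MetaboliteMatrix(vals, m.design, "scaled"))


class TestVarianceAttribution:
    def test_pure_background_score_attributed_to_background(self):
        rng = np.random.default_rng(5)
        design = make_balanced_design(50)
        v, w = 1.0, 0.25
        contrast = np.where(design.table["background"] == "C57", -np.sqrt(v), np.sqrt(v))
        scores = contrast + rng.normal(0, np.sqrt(w), design.n_samples)
        fit = mt.fit_factorial(scores, design)
        expected = 100 * v / (v + w)
        assert fit.loc["background", "percent_variance"] == pytest.approx(expected, abs=3)

    def test_null_scores_residual_dominates(self):
        rng = np.random.default_rng(6)
        design = make_balanced_design(5)
        reps = 400
        Y = rng.normal(size=(60, reps))
        res = mt.anova_matrix(Y, design.table)
        pct = 100 * res["ss"] / res["ss_total"]
        n = 60
        for i, term in enumerate(mt.TERMS):
            expected = 100 * res["df"][i] / (n - 1)
            assert pct[i].mean() == pytest.approx(expected, abs=1.0)
        assert pct[-1].mean() > 75

    def test_duplicating_all_samples_leaves_percentages_unchanged(self):
        rng = np.random.default_rng(7)
        design = make_balanced_design(2)
        y = rng.normal(size=design.n_samples)
        fit1 = mt.fit_factorial(y, design)
        big = pd.concat([design.table, design.table], ignore_index=True)
        big["sample_id"] = [f"r{i}" for i in range(len(big))]
        big["injection_order"] = np.arange(1, len(big) + 1)
        fit2 = mt.fit_factorial(np.concatenate([y, y]), mt.StudyDesign(big))
        assert np.allclose(fit1["percent_variance"], fit2["percent_variance"], atol=1e-9)

    def test_attribution_rows_sum_to_100(self, lumbar_scaled):
        scaled = lumbar_scaled[2]
        model = mt.fit_pca(scaled, K=6)
        att = mt.pc_variance_attribution(model, scaled.design)
        sums = att[[*mt.TERMS, "residual"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)


@pytest.fixture(scope="module")
def fitted(lumbar_scaled):
    scaled = lumbar_scaled[2]
    model = mt.fit_pca(scaled, K=5)
    traj = mt.build_trajectories(model, scaled.design, pcs=(2, 3))
    return scaled, model, traj


class TestTrajectories:

    def test_sem_is_sd_over_sqrt_n(self, fitted):
        scaled, model, traj = fitted
        meta = scaled.design.table
        sel = ((meta["background"] == "C57") & (meta["genotype"] == "NTG")
               & (meta["stage"] == "PRE")).to_numpy()
        s = model.scores.loc[sel, "PC2"]
        row = traj.table.loc[("C57-NTG", "PRE")]
        assert row["n"] == 5
        assert row["sem_PC2"] == pytest.approx(s.std(ddof=1) / np.sqrt(5))
        assert row["mean_PC2"] == pytest.approx(s.mean())

    def test_identical_samples_give_zero_sem(self):
        design = make_balanced_design(3)
        # scores constant within each cell -> zero within-cell scatter
        cells = design.table[["background", "genotype", "stage"]].agg("/".join, axis=1)
        codes = pd.Categorical(cells).codes.astype(float)
        scores = pd.DataFrame(
            {"PC1": codes, "PC2": -codes},
            index=pd.Index(design.sample_ids),
        )
        model = mt.PCAModel(
            loadings=pd.DataFrame(np.eye(2), index=["m0", "m1"], columns=["PC1", "PC2"]),
            scores=scores, explained_fraction=np.array([0.6, 0.4]),
        )
        traj = mt.build_trajectories(model, design, pcs=(1, 2))
        assert (traj.table[["sem_PC1", "sem_PC2"]].to_numpy() == 0).all()

    def test_alignment_zeroes_pre_and_preserves_segments(self, fitted):
        _, _, traj = fitted
        aligned = mt.align_trajectories(traj)
        assert aligned.aligned
        for g in aligned.groups:
            assert np.all(aligned.table.loc[(g, "PRE"), ["mean_PC2", "mean_PC3"]] == 0)
            before = np.diff(traj.group_means(g), axis=0)
            after = np.diff(aligned.group_means(g), axis=0)
            assert np.allclose(before, after, atol=1e-12)
        sem_cols = ["sem_PC2", "sem_PC3"]
        pd.testing.assert_frame_equal(aligned.table[sem_cols], traj.table[sem_cols])

    def test_alignment_idempotent(self, fitted):
        _, _, traj = fitted
        once = mt.align_trajectories(traj)
        twice = mt.align_trajectories(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_missing_pre_stage_errors(self, fitted):
        _, _, traj = fitted
        clipped = mt.TrajectorySet(
            table=traj.table.drop("PRE", level="stage"), pcs=traj.pcs
        )
        with pytest.raises(PCAError, match="PRE"):
            mt.align_trajectories(clipped)


class TestGeometry:
    def _traj_from_means(self, means_by_group, pcs=("PC1", "PC2")):
        rows = []
        for g, means in means_by_group.items():
            for stage, m in zip(("PRE", "ONS", "LATE"), means):
                rows.append({"group": g, "stage": stage, "n": 5,
                             **{f"mean_{pc}": v for pc, v in zip(pcs, m)},
                             **{f"sem_{pc}": 0.1 for pc in pcs}})
        return mt.TrajectorySet(pd.DataFrame(rows).set_index(["group", "stage"]),
                                pcs=tuple(pcs))

    def test_identical_trajectories_zero_angle_unit_ratio(self):
        means = [(0, 0), (1, 1), (3, 2)]
        t = self._traj_from_means({"a": means, "b": means})
        geom = mt.trajectory_geometry(t, [("a", "b")])
        assert np.allclose(geom.pairs["angle_deg"], 0.0, atol=1e-10)
        assert np.allclose(geom.pairs["path_length_ratio"], 1.0)

    def test_negated_trajectory_gives_180(self):
        means = [(0.0, 0.0), (1.0, 2.0), (2.0, 1.0)]
        neg = [(-a, -b) for a, b in means]
        t = self._traj_from_means({"a": means, "b": neg})
        geom = mt.trajectory_geometry(t, [("a", "b")])
        assert np.allclose(geom.pairs["angle_deg"], 180.0, atol=1e-10)

    def test_random_trajectories_match_direct_formula(self):
        rng = np.random.default_rng(8)
        ma = rng.normal(size=(3, 2))
        mb = rng.normal(size=(3, 2))
        t = self._traj_from_means({"a": ma, "b": mb})
        geom = mt.trajectory_geometry(t, [("a", "b")])
        for i in range(2):
            u, v = np.diff(ma, axis=0)[i], np.diff(mb, axis=0)[i]
            expected = np.degrees(
                np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            )
            assert geom.pairs["angle_deg"].iloc[i] == pytest.approx(expected, abs=1e-10)
        ratio = np.linalg.norm(np.diff(ma, axis=0), axis=1).sum() / \
            np.linalg.norm(np.diff(mb, axis=0), axis=1).sum()
        assert geom.pairs["path_length_ratio"].iloc[0] == pytest.approx(ratio, abs=1e-10)

    def test_zero_length_segment_reports_missing_angle(self):
        t = self._traj_from_means(
            {"a": [(0, 0), (0, 0), (1, 1)], "b": [(0, 0), (1, 0), (2, 0)]}
        )
        geom = mt.trajectory_geometry(t, [("a", "b")])
        first = geom.pairs[geom.pairs["segment"] == "PRE->ONS"]
        assert first["angle_deg"].isna().all()
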