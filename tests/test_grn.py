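import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socint.datamodel import DataValidationError
from socint.grn import (MetaSampleMatrix, RegulatoryMatrix, _forest_importance,
                        build_meta_samples, connectivity_summary,
                        cross_tissue_gene_correlation, infer_regulatory_matrix,
                        ranking_auroc)
from socint.simulate import SimConfig, simulate_experiment


def _meta_from_array(V, n_larva):
    """V: features x obs array -> MetaSampleMatrix with two tissues."""
    p, n = V.shape
    feats = [f"larva::g{i}" for i in range(n_larva)] + \
            [f"nurse_head::g{i}" for i in range(n_larva, p)]
    values = pd.DataFrame(V, index=feats, columns=[f"c{i}" for i in range(n)])
    tissue = pd.Series(["larva"] * n_larva + ["nurse_head"] * (p - n_larva),
                       index=feats)
    obs = pd.DataFrame({"colony": values.columns,
                        "stage": ["L1"] * n}).set_index("colony")
    return MetaSampleMatrix(values, tissue, obs)


class TestMetaSamples:
    def test_shape_and_tissue_partition(self, default_experiment):
        cfg, expr, truth = default_experiment
        genes = truth.genes[:30]
        meta = build_meta_samples(expr, genes, genes, "nurse_head")
        assert meta.values.shape == (60, cfg.n_colonies_per_stage * 5)
        counts = meta.feature_tissue.value_counts()
        assert counts["larva"] == 30 and counts["nurse_head"] == 30

    def test_missing_nurse_sample_drops_pairing(self, default_experiment):
        _, expr, truth = default_experiment
        nurse_ids = expr.samples.index[
            (expr.samples.tissue == "nurse_head")
            & (expr.samples.nurse_type == "stage_specific")]
        drop = nurse_ids[0]
        keep = [c for c in expr.values.columns if c != drop]
        from socint.datamodel import ExpressionMatrix
        sub = ExpressionMatrix(expr.values[keep], expr.samples.loc[keep])
        genes = truth.genes[:10]
        full = build_meta_samples(expr, genes, genes, "nurse_head")
        reduced = build_meta_samples(sub, genes, genes, "nurse_head")
        assert reduced.n_observations == full.n_observations - 1
        missing_colony = expr.samples.loc[drop, "colony"]
        assert missing_colony not in reduced.values.columns

    def test_values_are_asinh_transformed(self, default_experiment):
        _, expr, truth = default_experiment
        genes = truth.genes[:5]
        meta = build_meta_samples(expr, genes, genes, "nurse_head")
        colony = meta.values.columns[0]
        larva_sid = expr.samples.index[(expr.samples.colony == colony)
                                       & (expr.samples.tissue == "larva")][0]
        expected = np.arcsinh(expr.values.loc[genes[0], larva_sid])
        assert meta.values.loc[f"larva::{genes[0]}", colony] == pytest.approx(expected)

    def test_too_few_pairings_errors(self, default_experiment):
        _, expr, truth = default_experiment
        larva_ids = expr.samples.index[expr.samples.tissue == "larva"][:2]
        nurse_ids = expr.samples.index[
            (expr.samples.tissue == "nurse_head")
            & (expr.samples.nurse_type == "stage_specific")]
        keep = list(larva_ids) + list(nurse_ids)
        from socint.datamodel import ExpressionMatrix
        sub = ExpressionMatrix(expr.values[keep], expr.samples.loc[keep])
        with pytest.raises(DataValidationError, match="pairings"):
            build_meta_samples(sub, truth.genes[:5], truth.genes[:5],
                               "nurse_head")


class TestForestKernel:
    def test_matches_sklearn_on_strong_signal(self):
        """The numba CART kernel is cross-checked against sklearn's RF."""
        from sklearn.ensemble import RandomForestRegressor
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 20))
        y = 1.0 * X[:, 5] + 0.5 * X[:, 12] + 0.3 * rng.normal(size=30)
        imp = _forest_importance(np.ascontiguousarray(X), y, 4, 500,
                                 rng.integers(1, 2 ** 31 - 1, 500))
        rf = RandomForestRegressor(n_estimators=500, max_features=4,
                                   random_state=0).fit(X, y)
        r = np.corrcoef(imp / imp.sum(), rf.feature_importances_)[0, 1]
        assert r > 0.95
        assert set(np.argsort(imp)[-2:]) == {5, 12}

    def test_copy_regressor_ranks_first(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 60))
        y = X[:, 7].copy()
        imp = _forest_importance(np.ascontiguousarray(X), y, 7, 300,
                                 rng.integers(1, 2 ** 31 - 1, 300))
        assert imp.argmax() == 7

    def test_noise_importance_never_concentrates_like_signal(self):
        # max per-column share on pure noise stays far below the
        # copy-regressor regime (measured ~4x the uniform 1/(p-1) share)
        rng = np.random.default_rng(0)
        shares = []
        for rep in range(5):
            X = rng.normal(size=(25, 60))
            y = rng.normal(size=25)
            imp = _forest_importance(np.ascontiguousarray(X), y, 7, 100,
                                     rng.integers(1, 2 ** 31 - 1, 100))
            shares.append(imp.max() / imp.sum())
        assert np.median(shares) < 6 / 59


class TestInference:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(1)
        meta = _meta_from_array(rng.normal(size=(12, 10)), 6)
        r1 = infer_regulatory_matrix(meta, n_trees=30, n_runs=2, seed=5)
        r2 = infer_regulatory_matrix(meta, n_trees=30, n_runs=2, seed=5)
        pd.testing.assert_frame_equal(r1.importances, r2.importances)

    def test_diagonal_zero_and_nonnegative(self):
        rng = np.random.default_rng(2)
        meta = _meta_from_array(rng.normal(size=(10, 12)), 5)
        reg = infer_regulatory_matrix(meta, n_trees=30, seed=0)
        A = reg.importances.to_numpy()
        assert (np.diag(A) == 0).all()
        assert (A >= 0).all()

    def test_zero_variance_target_gets_zero_column(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(8, 10))
        V[2] = 4.2
        meta = _meta_from_array(V, 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            reg = infer_regulatory_matrix(meta, n_trees=30, seed=0)
        assert (reg.importances.iloc[:, 2] == 0).all()

    def test_run_averaging_reduces_variance(self):
        rng = np.random.default_rng(4)
        meta = _meta_from_array(rng.normal(size=(10, 15)), 5)
        spread = {}
        for n_runs in (1, 10):
            mats = [infer_regulatory_matrix(meta, n_trees=20, n_runs=n_runs,
                                            seed=s).importances.to_numpy()
                    for s in range(4)]
            spread[n_runs] = np.var(np.stack(mats), axis=0).mean()
        assert spread[10] < spread[1]


class TestConnectivity:
    def test_uniform_matrix_zero_sociality(self):
        p = 6
        A = np.full((p, p), 0.3)
        np.fill_diagonal(A, 0.0)
        feats = [f"larva::g{i}" for i in range(3)] + \
                [f"nurse_head::g{i}" for i in range(3, 6)]
        reg = RegulatoryMatrix(pd.DataFrame(A, index=feats, columns=feats),
                               pd.Series(["larva"] * 3 + ["nurse_head"] * 3,
                                         index=feats), 1)
        conn = connectivity_summary(reg)
        np.testing.assert_allclose(conn["within_connectivity"], 0.3)
        np.testing.assert_allclose(conn["sociality_index"], 0.0)

    def test_pure_social_gene(self):
        feats = ["larva::a", "larva::b", "nurse_head::c", "nurse_head::d"]
        A = np.zeros((4, 4))
        A[0, 2] = A[0, 3] = 1.0     # larva::a acts only across tissues
        reg = RegulatoryMatrix(pd.DataFrame(A, index=feats, columns=feats),
                               pd.Series(["larva", "larva", "nurse_head",
                                          "nurse_head"], index=feats), 1)
        conn = connectivity_summary(reg)
        row = conn.loc["larva::a"]
        assert row["within_connectivity"] == 0
        assert row["social_connectivity"] == 1.0
        assert row["sociality_index"] > 0

    def test_four_gene_toy_hand_computed(self):
        feats = ["larva::a", "larva::b", "nurse_head::c", "nurse_head::d"]
        A = np.arange(16, dtype=float).reshape(4, 4)
        np.fill_diagonal(A, 0.0)
        reg = RegulatoryMatrix(pd.DataFrame(A, index=feats, columns=feats),
                               pd.Series(["larva", "larva", "nurse_head",
                                          "nurse_head"], index=feats), 1)
        conn = connectivity_summary(reg)
        # row 0: within target = b (=1); social targets = c,d (=2,3)
        assert conn.loc["larva::a", "within_connectivity"] == pytest.approx(1.0)
        assert conn.loc["larva::a", "social_connectivity"] == pytest.approx(2.5)
        assert conn.loc["larva::a", "sociality_index"] == pytest.approx(1.5)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for rep in range(10):
            p_l, p_n = rng.integers(2, 6, 2)
            p = p_l + p_n
            A = rng.random((p, p))
            np.fill_diagonal(A, 0.0)
            feats = [f"larva::g{i}" for i in range(p_l)] + \
                    [f"nurse_head::g{i}" for i in range(p_l, p)]
            tissues = ["larva"] * p_l + ["nurse_head"] * p_n
            reg = RegulatoryMatrix(pd.DataFrame(A, index=feats, columns=feats),
                                   pd.Series(tissues, index=feats), 1)
            conn = connectivity_summary(reg)
            for i in range(p):
                w, s = [], []
                for j in range(p):
                    if j == i:
                        continue
                    (w if tissues[j] == tissues[i] else s).append(A[i, j])
                assert conn.iloc[i]["within_connectivity"] == pytest.approx(
                    np.mean(w), abs=1e-12)
                assert conn.iloc[i]["social_connectivity"] == pytest.approx(
                    np.mean(s), abs=1e-12)

    def test_incoming_mode_transposes(self):
        feats = ["larva::a", "larva::b", "nurse_head::c"]
        A = np.zeros((3, 3))
        A[0, 2] = 2.0
        reg = RegulatoryMatrix(pd.DataFrame(A, index=feats, columns=feats),
                               pd.Series(["larva", "larva", "nurse_head"],
                                         index=feats), 1)
        out = connectivity_summary(reg, direction="outgoing")
        inc = connectivity_summary(reg, direction="incoming")
        assert out.loc["larva::a", "social_connectivity"] == 2.0
        assert inc.loc["nurse_head::c", "social_connectivity"] == 1.0


class TestCrossTissueCorrelation:
    def test_monotone_transform_gives_rho_one(self, default_experiment):
        _, expr, truth = default_experiment
        # gene vs itself across tissues is not forced; build explicit case
        g = truth.genes[0]
        vals = expr.values.copy()
        larva_ids = expr.samples.index[expr.samples.tissue == "larva"]
        nurse_ids = expr.samples.index[
            (expr.samples.tissue == "nurse_head")
            & (expr.samples.nurse_type == "stage_specific")]
        by_colony = expr.samples.loc[larva_ids].reset_index().set_index("colony")
        for nid in nurse_ids:
            colony = expr.samples.loc[nid, "colony"]
            lid = by_colony.loc[colony, "sample_id"]
            vals.loc[g, nid] = vals.loc[g, lid] ** 2   # monotone on positives
        from socint.datamodel import ExpressionMatrix
        expr2 = ExpressionMatrix(vals, expr.samples.copy())
        res = cross_tissue_gene_correlation(expr2, g, "larva", g, "nurse_head")
        assert res.rho == pytest.approx(1.0)

    def test_planted_negative_copula_pair_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(20):
            z1 = rng.normal(size=25)
            z2 = -0.5 * z1 + np.sqrt(1 - 0.25) * rng.normal(size=25)
            rho = stats.spearmanr(np.exp(z1), np.exp(z2))[0]
            hits += -0.8 < rho < -0.2
        assert hits >= 17

    def test_constant_vector_flagged(self, default_experiment):
        _, expr, truth = default_experiment
        g = truth.genes[1]
        vals = expr.values.copy()
        vals.loc[g] = 1.0
        from socint.datamodel import ExpressionMatrix
        expr2 = ExpressionMatrix(vals, expr.samples.copy())
        res = cross_tissue_gene_correlation(expr2, g, "larva",
                                            truth.genes[2], "nurse_head")
        assert not res.defined
        assert np.isnan(res.rho)


class TestPlantedNetworkRecovery:
    def test_social_regulators_recovered_single_seed(self):
        cfg = SimConfig(n_genes_per_tissue=60, n_colonies_per_stage=5,
                        planted_module_fraction=0.0, seed=0)
        expr, truth = simulate_experiment(cfg)
        meta = build_meta_samples(expr, truth.genes, truth.genes, "nurse_head")
        reg = infer_regulatory_matrix(meta, n_trees=100, n_runs=5, seed=0)
        conn = connectivity_summary(reg)
        labels = [truth.is_social_regulator[g] for g in conn["gene_id"]]
        assert ranking_auroc(conn["social_connectivity"], labels) > 0.75

    def test_within_social_tradeoff_negative_rank_correlation(self):
        cfg = SimConfig(n_genes_per_tissue=60, n_colonies_per_stage=5, seed=1)
        expr, truth = simulate_experiment(cfg)
        meta = build_meta_samples(expr, truth.genes, truth.genes, "nurse_head")
        reg = infer_regulatory_matrix(meta, n_trees=100, n_runs=5, seed=1)
        conn = connectivity_summary(reg)
        rho = stats.spearmanr(conn["within_connectivity"],
                              conn["social_connectivity"])[0]
        assert rho < 0
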