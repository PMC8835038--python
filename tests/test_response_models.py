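import numpy as np
import pandas as pd
import pytest

from drugsense.response_models import (
    SimilarityWeights,
    assemble_design,
    cdcn_predict,
    concat_evaluate,
    crossval_rf,
    evaluate,
    similarity_weights,
)
from drugsense.transport import DistanceMatrix


def _toy_tables(n_cells=4, n_drugs=3, n_genes=5, n_desc=2, seed=0):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    drugs = [f"d{i}" for i in range(n_drugs)]
    expr = pd.DataFrame(rng.random((n_cells, n_genes)) + 0.1, index=cells,
                        columns=[f"g{i}" for i in range(n_genes)])
    desc = pd.DataFrame(rng.random((n_drugs, n_desc)), index=drugs,
                        columns=[f"x{i}" for i in range(n_desc)])
    resp = pd.DataFrame(rng.normal(size=(n_cells, n_drugs)), index=cells, columns=drugs)
    return expr, desc, resp


class TestAssembleDesign:
    def test_mask_semantics(self):
        expr, desc, resp = _toy_tables(2, 3)
        resp.iloc[0, 1] = np.nan
        design = assemble_design(["c0", "c1"], ["d0", "d1", "d2"], expr, desc, resp)
        assert design.n_rows == 5
        assert ("c0", "d1") not in design.pairs

    def test_feature_concatenation_width(self):
        expr, desc, resp = _toy_tables(3, 2, n_genes=7, n_desc=4)
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp)
        assert design.X.shape[1] == 11
        assert design.n_gene_features == 7

    def test_fully_missing_drug_contributes_nothing(self):
        expr, desc, resp = _toy_tables(3, 3)
        resp["d2"] = np.nan
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp)
        assert all(d != "d2" for _, d in design.pairs)

    def test_no_observed_pairs_errors(self):
        expr, desc, resp = _toy_tables(2, 2)
        resp[:] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            assemble_design(list(expr.index), list(desc.index), expr, desc, resp)


class TestCrossvalRF:
    def test_constant_target_predicts_constant(self):
        expr, desc, resp = _toy_tables(5, 3)
        resp[:] = 2.5
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp)
        preds = crossval_rf(design, seed=0)
        np.testing.assert_allclose(preds, 2.5)

    def test_linear_signal_recovered(self):
        rng = np.random.default_rng(0)
        n = 300
        cells = [f"c{i}" for i in range(n)]
        x1 = rng.normal(size=n)
        noise_feats = rng.normal(size=(n, 10))
        expr = pd.DataFrame(np.column_stack([x1, noise_feats]) + 10.0, index=cells,
                            columns=[f"g{i}" for i in range(11)])
        desc = pd.DataFrame({"x0": [0.5]}, index=["d0"])
        resp = pd.DataFrame({"d0": x1 + rng.normal(0, 0.1, n)}, index=cells)
        design = assemble_design(cells, ["d0"], expr, desc, resp)
        preds = crossval_rf(design, seed=0)
        assert evaluate(preds, design.y).r2 >= 0.8

    def test_no_signal_control(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            cells = [f"c{i}" for i in range(n)]
            expr = pd.DataFrame(rng.normal(size=(n, 10)) + 10.0, index=cells,
                                columns=[f"g{i}" for i in range(10)])
            desc = pd.DataFrame({"x0": [0.5]}, index=["d0"])
            resp = pd.DataFrame({"d0": rng.normal(size=n)}, index=cells)
            design = assemble_design(cells, ["d0"], expr, desc, resp)
            preds = crossval_rf(design, seed=seed)
            r2s.append(evaluate(preds, design.y).r2)
        assert np.mean(r2s) <= 0.1

    def test_deterministic_given_seed(self):
        expr, desc, resp = _toy_tables(6, 4, seed=3)
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp)
        p1 = crossval_rf(design, seed=11)
        p2 = crossval_rf(design, seed=11)
        np.testing.assert_array_equal(p1, p2)
        p3 = crossval_rf(design, seed=12)
        assert not np.array_equal(p1, p3)

    def test_every_row_predicted_once(self):
        expr, desc, resp = _toy_tables(6, 4, seed=4)
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp)
        preds = crossval_rf(design, seed=0)
        assert len(preds) == design.n_rows
        assert np.isfinite(preds).all()

    def test_too_few_rows_names_cluster(self):
        expr, desc, resp = _toy_tables(2, 2)
        design = assemble_design(list(expr.index), list(desc.index), expr, desc, resp,
                                 cell_cluster=3, drug_cluster=1)
        with pytest.raises(ValueError, match=r"\(3, 1\)"):
            crossval_rf(design, folds=3)


class TestEvaluate:
    def test_perfect_prediction(self):
        ev = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ev.r == pytest.approx(1.0)
        assert ev.r2 == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SS_res = 1, SS_tot = 2 -> R2 = 0.5
        ev = evaluate([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert ev.r2 == pytest.approx(0.5)
        assert ev.r == pytest.approx(0.9820, abs=1e-4)

    def test_constant_prediction_at_mean(self):
        obs = np.array([1.0, 2.0, 3.0])
        ev = evaluate(np.full(3, 2.0), obs)
        assert ev.r2 == pytest.approx(0.0)
        assert np.isnan(ev.r)

    def test_constant_observed_errors(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestConcatEvaluate:
    def test_single_cluster_identity(self):
        ev = evaluate([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        cat = concat_evaluate([ev])
        assert cat.r2 == pytest.approx(ev.r2)

    def test_two_perfect_clusters(self):
        e1 = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        e2 = evaluate([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        cat = concat_evaluate([e1, e2])
        assert cat.r == pytest.approx(1.0)
        assert cat.r2 == pytest.approx(1.0)

    def test_mean_predictors_gain_from_concatenation(self):
        # each cluster predicted by its own mean has R2 = 0 locally,
        # but the concatenation explains the between-cluster spread
        obs1 = np.array([-1.0, 0.0, 1.0])
        obs2 = np.array([9.0, 10.0, 11.0])
        e1 = evaluate(np.zeros(3), obs1)
        e2 = evaluate(np.full(3, 10.0), obs2)
        assert e1.r2 == pytest.approx(0.0)
        assert e2.r2 == pytest.approx(0.0)
        cat = concat_evaluate([e1, e2])
        assert cat.r2 > 0.9

    def test_order_invariant(self):
        e1 = evaluate([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        e2 = evaluate([0.0, 1.0, 3.0], [0.0, 1.0, 2.0])
        assert concat_evaluate([e1, e2]).r2 == pytest.approx(concat_evaluate([e2, e1]).r2)


class TestSimilarityWeights:
    def _dm(self, values, ids):
        return DistanceMatrix(ids=ids, values=np.asarray(values, dtype=float))

    def test_kernel_at_zero_distance(self):
        d = self._dm([[0, 0, 2], [0, 0, 2], [2, 2, 0]], ("a", "b", "c"))
        w = similarity_weights(d, d, mode="wasserstein-kernel")
        # identical pair (distance 0) -> kernel value 1 (diagonal excluded)
        assert w.w[0, 1] == pytest.approx(1.0)

    def test_kernel_at_bandwidth(self):
        # median off-diagonal distance = 2 -> at d = sigma the weight is e^{-1/2}
        d = self._dm([[0, 2, 2], [2, 0, 2], [2, 2, 0]], ("a", "b", "c"))
        w = similarity_weights(d, d, mode="wasserstein-kernel")
        assert w.sigma_cells == pytest.approx(2.0)
        assert w.w[0, 1] == pytest.approx(np.exp(-0.5))

    def test_pearson_clipping(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        feats = pd.DataFrame(
            {"f" + str(i): v for i, v in enumerate([x, -x + 0.1 * rng.normal(size=20)])}
        ).T
        w = similarity_weights(feats, feats, mode="pearson")
        assert w.w[0, 1] == 0.0  # anti-correlated pair clipped to zero


class TestCdcnPredict:
    def test_two_by_two_closed_form(self):
        resp = pd.DataFrame([[1.0, 2.0], [3.0, np.nan]], index=["c1", "c2"],
                            columns=["d1", "d2"])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        weights = SimilarityWeights(("c1", "c2"), w, ("d1", "d2"), w.copy())
        pred = cdcn_predict(resp, weights)
        # yhat(c2, d2) = (y(c1,d2) + y(c2,d1)) / 2 = (2 + 3) / 2
        assert pred.loc["c2", "d2"] == pytest.approx(2.5)

    def test_uniform_weights_give_row_column_mean(self):
        rng = np.random.default_rng(0)
        resp = pd.DataFrame(rng.normal(size=(4, 3)), index=[f"c{i}" for i in range(4)],
                            columns=[f"d{j}" for j in range(3)])
        w = np.ones((4, 4)) - np.eye(4)
        v = np.ones((3, 3)) - np.eye(3)
        weights = SimilarityWeights(tuple(resp.index), w, tuple(resp.columns), v)
        pred = cdcn_predict(resp, weights)
        c, d = "c1", "d2"
        others = np.concatenate([
            resp.loc[resp.index != c, d].to_numpy(),
            resp.loc[c, resp.columns != d].to_numpy(),
        ])
        assert pred.loc[c, d] == pytest.approx(others.mean())

    def test_constant_surface_reproduced(self):
        resp = pd.DataFrame(np.full((3, 3), 4.2), index=list("abc"), columns=list("xyz"))
        rng = np.random.default_rng(1)
        w = rng.random((3, 3)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        weights = SimilarityWeights(tuple("abc"), w, tuple("xyz"), w.copy())
        pred = cdcn_predict(resp, weights)
        np.testing.assert_allclose(pred.to_numpy(), 4.2)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(2)
        resp = pd.DataFrame(rng.normal(size=(4, 4)), index=list("abcd"), columns=list("wxyz"))
        resp.iloc[0, 1] = np.nan
        w = rng.random((4, 4)); w = (w + w.T) / 2; np.fill_diagonal(w, 0)
        v = rng.random((4, 4)); v = (v + v.T) / 2; np.fill_diagonal(v, 0)
        base = cdcn_predict(resp, SimilarityWeights(tuple("abcd"), w, tuple("wxyz"), v))
        scaled = cdcn_predict(resp, SimilarityWeights(tuple("abcd"), 7.3 * w, tuple("wxyz"), 7.3 * v))
        pd.testing.assert_frame_equal(base, scaled)

    def test_no_neighbors_gives_nan(self):
        resp = pd.DataFrame([[1.0, np.nan], [np.nan, np.nan]], index=["c1", "c2"],
                            columns=["d1", "d2"])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        weights = SimilarityWeights(("c1", "c2"), w, ("d1", "d2"), w.copy())
        pred = cdcn_predict(resp, weights)
        assert np.isnan(pred.loc["c2", "d2"])
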