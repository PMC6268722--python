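"""Filtering, beam forward selection, MLR statistics, LOO q²."""

import numpy as np
import pandas as pd
import pytest

from qsarkit.model2d import (ForwardSelectionMLR, filter_correlated,
                             filter_sparse, fit_mlr, forward_select, loo_q2)


class TestFilterSparse:
    def test_all_zero_column_removed(self, rng):
        X = pd.DataFrame({"z": np.zeros(20), "x": rng.normal(size=20)})
        kept, removed = filter_sparse(X, 0.5)
        assert removed == ["z"]

    def test_exactly_at_threshold_retained(self):
        col = np.ones(10)
        col[:2] = 0.0  # exactly 20% zeros
        X = pd.DataFrame({"edge": col})
        kept, removed = filter_sparse(X, 0.20)
        assert removed == [] and "edge" in kept.columns

    def test_survivors_match_independent_recount(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 12)),
                         columns=[f"c{j}" for j in range(12)])
        mask = rng.uniform(size=(50, 12)) < rng.uniform(0, 0.5, size=12)
        X = X.mask(pd.DataFrame(mask, columns=X.columns), 0.0)
        kept, removed = filter_sparse(X, 0.20)
        for c in X.columns:
            frac = float((X[c] == 0).mean())
            assert (c in removed) == (frac > 0.20)

    def test_everything_removed_raises(self):
        X = pd.DataFrame({"a": np.zeros(5), "b": np.zeros(5)})
        with pytest.raises(ValueError, match="threshold"):
            filter_sparse(X, 0.20)


class TestFilterCorrelated:
    def test_duplicated_column_loses_one_copy(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        y = x + rng.normal(scale=0.1, size=30)
        kept, removed = filter_correlated(X, y)
        assert len(removed) == 1 and removed[0] in {"a", "b"}

    def test_independent_columns_survive(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        kept, removed = filter_correlated(X, rng.normal(size=500))
        assert removed == []

    def test_constant_column_removed_first(self, rng):
        X = pd.DataFrame({"k": np.ones(20), "x": rng.normal(size=20)})
        kept, removed = filter_correlated(X, rng.normal(size=20))
        assert removed == ["k"]

    def test_no_surviving_pair_exceeds_threshold(self, rng):
        """Greedy result vs the defining constraint, on a structured case."""
        n = 200
        base = rng.normal(size=n)
        X = pd.DataFrame({
            "a": base,
            "b": base + rng.normal(scale=0.1, size=n),
            "c": base + rng.normal(scale=0.15, size=n),
            "d": rng.normal(size=n),
            "e": rng.normal(size=n),
        })
        y = base + rng.normal(scale=0.3, size=n)
        kept, removed = filter_correlated(X, y, r_threshold=0.8)
        C = np.abs(np.corrcoef(kept.to_numpy(), rowvar=False))
        np.fill_diagonal(C, 0)
        assert C.max() <= 0.8
        # the kept member of the correlated cluster is the one most
        # correlated with y
        cluster = {"a", "b", "c"}
        kept_cluster = cluster & set(kept.columns)
        ry = {c: abs(np.corrcoef(X[c], y)[0, 1]) for c in cluster}
        assert kept_cluster == {max(ry, key=ry.get)}


class TestForwardSelect:
    def test_single_perfect_descriptor_found_immediately(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=list("abcde"))
        y = 2.0 * X["c"]
        subsets = forward_select(X, y, max_descriptors=3)
        assert subsets[0][0] == ("c",)
        assert subsets[0][1] > 0.999

    def test_recovers_two_true_descriptors_among_decoys(self):
        rng = np.random.default_rng(77)
        X = pd.DataFrame(rng.normal(size=(80, 22)),
                         columns=[f"d{j}" for j in range(22)])
        signal = 1.0 * X["d0"] + 0.7 * X["d1"]
        y = signal + rng.normal(scale=0.1 * signal.std(), size=80)
        subsets = forward_select(X, y, max_descriptors=6)
        assert {"d0", "d1"} <= set(subsets[0][0])

    def test_fixed_stop_reaches_requested_size(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)),
                         columns=[f"x{j}" for j in range(10)])
        y = X["x0"] + rng.normal(scale=0.2, size=60)
        subsets = forward_select(X, y, max_descriptors=7, stop="fixed")
        assert len(subsets[0][0]) == 7

    def test_descriptor_count_guard(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 10)))
        X.columns = [f"x{j}" for j in range(10)]
        y = rng.normal(size=20)
        subsets = forward_select(X, y, max_descriptors=10, stop="fixed")
        assert len(subsets[0][0]) <= 4  # n/5 guard at n=20

    def test_invalid_arguments(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            forward_select(X, rng.normal(size=20), max_descriptors=0)


class TestFitMLR:
    def test_exact_line(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = 2.0 * X["x"] + 1.0
        m = fit_mlr(X, y)
        assert m.r2 == pytest.approx(1.0)
        assert m.se_train == pytest.approx(0.0, abs=1e-10)
        assert m.coefficients[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)

    def test_coefficients_match_normal_equations(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
            y = rng.normal(size=25)
            m = fit_mlr(X, y)
            A = np.column_stack([np.ones(25), X.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(m.intercept, beta[0], atol=1e-10)
            assert np.allclose(m.coefficients, beta[1:], atol=1e-10)

    def test_null_model_pvalues_calibrated(self):
        """Under H0 the F-test rejects at ~5%: a simulation of the null."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            X = pd.DataFrame({"x": rng.normal(size=60)})
            y = rng.normal(size=60)
            rejections += fit_mlr(X, y).model_pvalue < 0.05
        rate = rejections / n_sims
        # binomial(200, 0.05): 3 sd ≈ 0.046
        assert abs(rate - 0.05) < 0.05

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=20)})
        with pytest.raises(ValueError, match="collinear"):
            fit_mlr(X, rng.normal(size=20))

    def test_adding_descriptor_never_decreases_r2(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        y = X["a"] + rng.normal(size=40)
        r2 = [fit_mlr(X[list("abcdef")[:k]], y).r2 for k in range(1, 7)]
        assert all(r2[i + 1] >= r2[i] - 1e-12 for i in range(5))


class TestLooQ2:
    def test_perfect_linear_data(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = 3.0 * X.ravel() - 1.0
        q2, se = loo_q2(X, y)
        assert q2 == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_pure_noise_q2_nonpositive_on_average(self):
        rng = np.random.default_rng(99)
        q2s = [loo_q2(rng.normal(size=(30, 2)), rng.normal(size=30))[0]
               for _ in range(100)]
        assert np.mean(q2s) < 0

    def test_q2_never_exceeds_r2(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
            y = X["a"] + rng.normal(scale=0.5, size=25)
            m = fit_mlr(X, y)
            assert m.q2 <= m.r2 + 1e-9


class TestEstimator:
    def test_pipeline_stage_log_and_selection(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 8)),
                         columns=[f"x{j}" for j in range(8)])
        X["dup"] = X["x0"] + rng.normal(scale=0.01, size=n)
        X["sparse"] = 0.0
        y = X["x0"] - X["x1"] + rng.normal(scale=0.2, size=n)
        est = ForwardSelectionMLR(max_descriptors=5).fit(X, y)
        assert "sparse" in est.stage_log_["sparse_removed"]
        assert set(est.stage_log_["correlated_removed"]) & {"dup", "x0"}
        assert est.model_.r2 > 0.8
        preds = est.predict(X)
        assert preds.shape == (n,)

    def test_noiseless_selection_recovers_true_model(self, rng):
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"x{j}" for j in range(10)])
        y = 1.5 * X["x2"] - 0.8 * X["x5"] + 0.3
        est = ForwardSelectionMLR(max_descriptors=5).fit(X, y)
        assert set(est.selected_) == {"x2", "x5"}
        m = est.model_
        coefs = dict(zip(m.descriptors, m.coefficients))
        assert coefs["x2"] == pytest.approx(1.5, abs=1e-8)
        assert coefs["x5"] == pytest.approx(-0.8, abs=1e-8)
        assert m.intercept == pytest.approx(0.3, abs=1e-8)

    def test_sklearn_get_set_params_round_trip(self):
        est = ForwardSelectionMLR(max_descriptors=4)
        params = est.get_params()
        assert params["max_descriptors"] == 4
        est.set_params(max_descriptors=6)
        assert est.max_descriptors == 6
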