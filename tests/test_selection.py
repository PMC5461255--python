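"""Tests of the nested-selection LOOCV engine against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from vocopred import pls, selection


def _problem(rng, n=12, p=5, signal=2.0):
    X = rng.standard_normal((n, p))
    y = signal * X[:, 0] - signal * X[:, 1] + rng.standard_normal(n)
    return X, y


def _sklearn_vip(plsreg):
    """VIP from a fitted scikit-learn PLSRegression (independent route)."""
    W = plsreg.x_weights_
    T = plsreg.x_scores_
    q = plsreg.y_loadings_.ravel()
    ss = q**2 * np.sum(T**2, axis=0)
    p = W.shape[0]
    contrib = (W**2 / np.sum(W**2, axis=0)) @ ss
    return np.sqrt(p * contrib / ss.sum())


def _naive_nested_loocv(X, y, j):
    """Brute-force re-implementation of selection-inside-LOOCV built on
    scikit-learn; used as an oracle only."""
    from sklearn.cross_decomposition import PLSRegression

    n, p = X.shape
    preds = np.empty((n, 3))
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xt, yt = X[tr], y[tr]
        prelim = PLSRegression(n_components=2, scale=True).fit(Xt, yt[:, None])
        order = np.argsort(-_sklearn_vip(prelim), kind="stable")
        keep = np.sort(order[:j])
        preds[i, 0] = yt.mean()
        for a in (1, 2):
            m = PLSRegression(n_components=a, scale=True).fit(
                Xt[:, keep], yt[:, None]
            )
            preds[i, a] = m.predict(X[i : i + 1, keep]).ravel()[0]
    return preds


class TestRankByVIP:
    def test_two_variables_returns_both(self, rng):
        X, y = _problem(rng, 10, 2)
        assert sorted(selection.rank_by_vip(X, y)) == [0, 1]

    def test_ordering_matches_direct_vip(self, rng):
        X, y = _problem(rng, 15, 6)
        model = pls.fit(X, y, 2, scale=True)
        direct = np.argsort(-pls.vip(model), kind="stable")
        assert np.array_equal(selection.rank_by_vip(X, y), direct)

    def test_signal_variables_rank_first_under_strong_effects(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, y = _problem(r, 30, 8, signal=3.0)
            top2 = set(selection.rank_by_vip(X, y)[:2])
            hits += top2 == {0, 1}
        assert hits >= 18


class TestLoocvWithSelection:
    def test_null_prediction_is_leave_one_out_mean(self, rng):
        X, y = _problem(rng)
        res = selection.loocv_with_selection(X, y, 3, n_perm=0)
        n = len(y)
        expected = (y.sum() - y) / (n - 1)
        assert np.allclose(res.predictions[0], expected, atol=1e-12)

    def test_j_equal_p_reduces_to_plain_loocv(self, rng):
        X, y = _problem(rng)
        res = selection.loocv_with_selection(X, y, X.shape[1], n_perm=0)
        plain = selection._loocv_predictions(X, y, 2, scale=True)
        for a in range(3):
            assert np.allclose(res.predictions[a], plain[:, a], atol=1e-10)

    def test_matches_naive_oracle(self, rng):
        pytest.importorskip("sklearn")
        X, y = _problem(rng, n=12, p=5)
        res = selection.loocv_with_selection(X, y, 3, n_perm=0)
        oracle = _naive_nested_loocv(X, y, 3)
        for a in range(3):
            assert np.allclose(res.predictions[a], oracle[:, a], atol=1e-8)

    def test_invalid_j_rejected(self, rng):
        X, y = _problem(rng)
        with pytest.raises(ValueError, match="j must lie"):
            selection.loocv_with_selection(X, y, 1, n_perm=0)
        with pytest.raises(ValueError, match="j must lie"):
            selection.loocv_with_selection(X, y, 99, n_perm=0)

    def test_degenerate_predictor_rejected(self, rng):
        X, y = _problem(rng)
        X[:, 3] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            selection.loocv_with_selection(X, y, 3, n_perm=0)

    def test_seed_determinism(self, rng):
        X, y = _problem(rng)
        a = selection.loocv_with_selection(X, y, 3, n_perm=199, seed=5)
        b = selection.loocv_with_selection(X, y, 3, n_perm=199, seed=5)
        assert a.p_component1 == b.p_component1
        assert a.p_component2 == b.p_component2


class TestPairedPermutationTest:
    def test_identical_errors_not_significant(self, rng):
        e = rng.standard_normal(20)
        p = selection.paired_permutation_test(e, e, n_perm=499, seed=1)
        assert p >= 0.5

    def test_p_value_floor(self):
        # candidate strictly better on every subject: p hits its lower bound
        e_model = np.zeros(30)
        e_ref = np.ones(30)
        p = selection.paired_permutation_test(e_model, e_ref, n_perm=999, seed=2)
        assert p == pytest.approx(1 / 1000)

    def test_worse_model_large_p(self, rng):
        e_model = 3.0 + rng.standard_normal(25)
        e_ref = rng.standard_normal(25) * 0.1
        p = selection.paired_permutation_test(e_model, e_ref, n_perm=999, seed=3)
        assert p > 0.9

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            selection.paired_permutation_test(np.zeros(3), np.zeros(4))


class TestMSEP:
    def test_perfect_prediction_zero(self):
        y = np.arange(5.0)
        assert selection.msep(y, y) == 0.0

    def test_constant_predictor_equals_mean_square_deviation(self, rng):
        y = rng.standard_normal(50)
        c = 0.3
        assert selection.msep(np.full(50, c), y) == pytest.approx(
            np.mean((y - c) ** 2)
        )

    def test_rmsep_is_sqrt(self, rng):
        y = rng.standard_normal(20)
        yhat = y + rng.standard_normal(20)
        assert selection.rmsep(yhat, y) ** 2 == pytest.approx(
            selection.msep(yhat, y)
        )


class TestSweep:
    def test_row_count_and_consistency(self, rng):
        X, y = _problem(rng, 14, 5)
        df = selection.sweep_variable_counts(X, y, n_perm=0, seed=0)
        assert len(df) == (5 - 1) * 2  # j in 2..5, two components
        res3 = selection.loocv_with_selection(X, y, 3, n_perm=0)
        row = df[(df.j == 3) & (df.component == 2)].iloc[0]
        assert row.msep == pytest.approx(res3.msep[2], abs=1e-12)
        assert row.msep_null == pytest.approx(res3.msep[0], abs=1e-12)

    def test_calibrated_data_component_pattern(self):
        """On calibrated synthetic batteries the first component turns
        significant for some variable count while the second does not
        (majority over seeds)."""
        from vocopred import synthetic

        cfg = synthetic.default_config(missing_ospan_old=2)
        c1_hits, c2_holds = 0, 0
        for s in np.random.SeedSequence(21).spawn(10):
            ds = synthetic.generate_battery(cfg, seed=s)
            X, y, _ = ds.analysis_view()
            df = selection.sweep_variable_counts(X, y, n_perm=499, seed=s)
            c1_hits += (df[df.component == 1].p_value < 0.05).any()
            c2_holds += (df[df.component == 2].p_value >= 0.05).all()
        assert c1_hits >= 6
        assert c2_holds >= 6


class TestSubgroups:
    def test_union_reproduces_whole_sample_test(self, rng):
        X, y = _problem(rng, 16, 5)
        res = selection.loocv_with_selection(X, y, 3, n_perm=499, seed=9)
        one_group = np.array(["all"] * 16)
        sub = selection.subgroup_tests(res, one_group, n_perm=499, seed=9)
        whole = selection.paired_permutation_test(
            res.errors(1), res.errors(0), 499,
            np.random.SeedSequence(9).spawn(2)[0],
        )
        assert sub["all"]["component1"] == pytest.approx(whole)

    def test_single_subject_group_rejected(self, rng):
        X, y = _problem(rng, 10, 4)
        res = selection.loocv_with_selection(X, y, 3, n_perm=0)
        groups = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            selection.subgroup_tests(res, groups, n_perm=99)

    def test_matches_manual_subsetting(self, rng):
        X, y = _problem(rng, 16, 5)
        groups = np.array(["young"] * 8 + ["old"] * 8)
        res = selection.loocv_with_selection(X, y, 3, n_perm=0)
        out = selection.subgroup_tests(res, groups, n_perm=499, seed=4)
        ss = np.random.SeedSequence(4).spawn(4)
        sel = groups == "young"
        manual = selection.paired_permutation_test(
            res.errors(1)[sel], res.errors(0)[sel], 499, ss[0]
        )
        assert out["young"]["component1"] == pytest.approx(manual)


class TestEvaluateFinal:
    def test_noiseless_linear_response_r_near_one(self, rng):
        X = rng.standard_normal((20, 4))
        y = 2.0 * X[:, 0] + 5.0
        fin = selection.evaluate_final(X, y, [0, 1], n_perm=0)
        # two components span the two selected variables: exact recovery
        assert fin.r[2] > 0.999
        assert fin.rmsep[2] < 0.05 * y.std()
        assert fin.r[1] > 0.9  # one component close but inexact

    def test_r_invariant_to_affine_response_transform(self, rng):
        X, y = _problem(rng, 15, 5)
        f1 = selection.evaluate_final(X, y, [0, 1, 2], n_perm=0)
        f2 = selection.evaluate_final(X, 3.0 * y - 4.0, [0, 1, 2], n_perm=0)
        for a in (1, 2):
            assert f2.r[a] == pytest.approx(f1.r[a], abs=1e-10)

    def test_predictions_match_naive_per_fold_oracle(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.cross_decomposition import PLSRegression

        X, y = _problem(rng, 12, 5)
        cols = [0, 2, 4]
        fin = selection.evaluate_final(X, y, cols, n_perm=0)
        for i in range(12):
            tr = np.delete(np.arange(12), i)
            m = PLSRegression(n_components=2, scale=True).fit(
                X[tr][:, cols], y[tr][:, None]
            )
            assert fin.predictions[2][i] == pytest.approx(
                m.predict(X[i : i + 1, cols]).ravel()[0], abs=1e-8
            )

    def test_named_variable_selection(self, rng):
        X, y = _problem(rng, 12, 4)
        frame = pd.DataFrame(X, columns=list("abcd"))
        fin = selection.evaluate_final(frame, y, ["a", "c"], n_perm=0)
        assert fin.variables == ["a", "c"]


class TestUnivariateCorrelations:
    def test_self_correlation_and_sign_flip(self, rng):
        y = rng.standard_normal(25)
        X = np.column_stack([y, -y, rng.standard_normal(25)])
        out = selection.univariate_correlations(X, y, n_perm=199, seed=0)
        assert out.r[0] == pytest.approx(1.0)
        assert out.r[1] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        out = selection.univariate_correlations(X, y, n_perm=0)
        for k in range(4):
            assert out.r[k] == pytest.approx(
                np.corrcoef(X[:, k], y)[0, 1], abs=1e-12
            )


class TestZeroScoreRerun:
    def test_no_zero_scores_identical_selection(self, rng):
        X, y = _problem(rng, 14, 5)
        y = y - y.min() + 1.0  # strictly positive
        out = selection.rerun_excluding_zero_scores(
            X, y, n_selected=3, n_perm=0, seed=0
        )
        assert out["n_removed"] == 0
        assert out["primary"]["selected"] == out["excluding_zero"]["selected"]

    def test_removed_count_matches_zeros(self, rng):
        X, y = _problem(rng, 16, 5)
        y = y - y.min() + 1.0
        y[[1, 5, 9]] = 0.0
        out = selection.rerun_excluding_zero_scores(
            X, y, n_selected=3, n_perm=0, seed=0
        )
        assert out["n_removed"] == 3
        overlap = set(out["primary"]["selected"]) & set(
            out["excluding_zero"]["selected"]
        )
        assert out["selection_overlap"] == sorted(overlap)


class TestExhaustiveSubsets:
    def test_subset_count(self, rng):
        X, y = _problem(rng, 12, 3)
        out = selection.exhaustive_subset_regression(X, y, 3)
        assert len(out) == 7  # 2^3 - 1

    def test_noiseless_signal_recovered(self, rng):
        X = rng.standard_normal((15, 4))
        y = 3.0 * X[:, 2]
        out = selection.exhaustive_subset_regression(
            X, y, 2, variable_names=list("abcd")
        )
        assert "c" in out.iloc[0]["variables"]

    def test_press_matches_naive_refit(self, rng):
        X, y = _problem(rng, 10, 3)
        out = selection.exhaustive_subset_regression(X, y, 2)
        for _, row in out.iterrows():
            cols = [int(v[1:]) - 1 for v in row["variables"]]
            errs = []
            for i in range(10):
                tr = np.delete(np.arange(10), i)
                Z = np.column_stack([np.ones(9), X[tr][:, cols]])
                beta, *_ = np.linalg.lstsq(Z, y[tr], rcond=None)
                zi = np.concatenate([[1.0], X[i, cols]])
                errs.append(y[i] - zi @ beta)
            assert row["msep"] == pytest.approx(np.mean(np.square(errs)), abs=1e-8)
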