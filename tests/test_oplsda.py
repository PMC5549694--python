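"""O-PLS core: fitting, prediction, cross-validation, diagnostics."""

import numpy as np
import pytest

from lymphospec.oplsda import (
    OplsError,
    OplsModel,
    autofit,
    center_scale,
    classify,
    confusion_metrics,
    cross_validate_q2,
    dmodx,
    fit_opls,
    hotelling_t2,
    loading_correlations,
    predict_opls,
)

TOL = 1e-8


def random_instance(rng, n=None, m=None, informative=True):
    n = n or int(rng.integers(8, 21))
    m = m or int(rng.integers(4, 31))
    X = rng.normal(size=(n, m))
    if informative:
        y = X[:, 0] * 2.0 + X[:, 1] - X[:, 2] * 0.5 + rng.normal(0, 0.3, n)
    else:
        y = rng.normal(size=n)
    return X, y


class TestCenterScale:
    def test_constant_column_flagged(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        Xs, _, const = center_scale(X, np.arange(5.0), "uv")
        assert const["degenerate"][0] and not const["degenerate"][1]
        np.testing.assert_allclose(Xs[:, 0], 0.0)

    def test_unit_variance(self, rng):
        X = rng.normal(2.0, 5.0, size=(20, 6))
        Xs, ys, _ = center_scale(X, rng.normal(size=20), "uv")
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, rtol=1e-12)
        assert ys.std(ddof=1) == pytest.approx(1.0)

    def test_pareto_divides_by_root_sd(self):
        col = np.array([0.0, 4.0, 8.0, 4.0, 4.0])
        sd = col.std(ddof=1)
        X = np.column_stack([col, col * 0 + np.arange(5.0)])
        Xs, _, const = center_scale(X, np.arange(5.0), "pareto")
        assert const["x_scale"][0] == pytest.approx(np.sqrt(sd))

    def test_too_few_samples(self):
        with pytest.raises(OplsError):
            center_scale(np.ones((2, 3)), np.array([0.0, 1.0]), "uv")


class TestFit:
    def test_k0_matches_independent_pls1(self, rng):
        """With no orthogonal components the model is 1-LV PLS1; an
        independently implemented NIPALS oracle must agree on predictions."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(25):
            X, y = random_instance(rng)
            model = fit_opls(X, y, 0, "uv", y_kind="continuous")
            _, _, y_hat = predict_opls(model, X)
            oracle = sklearn.PLSRegression(n_components=1, scale=True)
            oracle.fit(X, y)
            np.testing.assert_allclose(
                y_hat, oracle.predict(X).ravel(), atol=TOL, rtol=0
            )

    def test_rank_one_noiseless_is_exact(self, rng):
        y = rng.normal(size=12)
        b = rng.normal(size=7)
        X = np.outer(y, b)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        r2 = 1.0 - float(model.F @ model.F) / float(
            ((y - y.mean()) / model.y_scale) @ ((y - y.mean()) / model.y_scale)
        )
        assert r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_structural_invariants(self, rng, k):
        """Reconstruction and all orthogonality constraints hold to 1e-8."""
        X, y = random_instance(rng, n=20, m=15)
        model = fit_opls(X, y, k, "uv", y_kind="continuous")
        Xs = (X - model.x_mean) / model.x_scale
        ys = (y - model.y_mean) / model.y_scale
        recon = np.outer(model.t1, model.p1) + model.To @ model.Po.T + model.E
        np.testing.assert_allclose(recon, Xs, atol=TOL)
        assert np.linalg.norm(model.w) == pytest.approx(1.0, abs=TOL)
        for a in range(k):
            assert np.linalg.norm(model.Wo[:, a]) == pytest.approx(1.0, abs=TOL)
            assert abs(model.To[:, a] @ ys) < TOL * max(1, np.abs(ys).max())
            assert abs(model.t1 @ model.To[:, a]) < 1e-6
            assert abs(model.Wo[:, a] @ model.w) < TOL

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X, y = random_instance(rng, n=25, m=18)
        model = fit_opls(X, y, 2, "uv", y_kind="continuous")
        ys = (y - model.y_mean) / model.y_scale
        for a in range(2):
            assert abs(np.dot(model.To[:, a], ys)) < TOL

    def test_sign_convention_malignant_high(self, rng):
        X = rng.normal(size=(16, 10))
        y = np.r_[np.zeros(8), np.ones(8)]
        X[:, 0] -= 3 * y  # strong *negative* association
        model = fit_opls(X, y, 1, "uv")
        assert model.t1[y == 1].mean() > model.t1[y == 0].mean()
        assert model.q1 >= 0

    def test_constant_response_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(OplsError):
            fit_opls(X, np.ones(10), 1)

    def test_k_too_large_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(OplsError):
            fit_opls(X, rng.normal(size=6), 3)


class TestPredict:
    def test_training_rows_reproduce_scores(self, rng):
        X, y = random_instance(rng, n=15, m=12)
        model = fit_opls(X, y, 2, "uv", y_kind="continuous")
        t1_new, To_new, _ = predict_opls(model, X)
        np.testing.assert_allclose(t1_new, model.t1, atol=TOL)
        np.testing.assert_allclose(To_new, model.To, atol=TOL)

    def test_mean_sample_predicts_mean_response(self, rng):
        X, y = random_instance(rng, n=15, m=12)
        model = fit_opls(X, y, 2, "uv", y_kind="continuous")
        t1, _, y_hat = predict_opls(model, X.mean(axis=0))
        assert t1[0] == pytest.approx(0.0, abs=TOL)
        assert y_hat[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_column_mismatch_error(self, rng):
        X, y = random_instance(rng, n=10, m=8)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        with pytest.raises(OplsError):
            predict_opls(model, np.ones((2, 5)))


class TestCrossValidation:
    def test_q2_bounded_by_r2(self, rng):
        for _ in range(5):
            X, y = random_instance(rng, n=21, m=15)
            rep = cross_validate_q2(X, y, 2, folds=7, y_kind="continuous")
            assert rep.q2y <= rep.r2y + 1e-6

    def test_rank_one_generalizes(self, rng):
        y = rng.normal(size=21)
        X = np.outer(y, rng.normal(size=10))
        rep = cross_validate_q2(X, y, 0, folds=7, y_kind="continuous")
        assert rep.q2y > 0.9

    def test_permuted_labels_have_no_skill(self, rng):
        X, y = random_instance(rng, n=21, m=15)
        q2s = [
            cross_validate_q2(X, rng.permutation(y), 1, folds=7,
                              y_kind="continuous").q2y
            for _ in range(20)
        ]
        assert np.mean(q2s) <= 0.05

    def test_too_few_folds_or_samples(self, rng):
        X, y = random_instance(rng, n=6, m=5)
        with pytest.raises(OplsError):
            cross_validate_q2(X, y, 0, folds=1, y_kind="continuous")

    def test_monotone_training_r2(self, rng):
        X, y = random_instance(rng, n=20, m=15)
        r2s = []
        for k in range(4):
            model = fit_opls(X, y, k, "uv", y_kind="continuous")
            ys = (y - model.y_mean) / model.y_scale
            r2s.append(1.0 - float(model.F @ model.F) / float(ys @ ys))
        assert np.all(np.diff(r2s) >= -1e-10)


class TestAutofit:
    def test_no_orthogonal_structure_gives_zero(self, rng):
        y = rng.normal(size=21)
        X = np.outer(y, rng.normal(size=10)) + rng.normal(0, 1e-3, (21, 10))
        assert autofit(X, y, max_ortho=4, y_kind="continuous") == 0

    def test_strong_orthogonal_factor_detected(self, rng):
        n, m = 28, 20
        y = rng.normal(size=n)
        signal = np.outer(y, rng.normal(size=m))
        ortho = np.outer(rng.normal(size=n), rng.normal(size=m)) * 5.0
        X = signal + ortho + rng.normal(0, 0.1, (n, m))
        assert autofit(X, y, max_ortho=4, y_kind="continuous") >= 1

    def test_max_ortho_zero(self, rng):
        X, y = random_instance(rng)
        assert autofit(X, y, max_ortho=0, y_kind="continuous") == 0


class TestDModX:
    def test_hand_computed_toy(self, rng):
        X, y = random_instance(rng, n=8, m=5)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        d = dmodx(model)
        # independent evaluation of the formula from the stored residuals
        n, m, A = 8, 5, 2
        E = model.E
        s = np.sqrt((E ** 2).sum(axis=1) / (m - A))
        s0 = np.sqrt((E ** 2).sum() / ((n - A - 1) * (m - A)))
        np.testing.assert_allclose(d, s / s0, rtol=1e-12)

    def test_equal_residual_rows_give_equal_dmodx(self, rng):
        X, y = random_instance(rng, n=10, m=6)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        model.E = np.tile(np.r_[1.0, -1.0, 0.5, 0.0, 2.0, -0.5], (10, 1))
        d = dmodx(model)
        np.testing.assert_allclose(d, d[0])

    def test_new_sample_in_model_plane_is_zero(self, rng):
        X, y = random_instance(rng, n=10, m=6)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        # build a new sample lying exactly in the predictive+orthogonal plane
        xs = 1.3 * model.p1 + 0.7 * model.Po[:, 0]
        x_new = xs * model.x_scale + model.x_mean
        d = dmodx(model, x_new)
        assert d[0] == pytest.approx(0.0, abs=1e-6)

    def test_m_not_exceeding_A_errors(self, rng):
        X, y = random_instance(rng, n=10, m=3)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        model.w = model.w[:2]  # force m = 2 = A
        with pytest.raises(OplsError):
            dmodx(model)


class TestHotellingT2:
    def test_origin_scores_zero(self, rng):
        X, y = random_instance(rng, n=12, m=8)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        t2, crit = hotelling_t2(model, scores=np.zeros((1, 2)))
        assert t2[0] == 0.0 and crit > 0.0

    def test_one_sd_score_gives_unit_t2(self, rng):
        X, y = random_instance(rng, n=12, m=8)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        sd = np.sqrt(model.score_variances[0])
        t2, _ = hotelling_t2(model, scores=np.array([[sd]]))
        assert t2[0] == pytest.approx(1.0)

    def test_two_component_hand_example(self, rng):
        X, y = random_instance(rng, n=12, m=8)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        model.score_variances = np.array([4.0, 1.0])
        t2, _ = hotelling_t2(model, scores=np.array([[2.0, 1.0]]))
        assert t2[0] == pytest.approx(2.0)  # 4/4 + 1/1

    def test_training_t2_nonnegative_with_crit(self, rng):
        X, y = random_instance(rng, n=15, m=10)
        model = fit_opls(X, y, 2, "uv", y_kind="continuous")
        t2, crit = hotelling_t2(model)
        assert np.all(t2 >= 0) and crit > 0


class TestLoadingCorrelations:
    def test_bin_proportional_to_scores(self, rng):
        """A column exactly linear in t1 has |correlation| 1."""
        X, y = random_instance(rng, n=15, m=10)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        X2 = X.copy()
        X2[:, 4] = model.t1 * 3.0 + 5.0
        res = loading_correlations(model, X2, orient_benign_positive=False)
        assert abs(res["correlation"][4]) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_flips_sign(self, rng):
        X, y = random_instance(rng, n=15, m=10)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        plain = loading_correlations(model, X, orient_benign_positive=False)
        flipped = loading_correlations(model, X, orient_benign_positive=True)
        np.testing.assert_allclose(
            flipped["correlation"], -plain["correlation"]
        )

    def test_constant_bin_flagged_zero(self, rng):
        X, y = random_instance(rng, n=15, m=10)
        X[:, 0] = 2.0
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        res = loading_correlations(model, X)
        assert res["degenerate"][0]
        assert res["correlation"][0] == 0.0


class TestClassify:
    @pytest.mark.parametrize("y_hat, call", [(0.9, 1), (0.1, 0), (0.5, 1)])
    def test_threshold_and_tie_rule(self, y_hat, call):
        assert classify(np.array([y_hat]))[0] == call

    def test_continuous_model_rejected(self, rng):
        X, y = random_instance(rng, n=10, m=6)
        model = fit_opls(X, y, 0, "uv", y_kind="continuous")
        with pytest.raises(OplsError):
            classify(np.array([0.4]), model)

    def test_confusion_metrics_formula(self, rng):
        for _ in range(10):
            y_true = rng.integers(0, 2, 30)
            y_call = rng.integers(0, 2, 30)
            (tp, fp, tn, fn), sens, spec = confusion_metrics(y_true, y_call)
            assert tp + fp + tn + fn == 30
            if tp + fn:
                assert sens == pytest.approx(100.0 * tp / (tp + fn))
            if tn + fp:
                assert spec == pytest.approx(100.0 * tn / (tn + fp))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = random_instance(rng, n=14, m=9)
        model = fit_opls(X, y, 2, "uv", y_kind="continuous")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = OplsModel.from_json(path)
        _, _, y1 = predict_opls(model, X)
        _, _, y2 = predict_opls(back, X)
        np.testing.assert_allclose(y2, y1, atol=1e-12)
        assert back.scaling_mode == model.scaling_mode

    def test_serialization_is_deterministic(self, rng):
        X, y = random_instance(rng, n=14, m=9)
        model = fit_opls(X, y, 1, "uv", y_kind="continuous")
        assert model.to_json() == model.to_json()
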