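"""Standardization, PLSR fitting, prediction, loadings and biomarker ranking."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from secretosurv import (
    ColumnStandardizer,
    ExpressionMatrix,
    SecretomeSurvivalPLS,
    SurvivalCurveMatrix,
    ValidationError,
    consensus_biomarkers,
    generate_secretome_survival,
    load_model,
    loading_map,
    rank_biomarkers_by_proximity,
    save_model,
    variance_explained,
)


class TestColumnStandardizer:
    def test_simple_column(self):
        z = ColumnStandardizer().fit_transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_zeroed_and_flagged(self):
        s = ColumnStandardizer().fit(np.array([[4.0, 1.0], [4.0, 2.0],
                                               [4.0, 3.0]]))
        z = s.transform(np.array([[4.0, 2.0]]))
        assert z[0, 0] == 0.0
        assert s.zero_variance_.tolist() == [True, False]

    def test_random_matrix_standardized_to_tolerance(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 500, (5, 35))
        s = ColumnStandardizer().fit(M)
        Z = s.transform(M)
        np.testing.assert_allclose(Z.mean(0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(s.inverse_transform(Z), M, atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            ColumnStandardizer().fit(np.array([[1.0, 2.0]]))


def _standardize(M):
    mu, sd = M.mean(0), M.std(0, ddof=1)
    return (M - mu) / sd


def _random_problem(rng, q=None):
    n = int(rng.integers(6, 11))
    p = int(rng.integers(5, 13))
    q = q or int(rng.integers(3, 9))
    return rng.normal(size=(n, p)), rng.normal(size=(n, q))


class TestFit:
    def test_coefficient_matrix_shape_contract(self):
        """5 x 35 predictors and 5 x 21 responses give a 36 x 21 coefficient
        matrix with the intercept row first."""
        expr, surv, _ = generate_secretome_survival(seed=1)
        model = SecretomeSurvivalPLS(n_components=2).fit(expr, surv)
        assert model.coef_.shape == (36, 21)
        # standardized blocks are centered, so the intercept row vanishes
        np.testing.assert_allclose(model.coef_[0], 0.0, atol=1e-9)

    def test_single_predictor_rank1_exact(self):
        """A response that is an exact (replicated) copy of the only
        predictor column is fitted exactly by one component."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 1))
        Y = np.tile(x, (1, 4)) * rng.uniform(0.5, 2.0, 4)
        model = SecretomeSurvivalPLS(n_components=1, clip=False).fit(x, Y)
        assert model.y_variance_explained_[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.predict(x), Y, atol=1e-9)

    def test_orthogonal_design_rank1_exact(self):
        """With sample-orthogonal predictors, a response equal to one
        predictor column is recovered exactly by the first component."""
        m = np.random.default_rng(5).normal(size=(8, 4))
        q_mat, _ = np.linalg.qr(m - m.mean(0))  # orthonormal and centered
        X = q_mat * np.sqrt(8 - 1)              # unit sample sd
        Y = np.tile(X[:, [1]], (1, 3))
        model = SecretomeSurvivalPLS(n_components=1, clip=False).fit(X, Y)
        assert model.y_variance_explained_[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.predict(X), Y, atol=1e-8)

    @pytest.mark.parametrize("algorithm, q_fixed", [
        ("simpls", 1),       # SIMPLS == NIPALS for univariate response
        ("nipals", None),    # multivariate response
    ])
    def test_predictions_match_reference_implementation(self, algorithm,
                                                        q_fixed):
        """Training predictions agree with scikit-learn's PLSRegression run
        on identically standardized blocks, to 1e-8, over 25 random
        problems per route."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            X, Y = _random_problem(rng, q=q_fixed)
            X0, Y0 = _standardize(X), _standardize(Y)
            model = SecretomeSurvivalPLS(
                n_components=2, algorithm=algorithm, clip=False).fit(X0, Y0)
            mine = model.predict(X0, destandardize=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = PLSRegression(n_components=2, scale=False, tol=1e-30,
                                    max_iter=20000).fit(X0, Y0)
            np.testing.assert_allclose(mine, ref.predict(X0).reshape(mine.shape),
                                       atol=1e-8)

    def test_variance_accounting_matches_reference(self):
        """Per-component explained fractions equal those reconstructed from
        the reference fit's scores and loadings."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            X, Y = _random_problem(rng)
            X0, Y0 = _standardize(X), _standardize(Y)
            model = SecretomeSurvivalPLS(n_components=2,
                                         algorithm="nipals").fit(X0, Y0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = PLSRegression(n_components=2, scale=False, tol=1e-30,
                                    max_iter=20000).fit(X0, Y0)
            ss_x = (X0 ** 2).sum()
            ss_y = (Y0 ** 2).sum()
            for a in range(2):
                t = ref.x_scores_[:, a]
                xa = np.outer(t, ref.x_loadings_[:, a])
                ya = np.outer(t, ref.y_loadings_[:, a])
                assert model.x_variance_explained_[a] == pytest.approx(
                    (xa ** 2).sum() / ss_x, abs=1e-8)
                assert model.y_variance_explained_[a] == pytest.approx(
                    (ya ** 2).sum() / ss_y, abs=1e-8)

    def test_cumulative_fraction_bounded_at_full_rank(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 10))
        Y = rng.normal(size=(6, 4))
        model = SecretomeSurvivalPLS(n_components=5).fit(X, Y)
        assert model.x_variance_explained_.sum() <= 1 + 1e-9
        assert model.y_variance_explained_.sum() <= 1 + 1e-9
        assert np.all(model.x_variance_explained_ >= -1e-12)

    def test_training_residuals_shrink_with_components(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(7, 10))
        Y = rng.normal(size=(7, 4))
        prev = np.inf
        for A in range(1, 7):
            model = SecretomeSurvivalPLS(n_components=A, clip=False).fit(X, Y)
            resid = np.linalg.norm(model.predict(X) - Y)
            assert resid <= prev + 1e-9
            prev = resid

    def test_component_cap_and_degenerate_inputs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 10))
        Y = rng.normal(size=(5, 3))
        with pytest.raises(ValidationError, match="n_components"):
            SecretomeSurvivalPLS(n_components=5).fit(X, Y)
        with pytest.raises(ValidationError, match="at least 3"):
            SecretomeSurvivalPLS().fit(X[:2], Y[:2])
        with pytest.raises(ValidationError, match="constant"):
            SecretomeSurvivalPLS().fit(np.ones((5, 3)), Y)

    def test_deterministic_sign_convention(self):
        expr, surv, _ = generate_secretome_survival(seed=8)
        m1 = SecretomeSurvivalPLS().fit(expr, surv)
        m2 = SecretomeSurvivalPLS().fit(expr, surv)
        np.testing.assert_array_equal(m1.x_weights_, m2.x_weights_)
        for a in range(2):
            j = np.argmax(np.abs(m1.x_weights_[:, a]))
            assert m1.x_weights_[j, a] > 0


class TestPredict:
    def test_rank2_noise_free_recovers_training_curves(self):
        expr, surv, _ = generate_secretome_survival(seed=6, noise_sd=0.0,
                                                    latent_rank=2)
        model = SecretomeSurvivalPLS(n_components=2).fit(expr, surv)
        assert model.y_variance_explained_.sum() == pytest.approx(1.0,
                                                                  abs=1e-9)
        pred = model.predict(expr)
        np.testing.assert_allclose(pred.values, surv.values, atol=1e-9)

    def test_clip_projects_into_unit_interval(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        Y = rng.uniform(0, 1, (5, 3))
        model = SecretomeSurvivalPLS(n_components=2, clip=False).fit(X, Y)
        shifted = X + 10.0  # extrapolation drives raw predictions outside
        raw = model.predict(shifted, clip=False)
        clipped = model.predict(shifted, clip=True)
        assert raw.max() > 1.0 or raw.min() < 0.0
        assert clipped.min() >= 0.0 and clipped.max() <= 1.0

    def test_monotone_projection_matches_exhaustive_oracle(self):
        """PAV output equals the best non-increasing fit found by
        enumerating every level partition of a 5-point sequence."""
        def brute(y):
            best, best_sse = None, np.inf
            n = len(y)
            for cuts in itertools.product([0, 1], repeat=n - 1):
                bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
                fit = np.concatenate([
                    np.full(b - a, np.mean(y[a:b]))
                    for a, b in zip(bounds, bounds[1:])])
                if np.all(np.diff(fit) <= 1e-12):
                    sse = ((fit - y) ** 2).sum()
                    if sse < best_sse - 1e-15:
                        best, best_sse = fit, sse
            return best

        from secretosurv.pls import _pav_nonincreasing
        rng = np.random.default_rng(12)
        for _ in range(25):
            y = rng.uniform(0, 1, 5)
            pav = _pav_nonincreasing(y)
            assert np.all(np.diff(pav) <= 1e-12)
            np.testing.assert_allclose(pav, brute(y), atol=1e-9)

    def test_monotone_flag_produces_valid_curves(self):
        expr, surv, _ = generate_secretome_survival(seed=3)
        model = SecretomeSurvivalPLS(monotone=True).fit(expr, surv)
        pred = model.predict(expr)
        assert np.all(np.diff(pred.values, axis=1) <= 1e-12)
        assert "monotone(PAV)" in pred.metadata["postprocessing"]

    def test_column_order_corrected_by_name(self):
        expr, surv, _ = generate_secretome_survival(seed=2)
        model = SecretomeSurvivalPLS().fit(expr, surv)
        shuffled = ExpressionMatrix(expr.frame[list(expr.frame.columns[::-1])])
        np.testing.assert_allclose(model.predict(shuffled).values,
                                   model.predict(expr).values)

    def test_analyte_mismatch_lists_names(self):
        expr, surv, _ = generate_secretome_survival(seed=2, n_analytes=5,
                                                    n_informative=3)
        model = SecretomeSurvivalPLS().fit(expr, surv)
        missing = ExpressionMatrix(expr.frame.drop(columns=["analyte03"]))
        with pytest.raises(ValidationError, match="analyte03"):
            model.predict(missing)

    def test_prediction_invariant_to_column_rescaling(self):
        """Standardization absorbs units: scaling any analyte's raw
        concentrations (train and test together) leaves predictions put."""
        expr, surv, _ = generate_secretome_survival(seed=4)
        base = SecretomeSurvivalPLS().fit(expr, surv).predict(expr)
        scaled_frame = expr.frame.copy()
        scaled_frame.iloc[:, 7] *= 1000.0
        scaled = ExpressionMatrix(scaled_frame)
        pred = SecretomeSurvivalPLS().fit(scaled, surv).predict(scaled)
        np.testing.assert_allclose(pred.values, base.values, atol=1e-9)

    def test_zero_variance_response_column_predicted_as_constant(self):
        expr, surv, _ = generate_secretome_survival(seed=5)
        # day 0 is all ones (zero variance) by construction
        model = SecretomeSurvivalPLS().fit(expr, surv)
        pred = model.predict(expr)
        np.testing.assert_allclose(pred.values[:, 0], 1.0, atol=1e-12)


class TestLoadingsAndRanking:
    @pytest.fixture(scope="class")
    def fitted(self):
        expr, surv, truth = generate_secretome_survival(seed=1)
        return SecretomeSurvivalPLS().fit(expr, surv), truth

    def test_loading_map_has_all_coordinates(self, fitted):
        model, _ = fitted
        lm = loading_map(model)
        assert len(lm.frame) == 35 + 21
        assert set(lm.frame["kind"]) == {"analyte", "timepoint"}

    def test_identical_variable_pair_is_parallel_and_rank1(self):
        expr, surv, _ = generate_secretome_survival(seed=7)
        frame = expr.frame.copy()
        # make one analyte a copy (after standardization) of one timepoint
        frame["analyte35"] = surv.frame.iloc[:, 10] * 1e4
        expr2 = ExpressionMatrix(frame)
        model = SecretomeSurvivalPLS().fit(expr2, surv)
        ranking = rank_biomarkers_by_proximity(model)
        top = ranking.frame.iloc[0]
        assert top["analyte"] == "analyte35"
        assert top["proximity"] == pytest.approx(1.0, abs=1e-9)
        assert top["rank"] == 1

    def test_full_ranking_is_permutation(self, fitted):
        model, _ = fitted
        ranking = rank_biomarkers_by_proximity(model, top_k=35)
        assert sorted(ranking.frame["rank"]) == list(range(1, 36))
        assert np.all(np.abs(ranking.frame["proximity"]) <= 1 + 1e-12)

    def test_planted_informative_sit_close_to_response_loadings(self):
        """At low noise every planted analyte's loading points almost
        exactly at the survival-timepoint loadings (cosine ~ 1), and the
        planted set dominates the proximity top-8.  A 2-D cosine cannot
        fully separate chance-correlated noise analytes at n = 5 groups,
        so exact top-8 recovery is not asserted."""
        overlaps = []
        for seed in range(30):
            expr, surv, truth = generate_secretome_survival(seed=seed,
                                                            noise_sd=0.02)
            model = SecretomeSurvivalPLS().fit(expr, surv)
            ranking = rank_biomarkers_by_proximity(model)
            prox = ranking.frame.set_index("analyte")["proximity"]
            assert prox.loc[truth.informative].min() > 0.98
            overlaps.append(
                len(set(ranking.top(8)) & set(truth.informative)))
        assert min(overlaps) >= 4
        assert np.mean(overlaps) >= 6.0

    def test_map_stable_across_refits(self, fitted):
        model, _ = fitted
        expr, surv, _ = generate_secretome_survival(seed=1)
        again = SecretomeSurvivalPLS().fit(expr, surv)
        np.testing.assert_array_equal(loading_map(model).frame["comp1"],
                                      loading_map(again).frame["comp1"])

    def test_requires_two_components(self):
        expr, surv, _ = generate_secretome_survival(seed=1)
        m1 = SecretomeSurvivalPLS(n_components=1).fit(expr, surv)
        with pytest.raises(ValidationError, match="2 components"):
            loading_map(m1)
        with pytest.raises(ValidationError, match="2 components"):
            rank_biomarkers_by_proximity(m1)


class TestConsensus:
    def test_published_hit_lists_overlap_in_eight(self):
        pearson = {"ANG-1", "BMP2", "EGF", "FGF1", "IL-15", "IL-6", "IL-8",
                   "RANTES", "VEGF-A", "THPO"}
        plsr = {"IL-6", "IL-8", "BMP2", "EGF", "FGF1", "MCP-1", "RANTES",
                "VEGF-A", "ANG-1"}
        cons = consensus_biomarkers(pearson, plsr)
        assert cons.overlap == sorted(
            ["ANG-1", "BMP2", "EGF", "FGF1", "IL-6", "IL-8", "RANTES",
             "VEGF-A"])
        assert cons.n_overlap == 8
        assert cons.n_pearson == 10 and cons.n_plsr == 9

    def test_disjoint_and_identical(self):
        assert consensus_biomarkers({"a"}, {"b"}).overlap == []
        assert consensus_biomarkers({"a", "b"}, {"b", "a"}).overlap == ["a", "b"]


class TestSerialization:
    def test_roundtrip_predictions_bit_identical(self, tmp_path):
        expr, surv, _ = generate_secretome_survival(seed=11)
        model = SecretomeSurvivalPLS().fit(expr, surv)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        p1 = model.predict(expr)
        p2 = back.predict(expr)
        assert np.array_equal(p1.values, p2.values)
        assert variance_explained(back)["y_cumulative"].iloc[-1] == \
            pytest.approx(model.y_variance_explained_.sum())

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text("{}")
        with pytest.raises(ValidationError, match="not a model file"):
            load_model(path)
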