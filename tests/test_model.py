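import numpy as np
import pandas as pd
import pytest

import xbrainage as xb


def _frame(arr, index=None):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, index=index,
                        columns=[f"f{j}" for j in range(arr.shape[1])])


class TestStandardize:
    def test_fresh_stats_give_zero_mean_unit_sd(self, rng):
        X = _frame(rng.normal(3, 5, size=(40, 6)))
        z, (mean, sd) = xb.standardize(X)
        np.testing.assert_allclose(z.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_own_stats_equal_fresh(self, rng):
        X = _frame(rng.normal(size=(20, 3)))
        z1, st = xb.standardize(X)
        z2, _ = xb.standardize(X, st)
        pd.testing.assert_frame_equal(z1, z2)

    def test_foreign_stats_hand_computed(self):
        A = _frame([[0.0, 10.0], [2.0, 20.0], [4.0, 30.0]])
        B = _frame([[1.0, 5.0], [3.0, 25.0], [5.0, 45.0]])
        _, st = xb.standardize(A)
        zB, _ = xb.standardize(B, st)
        # A stats: means (2, 20), sds (2, 10) -> hand-computed z of B
        expect = np.array([[-0.5, -1.5], [0.5, 0.5], [1.5, 2.5]])
        np.testing.assert_allclose(zB.to_numpy(), expect, atol=1e-12)

    def test_zero_sd_rejected(self):
        X = _frame([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="f0"):
            xb.standardize(X)


class TestFitLinearModel:
    def test_exact_interpolation_and_slope_units(self, rng):
        f1 = rng.normal(size=50)
        X = _frame(np.column_stack([f1, rng.normal(size=50)]))
        ages = pd.Series(2 * X["f0"] + 3, index=X.index)
        m = xb.fit_linear_model(X, ages, ["f0"])
        np.testing.assert_allclose(m.predict(X), ages, atol=1e-10)
        # coefficient is in years per SD of the feature
        assert m.coef[0] == pytest.approx(2 * X["f0"].std(ddof=1))

    def test_duplicated_column_min_norm(self, rng):
        X = _frame(rng.normal(size=(5, 2)))
        X["f1"] = X["f0"]
        ages = pd.Series(rng.uniform(8, 14, 5), index=X.index)
        m_dup = xb.fit_linear_model(X, ages, ["f0", "f1"])
        m_one = xb.fit_linear_model(X, ages, ["f0"])
        np.testing.assert_allclose(m_dup.predict(X), m_one.predict(X),
                                   atol=1e-8)
        # min-norm splits the coefficient across the two copies
        assert m_dup.coef[0] == pytest.approx(m_dup.coef[1])
        assert m_dup.coef[0] + m_dup.coef[1] == pytest.approx(m_one.coef[0])

    def test_more_features_than_subjects_interpolates(self, rng):
        X = _frame(rng.normal(size=(10, 30)))
        ages = pd.Series(rng.uniform(8, 14, 10), index=X.index)
        m = xb.fit_linear_model(X, ages, list(X.columns))
        pred = m.predict(X)
        assert np.isfinite(pred).all()
        np.testing.assert_allclose(pred, ages, atol=1e-8)

    def test_empty_feature_set_rejected(self, rng):
        X = _frame(rng.normal(size=(10, 2)))
        ages = pd.Series(rng.uniform(8, 14, 10), index=X.index)
        with pytest.raises(ValueError):
            xb.fit_linear_model(X, ages, [])


class TestEvaluate:
    def test_perfect_prediction(self):
        r, p, mae = xb.evaluate([8, 10, 12, 14], [8, 10, 12, 14])
        assert (r, mae) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_shift_invariance_of_r(self):
        r, p, mae = xb.evaluate([8, 10, 12, 14], [9, 11, 13, 15])
        assert r == pytest.approx(1.0)
        assert mae == pytest.approx(1.0)

    def test_arithmetic_oracle(self):
        actual = np.array([8, 10, 12, 14], float)
        pred = np.array([9, 9, 13, 13], float)
        r, p, mae = xb.evaluate(actual, pred)
        assert mae == pytest.approx(1.0)
        ac, pc = actual - actual.mean(), pred - pred.mean()
        r_expect = (ac * pc).sum() / np.sqrt((ac ** 2).sum() * (pc ** 2).sum())
        assert r == pytest.approx(r_expect, abs=1e-12)

    def test_constant_predictions_flagged(self):
        r, p, mae = xb.evaluate([8, 10, 12], [11, 11, 11])
        assert np.isnan(r) and np.isnan(p)
        assert mae == pytest.approx(5 / 3)


class TestCvPredict:
    def test_noiseless_data_near_perfect(self):
        cfg = xb.SimConfig(n_human=100, n_macaque=10, noise_sd=0.0,
                           baseline_sd=0.5, n_common_informative=5,
                           n_human_specific=5, n_macaque_specific=0,
                           latent_loading=0.0, rng_seed=19)
        cohort, features, truth = xb.generate_cohort(cfg)
        hum = cohort.index[cohort["species"] == "human"]
        res = xb.cv_predict(features.loc[hum], cohort.loc[hum, "age"],
                            truth.informative_features("human"),
                            n_reps=3, seed=0)
        assert res.r > 0.999
        assert res.mae < 0.01

    def test_determinism(self, rng):
        X = _frame(rng.normal(size=(40, 6)))
        ages = pd.Series(rng.uniform(8, 14, 40), index=X.index)
        X["f0"] = ages + rng.normal(size=40)
        a = xb.cv_predict(X, ages, list(X.columns), n_reps=4, seed=9)
        b = xb.cv_predict(X, ages, list(X.columns), n_reps=4, seed=9)
        pd.testing.assert_series_equal(a.predicted, b.predicted)

    def test_every_subject_predicted_each_repetition(self, rng):
        X = _frame(rng.normal(size=(35, 4)))
        ages = pd.Series(rng.uniform(8, 14, 35), index=X.index)
        res = xb.cv_predict(X, ages, list(X.columns), n_reps=5, seed=2)
        assert res.per_repetition.shape == (5, 35)
        assert np.isfinite(res.per_repetition.to_numpy()).all()

    def test_null_features_predict_near_mean(self, rng):
        X = _frame(rng.normal(size=(120, 5)))
        ages = pd.Series(rng.uniform(8, 14, 120), index=X.index)
        res = xb.cv_predict(X, ages, list(X.columns), n_reps=10, seed=3)
        # age-independent features: predictions hug the training mean age
        assert abs(res.predicted.mean() - ages.mean()) < 0.3
        assert res.predicted.std() < 0.5 * ages.std()

    def test_age_shift_equivariance(self, rng):
        X = _frame(rng.normal(size=(40, 5)))
        ages = pd.Series(rng.uniform(8, 14, 40), index=X.index)
        a = xb.cv_predict(X, ages, list(X.columns), n_reps=3, seed=5)
        b = xb.cv_predict(X, ages + 7.5, list(X.columns), n_reps=3, seed=5)
        np.testing.assert_allclose(b.predicted, a.predicted + 7.5,
                                   atol=1e-8)

    def test_feature_rescale_invariance(self, rng):
        X = _frame(rng.normal(size=(40, 5)))
        ages = pd.Series(rng.uniform(8, 14, 40), index=X.index)
        a = xb.cv_predict(X, ages, list(X.columns), n_reps=3, seed=6)
        X2 = X.copy()
        X2["f2"] = X2["f2"] * 1234.5
        b = xb.cv_predict(X2, ages, list(X.columns), n_reps=3, seed=6)
        np.testing.assert_allclose(b.predicted, a.predicted, atol=1e-8)


class TestFullModelAndTransfer:
    def test_full_model_equals_plain_fit(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        ages = pd.Series(rng.uniform(8, 14, 30), index=X.index)
        a = xb.fit_linear_model(X, ages, list(X.columns))
        b = xb.fit_full_model(X, ages, list(X.columns))
        np.testing.assert_allclose(a.coef, b.coef)
        assert a.intercept == b.intercept

    def test_in_sample_r_at_least_cv_r(self, human_tables):
        cohort, features, _, truth = human_tables
        feats = truth.informative_features("human")
        m = xb.fit_full_model(features, cohort["age"], feats)
        r_in, _, _ = xb.evaluate(cohort["age"], m.predict(features))
        res = xb.cv_predict(features, cohort["age"], feats, n_reps=3,
                            seed=4)
        assert r_in >= res.r

    def test_cross_predict_on_training_table_is_in_sample(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        ages = pd.Series(rng.uniform(8, 14, 30), index=X.index)
        m = xb.fit_full_model(X, ages, list(X.columns))
        np.testing.assert_allclose(xb.cross_predict(m, X), m.predict(X),
                                   atol=1e-10)

    def test_intercept_is_fallback_prediction(self, rng):
        X = _frame(rng.normal(size=(30, 3)))
        ages = pd.Series(rng.uniform(8, 14, 30), index=X.index)
        m = xb.fit_full_model(X, ages, list(X.columns))
        z = pd.DataFrame(np.zeros((4, 3)), columns=X.columns)
        np.testing.assert_allclose(m.predict_standardized(z),
                                   m.intercept, atol=1e-12)
        # intercept of z-scored OLS is the training mean age
        assert m.intercept == pytest.approx(ages.mean())

    def test_missing_homologous_feature_named(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        ages = pd.Series(rng.uniform(8, 14, 30), index=X.index)
        m = xb.fit_full_model(X, ages, list(X.columns))
        with pytest.raises(KeyError, match="f3"):
            xb.cross_predict(m, X.drop(columns=["f3"]))

    def test_planted_slopes_recovered_forward_fit(self, human_tables):
        """Feature-on-age OLS recovers planted slopes within ~2 SE."""
        cohort, features, _, truth = human_tables
        import statsmodels.api as sm
        age = sm.add_constant(cohort["age"].to_numpy())
        for f in truth.informative_features("human")[:15]:
            fit = sm.OLS(features[f].to_numpy(), age).fit()
            planted = truth.slopes_human[f]
            assert abs(fit.params[1] - planted) < 3 * fit.bse[1]
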