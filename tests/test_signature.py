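import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from fearsig import (
    BetaImageSet,
    CVScheme,
    SignatureModel,
    compute_metrics,
    crossvalidate,
    crossvalidate_apply,
    explained_variance_score,
    forced_choice_from_values,
    permutation_test,
    timeseries_expression,
    train_signature,
    trialwise_within_subject_eval,
)
from fearsig.datasets import PredictionPairSet


def svr_dual_qp_oracle(X, y, C=1.0, epsilon=0.1):
    """Independent ε-SVR weight oracle: solve the dual QP directly."""
    n = len(y)
    K = X @ X.T

    def objective(v):
        a, a_star = v[:n], v[n:]
        beta = a - a_star
        return 0.5 * beta @ K @ beta + epsilon * (a + a_star).sum() - y @ beta

    cons = {"type": "eq", "fun": lambda v: (v[:n] - v[n:]).sum()}
    bounds = [(0.0, C)] * (2 * n)
    best = None
    for s in range(3):
        rng = np.random.default_rng(s)
        res = minimize(
            objective, rng.uniform(0, C / 2, 2 * n), method="SLSQP",
            bounds=bounds, constraints=cons,
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta = best.x[:n] - best.x[n:]
    return X.T @ beta


class TestTraining:
    def test_constant_labels_rejected(self):
        ds = BetaImageSet(
            data=np.random.default_rng(0).normal(size=(6, 4)),
            subject_ids=np.arange(6),
            ratings=np.full(6, 3.0),
        )
        with pytest.raises(ValueError, match="constant"):
            train_signature(ds)

    def test_weights_match_qp_oracle_on_toy(self):
        """SVR weights agree with an independently solved dual QP."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 2))
        y = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        ds = BetaImageSet(data=X, subject_ids=np.arange(6), ratings=y)
        model = train_signature(ds)
        oracle_w = svr_dual_qp_oracle(X, y)
        assert np.max(np.abs(model.weights - oracle_w)) < 1e-4

    def test_training_deterministic(self, tiny_cohort):
        _, cond_set, _ = tiny_cohort
        m1 = train_signature(cond_set)
        m2 = train_signature(cond_set)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.intercept == m2.intercept

    def test_standardized_training_applies_to_raw_maps(self, tiny_cohort):
        _, cond_set, _ = tiny_cohort
        model = train_signature(cond_set, scaling="standardize")
        # the fold-back must reproduce predictions on standardized features
        X = cond_set.data
        mu, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1.0
        from sklearn.svm import SVR

        svr = SVR(kernel="linear", C=1.0, epsilon=0.1)
        svr.fit((X - mu) / sd, cond_set.ratings)
        expected = svr.predict((X - mu) / sd)
        np.testing.assert_allclose(model.apply(X), expected, atol=1e-8)


class TestCVScheme:
    def test_fold_sizes_six_or_seven_for_67_subjects(self):
        scheme = CVScheme(n_folds=10, n_repeats=1, seed=0)
        subjects = np.array([f"s{i}" for i in range(67)])
        sizes = [len(test) for _, _, test in scheme.splits(subjects)]
        assert set(sizes) == {6, 7}

    def test_subject_never_in_train_and_test(self, tiny_cohort, tiny_scheme):
        _, cond_set, _ = tiny_cohort
        for _, train, test in tiny_scheme.splits(cond_set.subjects):
            assert not set(train) & set(test)
        # and each subject is tested exactly once per repeat
        counts = {}
        for rep, _, test in tiny_scheme.splits(cond_set.subjects):
            for s in test:
                counts[(rep, s)] = counts.get((rep, s), 0) + 1
        assert set(counts.values()) == {1}

    def test_too_few_subjects_rejected(self, tiny_cohort):
        _, cond_set, _ = tiny_cohort
        with pytest.raises(ValueError, match="fewer subjects"):
            crossvalidate(cond_set, CVScheme(n_folds=50))

    def test_fold_models_independent_of_test_subjects(self, tiny_cohort):
        """Training-fold weights depend only on the training subjects."""
        _, cond_set, _ = tiny_cohort
        subjects = cond_set.subjects
        train = cond_set.subset_subjects(subjects[:6])
        w1 = train_signature(train).weights
        # retrain after removing an unrelated (held-out) subject from the set
        smaller = cond_set.subset_subjects(subjects[:7])
        w2 = train_signature(smaller.subset_subjects(subjects[:6])).weights
        assert np.array_equal(w1, w2)


class TestPatternExpression:
    def test_zero_image_returns_intercept(self):
        model = SignatureModel(weights=np.ones(5), intercept=2.25)
        assert model.apply(np.zeros(5)) == pytest.approx(2.25)

    def test_single_unit_weight(self):
        w = np.zeros(4)
        w[1] = 1.0
        model = SignatureModel(weights=w, intercept=0.0)
        img = np.array([9.0, 2.5, -1.0, 3.0])
        assert model.apply(img) == pytest.approx(2.5)

    def test_linearity_identity(self):
        rng = np.random.default_rng(1)
        model = SignatureModel(weights=rng.normal(size=6), intercept=0.7)
        A, B = rng.normal(size=6), rng.normal(size=6)
        alpha, beta = 1.7, -0.4
        lhs = model.apply(alpha * A + beta * B)
        rhs = (alpha * model.apply(A) + beta * model.apply(B)
               - (alpha + beta - 1) * model.intercept)
        assert lhs == pytest.approx(rhs)

    def test_mask_fingerprint_mismatch_rejected(self, tiny_cohort):
        _, cond_set, _ = tiny_cohort
        model = train_signature(cond_set)
        with pytest.raises(ValueError, match="space"):
            model.apply(cond_set.data, fingerprint="other-space")


class TestMetrics:
    def test_perfect_prediction_endpoints(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pairs = PredictionPairSet(predicted=y, actual=y,
                                  subject_ids=np.ones(5))
        m = compute_metrics(pairs)
        assert m.evs == pytest.approx(1.0)
        assert m.overall_r == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)

    def test_mean_prediction_gives_zero_evs(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert explained_variance_score(y, np.full(4, y.mean())) == \
            pytest.approx(0.0)

    def test_hand_computed_example(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 2.0, 4.0])
        assert explained_variance_score(y, yhat) == pytest.approx(2.0 / 3.0)
        pairs = PredictionPairSet(predicted=yhat, actual=y,
                                  subject_ids=np.ones(3))
        assert compute_metrics(pairs).rmse == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_agreement_with_hand_coded_formulas(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        yhat = 0.5 * y + rng.normal(size=40)
        subs = np.repeat(np.arange(4), 10)
        m = compute_metrics(PredictionPairSet(predicted=yhat, actual=y,
                                              subject_ids=subs))
        # independent formula implementations
        r_hand = (np.sum((y - y.mean()) * (yhat - yhat.mean()))
                  / np.sqrt(np.sum((y - y.mean()) ** 2)
                            * np.sum((yhat - yhat.mean()) ** 2)))
        rmse_hand = np.sqrt(np.sum((y - yhat) ** 2) / 40)
        d = y - yhat
        evs_hand = 1 - (np.sum((d - d.mean()) ** 2) / 39) / (
            np.sum((y - y.mean()) ** 2) / 39
        )
        assert abs(m.overall_r - r_hand) < 1e-12
        assert abs(m.rmse - rmse_hand) < 1e-12
        assert abs(m.evs - evs_hand) < 1e-12

    def test_constant_actual_gives_missing_evs(self):
        assert np.isnan(explained_variance_score(np.ones(5),
                                                 np.arange(5.0)))


class TestForcedChoice:
    def _toy(self):
        rng = np.random.default_rng(4)
        subs = np.repeat(np.arange(5), 5)
        ratings = np.tile(np.arange(1.0, 6.0), 5)
        values = ratings * 0.5 + rng.normal(0, 1.0, 25)
        return values, ratings, subs

    def test_equals_enumeration_oracle(self):
        """Accuracy matches direct per-subject comparison of condition means."""
        values, ratings, subs = self._toy()
        res = forced_choice_from_values(values, ratings, subs, ("high", "low"))
        wins = 0.0
        for s in range(5):
            hi = values[(subs == s) & np.isin(ratings, (4, 5))].mean()
            lo = values[(subs == s) & np.isin(ratings, (1, 2))].mean()
            wins += 1.0 if hi > lo else (0.5 if hi == lo else 0.0)
        assert res.accuracy == pytest.approx(wins / 5)

    def test_oracle_signature_on_noiseless_cohort(self, tiny_space,
                                                  noiseless_truth):
        from fearsig import CohortConfig, generate_cohort

        cfg = CohortConfig(n_subjects=5, trials_per_subject=25, seed=9,
                           drop_top_level_subjects=0)
        _, cond, _ = generate_cohort(tiny_space, noiseless_truth, cfg)
        model = SignatureModel(weights=noiseless_truth.encoding_pattern,
                               intercept=0.0)
        values = model.apply_dataset(cond)
        for contrast in (("high", "low"), ("high", "moderate"),
                         ("moderate", "low"), (5, 4), (3, 2)):
            res = forced_choice_from_values(values, cond.ratings,
                                            cond.subject_ids, contrast)
            assert res.accuracy == 1.0

    def test_successive_level_contrast(self):
        values, ratings, subs = self._toy()
        res = forced_choice_from_values(values, ratings, subs, (2, 1))
        assert 0.0 <= res.accuracy <= 1.0
        assert res.n_subjects == 5

    def test_subject_missing_condition_excluded(self):
        values = np.array([1.0, 2.0, 0.5, 1.5, 3.0])
        ratings = np.array([1.0, 5.0, 1.0, 2.0, 2.0])  # s1 lacks high
        subs = np.array([0, 0, 1, 1, 1])
        res = forced_choice_from_values(values, ratings, subs, ("high", "low"))
        assert res.n_subjects == 1


class TestPermutation:
    def test_perfect_predictor_minimal_p(self):
        ratings = np.tile(np.arange(1.0, 6.0), 4)
        subs = np.repeat(np.arange(4), 5)
        values = ratings.copy()  # perfect expressions

        def statistic(perm):
            return stats.pearsonr(values, perm)[0]

        obs, p = permutation_test(statistic, ratings, subs, n_perm=200, seed=0)
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 201.0)

    def test_p_in_unit_interval_and_warning(self):
        ratings = np.tile(np.arange(1.0, 6.0), 2)
        subs = np.repeat(np.arange(2), 5)
        with pytest.warns(UserWarning, match="n_perm"):
            _, p = permutation_test(lambda r: r.sum(), ratings, subs,
                                    n_perm=20, seed=1)
        assert 0 < p <= 1


class TestTimeseriesExpression:
    def test_zero_series_flat_at_intercept(self):
        model = SignatureModel(weights=np.ones(4), intercept=1.5)
        out = timeseries_expression(model, np.zeros((20, 4)), tr=2.0)
        assert np.allclose(out.expression, 1.5)

    def test_peristimulus_peak_latency_and_ordering(self, tiny_space,
                                                    noiseless_truth):
        """At high SNR the expression peaks 4-6 s post-onset (HRF latency)
        and the peak amplitude scales with rating."""
        import pandas as pd
        from fearsig import generate_timeseries

        onsets = 10.0 + np.arange(10) * 30.0
        events = pd.DataFrame({
            "onset": onsets, "duration": 0.5,  # brief event: peak ~5 s
            "rating": np.tile([1, 5], 5),
        })
        truth = noiseless_truth
        Y, _ = generate_timeseries(
            tiny_space, truth, events, 2.0, 170,
            drift_amplitude=0.0, ar_phi=0.0, noise_sd=0.05, seed=3,
        )
        model = SignatureModel(weights=truth.encoding_pattern, intercept=0.0)
        out = timeseries_expression(model, Y, 2.0, events, window_s=(0, 16))
        peri = out.peristimulus
        for level in (1.0, 5.0):
            curve = peri[peri.rating == level].set_index("time_s")["mean"]
            assert 4.0 <= curve.idxmax() <= 6.0
        peak = peri.groupby("rating")["mean"].max()
        assert peak[5.0] > peak[1.0]


class TestTrialwiseEval:
    def test_noiseless_cohort_perfect_within_subject_r(self, tiny_space,
                                                       noiseless_truth):
        from fearsig import CohortConfig, generate_cohort

        cfg = CohortConfig(n_subjects=4, trials_per_subject=20, seed=2,
                           drop_top_level_subjects=0)
        trials, _, _ = generate_cohort(tiny_space, noiseless_truth, cfg)
        model = SignatureModel(weights=noiseless_truth.encoding_pattern,
                               intercept=0.0)
        table = trialwise_within_subject_eval(model.apply_dataset(trials),
                                              trials)
        assert np.allclose(table.r, 1.0)

    def test_short_subjects_skipped(self, tiny_cohort):
        trials, _, _ = tiny_cohort
        table = trialwise_within_subject_eval(
            np.zeros(trials.n_obs) + np.random.default_rng(0).normal(
                size=trials.n_obs),
            trials, min_trials=31,
        )
        assert table.empty


def test_crossvalidate_apply_matches_direct_cv(tiny_cohort, tiny_scheme):
    """Applying fold models to the training set itself reproduces
    crossvalidate exactly."""
    _, cond_set, _ = tiny_cohort
    direct = crossvalidate(cond_set, tiny_scheme)
    via_apply = crossvalidate_apply(cond_set, cond_set, tiny_scheme)
    assert np.array_equal(direct.predicted, via_apply.predicted)
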