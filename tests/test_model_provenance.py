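"""Audited models: fits against independent oracles, provenance invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from fairprov.cohort_sim import CohortSpec, generate_cohort
from fairprov.model_provenance import (
    DEFAULT_FEATURES,
    PAPER_GRID,
    LogisticAuditModel,
    fit_forest,
    fit_logistic,
    load_model,
    predict_with_provenance,
    refit_without_feature,
    tune_forest,
)
from fairprov.seeding import substream


def _table(X, y, features):
    t = pd.DataFrame(X, columns=list(features))
    t["outcome"] = y
    t["patient_id"] = [f"P{i}" for i in range(len(y))]
    return t


class TestFitLogistic:
    def test_null_data_recovers_null_model(self):
        rng = substream(0, "null")
        X = rng.normal(size=(20_000, 3))
        y = (rng.random(20_000) < 0.5).astype(int)
        m = fit_logistic(_table(X, y, ["a", "b", "c"]), ["a", "b", "c"])
        assert all(abs(w) < 0.05 for w in m.weights.values())

    def test_matches_penalized_likelihood_oracle(self):
        """Tiny fixture: weights agree with a generic numeric optimizer of the
        stated objective (summed NLL + ||w||^2 / (2C), intercept free)."""
        X = np.array([[0.0, 1], [1, 0], [1, 1], [0, 0], [2, 1], [0.5, 0]])
        y = np.array([0, 1, 1, 0, 1, 0])
        C = 1.0

        def objective(params):
            w0, w = params[0], params[1:]
            z = w0 + X @ w
            nll = np.sum(np.logaddexp(0, z) - y * z)
            return nll + (w @ w) / (2 * C)

        oracle = minimize(objective, np.zeros(3), method="BFGS",
                          options={"gtol": 1e-12}).x
        m = fit_logistic(_table(X, y, ["f1", "f2"]), ["f1", "f2"], C=C, tol=1e-10)
        assert m.intercept == pytest.approx(oracle[0], abs=1e-6)
        assert m.weights["f1"] == pytest.approx(oracle[1], abs=1e-6)
        assert m.weights["f2"] == pytest.approx(oracle[2], abs=1e-6)

    def test_learned_gender_weight_is_negative(self, train_test):
        train, _ = train_test
        m = fit_logistic(train, DEFAULT_FEATURES)
        assert m.weights["gender"] < 0

    def test_single_class_errors(self):
        X = np.zeros((5, 1))
        with pytest.raises(ValueError, match="single outcome class"):
            fit_logistic(_table(X, np.ones(5, int), ["a"]), ["a"])

    def test_large_n_recovers_generating_coefficients(self):
        """Criterion: at n = 50,000 the fit recovers every DGP coefficient
        within +-0.1 (penalty negligible)."""
        cohort = generate_cohort(CohortSpec(n_patients=50_000, seed=77))
        m = fit_logistic(cohort.table, DEFAULT_FEATURES)
        expected = {"age_std": 0.50, "bmi_std": 0.40, "comorbidity": 1.00, "gender": -0.30}
        for f, b in expected.items():
            assert m.weights[f] == pytest.approx(b, abs=0.1)
        assert m.intercept == pytest.approx(-1.0, abs=0.1)


class TestFitForest:
    def test_pure_signal_feature_dominates(self):
        rng = substream(1, "pure")
        X = np.c_[(rng.random(500) < 0.5).astype(float), rng.normal(size=500)]
        y = X[:, 0].astype(int)  # outcome equals the first feature exactly
        m = fit_forest(_table(X, y, ["sig", "noise"]), ["sig", "noise"], seed=0)
        assert m.importances["sig"] > 0.9

    def test_depth_one_split_matches_exhaustive_oracle(self):
        """A single depth-1 tree picks the split that exhaustive enumeration of
        all candidate (feature, midpoint) splits says minimizes weighted Gini."""
        X = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 9.0], [4.0, 2.0]])
        y = np.array([0, 0, 1, 1])

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = labels.mean()
            return 2 * p * (1 - p)

        best = (np.inf, None, None)
        for f in range(2):
            vals = np.unique(X[:, f])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = y[X[:, f] <= thr]
                right = y[X[:, f] > thr]
                score = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
                if score < best[0] - 1e-12:
                    best = (score, f, thr)

        m = fit_forest(
            _table(X, y, ["f1", "f2"]), ["f1", "f2"],
            hyperparams={"n_estimators": 1, "max_depth": 1, "bootstrap": False,
                         "max_features": None},
            seed=0,
        )
        tree = m.trees[0]
        assert int(tree.feature[0]) == best[1]
        assert float(tree.threshold[0]) == pytest.approx(best[2])

    def test_gender_importance_far_below_clinical_features(self, train_test):
        train, _ = train_test
        m = fit_forest(train, DEFAULT_FEATURES, seed=42)
        assert m.importances["gender"] < m.importances["age_std"] / 3
        assert m.importances["gender"] < m.importances["bmi_std"] / 3

    def test_importances_sum_to_one(self, train_test):
        train, _ = train_test
        m = fit_forest(train, DEFAULT_FEATURES, seed=9)
        assert sum(m.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in m.importances.values())

    def test_replay_matches_backend_probabilities(self, train_test):
        """Dual route: our stored-tree replay reproduces the fitting backend's
        ensemble probabilities exactly."""
        train, test = train_test
        m = fit_forest(train, DEFAULT_FEATURES, seed=4)
        sk = RandomForestClassifier(
            n_estimators=100, criterion="gini", bootstrap=True, max_features="sqrt",
            random_state=4, n_jobs=1,
        ).fit(train[list(DEFAULT_FEATURES)].to_numpy(), train["outcome"].to_numpy())
        pos = int(np.where(sk.classes_ == 1)[0][0])
        expected = sk.predict_proba(test[list(DEFAULT_FEATURES)].to_numpy())[:, pos]
        np.testing.assert_allclose(m.predict_proba(test), expected, atol=1e-12)


class TestTuneForest:
    def test_paper_grid_evaluates_18_candidates(self, train_test):
        train, _ = train_test
        small = train.iloc[:200]
        res = tune_forest(
            small,
            {"n_estimators": (5, 10, 15), "max_depth": (None, 10, 20),
             "min_samples_split": (2, 5)},
            seed=0,
        )
        assert len(res.candidates) == 18 == len(res.mean_scores)
        assert res.selected in res.candidates
        assert res.selected_score == max(res.mean_scores)

    def test_single_candidate_selected(self, train_test):
        train, _ = train_test
        res = tune_forest(train.iloc[:150], {"n_estimators": (5,)}, seed=0)
        assert res.selected == {"n_estimators": 5}

    def test_empty_grid_rejected(self, train_test):
        with pytest.raises(ValueError):
            tune_forest(train_test[0], {}, seed=0)


class TestPredictionProvenance:
    def test_logistic_contribution_sum_identity(self, train_test):
        train, test = train_test
        m = fit_logistic(train, DEFAULT_FEATURES)
        for _, row in test.iloc[:20].iterrows():
            prob, cls, prov = predict_with_provenance(m, row)
            mech = prov.mechanism
            total = mech["intercept"] + sum(mech["contributions"].values())
            assert total == mech["logit"]  # exact: the logit is that sum
            assert prob == pytest.approx(expit(mech["logit"]))
            assert cls == (1 if prob >= 0.5 else 0)

    def test_forest_paths_replay_to_votes(self, train_test):
        train, test = train_test
        m = fit_forest(train, DEFAULT_FEATURES, seed=2,
                       hyperparams={"n_estimators": 10})
        for _, row in test.iloc[:5].iterrows():
            prob, _, prov = predict_with_provenance(m, row)
            mech = prov.mechanism
            fractions = [m.replay_path(t, path) for t, path in enumerate(mech["paths"])]
            votes = [1 if f >= 0.5 else 0 for f in fractions]
            assert votes == mech["tree_votes"]
            assert prob == pytest.approx(np.mean(fractions))

    def test_printed_gender_contribution(self):
        """A male patient under w_gender = -0.733 logs a -0.733 contribution."""
        m = LogisticAuditModel(
            feature_names=("gender",), weights={"gender": -0.733}, intercept=0.0,
            config={}, model_version="x",
        )
        _, _, prov = predict_with_provenance(m, {"patient_id": "p", "gender": 1})
        assert prov.mechanism["contributions"]["gender"] == pytest.approx(-0.733)

    def test_missing_feature_named(self, train_test):
        train, _ = train_test
        m = fit_logistic(train, DEFAULT_FEATURES)
        with pytest.raises(ValueError, match="gender"):
            predict_with_provenance(m, {"age_std": 0, "bmi_std": 0, "comorbidity": 0})

    def test_double_gender_flip_restores_probability(self, train_test):
        train, test = train_test
        for model in (fit_logistic(train, DEFAULT_FEATURES),
                      fit_forest(train, DEFAULT_FEATURES, seed=1,
                                 hyperparams={"n_estimators": 20})):
            row = test.iloc[0].to_dict()
            p0, _, _ = predict_with_provenance(model, row)
            row["gender"] = 1 - row["gender"]
            row["gender"] = 1 - row["gender"]
            p2, _, _ = predict_with_provenance(model, row)
            assert p2 == p0


class TestRefitWithoutFeature:
    def test_no_gender_term_in_provenance(self, train_test):
        train, test = train_test
        m = refit_without_feature(fit_logistic(train, DEFAULT_FEATURES), train, "gender")
        assert "gender" not in m.feature_names
        _, _, prov = predict_with_provenance(m, test.iloc[0])
        assert "gender" not in prov.mechanism["contributions"]

    def test_refuses_unknown_or_all_features(self, train_test):
        train, _ = train_test
        m = fit_logistic(train, DEFAULT_FEATURES)
        with pytest.raises(ValueError):
            refit_without_feature(m, train, "height")
        solo = fit_logistic(train, ["gender"])
        with pytest.raises(ValueError, match="every feature"):
            refit_without_feature(solo, train, "gender")

    def test_null_gender_leaves_dpd_unchanged(self):
        """Gender independent of outcome and the other features: ablating it
        shifts the DPD only by Monte-Carlo noise (replicate null check)."""
        from fairprov.cohort_sim import stratified_split
        from fairprov.fairness_metrics import demographic_parity_difference

        diffs = []
        for seed in range(50):
            cohort = generate_cohort(
                CohortSpec(n_patients=600, beta_gender=0.0, seed=seed)
            )
            split = stratified_split(cohort, 0.3, seed=seed)
            train, test = cohort.view(split.train_ids), cohort.view(split.test_ids)
            full = fit_logistic(train, DEFAULT_FEATURES)
            ablated = refit_without_feature(full, train, "gender")
            y, g = test["outcome"].to_numpy(), test["gender"].to_numpy()
            diffs.append(
                demographic_parity_difference(y, full.predict(test), g)
                - demographic_parity_difference(y, ablated.predict(test), g)
            )
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-12


class TestModelVersion:
    def test_stable_across_reruns_and_sensitive_to_changes(self, train_test):
        train, _ = train_test
        a = fit_logistic(train, DEFAULT_FEATURES)
        b = fit_logistic(train, DEFAULT_FEATURES)
        c = fit_logistic(train, DEFAULT_FEATURES, C=0.5)
        d = fit_logistic(train.iloc[:-1], DEFAULT_FEATURES)
        assert a.model_version == b.model_version
        assert a.model_version != c.model_version
        assert a.model_version != d.model_version

    def test_archive_roundtrip(self, train_test):
        train, test = train_test
        for m in (fit_logistic(train, DEFAULT_FEATURES),
                  fit_forest(train, DEFAULT_FEATURES, seed=3,
                             hyperparams={"n_estimators": 10})):
            back = load_model(m.to_dict())
            np.testing.assert_allclose(back.predict_proba(test), m.predict_proba(test))
            assert back.model_version == m.model_version
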