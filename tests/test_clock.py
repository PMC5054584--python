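"""Elastic-net clock: CV machinery, training, prediction, metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import ElasticNet

from gaclock import (
    BetaMatrix,
    ClockModel,
    GestationalAgeClock,
    SampleSheet,
    TrainingConfig,
    ValidationError,
    accuracy_metrics,
    predict_ga,
)
from gaclock.clock import _fold_assignment, _standardize


def _planted(rng, n=200, p=30, k=3, noise=0.0):
    X = rng.uniform(0.1, 0.9, size=(n, p))
    coef = np.zeros(p)
    coef[:k] = [8.0, -6.0, 4.0]
    y = 32.0 + X @ coef + rng.normal(0, noise, n)
    return X, y


class TestCvLambda:
    def test_deterministic_given_seed(self, rng):
        X, y = _planted(rng, n=50, p=10, noise=0.5)
        cfg = TrainingConfig(seed=42, n_lambda=20)
        lam1, c1 = GestationalAgeClock(X, y, config=cfg).cv_lambda()
        lam2, c2 = GestationalAgeClock(X, y, config=cfg).cv_lambda()
        assert lam1 == lam2
        pd.testing.assert_frame_equal(c1, c2)

    def test_fold_partition_near_equal(self):
        folds = _fold_assignment(95, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.min() >= 9 and sizes.max() <= 10

    def test_curve_matches_manual_fold_loop_oracle(self, rng):
        """CV curve equals an independent fold-loop recomputation on a tiny
        instance: same partition, fresh fit per (fold, lambda), held-out
        MSE averaged across folds."""
        X, y = _planted(rng, n=20, p=5, noise=1.0)
        lambdas = np.array([0.5, 0.1, 0.02])
        cfg = TrainingConfig(seed=7, n_folds=10, tol=1e-12, max_iter=2_000_000)
        _, curve = GestationalAgeClock(X, y, config=cfg).cv_lambda(lambdas=lambdas)

        folds = _fold_assignment(20, 10, seed=7)
        expected = []
        for lam in lambdas:
            fold_mse = []
            for f in range(10):
                tr, te = folds != f, folds == f
                Xtr, mean, sd = _standardize(X[tr], True)
                m = ElasticNet(alpha=lam, l1_ratio=0.5, tol=1e-12, max_iter=2_000_000)
                m.fit(Xtr, y[tr])
                pred = m.predict((X[te] - mean) / sd)
                fold_mse.append(np.mean((y[te] - pred) ** 2))
            expected.append(np.mean(fold_mse))
        np.testing.assert_allclose(curve["cv_mse"].to_numpy(), expected,
                                   atol=1e-10, rtol=0)

    def test_noiseless_linear_signal_reaches_tiny_cv_mse(self, rng):
        X, y = _planted(rng, n=200, p=10, noise=0.0)
        cfg = TrainingConfig(seed=1, n_lambda=60)
        lam, curve = GestationalAgeClock(X, y, config=cfg).cv_lambda()
        assert curve["cv_mse"].min() < 1e-3

    def test_degenerate_response_raises(self, rng):
        X = rng.uniform(size=(30, 5))
        with pytest.raises(ValidationError):
            GestationalAgeClock(X, np.full(30, 39.0))


class TestTrainClock:
    def test_planted_simulation_recall_and_holdout(self):
        """2000 probes, 50 GA-driven CpGs, 300 training samples: the
        selected set overlaps the causal set and held-out predictions
        track the true GA."""
        from gaclock import SimulationConfig, simulate_dataset

        beta, _, sheet, truth = simulate_dataset(SimulationConfig(
            n_samples=400, n_probes=2000, n_causal=50, seed=41,
        ))
        train_ids = list(beta.sample_ids[:300])
        test_ids = list(beta.sample_ids[300:])
        y = sheet.effective_ga()
        cfg = TrainingConfig(seed=5, n_lambda=50)
        res = GestationalAgeClock(
            beta.data[train_ids].to_numpy().T, y.loc[train_ids].to_numpy(),
            probe_ids=beta.probe_ids, config=cfg,
        ).fit()
        recall = len(set(res.coefficients.index) & set(truth.causal_slopes.index)) / 50
        assert recall >= 0.6
        pred = res.intercept + beta.data[test_ids].to_numpy().T @ res._dense_coef()
        r, *_ = accuracy_metrics(pred, y.loc[test_ids].to_numpy())
        assert r >= 0.9

    def test_ridge_limit_keeps_all_coefficients(self, rng):
        X, y = _planted(rng, n=60, p=8, noise=0.5)
        cfg = TrainingConfig(alpha=0.0, n_lambda=10)
        res = GestationalAgeClock(X, y, config=cfg).fit(lambda_=0.01)
        assert res.n_selected == 8

    def test_model_object_round_trip(self, rng):
        X, y = _planted(rng, n=80, p=12, noise=0.2)
        res = GestationalAgeClock(X, y, config=TrainingConfig(seed=2, n_lambda=30)).fit()
        model = res.to_clock_model()
        assert isinstance(model, ClockModel)
        assert len(model) == res.n_selected
        assert model.metadata["alpha"] == 0.5

    def test_prediction_affine_in_beta(self, rng):
        X, y = _planted(rng, n=60, p=10, noise=0.3)
        res = GestationalAgeClock(X, y, config=TrainingConfig(seed=3, n_lambda=20)).fit()
        b = res._dense_coef()
        x1, x2 = X[0], X[1]
        for c in (0.0, 0.3, 0.7, 1.0):
            mix = c * x1 + (1 - c) * x2
            lhs = res.intercept + mix @ b
            rhs = c * (res.intercept + x1 @ b) + (1 - c) * (res.intercept + x2 @ b)
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_objective_no_worse_than_zero_vector(self, rng):
        X, y = _planted(rng, n=60, p=10, noise=0.5)
        cfg = TrainingConfig(seed=4)
        clock = GestationalAgeClock(X, y, config=cfg)
        lam = 0.05
        res = clock.fit(lambda_=lam)
        Xs, _, _ = _standardize(X, True)

        def objective(b, b0):
            r = y - b0 - Xs @ b
            return (0.5 / len(y)) * r @ r + lam * (
                0.5 * np.abs(b).sum() + 0.25 * b @ b
            )

        full = pd.Series(0.0, index=clock.probe_ids)
        full.loc[res.coefficients.index] = res.coefficients.to_numpy()
        # refit coefficient on the standardized scale for the comparison
        m = ElasticNet(alpha=lam, l1_ratio=0.5, tol=1e-10, max_iter=1_000_000)
        m.fit(Xs, y)
        assert objective(m.coef_, m.intercept_) <= objective(np.zeros(10), y.mean()) + 1e-12


class TestPredictGA:
    def _beta(self, values, probes, samples):
        return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))

    def test_linear_arithmetic(self):
        model = ClockModel(intercept=38.0, coefficients=pd.Series({"cg1": -2.0}))
        beta = self._beta([[0.5]], ["cg1"], ["s1"])
        pred = predict_ga(beta, model)
        assert pred.table["dnam_ga_weeks"].iloc[0] == pytest.approx(37.0)

    def test_intercept_only_prediction(self):
        model = ClockModel(intercept=40.0, coefficients=pd.Series({"cg1": 0.0}))
        beta = self._beta([[0.1, 0.9]], ["cg1"], ["s1", "s2"])
        pred = predict_ga(beta, model)
        assert (pred.table["dnam_ga_weeks"] == 40.0).all()

    def test_too_many_missing_probes_raises(self):
        model = ClockModel(intercept=38.0, coefficients=pd.Series(
            {f"cg{i}": 1.0 for i in range(10)}))
        beta = self._beta(np.full((5, 1), 0.5), [f"cg{i}" for i in range(5)], ["s1"])
        with pytest.raises(ValidationError, match="unreliable"):
            predict_ga(beta, model)

    def test_noiseless_training_recovery(self, rng):
        X, y = _planted(rng, n=150, p=20, noise=0.0)
        res = GestationalAgeClock(X, y, config=TrainingConfig(seed=6, n_lambda=40)).fit()
        r, *_ = accuracy_metrics(res.fittedvalues(), y)
        assert r > 0.99

    def test_accuracy_against_effective_ga_for_spots(self):
        model = ClockModel(intercept=30.0, coefficients=pd.Series({"cg1": 0.0}))
        beta = self._beta([[0.5, 0.5, 0.5]], ["cg1"], ["a", "b", "c"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "clinical_ga_weeks": [30.0, 29.0, 28.0],
            "tissue": ["spot"] * 3,
            "days_to_sampling": [0, 7, 14],
        }))
        pred = predict_ga(beta, model, sheet=sheet)
        # effective GA is 30 for every sample -> zero error
        assert pred.median_abs_err == pytest.approx(0.0)


class TestAccuracyMetrics:
    def test_perfect_agreement(self):
        r, med, mean, sd = accuracy_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)
        assert med == mean == 0.0

    def test_constant_shift(self):
        pred = np.array([30.0, 35.0, 40.0]) + 1.0
        r, med, mean, sd = accuracy_metrics(pred, [30.0, 35.0, 40.0])
        assert r == pytest.approx(1.0)
        assert med == pytest.approx(1.0)

    def test_matches_textbook_formula_oracle(self, rng):
        a = rng.normal(35, 3, 40)
        b = a + rng.normal(0, 1.5, 40)
        r, med, mean, sd = accuracy_metrics(b, a)
        d = b - a
        r_oracle = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert med == pytest.approx(np.median(np.abs(d)), abs=1e-12)
        assert mean == pytest.approx(np.mean(np.abs(d)), abs=1e-12)
        assert sd == pytest.approx(np.std(np.abs(d), ddof=1), abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValidationError):
            accuracy_metrics([1.0, 2.0], [1.0, 2.0])
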