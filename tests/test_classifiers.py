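"""The four binary classifiers and their ensemble."""

import numpy as np
import pytest
from scipy.optimize import minimize

import biodyn as bd
from biodyn.classifiers import (
    TrainingSet,
    _logistic_cost_grad,
    fit_logistic,
    squashed_logistic,
)


def _toy_1d(rng, n_per_class=10, sep=1.0, noise=0.2):
    y = np.array([-1.0] * n_per_class + [1.0] * n_per_class)
    F = (sep * y + noise * rng.normal(size=2 * n_per_class))[:, None]
    return TrainingSet(F=F, y=y)


class TestLogistic:
    def test_separable_toy_training_signs(self, rng):
        train = _toy_1d(rng)
        for f, y in zip(train.F, train.y):
            assert np.sign(bd.logistic_classifier(train, f)) == y

    def test_matches_independent_optimizer(self, rng):
        """The in-house gradient descent lands on the same ridge optimum as
        a quasi-Newton optimizer applied to the identical cost."""
        for _ in range(5):
            n, d = 12, 4
            y = np.array([-1.0] * 6 + [1.0] * 6)
            F = rng.normal(size=(n, d)) + 0.7 * y[:, None] * rng.normal(size=d)
            train = TrainingSet(F=F, y=y)
            b, w, _ = fit_logistic(train)
            res = minimize(
                lambda th: _logistic_cost_grad(th, F, y, 0.1)[0],
                np.zeros(d + 1),
                jac=lambda th: _logistic_cost_grad(th, F, y, 0.1)[1],
                method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
            f_test = rng.normal(size=d)
            P_gd = squashed_logistic(b + f_test @ w)
            P_or = squashed_logistic(res.x[0] + f_test @ res.x[1:])
            assert abs(P_gd - P_or) < 1e-4

    def test_symmetric_data_predicts_zero_at_origin(self):
        F = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        P = bd.logistic_classifier(TrainingSet(F=F, y=y), np.zeros(1))
        assert abs(P) < 1e-6

    def test_ridge_limit_kills_weights(self, rng):
        train = _toy_1d(rng)
        b, w, _ = fit_logistic(train, lam=1e9)
        assert np.abs(w).max() < 1e-3

    def test_label_swap_antisymmetry(self, rng):
        train = _toy_1d(rng)
        flipped = TrainingSet(F=train.F, y=-train.y)
        f_test = np.array([0.37])
        assert bd.logistic_classifier(train, f_test) == pytest.approx(
            -bd.logistic_classifier(flipped, f_test), abs=1e-8)


class TestGibbsRnn:
    def test_orthogonal_class_subspaces_exact_label(self):
        """A test vector inside one class's subspace, orthogonal to the
        other class after centering, is assigned that class's label exactly."""
        F = np.array([[1.0, 1.0, 0.0, 0.0],
                      [1.0, 1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0, 1.0],
                      [0.0, 0.0, 1.0, 1.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        train = TrainingSet(F=F, y=y)
        P = bd.gibbs_rnn_classifier(train, F[0], np.random.default_rng(0))
        assert P == 1.0
        P = bd.gibbs_rnn_classifier(train, F[2], np.random.default_rng(0))
        assert P == -1.0

    def test_seed_determinism(self, rng):
        train = _toy_1d(rng, n_per_class=6)
        f = np.array([0.4])
        p1 = bd.gibbs_rnn_classifier(train, f, np.random.default_rng(77))
        p2 = bd.gibbs_rnn_classifier(train, f, np.random.default_rng(77))
        assert p1 == p2

    def test_single_class_degenerate(self, rng):
        F = rng.normal(size=(4, 3)) + 2.0
        train = TrainingSet(F=F, y=np.ones(4))
        P = bd.gibbs_rnn_classifier(train, F[0], np.random.default_rng(0))
        assert P == 1.0

    def test_output_in_range(self, rng):
        train = _toy_1d(rng)
        for seed in range(5):
            P = bd.gibbs_rnn_classifier(train, rng.normal(size=1),
                                        np.random.default_rng(seed))
            assert -1.0 <= P <= 1.0


class TestLogLik:
    def test_midpoint_of_symmetric_classes_zero(self):
        F = np.array([[1.0, 2.0], [1.2, 2.2], [-1.0, -2.0], [-1.2, -2.2]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        P = bd.loglik_classifier(TrainingSet(F=F, y=y), np.zeros(2))
        assert abs(P) < 1e-10

    def test_class_mean_dominance(self, rng):
        train = _toy_1d(rng, sep=2.0)
        assert bd.loglik_classifier(train, np.array([2.0])) > 0.5
        assert bd.loglik_classifier(train, np.array([-2.0])) < -0.5

    def test_consistent_rescaling_invariance(self, rng):
        """Scaling features (hence class means and sds) by a common factor
        leaves the log-likelihood difference, and P, unchanged."""
        train = _toy_1d(rng, n_per_class=6)
        f = np.array([0.3])
        scaled = TrainingSet(F=2.0 * train.F, y=train.y)
        assert bd.loglik_classifier(train, f) == pytest.approx(
            bd.loglik_classifier(scaled, 2.0 * f), rel=1e-9)

    def test_single_member_class_rejected(self):
        F = np.array([[1.0], [2.0], [-1.0]])
        y = np.array([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            bd.loglik_classifier(TrainingSet(F=F, y=y), np.array([0.0]))

    def test_label_swap_antisymmetry(self, rng):
        train = _toy_1d(rng)
        flipped = TrainingSet(F=train.F, y=-train.y)
        f = np.array([0.6])
        assert bd.loglik_classifier(train, f) == pytest.approx(
            -bd.loglik_classifier(flipped, f), rel=1e-9)


class TestNetworkClassifier:
    def test_unanimous_neighbors(self, rng):
        base = rng.normal(size=4)
        F = np.vstack([base + 0.01 * rng.normal(size=4) for _ in range(3)]
                      + [-base for _ in range(3)])
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        P = bd.network_classifier(TrainingSet(F=F, y=y), base, k=3)
        assert P == 1.0

    def test_split_vote_fractions(self):
        F = np.array([[1.0, 0.0], [0.9, 0.1], [0.8, 0.2], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        P = bd.network_classifier(TrainingSet(F=F, y=y), np.array([1.0, 0.0]), k=3)
        assert P == pytest.approx(1 / 3)

    def test_equals_bruteforce_knn_on_exhaustive_small_instances(self, rng):
        """Exhaustive check against an independent k-NN vote for every label
        assignment on cohorts of up to 6 patients."""
        for n in (3, 4, 5, 6):
            F = rng.normal(size=(n, 3))
            f_test = rng.normal(size=3)
            for assignment in range(2 ** n):
                y = np.array([1.0 if assignment >> i & 1 else -1.0
                              for i in range(n)])
                for k in range(1, n + 1):
                    P = bd.network_classifier(TrainingSet(F=F, y=y), f_test, k=k)
                    # independent oracle: explicit similarity formula + sort
                    sims = []
                    for fp in F:
                        beta = np.linalg.norm(f_test) / np.linalg.norm(fp)
                        cos = f_test @ fp / (np.linalg.norm(f_test)
                                             * np.linalg.norm(fp))
                        sims.append(2 * np.sqrt(beta) / (1 + beta) * cos)
                    order = sorted(range(n), key=lambda j: (-sims[j], j))
                    expected = np.mean(y[order[:k]])
                    assert P == pytest.approx(expected, abs=1e-12)

    def test_label_swap_antisymmetry(self, rng):
        F = rng.normal(size=(6, 3))
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        f = rng.normal(size=3)
        assert bd.network_classifier(TrainingSet(F=F, y=y), f) == pytest.approx(
            -bd.network_classifier(TrainingSet(F=F, y=-y), f))


class TestEnsemble:
    def test_se_of_split_predictions(self):
        preds = np.array([1.0, 1.0, -1.0, -1.0])
        se = preds.std(ddof=1) / 2
        assert se == pytest.approx((2 / np.sqrt(3)) / 2, rel=1e-12)

    def test_ensemble_mean_and_se(self, rng):
        train = _toy_1d(rng, sep=2.0, noise=0.1)
        ep = bd.ensemble_predict(train, np.array([2.0]),
                                 np.random.default_rng(0), n_resamples=0)
        assert len(ep.per_classifier) == 4
        vals = [ep.per_classifier[n] for n in ("logistic", "rnn", "loglik",
                                               "network")]
        assert ep.mean == pytest.approx(np.mean(vals))
        assert ep.se == pytest.approx(np.std(vals, ddof=1) / 2)
        assert ep.failed == []

    def test_resampling_only_inflates_se(self, rng):
        train = _toy_1d(rng)
        f = np.array([0.5])
        base = bd.ensemble_predict(train, f, np.random.default_rng(5),
                                   n_resamples=0)
        with_rs = bd.ensemble_predict(train, f, np.random.default_rng(5),
                                      n_resamples=6)
        assert with_rs.se >= base.se - 1e-12

    def test_all_outputs_in_range(self, rng):
        train = _toy_1d(rng)
        ep = bd.ensemble_predict(train, rng.normal(size=1),
                                 np.random.default_rng(1), n_resamples=0)
        for v in ep.per_classifier.values():
            assert -1.0 <= v <= 1.0
        assert -1.0 <= ep.mean <= 1.0

    def test_seed_determinism(self, rng):
        train = _toy_1d(rng)
        f = np.array([0.2])
        e1 = bd.ensemble_predict(train, f, np.random.default_rng(9))
        e2 = bd.ensemble_predict(train, f, np.random.default_rng(9))
        assert e1.mean == e2.mean and e1.se == e2.se
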