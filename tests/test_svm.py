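import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import LinearConstraint, minimize

from conftest import (numeric_prox_hinge_1d, numeric_prox_hinge_conjugate_1d,
                      numeric_prox_regularizer_1d)
from fedssvm import (Classifier, Dataset, Hyperparams, build_margin_operator,
                     hinge_losses, hyperparams_from_c_eps, objective,
                     predict_accuracy, prox_hinge_conjugate, prox_regularizer,
                     solve_centralized_qp)
from fedssvm.svm import load_classifier, save_classifier


def _toy(labels, features):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    names = [f"f{i}" for i in range(features.shape[1])]
    return Dataset(features, np.asarray(labels), names)


class TestHinge:
    def test_zero_classifier_gives_unit_losses(self, small_cohort):
        clf = Classifier(np.zeros(small_cohort.n_features), 0.0)
        np.testing.assert_array_equal(hinge_losses(clf, small_cohort),
                                      np.ones(small_cohort.n_samples))

    def test_confident_correct_is_zero(self):
        data = _toy([1], [[2.0]])
        clf = Classifier([1.0], 0.0)  # margin = 2
        assert hinge_losses(clf, data)[0] == 0.0

    def test_wrong_side_hand_value(self):
        # l = -1, score 0.5 -> hinge = 1 - (-1)(0.5) = 1.5
        data = _toy([-1], [[0.5]])
        clf = Classifier([1.0], 0.0)
        assert hinge_losses(clf, data)[0] == pytest.approx(1.5)

    def test_dimension_mismatch(self, small_cohort):
        clf = Classifier(np.zeros(small_cohort.n_features + 1), 0.0)
        with pytest.raises(ValueError):
            hinge_losses(clf, small_cohort)


class TestObjective:
    def test_zero_classifier_counts_samples(self):
        data = _toy([1, -1, 1, -1], np.zeros((4, 2)))
        clf = Classifier(np.zeros(2), 0.0)
        assert objective(clf, data, Hyperparams(1.0, 1.0)) == 4.0

    def test_no_penalties_reduces_to_hinge_sum(self, small_cohort):
        rng = np.random.default_rng(0)
        clf = Classifier(rng.standard_normal(small_cohort.n_features), 0.3)
        assert objective(clf, small_cohort, Hyperparams(0, 0)) == \
            pytest.approx(hinge_losses(clf, small_cohort).sum())

    def test_hand_value(self):
        # theta=(1,-2), theta0=0.5, one sample l=+1 phi=(0,0):
        # hinge 0.5, ridge 0.5*2*5=5, L1 1*3=3 -> 8.5
        data = _toy([1], [[0.0, 0.0]])
        clf = Classifier([1.0, -2.0], 0.5)
        assert objective(clf, data, Hyperparams(2.0, 1.0)) == pytest.approx(8.5)

    def test_convexity_property(self, small_cohort):
        rng = np.random.default_rng(7)
        hp = Hyperparams(0.7, 0.4)
        d = small_cohort.n_features
        for _ in range(100):
            a = Classifier(rng.standard_normal(d), rng.standard_normal())
            b = Classifier(rng.standard_normal(d), rng.standard_normal())
            for lam in (0.25, 0.5, 0.75):
                mid = Classifier(lam * a.theta + (1 - lam) * b.theta,
                                 lam * a.theta0 + (1 - lam) * b.theta0)
                lhs = objective(mid, small_cohort, hp)
                rhs = (lam * objective(a, small_cohort, hp)
                       + (1 - lam) * objective(b, small_cohort, hp))
                assert lhs <= rhs + 1e-9


class TestHyperparamConversion:
    def test_example(self):
        hp = hyperparams_from_c_eps(2.0, 1.0)
        assert (hp.psi, hp.rho) == (0.5, 0.5)

    def test_eps_zero(self):
        hp = hyperparams_from_c_eps(1.0, 0.0)
        assert (hp.psi, hp.rho) == (1.0, 0.0)

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValueError):
            hyperparams_from_c_eps(0.0, 1.0)

    def test_argmins_coincide_with_qp_oracle(self):
        # solve the (c, eps) form directly as a QP and compare with the
        # converted-coefficient solution of the standard form
        rng = np.random.default_rng(5)
        n, d = 20, 3
        phi = rng.standard_normal((n, d))
        lab = rng.choice([-1, 1], size=n)
        data = Dataset(phi, lab, [f"f{i}" for i in range(d)])
        c, eps = 2.0, 0.5

        nv = 2 * d + 1 + n
        lphi = lab[:, None] * phi

        def fun(z):
            tp, tm, zeta = z[:d], z[d:2 * d], z[2 * d + 1:]
            th = tp - tm
            return 0.5 * th @ th + c * zeta.sum() + eps * (tp.sum() + tm.sum())

        a_lin = np.hstack([lphi, -lphi, lab[:, None].astype(float), np.eye(n)])
        lb = np.zeros(nv)
        lb[2 * d] = -np.inf
        res = minimize(fun, np.zeros(nv), method="trust-constr",
                       constraints=[LinearConstraint(a_lin, 1.0, np.inf)],
                       bounds=list(zip(lb, [np.inf] * nv)),
                       options={"gtol": 1e-12, "xtol": 1e-14,
                                "maxiter": 5000})
        theta_direct = res.x[:d] - res.x[d:2 * d]

        sol = solve_centralized_qp(data, hyperparams_from_c_eps(c, eps))
        np.testing.assert_allclose(sol.classifier.theta, theta_direct,
                                   atol=1e-5)
        np.testing.assert_allclose(sol.classifier.theta0, res.x[2 * d],
                                   atol=1e-5)


class TestPredict:
    def test_ground_truth_perfect_on_separable(self, separable_cohort):
        gt = separable_cohort.ground_truth
        _, acc = predict_accuracy(Classifier(gt.theta, gt.theta0),
                                  separable_cohort)
        assert acc == 1.0

    def test_zero_classifier_tie_rule(self, small_cohort):
        clf = Classifier(np.zeros(small_cohort.n_features), 0.0)
        preds, acc = predict_accuracy(clf, small_cohort)
        assert np.all(preds == 1)
        assert acc == pytest.approx(np.mean(small_cohort.labels == 1))

    def test_flip_complement_identity(self, small_cohort):
        rng = np.random.default_rng(3)
        clf = Classifier(rng.standard_normal(small_cohort.n_features), 0.17)
        flipped = Dataset(small_cohort.features, -small_cohort.labels,
                          small_cohort.feature_names)
        _, acc_a = predict_accuracy(clf, small_cohort)
        _, acc_b = predict_accuracy(clf, flipped)
        assert acc_a + acc_b == pytest.approx(1.0)

    def test_empty_data_raises(self):
        data = Dataset(np.zeros((0, 2)), np.zeros(0), ["a", "b"])
        with pytest.raises(ValueError):
            predict_accuracy(Classifier([0.0, 0.0], 0.0), data)


class TestProxRegularizer:
    def test_soft_threshold(self):
        hp = Hyperparams(0.0, 1.0)
        out = prox_regularizer(np.array([3.0, 0.0]), 1.0, hp)
        assert out[0] == pytest.approx(2.0)

    def test_inside_threshold_zeroed(self):
        hp = Hyperparams(0.0, 1.0)
        out = prox_regularizer(np.array([0.5, 0.0]), 1.0, hp)
        assert out[0] == 0.0

    def test_elastic_net_hand_value(self):
        # soft(3, 1)/(1 + 1) = 1; cross-checked against the numeric oracle
        hp = Hyperparams(1.0, 1.0)
        out = prox_regularizer(np.array([3.0, 0.0]), 1.0, hp)
        assert out[0] == pytest.approx(1.0)
        assert out[0] == pytest.approx(
            numeric_prox_regularizer_1d(3.0, 1.0, 1.0, 1.0), abs=1e-10)

    def test_bias_passes_through(self):
        hp = Hyperparams(2.0, 3.0)
        u = np.array([1.0, -2.0, 0.7])
        assert prox_regularizer(u, 0.5, hp)[-1] == 0.7

    def test_against_numeric_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            u = float(rng.normal(0, 3))
            tau = float(rng.uniform(0.01, 5))
            hp = Hyperparams(float(rng.uniform(0, 3)), float(rng.uniform(0, 3)))
            got = prox_regularizer(np.array([u, 0.0]), tau, hp)[0]
            want = numeric_prox_regularizer_1d(u, tau, hp.psi, hp.rho)
            assert got == pytest.approx(want, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    def test_contraction_property(self, a, b):
        n = min(len(a), len(b))
        u, v = np.array(a[:n]), np.array(b[:n])
        hp = Hyperparams(0.8, 1.3)
        pu, pv = (prox_regularizer(w, 0.7, hp) for w in (u, v))
        assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-12


class TestProxHingeConjugate:
    def test_shift_clips_to_zero(self):
        assert prox_hinge_conjugate(np.array([0.5]), 0.2)[0] == 0.0
        assert prox_hinge_conjugate(np.array([0.5]), 0.2)[0] == pytest.approx(
            numeric_prox_hinge_conjugate_1d(0.5, 0.2), abs=1e-12)

    def test_clips_at_lower_bound(self):
        assert prox_hinge_conjugate(np.array([-2.0]), 0.1)[0] == -1.0
        assert prox_hinge_conjugate(np.array([-2.0]), 0.1)[0] == pytest.approx(
            numeric_prox_hinge_conjugate_1d(-2.0, 0.1), abs=1e-12)

    def test_interior_value(self):
        # v - sigma lands inside [-1, 0]
        assert prox_hinge_conjugate(np.array([-0.3]), 0.2)[0] == \
            pytest.approx(-0.5)

    def test_moreau_identity(self):
        # v = prox_{s h*}(v) + s * prox_{h/s}(v/s), h = hinge
        rng = np.random.default_rng(4)
        for _ in range(100):
            v = float(rng.normal(0, 3))
            s = float(rng.uniform(0.05, 5))
            lhs = prox_hinge_conjugate(np.array([v]), s)[0]
            rhs = numeric_prox_hinge_1d(v / s, s)
            assert v == pytest.approx(lhs + s * rhs, abs=1e-10)

    def test_vector_sigma(self):
        v = np.array([0.5, -2.0, -0.3])
        sig = np.array([0.2, 0.1, 0.2])
        np.testing.assert_allclose(prox_hinge_conjugate(v, sig),
                                   [0.0, -1.0, -0.5])


class TestMarginOperator:
    def test_positive_row(self):
        data = _toy([1], [[1.0, 2.0]])
        np.testing.assert_array_equal(build_margin_operator(data),
                                      [[1.0, 2.0, 1.0]])

    def test_negative_row(self):
        data = _toy([-1], [[1.0, 2.0]])
        np.testing.assert_array_equal(build_margin_operator(data),
                                      [[-1.0, -2.0, -1.0]])

    def test_margins_at_least_one_on_scaled_separable(self, separable_cohort):
        gt = separable_cohort.ground_truth
        x = np.append(gt.theta, gt.theta0)
        a = build_margin_operator(separable_cohort)
        scale = 1.0 / (a @ x).min()  # noiseless: all margins > 0
        assert np.all(a @ (scale * x) >= 1.0 - 1e-12)

    def test_hinge_via_operator_matches(self, small_cohort):
        rng = np.random.default_rng(6)
        a = build_margin_operator(small_cohort)
        for _ in range(20):
            theta = rng.standard_normal(small_cohort.n_features)
            theta0 = float(rng.standard_normal())
            clf = Classifier(theta, theta0)
            via_op = np.maximum(0.0, 1.0 - a @ np.append(theta, theta0)).sum()
            assert via_op == pytest.approx(
                hinge_losses(clf, small_cohort).sum(), abs=1e-12)


class TestSerialisation:
    def test_round_trip(self, tmp_path):
        clf = Classifier(np.array([0.5, -1.25, 0.0]), 0.75)
        save_classifier(clf, tmp_path / "clf.json", ["a", "b", "c"])
        back, names = load_classifier(tmp_path / "clf.json")
        np.testing.assert_array_equal(back.theta, clf.theta)
        assert back.theta0 == clf.theta0
        assert names == ["a", "b", "c"]
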