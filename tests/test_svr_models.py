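import numpy as np
import pytest

from survsvr.kernels import KernelSpec
from survsvr.km_mrl import MRLTable, mrl_augment
from survsvr.metrics import c_index
from survsvr.survdata import SurvivalDataset
from survsvr.svr_models import (
    FitError,
    HyperParams,
    comparable_neighbors,
    fit_cox_baseline,
    fit_model1,
    fit_model2,
    fit_ssvr_mrl,
    fit_svr,
    predict,
)

from .conftest import linear_survival, random_survival

LINEAR = KernelSpec("linear")


class TestComparableNeighbors:
    def test_censoring_rule(self):
        nb = comparable_neighbors(np.array([1.0, 2, 3]), np.array([1, 0, 1]))
        # censored-at-2 is comparable to event-at-1; event-at-3 pairs with the
        # event-at-1 (the censored observation's order vs 3 is unknown)
        np.testing.assert_array_equal(nb.neighbor, [-1, 0, 0])

    def test_all_censored_none(self):
        nb = comparable_neighbors(np.array([1.0, 2, 3]), np.zeros(3, int))
        np.testing.assert_array_equal(nb.neighbor, [-1, -1, -1])

    def test_all_events_strict_order(self):
        nb = comparable_neighbors(np.array([3.0, 1, 2]), np.ones(3, int))
        np.testing.assert_array_equal(nb.neighbor, [2, -1, 1])

    def test_tie_broken_to_smallest_index(self):
        y = np.array([2.0, 1.0, 1.0, 3.0])
        nb = comparable_neighbors(y, np.ones(4, int))
        assert nb.neighbor[0] == 1  # both events at t=1; smallest index wins
        assert nb.neighbor[3] == 0

    def test_neighbor_time_strictly_smaller(self, rng):
        y = rng.integers(1, 6, 25).astype(float)
        delta = rng.integers(0, 2, 25)
        nb = comparable_neighbors(y, delta)
        for i, j in nb.pairs:
            assert y[j] < y[i]
            assert delta[j] == 1


class TestModel1:
    def test_two_point_interpolation(self):
        ds = SurvivalDataset(np.array([[0.0], [1.0]]), [1, 2], [1, 1])
        m = fit_model1(ds, LINEAR, HyperParams(gamma=1e4))
        u = predict(m, ds.X)
        np.testing.assert_allclose(u, [1, 2], atol=1e-3)

    def test_all_censored_degenerate(self):
        ds = SurvivalDataset(np.arange(4.0).reshape(-1, 1), [1, 2, 3, 4],
                             np.zeros(4, int))
        m = fit_model1(ds, LINEAR, HyperParams(gamma=1.0))
        assert m.degenerate
        np.testing.assert_array_equal(m.beta, 0)
        assert m.b == 4.0

    def test_dual_expansion_matches_primal_weights(self, rng):
        ds = random_survival(rng, 25, d=3)
        m = fit_model1(ds, LINEAR, HyperParams(gamma=2.0))
        np.testing.assert_allclose(
            predict(m, ds.X), ds.X @ m.w_linear + m.b, atol=1e-6
        )

    def test_censored_overprediction_unpenalized(self, rng):
        # with every subject censored except one, predictions may exceed y
        y = np.array([1.0, 1.0, 1.0, 5.0])
        ds = SurvivalDataset(np.zeros((4, 1)), y, np.array([0, 0, 0, 1]))
        m = fit_model1(ds, LINEAR, HyperParams(gamma=10.0))
        assert predict(m, np.zeros((1, 1)))[0] >= 5 - 1e-6

    def test_parameter_recovery_noiseless(self, rng):
        w_true = np.array([2.0, -1.0, 0.5])
        ds = linear_survival(rng, 120, w_true)
        m = fit_model1(ds, LINEAR, HyperParams(gamma=100.0))
        cos = m.w_linear @ w_true / np.linalg.norm(m.w_linear) / np.linalg.norm(w_true)
        assert cos > 0.99

    def test_gamma_monotone_training_loss(self, rng):
        ds = random_survival(rng, 40, d=2)

        def train_loss(m):
            u = predict(m, ds.X)
            under = np.maximum(ds.y - u, 0)
            over = np.where(ds.delta == 1, np.maximum(u - ds.y, 0), 0)
            return (under + over).sum()

        losses = [
            train_loss(fit_model1(ds, LINEAR, HyperParams(gamma=g)))
            for g in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))


class TestModel2:
    def test_mu_zero_equals_model1(self, rng):
        ds = random_survival(rng, 30)
        m1 = fit_model1(ds, LINEAR, HyperParams(gamma=1.0))
        m2 = fit_model2(ds, LINEAR, HyperParams(gamma=1.0, mu=0.0))
        np.testing.assert_allclose(predict(m2, ds.X), predict(m1, ds.X), atol=1e-5)

    def test_ranking_constraints_enforce_order(self, rng):
        w = np.array([3.0])
        tr = linear_survival(rng, 60, w)
        m = fit_model2(tr, LINEAR, HyperParams(gamma=1.0, mu=50.0))
        Xte = np.linspace(-2, 2, 20).reshape(-1, 1)
        yte = (Xte @ w + 10.0).ravel()
        u = predict(m, Xte)
        assert c_index(u, yte, np.ones(20, int)) == 1.0

    def test_all_censored_degenerate(self):
        ds = SurvivalDataset(np.arange(3.0).reshape(-1, 1), [1, 2, 3], np.zeros(3, int))
        m = fit_model2(ds, LINEAR, HyperParams(gamma=1.0, mu=1.0))
        assert m.degenerate


class TestSSVRMRL:
    def test_all_events_equals_model1(self, rng):
        ds = random_survival(rng, 25, censor_frac=0.0)
        assert ds.n_events == ds.n
        m1 = fit_model1(ds, LINEAR, HyperParams(gamma=1.0))
        mm = fit_ssvr_mrl(ds, LINEAR, HyperParams(gamma=1.0, mu=5.0), mrl_augment(ds))
        np.testing.assert_allclose(predict(mm, ds.X), predict(m1, ds.X), atol=1e-6)
        np.testing.assert_allclose(mm.b, m1.b, atol=1e-6)

    def test_mu_zero_equals_model1(self, rng):
        ds = random_survival(rng, 25)
        m1 = fit_model1(ds, LINEAR, HyperParams(gamma=1.0))
        mm = fit_ssvr_mrl(ds, LINEAR, HyperParams(gamma=1.0, mu=0.0), mrl_augment(ds))
        np.testing.assert_allclose(predict(mm, ds.X), predict(m1, ds.X), atol=1e-5)

    def test_large_mu_activates_upper_bound(self):
        # one censored subject with a tiny MRL: its prediction must not
        # exceed y_i + MRL_i by more than a whisker when mu is large
        y = np.array([1.0, 2.0, 3.0, 1.5])
        delta = np.array([1, 1, 1, 0])
        X = np.array([[0.0], [1.0], [2.0], [0.5]])
        ds = SurvivalDataset(X, y, delta)
        mrl = MRLTable(mrl=np.array([0.0, 0.0, 0.0, 1e-3]))
        m = fit_ssvr_mrl(ds, LINEAR, HyperParams(gamma=10.0, mu=1e4), mrl)
        u = predict(m, X[3:4])[0]
        assert u <= y[3] + mrl.mrl[3] + 1e-4

    def test_misaligned_mrl_rejected(self, rng):
        ds = random_survival(rng, 10)
        with pytest.raises(FitError):
            fit_ssvr_mrl(ds, LINEAR, HyperParams(gamma=1.0), MRLTable(mrl=np.zeros(3)))


class TestPredict:
    def test_expansion_arithmetic(self):
        from survsvr.svr_models import TrainedSVR

        m = TrainedSVR(
            model_kind="model1", beta=np.array([1.0, -1.0]), b=0.0,
            kernel=LINEAR, X_train=np.array([[1.0], [2.0]]),
            hp=HyperParams(gamma=1.0),
        )
        assert predict(m, np.array([[3.0]]))[0] == pytest.approx(-3.0)

    def test_constant_model(self):
        from survsvr.svr_models import TrainedSVR

        m = TrainedSVR(
            model_kind="model1", beta=np.zeros(2), b=7.5,
            kernel=LINEAR, X_train=np.zeros((2, 3)), hp=HyperParams(gamma=1.0),
        )
        np.testing.assert_array_equal(predict(m, np.zeros((4, 3))), 7.5)

    def test_dimension_mismatch(self, rng):
        ds = random_survival(rng, 10, d=2)
        m = fit_model1(ds, LINEAR, HyperParams(gamma=1.0))
        with pytest.raises(ValueError):
            predict(m, np.zeros((2, 5)))


class TestNonlinearKernels:
    @pytest.mark.parametrize(
        "spec",
        [KernelSpec("polynomial", degree=2), KernelSpec("rbf", gamma_rbf=0.5)],
    )
    def test_models_fit_and_predict(self, spec, rng):
        ds = random_survival(rng, 30, d=2)
        for kind in ["model1", "model2", "ssvr_mrl"]:
            m = fit_svr(ds, spec, HyperParams(gamma=1.0, mu=1.0), kind)
            u = predict(m, ds.X)
            assert np.isfinite(u).all()


class TestCoxBaseline:
    def test_sign_convention_two_groups(self, rng):
        # group 1 dies faster -> its (negated) prognostic index is lower
        n = 200
        z = rng.integers(0, 2, n)
        t = rng.exponential(np.where(z == 1, 0.5, 2.0))
        ds = SurvivalDataset(z.reshape(-1, 1).astype(float), t + 1e-3,
                             np.ones(n, int))
        model = fit_cox_baseline(ds)
        assert model.coef[0] > 0  # z=1 has higher hazard
        u = model.predict(ds.X)
        assert u[z == 1].mean() < u[z == 0].mean()

    def test_score_equation_root_oracle(self, rng):
        from scipy.optimize import minimize_scalar

        from .oracles import breslow_partial_loglik

        n = 80
        z = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(z == 1, 0.7, 1.8)) + 1e-3
        delta = np.ones(n, int)
        ds = SurvivalDataset(z.reshape(-1, 1), t, delta)
        model = fit_cox_baseline(ds)
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, z, t, np.ones(n, bool)),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert model.coef[0] == pytest.approx(res.x, abs=1e-4)

    def test_null_covariate_small_coef(self, rng):
        n = 400
        x = rng.standard_normal(n)
        t = rng.exponential(1, n) + 1e-3
        ds = SurvivalDataset(x.reshape(-1, 1), t, np.ones(n, int))
        model = fit_cox_baseline(ds)
        assert abs(model.coef[0]) < 0.15
        assert c_index(model.predict(ds.X), ds.y, ds.delta) == pytest.approx(0.5, abs=0.05)

    def test_duplication_invariance(self, rng):
        ds = random_survival(rng, 50, d=2)
        dup = SurvivalDataset(
            np.vstack([ds.X, ds.X]), np.concatenate([ds.y, ds.y]),
            np.concatenate([ds.delta, ds.delta]),
        )
        a = fit_cox_baseline(ds)
        b = fit_cox_baseline(dup)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-4)

    def test_no_events_raises(self):
        ds = SurvivalDataset(np.zeros((5, 1)), np.arange(1.0, 6.0), np.zeros(5, int))
        with pytest.raises(FitError):
            fit_cox_baseline(ds)
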