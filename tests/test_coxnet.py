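import numpy as np
import pytest

from ltrcnet import (
    LTRCDataset,
    cross_validate,
    fit_path,
    lambda_max,
    lambda_path,
    partial_loglik,
    penalized_objective,
    risk_set_indices,
)
from ltrcnet.coxnet import CoxPath, DegenerateDataError, EmptyRiskSetError, NoEventsError

from _oracles import brute_partial_loglik, random_ltrc_case
from conftest import simulate_ltrc


class TestRiskSets:
    def test_hand_enumeration(self, toy_ltrc):
        sets = {t: idx.tolist() for t, idx in risk_set_indices(toy_ltrc, adjust=True)}
        assert sets == {2.0: [0, 2], 4.0: [1, 2], 6.0: [2]}
        unadj = {t: idx.tolist() for t, idx in risk_set_indices(toy_ltrc, adjust=False)}
        assert unadj == {2.0: [0, 1, 2], 4.0: [1, 2], 6.0: [2]}

    def test_truncation_free_reduction(self):
        ds, _ = simulate_ltrc(3, n=40, trunc_prob=0.0)
        adj = risk_set_indices(ds, adjust=True)
        un = risk_set_indices(ds, adjust=False)
        for (t1, i1), (t2, i2) in zip(adj, un):
            assert t1 == t2 and np.array_equal(i1, i2)

    def test_entry_exactly_at_event_time_excluded(self):
        # strict inequality t > v: entering at the event time is too late
        ds = LTRCDataset(
            entry=[0.0, 2.0],
            time=[2.0, 5.0],
            event=[1, 0],
            predictors=np.zeros((2, 1)),
            predictor_names=["x"],
        )
        (t, idx), = risk_set_indices(ds, adjust=True)
        assert t == 2.0 and idx.tolist() == [0]

    def test_adjusted_subset_of_unadjusted(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y, v, e, X = random_ltrc_case(rng)
            ds = LTRCDataset(v, y, e, X, [f"x{i}" for i in range(X.shape[1])])
            un = dict(risk_set_indices(ds, adjust=False))
            for t, idx in risk_set_indices(ds, adjust=True):
                assert set(idx).issubset(set(un[t]))

    def test_no_events_error(self):
        ds = LTRCDataset([0.0], [1.0], [0], np.zeros((1, 1)), ["x"])
        with pytest.raises(NoEventsError):
            risk_set_indices(ds)


class TestPartialLoglik:
    def test_null_beta_hand_value(self, toy_ltrc):
        # each event term is -log |R*_i|: risk sets of size 2, 2, 1
        val = partial_loglik(toy_ltrc, [0.0], adjust=True)
        assert val == pytest.approx(-(np.log(2) + np.log(2)), abs=1e-12)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            y, v, e, X = random_ltrc_case(rng)
            beta = rng.uniform(-1, 1, X.shape[1])
            ds = LTRCDataset(v, y, e, X, [f"x{i}" for i in range(X.shape[1])])
            for adjust in (True, False):
                try:
                    expected = brute_partial_loglik(y, v, e, X, beta, adjust)
                except ZeroDivisionError:
                    with pytest.raises(EmptyRiskSetError):
                        partial_loglik(ds, beta, adjust=adjust)
                    continue
                assert partial_loglik(ds, beta, adjust=adjust) == pytest.approx(
                    expected, abs=1e-9
                )
                checked += 1
        assert checked > 150

    def test_truncation_free_equals_standard(self):
        ds, beta = simulate_ltrc(5, n=60, trunc_prob=0.0)
        assert partial_loglik(ds, beta, adjust=True) == pytest.approx(
            partial_loglik(ds, beta, adjust=False), abs=1e-10
        )


class TestPenalizedObjective:
    def test_zero_beta_zero_penalty(self, toy_ltrc):
        val = penalized_objective(toy_ltrc, [0.0], lam=0.7, alpha_mix=0.5)
        assert val == pytest.approx((2 / 3) * partial_loglik(toy_ltrc, [0.0]))

    def test_lambda_zero(self):
        ds, beta = simulate_ltrc(1, n=50)
        assert penalized_objective(ds, beta, lam=0.0, alpha_mix=1.0) == pytest.approx(
            (2 / ds.n) * partial_loglik(ds, beta)
        )

    def test_closed_form_penalty(self):
        ds, _ = simulate_ltrc(2, n=50, p=2)
        beta = np.array([0.5, -0.5])
        with_pen = penalized_objective(ds, beta, lam=0.1, alpha_mix=1.0)
        without = (2 / ds.n) * partial_loglik(ds, beta)
        assert without - with_pen == pytest.approx(0.1 * 1.0, abs=1e-12)

    def test_negative_lambda_rejected(self, toy_ltrc):
        with pytest.raises(ValueError):
            penalized_objective(toy_ltrc, [0.0], lam=-0.1)


class TestLambdaPath:
    def test_all_zero_at_and_above_lambda_max(self, ltrc_200):
        ds, _ = ltrc_200
        lmax = lambda_max(ds, 1.0)
        for lam in (lmax, 1.0001 * lmax):
            path = fit_path(ds, 1.0, lambdas=[lam])
            assert np.all(path.coef == 0.0)

    def test_kkt_boundary_just_below(self, ltrc_200):
        ds, _ = ltrc_200
        lmax = lambda_max(ds, 1.0)
        path = fit_path(ds, 1.0, lambdas=[0.99 * lmax])
        assert path.n_nonzero[0] >= 1

    def test_path_geometry(self, ltrc_200):
        ds, _ = ltrc_200
        lams = lambda_path(ds, 1.0, n_lambda=100, ratio=0.01)
        assert len(lams) == 100
        assert lams[0] / lams[-1] == pytest.approx(100.0)
        assert np.all(np.diff(lams) < 0)


class TestFitPath:
    def test_unpenalized_matches_newton_oracle(self, ltrc_200):
        # independent Newton-Raphson LTRC Cox MLE (lifelines) at lambda=0
        from lifelines import CoxPHFitter

        ds, _ = ltrc_200
        path = fit_path(ds, 1.0, lambdas=[0.0], adjust=True)
        df = ds.to_frame()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event", entry_col="entry")
        assert np.abs(path.coef[:, 0] - cph.params_.values).max() < 1e-4

    def test_truncation_free_equivalence(self):
        ds, _ = simulate_ltrc(11, n=150, trunc_prob=0.0)
        lams = lambda_path(ds, 1.0, n_lambda=30)
        a = fit_path(ds, 1.0, lambdas=lams, adjust=True)
        b = fit_path(ds, 1.0, lambdas=lams, adjust=False)
        assert np.abs(a.coef - b.coef).max() < 1e-10

    def test_untruncated_path_matches_sksurv(self):
        # right-censored elastic-net Cox oracle on pre-standardized X;
        # the oracle's penalty scale is half ours (1/n vs 2/n loglik)
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        ds, _ = simulate_ltrc(13, n=250, p=6, trunc_prob=0.0)
        X = (ds.predictors - ds.predictors.mean(0)) / ds.predictors.std(0)
        ds = LTRCDataset(ds.entry, ds.time, ds.event, X, ds.predictor_names)
        for alpha_mix in (1.0, 0.5):
            lams = lambda_path(ds, alpha_mix, n_lambda=25)
            mine = fit_path(ds, alpha_mix, lambdas=lams)
            oracle = CoxnetSurvivalAnalysis(
                l1_ratio=alpha_mix, normalize=False, tol=1e-12, alphas=lams / 2
            )
            oracle.fit(X, Surv.from_arrays(ds.event.astype(bool), ds.time))
            assert np.abs(mine.coef - oracle.coef_).max() < 1e-4

    def test_kkt_conditions_at_convergence(self, ltrc_200):
        from ltrcnet.coxnet import _RiskStructure, _standardize

        ds, _ = ltrc_200
        lams = lambda_path(ds, 1.0, n_lambda=20)
        path = fit_path(ds, 1.0, lambdas=lams)
        Xs, _, scale, _ = _standardize(ds.predictors)
        work = _RiskStructure(ds.time, ds.entry, ds.event, True)
        for l, lam in enumerate(path.lambdas):
            b_std = path.coef[:, l] * scale
            _, grad, _ = work.quantities(Xs @ b_std)
            g = (2.0 / ds.n) * (Xs.T @ grad)
            nz = b_std != 0
            if nz.any():
                assert np.abs(np.abs(g[nz] - lam * 0.0 * b_std[nz]) - lam).max() < 1e-4
            if (~nz).any():
                assert np.abs(g[~nz]).max() <= lam + 1e-4

    def test_monotone_ascent_along_warm_starts(self, ltrc_200):
        # objective at each lambda's solution must not fall below the
        # objective of its warm start (the previous solution); checked on
        # pre-standardized predictors, the scale the penalty acts on
        ds, _ = ltrc_200
        X = (ds.predictors - ds.predictors.mean(0)) / ds.predictors.std(0)
        ds = LTRCDataset(ds.entry, ds.time, ds.event, X, ds.predictor_names)
        lams = lambda_path(ds, 1.0, n_lambda=30)
        path = fit_path(ds, 1.0, lambdas=lams)
        for l in range(1, len(path.lambdas)):
            lam = path.lambdas[l]
            obj_warm = penalized_objective(ds, path.coef[:, l - 1], lam, 1.0)
            obj_fit = penalized_objective(ds, path.coef[:, l], lam, 1.0)
            assert obj_fit >= obj_warm - 1e-8

    def test_parameter_recovery(self):
        # n=2000, p=5, ~30% positive entries: adjusted near-unpenalized fit
        # recovers the generating coefficients
        ds, beta = simulate_ltrc(17, n=2000, p=5, trunc_prob=0.3)
        path = fit_path(ds, 1.0, lambdas=[0.0], adjust=True)
        assert np.abs(path.coef[:, 0] - beta).max() < 0.1

    def test_zero_variance_predictor_warned_and_zeroed(self):
        ds, _ = simulate_ltrc(19, n=80, p=2)
        X = np.hstack([ds.predictors, np.ones((ds.n, 1))])
        ds2 = LTRCDataset(ds.entry, ds.time, ds.event, X, ["a", "b", "const"])
        with pytest.warns(UserWarning, match="zero-variance"):
            path = fit_path(ds2, 1.0, lambdas=[0.05])
        assert path.coef[2, 0] == 0.0

    def test_json_round_trip(self, tmp_path, ltrc_200):
        ds, _ = ltrc_200
        path = fit_path(ds, 0.9, lambdas=lambda_path(ds, 0.9, n_lambda=8))
        path.to_json(tmp_path / "m.json")
        back = CoxPath.from_json(tmp_path / "m.json")
        assert np.array_equal(back.coef, path.coef)
        assert np.array_equal(back.lambdas, path.lambdas)
        assert back.alpha_mix == path.alpha_mix


class TestCrossValidate:
    def test_deterministic_under_seed(self, ltrc_200):
        ds, _ = ltrc_200
        a = cross_validate(ds, n_folds=5, seed=3, n_lambda=20)
        b = cross_validate(ds, n_folds=5, seed=3, n_lambda=20)
        assert np.array_equal(a.fold_assignments, b.fold_assignments)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.cv_deviance_mean, b.cv_deviance_mean)

    def test_lambda_min_is_argmin_and_1se_above(self, ltrc_200):
        ds, _ = ltrc_200
        cv = cross_validate(ds, n_folds=5, seed=1, n_lambda=20)
        i = int(np.argmin(cv.cv_deviance_mean))
        assert cv.lambda_min == cv.lambdas[i]
        assert np.all(cv.cv_deviance_mean >= cv.cv_deviance_mean[i])
        assert cv.lambda_1se >= cv.lambda_min

    def test_pure_noise_selects_null_model(self):
        # with no true signal, CV deviance should favor heavy penalty:
        # the selected model is (nearly) empty in a majority of runs
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, p = 500, 10
            X = rng.standard_normal((n, p))
            T = rng.exponential(1.0, n)
            U = rng.exponential(2.0, n)
            ds = LTRCDataset(
                np.zeros(n),
                np.minimum(T, U),
                (T <= U).astype(int),
                X,
                [f"x{i}" for i in range(p)],
            )
            cv = cross_validate(ds, n_folds=5, seed=seed, n_lambda=40)
            k = int(np.argmin(cv.cv_deviance_mean))
            if cv.path.n_nonzero[k] <= 2 or k <= 10:
                wins += 1
        assert wins > 10

    def test_empty_fold_advises_fewer_folds(self):
        rng = np.random.default_rng(0)
        n = 12
        ds = LTRCDataset(
            np.zeros(n),
            rng.uniform(1, 2, n),
            np.array([1, 1] + [0] * (n - 2)),
            rng.standard_normal((n, 2)),
            ["a", "b"],
        )
        with pytest.raises(DegenerateDataError, match="fewer folds"):
            cross_validate(ds, n_folds=6, seed=0, n_lambda=5)
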