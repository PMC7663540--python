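import numpy as np
import pandas as pd
import pytest

from blocksurv.coxmodel import (ConvergenceError, CoxFit, StepwiseCoxPH, fit_cox,
                                hazard_ratio, null_log_partial_likelihood, report_table,
                                stepwise_aic)
from blocksurv.integrate import IntegratedDataset
from blocksurv.spca import SparseComponent

from conftest import make_survival


def make_data(X, names=None):
    n = X.shape[0]
    ids = [f"s{i:03d}" for i in range(n)]
    df = pd.DataFrame(X, columns=names or [f"c{i}" for i in range(X.shape[1])], index=ids)
    return IntegratedDataset(df, {})


def simulate_cox(rng, beta, n, censor_frac=0.0):
    """Exponential proportional-hazards draw for coefficient-recovery tests."""
    p = len(beta)
    X = rng.standard_normal((n, p))
    rate = np.exp(X @ np.asarray(beta))
    t = rng.exponential(1.0 / rate)
    if censor_frac > 0:
        c = rng.exponential(np.quantile(t, 1 - censor_frac) * 2, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    else:
        time, event = t, np.ones(n, int)
    return make_data(X), make_survival(np.maximum(time, 1e-9), event)


class TestHazardRatio:
    @pytest.mark.parametrize("coef,hr", [(-0.40, 0.67), (-0.19, 0.83), (0.0, 1.0)])
    def test_exp_identity_two_decimals(self, coef, hr):
        assert round(hazard_ratio(coef), 2) == hr

    def test_infinite_coefficient_rejected(self):
        with pytest.raises(ValueError):
            hazard_ratio(float("inf"))


class TestFitCox:
    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        data, surv = simulate_cox(rng, [0.5, -0.3], 150, censor_frac=0.2)
        # round times to force ties, exercising the Efron correction
        surv = make_survival(np.ceil(surv.time * 10), surv.event)
        fit = fit_cox(data, surv)
        df = data.scores.copy()
        df["T"], df["E"] = surv.time, surv.event
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-8)

    def test_tiny_dataset_matches_grid_search_oracle(self):
        # brute-force maximization of the written partial likelihood
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 0, 1, 1])

        def logpl(b):
            eta = b * x
            total = 0.0
            for j in range(len(x)):
                if event[j]:
                    risk = time >= time[j]
                    total += eta[j] - np.log(np.exp(eta[risk]).sum())
            return total

        grid = np.arange(-5, 5, 1e-3)
        b_oracle = grid[np.argmax([logpl(b) for b in grid])]
        fit = fit_cox(make_data(x[:, None]), make_survival(time, event))
        assert fit.coef[0] == pytest.approx(b_oracle, abs=2e-3)

    def test_null_covariate_small_coefficient(self, rng):
        data, surv = simulate_cox(rng, [0.0], 500)
        fit = fit_cox(data, surv)
        assert abs(fit.coef[0]) < 0.1

    def test_coefficient_recovery_within_three_se(self, rng):
        data, surv = simulate_cox(rng, [0.5, -0.5], 1000, censor_frac=0.2)
        fit = fit_cox(data, surv)
        for b_hat, se, b_true in zip(fit.coef, fit.se, [0.5, -0.5]):
            assert abs(b_hat - b_true) < 3 * se

    def test_aic_identity_exact(self, rng):
        data, surv = simulate_cox(rng, [0.3, 0.1], 80)
        fit = fit_cox(data, surv)
        assert fit.aic == -2 * fit.log_likelihood + 2 * len(fit.labels)
        np.testing.assert_allclose(fit.hazard_ratios, np.exp(fit.coef), rtol=1e-12)

    def test_efron_breslow_agree_without_ties(self, rng):
        data, surv = simulate_cox(rng, [0.4], 60)
        assert len(np.unique(surv.time)) == 60
        fe = fit_cox(data, surv, ties="efron")
        fb = fit_cox(data, surv, ties="breslow")
        assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-10)
        assert fe.log_likelihood == pytest.approx(fb.log_likelihood, abs=1e-10)

    def test_collinear_covariates_rejected(self, rng):
        X = rng.standard_normal((50, 1))
        data = make_data(np.hstack([X, X]), names=["a", "b"])
        surv = make_survival(rng.exponential(1, 50) + 0.01, np.ones(50, int))
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(data, surv)

    def test_perfect_separation_flagged(self):
        # marker perfectly ordering event times drives |beta| -> inf
        n = 12
        x = np.arange(n, dtype=float)
        time = np.arange(1, n + 1, dtype=float)
        with pytest.raises(ConvergenceError, match="monotone|diverging"):
            fit_cox(make_data((-x)[:, None]), make_survival(time, np.ones(n, int)))

    def test_fewer_than_two_events_rejected(self, rng):
        data = make_data(rng.standard_normal((10, 1)))
        surv = make_survival(np.arange(1, 11), [1] + [0] * 9)
        with pytest.raises(ValueError, match="2 observed events"):
            fit_cox(data, surv)

    def test_empty_model_loglik_matches_null(self, rng):
        data, surv = simulate_cox(rng, [0.3], 40)
        fit = fit_cox(data, surv, covariates=[])
        assert fit.log_likelihood == pytest.approx(null_log_partial_likelihood(surv))
        assert fit.aic == -2 * fit.log_likelihood


class TestStepwiseAIC:
    def test_signal_kept_noise_dropped(self):
        # AIC drops a pure-noise covariate iff its Wald chi2 < 2, which
        # happens with probability ~0.843 per draw; the signal (true b=1,
        # n=500) is retained essentially always
        signal_kept = noise_dropped = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((500, 2))
            rate = np.exp(1.0 * X[:, 0])
            t = r.exponential(1.0 / rate)
            data = make_data(X, names=["signal", "noise"])
            surv = make_survival(t + 1e-9, np.ones(500, int))
            selected, fit = stepwise_aic(data, surv)
            signal_kept += "signal" in selected
            noise_dropped += "noise" not in selected
        assert signal_kept == 10
        assert noise_dropped >= 7

    def test_single_covariate_aic_comparison(self, rng):
        X = rng.standard_normal((200, 1))
        surv = make_survival(rng.exponential(1, 200) + 1e-9, np.ones(200, int))
        data = make_data(X)
        selected, fit = stepwise_aic(data, surv)
        full = fit_cox(data, surv)
        null = fit_cox(data, surv, covariates=[])
        assert fit.aic == pytest.approx(min(full.aic, null.aic))

    def test_stepwise_aic_never_above_full_model(self, rng):
        X = rng.standard_normal((150, 5))
        rate = np.exp(0.8 * X[:, 0] - 0.5 * X[:, 3])
        surv = make_survival(rng.exponential(1.0 / rate) + 1e-9, np.ones(150, int))
        data = make_data(X)
        selected, fit = stepwise_aic(data, surv)
        assert fit.aic <= fit_cox(data, surv).aic + 1e-9

    def test_identical_columns_surface_label_error(self, rng):
        X = rng.standard_normal((60, 1))
        data = make_data(np.hstack([X, X]), names=["a", "b"])
        surv = make_survival(rng.exponential(1, 60) + 1e-9, np.ones(60, int))
        with pytest.raises(ValueError, match="collinear"):
            stepwise_aic(data, surv)


def _component(label, names, loadings):
    return SparseComponent(
        layer_id=label.rstrip("0123456789"), block_index=1, label=label,
        variable_names=names, loadings=np.asarray(loadings, float),
        scores=pd.Series(dtype=float), k=int(np.count_nonzero(loadings)), ridge=1e-6,
    )


class TestReportTable:
    def test_row_per_selected_component(self, rng):
        fit = CoxFit(["D1", "D2"], np.array([0.0, 0.5]), np.array([0.1, 0.2]),
                     np.array([1.0, 0.01]), -100.0, 40)
        prov = {
            "D1": _component("D1", ["g1", "g2", "g3"], [0.9, 0.0, 0.44]),
            "D2": _component("D2", ["g4", "g5"], [1.0, 0.0]),
        }
        table = report_table(fit, prov)
        assert len(table) == 2
        assert table.loc[0, "hazard_ratio"] == pytest.approx(1.0)
        assert table.loc[0, "n_variables"] == 3
        assert table.loc[0, "n_variables_remained"] == 2

    def test_missing_provenance_rejected(self):
        fit = CoxFit(["D1"], np.array([0.1]), np.array([0.1]), np.array([0.5]), -10.0, 5)
        with pytest.raises(KeyError, match="D1"):
            report_table(fit, {})


class TestStepwiseCoxPHEstimator:
    def test_fit_predict_marker(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        rate = np.exp(X["a"].to_numpy())
        y = pd.DataFrame({"time": rng.exponential(1 / rate) + 1e-9, "status": 1},
                         index=X.index)
        est = StepwiseCoxPH().fit(X, y)
        assert "a" in est.selected_
        marker = est.predict(X)
        assert marker.shape == (200,)
        assert est.score(X, y) > 0.6

    def test_no_selection_keeps_full_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        y = pd.DataFrame({"time": rng.exponential(1, 100) + 1e-9, "status": 1},
                         index=X.index)
        est = StepwiseCoxPH(select=False).fit(X, y)
        assert est.selected_ == ["a", "b", "c"]
        assert est.aic_ == pytest.approx(est.fit_.aic)

    def test_sklearn_params_roundtrip(self):
        est = StepwiseCoxPH(select=False, ties="breslow")
        assert StepwiseCoxPH(**est.get_params()).get_params() == est.get_params()
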