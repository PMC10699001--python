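import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.optimize import minimize_scalar

from m6atlas import survival as surv
from m6atlas.io import ClinicalTable
from tests.conftest import make_expression


def _clin(times, events, ids=None):
    ids = ids or [f"S{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"os_time": times, "os_event": events}, index=ids)
    )


class TestCoxFit:
    def test_six_subject_brute_force_likelihood(self):
        # no ties: the partial likelihood can be written out term by term and
        # maximized directly, independent of the Newton implementation
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.5, -1.0, 0.3, 1.2, -0.7, 0.1])

        def neg_lpl(beta):
            ll = 0.0
            for i in range(6):
                if events[i]:
                    risk = times >= times[i]
                    ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        ref = minimize_scalar(neg_lpl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        fit = surv.cox_fit(_clin(times, events), pd.DataFrame({"x": x}, index=[f"S{i}" for i in range(6)]))
        assert fit.coefficients.iloc[0] == pytest.approx(ref.x, abs=1e-4)
        assert fit.log_partial_likelihood == pytest.approx(-ref.fun, abs=1e-8)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(1)
        n = 150
        x = rng.normal(size=(n, 2))
        T = np.ceil(np.exp(-0.5 * x[:, 0] + 0.3 * x[:, 1]) * rng.exponential(20, n))
        C = rng.uniform(0, 60, n)
        t_obs, ev = np.minimum(T, C), (T <= C).astype(int)
        fit = surv.cox_fit(_clin(t_obs, ev), pd.DataFrame(x, columns=["a", "b"],
                                                          index=[f"S{i}" for i in range(n)]))
        ref = CoxPHFitter().fit(
            pd.DataFrame({"T": t_obs, "E": ev, "a": x[:, 0], "b": x[:, 1]}), "T", "E"
        )
        np.testing.assert_allclose(fit.coefficients, ref.params_, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.standard_errors_, atol=1e-6)

    def test_planted_hazard_recovered(self, toy_survival):
        clin, cov = toy_survival
        fit = surv.cox_fit(clin, cov)
        assert fit.converged
        assert fit.coefficients.iloc[0] == pytest.approx(0.7, abs=0.15)
        assert fit.hazard_ratios.iloc[0] == pytest.approx(np.exp(fit.coefficients.iloc[0]))

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            surv.cox_fit(_clin([1.0, 2.0], [0, 0]),
                         pd.DataFrame({"x": [0.1, 0.2]}, index=["S0", "S1"]))

    def test_constant_covariate_named(self):
        with pytest.raises(ValueError, match="x"):
            surv.cox_fit(_clin([1, 2, 3], [1, 1, 1]),
                         pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=["S0", "S1", "S2"]))

    def test_separation_flagged_not_fatal(self):
        # perfectly ordered covariate -> monotone likelihood
        times = np.arange(1.0, 9.0)
        x = -times
        with pytest.warns(RuntimeWarning, match="separated"):
            fit = surv.cox_fit(_clin(times, np.ones(8, int)),
                               pd.DataFrame({"x": x}, index=[f"S{i}" for i in range(8)]))
        assert not fit.converged
        assert np.abs(fit.coefficients.iloc[0]) <= surv.BETA_CAP


class TestUnivariateScreen:
    def test_prognostic_gene_found_noise_gene_not(self, cohort):
        X, clin, _, _, truth = cohort
        prog = sorted(truth.planted_prognostic_genes)[:3]
        noise = [g for g in X.gene_ids if g.startswith("NOISE")][:3]
        table, sig = surv.univariate_screen(X, clin, prog + noise)
        assert set(prog) <= sig
        assert table.loc[prog, "p"].max() < 0.05

    def test_boundary_strict(self):
        # a gene with p exactly at alpha must be excluded -> emulate via alpha
        rng = np.random.default_rng(0)
        X = make_expression(rng.uniform(2, 8, size=(2, 50)))
        clin = _clin(rng.exponential(100, 50), np.ones(50, int), ids=X.sample_ids)
        table, sig = surv.univariate_screen(X, clin, X.gene_ids, alpha=0.0)
        assert sig == set()  # strict inequality: nothing can beat alpha=0


class TestKaplanMeier:
    def test_two_events_product_limit(self):
        km = surv.km_estimate(_clin([1.0, 2.0], [1, 1]))["all"]
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_censor_then_event(self):
        km = surv.km_estimate(_clin([1.0, 2.0], [0, 1]))["all"]
        assert km.at(1.0) == 1.0  # no event at t=1
        assert km.at(2.0) == 0.0  # 1 at risk, 1 event

    def test_all_censored_flat(self):
        km = surv.km_estimate(_clin([1.0, 2.0, 3.0], [0, 0, 0]))["all"]
        assert km.times.size == 0 and km.at(99.0) == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0.1, 100), min_size=3, max_size=40))
    def test_no_censoring_equals_empirical_survival(self, times):
        times = np.round(np.array(times), 3)
        km = surv.km_estimate(_clin(times, np.ones(len(times), int)))["all"]
        for t in km.times:
            emp = (times > t).mean()
            assert km.at(t) == pytest.approx(emp, abs=1e-9)

    def test_unknown_group_label(self):
        clin = _clin([1.0, 2.0], [1, 1])
        labels = pd.Series(["a"], index=["S0"])  # S1 missing
        with pytest.raises(ValueError, match="S1"):
            surv.km_estimate(clin, labels)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        ids = [f"S{i}" for i in range(8)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        chi2, df, p = surv.logrank_test(_clin(times, events, ids), labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_groups_df(self, cohort):
        _, clin, _, _, truth = cohort
        chi2, df, p = surv.logrank_test(clin, truth.true_labels)
        assert df == 3
        assert p < 0.05  # planted cluster-specific survival

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        n = 120
        g = rng.integers(0, 3, n)
        T = rng.exponential(np.where(g == 0, 50, 100), n)
        C = rng.uniform(0, 150, n)
        t_obs, ev = np.minimum(T, C), (T <= C).astype(int)
        ids = [f"S{i}" for i in range(n)]
        chi2, df, p = surv.logrank_test(_clin(t_obs, ev, ids), pd.Series(g, index=ids))
        ref = multivariate_logrank_test(t_obs, g, ev)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_single_group_rejected(self):
        clin = _clin([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            surv.logrank_test(clin, pd.Series(["a", "a"], index=["S0", "S1"]))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(9)
    n = 300
    beta_true = {"PG1": 0.7, "PG2": -0.6, "PG3": 0.5}
    genes = list(beta_true) + [f"N{j}" for j in range(30)]
    expr = rng.normal(6, 1, size=(len(genes), n)).clip(0)
    X = make_expression(expr, genes=genes)
    eta = sum(b * (X.values.loc[g] - 6) for g, b in beta_true.items())
    T = np.exp(-eta.to_numpy()) * rng.exponential(1000, n)
    C = rng.uniform(0, 3000, n)
    clin = _clin(np.minimum(T, C), (T <= C).astype(int), ids=X.sample_ids)
    return X, clin, beta_true


@pytest.fixture(scope="module")
def planted_risk():
    rng = np.random.default_rng(13)
    n = 200
    genes = ["A", "B"] + [f"N{j}" for j in range(10)]
    expr = rng.normal(6, 1, size=(len(genes), n)).clip(0)
    X = make_expression(expr, genes=genes)
    eta = 0.8 * (X.values.loc["A"] - 6) - 0.8 * (X.values.loc["B"] - 6)
    T = np.exp(-eta.to_numpy()) * rng.exponential(800, n)
    C = rng.uniform(0, 2500, n)
    clin = _clin(np.minimum(T, C), (T <= C).astype(int), ids=X.sample_ids)
    path = surv.lasso_cox(X, clin, n_folds=4, seed=0, n_lambda=20)
    return path, X, clin


class TestLassoCox:
    def test_all_zero_at_lambda_max(self, planted):
        X, clin, _ = planted
        path = surv.lasso_cox(X, clin, n_folds=4, seed=0, n_lambda=10)
        assert (path.coefs.iloc[:, 0] == 0).all()

    def test_lambda_zero_equals_unpenalized(self, planted):
        X, clin, beta_true = planted
        genes = list(beta_true)
        path = surv.lasso_cox(X, clin, genes=genes, seed=0, lambda_grid=[0.0])
        fit = surv.cox_fit(clin, X.values.loc[genes].T, ties="breslow")
        np.testing.assert_allclose(
            path.coefs.iloc[:, 0].to_numpy(), fit.coefficients.to_numpy(), atol=1e-4
        )

    def test_training_deviance_monotone_in_lambda(self, planted):
        X, clin, _ = planted
        path = surv.lasso_cox(X, clin, n_folds=4, seed=0, n_lambda=15)
        assert np.all(np.diff(path.train_deviance) <= 1e-6)

    def test_planted_genes_selected(self, planted):
        X, clin, beta_true = planted
        path = surv.lasso_cox(X, clin, n_folds=5, seed=3, n_lambda=30)
        assert set(beta_true) <= set(path.active_genes)

    def test_too_few_events_for_folds(self):
        clin = _clin([1.0, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0])
        X = make_expression(np.random.default_rng(0).uniform(2, 8, (3, 6)),
                            samples=clin.sample_ids)
        with pytest.raises(ValueError, match="n_folds"):
            surv.lasso_cox(X, clin, n_folds=5, seed=0)


class TestTdAUC:
    def test_perfect_ranking(self):
        t = np.arange(1.0, 21.0)
        scores = -t  # higher score = earlier event
        assert surv.td_auc(scores, t, np.ones(20, int), 10.0) == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        n = 100
        sc = rng.normal(size=n)
        T = np.exp(-sc) * rng.exponential(50, n)
        C = rng.uniform(0, 120, n)
        t_obs, ev = np.minimum(T, C), (T <= C).astype(int)
        a1 = surv.td_auc(sc, t_obs, ev, 30.0)
        a2 = surv.td_auc(np.exp(3 * sc) + 7, t_obs, ev, 30.0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sksurv(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(3)
        n = 200
        sc = rng.normal(size=n)
        T = np.exp(-0.8 * sc) * rng.exponential(100, n)
        C = rng.uniform(0, 300, n)
        t_obs, ev = np.minimum(T, C), T <= C
        y = Surv.from_arrays(ev, t_obs)
        ref, _ = cumulative_dynamic_auc(y, y, sc, [60.0])
        ours = surv.td_auc(sc, t_obs, ev.astype(int), 60.0)
        assert ours == pytest.approx(float(ref[0]), abs=1e-10)

    def test_horizon_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            surv.td_auc(np.array([1.0, 2.0]), np.array([5.0, 6.0]),
                        np.array([1, 1]), 100.0)


class TestRiskModel:
    def test_median_split_and_translation_invariance(self, planted_risk):
        path, X, clin = planted_risk
        model = surv.risk_model(path, X, clin)
        assert set(model.groups.unique()) == {"High", "Low"}
        assert abs((model.groups == "High").sum() - (model.groups == "Low").sum()) <= 1
        shifted = model.scores + 100.0
        assert ((shifted > shifted.median()) == (model.groups == "High")).all()

    def test_informative_model_beats_chance(self, planted_risk):
        path, X, clin = planted_risk
        model = surv.risk_model(path, X, clin, horizons=[365, 730])
        assert model.td_auc[365] > 0.6


class TestRankHelpers:
    def test_kruskal_hand_example(self):
        values = [1, 2, 3, 4, 5, 6]
        labels = ["a", "a", "b", "b", "c", "c"]
        H, df, p = surv.kruskal_wallis(values, labels)
        assert H == pytest.approx(32 / 7, abs=1e-3)  # 4.571 by the rank formula
        assert df == 2

    def test_kruskal_all_ties(self):
        H, df, p = surv.kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert H == 0.0 and p == 1.0

    def test_chi2_hand_example(self):
        chi2, df, p = surv.chi_square([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_chi2_negative_cell(self):
        with pytest.raises(ValueError):
            surv.chi_square([[1, -2], [3, 4]])

    def test_spearman_perfect_antimonotone(self):
        rho, p = surv.spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_spearman_needs_three(self):
        with pytest.raises(ValueError):
            surv.spearman([1, 2], [2, 1])
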