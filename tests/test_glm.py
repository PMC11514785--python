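import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from swfe.design import CellSizes, Design, expand
from swfe.glm import (
    FitResult,
    TrialData,
    aic_bic,
    fit,
    glm_weights,
    information_matrix,
    interval_from_estimate,
    mean_response,
    period_homogeneity_check,
    wald_ci,
    wald_one_sided,
)
from swfe.simulate import PopulationParams, replicate_rng, simulate_trial
from swfe.variance import var_delta


def _stub_fit(delta_hat=0.0, se=1.0, loglik=0.0, n_obs=20, n_params=3) -> FitResult:
    cov = np.eye(n_params) * se**2
    beta = np.zeros(n_params)
    beta[0] = delta_hat
    return FitResult(
        beta_hat=beta, cov=cov, delta_hat=delta_hat, se_delta=se,
        loglik=loglik, n_obs=n_obs, n_params=n_params, converged=True,
        n_iter=1, column_map=("Z",) * n_params, family="binary",
    )


class TestMeanAndWeights:
    @pytest.mark.parametrize(
        "eta, family, expected",
        [
            (0.0, "binary", 0.5),
            (np.log(0.3 / 0.7), "binary", 0.30),
            (np.log(0.30), "count", 0.30),
        ],
    )
    def test_mean_response(self, eta, family, expected):
        X = np.array([[1.0]])
        mu = mean_response(X, np.array([eta]), family)
        assert mu[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "mu, family, expected",
        [(0.5, "binary", 0.25), (0.3, "binary", 0.21), (0.3, "count", 0.3)],
    )
    def test_weights(self, mu, family, expected):
        assert glm_weights(np.array([mu]), family)[0] == pytest.approx(expected)

    def test_weight_domain_errors(self):
        with pytest.raises(ValueError):
            glm_weights(np.array([1.0]), "binary")
        with pytest.raises(ValueError):
            glm_weights(np.array([0.0]), "count")

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mean_response(np.ones((3, 2)), np.ones(3), "binary")


class TestInformationMatrix:
    def test_single_column(self):
        M = information_matrix(np.ones((2, 1)), np.array([2.0, 3.0]))
        assert M.shape == (1, 1)
        assert M[0, 0] == pytest.approx(5.0)

    def test_matches_rowwise_accumulation_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        w = rng.uniform(0.1, 2.0, size=20)
        brute = np.zeros((4, 4))
        for i in range(20):
            brute += w[i] * np.outer(X[i], X[i])
        np.testing.assert_allclose(information_matrix(X, w), brute, rtol=1e-12)

    def test_exactly_symmetric(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 6))
        M = information_matrix(X, rng.uniform(0.5, 1.5, size=50))
        np.testing.assert_array_equal(M, M.T)

    def test_first_element_is_total_exposed_weight(self, design55):
        # (1,1) of X'VX is the sum of weights over intervention-exposed rows
        sizes = CellSizes.constant(design55, 4)
        ex = expand(design55, sizes)
        rng = np.random.default_rng(5)
        w = rng.uniform(0.1, 0.25, size=ex.n_obs)
        M = information_matrix(ex.X, w)
        assert M[0, 0] == pytest.approx(w[ex.X[:, 0] == 1].sum())

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            information_matrix(np.ones((2, 1)), np.array([1.0, 0.0]))


def _saturated_fixture():
    """2x2 trial whose model is saturated: 4 cells, 4 parameters.

    Cell event proportions are set to exact rationals; the unique beta*
    solving the saturated logit equations is obtained by a linear solve,
    independent of the IRLS path.
    """
    design = Design(Z=np.array([[0, 1], [0, 0]]), roles=("stepped", "unexposed"))
    n = 40
    props = {(1, 1): 10 / n, (1, 2): 18 / n, (2, 1): 14 / n, (2, 2): 16 / n}
    # cell design vectors in column order (Z, phi_2, alpha_1, alpha_2)
    cells = {(1, 1): [0, 0, 1, 0], (1, 2): [1, 1, 1, 0],
             (2, 1): [0, 0, 0, 1], (2, 2): [0, 1, 0, 1]}
    keys = sorted(cells)
    A = np.array([cells[k] for k in keys], dtype=float)
    b = logit(np.array([props[k] for k in keys]))
    beta_star = np.linalg.solve(A, b)

    rows = []
    for (i, j), p in props.items():
        events = round(p * n)
        ys = [1] * events + [0] * (n - events)
        for y in ys:
            rows.append({"cluster": i, "period": j,
                         "treat": int(design.Z[i - 1, j - 1]), "y": y})
    data = TrialData(records=pd.DataFrame(rows), family="binary")
    return design, data, beta_star


class TestFit:
    def test_saturated_fit_recovers_closed_form_solution(self):
        design, data, beta_star = _saturated_fixture()
        res = fit(data, expand(design, data.cell_sizes(design)))
        assert res.converged
        np.testing.assert_allclose(res.beta_hat, beta_star, atol=1e-8)

    def test_agrees_with_statsmodels(self, binary_trial, design55):
        sm = pytest.importorskip("statsmodels.api")
        ex = expand(design55, binary_trial.cell_sizes(design55))
        res = fit(binary_trial, ex)
        y = binary_trial.records.sort_values(
            ["cluster", "period"], kind="stable")["y"].to_numpy(dtype=float)
        ref = sm.GLM(y, ex.X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.beta_hat, ref.params, rtol=1e-6)
        np.testing.assert_allclose(res.se_delta, ref.bse[0], rtol=1e-5)

    def test_all_zero_cluster_flags_separation(self, design55):
        rng = replicate_rng(7, 0, 0)
        params = PopulationParams(delta=0.0, mu_alpha=0.0, tau2=0.0,
                                  family="binary", size_shape=30.0)
        data = simulate_trial(design55, params, rng)
        df = data.records.copy()
        df.loc[df["cluster"] == 2, "y"] = 0
        broken = TrialData(records=df, family="binary")
        res = fit(broken, expand(design55, broken.cell_sizes(design55)))
        assert not res.converged
        assert res.diagnosis == "separation"

    def test_rank_deficiency_names_columns(self, design55, binary_trial):
        ex = expand(design55, binary_trial.cell_sizes(design55))
        X_bad = np.column_stack([ex.X, ex.X[:, 1]])
        from swfe.design import ExpandedDesign
        bad = ExpandedDesign(X=X_bad, column_map=ex.column_map + ("phi_2_dup",),
                             row_index=ex.row_index, design=design55)
        with pytest.raises(ValueError, match="rank deficient"):
            fit(binary_trial, bad)

    def test_loglik_nondecreasing_over_iterations(self, binary_trial, design55):
        res = fit(binary_trial, expand(design55, binary_trial.cell_sizes(design55)))
        path = np.array(res.loglik_path)
        assert (np.diff(path) >= -1e-9).all()

    def test_count_score_zero_at_mle(self, design55):
        # Poisson score equations: fitted totals reproduce observed totals
        rng = replicate_rng(11, 0, 0)
        params = PopulationParams(delta=np.log(0.8), mu_alpha=np.log(0.3),
                                  tau2=0.077, family="count", size_shape=50.0)
        data = simulate_trial(design55, params, rng)
        ex = expand(design55, data.cell_sizes(design55))
        res = fit(data, ex)
        assert res.converged
        y = data.records.sort_values(["cluster", "period"], kind="stable")["y"].to_numpy()
        mu = mean_response(ex.X, res.beta_hat, "count")
        score = ex.X.T @ (y - mu)
        assert np.abs(score).max() < 1e-6

    def test_cov_matches_analytic_schur_path(self, binary_trial, design55):
        sizes = binary_trial.cell_sizes(design55)
        res = fit(binary_trial, expand(design55, sizes))
        v_analytic = var_delta(design55, sizes, res.beta_hat, "binary")
        assert res.cov[0, 0] == pytest.approx(v_analytic, rel=1e-8)


class TestWald:
    def test_null_estimate_gives_half_p(self):
        t = wald_one_sided(_stub_fit(0.0, 1.0), "greater")
        assert t.p_value == pytest.approx(0.5)
        assert not t.reject

    def test_two_sigma_rejects(self):
        t = wald_one_sided(_stub_fit(2.0, 1.0), "greater")
        assert t.p_value == pytest.approx(0.02275, abs=1e-5)
        assert t.reject

    def test_less_direction_symmetric(self):
        t = wald_one_sided(_stub_fit(-2.0, 1.0), "less")
        assert t.reject

    def test_nonconverged_fit_refused(self):
        bad = _stub_fit()
        object.__setattr__(bad, "converged", False)
        with pytest.raises(ValueError):
            wald_one_sided(bad, "greater")

    def test_published_upper_bound(self):
        # delta_hat 0.053, SE 0.176 -> upper bound 0.398 at 3 d.p.
        ci = interval_from_estimate(0.053, 0.176)
        assert round(ci.upper, 3) == 0.398

    def test_exponentiated_bounds_from_linear_bounds(self):
        # linear CI (-0.294, 0.398) -> OR CI (0.745, 1.489) at 3 d.p.
        assert round(float(np.exp(-0.294)), 3) == 0.745
        assert round(float(np.exp(0.398)), 3) == 1.489
        ci = wald_ci(_stub_fit(0.053, 0.176))
        assert ci.exp_lower == pytest.approx(np.exp(ci.lower))
        assert ci.exp_upper == pytest.approx(np.exp(ci.upper))

    def test_zero_se_degenerate_interval(self):
        ci = wald_ci(_stub_fit(0.3, 0.0))
        assert ci.lower == ci.upper == 0.3


class TestCriteria:
    @pytest.mark.parametrize(
        "loglik, p, n, aic, bic",
        [(0.0, 3, 20, 6.0, 3 * np.log(20)), (-10.0, 2, 100, 24.0, 20 + 2 * np.log(100))],
    )
    def test_aic_bic_arithmetic(self, loglik, p, n, aic, bic):
        a, b = aic_bic(_stub_fit(loglik=loglik, n_params=p, n_obs=n))
        assert a == pytest.approx(aic)
        assert b == pytest.approx(bic)


class TestPeriodHomogeneity:
    def _simulate(self, design55, seed, unexposed_shift=0.0, size=80):
        rng = replicate_rng(seed, 0, 0)
        params = PopulationParams(delta=np.log(1.25), mu_alpha=logit(0.3),
                                  tau2=0.0, family="binary", size_shape=float(size))
        data = simulate_trial(design55, params, rng)
        if unexposed_shift:
            # give the unexposed cluster its own deviating period profile
            df = data.records
            for j in range(2, 6):
                rows = (df["cluster"] == 5) & (df["period"] == j)
                p = expit(logit(0.3) + 0.1 * (j - 1) + unexposed_shift * (j - 1))
                df.loc[rows, "y"] = replicate_rng(seed, 1, j).binomial(1, p, rows.sum())
        return data

    def test_homogeneous_data_favors_base_model_by_bic(self, design55):
        favored = [
            period_homogeneity_check(self._simulate(design55, s), design55).bic_favors
            for s in range(12)
        ]
        assert favored.count("base") >= 10

    def test_deviating_profile_favors_interaction_model_by_aic(self, design55):
        favored = [
            period_homogeneity_check(
                self._simulate(design55, 100 + s, unexposed_shift=0.8, size=200),
                design55,
            ).aic_favors
            for s in range(12)
        ]
        assert favored.count("interaction") >= 7

    def test_no_estimable_interactions_gives_identical_criteria(self, design55):
        data = self._simulate(design55, 55)
        df = data.records
        trimmed = df[(df["cluster"] != 5) | (df["period"] == 1)].reset_index(drop=True)
        data1 = TrialData(records=trimmed, family="binary")
        rep = period_homogeneity_check(data1, design55)
        assert rep.n_interaction_terms == 0
        assert rep.aic_base == rep.aic_interaction
        assert rep.bic_base == rep.bic_interaction

    def test_requires_unexposed_cluster(self, wedge45, binary_trial):
        with pytest.raises(ValueError):
            period_homogeneity_check(binary_trial, wedge45)


class TestTrialDataIO:
    def test_csv_round_trip(self, binary_trial, tmp_path):
        path = tmp_path / "trial.csv"
        binary_trial.to_csv(path)
        back = TrialData.from_csv(path, "binary")
        pd.testing.assert_frame_equal(back.records, binary_trial.records)

    def test_treat_mismatch_detected(self, design55, binary_trial):
        df = binary_trial.records.copy()
        df.loc[0, "treat"] = 1 - df.loc[0, "treat"]
        with pytest.raises(ValueError, match="disagree"):
            TrialData(records=df, family="binary").check_against(design55)

    def test_bad_outcomes_rejected(self):
        df = pd.DataFrame({"cluster": [1], "period": [1], "treat": [0], "y": [2]})
        with pytest.raises(ValueError):
            TrialData(records=df, family="binary")
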