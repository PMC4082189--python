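import numpy as np
import pytest
from scipy import stats

from dcmfill.cohort import sample_connectivity
from dcmfill.forward import HemodynamicParams, NodeTimeSeries
from dcmfill.inversion import (InversionSettings, ParameterVector,
                               _jacobian, default_priors, invert_dcm,
                               log_evidence, parameter_names,
                               predict_response, true_parameter_vector,
                               variational_laplace)

from .conftest import box_stimulus

SETT = InversionSettings(max_iter=16, tol=1e-3)


class TestParameterVector:
    def test_roundtrip_bijection(self, true_model):
        names = parameter_names(true_model)
        rng = np.random.default_rng(0)
        values = rng.normal(size=len(names))
        pv = ParameterVector(names, values)
        rebuilt = ParameterVector(tuple(pv.to_dict()),
                                  np.array(list(pv.to_dict().values())))
        assert rebuilt.names == pv.names
        np.testing.assert_array_equal(rebuilt.values, pv.values)

    def test_lookup(self, true_model):
        pv = ParameterVector(parameter_names(true_model),
                             np.arange(len(parameter_names(true_model))))
        assert pv.get(pv.names[3]) == 3.0
        with pytest.raises(KeyError):
            pv.get("no-such-parameter")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ParameterVector(("a", "b"), np.zeros(3))


class TestDefaultPriors:
    def test_absent_edge_fixed_at_zero(self, family):
        model = family[0]   # only the base V->M edge
        pr = default_priors(model)
        i = pr.mean.index("A:A->P")
        assert pr.cov[i, i] == 0.0
        j = pr.mean.index("A:V->M")
        assert pr.cov[j, j] > 0.0

    def test_h_prior_means_are_documented_constants(self, true_model):
        # log-multiplier priors centred at 0 <=> constants at prior means
        pr = default_priors(true_model)
        h = HemodynamicParams.prior_means()
        assert (h.tau, h.alpha_grubb, h.E0) == (0.98, 0.32, 0.34)
        for name in pr.mean.names:
            if name.startswith("h:"):
                assert pr.mean.get(name) == 0.0

    def test_all_zero_mean(self, true_model):
        pr = default_priors(true_model)
        np.testing.assert_array_equal(pr.mean.values, 0.0)

    def test_free_mask(self, true_model):
        pr = default_priors(true_model)
        # 4 edges + 1 modulation + 2 inputs + 4 h components x 4 nodes
        assert int(pr.free.sum()) == 4 + 1 + 2 + 16


class TestPredictResponse:
    def test_true_theta_reproduces_fine_simulation(self, true_model,
                                                   small_cohort):
        k = 0
        series = small_cohort.subjects[k]
        theta = true_parameter_vector(true_model,
                                      small_cohort.true_connectivity[k],
                                      small_cohort.true_hemo[k])
        factor = int(round(0.06 / series.dt))
        n_blocks = series.inputs.shape[0] // factor
        stim = series.inputs[:n_blocks * factor].reshape(
            n_blocks, factor, -1).mean(axis=1)
        pred = predict_response(theta, true_model, stim, series.tr,
                                series.n_samples, dt=0.06)
        # matches the dt=5 ms noisy observation up to thermal noise and
        # input-jitter integration differences
        rms = np.sqrt(np.mean((pred - series.bold) ** 2))
        assert rms < 0.05 * np.ptp(series.bold)

    def test_zero_c_flat(self, true_model):
        pr = default_priors(true_model)
        stim = box_stimulus(1000, 0.12)
        pred = predict_response(pr.mean, true_model, stim, 3.0, 40)
        np.testing.assert_allclose(pred, 0.0, atol=1e-12)

    def test_fd_jacobian_matches_central_oracle(self, true_model):
        pr = default_priors(true_model)
        theta = pr.mean.values.copy()
        free = pr.free
        theta[pr.mean.index("A:V->P")] = 0.4
        theta[pr.mean.index("C:u1->V")] = 1.0
        theta[pr.mean.index("C:u2->A")] = 1.0
        stim = box_stimulus(500, 0.12)

        def response(free_vals):
            full = theta.copy()
            full[free] = free_vals
            return predict_response(ParameterVector(pr.mean.names, full),
                                    true_model, stim, 3.0, 20)

        x0 = theta[free]
        g0 = response(x0)
        J = _jacobian(response, x0, g0, 1e-5)
        k = list(np.flatnonzero(free)).index(pr.mean.index("A:V->P"))
        h = 1e-4
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        central = (response(xp) - response(xm)) / (2 * h)
        scale = np.max(np.abs(central))
        assert np.max(np.abs(J[:, :, k] - central)) < 1e-4 * scale


class TestVariationalLaplaceLinearLimit:
    def rig(self, seed=0, T=60, N=3, lam=4.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(T, N))
        m0 = rng.normal(size=N) * 0.3
        S0 = np.diag(rng.uniform(0.5, 2.0, N))
        theta = rng.normal(size=N)
        y = (X @ theta + rng.normal(0, 1 / np.sqrt(lam), T)).reshape(-1, 1)
        return X, m0, S0, y, lam

    def closed_form_log_evidence(self, X, m0, S0, y, lam):
        Cy = np.eye(len(y)) / lam + X @ S0 @ X.T
        return stats.multivariate_normal.logpdf(y.ravel(), X @ m0, Cy)

    def test_matches_bayesian_linear_regression(self):
        X, m0, S0, y, lam = self.rig()
        res = variational_laplace(lambda t: (X @ t).reshape(-1, 1), y, m0,
                                  S0, noise_precision=lam)
        expected = self.closed_form_log_evidence(X, m0, S0, y, lam)
        assert res["free_energy"] == pytest.approx(expected, abs=1e-3)

    def test_posterior_matches_conjugate_solution(self):
        X, m0, S0, y, lam = self.rig(seed=1)
        res = variational_laplace(lambda t: (X @ t).reshape(-1, 1), y, m0,
                                  S0, noise_precision=lam)
        P = np.linalg.inv(S0) + lam * X.T @ X
        mean = np.linalg.solve(P, np.linalg.inv(S0) @ m0
                               + lam * X.T @ y.ravel())
        np.testing.assert_allclose(res["mean"], mean, atol=1e-6)
        np.testing.assert_allclose(res["cov"], np.linalg.inv(P), atol=1e-8)

    def test_invariant_to_parameter_ordering(self):
        X, m0, S0, y, lam = self.rig(seed=2)
        perm = np.array([2, 0, 1])
        a = variational_laplace(lambda t: (X @ t).reshape(-1, 1), y, m0, S0,
                                noise_precision=lam)
        b = variational_laplace(
            lambda t: (X[:, perm] @ t).reshape(-1, 1), y, m0[perm],
            S0[np.ix_(perm, perm)], noise_precision=lam)
        assert a["free_energy"] == pytest.approx(b["free_energy"], abs=1e-8)


class TestInvertDCM:
    def test_prior_mean_data_keeps_posterior_at_prior(self, true_model):
        # flat response + negligible noise carries no information
        rng = np.random.default_rng(0)
        dt = 0.005
        stim = box_stimulus(int(120 / dt), dt)
        bold = rng.normal(0.0, 1e-6, size=(40, 4))
        data = NodeTimeSeries(bold, tr=3.0, inputs=stim * 0.0, dt=dt)
        post = invert_dcm(data, true_model, settings=SETT)
        assert np.max(np.abs(post.mean.values)) < 0.05

    def test_parameter_recovery_and_diagnostics(self, true_model,
                                                small_cohort):
        hits = total = 0
        for k in range(small_cohort.n_subjects):
            post = invert_dcm(small_cohort.subjects[k], true_model,
                              settings=SETT)
            tv = true_parameter_vector(true_model,
                                       small_cohort.true_connectivity[k],
                                       small_cohort.true_hemo[k])
            # free energy nondecreasing over accepted iterations
            gains = np.diff(post.f_trace)
            assert np.all(gains >= -1e-6 * np.abs(post.f_trace[:-1]))
            # posterior covariance positive definite on the free block
            np.linalg.cholesky(post.cov[np.ix_(post.free, post.free)])
            for name in post.mean.names:
                i = post.mean.index(name)
                if name.startswith("A:") and post.free[i]:
                    total += 1
                    hits += (abs(post.mean.values[i] - tv.values[i])
                             <= 2 * post.sd(name))
        assert total == 4 * small_cohort.n_subjects
        assert hits / total >= 0.8

    def test_nonconvergence_flagged_not_raised(self, true_model,
                                               small_cohort):
        post = invert_dcm(small_cohort.subjects[0], true_model,
                          settings=InversionSettings(max_iter=1))
        assert not post.converged
        assert np.isfinite(post.free_energy)


class TestLogEvidence:
    def test_true_model_beats_submodel_missing_strong_edge(self, family,
                                                           small_cohort,
                                                           true_model):
        # model 4 lacks the true P->M edge
        sub = family[3]
        wins = 0
        for k in range(3):
            f_true = invert_dcm(small_cohort.subjects[k], true_model,
                                settings=SETT).free_energy
            f_sub = invert_dcm(small_cohort.subjects[k], sub,
                               settings=SETT).free_energy
            wins += f_true > f_sub
        assert wins >= 2

    def test_superset_penalized_on_nested_data(self, family, small_cohort,
                                               true_model):
        # model 16 = true model + spurious A->M edge
        superset = family[15]
        wins = 0
        for k in range(3):
            f_true = invert_dcm(small_cohort.subjects[k], true_model,
                                settings=SETT).free_energy
            f_sup = invert_dcm(small_cohort.subjects[k], superset,
                               settings=SETT).free_energy
            wins += f_true >= f_sup
        assert wins >= 2

    def test_self_relative_evidence_zero(self, true_model, small_cohort):
        post = invert_dcm(small_cohort.subjects[0], true_model,
                          settings=InversionSettings(max_iter=4))
        assert log_evidence(post) - log_evidence(post) == 0.0

    def test_alternative_estimators(self, true_model, small_cohort):
        post = invert_dcm(small_cohort.subjects[0], true_model,
                          settings=InversionSettings(max_iter=4))
        f = log_evidence(post)
        bic = log_evidence(post, "bic")
        aic = log_evidence(post, "aic")
        assert np.isfinite([f, bic, aic]).all()
        assert bic < aic   # BIC penalty exceeds AIC at n_obs = 800
        with pytest.raises(ValueError):
            log_evidence(post, "dic")
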