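import numpy as np
import pytest

from omixstat.kernels import Kernel, covariance_structure
from omixstat.synthetic import SimTruth, simulate_multiomics
from omixstat.varcomp import (
    VarianceModel,
    core_reml_fit,
    greml_power,
    lrt,
    reml_fit,
    variance_proportions,
)

from conftest import random_psd_kernel


def logl_oracle(y, X, mats, theta):
    """Independent dense evaluation of the restricted log-likelihood."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, A in zip(theta[:-1], mats):
        V = V + t * A
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * (ldV + ldX + y @ P @ y)


def toy_problem(n=30, seed=0, h2=0.5):
    rng = np.random.default_rng(seed)
    K = random_psd_kernel(n, rank=max(4, n // 2), seed=seed + 100)
    K.values[np.diag_indices(n)] += 0.05  # keep V well-conditioned
    from omixstat.kernels import trace_normalize

    K = trace_normalize(K)
    S = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
    y = np.sqrt(h2) * (S @ rng.standard_normal(n)) + np.sqrt(1 - h2) * rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    return y, X, K


class TestRemlFit:
    def test_residual_only_closed_form(self, rng):
        y = rng.standard_normal(60)
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        fit = reml_fit(y, X, VarianceModel(terms=[]))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        s2 = (r @ r) / (60 - 2)
        assert fit.theta["residual"] == pytest.approx(s2, rel=1e-12)
        assert fit.logL == pytest.approx(logl_oracle(y, X, [], np.array([s2])), abs=1e-8)

    def test_logl_matches_dense_oracle(self):
        y, X, K = toy_problem(n=12, seed=3)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]), tol=1e-12)
        theta = np.array([fit.theta["G"], fit.theta["residual"]])
        assert fit.logL == pytest.approx(logl_oracle(y, X, [K.values], theta), abs=1e-8)

    def test_random_search_oracle(self):
        y, X, K = toy_problem(n=30, seed=5)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]))
        theta_hat = np.array([fit.theta["G"], fit.theta["residual"]])
        best = logl_oracle(y, X, [K.values], theta_hat)
        rng = np.random.default_rng(17)
        for _ in range(200):
            cand = rng.uniform(0.01, 3.0, size=2)
            assert logl_oracle(y, X, [K.values], cand) <= best + 1e-6

    def test_em_ai_shared_fixed_point(self):
        y, X, K = toy_problem(n=40, seed=7)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]), tol=1e-12)
        theta = np.array([fit.theta["G"], fit.theta["residual"]])
        # EM move = 2 theta^2 * dlogL/dtheta / n, with the gradient taken by
        # central finite differences of the independent oracle
        n = len(y)
        for j in range(2):
            h = 1e-6 * theta[j]
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            grad = (logl_oracle(y, X, [K.values], up) - logl_oracle(y, X, [K.values], dn)) / (2 * h)
            em_move = 2 * theta[j] ** 2 * grad / n
            assert abs(em_move) <= 1e-6 * max(theta[j], 1e-3)

    def test_permutation_equivariance(self):
        y, X, K1 = toy_problem(n=60, seed=9)
        K2 = random_psd_kernel(60, rank=20, seed=1)
        model = VarianceModel(terms=[("A", K1), ("B", K2)])
        fit = reml_fit(y, X, model)
        rng = np.random.default_rng(4)
        perm = rng.permutation(60)
        ids = [K1.sample_ids[i] for i in perm]
        K1p = K1.subset(ids)
        K2p = K2.subset(ids)
        fit_p = reml_fit(y[perm], X[perm], VarianceModel(terms=[("A", K1p), ("B", K2p)]))
        assert fit_p.logL == pytest.approx(fit.logL, abs=1e-10)
        for nm in ("A", "B", "residual"):
            assert fit_p.theta[nm] == pytest.approx(fit.theta[nm], abs=1e-8)

    def test_recovery_smoke(self):
        truth = SimTruth({"G": 0.5, "residual": 0.5}, seed=42)
        res = simulate_multiomics(500, {"G": 400}, truth)
        fit = reml_fit(res.liability, None, VarianceModel(terms=[("G", res.kernels["G"])]))
        assert fit.converged
        assert fit.proportions["G"][0] == pytest.approx(0.5, abs=0.2)

    def test_constant_phenotype_rejected(self):
        K = random_psd_kernel(20, seed=2)
        with pytest.raises(ValueError, match="constant"):
            reml_fit(np.ones(20), None, VarianceModel(terms=[("G", K)]))

    def test_too_few_samples_rejected(self):
        K = random_psd_kernel(3, seed=2)
        with pytest.raises(ValueError, match="too small"):
            reml_fit(np.array([0.0, 1.0, 2.0]), None, VarianceModel(terms=[("G", K)]))

    def test_non_convergence_warns_not_silent(self):
        y, X, K = toy_problem(n=50, seed=13)
        with pytest.warns(UserWarning, match="did not converge"):
            fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]), max_iter=1)
        assert fit.converged is False

    def test_spectral_and_dense_engines_agree(self):
        y, X, K = toy_problem(n=40, seed=21)
        model = VarianceModel(terms=[("G", K)])
        fit_s = reml_fit(y, X, model, tol=1e-10, engine="spectral")
        fit_d = reml_fit(y, X, model, tol=1e-10, engine="dense")
        assert fit_d.theta["G"] == pytest.approx(fit_s.theta["G"], rel=1e-6)
        assert fit_d.logL == pytest.approx(fit_s.logL, abs=1e-8)
        assert fit_d.se["G"] == pytest.approx(fit_s.se["G"], rel=1e-4)


class TestCoreReml:
    def test_requires_cov_pairs(self):
        K = random_psd_kernel(20, seed=1)
        with pytest.raises(ValueError, match="cov_pairs"):
            core_reml_fit(np.random.default_rng(0).standard_normal(20), None,
                          VarianceModel(terms=[("G", K)]))

    def test_aliased_kernels_flagged(self):
        rng = np.random.default_rng(3)
        K = random_psd_kernel(60, rank=30, seed=3)
        from omixstat.kernels import trace_normalize

        K = trace_normalize(K)
        y = rng.standard_normal(60)
        C = covariance_structure(K, K)
        model = VarianceModel(
            terms=[("A", K), ("B", Kernel(values=K.values.copy(), sample_ids=K.sample_ids))],
            cov_pairs=[("rA.B", "A", "B", C)],
        )
        with pytest.warns(UserWarning):
            fit = core_reml_fit(y, None, model)
        assert (not fit.converged) or any(np.isnan(s) for s in fit.se.values())

    def test_cov_estimate_bounded(self):
        truth = SimTruth({"G": 0.3, "E": 0.3, "residual": 0.4}, {"rG.E": 0.25}, seed=6)
        res = simulate_multiomics(400, {"G": 300, "E": 150}, truth)
        C = covariance_structure(res.kernels["G"], res.kernels["E"])
        model = VarianceModel(
            terms=[("G", res.kernels["G"]), ("E", res.kernels["E"])],
            cov_pairs=[("rG.E", "G", "E", C)],
        )
        fit = core_reml_fit(res.liability, None, model)
        bound = np.sqrt(fit.theta["G"] * fit.theta["E"])
        assert abs(fit.theta["rG.E"]) <= bound + 1e-12
        r, _se = fit.correlations["rG.E"]
        assert abs(r) <= 1.0 + 1e-9


class TestWald:
    def test_one_sided_variance_pvalue(self):
        y, X, K = toy_problem(n=50, seed=41)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]))
        from scipy import stats as ss

        p = fit.wald_pvalues()
        z = fit.theta["G"] / fit.se["G"]
        assert p["G"] == pytest.approx(float(ss.norm.sf(z)), rel=1e-12)
        assert 0.0 <= p["residual"] <= 1.0


class TestLrt:
    class _F:
        def __init__(self, logL):
            self.logL = logL

    def test_zero_statistic(self):
        assert lrt(self._F(-10.0), self._F(-10.0)) == 1.0
        assert lrt(self._F(-10.0), self._F(-10.0), boundary=True) == 1.0

    def test_chi2_quantile(self):
        p = lrt(self._F(0.0), self._F(-1.92), df=1)
        assert p == pytest.approx(0.05004352, abs=1e-6)

    def test_boundary_mixture(self):
        p = lrt(self._F(0.0), self._F(-1.355), boundary=True)
        assert p == pytest.approx(0.04986050, abs=1e-6)

    def test_logl_inversion_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(self._F(-12.0), self._F(-10.0))


class TestVarianceProportions:
    def test_equal_split(self):
        y, X, K = toy_problem(n=50, seed=31)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]))
        props = variance_proportions(fit)
        total = sum(h for h, _ in props.values())
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_delta_se_matches_finite_differences(self):
        y, X, K = toy_problem(n=60, seed=33)
        fit = reml_fit(y, X, VarianceModel(terms=[("G", K)]), tol=1e-12)
        names = fit.param_names
        theta = np.array([fit.theta[nm] for nm in names])
        total = theta.sum()
        C = fit.param_cov
        for i, nm in enumerate(names):
            grad = np.empty(len(names))
            for j in range(len(names)):
                h = 1e-7 * max(theta[j], 1e-4)
                up, dn = theta.copy(), theta.copy()
                up[j] += h
                dn[j] -= h
                grad[j] = (up[i] / up.sum() - dn[i] / dn.sum()) / (2 * h)
            se_num = np.sqrt(grad @ C @ grad)
            assert fit.proportions[nm][1] == pytest.approx(se_num, abs=1e-6)


class TestGremlPower:
    def test_closed_form(self):
        res = greml_power(n=10000, h2=0.025, var_offdiag=2e-5)
        assert res.se_h2 == pytest.approx(0.0316227766, rel=1e-9)

    def test_null_limit_power_alpha(self):
        res = greml_power(n=10000, h2=1e-9, var_offdiag=2e-5, alpha=0.05)
        assert res.power == pytest.approx(0.05, abs=1e-6)
        assert res.ncp == pytest.approx(0.0, abs=1e-12)

    def test_doubling_n_halves_se(self):
        a = greml_power(n=5000, h2=0.1)
        b = greml_power(n=10000, h2=0.1)
        assert a.se_h2 == pytest.approx(2 * b.se_h2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            greml_power(n=1, h2=0.5)
        with pytest.raises(ValueError):
            greml_power(n=100, h2=1.5)
        with pytest.raises(ValueError):
            greml_power(n=100, h2=0.5, var_offdiag=0.0)
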