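import numpy as np
import pytest

from omixstat.kernels import trace_normalize
from omixstat.mediation import (
    blup_risk_score,
    cv_risk_scores,
    mediate_linear,
    summarize_cv_mediation,
)
from omixstat.synthetic import SimTruth, simulate_multiomics
from omixstat.varcomp import VarianceModel, reml_fit

from conftest import random_psd_kernel


def _train_test_fit(n=400, m=200, h2=0.5, seed=0, n_test=None):
    n_test = n_test or n // 5
    truth = SimTruth({"G": h2, "residual": 1 - h2}, seed=seed)
    res = simulate_multiomics(n, {"G": m}, truth)
    ids = res.sample_ids
    train_ids, test_ids = ids[n_test:], ids[:n_test]
    kern = res.kernels["G"]
    sub = kern.subset(train_ids)
    idx = {s: i for i, s in enumerate(ids)}
    tr = [idx[s] for s in train_ids]
    fit = reml_fit(res.liability[tr], None, VarianceModel(terms=[("G", sub)]))
    K_cross = kern.cross_block(test_ids, train_ids)
    return res, fit, K_cross, train_ids, test_ids, tr


class TestBlup:
    def test_zero_variance_gives_zero_scores(self):
        res, fit, K_cross, train_ids, test_ids, tr = _train_test_fit(seed=1)
        fit.theta["G"] = 0.0
        scores = blup_risk_score(fit, K_cross, test_ids, "G")
        assert np.allclose(scores, 0.0)

    def test_leakage_rejected(self):
        res, fit, K_cross, train_ids, test_ids, tr = _train_test_fit(seed=2)
        with pytest.raises(ValueError, match="test samples present"):
            blup_risk_score(fit, K_cross, train_ids[:5], "G")

    def test_unknown_term_rejected(self):
        res, fit, K_cross, train_ids, test_ids, tr = _train_test_fit(seed=3)
        with pytest.raises(KeyError):
            blup_risk_score(fit, K_cross, test_ids, "nope")

    def test_accuracy_matches_theory(self):
        # realized correlation(score, true effect) vs the closed-form BLUP
        # accuracy sqrt(sigma_g^2 tr(K_ct P K_tc) / tr K_test) at the true
        # variance components
        emp, theo = [], []
        for seed in range(12):
            res, fit, K_cross, train_ids, test_ids, tr = _train_test_fit(
                n=1000, m=400, seed=seed, n_test=200
            )
            g_true = res.effects["G"]
            idx = {s: i for i, s in enumerate(res.sample_ids)}
            te = [idx[s] for s in test_ids]
            scores = blup_risk_score(fit, K_cross, test_ids, "G")
            emp.append(np.corrcoef(scores, g_true[te])[0, 1])
            # theory at the true components
            K = res.kernels["G"]
            Ktt = K.subset(train_ids).values
            nt = len(train_ids)
            V = 0.5 * Ktt + 0.5 * np.eye(nt)
            Vinv = np.linalg.inv(V)
            X = np.ones((nt, 1))
            P = Vinv - Vinv @ X @ np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv
            Q = K_cross @ P @ K_cross.T
            trK_test = np.trace(K.subset(test_ids).values)
            theo.append(np.sqrt(0.5 * np.trace(Q) / trK_test))
        mc_se = np.std(emp) / np.sqrt(len(emp))
        assert np.mean(emp) > 0
        assert abs(np.mean(emp) - np.mean(theo)) <= 2 * mc_se + 0.02


class TestCvRiskScores:
    def _setup(self, n=100, seed=0):
        truth = SimTruth({"G": 0.5, "residual": 0.5}, seed=seed)
        res = simulate_multiomics(n, {"G": 60}, truth)
        return res

    def test_fold_sizes_exact_division(self):
        res = self._setup(100)
        rs = cv_risk_scores(res.liability, None, {"G": res.kernels["G"]},
                            status=res.status, k=5, seed=1)
        sizes = np.bincount(rs.fold)
        assert sizes.tolist() == [20, 20, 20, 20, 20]

    def test_partition_property(self):
        res = self._setup(110, seed=3)
        rs = cv_risk_scores(res.liability, None, {"G": res.kernels["G"]},
                            status=res.status, k=5, seed=2)
        assert rs.fold.size == 110
        assert not rs.scores["G"].isna().any()

    def test_seed_determinism(self):
        res = self._setup(100, seed=4)
        a = cv_risk_scores(res.liability, None, {"G": res.kernels["G"]},
                           status=res.status, k=5, seed=7)
        b = cv_risk_scores(res.liability, None, {"G": res.kernels["G"]},
                           status=res.status, k=5, seed=7)
        assert np.array_equal(a.fold, b.fold)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())

    def test_k_too_small_rejected(self):
        res = self._setup(100, seed=5)
        with pytest.raises(ValueError, match="k must be"):
            cv_risk_scores(res.liability, None, {"G": res.kernels["G"]}, k=1)

    def test_n_too_small_rejected(self):
        res = self._setup(40, seed=6)
        with pytest.raises(ValueError, match="n >= 10"):
            cv_risk_scores(res.liability, None, {"G": res.kernels["G"]}, k=5)


def simulate_mediation(n, a=0.5, b=0.4, c_prime=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + rng.standard_normal(n)
    y = c_prime * x + b * m + rng.standard_normal(n)
    return x, m, y


class TestMediateLinear:
    def test_null_mediator(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        m = rng.standard_normal(2000)  # independent of x and y|x
        y = 0.5 * x + rng.standard_normal(2000)
        fit = mediate_linear(x, m, y, n_boot=200, seed=3)
        lo, hi = fit.ci["acme"]
        assert lo <= 0.0 <= hi
        assert abs(fit.acme) < 0.05

    def test_product_of_coefficients_recovery(self):
        acmes, props = [], []
        for seed in range(10):
            x, m, y = simulate_mediation(4000, seed=seed)
            fit = mediate_linear(x, m, y, n_boot=50, seed=seed)
            acmes.append(fit.acme)
            props.append(fit.prop_mediated)
        assert abs(np.mean(acmes) - 0.2) <= 2 * np.std(acmes) / np.sqrt(10) + 1e-3
        assert abs(np.mean(props) - 0.4) <= 2 * np.std(props) / np.sqrt(10) + 2e-3

    def test_total_equals_de_plus_acme(self):
        x, m, y = simulate_mediation(500, seed=5)
        fit = mediate_linear(x, m, y, n_boot=10, seed=1)
        assert fit.total == pytest.approx(fit.de + fit.acme, abs=1e-10)

    def test_difference_of_coefficients_identity(self):
        # acme == (coefficient of x in y ~ x) - c_prime, exactly, in OLS
        x, m, y = simulate_mediation(300, seed=9)
        fit = mediate_linear(x, m, y, n_boot=10, seed=1)
        xc = x - x.mean()
        marginal = float((xc @ (y - y.mean())) / (xc @ xc))
        assert fit.acme == pytest.approx(marginal - fit.c_prime, abs=1e-10)

    def test_zero_variance_rejected(self):
        x = np.ones(50)
        m = np.arange(50.0)
        with pytest.raises(ValueError, match="zero-variance"):
            mediate_linear(x, m, m, n_boot=10)

    def test_min_sample_size(self):
        with pytest.raises(ValueError, match="n >= 30"):
            mediate_linear(np.arange(10.0), np.arange(10.0), np.arange(10.0))

    def test_bootstrap_determinism(self):
        x, m, y = simulate_mediation(200, seed=2)
        f1 = mediate_linear(x, m, y, n_boot=100, seed=11)
        f2 = mediate_linear(x, m, y, n_boot=100, seed=11)
        assert f1.ci == f2.ci

    def test_ci_brackets_point_estimate(self):
        x, m, y = simulate_mediation(1000, seed=4)
        fit = mediate_linear(x, m, y, n_boot=500, seed=5)
        for key, val in (("acme", fit.acme), ("total", fit.total)):
            lo, hi = fit.ci[key]
            assert lo <= val <= hi


class TestSummarize:
    def _fit(self, prop):
        from omixstat.mediation import MediationFit

        return MediationFit(
            a=1, b=1, c_prime=1, acme=prop, de=1 - prop, total=1.0,
            prop_mediated=prop, ci={"prop_mediated": (prop - 0.1, prop + 0.1)},
        )

    def test_identical_fits_collapse_range(self):
        out = summarize_cv_mediation([self._fit(0.5)] * 3)
        assert out["range_prop_mediated"] == (0.5, 0.5)

    def test_reported_fold_arithmetic(self):
        # mean of (0.46, 0.60, 0.83, 0.55, 0.56) is 0.60, range [0.46, 0.83]
        fits = [self._fit(p) for p in (0.46, 0.60, 0.83, 0.55, 0.56)]
        out = summarize_cv_mediation(fits)
        assert out["mean_prop_mediated"] == pytest.approx(0.60, abs=1e-12)
        assert out["range_prop_mediated"] == (0.46, 0.83)

    def test_permutation_invariant_mean(self):
        fits = [self._fit(p) for p in (0.2, 0.5, 0.8)]
        a = summarize_cv_mediation(fits)
        b = summarize_cv_mediation(fits[::-1])
        assert a["mean_prop_mediated"] == b["mean_prop_mediated"]

    def test_requires_two_fits(self):
        with pytest.raises(ValueError):
            summarize_cv_mediation([self._fit(0.5)])
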