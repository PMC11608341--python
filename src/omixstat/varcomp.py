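"""Variance-component estimation by AI-REML, with optional covariance
components between random effects, likelihood-ratio tests, delta-method
variance proportions, and the GREML power calculator.

The covariance model is V(theta) = sum_i sigma2_i K_i + sum_p sigma12_p C_p
+ sigma2_e I, where K_i are additive/interaction kernels and C_p are
covariance-structure matrices built from kernel square roots.  The restricted
log-likelihood (up to a constant) is

    logL = -1/2 ( log|V| + log|X' V^-1 X| + y' P y ),
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Optimization runs EM warm-up steps followed by average-information Newton
steps with step halving; variances are clamped at a small floor and
covariances are projected so every implied 2x2 component matrix stays PSD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import lapack

from .kernels import Kernel

__all__ = [
    "VarianceModel",
    "RemlFit",
    "PowerResult",
    "reml_fit",
    "core_reml_fit",
    "lrt",
    "variance_proportions",
    "greml_power",
]

RESIDUAL = "residual"


@dataclass
class VarianceModel:
    """Which kernels enter the model, and which pairs get a covariance.

    ``terms`` is an ordered list of (name, Kernel) for additive and
    interaction components; ``cov_pairs`` entries are
    (name, term_a, term_b, covariance-structure Kernel).
    """

    terms: list[tuple[str, Kernel]]
    cov_pairs: list[tuple[str, str, str, Kernel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.terms] + [n for n, *_ in self.cov_pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in VarianceModel")
        if RESIDUAL in names:
            raise ValueError("'residual' is implicit and cannot be a term name")
        if not self.terms:
            pass  # residual-only model is legal
        ids = None
        for name, k in self.terms + [(n, k) for n, _a, _b, k in self.cov_pairs]:
            if ids is None:
                ids = k.sample_ids
            elif k.sample_ids != ids:
                raise ValueError(f"kernel {name!r} has mismatched sample ids")
        term_names = {n for n, _ in self.terms}
        for name, a, b, _k in self.cov_pairs:
            if a not in term_names or b not in term_names:
                raise ValueError(
                    f"cov_pair {name!r} references undeclared terms ({a}, {b})"
                )

    @property
    def sample_ids(self) -> list[str] | None:
        return self.terms[0][1].sample_ids if self.terms else None

    def param_names(self) -> list[str]:
        return [n for n, _ in self.terms] + [n for n, *_ in self.cov_pairs] + [RESIDUAL]


@dataclass
class RemlFit:
    """Converged (or flagged) REML solution."""

    param_names: list[str]
    theta: dict[str, float]
    se: dict[str, float]
    logL: float
    n_iter: int
    converged: bool
    constrained: dict[str, bool]
    proportions: dict[str, tuple[float, float]]
    correlations: dict[str, tuple[float, float]]
    n_samples: int
    #: inverse average-information matrix (parameter covariance estimate)
    param_cov: np.ndarray | None = None
    #: P y at the optimum == V^-1 (y - X beta_gls); used for BLUP scoring
    py: np.ndarray | None = None
    sample_ids: list[str] | None = None
    model: VarianceModel | None = None

    @property
    def vp(self) -> float:
        """Total phenotypic variance: sum of variance params incl. residual."""
        cov_names = {n for n, *_ in self.model.cov_pairs} if self.model else set()
        return sum(v for k, v in self.theta.items() if k not in cov_names)

    def wald_pvalues(self) -> dict[str, float]:
        """Wald p-values from est/SE against the standard normal: one-sided
        for variance parameters (H1: sigma2 > 0), two-sided for covariances."""
        cov_names = {n for n, *_ in self.model.cov_pairs} if self.model else set()
        out: dict[str, float] = {}
        for name in self.param_names:
            se = self.se.get(name, float("nan"))
            if not (se and np.isfinite(se) and se > 0):
                out[name] = float("nan")
                continue
            z = self.theta[name] / se
            if name in cov_names:
                out[name] = float(2.0 * stats.norm.sf(abs(z)))
            else:
                out[name] = float(stats.norm.sf(z))
        return out


@dataclass
class PowerResult:
    se_h2: float
    ncp: float
    power: float


# ---------------------------------------------------------------------------
# linear algebra backends


def _sym_inv_logdet(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of an SPD matrix via Cholesky + dpotri."""
    L = np.linalg.cholesky(V)  # raises LinAlgError if V is not SPD
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vinv, info = lapack.dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - dpotri failure after good potrf
        raise np.linalg.LinAlgError(f"dpotri failed with info={info}")
    Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
    return Vinv, logdet


class _DenseREML:
    """Generic dense evaluation of logL, scores and the AI matrix."""

    def __init__(self, y: np.ndarray, X: np.ndarray, mats: list[np.ndarray]):
        self.y = y
        self.X = X
        self.mats = mats  # last entry is I (residual)
        self.n, self.p = X.shape

    def evaluate(self, theta: np.ndarray, need_derivs: bool = True):
        n = self.n
        V = np.zeros((n, n))
        for t, A in zip(theta, self.mats[:-1]):
            if t != 0.0:
                V += t * A
        V[np.diag_indices_from(V)] += theta[-1]
        Vinv, logdetV = _sym_inv_logdet(V)
        VinvX = Vinv @ self.X
        XtViX = self.X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' V^-1 X is singular")
        P = Vinv - VinvX @ np.linalg.solve(XtViX, VinvX.T)
        Py = P @ self.y
        yPy = float(self.y @ Py)
        logL = -0.5 * (logdetV + logdetX + yPy)
        if not need_derivs:
            return logL, None, None, Py
        k = len(self.mats)
        score = np.empty(k)
        w = np.empty((k, n))
        for j, A in enumerate(self.mats):
            APy = A @ Py if A is not None else Py
            w[j] = APy
            trPA = float(np.sum(P * A)) if A is not None else float(np.trace(P))
            score[j] = -0.5 * (trPA - float(Py @ APy))
        Pw = P @ w.T  # n x k
        AI = 0.5 * (w @ Pw)
        return logL, score, AI, Py

    def trace_terms(self, theta: np.ndarray) -> np.ndarray:
        """tr(P A_j) for EM updates (recomputed with full P)."""
        raise NotImplementedError


class _SpectralREML:
    """Fast path for a single-kernel + residual model with the kernel
    eigendecomposition available: all quantities are O(n p^2) per step."""

    def __init__(self, y, X, kernel: Kernel):
        d, U = kernel.eigh()
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.y = U.T @ y
        self.X = U.T @ X
        self.n, self.p = X.shape

    def evaluate(self, theta: np.ndarray, need_derivs: bool = True):
        v = theta[0] * self.d + theta[1]
        if (v <= 0).any():
            raise np.linalg.LinAlgError("V is singular in spectral basis")
        vinv = 1.0 / v
        logdetV = float(np.sum(np.log(v)))
        VinvX = self.X * vinv[:, None]
        XtViX = self.X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' V^-1 X is singular")
        XtViX_inv = np.linalg.inv(XtViX)

        def P_dot(u):
            return vinv * u - VinvX @ (XtViX_inv @ (VinvX.T @ u))

        Py = P_dot(self.y)
        yPy = float(self.y @ Py)
        logL = -0.5 * (logdetV + logdetX + yPy)
        # Py is rotated back to the sample basis for external use (BLUP)
        if not need_derivs:
            return logL, None, None, self.U @ Py
        # tr(P A) for diagonal A = diag(a): tr(Vinv A) - tr(B' A B (X'ViX)^-1)
        mats = (self.d, np.ones(self.n))
        score = np.empty(2)
        w = np.empty((2, self.n))
        for j, a in enumerate(mats):
            trPA = float(np.sum(vinv * a)) - float(
                np.sum((VinvX.T * a) @ VinvX * XtViX_inv)
            )
            APy = a * Py
            w[j] = APy
            score[j] = -0.5 * (trPA - float(Py @ APy))
        AI = np.empty((2, 2))
        Pw = np.column_stack([P_dot(w[0]), P_dot(w[1])])
        AI[:, :] = 0.5 * (w @ Pw)
        return logL, score, AI, self.U @ Py


# ---------------------------------------------------------------------------
# optimizer


def _project(theta, n_terms, pair_index, floor):
    """Clamp variances at the floor; project covariances into the PSD box."""
    theta = theta.copy()
    constrained = np.zeros(theta.size, dtype=bool)
    for j in list(range(n_terms)) + [theta.size - 1]:
        if theta[j] < floor:
            theta[j] = floor
            constrained[j] = True
    for j, (ia, ib) in pair_index.items():
        bound = math.sqrt(theta[ia] * theta[ib])
        if abs(theta[j]) > bound:
            theta[j] = math.copysign(bound, theta[j])
            constrained[j] = True
    return theta, constrained


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    model: VarianceModel,
    max_iter: int = 100,
    tol: float = 1e-8,
    em_steps: int = 1,
    var_floor: float | None = None,
    init: np.ndarray | None = None,
    engine: str = "auto",
) -> RemlFit:
    """Fit the variance model by EM-warm-started average-information REML.

    Returns a :class:`RemlFit`; non-convergence is reported via
    ``converged=False`` and a warning, never silently.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; REML undefined")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X and y must have the same number of rows")
    rank_x = np.linalg.matrix_rank(X)
    k_terms = len(model.terms)
    k_pairs = len(model.cov_pairs)
    k = k_terms + k_pairs + 1
    if n < k + rank_x + 1:
        raise ValueError(f"n={n} too small for {k} parameters and rank(X)={rank_x}")
    if model.sample_ids is not None and len(model.sample_ids) != n:
        raise ValueError("kernel dimension does not match phenotype length")

    names = model.param_names()
    term_pos = {name: j for j, (name, _) in enumerate(model.terms)}
    pair_index = {
        k_terms + jp: (term_pos[a], term_pos[b])
        for jp, (_nm, a, b, _k) in enumerate(model.cov_pairs)
    }

    vp = float(np.var(y))
    floor = (1e-6 * vp) if var_floor is None else var_floor

    if k_terms == 0 and k_pairs == 0 and init is None:
        return _fit_residual_only(y, X, rank_x, model)

    if init is None:
        theta = np.zeros(k)
        theta[:k_terms] = vp / (k_terms + 1)
        theta[-1] = vp / (k_terms + 1)
    else:
        theta = np.asarray(init, dtype=float).copy()
        if theta.size != k:
            raise ValueError(f"init must have {k} entries")
    theta, _ = _project(theta, k_terms, pair_index, floor)

    if engine not in ("auto", "dense", "spectral"):
        raise ValueError(f"unknown engine {engine!r}")
    use_spectral = k_terms == 1 and k_pairs == 0 and engine != "dense"
    if engine == "spectral" and not use_spectral:
        raise ValueError("spectral engine requires a single-kernel model")
    if use_spectral:
        engine = _SpectralREML(y, X, model.terms[0][1])
    else:
        mats = [kern.values for _, kern in model.terms]
        # each covariance sigma12 enters V through both cross-blocks:
        # cov(g1,g2) + cov(g2,g1) = sigma12 (S1 S2' + S2 S1') = 2 C
        mats += [2.0 * kern.values for *_, kern in model.cov_pairs]
        mats.append(np.eye(n))
        engine = _DenseREML(y, X, mats)

    logL, score, AI, Py = engine.evaluate(theta)
    constrained_mask = _project(theta, k_terms, pair_index, floor)[1]
    converged = False
    singular_ai = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # active set: constrained parameters whose gradient pushes them
        # further out of bounds are frozen for this step
        active = np.zeros(k, dtype=bool)
        for j in list(range(k_terms)) + [k - 1]:
            if theta[j] <= floor * (1 + 1e-12) and score[j] < 0:
                active[j] = True
        for j, (ia, ib) in pair_index.items():
            bound = math.sqrt(theta[ia] * theta[ib])
            at_bound = abs(theta[j]) >= bound * (1 - 1e-12)
            pushing_out = score[j] * (theta[j] if theta[j] != 0 else score[j]) > 0
            if at_bound and pushing_out:
                active[j] = True
        free = ~active
        delta = np.zeros(k)
        if n_iter <= em_steps:
            # EM update for variance parameters (covariances held fixed:
            # they start at 0 and are refined by the AI steps)
            for j in list(range(k_terms)) + [k - 1]:
                delta[j] = 2.0 * theta[j] ** 2 * score[j] / n
        elif free.any():
            AIf = AI[np.ix_(free, free)]
            try:
                delta[free] = np.linalg.solve(AIf, score[free])
            except np.linalg.LinAlgError:
                delta[free] = np.linalg.lstsq(AIf, score[free], rcond=None)[0]
                singular_ai = True
        def _line_search(direction):
            step = 1.0
            for _ in range(12):
                cand, cons = _project(theta + step * direction, k_terms, pair_index, floor)
                if np.abs(cand - theta).max() == 0.0:
                    return None
                try:
                    out = engine.evaluate(cand)
                except np.linalg.LinAlgError:
                    step /= 2.0
                    continue
                if out[0] > logL + 1e-12 or (out[0] >= logL - 1e-10 and step == 1.0):
                    return cand, cons, out
                step /= 2.0
            return None

        best = _line_search(delta)
        if best is None and n_iter > em_steps:
            # AI direction blocked (typically a covariance pinned at its PSD
            # bound): fall back to steepest ascent, which can slide along the
            # constraint surface
            scale = 0.1 * max(float(np.max(np.abs(theta))), floor)
            grad_dir = score / max(float(np.max(np.abs(score))), 1e-300) * scale
            best = _line_search(grad_dir)
        if best is None:
            # walk along the PSD boundary itself: move one variance of an
            # active pair and keep the covariance pinned at the moving bound
            for jp, (ia, ib) in pair_index.items():
                if not active[jp] or best is not None:
                    continue
                for j, other in ((ia, ib), (ib, ia)):
                    for frac in (0.5, 0.1, 0.02):
                        for sgn in (1.0, -1.0):
                            cand = theta.copy()
                            cand[j] = max(theta[j] * (1.0 + sgn * frac), floor)
                            cand[jp] = math.copysign(
                                math.sqrt(cand[j] * cand[other]), theta[jp]
                            )
                            cand, cons = _project(cand, k_terms, pair_index, floor)
                            try:
                                out = engine.evaluate(cand)
                            except np.linalg.LinAlgError:
                                continue
                            if out[0] > logL + 1e-10:
                                best = (cand, cons, out)
                                break
                        if best is not None:
                            break
                    if best is not None:
                        break
        if best is None:
            # no feasible direction improves logL: this is the (possibly
            # boundary-constrained) optimum up to numerical noise
            converged = True
            break
        new_theta, constrained_mask, (new_logL, score, AI, Py) = best
        dlogL = new_logL - logL
        rel = np.max(
            np.abs(new_theta - theta) / np.maximum(np.abs(theta), max(floor, 1e-12))
        )
        theta, logL = new_theta, new_logL
        if n_iter > em_steps and abs(dlogL) < tol and rel < 1e-6:
            converged = True
            break

    cond = np.linalg.cond(AI)
    if cond > 1e10:
        singular_ai = True
    if singular_ai:
        converged = False
        param_cov = np.full((k, k), np.nan)
        warnings.warn(
            "average-information matrix is singular (unidentifiable model?); "
            "standard errors are undefined",
            stacklevel=2,
        )
    else:
        param_cov = np.linalg.inv(AI)
    if not converged:
        warnings.warn(
            f"REML did not converge after {n_iter} iterations (logL={logL:.6f})",
            stacklevel=2,
        )

    se = np.sqrt(np.clip(np.diag(param_cov), 0.0, np.inf))
    theta_d = dict(zip(names, theta))
    fit = RemlFit(
        param_names=names,
        theta=theta_d,
        se=dict(zip(names, se)),
        logL=float(logL),
        n_iter=n_iter,
        converged=converged,
        constrained=dict(zip(names, constrained_mask)),
        proportions={},
        correlations={},
        n_samples=n,
        param_cov=param_cov,
        py=Py,
        sample_ids=list(model.sample_ids) if model.sample_ids else None,
        model=model,
    )
    fit.proportions = variance_proportions(fit)
    fit.correlations = _correlations(fit)
    return fit


def _fit_residual_only(y: np.ndarray, X: np.ndarray, rank_x: int, model: VarianceModel) -> RemlFit:
    """Closed-form REML for V = sigma2 I: sigma2 = RSS / (n - rank X)."""
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - rank_x
    s2 = rss / dof
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    logL = -0.5 * (dof * math.log(s2) + logdet_xx + dof)
    se = s2 * math.sqrt(2.0 / dof)
    fit = RemlFit(
        param_names=[RESIDUAL],
        theta={RESIDUAL: s2},
        se={RESIDUAL: se},
        logL=float(logL),
        n_iter=1,
        converged=True,
        constrained={RESIDUAL: False},
        proportions={RESIDUAL: (1.0, 0.0)},
        correlations={},
        n_samples=n,
        param_cov=np.array([[se * se]]),
        py=resid / s2,
        sample_ids=None,
        model=model,
    )
    return fit


def core_reml_fit(y, X, model: VarianceModel, **opts) -> RemlFit:
    """REML with explicit covariance components between random effects.

    Identical engine to :func:`reml_fit`; the name documents intent and
    checks that the model actually declares covariance pairs.
    """
    if not model.cov_pairs:
        raise ValueError("core_reml_fit expects a model with cov_pairs")
    return reml_fit(y, X, model, **opts)


def _correlations(fit: RemlFit) -> dict[str, tuple[float, float]]:
    """r = sigma12 / sqrt(sigma2_a sigma2_b) with delta-method SEs."""
    out: dict[str, tuple[float, float]] = {}
    if fit.model is None or not fit.model.cov_pairs:
        return out
    names = fit.param_names
    pos = {nm: j for j, nm in enumerate(names)}
    theta = np.array([fit.theta[nm] for nm in names])
    for nm, a, b, _k in fit.model.cov_pairs:
        ja, jb, jp = pos[a], pos[b], pos[nm]
        va, vb, s12 = theta[ja], theta[jb], theta[jp]
        if va <= 0 or vb <= 0:
            out[nm] = (float("nan"), float("nan"))
            continue
        denom = math.sqrt(va * vb)
        r = s12 / denom
        grad = np.zeros(len(names))
        grad[jp] = 1.0 / denom
        grad[ja] = -0.5 * s12 / (denom * va)
        grad[jb] = -0.5 * s12 / (denom * vb)
        if fit.param_cov is None or np.isnan(fit.param_cov).any():
            se = float("nan")
        else:
            se = float(math.sqrt(max(0.0, grad @ fit.param_cov @ grad)))
        out[nm] = (float(r), se)
    return out


def variance_proportions(fit: RemlFit) -> dict[str, tuple[float, float]]:
    """Per-parameter fraction of total variance with delta-method SEs.

    Total variance is the sum of variance parameters including the residual
    (covariance parameters do not enter the denominator).
    """
    names = fit.param_names
    cov_names = {n for n, *_ in fit.model.cov_pairs} if fit.model else set()
    is_var = np.array([nm not in cov_names for nm in names])
    theta = np.array([fit.theta[nm] for nm in names])
    total = float(theta[is_var].sum())
    if total <= 0:
        raise ValueError("nonpositive total variance")
    C = fit.param_cov
    out: dict[str, tuple[float, float]] = {}
    for j, nm in enumerate(names):
        h = theta[j] / total
        grad = np.where(is_var, -theta[j] / total**2, 0.0)
        grad[j] += 1.0 / total
        if C is None or np.isnan(C).any():
            se = float("nan")
        else:
            se = float(math.sqrt(max(0.0, grad @ C @ grad)))
        out[nm] = (float(h), se)
    return out


def lrt(fit_full: RemlFit, fit_reduced: RemlFit, boundary: bool = False, df: int = 1) -> float:
    """Likelihood-ratio p-value for nested REML fits.

    With ``boundary=True`` and df=1 the null distribution is the
    half-half mixture of a point mass at 0 and chi-square(1), appropriate
    for a variance component tested at its boundary.
    """
    lam = 2.0 * (fit_full.logL - fit_reduced.logL)
    if lam < -1e-6:
        raise ValueError(
            f"full-model logL below reduced-model logL (Lambda={lam:.3e}); "
            "models are not nested or a fit failed"
        )
    lam = max(lam, 0.0)
    if boundary:
        if df != 1:
            raise ValueError("boundary mixture implemented for df=1 only")
        return 1.0 if lam == 0.0 else float(0.5 * stats.chi2.sf(lam, df=1))
    return 1.0 if lam == 0.0 else float(stats.chi2.sf(lam, df=df))


def greml_power(
    n: int,
    h2: float,
    var_offdiag: float = 2e-5,
    alpha: float = 0.05,
) -> PowerResult:
    """GREML power calculator (non-central chi-square approximation).

    se(h2) = sqrt(2 / (n^2 var_offdiag)); ncp = (h2/se)^2; power is the
    tail mass of chi-square(1, ncp) beyond the central 1-alpha quantile.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must lie in (0, 1), got {h2}")
    if var_offdiag <= 0:
        raise ValueError("var_offdiag must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    se_h2 = math.sqrt(2.0 / (n * n * var_offdiag))
    ncp = (h2 / se_h2) ** 2
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    power = float(stats.ncx2.sf(crit, df=1, nc=ncp))
    return PowerResult(se_h2=se_h2, ncp=ncp, power=power)
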