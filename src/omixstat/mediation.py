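"""Risk-score construction (BLUP) and linear mediation analysis.

Per-layer risk scores are best linear unbiased predictions of the random
effects on held-out samples; the mediation stage regresses mediator on
exposure and outcome on both, giving ACME = a*b, DE = c', total = c' + a*b,
and percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .kernels import Kernel
from .varcomp import RemlFit, VarianceModel, reml_fit

__all__ = [
    "RiskScores",
    "MediationFit",
    "blup_risk_score",
    "cv_risk_scores",
    "mediate_linear",
    "summarize_cv_mediation",
]

#: |total| below this multiple of sd(y) flags prop_mediated as unstable
TOTAL_EFFECT_FLOOR = 1e-3


@dataclass
class RiskScores:
    """Out-of-fold per-sample scores for each omics layer."""

    sample_ids: list[str]
    scores: pd.DataFrame  # columns = layer names, index = sample ids
    fold: np.ndarray  # fold assignment per sample
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.scores.index) != list(self.sample_ids):
            raise ValueError("scores index must equal sample_ids")


@dataclass
class MediationFit:
    a: float
    b: float
    c_prime: float
    acme: float
    de: float
    total: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    total_unstable: bool = False


def blup_risk_score(
    fit: RemlFit,
    K_cross: np.ndarray,
    test_ids: list[str],
    term: str,
) -> np.ndarray:
    """Score held-out samples for one random-effect term.

    g_test = sigma2_term * K_cross @ V_train^-1 (y_train - X beta); the last
    factor is exactly P y stored on the training fit.
    """
    if fit.py is None or fit.sample_ids is None:
        raise ValueError("fit does not carry training-sample information")
    if term not in fit.theta:
        raise KeyError(f"term {term!r} not in fitted model")
    leak = set(test_ids) & set(fit.sample_ids)
    if leak:
        raise ValueError(f"test samples present in training data: {sorted(leak)[:5]}")
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.shape != (len(test_ids), len(fit.sample_ids)):
        raise ValueError(
            f"K_cross shape {K_cross.shape} != ({len(test_ids)}, {len(fit.sample_ids)})"
        )
    return fit.theta[term] * (K_cross @ fit.py)


def cv_risk_scores(
    y: np.ndarray,
    X: np.ndarray | None,
    layer_kernels: dict[str, Kernel],
    status: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    reml_opts: dict | None = None,
) -> RiskScores:
    """K-fold out-of-sample BLUP scores, one column per layer.

    Folds are seeded and stratified by the ordinal status (or by the sign of
    y if no status is given); each layer is fit as a single-kernel model on
    the training complement of each fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10 * k:
        raise ValueError(f"need n >= 10*k = {10 * k} samples, got {n}")
    ids = None
    for kern in layer_kernels.values():
        if ids is None:
            ids = kern.sample_ids
        elif kern.sample_ids != ids:
            raise ValueError("layer kernels must share sample ids and order")
    assert ids is not None and len(ids) == n
    if X is None:
        X = np.ones((n, 1))
    strata = np.asarray(status) if status is not None else (y > np.median(y)).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(n, dtype=int)
    scores = pd.DataFrame(index=pd.Index(ids), columns=list(layer_kernels), dtype=float)
    opts = reml_opts or {}
    for f, (train, test) in enumerate(skf.split(np.zeros(n), strata)):
        if np.ptp(y[train]) == 0:
            raise ValueError(f"fold {f} has constant training phenotype")
        fold[test] = f
        train_ids = [ids[i] for i in train]
        test_ids = [ids[i] for i in test]
        for layer, kern in layer_kernels.items():
            sub = kern.subset(train_ids)
            model = VarianceModel(terms=[(layer, sub)])
            fit = reml_fit(y[train], X[train], model, **opts)
            K_cross = kern.cross_block(test_ids, train_ids)
            scores.iloc[test, scores.columns.get_loc(layer)] = blup_risk_score(
                fit, K_cross, test_ids, layer
            )
    return RiskScores(
        sample_ids=list(ids),
        scores=scores,
        fold=fold,
        provenance=f"cv(k={k}, seed={seed})",
    )


def _ols_mediation(x, m, y):
    """Closed-form a, c', b from the two mediation regressions."""
    xc = x - x.mean()
    mc = m - m.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxm = float(xc @ mc)
    smm = float(mc @ mc)
    sxy = float(xc @ yc)
    smy = float(mc @ yc)
    a = sxm / sxx
    det = sxx * smm - sxm * sxm
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return a, b, c_prime


def mediate_linear(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationFit:
    """Linear-linear mediation with percentile bootstrap CIs.

    Mediator model m ~ x, outcome model y ~ x + m; ACME = a*b, DE = c',
    total = c' + a*b, prop_mediated = ACME/total (flagged unstable when
    |total| < 1e-3 * sd(y)).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ValueError("x, m, y must have equal length")
    if n < 30:
        raise ValueError(f"need n >= 30 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(m).all() and np.isfinite(y).all()):
        raise ValueError("x, m, y must be finite")
    if np.ptp(x) == 0 or np.ptp(m) == 0:
        raise ValueError("zero-variance exposure or mediator")

    a, b, c_prime = _ols_mediation(x, m, y)
    acme = a * b
    total = c_prime + acme
    unstable = abs(total) < TOTAL_EFFECT_FLOOR * float(y.std())
    prop = acme / total if total != 0 else math.inf * np.sign(acme or 1.0)

    rng = np.random.default_rng(seed)
    draws = {"a": [], "b": [], "c_prime": [], "acme": [], "de": [], "total": [], "prop_mediated": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ab, bb, cb = _ols_mediation(x[idx], m[idx], y[idx])
        tb = cb + ab * bb
        draws["a"].append(ab)
        draws["b"].append(bb)
        draws["c_prime"].append(cb)
        draws["acme"].append(ab * bb)
        draws["de"].append(cb)
        draws["total"].append(tb)
        draws["prop_mediated"].append(ab * bb / tb if tb != 0 else np.nan)
    lo_q = (1.0 - ci_level) / 2.0
    ci = {}
    for key, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size:
            ci[key] = (
                float(np.quantile(arr, lo_q)),
                float(np.quantile(arr, 1.0 - lo_q)),
            )
        else:  # pragma: no cover - all-degenerate bootstrap
            ci[key] = (float("nan"), float("nan"))
    return MediationFit(
        a=float(a),
        b=float(b),
        c_prime=float(c_prime),
        acme=float(acme),
        de=float(c_prime),
        total=float(total),
        prop_mediated=float(prop),
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        total_unstable=bool(unstable),
    )


def summarize_cv_mediation(fits: list[MediationFit]) -> dict:
    """Mean and min-max range of the per-fold proportion mediated."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fold fits to summarize")
    props = np.array([f.prop_mediated for f in fits], dtype=float)
    return {
        "mean_prop_mediated": float(props.mean()),
        "range_prop_mediated": (float(props.min()), float(props.max())),
        "per_fold": [
            {"prop_mediated": float(f.prop_mediated), "ci": f.ci.get("prop_mediated")}
            for f in fits
        ],
    }
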