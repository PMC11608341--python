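"""Relationship-kernel construction and kernel algebra.

All layers (genomic, transcriptomic, metabolomic, exposomic) are reduced to
n x n sample-similarity kernels; interactions are Hadamard products and
between-effect covariance structures are symmetrized products of kernel
square roots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panels import OmicsPanel

__all__ = [
    "Kernel",
    "feature_kernel",
    "interaction_kernel",
    "kernel_sqrt",
    "covariance_structure",
    "trace_normalize",
]

#: relative symmetry tolerance for kernel validation
SYMMETRY_RTOL = 1e-10
#: eigenvalues above -PSD_TOL * max(eig) are treated as numerically zero
PSD_TOL = 1e-8
#: kernel_sqrt tolerates more noise: float32-serialized kernels (GCTA GRM
#: format) legitimately carry ~1e-7 relative eigenvalue error
SQRT_PSD_TOL = 1e-6


@dataclass
class Kernel:
    """A named symmetric sample-similarity matrix.

    ``psd_flag`` distinguishes additive/interaction kernels (PSD by
    construction) from covariance structures, which may be indefinite.
    """

    values: np.ndarray
    sample_ids: list[str]
    tag: str = "K"
    psd_flag: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} does not match {n} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in kernel")
        scale = max(np.abs(self.values).max(), 1.0) if n else 1.0
        if n and np.abs(self.values - self.values.T).max() > SYMMETRY_RTOL * scale:
            raise ValueError(f"kernel {self.tag!r} is not symmetric")
        # exact symmetrization so downstream eigendecompositions are stable
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))

    def eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition, cached on the instance (values are immutable
        by convention once the kernel is built)."""
        cache = self.meta.get("_eigh")
        if cache is None:
            cache = np.linalg.eigh(self.values)
            self.meta["_eigh"] = cache
        return cache

    def check_psd(self) -> None:
        w, _ = self.eigh()
        floor = -PSD_TOL * max(float(w[-1]), 1.0)
        if w[0] < floor:
            raise ValueError(
                f"kernel {self.tag!r} has eigenvalue {w[0]:.3e} below PSD tolerance"
            )

    def subset(self, ids: list[str]) -> "Kernel":
        """Restrict to ``ids`` (in the given order)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in ids])
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample id {e.args[0]!r} not in kernel") from None
        return Kernel(
            values=self.values[np.ix_(idx, idx)],
            sample_ids=list(ids),
            tag=self.tag,
            psd_flag=self.psd_flag,
        )

    def cross_block(self, row_ids: list[str], col_ids: list[str]) -> np.ndarray:
        """Off-diagonal block K[row_ids, col_ids]."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        r = np.array([pos[s] for s in row_ids])
        c = np.array([pos[s] for s in col_ids])
        return self.values[np.ix_(r, c)]


def _require_matching_ids(k1: Kernel, k2: Kernel) -> None:
    if k1.sample_ids != k2.sample_ids:
        for i, (a, b) in enumerate(zip(k1.sample_ids, k2.sample_ids)):
            if a != b:
                raise ValueError(
                    f"sample id mismatch at position {i}: {a!r} != {b!r}"
                )
        raise ValueError(
            f"kernels have {k1.n_samples} vs {k2.n_samples} samples"
        )


def feature_kernel(panel: OmicsPanel, standardize: bool = True) -> Kernel:
    """Build a relationship kernel K = Z Z' / p from a feature matrix.

    Columns are centered (and scaled to unit population variance when
    ``standardize``); constant columns carry no relational information and
    are dropped with a warning.
    """
    Z = panel.values.astype(float).copy()
    if not np.isfinite(Z).all():
        raise ValueError(f"non-finite values in layer {panel.layer!r}")
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)  # ddof=0: mean(diag K) is exactly 1 after scaling
    keep = sd > 1e-12 * np.maximum(np.abs(mu), 1.0)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"all {panel.n_features} features in {panel.layer!r} are constant")
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} constant feature(s) from layer {panel.layer!r}",
            stacklevel=2,
        )
    Z = Z[:, keep] - mu[keep]
    if standardize:
        Z /= sd[keep]
    p = Z.shape[1]
    K = (Z @ Z.T) / p
    return Kernel(
        values=K,
        sample_ids=list(panel.sample_ids),
        tag=panel.layer,
        psd_flag=True,
        meta={
            "n_features": p,
            "n_constant_dropped": n_dropped,
            # low-rank factor F with F F' == K; lets square roots and effect
            # draws run in O(n r^2) instead of O(n^3)
            "_factor": Z / np.sqrt(p),
        },
    )


def interaction_kernel(k1: Kernel, k2: Kernel, normalize: bool = True) -> Kernel:
    """Hadamard (elementwise) product kernel modelling interaction effects.

    PSD of the product is guaranteed for PSD inputs (Schur product theorem).
    When ``normalize``, the product is rescaled to mean diagonal 1 so its
    variance component is comparable with the additive ones.
    """
    _require_matching_ids(k1, k2)
    K = k1.values * k2.values
    tag = f"interaction:{k1.tag}x{k2.tag}"
    meta = {}
    f1, f2 = k1.meta.get("_factor"), k2.meta.get("_factor")
    if f1 is not None and f2 is not None:
        # K1.K2 factors through per-sample Kronecker products of the rows of
        # F1 and F2 (scale tracks later trace normalization)
        meta["_hadamard"] = (f1, f2, 1.0)
    out = Kernel(values=K, sample_ids=list(k1.sample_ids), tag=tag, psd_flag=True, meta=meta)
    if normalize:
        out = trace_normalize(out)
    return out


def kernel_sqrt(K: Kernel, eig_floor: float = 0.0, require_psd: bool = True) -> np.ndarray:
    """Symmetric square root S with S S' ~= K.

    Eigenvalues in the numerical-noise band [-PSD_TOL*max, 0) are clipped to
    ``eig_floor``; materially negative eigenvalues raise when ``require_psd``.
    """
    cached = K.meta.get("_sqrt")
    if cached is not None:
        return cached
    F = K.meta.get("_factor")
    if F is not None and eig_floor == 0.0:
        # K = F F' is PSD by construction; economy SVD of F gives the
        # nonzero spectrum in O(n r^2)
        U, s, _ = np.linalg.svd(F, full_matrices=False)
        S = (U * s) @ U.T
        S = (S + S.T) / 2.0
        K.meta["_sqrt"] = S
        return S
    w, U = K.eigh()
    wmax = max(float(w[-1]), 0.0)
    floor = -SQRT_PSD_TOL * max(wmax, 1.0)
    if require_psd and w[0] < floor:
        raise ValueError(
            f"kernel {K.tag!r} is materially indefinite (min eigenvalue {w[0]:.3e})"
        )
    w_clipped = np.where(w < eig_floor, eig_floor, w)
    w_clipped = np.clip(w_clipped, 0.0, None)
    S = (U * np.sqrt(w_clipped)) @ U.T
    S = (S + S.T) / 2.0
    if eig_floor == 0.0:
        K.meta["_sqrt"] = S
    return S


def sqrt_action(K: Kernel):
    """Return a callable z -> S z (S the symmetric kernel root) without
    materializing S when a low-rank factor is available."""
    F = K.meta.get("_factor")
    if F is not None:
        svd = K.meta.get("_factor_svd")
        if svd is None:
            U, s, _ = np.linalg.svd(F, full_matrices=False)
            svd = (U, s)
            K.meta["_factor_svd"] = svd
        U, s = svd
        return lambda z: U @ (s * (U.T @ z))
    S = kernel_sqrt(K)
    return lambda z: S @ z


def covariance_structure(k1: Kernel, k2: Kernel) -> Kernel:
    """Coefficient matrix of the covariance parameter between two random
    effects: C = (S1 S2' + S2 S1') / 2 with S_i the symmetric kernel roots.

    C is symmetric but generally indefinite, hence ``psd_flag=False``.
    """
    _require_matching_ids(k1, k2)
    f1, f2 = k1.meta.get("_factor"), k2.meta.get("_factor")
    if f1 is not None and f2 is not None:
        # S1 S2' = U1 (s1 o U1'U2 o s2) U2' from the factor SVDs: O(n r^2)
        U1, s1, _ = np.linalg.svd(f1, full_matrices=False)
        U2, s2, _ = np.linalg.svd(f2, full_matrices=False)
        B = (s1[:, None] * (U1.T @ U2)) * s2[None, :]
        M = (U1 @ B) @ U2.T
    else:
        S1 = kernel_sqrt(k1)
        S2 = kernel_sqrt(k2)
        M = S1 @ S2.T
    C = (M + M.T) / 2.0
    return Kernel(
        values=C,
        sample_ids=list(k1.sample_ids),
        tag=f"covstruct:{k1.tag},{k2.tag}",
        psd_flag=False,
    )


def trace_normalize(K: Kernel) -> Kernel:
    """Rescale so that mean(diag) = 1; the factor is kept in ``meta``."""
    d = K.mean_diag()
    if d <= 0:
        raise ValueError(f"kernel {K.tag!r} has nonpositive mean diagonal {d:.3e}")
    meta = {k: v for k, v in K.meta.items() if k not in ("_eigh", "_sqrt")}
    meta["trace_norm_factor"] = d
    if "_factor" in meta:
        meta["_factor"] = meta["_factor"] / np.sqrt(d)
    if "_hadamard" in meta:
        f1, f2, scale = meta["_hadamard"]
        meta["_hadamard"] = (f1, f2, scale / np.sqrt(d))
    return Kernel(
        values=K.values / d,
        sample_ids=list(K.sample_ids),
        tag=K.tag,
        psd_flag=K.psd_flag,
        meta=meta,
    )
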