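"""Ordinal disease-status coding and fixed-effect pre-adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhenotypeVector", "encode_status", "adjust_phenotype"]

SEVERITY_FLAGS = ("hospitalized", "icu_or_respiratory_support", "died_covid_primary")


@dataclass
class PhenotypeVector:
    """Ordinal status (0 control / 1 moderate / 2 severe) plus the adjusted
    residual used as the quantitative outcome downstream."""

    sample_ids: list[str]
    status: np.ndarray
    adjusted: np.ndarray | None = None
    fixed_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status)
        if not np.isin(self.status, (0, 1, 2)).all():
            raise ValueError("status codes must be 0, 1 or 2")
        if len(self.sample_ids) != len(self.status):
            raise ValueError("sample_ids / status length mismatch")
        if self.adjusted is not None:
            self.adjusted = np.asarray(self.adjusted, dtype=float)
            if self.adjusted.shape != self.status.shape:
                raise ValueError("adjusted residual length mismatch")


def encode_status(records: pd.DataFrame) -> np.ndarray:
    """Map per-sample clinical flags to the ordinal 0/1/2 code.

    2 = test-positive with hospitalization, ICU/respiratory support, or
    death with the disease as primary cause; 1 = any other positive
    (including clinical diagnosis / quarantine); 0 = not positive.
    """
    required = {"tested_positive", *SEVERITY_FLAGS}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing flag columns: {sorted(missing)}")
    flags = records.astype(bool)
    positive = flags["tested_positive"].to_numpy()
    severe = np.zeros(len(flags), dtype=bool)
    for col in SEVERITY_FLAGS:
        severe |= flags[col].to_numpy()
    contradictory = severe & ~positive
    if contradictory.any():
        bad = np.nonzero(contradictory)[0][0]
        raise ValueError(
            f"record {bad} has a severity flag without a positive test"
        )
    return np.where(positive & severe, 2, np.where(positive, 1, 0))


def _dummy_design(factors: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + drop-first dummy coding; single-level factors dropped."""
    cols: list[np.ndarray] = [np.ones(len(factors))]
    names = ["intercept"]
    for name in factors.columns:
        levels = pd.Categorical(factors[name].astype(str))
        if len(levels.categories) < 2:
            warnings.warn(f"factor {name!r} has a single level; dropped", stacklevel=3)
            continue
        for lev in levels.categories[1:]:
            cols.append((levels == lev).astype(float))
            names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def adjust_phenotype(
    y: np.ndarray,
    factors: pd.DataFrame | None = None,
    standardize: bool = True,
) -> np.ndarray:
    """Residualize the numeric 0/1/2 status on dummy-coded factor covariates.

    Ordinary least squares with an intercept; residuals are optionally
    standardized to unit (population) variance so variance components read
    as fractions of adjusted phenotypic variance.
    """
    y = np.asarray(y, dtype=float)
    if factors is None or factors.shape[1] == 0:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    else:
        if len(factors) != len(y):
            raise ValueError("factors and y must cover the same samples")
        if factors.isna().any().any():
            raise ValueError("every sample must have all factor levels observed")
        X, names = _dummy_design(factors)
    # rank check with column pivoting so aliased columns can be named
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if standardize:
        sd = resid.std()
        if sd > 1e-12 * max(np.abs(y).max(), 1.0):
            resid = resid / sd
    return resid
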