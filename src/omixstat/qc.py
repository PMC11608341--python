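"""SNP/sample quality control and genomic relationship matrix construction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import Kernel
from .panels import SnpPanel

__all__ = [
    "QcReport",
    "hwe_test",
    "snp_qc",
    "sample_qc",
    "compute_grm",
    "relatedness_prune",
]


@dataclass
class QcReport:
    """Per-filter removal counts for one QC pass."""

    axis: str  # "snp" or "sample"
    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    #: number of SNPs failing at least one filter (filters can overlap)
    n_removed: int = 0

    def __post_init__(self) -> None:
        if self.n_removed + self.n_retained != self.n_input:
            raise ValueError("removed + retained must equal input count")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Returns 1.0 for monomorphic SNPs (an expected genotype class is empty).
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    if (expected == 0).any():
        return 1.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorized HWE p-values per SNP column (missing entries ignored)."""
    n_AA = np.nansum(dosages == 2, axis=0).astype(float)
    n_Aa = np.nansum(dosages == 1, axis=0).astype(float)
    n_aa = np.nansum(dosages == 0, axis=0).astype(float)
    n = n_AA + n_Aa + n_aa
    out = np.ones(dosages.shape[1])
    ok = n >= 1
    p = np.zeros_like(out)
    p[ok] = (2 * n_AA[ok] + n_Aa[ok]) / (2 * n[ok])
    q = 1.0 - p
    for j in np.nonzero(ok)[0]:
        exp = n[j] * np.array([p[j] ** 2, 2 * p[j] * q[j], q[j] ** 2])
        if (exp == 0).any():
            continue  # monomorphic -> p = 1
        obs = np.array([n_AA[j], n_Aa[j], n_aa[j]])
        out[j] = stats.chi2.sf(float(((obs - exp) ** 2 / exp).sum()), df=1)
    return out


def snp_qc(
    panel: SnpPanel,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-7,
    call_rate_min: float = 0.95,
    info_min: float = 0.60,
) -> tuple[SnpPanel, QcReport]:
    """Remove SNPs failing MAF / HWE / call-rate / info-score / duplicate-id
    filters.  All statistics are computed once on the input panel (filters
    are not re-estimated sequentially)."""
    for name, val in (
        ("maf_min", maf_min),
        ("hwe_alpha", hwe_alpha),
        ("call_rate_min", call_rate_min),
        ("info_min", info_min),
    ):
        if not (0.0 < val < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {val}")

    af = panel.allele_frequencies()
    maf = np.fmin(af, 1.0 - af)
    call_rate = 1.0 - panel.missing_rate_per_snp()
    hwe_p = _hwe_pvalues(panel.dosages)
    info = panel.snp_meta["info_score"].to_numpy(dtype=float)

    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_hwe = hwe_p < hwe_alpha
    fail_call = call_rate < call_rate_min
    fail_info = info < info_min
    dup = panel.snp_meta["id"].duplicated(keep="first").to_numpy()

    fail_any = fail_maf | fail_hwe | fail_call | fail_info | dup
    keep = ~fail_any
    if not keep.any():
        raise ValueError("SNP QC removed every SNP: empty panel")

    report = QcReport(
        axis="snp",
        n_input=panel.n_snps,
        n_retained=int(keep.sum()),
        n_removed=int(fail_any.sum()),
        removed={
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
            "call_rate": int(fail_call.sum()),
            "info": int(fail_info.sum()),
            "duplicate_id": int(dup.sum()),
        },
        thresholds={
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
            "call_rate_min": call_rate_min,
            "info_min": info_min,
        },
    )
    return panel.take_snps(np.nonzero(keep)[0]), report


def sample_qc(
    panel: SnpPanel,
    miss_max: float = 0.05,
    exclusion_flags: np.ndarray | None = None,
) -> tuple[SnpPanel, QcReport]:
    """Remove samples with genotype missing rate above ``miss_max``.

    ``exclusion_flags`` carries externally determined removals (gender
    mismatch, aneuploidy, ...) that are not computable from dosages.
    """
    if not (0.0 <= miss_max < 1.0):
        raise ValueError(f"miss_max must lie in [0, 1), got {miss_max}")
    miss = panel.missing_rate_per_sample()
    fail_miss = miss > miss_max
    if exclusion_flags is None:
        flagged = np.zeros(panel.n_samples, dtype=bool)
    else:
        flagged = np.asarray(exclusion_flags, dtype=bool)
        if flagged.shape != (panel.n_samples,):
            raise ValueError("exclusion_flags length must match n_samples")
    fail_any = fail_miss | flagged
    keep = ~fail_any
    if keep.sum() < 2:
        raise ValueError("sample QC left fewer than 2 samples: empty panel")
    report = QcReport(
        axis="sample",
        n_input=panel.n_samples,
        n_retained=int(keep.sum()),
        n_removed=int(fail_any.sum()),
        removed={
            "sample_missingness": int(fail_miss.sum()),
            "flagged": int(flagged.sum()),
        },
        thresholds={"miss_max": miss_max},
    )
    return panel.take_samples(np.nonzero(keep)[0]), report


def compute_grm(panel: SnpPanel) -> Kernel:
    """GCTA-style genomic relationship matrix.

    A_ij = mean_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)) over
    polymorphic SNPs, with missing dosages mean-imputed to 2 p_k.
    """
    af = panel.allele_frequencies()
    with np.errstate(invalid="ignore"):
        varies = np.nanvar(panel.dosages, axis=0) > 0
    poly = ~np.isnan(af) & (af > 0.0) & (af < 1.0) & varies
    m = int(poly.sum())
    if m < 1:
        raise ValueError("no polymorphic SNPs: GRM undefined")
    X = panel.dosages[:, poly].copy()
    p = af[poly]
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = (2.0 * p)[np.nonzero(nan_mask)[1]]
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    A = (W @ W.T) / m
    return Kernel(
        values=A,
        sample_ids=list(panel.sample_ids),
        tag="G",
        psd_flag=True,
        meta={
            "n_snps_used": m,
            "n_monomorphic_skipped": int(panel.n_snps - m),
            "_factor": W / np.sqrt(m),
        },
    )


def relatedness_prune(grm: Kernel, cutoff: float = 0.05) -> list[str]:
    """Greedy relatedness pruning mirroring a GRM cutoff.

    While any off-diagonal |A_ij| > cutoff remains, drop the sample in the
    most offending pairs (ties broken by input order).  The returned ids
    preserve input order and induce no off-diagonal above the cutoff.
    """
    A = np.abs(grm.values.copy())
    np.fill_diagonal(A, 0.0)
    active = np.ones(grm.n_samples, dtype=bool)
    while True:
        viol = (A > cutoff) & active[:, None] & active[None, :]
        degree = viol.sum(axis=1)
        if degree.max(initial=0) == 0:
            break
        drop = int(np.argmax(degree))  # argmax takes the first max: input-order tie-break
        active[drop] = False
    return [s for s, a in zip(grm.sample_ids, active) if a]
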