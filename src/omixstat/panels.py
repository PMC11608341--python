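"""Sample-by-feature data containers for the genotype and omics layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SnpPanel", "OmicsPanel"]

#: columns expected in :attr:`SnpPanel.snp_meta`
SNP_META_COLUMNS = ("id", "chrom", "pos", "allele1", "allele2", "info_score")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class SnpPanel:
    """Hard-called dosage matrix (samples x SNPs) with per-SNP metadata.

    Missing dosages are stored as NaN; observed entries must be 0, 1 or 2.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n < 2:
            raise ValueError("a SnpPanel needs at least 2 samples")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_meta) != m:
            raise ValueError(f"{len(self.snp_meta)} metadata rows for {m} SNPs")
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta missing columns: {sorted(missing_cols)}")
        _check_unique(self.sample_ids, "sample id")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0/1/2/missing, got {bad}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [str(s) for s in self.snp_meta["id"]]

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (NaN if fully missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate_per_snp(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def take_snps(self, index: np.ndarray) -> "SnpPanel":
        return SnpPanel(
            dosages=self.dosages[:, index],
            sample_ids=list(self.sample_ids),
            snp_meta=self.snp_meta.iloc[np.asarray(index)].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "SnpPanel":
        index = np.asarray(index)
        return SnpPanel(
            dosages=self.dosages[index, :],
            sample_ids=[self.sample_ids[i] for i in index],
            snp_meta=self.snp_meta.copy(),
        )


@dataclass
class OmicsPanel:
    """Continuous feature matrix (samples x features) for one omics layer.

    ``layer`` identifies the layer, e.g. ``"transcriptome:coronary"``,
    ``"metabolome"`` or ``"exposome"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    layer: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("an OmicsPanel needs at least 1 feature")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.feature_ids, "feature id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
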