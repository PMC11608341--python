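"""File formats: GCTA binary GRM, PLINK .raw dosage text, TSV panels,
GCTA-style .hsq result text, and run manifests."""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import Kernel
from .panels import OmicsPanel, SnpPanel
from .varcomp import RemlFit

__all__ = [
    "write_gcta_grm",
    "read_gcta_grm",
    "write_plink_raw",
    "read_plink_raw",
    "write_omics_tsv",
    "read_omics_tsv",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_hsq",
    "write_manifest",
]

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# GCTA binary GRM (lower triangle incl. diagonal, float32 little-endian)


def write_gcta_grm(kernel: Kernel, prefix: str | Path, n_counts: np.ndarray | None = None) -> None:
    prefix = str(prefix)
    n = kernel.n_samples
    tri = kernel.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    if n_counts is None:
        n_counts = np.full(tri.shape, float(kernel.meta.get("n_snps_used", 1)))
    np.asarray(n_counts, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in kernel.sample_ids:
            fh.write(f"{s}\t{s}\n")


def read_gcta_grm(prefix: str | Path, tag: str = "G") -> Kernel:
    prefix = str(prefix)
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                parts = line.split()
            ids.append(parts[1])
    n = len(ids)
    expected = n * (n + 1) // 2
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if tri.size != expected:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} values but {n} ids imply {expected}"
        )
    K = np.zeros((n, n))
    il = np.tril_indices(n)
    K[il] = tri
    K = K + np.tril(K, -1).T
    return Kernel(values=K, sample_ids=ids, tag=tag)


# ---------------------------------------------------------------------------
# PLINK .raw additive dosage text

RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(panel: SnpPanel, path: str | Path, phenotype: np.ndarray | None = None) -> None:
    meta = panel.snp_meta
    cols = [f"{sid}_{a1}" for sid, a1 in zip(meta["id"], meta["allele1"])]
    with open(path, "w") as fh:
        fh.write(" ".join(RAW_LEAD + cols) + "\n")
        for i, sample in enumerate(panel.sample_ids):
            ph = "-9" if phenotype is None else FLOAT_FMT % phenotype[i]
            row = [sample, sample, "0", "0", "0", ph]
            for v in panel.dosages[i]:
                row.append("NA" if np.isnan(v) else str(int(v)))
            fh.write(" ".join(row) + "\n")


def read_plink_raw(path: str | Path) -> SnpPanel:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(RAW_LEAD)] != RAW_LEAD:
            raise ValueError(
                f"not a PLINK .raw header (expected it to start with {' '.join(RAW_LEAD)})"
            )
        snp_cols = header[len(RAW_LEAD):]
        ids, alleles = [], []
        for c in snp_cols:
            sid, _, a1 = c.rpartition("_")
            if not sid:
                sid, a1 = c, "?"
            ids.append(sid)
            alleles.append(a1)
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"line {lineno}: {len(parts)} fields, expected {len(header)}"
                )
            sample_ids.append(parts[1])
            vals = np.empty(len(snp_cols))
            for j, tok in enumerate(parts[len(RAW_LEAD):]):
                if tok == "NA":
                    vals[j] = np.nan
                elif tok in ("0", "1", "2"):
                    vals[j] = float(tok)
                else:
                    raise ValueError(
                        f"non-integer dosage {tok!r} at line {lineno}, "
                        f"column {snp_cols[j]!r}"
                    )
            rows.append(vals)
    meta = pd.DataFrame(
        {
            "id": ids,
            "chrom": 0,
            "pos": 0,
            "allele1": alleles,
            "allele2": "?",
            "info_score": 1.0,
        }
    )
    return SnpPanel(dosages=np.vstack(rows), sample_ids=sample_ids, snp_meta=meta)


# ---------------------------------------------------------------------------
# TSV panels and phenotypes


def write_omics_tsv(panel: OmicsPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.values, index=panel.sample_ids, columns=panel.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_omics_tsv(path: str | Path, layer: str = "omics") -> OmicsPanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsPanel(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        layer=layer,
    )


def write_phenotype_tsv(
    path: str | Path,
    sample_ids: list[str],
    status: np.ndarray,
    adjusted: np.ndarray | None = None,
    factors: pd.DataFrame | None = None,
) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "status": status})
    if adjusted is not None:
        df["adjusted"] = adjusted
    if factors is not None:
        for c in factors.columns:
            df[c] = factors[c].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype TSV must have a 'sample_id' column")
    return df


# ---------------------------------------------------------------------------
# GCTA-style .hsq result text


def write_hsq(fit: RemlFit, path: str | Path) -> None:
    """Source/Variance/SE table plus proportions, logL, n and convergence."""
    lines = ["Source\tVariance\tSE"]
    for name in fit.param_names:
        label = "V(e)" if name == "residual" else f"V({name})"
        lines.append(
            f"{label}\t{FLOAT_FMT % fit.theta[name]}\t{FLOAT_FMT % fit.se[name]}"
        )
    lines.append(f"Vp\t{FLOAT_FMT % fit.vp}\t")
    for name, (h, se) in fit.proportions.items():
        label = "V(e)" if name == "residual" else f"V({name})"
        lines.append(f"{label}/Vp\t{FLOAT_FMT % h}\t{FLOAT_FMT % se}")
    for name, (r, se) in fit.correlations.items():
        lines.append(f"r({name})\t{FLOAT_FMT % r}\t{FLOAT_FMT % se}")
    for name, p in fit.wald_pvalues().items():
        label = "V(e)" if name == "residual" else f"V({name})"
        lines.append(f"Pval_Wald({label})\t{FLOAT_FMT % p}\t")
    lines.append(f"logL\t{FLOAT_FMT % fit.logL}\t")
    lines.append(f"n\t{fit.n_samples}\t")
    lines.append(f"n_iter\t{fit.n_iter}\t")
    lines.append(f"converged\t{'yes' if fit.converged else 'no'}\t")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, command: str, params: dict) -> None:
    from . import __version__

    payload = {"command": command, "version": __version__, "params": params}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
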