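"""Synthetic multi-omics data with known ground-truth variance components.

The generator mirrors the structure of the analysed cohort: biallelic
dosages with a uniform allele-frequency spectrum, continuous feature layers
(optionally coupled to the genotypes), additive / interaction / covariance
effect components drawn through kernel square roots, and an ordinal 0/1/2
phenotype obtained by thresholding the continuous liability.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams (see ``_streams``), so every
sub-draw is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    Kernel,
    feature_kernel,
    interaction_kernel,
    kernel_sqrt,
    sqrt_action,
    trace_normalize,
)
from .panels import OmicsPanel, SnpPanel
from .qc import compute_grm

__all__ = [
    "SimTruth",
    "SimResult",
    "simulate_genotypes",
    "simulate_multiomics",
    "liability_to_ordinal",
]

ADDITIVE_TERMS = ("G", "T", "M", "E")
INTERACTION_TERMS = ("GxE", "TxE", "MxE", "GxT", "TxM")
COV_PAIRS = ("rG.E", "rG.T", "rT.E", "rT.M", "rM.E")

LAYER_TAGS = {"G": "G", "T": "transcriptome", "M": "metabolome", "E": "exposome"}


@dataclass
class SimTruth:
    """Ground-truth generative parameters.

    ``var_components`` maps term names (G, T, M, E, GxE, TxE, MxE, GxT, TxM,
    residual) to fractions of total phenotypic variance (must sum to 1);
    ``cov_components`` maps pair names (rG.E, ...) to raw covariances.
    """

    var_components: dict[str, float]
    cov_components: dict[str, float] = field(default_factory=dict)
    thresholds: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        valid = set(ADDITIVE_TERMS) | set(INTERACTION_TERMS) | {"residual"}
        for name, v in self.var_components.items():
            if name not in valid:
                raise ValueError(f"unknown variance term {name!r}")
            if v < 0:
                raise ValueError(f"variance for {name!r} must be >= 0, got {v}")
        total = sum(self.var_components.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"variance components must sum to 1, got {total}")
        if "residual" not in self.var_components:
            raise ValueError("truth must include a residual component")
        for pair, sigma12 in self.cov_components.items():
            if pair not in COV_PAIRS:
                raise ValueError(f"unknown covariance pair {pair!r}")
            a, b = _parse_pair(pair)
            va = self.var_components.get(a, 0.0)
            vb = self.var_components.get(b, 0.0)
            bound = math.sqrt(va * vb)
            if abs(sigma12) > bound + 1e-12:
                raise ValueError(
                    f"|{pair}| = {abs(sigma12)} exceeds sqrt(var_{a} * var_{b}) = {bound}"
                )

    def additive_layers(self) -> list[str]:
        return [t for t in ADDITIVE_TERMS if t in self.var_components]

    def interaction_terms(self) -> list[str]:
        return [t for t in INTERACTION_TERMS if t in self.var_components]


def _parse_pair(pair: str) -> tuple[str, str]:
    a, b = pair[1:].split(".")
    return a, b


def _draw_effect(kernel: Kernel, rng: np.random.Generator) -> np.ndarray:
    """Draw u ~ N(0, K) through whichever factorization is cheapest."""
    had = kernel.meta.get("_hadamard")
    if had is not None:
        F1, F2, scale = had
        A = rng.standard_normal((F1.shape[1], F2.shape[1]))
        return scale * np.einsum("ij,ij->i", F1 @ A, F2)
    F = kernel.meta.get("_factor")
    if F is not None:
        return F @ rng.standard_normal(F.shape[1])
    return kernel_sqrt(kernel) @ rng.standard_normal(kernel.n_samples)


@dataclass
class SimResult:
    """Everything a recovery test needs: panels, kernels built from them,
    per-term realized effect vectors, the liability and its ordinal code."""

    snp_panel: SnpPanel | None
    omics_panels: list[OmicsPanel]
    kernels: dict[str, Kernel]
    liability: np.ndarray
    status: np.ndarray
    effects: dict[str, np.ndarray]
    truth: SimTruth
    sample_ids: list[str]


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Deterministic named sub-streams spawned from one root seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SnpPanel:
    """Binomial(2, p) dosages with per-SNP p drawn uniformly in ``maf_range``."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must lie in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, p, size=(n_samples, n_snps)).astype(float)
    if missing_rate > 0:
        mask = rng.random(size=dosages.shape) < missing_rate
        dosages[mask] = np.nan
    meta = pd.DataFrame(
        {
            "id": [f"snp{k}" for k in range(n_snps)],
            "chrom": np.ones(n_snps, dtype=int),
            "pos": np.arange(1, n_snps + 1) * 1000,
            "allele1": ["A"] * n_snps,
            "allele2": ["C"] * n_snps,
            "info_score": np.ones(n_snps),
        }
    )
    meta.attrs["drawn_freq"] = p
    return SnpPanel(
        dosages=dosages,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        snp_meta=meta,
    )


def _layer_panel(
    layer: str,
    n_samples: int,
    n_features: int,
    rng: np.random.Generator,
    sample_ids: list[str],
    geno_signal: np.ndarray | None,
    coupling: float,
) -> OmicsPanel:
    values = rng.standard_normal((n_samples, n_features))
    if geno_signal is not None and coupling > 0:
        # each feature mixes in one standardized SNP column: features become
        # linear functions of dosages plus noise, giving the layer kernel a
        # mechanistic genetic component
        cols = rng.integers(0, geno_signal.shape[1], size=n_features)
        values = math.sqrt(coupling) * geno_signal[:, cols] + math.sqrt(1 - coupling) * values
    return OmicsPanel(
        values=values,
        sample_ids=list(sample_ids),
        feature_ids=[f"{layer}_f{j}" for j in range(n_features)],
        layer=LAYER_TAGS[layer] if layer != "T" else "transcriptome:sim",
    )


def simulate_multiomics(
    n_samples: int,
    layer_sizes: dict[str, int],
    truth: SimTruth,
    maf_range: tuple[float, float] = (0.05, 0.5),
    g_coupling: dict[str, float] | None = None,
    case_fraction: float = 0.095,
    severe_fraction_of_cases: float = 0.5,
) -> SimResult:
    """Generate panels, kernels, realized effects and the phenotype.

    Additive effects are g_i = sigma_i * S_i z_i with S_i the symmetric root
    of the (trace-normalized) layer kernel.  A requested covariance
    sigma_12 between two layers is induced by sharing latent normals:
    g_2 = S_2 (rho sigma_2 z_1 + sqrt(1 - rho^2) sigma_2 z_2) with
    rho = sigma_12 / (sigma_1 sigma_2).  Interaction effects are drawn
    through the root of the Hadamard kernel.
    """
    layers = truth.additive_layers()
    needed = set(layers)
    for t in truth.interaction_terms():
        a, b = t.split("x")
        needed.update((a, b))
    missing = needed - set(layer_sizes)
    if missing:
        raise ValueError(f"layer_sizes missing entries for: {sorted(missing)}")

    stream_names = (
        ["genotypes"]
        + [f"panel:{l}" for l in ("T", "M", "E")]
        + [f"z:{t}" for t in ADDITIVE_TERMS + INTERACTION_TERMS]
        + ["residual", "coupling"]
    )
    rng = _streams(truth.seed, stream_names)
    g_coupling = dict(g_coupling or {})

    sample_ids = [f"s{i}" for i in range(n_samples)]
    snp_panel: SnpPanel | None = None
    geno_std: np.ndarray | None = None
    kernels: dict[str, Kernel] = {}
    omics_panels: list[OmicsPanel] = []

    build = sorted(needed, key=ADDITIVE_TERMS.index)
    if "G" in build or g_coupling:
        if "G" not in layer_sizes:
            raise ValueError("g_coupling requires a 'G' entry in layer_sizes")
        snp_panel = simulate_genotypes(
            n_samples,
            layer_sizes["G"],
            maf_range=maf_range,
            seed=rng["genotypes"].integers(2**63),
        )
        p = snp_panel.allele_frequencies()
        sd = np.sqrt(2 * p * (1 - p))
        ok = sd > 0
        geno_std = np.zeros_like(snp_panel.dosages)
        geno_std[:, ok] = (snp_panel.dosages[:, ok] - 2 * p[ok]) / sd[ok]
        if "G" in build:
            kernels["G"] = trace_normalize(compute_grm(snp_panel))

    for layer in ("T", "M", "E"):
        if layer not in build:
            continue
        panel = _layer_panel(
            layer,
            n_samples,
            layer_sizes[layer],
            rng[f"panel:{layer}"],
            sample_ids,
            geno_std,
            g_coupling.get(layer, 0.0),
        )
        omics_panels.append(panel)
        k = trace_normalize(feature_kernel(panel))
        k.tag = layer
        kernels[layer] = k

    for term in truth.interaction_terms():
        a, b = term.split("x")
        kernels[term] = interaction_kernel(kernels[a], kernels[b])
        kernels[term].tag = term

    # covariance bookkeeping: which layer shares its latent draw with which
    partner: dict[str, tuple[str, float]] = {}
    for pair, sigma12 in truth.cov_components.items():
        a, b = _parse_pair(pair)
        for x in (a, b):
            if x in partner:
                raise ValueError(f"layer {x} appears in more than one covariance pair")
        partner[b] = (a, sigma12)
        partner[a] = ("", 0.0)  # marks 'a' as a lead layer

    cov_layers = {x for x in partner}
    effects: dict[str, np.ndarray] = {}
    # layers in covariance pairs share n-dimensional latent normals through
    # the symmetric kernel roots; everything else is drawn through a kernel
    # factor (same law, no O(n^3) square root)
    z = {
        name: rng[f"z:{name}"].standard_normal(n_samples)
        for name in layers
        if name in cov_layers
    }
    for name in layers:
        sigma = math.sqrt(truth.var_components[name])
        if name in cov_layers:
            act = sqrt_action(kernels[name])
            lead = partner[name]
            if lead[0]:
                lead_name, sigma12 = lead
                sigma1 = math.sqrt(truth.var_components[lead_name])
                rho = 0.0 if sigma1 * sigma == 0 else sigma12 / (sigma1 * sigma)
                if abs(rho) > 1 + 1e-12:
                    raise ValueError(f"covariance for pair with {name} implies |rho| > 1")
                rho = float(np.clip(rho, -1.0, 1.0))
                latent = rho * z[lead_name] + math.sqrt(max(0.0, 1 - rho * rho)) * z[name]
            else:
                latent = z[name]
            effects[name] = sigma * act(latent)
        else:
            effects[name] = sigma * _draw_effect(kernels[name], rng[f"z:{name}"])
    for term in truth.interaction_terms():
        sigma = math.sqrt(truth.var_components[term])
        effects[term] = sigma * _draw_effect(kernels[term], rng[f"z:{term}"])

    resid_sd = math.sqrt(truth.var_components["residual"])
    eps = resid_sd * rng["residual"].standard_normal(n_samples)
    liability = eps.copy()
    for g in effects.values():
        liability = liability + g
    effects["residual"] = eps

    status = liability_to_ordinal(liability, case_fraction, severe_fraction_of_cases)
    return SimResult(
        snp_panel=snp_panel,
        omics_panels=omics_panels,
        kernels=kernels,
        liability=liability,
        status=status,
        effects=effects,
        truth=truth,
        sample_ids=sample_ids,
    )


def liability_to_ordinal(
    liability: np.ndarray,
    case_fraction: float,
    severe_fraction_of_cases: float = 0.5,
) -> np.ndarray:
    """Quantile-threshold the liability into 0/1/2 codes.

    The top ``case_fraction`` of the liability distribution is coded >= 1;
    within cases the top ``severe_fraction_of_cases`` is coded 2.  Counts
    match the requested fractions to within integer rounding.
    """
    liability = np.asarray(liability, dtype=float)
    if not (0.0 < case_fraction < 1.0):
        raise ValueError(f"case_fraction must lie in (0, 1), got {case_fraction}")
    if not (0.0 <= severe_fraction_of_cases <= 1.0):
        raise ValueError("severe_fraction_of_cases must lie in [0, 1]")
    n = liability.size
    if n == 0 or np.ptp(liability) == 0:
        raise ValueError("constant liability vector: thresholds undefined")
    n_cases = int(round(case_fraction * n))
    n_severe = int(round(severe_fraction_of_cases * n_cases))
    order = np.argsort(-liability, kind="stable")
    status = np.zeros(n, dtype=int)
    status[order[:n_cases]] = 1
    status[order[:n_severe]] = 2
    return status
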