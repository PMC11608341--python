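# omixstat

Multi-omics variance partitioning for an ordinal disease phenotype:

- **Synthetic data** — genotype dosage panels, continuous omics layers
  (transcriptome / metabolome / exposome), additive, interaction (Hadamard)
  and between-layer covariance effect components with known ground truth,
  and a liability-threshold ordinal (0/1/2) phenotype.
- **Genotype QC** — SNP filters (MAF, Hardy-Weinberg, call rate, info score,
  duplicate ids), sample missingness filters, the GCTA-style genomic
  relationship matrix, and greedy relatedness pruning.
- **Kernels** — feature-based relationship matrices (TRM/MRM/ERM analogues),
  Hadamard interaction kernels, symmetric kernel square roots, and
  covariance structures C = (S1·S2' + S2·S1')/2 between random effects.
- **Variance components** — multi-kernel AI-REML with EM warm-up,
  covariance components between random effects (CORE-style), boundary
  handling, delta-method variance proportions and effect correlations,
  likelihood-ratio tests (including the boundary ½χ²₀+½χ²₁ mixture), and a
  GREML power calculator.
- **Mediation** — out-of-sample BLUP risk scores per omics layer (80/20 or
  stratified k-fold CV), linear mediation (ACME / direct / total /
  proportion mediated) with percentile-bootstrap confidence intervals.
- **IO / CLI** — GCTA binary GRM format (bit-exact round trip), PLINK
  `.raw` dosage text, TSV panels and phenotypes, GCTA-style `.hsq` results,
  and a `click` CLI covering the whole pipeline.

## CLI

```sh
omixstat simulate --config sim.yaml --out-dir data --seed 1
omixstat qc --dosages data/genotypes.raw --out data/clean.raw
omixstat make-grm --dosages data/clean.raw --out data/G
omixstat make-kernel --layer data/exposome.tsv --layer-name exposome --out data/E
omixstat make-kernel --interaction data/G,data/E --out data/GxE
omixstat make-kernel --covstruct data/G,data/E --out data/covGE
omixstat adjust --pheno data/phenotype.tsv --factors batch,centre --out data/adj.tsv
omixstat reml --pheno data/adj.tsv --grm G=data/G --grm E=data/E --out fit.hsq
omixstat core-reml --pheno data/adj.tsv --grm G=data/G --grm E=data/E \
    --cov-pair G,E --out fit.hsq
omixstat mediate --scores scores.tsv --exposure G --mediator E --outcome y \
    --out mediation.json
omixstat power --n 10000 --h2 0.025 --var-offdiag 2e-5
```

A minimal `sim.yaml`:

```yaml
n_samples: 500
layer_sizes: {G: 300, E: 100}
var_components: {G: 0.25, E: 0.25, GxE: 0.2, residual: 0.3}
cov_components: {rG.E: 0.1}
```

## Model

The phenotype covariance is V(θ) = Σᵢ σ²ᵢ Kᵢ + Σₚ σ₁₂,ₚ (S₁S₂'+S₂S₁')ₚ +
σ²ₑI, with Kᵢ additive or Hadamard-interaction kernels normalized to unit
mean diagonal. REML maximizes −½(log|V| + log|X'V⁻¹X| + y'Py). Variance
parameters are clamped at a small floor (GCTA-style) and covariance
parameters are projected so every implied 2×2 component matrix stays PSD;
boundary contact is flagged per parameter.
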