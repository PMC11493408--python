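# dgrpkit

Analytical toolkit for harmonized phenomics on inbred reference panels such as
the *Drosophila* Genetic Reference Panel (DGRP). Panels of near-fully
homozygous lines are phenotyped by many independent studies; once the tables
are harmonized (one line per row, sex-stratified, consistent identifiers and
NA conventions), three analyses become routine, and this package implements
them as a tested library with a CLI:

- **Cross-study phenotype correlation.** For every same-sex pair of
  quantitative phenotypes, Spearman's ρ over the lines both studies measured,
  with Benjamini–Hochberg FDR control, within- vs cross-study summaries, and
  focal-phenotype queries whose significant hits are clustered into
  focal-like / correlated / anti-correlated groups.
- **Covariate-adjusted association (GWAS-lite) and PheWAS.** Per biallelic
  variant *v* with homozygous calls g ∈ {0,1}, ordinary least squares of the
  rank-inverse-normal transformed phenotype on [1, g, C], where C holds six
  known covariates (symbiont infection status plus five structural-variant
  factors); only the genotype term β̂, se, t, p is reported. Variants are
  filtered at ≤ 20% missing calls and MAF ≥ 0.01, and a PheWAS lookup
  returns one variant's statistics across all stored phenotypes.
- **Fraction-of-extremeness (FoE) scoring.** Per phenotype, lines are ranked
  (ties → minimum rank); ranks within c = ⌈0.15·R_max⌉ of either end are
  labelled −1/+1. A line's FoE is the share of its phenotypes labelled ±1;
  the adjusted value r/R_max (reflected about 0.5) and a cross-sex pairing
  rule identify lines that are consistently extreme or moderate in both
  sexes.

A fully seeded synthetic-panel generator (factor-model phenotypes with
configurable within-study, cross-study and cross-sex correlation, spiked
causal variants, covariate effects, MCAR missingness) makes every analysis
testable without any external download.

## Worked example

```python
from dataclasses import replace
import numpy as np
from dgrpkit import (SimConfig, SpikedEffect, simulate_panel,
                     correlate_registry, within_cross_summary,
                     run_gwas, extremeness_pipeline, cross_sex_pairings)
from dgrpkit.genotypes import minor_allele_frequency
from dgrpkit.simulate import simulate_genotypes

base = SimConfig(n_lines=200, n_variants=1000, n_studies=2,
                 phenos_per_study=(5, 5), within_corr=0.6,
                 cross_corr=0.05, seed=42)
maf = minor_allele_frequency(simulate_genotypes(base))
causal = int(np.argmin(np.abs(maf - 0.25)))     # spike a common variant
cfg = replace(base, causal_effects=(SpikedEffect(causal, 1.5),))
panel, cov, reg = simulate_panel(cfg)

records, _ = correlate_registry(reg)
s = within_cross_summary(records)
print(f"within-study pairs: {s['within'].count}, mean |rho| = {s['within'].mean_abs_rho:.3f}")
print(f"cross-study pairs:  {s['cross'].count}, mean |rho| = {s['cross'].mean_abs_rho:.3f}")

run = run_gwas(reg.tables["S1"].values_for("p1", "F"), panel, cov)
top = run.results.iloc[0]
print(f"spiked variant: {panel.variant_ids[causal]} (MAF {maf[causal]:.3f})")
print(f"top hit:        {top['variant_id']}  beta = {top['beta']:.3f}  p = {top['p']:.3g}")

res = extremeness_pipeline(reg, min_phenos=5)
pair = cross_sex_pairings(res.records)
print(f"extremeness records: {len(res.records)}; violation rate = {res.violations.rate:.4f}")
print(f"most extreme line across sexes: {pair.extreme}; most moderate: {pair.moderate}")
```

which prints:

```
within-study pairs: 40, mean |rho| = 0.564
cross-study pairs:  50, mean |rho| = 0.080
spiked variant: 3L:12049249 (MAF 0.250)
top hit:        3L:12049249  beta = 1.046  p = 5.57e-11
extremeness records: 400; violation rate = 0.0050
most extreme line across sexes: DGRP_003; most moderate: DGRP_023
```

Phenotypes of the same study correlate far more strongly (mean |ρ| 0.56 at a
ρ_w = 0.6 target) than phenotypes of different studies (0.08 at ρ_x = 0.05);
the β = 1.5σ spiked variant is recovered as the top association hit; and the
FoE violation rate — extreme assignments whose unrounded adjusted value
exceeds 0.15, a side effect of the inclusive cut-off rounding — stays at a
few per mille.

The same pipeline is available from the shell:

```bash
dgrpkit simulate --seed 1 --outdir fixtures/
dgrpkit validate --registry fixtures/
dgrpkit correlate --registry fixtures/ --focal S1:p1:F --alpha 0.05 --outdir out/corr
dgrpkit gwas --registry fixtures/ --phenotype S1:p1:F \
    --genotypes fixtures/genotypes.tsv --variants fixtures/variants.tsv \
    --covariates fixtures/covariates.tsv --store out/store --outdir out/gwas
dgrpkit phewas --variant 2R:8072884 --store out/store
dgrpkit extremeness --registry fixtures/ --min-phenos 50 --outdir out/ext
```

## Input formats

Phenotype tables follow the community data-sharing guidelines: TSV/CSV
matrices with canonical line IDs (`DGRP_XXX`) in the first column, sex
(M/F/NA) in the second, one column per phenotype, and a single NA token.
`dgrpkit validate` reports malformed identifiers, duplicated (line, sex)
rows, unitless quantitative phenotypes and mixed NA conventions. Genotypes
are a lines × variants TSV over {0, 1, NA} plus a variant metadata TSV
(`chrom:pos` IDs on arms 2L/2R/3L/3R/X/4, ref/alt, class ∈ {SNP, deletion,
insertion, MNP}).

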