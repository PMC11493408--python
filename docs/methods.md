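# Methods

This note documents the statistical procedures dgrpkit implements, the
generative model behind its synthetic panels, the defaults that matter, and
the numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A *panel* is a set of inbred, near-fully homozygous lines. Each line has one
genotype shared across laboratories, so phenotypes join across studies on the
canonical line identifier `DGRP_XXX` (zero-padded three-digit number; all
published line numbers fit in three digits, and `normalize_line_id` rejects
anything larger). Phenotypes are sex-stratified: a phenotype descriptor is
the triple (study, phenotype, sex) with sex ∈ {M, F, NA}, where NA covers
sex-mixed and population-level traits. Descriptors declare their unit and
dtype (quantitative vs categorical) as metadata — dtype is never inferred
from values, because inference is fragile at panel-scale n. Categorical
phenotypes are excluded from every correlation analysis.

Genotype calls are coded 0 (ref/ref) and 1 (alt/alt) — a homozygous panel
has no dosage axis — with NaN for missing calls. MAF is computed on
non-missing calls and folded to ≤ 0.5.

## Synthetic panels

The generator exists so that every engine can be exercised against known
structure. Phenotypes follow a two-level factor model: with a global factor
g, per-study factors f_s and unique noise e_j, all standard normal per line,

    x_{j,s} = sqrt(rho_x) g + sqrt(rho_w - rho_x) f_s + noise_sd * sqrt(1 - rho_w) e_j

At `noise_sd = 1` (the default, and the scale in which spiked effect sizes
are expressed) the expected correlation is rho_w within a study and rho_x
across studies. Sexes combine a shared core x with an independent draw z of
the same structure, `y_sex = sqrt(a) x + sqrt(1-a) z_sex`, which leaves
within-sex structure untouched while giving the same phenotype a cross-sex
correlation of a. Spiked causal variants add `beta * g_v` and covariates add
`C @ gamma` to their designated phenotypes after this construction.

Defaults the generator treats as its study conditions: 200 lines, MAF drawn
uniformly in [0.05, 0.5], rho_w = 0.6 and rho_x = 0.05 (a strong within-study
block against weak cross-study background), cross-sex a = 0.5, symbiont
prevalence 0.5, five structural-variant factors with three categories at
probabilities (0.6, 0.3, 0.1), no missingness unless requested (missingness
is MCAR — no mechanism is modelled), and study categories defaulting to
"Life history traits" so category filtering is exercisable. Every generator
stream is keyed by SHA-256 of (seed, stream-name), so identical configs are
bit-identical and the genotype draw does not change when phenotype settings
do.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent; per-variant tests do not need LD), batch effects beyond the
study-factor construction, informative missingness, replicate-level (per-fly)
raw data, and realistic allele-frequency spectra. Passing tests therefore
demonstrate correctness of the procedures under clean factor-model
conditions, not robustness to those real-data complications.

Panels beyond 999 lines (used only in sampling-calibration tests) receive
wider synthetic line numbers that fall outside the three-digit guideline.

## Correlation engine

Spearman's rho is the Pearson correlation of mid-ranks (average ranks on
ties) over the lines where both phenotypes have values, with the two-sided
t-approximation p-value; pairs are formed within sex only, and pairs with
fewer than `min_overlap` shared lines (default 10 — rank-correlation
p-values are unstable below roughly ten pairs) or a constant ranked vector
are skipped and counted rather than emitted as NaN, keeping downstream
summaries well-defined. Within- vs cross-study summaries report mean and
median of |rho| per group.

FDR control uses Benjamini–Hochberg. For a focal-phenotype query the family
is that query's candidate set (one family per focal phenotype), not the
global pair matrix; the registry-wide run adjusts over all emitted pairs.
Candidates match the focal phenotype's sex by default; a flag admits all
sexes (values still join on shared lines). Significant hits are partitioned
by average-linkage hierarchical clustering on distance 1 − rho of their
mutual correlation matrix, cut into three groups; groups are labelled
focal-like / correlated / anti-correlated by their mean correlation with the
focal phenotype. With fewer than three hits, clustering is skipped and hits
are grouped by the sign of rho.

## Association engine

The per-variant model mirrors a PLINK2-style `--glm hide-covar` run:

1. The phenotype is rank-inverse-normal transformed,
   Phi^{-1}((r − c)/(n − 2c + 1)) with mid-ranks and the Blom offset
   c = 3/8 (the conventional choice; configurable). This makes association
   p-values invariant under any strictly increasing transform of the
   phenotype. With the transform off, the phenotype is centred and
   variance-standardized instead.
2. Variants are filtered on missing-call fraction ≤ 0.2 then MAF ≥ 0.01
   (reasons mutually exclusive, missingness checked first; retained +
   excluded = total).
3. Each retained variant is fit by OLS of y on [1, g, C]; only the genotype
   term is reported. Lines missing the phenotype are dropped once; lines
   missing a call are dropped for that variant only (per-variant complete
   case). The symbiont covariate enters as its 0/1 value (standardized when
   variance-standardization is on); each structural-variant factor enters as
   indicator contrasts with the most frequent category as reference — a
   deterministic contrast choice. Collinear covariate columns are dropped
   with a warning; a genotype collinear with the covariates, or monomorphic
   among the used lines, is skipped and counted.

Variants with complete calls share one covariate projection, so their
genotype terms are computed in a single Frisch–Waugh residualization pass;
variants with missing calls fall back to per-variant OLS. The two paths are
algebraically identical and a test asserts their agreement to 1e−9.

p-values are two-sided from the t distribution with n − k − 1 residual
degrees of freedom and are floored at the smallest positive double, never
reported as 0 (log-scale plotting safety). Ties in p keep the panel's
variant order, so result tables are bit-reproducible.

Covariate screening (Kruskal–Wallis per factor one at a time, one
multifactor ANOVA over all six factors jointly — type-II sums of squares —
and Shapiro–Wilk normality of the raw phenotype) is advisory only: the
association model always includes all known covariates. Single-category
factors are skipped with a note.

The Bonferroni threshold is alpha / (number of tested variants); over the
full published variant catalogue (3,963,420 SNPs + 293,363 deletions +
169,053 insertions + 12,591 MNPs = 4,438,427 variants) at alpha = 0.05 this
is 1.1265e−8. The PheWAS lookup returns one variant's association row from
every stored phenotype run, sorted by ascending p; phenotypes where the
variant failed filters are simply absent.

## Extremeness engine

Per phenotype, lines are ranked ascending with ties assigned the minimum
rank; R_max is the maximum assigned rank (with heavy ties R_max < n — the
cut-off is computed from R_max, consistent with the adjusted value r/R_max).
The band cut-off is c = ⌈0.15 · R_max⌉, rounded up to be inclusive at both
ends (raw cut-offs of 1.2 and 1.8 both become 2). Ranks ≤ c are assigned
−1, ranks ≥ R_max − c are assigned +1, the rest 0. The upper rule captures
one more rank than the lower band; the asymmetry is reproduced deliberately
and flagged rather than "fixed", so results match the established procedure.
When c ≥ R_max − c the bands overlap, every line is extreme, and the
phenotype is flagged degenerate (the −1 test wins on overlap).

A line's FoE for one sex is the count of ±1 assignments divided by the
number of phenotypes with a value for that line; line-level reports require
at least 50 phenotypes per (line, sex) — the per-sex application matches
plotting sexes separately — and excluding a line never changes another
line's score. The adjusted value is r/R_max, reflected about 0.5 (0.91 →
0.09; exactly 0.5 is not reflected). Because c is rounded up while the
adjusted value is not, a ±1 assignment can carry an adjusted value above
0.15; the pipeline counts these as violations and reports the rate.

Cross-sex pairing: among lines with records for both sexes and
|FoE_F − FoE_M| ≤ 0.05, the lines with the highest and lowest mean FoE are
the extreme and moderate picks.

## CLI

All subcommands are thin wrappers over the library. Every run writes a
`manifest.json` (parameter echo, SHA-256 input digests, package version);
tabular outputs are written to a temp file and renamed. Exit codes separate
usage errors (2), missing/malformed inputs (3) and invalid configurations
(4). Association processes variants in a deterministic order; nothing in the
pipeline introduces hidden randomness, so a fixed seed and fixed inputs give
byte-identical outputs.

## Verification sizes and expectations

The statistical acceptance tests run at panel scale chosen to keep the whole
suite under a minute of simulation per check: type-I error pools 10 seeds of
200 lines × 2,000 null variants (empirical size expected 0.05 ± 0.01; QQ
points inside the central 95% beta order-statistic band except ≤ 5%);
spiked-variant recovery uses β = 1.5σ at n = 200 over 20 replicates, with
the spike placed on the variant whose MAF is closest to 0.25 so the
condition is a well-powered common-variant effect; correlation-structure
recovery uses ρ_w = 0.6 vs ρ_x = 0.05 over 20 seeds; FDR control runs a
50-candidate independent-null focal query over 50 seeds (mean realized
false-discovery proportion ≤ 0.08, i.e. α plus Monte-Carlo slack). Oracle
equivalences hold to 1e−12 (Spearman vs rank-then-Pearson), 1e−10
(no-covariate OLS vs closed form), exactly (BH vs brute-force step-up) and
value-for-value (pipeline vs a literal transcription of the extremeness
rules on ≤ 8 × 6 registries).

## Known limitations

No mixed-model or kinship correction (fixed covariates only), no genotype
imputation, no LD-aware analyses, no meta-analysis across studies, no
variant functional annotation, and no partial correlations. Units are free
text — no canonical vocabulary is enforced. Excel ingestion is out of
scope; inputs are TSV/CSV with delimiter auto-detection.
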