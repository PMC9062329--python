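# Methods

This note documents the models behind `eqtl-design`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## The attenuation model

For a gene with true expression `y` and a SNP with dosage `g` (both
standardized), write the noisy expression estimate as `y~ = R·y + ε` with
`R = cor(y, y~)` and zero-mean noise. Then `cov(g, y~) = R·cov(g, y)`, so
the fitted effect attenuates to `R·β`, and the chi-square-scale
association statistic `x = N·cor²(g, y)` attenuates to `R²·x`. A study of
`N` noisily measured samples therefore behaves like a study of
`Neff = R²·N` perfectly measured ones, and power falls by the factor
`1/R²`. Two caveats are deliberate:

* The algebra treats `ε` as unit-variance noise without scaling it by
  `√(1 − R²)`, so the variance bookkeeping of `y~` is not exactly 1; the
  implementation standardizes internally and treats the relation as exact
  in expectation for standardized inputs, approximate otherwise.
* `R` is taken non-negative; an anti-correlated estimate is flagged and
  its magnitude used.

`power.attenuation_experiment` validates the law end-to-end with no
shortcuts: it simulates read counts, thins them to a fraction of the
reads, measures each gene's empirical R² between full and thinned TPM (on
the TPM scale, matching how coverage-accuracy is reported elsewhere in the
package), and regresses the low-coverage association statistics on the
full-coverage ones through the origin. The slope tracks the mean per-gene
R²; residual positive bias of a few hundredths is expected because the
through-origin estimator weights genes by their squared statistic, and
well-powered genes tend to be better quantified. The default experiment
uses 1,000 genes × 300 samples and a 10× read reduction.

## Synthetic cohorts

The generator emulates the statistical skeleton of a bulk RNA-seq eQTL
cohort; every draw flows from one integer seed through documented
sub-streams (`default_rng([seed, stream…])`), so all outputs are
bit-reproducible.

* **Abundance.** Per-gene molar abundance θ is log-normal with σ = 2 on
  the natural-log scale (heavy-tailed: most genes lowly expressed, the top
  quintile carrying ~87 % of read mass). Gene lengths are log-uniform in
  200–10,000 bp; biotypes are a configurable protein-coding fraction.
* **Genotypes.** SNP dosages are Binomial(2, MAF) — Hardy-Weinberg, no
  relatedness or population structure — with MAF uniform in (0.05, 0.5]
  by default and positions uniform in each gene's ±1 Mb cis window. Genes
  are spaced 2.5 Mb apart so windows never overlap.
* **Effects.** A configurable fraction of genes get one causal cis SNP
  with effect β on log2 abundance (default β = 0.5, residual SD 0.5, both
  on the log2 scale — mid-range for whole-blood cis-eQTLs); the genotype
  is mean-centered so dosage groups stay comparable in library
  composition. Remaining window SNPs are null, exercising leading-SNP
  selection.
* **Reads.** Counts per sample are Multinomial(T, π) with π ∝ θ·length —
  the minimal generative model consistent with TPM semantics. Library
  sizes are log-normal around a target with SD = target/3, matching the
  sample-to-sample spread of mapped reads in real cohorts.

**Depth-equivalent scaling.** A panel of G synthetic genes represents
G/45,910 of a transcriptome, so experiments scale library sizes by that
share: "10 million reads/sample" over 2,000 genes is simulated as
10 M × 2000/45910 reads. This keeps reads-per-gene — the quantity that
drives quantification accuracy — in the real regime while keeping
simulations desk-sized; coverages are always reported on the nominal
scale. Default experiment sizes (1,000–2,000 genes, 150–300 samples,
1,000 permutations) were chosen on the same principle.

What the generator does **not** model: read-level sequence content, GC or
positional bias, isoforms, correlated LD blocks beyond the causal/null
layout, batch structure, or relatedness. Tests passing on these cohorts
show the machinery and the attenuation law are correct under the stated
model; they do not certify accuracy values for any particular tissue or
library-prep protocol.

## Quantification and the coverage response

* **TPM**: `(c/L) / Σ(c/L) × 1e6`; all-zero samples map to all-zero
  columns and are logged.
* **Downsampling** is count-level binomial thinning with per-sample keep
  probability `p = target/current`: exactly the law of keeping each read
  independently, hence equivalent to read-level uniform subsampling.
  Upsampling is refused; `allow_partial=True` lets samples already below
  the target keep all reads (needed when thinning a cohort whose library
  sizes scatter around the full target). Thinning composes
  (p then q ≡ p·q) in the large-library regime.
* **Per-gene accuracy** is the squared Pearson correlation across samples
  between full and reduced TPM. Genes with zero variance in either matrix
  are excluded from the mean and tallied rather than imputed as 0 —
  Pearson is undefined there, and 0 would conflate "undetected" with
  "uncorrelated".
* **Expression filter**: kept iff TPM > 0.1 in at least ⌈0.2·n⌉ samples
  (the boundary "exactly 20 % of samples" is kept).
* **Strata**: genes ranked by mean TPM, split into quantile-balanced
  groups (sizes differ by ≤ 1, ties by gene order).
* **Response curve**: mean R² = α + β·ln(coverage), least squares over all
  replicate points, clamped to [0, 1] at evaluation; a negative slope
  triggers a warning. A saturating alternative `rmax·x/(x+κ)` is available
  behind `model="saturating"` but is not the default — the log form is the
  conventional description and fits the simulated response well on the
  1–50 M range. The mapping-rate adjustment evaluates the raw curve at
  `expected coverage = target × mapping rate`; the fit itself is on
  measured (mapped) coverages.

## Cis-eQTL mapping

Phenotype: log2(TPM + 1), residualized on an intercept, genotype PCs and
expression PCs (centered SVD with a deterministic sign convention — the
largest-magnitude loading positive). Defaults are 3 genotype and 10
expression PCs: synthetic cohorts of 100–300 samples carry no batch
structure, so burning 50 degrees of freedom on expression PCs would cost
power for nothing; both counts are parameters.

Per gene, SNPs in the ±1 Mb window (1-based inclusive, clipped at
position 1) with empirical MAF ≥ 0.01 and non-zero variance are tested by
simple OLS with two-sided t p-values; perfect fits get the minimum
representable p and a flag. The leading SNP is the minimum nominal p,
ties broken by distance to TSS, then SNP id.

Gene-level significance is a permutation pass (default 1,000 phenotype
permutations) whose statistic is the maximum |correlation| over the
window; `perm_p = (1 + #{perm ≥ obs})/(n_perm + 1)`. A Beta(a, b)
approximation fitted by MLE to the per-permutation minimum p-values is
available but off by default: at window sizes of a few dozen SNPs the
exact empirical p is affordable, so the approximation is exposed for
parity rather than speed. Either p-value can feed the FDR step
(`use_beta_approx_p`); the direct permutation p is the default.

FDR: Storey q-values, computed as π̂₀ × the Benjamini-Hochberg adjusted
p-values, with π̂₀ estimated at fixed λ = 0.5 (a cubic-polynomial smoother
over a λ grid is optional). With π̂₀ = 1 this reduces exactly to BH, which
is also available directly. eGenes are q < 0.05 by default.

Concordance between two runs on the same genotype panel reports shared
eGenes, shared leading eSNPs, squared effect correlation over same-eSNP
genes (sign-insensitive, logged), the −log10 p regression slope, and mean
LD r² between leading eSNPs.

## Budget model

`B = N·e + N·g + N·a + N·b·c/d + f` with a = library prep $/sample,
b = target coverage (million reads), c = $/lane, d = million reads/lane,
e = extraction, g = genotyping, f = fixed costs. The genotyping symbol is
`genotyping`/`g_cost` in code to avoid colliding with genotype g. Money
arithmetic is exact (`fractions.Fraction`); displayed dollars are floored.
`samples_affordable` floors `(B − f)/(per-sample cost)` — whole samples
only, which reproduces the published worked examples (1,378 at 13 M,
1,274 at 16 M under the $300 k scenario). `b` is *target* (purchased)
coverage; accuracy uses expected mapped coverage `b × mapping rate`,
reconciling lane purchasing with mapped-read accounting. The frontier is
evaluated on a default grid of 1–60 M in 0.5 M steps; the optimizer
breaks ties toward lower coverage (cheaper per sample).

## Numerical details and edge cases

* Zero-abundance genes stay exactly zero through expression and reads; a
  sample with zero total read mass can only be drawn with zero reads.
* Monomorphic SNP windows skip the gene with a log entry rather than
  erroring the whole scan.
* Collinear covariate columns are dropped via pivoted QR before
  residualization; residuals are orthogonal to retained columns to 1e-8.
* Permutation p-values are floored at 1/(n_perm+1); nominal p at the
  smallest positive float.
* The unimodality of Neff(b) is asserted after smoothing the integer-N
  staircase; plateaus from flooring are tolerated.

## Known limitations

* The generator's parameters are not calibrated to any real dataset; the
  published real-data values (eGene counts, concordance R², quintile
  accuracies) are reproduced in structure and direction only.
* The attenuation slope is compared to the *mean* per-gene R²; under
  strong heterogeneity the statistic-weighted slope sits slightly above
  it (see above), so the check uses a ±0.1 band rather than equality.
* Count-level thinning cannot reproduce read-level artifacts (duplicates,
  positional bias); it matches seqtk-style subsampling only in the
  exchangeable-reads idealization.
* Trans-eQTLs, conditional secondary signals, interaction effects and
  imputation are out of scope.
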