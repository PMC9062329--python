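# eqtl-design

Study-design analysis for expression quantitative trait locus (eQTL)
mapping with low-coverage bulk RNA-seq.

eQTL studies regress gene expression on SNP dosage; their discovery power
is limited by how many samples a sequencing budget buys. Because the
association statistic for a gene scales as `x = N * cor²(g, y)`, measuring
expression noisily — e.g. sequencing each sample at a lower depth — simply
attenuates the statistic by the squared correlation `R²` between the noisy
and the true expression: a cohort of `N` shallowly sequenced samples is
worth `Neff = R²adj · N` perfectly measured ones. Since `R²` falls slowly
with coverage (roughly logarithmically) while the affordable `N` falls
quickly, the effective sample size under a fixed budget is maximized at a
coverage far below the conventional 30–50 million reads/sample.

This package provides the full toolchain to quantify that trade-off
without any external data:

* **`eqtl_design.sim`** — a seeded synthetic-cohort generator: heavy-tailed
  (log-normal) gene abundances, Hardy-Weinberg SNP dosages in ±1 Mb cis
  windows, cis effects on log2 abundance, and length-weighted multinomial
  read sampling at realistic library sizes.
* **`eqtl_design.quantify`** — TPM computation, binomial read thinning
  (the count-level equivalent of uniform read subsampling), per-gene
  squared-correlation accuracy against full-coverage data, expression
  filtering (TPM > 0.1 in ≥ 20 % of samples), quintile stratification, and
  the `R² = α + β·ln(coverage)` response-curve fit with a mapping-rate
  adjustment (`expected coverage = target coverage × mapping rate`).
* **`eqtl_design.mapping`** — cis-eQTL scan: PCA covariates, OLS per SNP,
  gene-level permutation p-values (statistic: max |cor| over the window),
  Storey q-value / Benjamini-Hochberg FDR, leading-eSNP calling, and
  cross-dataset concordance metrics (shared eGenes, effect R², −log10 p
  slope, leading-eSNP LD).
* **`eqtl_design.power`** — the attenuation relations (`R·β`, `R²·x`,
  `Neff = R²·N`, power fold-change `1/R²`) plus an end-to-end simulation
  that validates them against the read-level generator.
* **`eqtl_design.design`** — the budget model
  `B = N·e + N·g + N·a + N·b·c/d + f`, affordable-sample inversion,
  effective-sample-size frontier over a coverage grid, optimizer, and
  cost-to-match comparisons.
* **`eqtl_design.pipeline` / `eqtl-design` CLI** — reproducible
  orchestration of all stages from a YAML config.

## Worked example

A synthetic panel of 2,000 genes stands in for a ~46,000-gene
transcriptome, so library sizes are scaled by 2000/45910 to keep per-gene
read depth — the quantity that drives quantification accuracy — equal to a
real experiment's at each nominal coverage.

```python
import numpy as np
import eqtl_design as ed
from eqtl_design.design import MappingModel

cohort = ed.simulate_cohort(
    n_genes=2000, n_samples=150, snps_per_gene=2,
    target_coverage_million=50 * 2000 / 45910,   # 50M-read-equivalent depth
    frac_egenes=0.5, beta=0.5, noise_sd=0.5, seed=11,
)

nominal = (1, 2.5, 5, 10, 25, 50)                # million reads/sample
grid = [c * 2000 / 45910 for c in nominal]
points, table = ed.coverage_response_table(
    cohort.counts, cohort.panel, grid, n_replicates=5, seed=4)
for p, nom in zip(points, np.repeat(nominal, 5)):
    p.coverage = float(nom)                      # report on the nominal scale
curve = ed.fit_coverage_response(points)

for nom, m in zip(nominal, table.groupby("coverage")["mean_r2"].mean()):
    print(f"mean R2 at {nom:>4}M reads/sample: {m:.3f}")
print(f"fitted response: R2 = {curve.alpha:.3f} + {curve.beta_ln:.3f} * ln(coverage)")

costs = ed.CostModel()   # $87 prep, $1790 per 300M-read lane, $53 genotyping, $300k
frontier = ed.effective_curve(costs, curve, MappingModel(0.6), ed.default_grid())
best = ed.optimize_coverage(frontier)
print(f"optimum under $300,000: {best.b:g}M reads/sample, "
      f"N={best.n}, R2adj={best.r2_adj:.3f}, Neff={best.n_eff:.0f}")
match = ed.cost_to_match(best.n_eff, costs, b_ref=50, comparison_budget=costs.budget)
print(f"same Neff at 50M reads/sample: N={match['n_ref']}, cost=${match['cost']:,.0f} "
      f"-> this design costs {100 * match['cost_ratio']:.1f}% of that")
```

prints

```
mean R2 at    1M reads/sample: 0.340
mean R2 at  2.5M reads/sample: 0.472
mean R2 at    5M reads/sample: 0.587
mean R2 at   10M reads/sample: 0.712
mean R2 at   25M reads/sample: 0.886
mean R2 at   50M reads/sample: 0.985
fitted response: R2 = 0.327 + 0.169 * ln(coverage)
optimum under $300,000: 8.5M reads/sample, N=1573, R2adj=0.602, Neff=947
same Neff at 50M reads/sample: N=948, cost=$415,540 -> this design costs 72.2% of that
```

Quantification accuracy decays slowly as coverage drops (R² ≈ 0.59 with a
tenth of the reads), so at a 60 % mapping rate the budget optimum sits at
8.5 million reads/sample: 1,573 shallow samples carry the statistical
power of 947 perfectly measured ones, which would cost ~1.4× as much to
obtain at 50 million reads/sample.

The same run from a shell:

```sh
eqtl-design run-all --config demo.yaml   # simulate → quantify → fit-curve → map-eqtl → design
eqtl-design power --r2 0.25,0.4,1.0      # attenuation table
eqtl-design design --curve-file runs/demo/curve.yaml --mapping-rate 0.6
```

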