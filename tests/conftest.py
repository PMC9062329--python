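import numpy as np
import pytest

import eqtl_design as ed

# nominal full coverage of the emulated experiment, million reads/sample
FULL_COVERAGE = 50.0
# a synthetic panel of G genes represents G/45910 of the transcriptome, so
# library sizes scale by that share to preserve per-gene read depth
TRANSCRIPTOME_GENES = 45_910


def scaled(coverage_million: float, n_genes: int) -> float:
    return coverage_million * n_genes / TRANSCRIPTOME_GENES


@pytest.fixture(scope="session")
def cohort():
    """Mid-size cohort with cis effects for mapping and concordance tests."""
    return ed.simulate_cohort(
        n_genes=150,
        n_samples=150,
        snps_per_gene=8,
        target_coverage_million=scaled(FULL_COVERAGE, 150),
        frac_egenes=0.5,
        beta=0.5,
        noise_sd=0.5,
        seed=21,
    )


@pytest.fixture(scope="session")
def quant_cohort():
    """Larger, genotype-light cohort for coverage-response properties."""
    return ed.simulate_cohort(
        n_genes=2000,
        n_samples=150,
        snps_per_gene=2,
        target_coverage_million=scaled(FULL_COVERAGE, 2000),
        frac_egenes=0.5,
        beta=0.5,
        noise_sd=0.5,
        seed=11,
    )
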