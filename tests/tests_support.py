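"""Shared helpers for the test suite."""

TRANSCRIPTOME_GENES = 45_910

#: nominal coverage grid (million reads/sample) of the downsampling study
NOMINAL_GRID = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0)


def scaled_grid(n_genes: int, grid=NOMINAL_GRID) -> list[float]:
    """Library sizes for a panel covering n_genes/45910 of the transcriptome."""
    return [c * n_genes / TRANSCRIPTOME_GENES for c in grid]
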