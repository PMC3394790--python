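"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from refaudit.genomic_io import GenomeCoordinate, VariantSite
from refaudit.ld_blocks import GenotypeMatrix
from refaudit.synthetic import BlockLayout, CohortSpec, simulate_cohort


def make_site(pos, ref="A", alts=("C",), genotypes=(), chrom="1", id=None):
    return VariantSite(
        coord=GenomeCoordinate(chrom, pos),
        ref=ref,
        alts=list(alts),
        genotypes=list(genotypes),
        id=id,
    )


@pytest.fixture
def small_cohort():
    """Two planted 10-marker blocks, 100 samples, no missingness."""
    spec = CohortSpec(
        n_samples=100,
        blocks=tuple(BlockLayout() for _ in range(2)),
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def random_matrix(rng, n_markers=20, n_samples=30, missing_rate=0.0, spacing=100):
    """An unstructured genotype matrix for oracle comparisons."""
    dosage = rng.integers(0, 3, size=(n_markers, n_samples)).astype(np.int8)
    if missing_rate:
        dosage[rng.random(dosage.shape) < missing_rate] = -1
    markers = [
        (GenomeCoordinate("1", 1000 + spacing * k), "A", "G")
        for k in range(n_markers)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        markers=markers,
        dosage=dosage,
    )
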