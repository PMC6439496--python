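import numpy as np
import pytest

from goshawkpop.core import GenotypeMatrix, SiteRecord


def make_matrix(dosage, quality=None, sample_ids=None, sites=None, spacing=1000):
    """GenotypeMatrix from a plain dosage array, with generated ids/sites."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    if sites is None:
        sites = [
            SiteRecord("scaffold_001", (j + 1) * spacing, "A", "G")
            for j in range(m)
        ]
    return GenotypeMatrix(sample_ids, sites, dosage, quality)


@pytest.fixture
def two_pop_matrix():
    """Two drifted populations (20 + 20 samples, 800 SNPs) without missingness."""
    from goshawkpop.simulate import (
        SimulationConfig,
        simulate_allele_frequencies,
        simulate_genotypes,
    )

    cfg = SimulationConfig(
        n_sites=800,
        region_sizes={"HG": 20, "East": 20},
        drift_F={"HG": 0.08, "East": 0.08},
        source_tiers={"HG": {"tissue": 1.0}, "East": {"tissue": 1.0}},
        seed=3,
    )
    g, meta = simulate_genotypes(simulate_allele_frequencies(cfg), cfg)
    return g, meta
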