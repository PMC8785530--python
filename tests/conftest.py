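import numpy as np
import pytest
from hypothesis import settings

import lactoqtl as lq

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_study():
    """Small mixed-breed study with one strong planted recessive QTL."""
    cfg = lq.PopulationConfig(
        n_animals=700, n_structure_snps=100, n_dense_variants=260,
        n_chromosomes=2, chrom_length_bp=30_000_000, seed=42,
    )
    pools = lq.simulate_haplotype_pools(cfg)
    pos = int(pools.variants.query("chrom == 1 and panel == 'test'")["pos"].iloc[20])
    specs = [lq.QTLSpec(chrom=1, pos=pos, maf_target=0.2, a_true=-0.5, d_true=0.5)]
    return lq.simulate_study(cfg, specs, h2=0.25, delta2=0.04)


@pytest.fixture(scope="session")
def small_scan(small_study):
    """DominanceScan fit of the small study (shared; treat as read-only)."""
    scan = lq.DominanceScan(n_retained=200, burn_in=150, thin=1, seed=9)
    scan.fit(small_study.genotypes, small_study.phenotypes)
    return scan
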