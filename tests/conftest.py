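import numpy as np
import pandas as pd
import pytest

from csskit import HaplotypePanel


def make_panel(haps, positions=None, chroms=None, breeds=None, snp_ids=None):
    """Build a small panel from an explicit haplotype matrix.

    ``haps`` has 2 rows per sample; samples are named s1, s2, ...
    """
    haps = np.asarray(haps, dtype=np.int8)
    n_snps = haps.shape[1]
    n_samples = haps.shape[0] // 2
    positions = np.arange(1, n_snps + 1) * 10_000 if positions is None else positions
    chroms = np.ones(n_snps, int) if chroms is None else np.asarray(chroms)
    if snp_ids is None:
        snp_ids = [f"s{c}_{p}" for c, p in zip(chroms, positions)]
    bases_a = ["A"] * n_snps
    bases_d = ["G"] * n_snps
    snp_map = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "snp_id": snp_ids,
         "ancestral": bases_a, "derived": bases_d}
    )
    if breeds is None:
        breeds = ["BR1"] * n_samples
    samples = pd.DataFrame(
        {"sample_id": [f"s{i+1}" for i in range(n_samples)],
         "breed": breeds, "cattle_type": ["test"] * n_samples}
    )
    return HaplotypePanel(snp_map, haps, samples)


@pytest.fixture
def toy_panel():
    """4 samples x 5 SNPs with hand-enumerable dosages."""
    haps = [
        [0, 1, 1, 0, 1],
        [0, 1, 0, 0, 1],
        [0, 0, 1, 1, 0],
        [0, 0, 0, 1, 0],
        [0, 1, 1, 0, 1],
        [0, 1, 0, 0, 1],
        [0, 0, 0, 1, 1],
        [0, 1, 0, 0, 1],
    ]
    return make_panel(haps, breeds=["BR1", "BR1", "BR2", "BR2"])


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated panel with strong selection, reused across tests."""
    from csskit import SimConfig, simulate_panel, simulate_phenotypes

    cfg = SimConfig(
        seed=42, n_chromosomes=3, chrom_length_bp=30_000_000,
        n_snps_per_chrom=300, n_breeds=12, samples_per_breed=6,
        n_generations_drift=15, effective_size_per_breed=30,
        trait_loci=[(1, 15_000_000, 5.0), (2, 15_000_000, -5.0)],
    )
    panel, truth = simulate_panel(cfg)
    pheno = simulate_phenotypes(truth, cfg)
    return cfg, panel, truth, pheno
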