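import numpy as np
import pandas as pd
import pytest

from selsig import GenotypeDataset, SimConfig, SelectedCluster, generate


def make_dataset(genotypes, chroms=None, positions=None, breeds=None,
                 groups=None):
    """Hand-build a small GenotypeDataset from a dosage matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    chroms = chroms if chroms is not None else [1] * m
    positions = positions if positions is not None else [
        1000 * (i + 1) for i in range(m)]
    breeds = breeds if breeds is not None else ["B1"] * n
    groups = groups if groups is not None else ["G1"] * n
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": chroms, "pos": positions, "a1": "A", "a2": "B"})
    animals = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(n)],
        "breed": breeds, "group": groups})
    return GenotypeDataset(g, animals, snps)


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-group panel used by fast module tests."""
    return SimConfig(
        breeds=[("B1", "MEAT", 15), ("B2", "MEAT", 15),
                ("B3", "MILK", 15), ("B4", "MILK", 15)],
        n_chromosomes=2, snps_per_chromosome=300,
        chromosome_length_bp=30_000_000,
        selected_clusters=[SelectedCluster(1, 150, 20, 0.6)],
        missing_rate=0.01, seed=7)


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    return generate(tiny_config)
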