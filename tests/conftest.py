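"""Shared fixtures: small random panels and one structured simulated panel."""

import numpy as np
import pandas as pd
import pytest

from gpsmap.io_formats import GenotypeMatrix
from gpsmap.lmm_core import compute_grm
from gpsmap.sim_forward import Scenario, sample_individuals, simulate_scenario


def make_random_geno(n: int, m: int, seed: int = 0,
                     maf_low: float = 0.1) -> GenotypeMatrix:
    """Unstructured binomial-dosage panel (no LD, no relatedness)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, 0.5, m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    snps = pd.DataFrame({
        "chrom": "1", "pos_bp": np.arange(1, m + 1) * 1000,
        "id": [f"s{i}" for i in range(m)],
        "allele1": "A", "allele0": "B",
    })
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps, dosage)


@pytest.fixture(scope="session")
def random_geno():
    return make_random_geno(300, 2000, seed=11)


@pytest.fixture(scope="session")
def random_grm(random_geno):
    return compute_grm(random_geno)


@pytest.fixture(scope="session")
def sim_panel():
    """One small selection-scenario panel with truth, reused across tests."""
    scenario = Scenario(
        n_chrom=2, sites_per_chrom=2000, n_founders=500, ne_target=100,
        n_qtl=20, n_crosses=600, n_generations=8, burn_in=3,
        selection="tbv_truncation", n_sampled=600,
        n_males_selected=30, n_females_selected=250, seed=1234)
    truth = simulate_scenario(scenario)
    geno, samples = sample_individuals(truth, seed=1234)
    return truth, geno, samples
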