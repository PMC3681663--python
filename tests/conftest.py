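import pandas as pd
import pytest

from transrep.synthetic_data import (
    DbSimConfig,
    HapSimConfig,
    gen_replication_database,
    gen_two_pop_haplotypes,
)


@pytest.fixture(scope="session")
def small_db():
    """A modest synthetic database with mixed sharing (seeded)."""
    return gen_replication_database(
        DbSimConfig(n_diseases=10, assoc_per_disease=4, pi_share=0.7, seed=11)
    )


@pytest.fixture(scope="session")
def drifted_panels():
    """A two-population region with typical drift (650 SNPs, seeded)."""
    return gen_two_pop_haplotypes(HapSimConfig(seed=7))


@pytest.fixture(scope="session")
def exchangeable_panels():
    """Two panels sampled from one pool (no drift): exchangeable."""
    return gen_two_pop_haplotypes(
        HapSimConfig(seed=13, drift_generations=0, n_snps=120,
                     n_per_pop=40, n_hap_pool=600)
    )


@pytest.fixture()
def toy_attempts():
    """Ten attempts over three SNPs with hand-set sizes and powers."""
    return pd.DataFrame({
        "snp_id": ["rs1"] * 4 + ["rs2"] * 3 + ["rs3"] * 3,
        "replication_study_id": [f"S{i}" for i in range(10)],
        "ancestry": ["EastAsian"] * 10,
        "or_replication": [1.2, 1.1, 0.95, 1.3, 1.15, 1.05, 1.2, 0.9, 1.0, 1.4],
        "p_replication": [0.01, 0.2, 0.6, 0.001, 0.03, 0.4, 0.02, 0.7, 1.0,
                          0.004],
        "n_cases": [500, 1000, 2500, 800, 1200, 600, 700, 900, 1100, 1300],
        "n_controls": [500, 1000, 2500, 800, 1200, 600, 700, 900, 1100, 1300],
        "raf_replication_pop": [0.3] * 10,
        "allele_shift_flag": [False] * 10,
        "power": [0.5, 0.8, 0.95, 0.7, 0.85, 0.55, 0.6, 0.75, 0.8, 0.9],
        "success": [True, False, False, True, True, False, True, False,
                    False, True],
    })
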