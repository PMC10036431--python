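import numpy as np
import pandas as pd
import pytest

import pgsrisk as pr


@pytest.fixture(scope="session")
def adult_config():
    return pr.SimulationConfig(cohort_design="adult", n_individuals=800,
                               n_variants=120, seed=11)


@pytest.fixture(scope="session")
def adult_genotypes(adult_config):
    return pr.simulate_genotypes(adult_config)


@pytest.fixture(scope="session")
def adult_truth(adult_genotypes, adult_config):
    return pr.draw_true_effects(adult_genotypes, adult_config)


@pytest.fixture(scope="session")
def adult_cohort(adult_genotypes, adult_truth, adult_config):
    return pr.simulate_cohort(adult_genotypes, adult_truth, adult_config)


@pytest.fixture(scope="session")
def adult_sumstats(adult_genotypes, adult_config):
    return pr.simulate_summary_stats(adult_genotypes, adult_config, 200_000)


@pytest.fixture
def toy_genotypes():
    """5 samples x 3 variants with fixed dosages for hand calculations."""
    variants = pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "pos": [1000, 5000, 1000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
    })
    dosages = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 1.0, 0.0],
        [2.0, 0.0, 1.0],
        [0.5, 2.0, 1.5],
        [1.0, 1.0, 1.0],
    ])
    return pr.GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(5)],
        variants=variants, dosages=dosages,
        info_scores=np.array([0.9, 0.95, 0.99]),
        eaf=np.array([0.3, 0.4, 0.5]),
    )
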