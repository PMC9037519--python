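import numpy as np
import pandas as pd
import pytest

import gutmint as gm


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = gm.SynthConfig(
        n_per_class=30,
        n_species=50,
        n_families=12,
        n_metabolites=20,
        n_informative_taxa=5,
        n_informative_metabolites=4,
        n_subgroup_taxa=6,
        n_subgroup_metabolites=4,
        effect_size=1.0,
        n_subgroups=2,
        subgroup_shift=1.0,
        n_pheno_continuous=10,
        n_pheno_binary=5,
        n_pheno_linked=2,
        missing_rate=0.1,
        seed=42,
    )
    return gm.generate_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_feature_table():
    data = pd.DataFrame(
        {
            "sp1": [0.3, 0.1, 0.5],
            "sp2": [0.2, 0.4, 0.1],
            "sp3": [0.5, 0.5, 0.4],
        },
        index=["a", "b", "c"],
    )
    return gm.FeatureTable(data, blocks="taxon", rank="species")
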