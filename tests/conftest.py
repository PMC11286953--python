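import numpy as np
import pandas as pd
import pytest

import demoscan as d
from demoscan.pipeline import published_run_ensemble

SAMPLES_PER_STAND = {"N3": 21, "N4": 25, "S1": 24, "S5": 26}


@pytest.fixture
def toy_dataset():
    """Two regions, three SNPs, two stands of two diploids each."""
    genotypes = np.array(
        [[0, 1, 2, 0], [1, 1, -1, 0], [0, 0, 1, 2]], dtype=np.int8
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["N3_000", "N3_001", "S5_000", "S5_001"],
            "stand": ["N3", "N3", "S5", "S5"],
            "slope": ["N", "N", "S", "S"],
        }
    )
    sites = pd.DataFrame({"region": ["regA", "regA", "regB"], "pos": [10, 40, 7]})
    regions = pd.DataFrame(
        {"length": [100, 50]}, index=pd.Index(["regA", "regB"], name="region")
    )
    return d.GenotypeDataset(genotypes, samples, sites, regions)


@pytest.fixture(scope="session")
def study_design():
    return d.StudyDesign(n_regions=300)


@pytest.fixture(scope="session")
def neutral_small(study_design):
    """One neutral draw at the published parameter medians (reduced scale)."""
    return d.generate_neutral_dataset(study_design, d.PUBLISHED_MEDIANS, seed=101)


@pytest.fixture(scope="session")
def resampled_params():
    """Reduced-scale parameter-uncertainty ensemble (10 resampled sets)."""
    ens = published_run_ensemble(n=30, seed=11)
    blocks = d.correlation_blocks(ens, r_threshold=0.7)
    return d.resample_parameter_sets(ens, blocks, n=10, seed=12)


@pytest.fixture(scope="session")
def null_small(resampled_params):
    """Compiled neutral reference at the reduced 10 x 50-fragment scale."""
    return d.build_neutral_reference(
        resampled_params, fragments_per_set=50,
        sample_sizes=SAMPLES_PER_STAND, seed=13,
    )


@pytest.fixture(scope="session")
def null_power(resampled_params):
    """Larger compiled null (10 x 300 fragments) for power studies."""
    return d.build_neutral_reference(
        resampled_params, fragments_per_set=300,
        sample_sizes=SAMPLES_PER_STAND, seed=13,
    )
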