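import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from specdelim import syndata


@pytest.fixture(scope="session")
def small_config():
    """Three groups, three diploid individuals each, short loci — enough
    structure for every stage while staying fast."""
    return syndata.default_config(
        seed=11,
        n_groups=3,
        species_tree_depths=(1.5, 3.0),
        n_individuals_per_group=3,
        locus_lengths=(200, 180, 180, 180),
        landmark_mean_shapes=syndata.default_mean_shapes(3),
        feature_group_means=syndata.default_feature_params(3)[0],
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return syndata.simulate_genetic_data(small_config)


@pytest.fixture(scope="session")
def small_reads(small_truth, small_config):
    return syndata.simulate_amplicon_reads(small_truth, small_config)
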