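import numpy as np
import pytest

import srnascape as s
from srnascape.pipeline import PipelineConfig, run_pipeline


SMALL_CONFIG = dict(
    genome_length=60_000,
    n_cds=40,
    n_rrna=1,
    n_trna=2,
    n_srna_per_class={"intra": 8, "as": 3, "inter": 2, "intra_as": 1},
)


@pytest.fixture(scope="session")
def landscape():
    """Full-scale synthetic landscape: 200 kb genome, 60 planted sRNAs,
    default noise, fixed seed — shared by the recovery and motif tests."""
    dataset = s.generate_dataset(s.SyntheticConfig(seed=1))
    result = run_pipeline(PipelineConfig(), dataset=dataset)
    return dataset, result


@pytest.fixture(scope="session")
def small_dataset():
    return s.generate_dataset(s.SyntheticConfig(seed=3, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_noise_free():
    dataset = s.generate_dataset(s.SyntheticConfig(seed=3, noise=0.0, **SMALL_CONFIG))
    result = run_pipeline(PipelineConfig(), dataset=dataset)
    return dataset, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
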