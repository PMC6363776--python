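import pytest
from hypothesis import settings

from lncrep.pipeline import run_all
from lncrep.simulate import SimulationSpec, generate, make_fixture

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny():
    """Small single-chromosome dataset, both cell types stranded."""
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def paper_like():
    """Scaled-down study design: 3 vs 2 ATAC replicates, non-stranded B."""
    return make_fixture("paper_like", seed=0)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Noise-free generation plus a full pipeline run over it."""
    dataset = generate(SimulationSpec(seed=1).zero_noise())
    return dataset, run_all(dataset)
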