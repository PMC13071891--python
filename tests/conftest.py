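import pytest
from hypothesis import HealthCheck, settings

from nanohgt.synthdata import SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """The reference synthetic dataset: seed 1, 200 native / 20 HGT /
    10 contaminant genes, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(SimConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def sim_truth(sim_dataset):
    return sim_dataset.truth
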