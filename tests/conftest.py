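import pytest
from hypothesis import HealthCheck, settings

from bivseq.pipeline import classify_promoters
from bivseq.synthetic_data import SimConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A fast small-scale simulation configuration for unit tests."""
    defaults = dict(n_genes=120, chrom_length=1_440_000, seed=seed)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One full-size simulation at the default study-like conditions."""
    outdir = tmp_path_factory.mktemp("sim_default")
    return simulate(SimConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def default_classification(default_sim):
    """Full pipeline run (enrichment + classification) on the default simulation."""
    p = default_sim.paths
    return classify_promoters(
        p["genes"], p["k4_ip"], p["k27_ip"], p["k4_input"], p["k27_input"]
    )
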