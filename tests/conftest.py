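import pytest

from socialmass import PartitionModel, RunConfig, profile_from_caption, simulate


@pytest.fixture(scope="session")
def model():
    return PartitionModel()


@pytest.fixture(scope="session")
def fig3_run():
    """Deterministic long run of the slow-losing male preset (Forbes)."""
    cfg = RunConfig(profile=profile_from_caption("fig3"), horizon_days=4000)
    return simulate(cfg)


@pytest.fixture(scope="session")
def fig4_run():
    """Deterministic long run of the slow-gaining female preset (Forbes)."""
    cfg = RunConfig(profile=profile_from_caption("fig4"), horizon_days=4000)
    return simulate(cfg)
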