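import pytest

from epimem import synthetic as syn


@pytest.fixture(scope="session")
def base_cfg():
    return syn.SimConfig(
        seed=1,
        planted_dmr_genes=("GENE0001",),
        planted_lost_peak_genes=("GENE0001",),
    )


@pytest.fixture(scope="session")
def scenario(base_cfg):
    """Default end-to-end scenario: only GENE0001 planted in both layers."""
    return syn.generate_scenario(base_cfg)


@pytest.fixture(scope="session")
def annotation(scenario):
    return scenario.annotation


@pytest.fixture(scope="session")
def manifest(scenario):
    return scenario.manifest
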