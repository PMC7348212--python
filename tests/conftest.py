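import pytest

from cablecensus import ScenarioSpec, gen_porewater, load_qpcr_primers


@pytest.fixture(scope="session")
def qpcr_primers():
    return load_qpcr_primers()


@pytest.fixture(scope="session")
def electrogenic_spec():
    return ScenarioSpec(seed=11)


@pytest.fixture(scope="session")
def electrogenic_profiles(electrogenic_spec):
    return gen_porewater(electrogenic_spec)
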