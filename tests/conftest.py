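import pytest

from rnplc import hcip, tmt
from rnplc.simulate import SimConfig, make_truth, simulate_ip


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def truth(default_config):
    return make_truth(default_config)


@pytest.fixture(scope="session")
def raw_table(truth, default_config):
    return simulate_ip(truth, default_config)


@pytest.fixture(scope="session")
def norm_table(raw_table):
    return tmt.normalize(raw_table)


@pytest.fixture(scope="session")
def failed_report(norm_table):
    return tmt.flag_failed_ips(norm_table)


@pytest.fixture(scope="session")
def typed_edges(norm_table, failed_report):
    edges, _ = hcip.call_all_baits(norm_table, failed_report)
    return edges
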