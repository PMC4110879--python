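import pytest

from spikeoc import scenario_a, scenario_b, scenario_c, scenario_d_sim


@pytest.fixture(scope="session")
def proto_a():
    return scenario_a()


@pytest.fixture(scope="session")
def trace_a(proto_a):
    return proto_a.run(0)


@pytest.fixture(scope="session")
def proto_b():
    return scenario_b()


@pytest.fixture(scope="session")
def trace_b(proto_b):
    return proto_b.run(0)


@pytest.fixture(scope="session")
def proto_c():
    return scenario_c()


@pytest.fixture(scope="session")
def trace_c(proto_c):
    return proto_c.run(0)


@pytest.fixture(scope="session")
def scenario_d_runs():
    """(protocol, trace) per seed for the reinforced conveyor task."""
    out = {}
    for seed in range(5):
        proto = scenario_d_sim(seed, n_pieces=60)
        out[seed] = (proto, proto.run(seed))
    return out
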