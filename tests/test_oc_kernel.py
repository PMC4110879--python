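"""Structure and invariants of the OC kernel and its compositions."""

import pandas as pd
import pytest

from spikeoc.network import ConfigurationError, run
from spikeoc.oc_kernel import (
    build_dual_kernel,
    build_kernel,
    build_multicue_kernels,
    kernel_census,
    predictor_fire_weight,
)
from spikeoc.scenarios import scenario_a, scenario_b, scenario_c, scenario_d_sim


def test_kernel_census_three_neurons_three_synapses_two_rules():
    _, kernel = build_kernel("vibration", "light", "emit-sound")
    assert kernel_census(kernel) == {
        "neurons": 3, "inner_synapses": 3,
        "habituation_rules": 1, "stdp_rules": 1,
    }


def test_outer_box_two_transducers_one_actuator_three_outer_synapses():
    net, kernel = build_kernel("vibration", "light", "emit-sound")
    assert len(net.transducers) == 2
    assert len(net.actuators) == 1
    inner = {s.key for s in kernel.inner_synapses}
    outer = [s for s in net.synapses if s.key not in inner]
    assert len(outer) == 3


def test_default_weights_satisfy_the_ordering_invariant():
    _, kernel = build_kernel("vibration", "light", "emit-sound")
    assert (kernel.cue_action.weight > kernel.predictor_action.weight
            > kernel.cue_predictor.weight)


@pytest.mark.parametrize("override, fragment", [
    ({"cue_action_weight": 10}, "cue->action"),
    ({"cue_predictor_weight": 95}, "cue->predictor"),
])
def test_ordering_violations_name_the_broken_inequality(override, fragment):
    with pytest.raises(ConfigurationError, match=fragment):
        build_kernel("vibration", "light", "emit-sound", weights=override)


def test_punishment_polarity_inverts_the_motor_coupling():
    net, kernel = build_kernel("vibration", "light", "emit-sound",
                               polarity="punishment-avoiding")
    motor_link = net.synapse(kernel.action, "motor")
    assert motor_link.polarity == "inhibitory"


def test_dual_kernel_census_one_predictor_per_reinforcer():
    net, kernels = build_dual_kernel("vibration", "light", "heat", "emit-sound")
    assert kernels["reward"].predictor != kernels["punishment"].predictor
    assert kernels["reward"].cue == kernels["punishment"].cue
    for k in kernels.values():
        k.validate()
    # one inhibitory interneuron per direction
    inhib = [s for s in net.synapses if s.polarity == "inhibitory"
             and s.pre.startswith("inhib")]
    assert len(inhib) == 2


def test_dual_kernel_with_silent_punishment_matches_single_kernel(proto_a, trace_a):
    proto = scenario_b()
    proto.world = proto_a.world  # scenario A world: punishment never delivered
    proto.cycles = proto_a.cycles
    dual_trace = proto.run(0)
    shared = [c for c in trace_a.columns if c in dual_trace.columns]
    assert any(c.startswith("spike_") for c in shared)
    pd.testing.assert_frame_equal(dual_trace[shared], trace_a[shared])


def test_multicue_shares_one_action_with_independent_habituation():
    net, kernels = build_multicue_kernels(["color-green", "color-red"], "arm-down")
    cues = {k.cue for k in kernels.values()}
    actions = {k.action for k in kernels.values()}
    assert len(cues) == 2 and actions == {"action"}
    assert len(kernels) == 2  # reward-only: one predictor per cue
    habs = [k.cue_action.habituation for k in kernels.values()]
    assert habs[0] is not habs[1]
    # per-cue transducers carry sensory adaptation
    cue_trs = [t for t in net.transducers if t.channel.startswith("color-")]
    assert all(t.adaptation is not None for t in cue_trs)


def test_multicue_requires_at_least_two_cues():
    with pytest.raises(ConfigurationError):
        build_multicue_kernels(["color-green"], "arm-down")


def test_inner_box_is_isomorphic_across_all_scenarios():
    signatures = set()
    for proto in (scenario_a(), scenario_b(), scenario_c(), scenario_d_sim(0)):
        for kernel in proto.kernels.values():
            if kernel.polarity == "reward-seeking":
                signatures.add(kernel.signature())
    assert len(signatures) == 1
    punishment = {k.signature() for proto in (scenario_b(), scenario_c())
                  for k in proto.kernels.values() if k.polarity != "reward-seeking"}
    assert len(punishment) == 1


def test_predictor_fire_weight_is_between_weak_and_intermediate():
    from spikeoc.defaults import DEFAULTS
    threshold = predictor_fire_weight()
    assert DEFAULTS["cue_predictor_weight"] < threshold <= DEFAULTS["cue_action_weight"]
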