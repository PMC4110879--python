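"""Closed-loop scenario protocols, classification and calibration."""

import numpy as np
import pandas as pd
import pytest

from spikeoc.defaults import DEFAULTS
from spikeoc.scenarios import (
    ABLATIONS,
    CalibrationConstraintSet,
    CalibrationFailure,
    SCENARIO_C_ZONES,
    action_cycles,
    calibrate_defaults,
    classify_phases,
    crossing_cycle,
    reflex_cessation_cycle,
    run_ablation,
    scenario_a,
    scenario_c,
    scenario_d_sim,
)


# ---------------------------------------------------------------------------
# Scenario A
# ---------------------------------------------------------------------------

def test_scenario_a_reflex_ceases_near_cycle_100(proto_a, trace_a):
    cessation = reflex_cessation_cycle(trace_a, proto_a)
    assert 85 <= cessation <= 115


def test_scenario_a_cue_driven_prediction_absent_early(proto_a, trace_a):
    # the cue->predictor weight stays below the predictor-firing threshold
    # through most of the initial reflex period
    cross = crossing_cycle(trace_a, proto_a.key_synapse, proto_a.fire_threshold)
    assert cross is not None and cross >= 85


def test_scenario_a_behavior_persists_after_reward_removal(proto_a, trace_a):
    lights = trace_a.loc[trace_a.stim_light > 0, "cycle"]
    assert lights.max() < 180  # reward discontinued at cycle 175 (plus latency)
    acts = action_cycles(trace_a, proto_a.action)
    assert any(acts >= 185)


def test_scenario_a_phase_classification(proto_a, trace_a):
    assert classify_phases(trace_a, proto_a).labels() == proto_a.expected


def test_first_reinforced_pairing_strictly_increases_weight(proto_a, trace_a):
    wcol = f"w_{proto_a.key_synapse}"
    first_light = int(trace_a.loc[trace_a.stim_light > 0, "cycle"].iloc[0])
    window = DEFAULTS["stdp_window"]
    after = trace_a.loc[trace_a.cycle <= first_light + window + 5, wcol]
    assert after.max() > after.iloc[0]


def test_contingent_reinforcer_always_follows_an_action(proto_a, trace_a):
    acts = set(action_cycles(trace_a, proto_a.action))
    latency = DEFAULTS["reinforcer_latency"]
    for pulse in trace_a.loc[trace_a.stim_light > 0, "cycle"]:
        assert (pulse - latency) in acts


def test_classifier_handles_empty_trace_and_ignores_column_order(proto_a, trace_a):
    zero = trace_a.copy()
    for col in zero.columns:
        if col != "cycle":
            zero[col] = np.where(col.startswith("w_"), zero[col].iloc[0], 0)
    report = classify_phases(zero, proto_a)
    assert all(p.classification == "none" for p in report.phases)
    shuffled = trace_a[list(reversed(trace_a.columns))]
    assert classify_phases(shuffled, proto_a).labels() == \
        classify_phases(trace_a, proto_a).labels()


def test_classifier_rejects_mismatched_trace(proto_a, trace_a):
    with pytest.raises(ValueError, match="missing column"):
        classify_phases(trace_a.drop(columns=[f"act_{proto_a.action}"]), proto_a)


# ---------------------------------------------------------------------------
# The four control situations
# ---------------------------------------------------------------------------

def test_ablation_without_habituation_the_action_never_stops(proto_a):
    report, trace = run_ablation(proto_a, "no-habituation")
    for phase in report.phases:
        assert phase.action_count > 0


def test_ablation_without_stdp_reward_is_always_required(proto_a):
    report, trace = run_ablation(proto_a, "no-stdp")
    acts = action_cycles(trace, proto_a.action)
    assert len(acts) > 0
    assert acts.max() < 200          # stops shortly after reward removal at 175
    assert report.phase("expectation").action_count <= 1
    assert (trace[f"w_{proto_a.key_synapse}"] == trace[f"w_{proto_a.key_synapse}"].iloc[0]).all()


def test_ablation_reversed_timing_depresses_and_stops(proto_a):
    report, trace = run_ablation(proto_a, "reward-precedes-action")
    wcol = f"w_{proto_a.key_synapse}"
    supervised = trace.loc[trace.cycle < 175, wcol]
    assert supervised.iloc[-1] < supervised.iloc[0]
    assert report.phase("late").action_count == 0


def test_ablation_cue_removed_extinguishes_the_association(proto_a):
    report, trace = run_ablation(proto_a, "cue-removed")
    acts = action_cycles(trace, proto_a.action)
    assert acts.max() <= 160
    wcol = f"w_{proto_a.key_synapse}"
    assert trace[wcol].iloc[-1] == trace[wcol].iloc[0]  # back to baseline
    assert trace[wcol].max() > trace[wcol].iloc[0]      # after having learned
    assert "extinction" in report.labels().values()


def test_unknown_ablation_is_rejected(proto_a):
    with pytest.raises(ValueError):
        run_ablation(proto_a, "no-coffee")


# ---------------------------------------------------------------------------
# Scenario B
# ---------------------------------------------------------------------------

def test_scenario_b_acquisition_expectation_then_reversal(proto_b, trace_b):
    acts = action_cycles(trace_b, proto_b.action)
    assert sum(acts < 250) > 0
    assert sum((acts >= 250) & (acts < 500)) > 0
    assert sum(acts >= 750) == 0
    heat = trace_b.loc[trace_b.stim_heat > 0, "cycle"]
    assert heat.min() >= 500


def test_scenario_b_punishment_predictor_fires_without_punishment(proto_b, trace_b):
    tail = trace_b[trace_b.cycle >= 800]
    assert tail["spike_predictor_p"].sum() > 0
    assert (tail["stim_heat"] == 0).all()


def test_scenario_b_phase_labels(proto_b, trace_b):
    labels = classify_phases(trace_b, proto_b).labels()
    for name, expected in proto_b.expected.items():
        assert labels[name] == expected, (name, labels)


# ---------------------------------------------------------------------------
# Scenario C
# ---------------------------------------------------------------------------

def zone_presses(trace, n_zones=8, per_zone=100):
    return [int(trace[(trace.cycle >= i * per_zone)
                      & (trace.cycle < (i + 1) * per_zone)]["press"].sum())
            for i in range(n_zones)]


def test_scenario_c_has_eight_zones(proto_c):
    assert len(SCENARIO_C_ZONES) == 8
    assert len(proto_c.phases) == 8


def test_scenario_c_end_state_presses_red_avoids_green(trace_c):
    presses = zone_presses(trace_c)
    final_green = [p for p, color in zip(presses, SCENARIO_C_ZONES)
                   if color == "green"][-1]
    final_red = [p for p, color in zip(presses, SCENARIO_C_ZONES)
                 if color == "red"][-1]
    assert final_green == 0
    assert final_red > 0


def test_scenario_c_without_reinforcement_presses_fade_and_recover():
    proto = scenario_c(reinforced=False)
    trace = proto.run(0)
    presses = zone_presses(trace)
    assert presses[0] > 0 and presses[1] > 0      # responds to each fresh color
    assert sum(presses[4:]) < sum(presses[:4])    # overall fading
    # within the first zone, pressing stops before the zone ends
    first = trace[(trace.cycle < 100) & (trace.press > 0)]["cycle"]
    assert first.max() < 80


# ---------------------------------------------------------------------------
# Scenario D (simulated conveyor)
# ---------------------------------------------------------------------------

def test_scenario_d_steady_state_sorts_by_color(scenario_d_runs):
    for seed, (proto, _) in scenario_d_runs.items():
        world = proto.world
        cut = world.piece_onsets[35]
        assert world.ejection_rate("red", skip_first=cut) == 1.0, seed
        assert world.ejection_rate("blue", skip_first=cut) == 0.0, seed


def test_scenario_d_reinforcer_beyond_stdp_window_learns_nothing():
    proto = scenario_d_sim(0, touch_latency=DEFAULTS["stdp_window"] + 5, n_pieces=40)
    trace = proto.run(0)
    wcol = f"w_{proto.key_synapse}"
    assert (trace[wcol] == trace[wcol].iloc[0]).all()


def test_scenario_d_without_reinforcement_ejection_fades():
    proto = scenario_d_sim(1, reinforced_color=None, n_pieces=60)
    proto.run(1)
    world = proto.world
    mid = world.piece_onsets[30]
    for color in ("red", "blue"):
        early = world.ejection_rate(color)
        late = world.ejection_rate(color, skip_first=mid)
        assert late < 1.0 and late <= early


# ---------------------------------------------------------------------------
# Calibration harness
# ---------------------------------------------------------------------------

def test_calibration_reproduces_the_shipped_defaults():
    bundle = calibrate_defaults()
    for key, value in bundle.items():
        assert DEFAULTS[key] == value, key


def test_overtight_constraints_fail_with_named_constraint():
    with pytest.raises(CalibrationFailure, match="cessation"):
        calibrate_defaults(CalibrationConstraintSet(cessation_window=(0, 1),
                                                    check_scenario_b=False,
                                                    check_scenario_d=False))
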