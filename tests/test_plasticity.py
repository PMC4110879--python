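"""Sensory adaptation, habituation and STDP rule dynamics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeoc.plasticity import (
    AdaptationState,
    HabituationState,
    StdpState,
    apply_adaptation,
    apply_habituation,
    apply_stdp,
    build_stdp_curves,
)


# ---------------------------------------------------------------------------
# Sensory adaptation
# ---------------------------------------------------------------------------

def test_adaptation_decays_under_constant_stimulus():
    state = AdaptationState()
    values = []
    for _ in range(30):
        apply_adaptation(state, True)
        values.append(state.efficacy)
    assert values[-1] < 100
    assert all(b <= a for a, b in zip(values, values[1:]))


def test_adaptation_fully_recovers_after_stimulus_removal():
    state = AdaptationState(efficacy=0)
    for _ in range(200):
        apply_adaptation(state, False)
    assert state.efficacy == 100


def test_sparse_stimulus_leaves_adaptation_essentially_intact():
    # 1 cycle on / 20 off: the fast recovery dominates at low duty cycle
    state = AdaptationState()
    for _ in range(10):
        apply_adaptation(state, True)
        for _ in range(20):
            apply_adaptation(state, False)
    assert state.efficacy >= 95


# ---------------------------------------------------------------------------
# Habituation
# ---------------------------------------------------------------------------

def run_habituation(spike_cycles, total):
    state = HabituationState()
    spikes = set(spike_cycles)
    series = []
    for cycle in range(total):
        apply_habituation(state, cycle in spikes, cycle)
        series.append(state.efficacy)
    return state, series


def test_periodic_input_drives_efficacy_monotonically_down():
    state, series = run_habituation(range(0, 100, 5), 100)
    assert series[-1] < series[0]
    assert all(b <= a for a, b in zip(series, series[1:]))
    assert all(state.floor <= v <= 100 for v in series)


def test_shorter_isi_habituates_at_least_as_deeply():
    n = 12
    fast, _ = run_habituation(range(0, 2 * n, 2), 2 * n)
    slow, _ = run_habituation(range(0, 10 * n, 10), 10 * n)
    assert fast.efficacy <= slow.efficacy


def test_full_recovery_after_the_recovery_horizon():
    state, _ = run_habituation(range(0, 100, 5), 100)
    start = 100
    for cycle in range(start, start + state.recovery_horizon + 1):
        apply_habituation(state, False, cycle)
    assert state.efficacy == 100


@settings(max_examples=100, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=300))
def test_habituation_bounded_for_any_input_stream(stream):
    state = HabituationState()
    for cycle, fired in enumerate(stream):
        apply_habituation(state, fired, cycle)
        assert state.floor <= state.efficacy <= 100


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------

def run_stdp(events, total, weight=30, **kwargs):
    """events: {cycle: 'pre'|'post'|'both'}; returns (weight, trajectory)."""
    state = StdpState(baseline=weight, **kwargs)
    series = []
    for cycle in range(total):
        kind = events.get(cycle)
        pre = cycle if kind in ("pre", "both") else None
        post = cycle if kind in ("post", "both") else None
        weight = apply_stdp(state, weight, pre, post, cycle)
        series.append(weight)
    return weight, series


def test_pre_before_post_potentiates():
    w, _ = run_stdp({10: "pre", 12: "post"}, 40)
    assert w > 30


def test_post_before_pre_depresses():
    w, _ = run_stdp({10: "post", 12: "pre"}, 40)
    assert w < 30


def test_pairing_outside_window_changes_nothing():
    state = StdpState(baseline=30)
    window = state.window
    w, _ = run_stdp({10: "pre", 10 + window + 1: "post"}, 10 + window + 2)
    assert w == 30


def test_sign_and_magnitude_over_the_full_dt_grid():
    # measured right after the pairing resolves, before any forgetting drift
    window = StdpState().window
    pot_mags, dep_mags = [], []
    for dt in range(1, window + 1):
        total = 20 + dt + window + 2
        w_pot, _ = run_stdp({20: "pre", 20 + dt: "post"}, total)
        assert w_pot > 30, f"no potentiation at dt={dt}"
        pot_mags.append(w_pot - 30)
        w_dep, _ = run_stdp({20: "post", 20 + dt: "pre"}, total)
        assert w_dep < 30, f"no depression at dt={-dt}"
        dep_mags.append(30 - w_dep)
    assert all(b <= a for a, b in zip(pot_mags, pot_mags[1:]))
    assert all(b <= a for a, b in zip(dep_mags, dep_mags[1:]))


def test_weight_clamped_at_bounds():
    w, _ = run_stdp({10: "pre", 12: "post"}, 40, weight=100)
    assert w == 100
    w, _ = run_stdp({10: "post", 12: "pre"}, 40, weight=0)
    assert w == 0


def test_nearest_neighbour_no_double_counting():
    # one pre followed by two posts: only the first post pairs
    w_single, _ = run_stdp({10: "pre", 13: "post"}, 25)
    w_double, _ = run_stdp({10: "pre", 13: "post", 16: "post"}, 25)
    assert w_single > 30
    assert w_double == w_single


def test_simultaneous_pre_post_is_neutral():
    w, _ = run_stdp({10: "both"}, 40)
    assert w == 30


def test_causal_potentiation_outranks_reverse_pairing():
    # post(8) pre(10) post(13): the pre potentiates with the later post
    # inside its window instead of depressing with the earlier one
    w, _ = run_stdp({8: "post", 10: "pre", 13: "post"}, 20)
    assert w > 30


def test_weight_forgets_back_to_baseline_after_long_silence():
    state = StdpState(baseline=20)
    weight = 20
    events = {10: "pre", 12: "post"}
    horizon = state.recovery_delay + state.recovery_period * 100
    for cycle in range(horizon):
        kind = events.get(cycle)
        weight = apply_stdp(state, weight,
                            cycle if kind == "pre" else None,
                            cycle if kind == "post" else None, cycle)
    assert weight == 20


def test_curve_builder_rejects_overlarge_steps():
    with pytest.raises(ValueError):
        build_stdp_curves(peak=11)
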