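"""The three learning rules: sensory adaptation, habituation and STDP.

All three follow the integer lookup-curve convention of the neuron model:
updates are integer steps selected from small tables, states are bounded to
[0, 100], and every rule has a decay part under stimulation and a recovery
part under silence.

* Sensory adaptation acts at a transducer, scaling the receptor-potential
  amplitude.  It decays fast (quasi-exponentially, proportional steps) under
  a maintained stimulus and recovers fast when the stimulus ceases, so brief
  or sparse stimuli pass essentially unattenuated while constant ones are
  throttled.
* Habituation acts at a synapse, scaling the PSP amplitude launched by each
  presynaptic spike.  Its decay step depends on the recent inter-spike
  interval (short ISI / high frequency habituate faster) and its recovery is
  slow, so it filters redundant input on longer, history-dependent time
  scales.
* STDP acts on the synaptic weight itself: a presynaptic spike shortly
  before a postsynaptic one potentiates, the reverse order depresses, with
  magnitude falling off with |Δt| inside a finite coincidence window and
  nearest-neighbour spike pairing (each spike enters at most one pair).
  With no pairings over a long silent horizon the weight drifts back to its
  configured baseline — the forgetting that underlies extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .lif_core import SCALE_MAX, clamp, iround


# ---------------------------------------------------------------------------
# Sensory adaptation (transducer site)
# ---------------------------------------------------------------------------

@dataclass
class AdaptationState:
    efficacy: int = 100                 # percent multiplying transducer output
    decay_fraction: float = 0.05        # proportional (quasi-exponential) decay
    recovery_fraction: float = 0.10     # proportional fast recovery
    floor: int = 0
    cycles_since_stimulus: int = 0


def apply_adaptation(state: AdaptationState, stimulus_present: bool) -> AdaptationState:
    """One per-cycle update of a transducer's adaptation efficacy."""
    if stimulus_present:
        step = max(1, iround(state.decay_fraction * state.efficacy))
        state.efficacy = max(state.floor, state.efficacy - step)
        state.cycles_since_stimulus = 0
    else:
        state.cycles_since_stimulus += 1
        if state.efficacy < 100:
            step = max(1, iround(state.recovery_fraction * (100 - state.efficacy)))
            state.efficacy = min(100, state.efficacy + step)
    return state


# ---------------------------------------------------------------------------
# Habituation (synaptic site)
# ---------------------------------------------------------------------------

# ISI-bucketed decay steps: (inclusive upper ISI bound, step). Shorter
# inter-spike intervals habituate harder; the last bucket catches the rest.
DEFAULT_HABITUATION_BUCKETS = ((3, 8), (12, 3), (None, 2))


@dataclass
class HabituationState:
    efficacy: int = 100                 # percent multiplying the launched PSP
    floor: int = 0
    decay_buckets: tuple = DEFAULT_HABITUATION_BUCKETS
    recovery_delay: int = 80            # silent cycles before recovery engages
    recovery_step: int = 1
    recovery_period: int = 2            # cycles per recovery step
    window: int = 8                     # bounded history of recent pre spikes
    recent_pre_cycles: list = field(default_factory=list)
    silent_cycles: int = 0

    @property
    def recovery_horizon(self) -> int:
        """Silent cycles guaranteeing full recovery from the floor."""
        span = 100 - self.floor
        return self.recovery_delay + self.recovery_period * (
            (span + self.recovery_step - 1) // self.recovery_step)

    def decay_step(self, isi: Optional[int]) -> int:
        for bound, step in self.decay_buckets:
            if bound is None or (isi is not None and isi <= bound):
                return step
        return self.decay_buckets[-1][1]


def apply_habituation(state: HabituationState, pre_spiked: bool, cycle: int) -> HabituationState:
    """One per-cycle update of a synapse's habituation efficacy."""
    if pre_spiked:
        isi = cycle - state.recent_pre_cycles[-1] if state.recent_pre_cycles else None
        state.efficacy = max(state.floor, state.efficacy - state.decay_step(isi))
        state.recent_pre_cycles.append(cycle)
        del state.recent_pre_cycles[:-state.window]
        state.silent_cycles = 0
    else:
        state.silent_cycles += 1
        past_delay = state.silent_cycles - state.recovery_delay
        if past_delay > 0 and past_delay % state.recovery_period == 0:
            state.efficacy = min(100, state.efficacy + state.recovery_step)
    return state


# ---------------------------------------------------------------------------
# STDP (synaptic weight)
# ---------------------------------------------------------------------------

def build_stdp_curves(window: int = 15, peak: int = 8, slope_cycles: int = 2):
    """Integer potentiation/depression magnitude tables.

    Index |Δt| in 1..window; magnitude decreases stepwise from `peak` by one
    unit every `slope_cycles` cycles of separation, never below 1.  Both the
    peak and any single-pair change respect the global 10-unit cap.
    """
    if peak > 10:
        raise ValueError("single-pair change may not exceed 10 units")
    mags = tuple(max(1, peak - (dt - 1) // slope_cycles) for dt in range(1, window + 1))
    return mags


@dataclass
class StdpState:
    window: int = 15
    potentiation_curve: tuple = field(default_factory=build_stdp_curves)
    depression_curve: tuple = field(default_factory=build_stdp_curves)
    baseline: int = 0                   # weight the synapse forgets back to
    weight_bounds: tuple = (0, SCALE_MAX)
    recovery_delay: int = 30            # pairing-free cycles before drift
    recovery_period: int = 2            # cycles per unit of drift
    # pairing bookkeeping (potentiation-priority nearest-neighbour: each
    # spike enters at most one pairing; a post->pre candidate depression is
    # held until the pre's own potentiation window has expired, so a causal
    # pre-post pairing always takes priority over the accidental reverse
    # pairing with the previous post)
    last_pre_cycle: Optional[int] = None
    last_post_cycle: Optional[int] = None
    pre_paired: bool = True
    post_paired: bool = True
    pending_depression: Optional[tuple] = None   # (post_cycle, pre_cycle)
    last_pairing_cycle: Optional[int] = None

    def increment(self, dt: int) -> int:
        """Signed weight change for a pairing with Δt = t_post − t_pre."""
        if dt > 0 and dt <= self.window:
            return self.potentiation_curve[dt - 1]
        if dt < 0 and -dt <= self.window:
            return -self.depression_curve[-dt - 1]
        return 0


def apply_stdp(
    state: StdpState,
    weight: int,
    pre_spike_cycle: Optional[int],
    post_spike_cycle: Optional[int],
    cycle: Optional[int] = None,
) -> int:
    """One per-cycle STDP update; returns the new weight.

    `pre_spike_cycle` / `post_spike_cycle` are the cycles of spikes emitted
    THIS cycle (or None).  Exactly one update happens per new pre/post pair;
    a spike already consumed by a pairing is never paired again.  With no
    pairing over the recovery horizon the weight drifts one unit per
    `recovery_period` cycles back toward `baseline`.
    """
    if cycle is None:
        cycle = post_spike_cycle if post_spike_cycle is not None else pre_spike_cycle
        if cycle is None:
            raise ValueError("cycle required on spike-free updates")
    lo, hi = state.weight_bounds
    new_weight = weight
    paired = False

    if pre_spike_cycle is not None and post_spike_cycle is not None:
        # simultaneous arrival: Δt = 0 lies outside both curves; both spikes
        # are consumed without a weight change.
        state.last_pre_cycle, state.pre_paired = pre_spike_cycle, True
        state.last_post_cycle, state.post_paired = post_spike_cycle, True
        state.pending_depression = None
        state.last_pairing_cycle = cycle
        paired = True
    elif post_spike_cycle is not None:
        if (state.last_pre_cycle is not None and not state.pre_paired
                and state.increment(post_spike_cycle - state.last_pre_cycle)):
            inc = state.increment(post_spike_cycle - state.last_pre_cycle)
            new_weight = clamp(weight + inc, lo, hi)
            state.pre_paired = True
            state.last_post_cycle, state.post_paired = post_spike_cycle, True
            if (state.pending_depression is not None
                    and state.pending_depression[1] == state.last_pre_cycle):
                state.pending_depression = None
            state.last_pairing_cycle = cycle
            paired = True
        else:
            state.last_post_cycle, state.post_paired = post_spike_cycle, False
    else:
        # a new pre spike forces any older depression candidate to resolve
        due = state.pending_depression is not None and (
            pre_spike_cycle is not None
            or cycle - state.pending_depression[1] >= state.window)
        if due:
            post_c, pre_c = state.pending_depression
            inc = state.increment(post_c - pre_c)
            if inc:
                new_weight = clamp(weight + inc, lo, hi)
                state.last_pairing_cycle = cycle
                paired = True
            if state.last_pre_cycle == pre_c:
                state.pre_paired = True
            state.pending_depression = None
        if pre_spike_cycle is not None:
            if (state.last_post_cycle is not None and not state.post_paired
                    and state.increment(state.last_post_cycle - pre_spike_cycle)):
                # hold the reverse pairing: the pre may yet potentiate with a
                # post inside its own window, which takes priority
                state.pending_depression = (state.last_post_cycle, pre_spike_cycle)
                state.post_paired = True
            state.last_pre_cycle, state.pre_paired = pre_spike_cycle, False

    if not paired and new_weight != state.baseline:
        ref = state.last_pairing_cycle
        since = cycle - ref if ref is not None else cycle
        if since >= state.recovery_delay and since % state.recovery_period == 0:
            new_weight += 1 if new_weight < state.baseline else -1
    return new_weight
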