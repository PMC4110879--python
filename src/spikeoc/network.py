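"""Network topology, transducers, actuators and the synchronous cycle engine.

The simulation advances on a global discrete clock.  Within a cycle the
fixed order of operations is:

    sense -> transduce -> integrate/fire -> plasticity update -> actuate
          -> world update

Spikes emitted this cycle become visible to downstream neurons on the next
cycle: each spike launches one 5-entry PSP delta sequence per outgoing
synapse (scaled by the weight-indexed lookup curve and the synapse's
habituation efficacy, negated on inhibitory links), and all deltas arriving
at a neuron on a given cycle sum before integration (temporal summation).
This previous-cycle visibility makes the trace independent of the order in
which neurons and synapses are iterated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .lif_core import (
    SCALE_MAX,
    NeuronParams,
    NeuronState,
    PspTable,
    build_psp_table,
    clamp,
    integrate_cycle,
    iround,
    reported_potential,
)
from .plasticity import (
    AdaptationState,
    HabituationState,
    StdpState,
    apply_adaptation,
    apply_habituation,
    apply_stdp,
)

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"

STIMULUS_CHANNELS = (
    "vibration", "light", "heat", "color-green", "color-red", "color-blue",
    "touch", "sound",
)
WORLD_ACTIONS = ("emit-sound", "arm-down", "arm-up", "eject", "wheels-forward")


class ConfigurationError(ValueError):
    """Raised at load/validation time for inconsistent network wiring."""


@dataclass
class SynapseSpec:
    pre: str
    post: str
    weight: int
    polarity: str = EXCITATORY
    habituation: Optional[HabituationState] = None
    stdp: Optional[StdpState] = None
    initial_weight: int = field(init=False)

    def __post_init__(self):
        if not 0 <= self.weight <= SCALE_MAX:
            raise ConfigurationError(f"synapse {self.key}: weight {self.weight} out of [0,100]")
        if self.polarity not in (EXCITATORY, INHIBITORY):
            raise ConfigurationError(f"synapse {self.key}: unknown polarity {self.polarity!r}")
        self.initial_weight = self.weight
        if self.stdp is not None:
            self.stdp.baseline = self.weight

    @property
    def key(self) -> str:
        return f"{self.pre}->{self.post}"

    @property
    def sign(self) -> int:
        return -1 if self.polarity == INHIBITORY else 1


@dataclass
class Transducer:
    """Bridge from a named world stimulus to a neuron: stimulus intensity
    indexes the shared lookup table, producing a graded receptor-potential
    sequence (same 5-cycle, max-10 format as PSPs), optionally scaled by a
    sensory-adaptation efficacy.  While the stimulus persists, a finished
    sequence retriggers; sequences never self-overlap."""
    channel: str
    target: str
    adaptation: Optional[AdaptationState] = None

    @property
    def key(self) -> str:
        return f"{self.channel}->{self.target}"


@dataclass
class Actuator:
    """Motor-neuron spikes feed a graded motor potential; when it crosses the
    trigger threshold the named world action fires once and the potential
    resets (debouncing spike trains into discrete world events)."""
    source: str
    action: str
    trigger_threshold: int = 10
    decay_fraction: float = 0.2


@dataclass
class NetworkSpec:
    neurons: dict[str, NeuronParams] = field(default_factory=dict)
    synapses: list[SynapseSpec] = field(default_factory=list)
    transducers: list[Transducer] = field(default_factory=list)
    actuators: list[Actuator] = field(default_factory=list)
    psp_table: PspTable = field(default_factory=build_psp_table)

    def validate(self) -> "NetworkSpec":
        for syn in self.synapses:
            for nid in (syn.pre, syn.post):
                if nid not in self.neurons:
                    raise ConfigurationError(f"synapse {syn.key}: unknown neuron id {nid!r}")
        seen = set()
        for syn in self.synapses:
            if syn.key in seen:
                raise ConfigurationError(f"duplicate synapse {syn.key}")
            seen.add(syn.key)
        for tr in self.transducers:
            if tr.target not in self.neurons:
                raise ConfigurationError(f"transducer {tr.key}: unknown neuron id {tr.target!r}")
            if tr.channel not in STIMULUS_CHANNELS:
                raise ConfigurationError(f"transducer {tr.key}: unknown channel {tr.channel!r}")
        for act in self.actuators:
            if act.source not in self.neurons:
                raise ConfigurationError(f"actuator {act.action}: unknown neuron id {act.source!r}")
            if act.action not in WORLD_ACTIONS:
                raise ConfigurationError(f"actuator from {act.source}: unknown action {act.action!r}")
        return self

    def merge(self, other: "NetworkSpec") -> "NetworkSpec":
        """Compose two fragments, sharing neurons with identical ids."""
        merged = NetworkSpec(psp_table=self.psp_table)
        merged.neurons.update(self.neurons)
        merged.neurons.update(other.neurons)
        keys = {s.key for s in self.synapses}
        merged.synapses = self.synapses + [s for s in other.synapses if s.key not in keys]
        tkeys = {t.key for t in self.transducers}
        merged.transducers = self.transducers + [t for t in other.transducers if t.key not in tkeys]
        akeys = {(a.source, a.action) for a in self.actuators}
        merged.actuators = self.actuators + [a for a in other.actuators
                                             if (a.source, a.action) not in akeys]
        return merged

    def synapse(self, pre: str, post: str) -> SynapseSpec:
        for syn in self.synapses:
            if syn.pre == pre and syn.post == post:
                return syn
        raise KeyError(f"no synapse {pre}->{post}")


# ---------------------------------------------------------------------------
# Runtime state
# ---------------------------------------------------------------------------

@dataclass
class _Sequence:
    target: str
    entries: list[int]
    pos: int = 0

    def current(self) -> int:
        return self.entries[self.pos]

    def advance(self) -> bool:
        self.pos += 1
        return self.pos < len(self.entries)


@dataclass
class SimStates:
    neuron: dict[str, NeuronState]
    psps: list[_Sequence]
    pending_psps: list[_Sequence]
    transducer_seq: dict[str, Optional[_Sequence]]
    motor: dict[int, tuple[int, list[_Sequence]]]  # actuator idx -> (accum, seqs)


def init_states(network: NetworkSpec) -> SimStates:
    return SimStates(
        neuron={nid: NeuronState.resting(p) for nid, p in network.neurons.items()},
        psps=[],
        pending_psps=[],
        transducer_seq={tr.key: None for tr in network.transducers},
        motor={i: (0, []) for i in range(len(network.actuators))},
    )


# ---------------------------------------------------------------------------
# One synchronous cycle
# ---------------------------------------------------------------------------

def step(
    network: NetworkSpec,
    states: SimStates,
    world_inputs: dict[str, int],
    cycle: int,
) -> tuple[SimStates, list[str], dict]:
    """Advance the whole network one cycle.

    `world_inputs` maps stimulus channels to intensities in [0, 100].
    Returns the updated states, the world actions emitted this cycle and the
    trace row.
    """
    inputs: dict[str, int] = {nid: 0 for nid in network.neurons}

    # -- sense + transduce -------------------------------------------------
    for tr in network.transducers:
        intensity = clamp(int(world_inputs.get(tr.channel, 0)))
        present = intensity > 0
        if tr.adaptation is not None:
            apply_adaptation(tr.adaptation, present)
        seq = states.transducer_seq[tr.key]
        if seq is None and present:
            eff = tr.adaptation.efficacy if tr.adaptation is not None else 100
            entries = [iround(d * eff / 100) for d in network.psp_table.curve(intensity)]
            seq = _Sequence(tr.target, entries)
            states.transducer_seq[tr.key] = seq
        if seq is not None:
            inputs[seq.target] += seq.current()
            if not seq.advance():
                states.transducer_seq[tr.key] = None

    # -- PSPs in flight ----------------------------------------------------
    states.psps.extend(states.pending_psps)
    states.pending_psps = []
    still = []
    for seq in states.psps:
        inputs[seq.target] += seq.current()
        if seq.advance():
            still.append(seq)
    states.psps = still

    # -- integrate / fire --------------------------------------------------
    spikes: dict[str, bool] = {}
    for nid, params in network.neurons.items():
        states.neuron[nid] = integrate_cycle(states.neuron[nid], params, [inputs[nid]], cycle)
        spikes[nid] = states.neuron[nid].spiked_this_cycle

    # -- launch new PSPs (visible from next cycle) -------------------------
    for syn in network.synapses:
        if spikes[syn.pre]:
            eff = syn.habituation.efficacy if syn.habituation is not None else 100
            entries = [syn.sign * iround(d * eff / 100)
                       for d in network.psp_table.curve(syn.weight)]
            states.pending_psps.append(_Sequence(syn.post, entries))

    # -- plasticity --------------------------------------------------------
    for syn in network.synapses:
        if syn.habituation is not None:
            apply_habituation(syn.habituation, spikes[syn.pre], cycle)
        if syn.stdp is not None:
            syn.weight = apply_stdp(
                syn.stdp, syn.weight,
                cycle if spikes[syn.pre] else None,
                cycle if spikes[syn.post] else None,
                cycle)

    # -- actuate -----------------------------------------------------------
    actions: list[str] = []
    for i, act in enumerate(network.actuators):
        accum, seqs = states.motor[i]
        if spikes[act.source]:
            seqs.append(_Sequence(act.source, list(network.psp_table.curve(SCALE_MAX))))
        accum -= iround(act.decay_fraction * accum)
        live = []
        for seq in seqs:
            accum += seq.current()
            if seq.advance():
                live.append(seq)
        if accum >= act.trigger_threshold:
            actions.append(act.action)
            accum, live = 0, []
        states.motor[i] = (accum, live)

    # -- trace row ---------------------------------------------------------
    row: dict = {"cycle": cycle}
    for nid, params in network.neurons.items():
        row[f"pot_{nid}"] = reported_potential(states.neuron[nid], params)
        row[f"spike_{nid}"] = int(spikes[nid])
    for syn in network.synapses:
        row[f"w_{syn.key}"] = syn.weight
        if syn.habituation is not None:
            row[f"eff_{syn.key}"] = syn.habituation.efficacy
    for tr in network.transducers:
        if tr.adaptation is not None:
            row[f"adapt_{tr.key}"] = tr.adaptation.efficacy
    for ch in sorted({t.channel for t in network.transducers}):
        row[f"stim_{ch}"] = clamp(int(world_inputs.get(ch, 0)))
    for act in network.actuators:
        row.setdefault(f"act_{act.action}", 0)
    for a in actions:
        row[f"act_{a}"] = 1
    return states, actions, row


# ---------------------------------------------------------------------------
# Closed-loop run
# ---------------------------------------------------------------------------

def run(network: NetworkSpec, world, cycles: int, seed: int = 0) -> pd.DataFrame:
    """Run the network in closed loop against a world model.

    The world must provide ``reset(seed)``, ``stimuli(cycle) -> dict`` and
    ``update(cycle, actions)``.  The run is deterministic for a fixed
    (network, world, cycles, seed) and returns the complete per-cycle trace.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    network.validate()
    # runs never mutate the caller's spec: weights and plasticity states
    # evolve on a private copy, and everything observable lands in the trace
    network = copy.deepcopy(network)
    world.reset(seed)
    states = init_states(network)
    rows = []
    for cycle in range(cycles):
        stim = world.stimuli(cycle)
        states, actions, row = step(network, states, stim, cycle)
        extra = world.update(cycle, actions)
        if extra:
            row.update(extra)
        rows.append(row)
    trace = pd.DataFrame(rows).fillna(0)
    return trace.astype(int)


class NullWorld:
    """A world that provides a fixed stimulus schedule and ignores actions."""

    def __init__(self, schedule: Optional[Callable[[int], dict]] = None):
        self.schedule = schedule or (lambda cycle: {})

    def reset(self, seed: int):
        pass

    def stimuli(self, cycle: int) -> dict:
        return self.schedule(cycle)

    def update(self, cycle: int, actions: Sequence[str]):
        return {}
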