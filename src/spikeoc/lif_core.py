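"""Discrete-time integer leaky integrate-and-fire neuron with lookup-table PSPs.

All membrane quantities live on a normalized integer scale [0, 100]:
0 is maximal hyperpolarization, 63 the firing threshold and 100 the level of
an emitted spike.  Instead of integrating the continuous LIF state equation,
every time-extended quantity (post-synaptic potentials, receptor potentials,
motor potentials, the leak) is a small integer lookup table sampled once per
simulation cycle.  A synaptic weight in [0, 100] indexes a family of 5-entry
per-cycle membrane-delta curves; the leak is a table of per-cycle decay steps
pulling the potential back toward rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

SCALE_MAX = 100
PSP_LENGTH = 5      # fixed curve length, in cycles
MAX_STEP = 10       # maximum per-cycle membrane change, normalized units


def iround(x: float) -> int:
    """Round half away from zero (the rounding contract used everywhere)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def clamp(v: int, lo: int = 0, hi: int = SCALE_MAX) -> int:
    return lo if v < lo else hi if v > hi else v


class CalibrationError(ValueError):
    """Raised when a requested lookup-table calibration cannot be met."""


# ---------------------------------------------------------------------------
# Leak
# ---------------------------------------------------------------------------

def build_leak_table(
    resting_potential: int = 50,
    depolarized_fraction: float = 0.10,
    hyperpolarized_fraction: float = 0.25,
) -> tuple[int, ...]:
    """Per-potential leak steps pulling the membrane toward rest.

    Index = current potential (0..100), value = signed delta applied that
    cycle.  Decay above rest is slow (passive diffusion); recovery from
    hyperpolarization below rest is faster, matching the rapid post-spike
    return to baseline.  Steps are at least 1 off rest so the potential
    reaches rest in finitely many cycles, and capped at MAX_STEP.
    """
    table = []
    for pot in range(SCALE_MAX + 1):
        dev = pot - resting_potential
        if dev == 0:
            table.append(0)
        elif dev > 0:
            table.append(-min(MAX_STEP, max(1, iround(depolarized_fraction * dev))))
        else:
            table.append(min(MAX_STEP, max(1, iround(hyperpolarized_fraction * -dev))))
    return tuple(table)


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    threshold: int = 63
    spike_level: int = SCALE_MAX
    hyperpolarized_reset: int = 20
    resting_potential: int = 50
    refractory_cycles: int = 4
    leak_table: tuple[int, ...] = field(default_factory=build_leak_table)

    def __post_init__(self):
        if not (0 <= self.hyperpolarized_reset < self.resting_potential
                < self.threshold < self.spike_level == SCALE_MAX):
            raise ValueError(
                "need 0 <= hyperpolarized_reset < resting_potential < "
                f"threshold < spike_level == {SCALE_MAX}, got "
                f"{self.hyperpolarized_reset}/{self.resting_potential}/"
                f"{self.threshold}/{self.spike_level}")
        if self.refractory_cycles < 1:
            raise ValueError("refractory_cycles must be >= 1")
        if len(self.leak_table) != SCALE_MAX + 1:
            raise ValueError("leak_table must have one entry per potential 0..100")

    def leak_step(self, potential: int) -> int:
        return self.leak_table[clamp(potential)]


@dataclass
class NeuronState:
    potential: int = 50
    refractory_remaining: int = 0
    spiked_this_cycle: bool = False
    last_spike_cycle: Optional[int] = None

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        return cls(potential=params.resting_potential)


# ---------------------------------------------------------------------------
# PSP lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationConstraints:
    """A single PSP at `must_spike_weight`, arriving at rest, must drive the
    membrane across threshold within the 5-cycle curve."""
    must_spike_weight: int = 95
    params: NeuronParams = field(default_factory=NeuronParams)


@dataclass(frozen=True)
class PspTable:
    """Weight-indexed family of 5-entry per-cycle membrane-delta curves."""
    curves: tuple[tuple[int, ...], ...]   # index: weight 0..100
    curve_length: int = PSP_LENGTH
    max_step: int = MAX_STEP

    def __post_init__(self):
        if len(self.curves) != SCALE_MAX + 1:
            raise ValueError("need one curve per weight 0..100")
        for w, curve in enumerate(self.curves):
            if len(curve) != self.curve_length:
                raise ValueError(f"curve for weight {w} has wrong length")
            if any(abs(d) > self.max_step for d in curve):
                raise ValueError(f"curve for weight {w} exceeds max step {self.max_step}")
        if any(self.curves[0]):
            raise ValueError("weight 0 must map to the all-zero curve")
        peaks = [max(_cumsums(c)) for c in self.curves]
        if any(b < a for a, b in zip(peaks, peaks[1:])):
            raise ValueError("cumulative curve amplitude must be non-decreasing in weight")

    def curve(self, weight: int) -> tuple[int, ...]:
        return self.curves[clamp(weight)]

    def to_csv(self, path: str):
        """Export the full 101x5 integer table for inspection."""
        with open(path, "w") as fh:
            fh.write("weight," + ",".join(f"cycle{i}" for i in range(self.curve_length)) + "\n")
            for w, curve in enumerate(self.curves):
                fh.write(f"{w}," + ",".join(str(d) for d in curve) + "\n")


def _cumsums(curve: Sequence[int]) -> list[int]:
    total, out = 0, [0]
    for d in curve:
        total += d
        out.append(total)
    return out


DEFAULT_SHAPE_PROFILE = (1.0, 0.8, 0.5, 0.25, 0.1)


def build_psp_table(
    shape_profile: Sequence[float] = DEFAULT_SHAPE_PROFILE,
    calibration: Optional[CalibrationConstraints] = None,
    gamma: float = 1.0,
    max_step: int = MAX_STEP,
) -> PspTable:
    """Generate the weight-indexed PSP family from a rise-then-decay template.

    `shape_profile` gives the relative per-cycle deltas (leading entries
    large, trailing small); the peak entry for weight w is
    round(max_step * (w/100)**gamma), a progressive intensity scale.  The
    calibration constraint checks that a lone PSP at the stated weight fires
    a resting neuron within the curve, as the reference dynamics require.
    """
    if len(shape_profile) != PSP_LENGTH:
        raise ValueError(f"shape_profile must have {PSP_LENGTH} entries")
    if max(shape_profile) <= 0 or any(s < 0 for s in shape_profile):
        raise ValueError("shape_profile must be non-negative with a positive peak")
    norm = max(shape_profile)
    curves = []
    for w in range(SCALE_MAX + 1):
        peak = iround(max_step * (w / SCALE_MAX) ** gamma)
        curves.append(tuple(iround(peak * s / norm) for s in shape_profile))
    table = PspTable(curves=tuple(curves), max_step=max_step)

    if calibration is not None:
        params = calibration.params
        state = NeuronState.resting(params)
        fired = False
        for cycle, delta in enumerate(table.curve(calibration.must_spike_weight)):
            state = integrate_cycle(state, params, [delta], cycle)
            if state.spiked_this_cycle:
                fired = True
                break
        if not fired:
            raise CalibrationError(
                f"a single PSP at weight {calibration.must_spike_weight} does not "
                "cross threshold from rest within the curve length")
    return table


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_cycle(
    state: NeuronState,
    params: NeuronParams,
    incoming_deltas: Sequence[int],
    cycle: int,
) -> NeuronState:
    """Advance one neuron by one cycle.

    During absolute refractoriness incoming deltas are discarded and the
    potential follows the leak-driven recovery toward rest.  Otherwise the
    deltas of all concurrently active PSPs sum with the leak step (temporal
    summation), the result is clamped to [0, 100], and a threshold crossing
    emits a spike: the output is reported at spike level while the stored
    potential resets to the hyperpolarized level with a fresh refractory
    countdown.
    """
    if state.refractory_remaining > 0:
        pot = clamp(state.potential + params.leak_step(state.potential))
        return NeuronState(
            potential=pot,
            refractory_remaining=state.refractory_remaining - 1,
            spiked_this_cycle=False,
            last_spike_cycle=state.last_spike_cycle,
        )
    pot = clamp(state.potential + sum(incoming_deltas) + params.leak_step(state.potential))
    if pot >= params.threshold:
        return NeuronState(
            potential=params.hyperpolarized_reset,
            refractory_remaining=params.refractory_cycles,
            spiked_this_cycle=True,
            last_spike_cycle=cycle,
        )
    return NeuronState(
        potential=pot,
        refractory_remaining=0,
        spiked_this_cycle=False,
        last_spike_cycle=state.last_spike_cycle,
    )


def reported_potential(state: NeuronState, params: NeuronParams) -> int:
    """Potential as written to the trace: spike level on spike cycles."""
    return params.spike_level if state.spiked_this_cycle else state.potential
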