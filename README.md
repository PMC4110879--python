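# spikeoc

Operant conditioning from a minimal spiking micro-circuit, for
neurorobotics-style closed-loop simulation.

Operant conditioning (OC) is the form of associative learning in which an
agent changes how often it performs a behavior based on the rewarding or
punishing consequences of its own previous actions. `spikeoc` implements a
deliberately minimal spiking account of it: a discrete-time integer
leaky integrate-and-fire network in which all dynamics (post-synaptic
potentials, leak, receptor and motor potentials, learning-rule updates) are
5-cycle integer lookup tables on a normalized [0, 100] scale, with firing
threshold 63 and spike level 100.

The core is an invariant three-neuron kernel:

```
        strong, habituating
  Cue ───────────────────────▶ Action ──▶ actuator
   │                             ▲
   │ weak, STDP                  │ intermediate, static
   ▼                             │
  Predictor ◀── reinforcer input─┘(world reward/punishment)
```

A periodic cue drives a reflex action through the strong habituating link,
which fades under repetition. Each self-produced action earns a reinforcer
from the world a short latency later; the reinforcer fires the Predictor
inside the STDP coincidence window of the preceding cue spike, so the weak
Cue→Predictor link grows (pair-based STDP: Δw = +max(1, 8−(Δt−1)/2) for
pre-before-post, −max(1, 4−(|Δt|−1)/2) for the reverse, window ±15 cycles)
until the cue alone predicts the outcome and drives the action — behavior
that then persists when the reinforcer is withdrawn (expectation) and
decays back when the cue disappears (extinction). Swapping the action's
motor coupling to inhibitory, duplicating the kernel per reinforcer with
mutual inhibition, or duplicating it per cue with a shared Action neuron
yields behavior reversal, reward/punishment opposition and multi-cue
discrimination from the same unchanged inner circuit.

Four closed-loop scenarios exercise the kernel: **A** sound emission for a
light reward; **B** reward acquisition then punishment-driven reversal of
the same behavior; **C** a moving agent pressing colored floor zones with a
mid-run reversal of the color–reinforcer contingencies; **D** a simulated
conveyor-sorting task with randomized piece colors and jittered
reinforcer timing. An ablation harness covers the four control situations
(no habituation, no STDP, reward preceding the action, cue removal), and a
calibration harness fixes all timeline-sensitive defaults.

## Worked example

Run the reference protocol (scenario A) from the CLI:

```
$ spikeoc run a --seed 0 --out trace_a.csv
phase reflex (0, 85): reflex (7 actions)
phase habituated (85, 120): habituated (3 actions)
phase acquisition (120, 175): acquisition (5 actions)
phase expectation (175, 250): expectation (6 actions)
wrote trace_a.csv (250 cycles)
```

Reading: during cycles 0–85 the cue elicits 7 reflex sounds, each followed
by a rewarding light. Around cycle 90 the habituating Cue→Action link
collapses below the firing requirement (the reflex "ceases near cycle
100"), and just after, the Cue→Predictor weight crosses the
predictor-firing threshold (weight 55 with the shipped tables) — the
handover window labelled *habituated*. The reward is discontinued at cycle
175, yet the expectation phase still contains 6 predictor-driven sounds:
the conditioned behavior has become independent of the reinforcer.

The same from Python:

```python
from spikeoc import scenario_a, classify_phases, reflex_cessation_cycle

proto = scenario_a()
trace = proto.run(seed=0)            # pandas DataFrame, one row per cycle
print(reflex_cessation_cycle(trace, proto))   # -> 90
print(classify_phases(trace, proto).labels())
# {'reflex': 'reflex', 'habituated': 'habituated',
#  'acquisition': 'acquisition', 'expectation': 'expectation'}
```

Other entry points: `spikeoc run b|c|d`, `spikeoc ablate no-stdp`,
`spikeoc build dual --out net.yaml`, `spikeoc run net.yaml --cycles 200
--out t.csv`, `spikeoc calibrate`, `spikeoc plot trace_a.csv --out
panels.png`. For the conveyor task, `spikeoc run d --seed 0 --out d.csv`
prints the per-color ejection rates over the whole run (red 1.00, blue 0.74
at seed 0 — the blue rate includes the pre-learning transient; it is 0.0
in steady state).

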