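# Methods

## The model

`spikeoc` simulates small spiking networks on a synchronous discrete clock.
Every dynamical variable is an integer on a normalized [0, 100] scale: 0 is
maximal hyperpolarization, 50 the resting potential, 63 the firing
threshold and 100 the level of an emitted spike. Instead of integrating the
continuous leaky integrate-and-fire equation, all time-extended quantities
are small integer lookup tables sampled once per cycle:

* **PSP curves.** A synaptic weight w ∈ [0, 100] indexes a family of
  5-entry per-cycle membrane-delta curves generated from a rise-then-decay
  template (relative entries 1, 0.8, 0.5, 0.25, 0.1 of the peak; the peak is
  `round(10·w/100)`). Every entry is bounded by 10 units per cycle, weight 0
  maps to the all-zero curve, and cumulative amplitude is non-decreasing in
  weight. Transducer (receptor-potential) and actuator (motor-potential)
  responses reuse the same table, indexed by stimulus intensity.
* **Leak.** A per-potential table of decay steps pulls the membrane back
  toward rest: `max(1, round(0.10·d))` per cycle above rest and
  `max(1, round(0.25·d))` below it, where d is the distance from rest. The
  asymmetry gives a slow passive decay of depolarization and a brisk
  post-spike return from the hyperpolarized reset (level 20), and the step
  floor of 1 guarantees convergence to rest in finitely many cycles.
* **Firing.** Deltas of all concurrently active PSPs sum before
  integration (temporal summation), the result is clamped to [0, 100], and a
  threshold crossing emits a spike, resets the potential to the
  hyperpolarized level and opens a 4-cycle absolute refractory period during
  which inputs are discarded.

A calibration constraint anchors the table scale: a single PSP at weight
95, arriving at rest, must cross threshold within its 5 cycles. A useful
derived quantity is the *predictor-firing weight* (55 with the shipped
tables): the smallest weight whose lone PSP fires a resting neuron. The
phase classifier uses it to locate the moment a learned association becomes
behaviorally effective.

Within a cycle the order of operations is fixed: sense → transduce →
integrate/fire → plasticity update → actuate → world update. Spikes emitted
in a cycle become visible to downstream neurons on the next cycle, which
makes the trace independent of iteration order. A re-spike before a PSP
completes launches a fresh sequence that superposes with the old one.
Actuators accumulate motor potential (with 20 % per-cycle decay) and fire
their world action once a trigger threshold (10) is crossed, then reset —
debouncing spike trains into discrete world events.

## Learning rules

All three rules are integer lookup curves with a decay part under
stimulation and a recovery part under silence.

**Sensory adaptation** (transducer site): efficacy multiplying the receptor
potential; proportional decay `max(1, round(0.015·e))` per stimulated cycle
and fast proportional recovery `max(1, round(0.10·(100−e)))` per silent
cycle. Brief or sparse stimuli pass unattenuated; a constant stimulus
throttles itself within ~50–100 cycles.

**Habituation** (synapse site): efficacy multiplying the PSP launched by
each presynaptic spike. The per-spike decay step depends on the
inter-spike interval: 8 units for ISI ≤ 3, 5 for ISI ≤ 10, 3 for ISI ≤ 12
and 4 beyond. The raised sparse-ISI step is deliberate: a rarely presented
cue (one spike per stimulus presentation) must still habituate over tens of
presentations, while the ISI-12 regime of the reference cue pacing
habituates at the slower rate the acquisition timeline requires; massed
stimulation (short ISI) still habituates fastest, preserving the
frequency-sensitivity ordering. Recovery is slow — after 150 silent
cycles, 1 unit per 6 cycles — so spontaneous recovery needs sustained
stimulus absence (full recovery horizon 750 cycles).

**STDP** (synaptic weight): pair-based, with a ±15-cycle coincidence
window. Magnitudes fall off stepwise with |Δt|: potentiation
`max(1, 8 − (Δt−1)//2)`, depression `max(1, 4 − (|Δt|−1)//2)` (asymmetric:
reverse pairings are weaker than causal ones). Pairing is
*potentiation-priority nearest-neighbour*: each spike enters at most one
pairing; when a pre spike arrives shortly after an unpaired post, the
reverse (depressing) pairing is held pending for one window and cancelled
if a post arrives inside the pre's own potentiation window. This
resolves the closed-loop ambiguity in which the reinforcer-driven
predictor spike from the *previous* action would otherwise consume the cue
spike that is about to be causally rewarded; with plain consumption-order
pairing the reward loop depresses the very association it should build.
With no pairing for 250 cycles the weight drifts back toward its
configured baseline at 1 unit per 3 cycles — the forgetting that produces
extinction, slow enough that learned predictions survive the longest
jittered gaps in the sorting task.

## The operant-conditioning kernel

The invariant inner box is three neurons and three typed links: Cue→Action
(weight 90, habituating), Cue→Predictor (weight 20, STDP) and
Predictor→Action (weight 60, static), satisfying the ordering
cue_action > predictor_action > cue_predictor. The contextual outer box
adds a cue transducer and sensory relay, a reinforcer transducer and relay
into the Predictor, and a motor relay with one actuator (inhibitory
Action→motor coupling for the punishment-avoiding polarity). Acquisition
works because the reinforcer, arriving a fixed short latency after the
agent's own action, fires the Predictor inside the STDP window of the
preceding Cue spike; the association grows until the cue alone drives the
Predictor (weight ≥ 55), at which point behavior survives both habituation
of the reflex and removal of the reinforcer.

Compositions: the *dual kernel* adds an opposing Predictor driven by the
punishment reinforcer, coupled to the shared Action by an inhibitory link
of the same intermediate strength, plus one inhibitory interneuron per
direction between the opposing predictors (mutual exclusion of the
behaviors). The punishment veto works on timing: the punishment
prediction's inhibitory PSP lands before the reward prediction's
excitatory PSP finishes integrating. The *multi-cue* composition gives
each cue channel its own kernel (with adaptation on the cue transducers)
sharing one Action neuron; a shared reinforcer relay drives every
predictor, and STDP performs the credit assignment because only the
recently active cue has an unpaired spike inside the window.

## Scenarios and the classifier

* **A** (250 cycles): vibration pulse every 12 cycles; light follows each
  sound with latency 2 during [0, 175). With the shipped defaults the
  reflex ceases around cycle 90–105 and the cue→predictor weight crosses
  the predictor-firing threshold just afterwards, so behavior hands over
  near-seamlessly. A strict zero-action gap between cessation and takeover
  cannot exist here: the reward is contingent on the action, so a silent
  gap would cut off the pairings that feed learning. The classifier
  therefore labels as *habituated* the phase containing the threshold
  crossing, provided the reflex link's efficacy has genuinely collapsed
  (< 75); *reflex* precedes the crossing, *acquisition* follows it with
  rewards still arriving and the weight still rising, *expectation* has
  actions without rewards, *reversal* has punishments with actions dying
  out, *extinction* a declining weight with no actions.
* **B** (1000 cycles): the dual kernel; reward during [0, 250), punishment
  from cycle 500. Sounds persist through the expectation window and cease
  once the punishment prediction crosses threshold (~cycle 650); the final
  quarter is silent while the punishment predictor keeps firing from the
  cue alone.
* **C** (800 cycles): eight 100-cycle floor zones, colors
  R G R G R G G R, traversed at constant speed; arm presses on green are
  rewarded and on red punished during the first half, reversed at cycle
  400. A touch reflex raises the arm after each press. The zone layout is
  chosen so the final green zone directly follows a punished green zone
  (the fresh punishment prediction carries over with no forgetting gap)
  while the last red zone is separated from red's punishment history by
  ~250 silent cycles (full drift back to baseline). End state: the last
  green zone draws zero presses, the last red zone is pressed and
  rewarded.
* **D** (simulated conveyor, default 48–60 pieces): red/blue pieces at
  50 ± 5-cycle intervals, visible 15 cycles; ejecting a piece of the
  reinforced color earns a touch reward at latency 1 + jitter ≤ 3 (inside
  the STDP window). Ejection of the unreinforced color fades by
  habituation of the sparse cue; the reinforced color's association
  crosses threshold within a handful of rewarded ejections and sustains
  ejection indefinitely. With the reinforcer delayed beyond the STDP
  window (+5) the weight trajectory is flat and no selectivity emerges;
  with the reinforcer withheld, ejection of both colors declines, though
  genuinely long random same-color gaps can transiently resurrect the
  habituated reflex (spontaneous recovery), so "no selectivity" is
  asserted as no association crossing plus declining ejection, not
  absolute zero. The piece interval exceeds the STDP window plus the
  reinforcer chain latency so the delayed-reinforcer control cannot form
  spurious pairings with the next piece's cue.

The four controls on scenario A: removing habituation (the action never
stops), removing STDP (behavior survives only while rewarded — the
reinforcer-driven predictor loop sustains it until reward removal),
scheduling the reward ahead of the cue-driven action (reverse pairings
drive the association below baseline and behavior never resumes; the cue
period is raised above the STDP window here because with a period shorter
than the window every reinforcer spike would find a causal pre to
potentiate), and removing the cue mid-run (the association drifts back to
baseline — extinction; run length 700 cycles to cover the drift horizon).

## Calibration

`calibrate_defaults` fixes the timeline-sensitive parameters by a
deterministic grid search over cue period (10, 12), habituation step
profile and STDP potentiation peak (6, 8), accepting the first candidate
whose scenario-A trace has reflex cessation in cycle 100 ± 15 and
acquisition complete before reward removal at 175 with post-removal
actions, whose scenario-B reversal completes within the punishment phase,
and whose scenario-D steady state sorts perfectly on two seeds. The
shipped defaults are exactly its output, and a regression test re-runs the
search and compares bit-for-bit.

## Determinism, sizes and numerics

All arithmetic is integer with round-half-away-from-zero at every scaling
step. The only stochastic elements are scenario D's piece colors, piece
intervals and reinforcer latency, drawn from a seeded generator; for a
fixed (network, world, cycles, seed) every run is bit-identical, a
re-run of the first N cycles is a prefix of a longer run, and trace CSV
files are byte-identical across runs. Problem sizes (250–2 500 cycles,
6–20 neurons) keep every scenario under a second of wall time, so the full
test suite and the acceptance script each run in seconds.

## What the synthetic worlds do and do not show

The worlds are caricatures: stimuli are square pulses on named channels,
actions are discrete debounced events, reinforcement contingencies are
exact and latencies near-deterministic. Passing tests therefore
demonstrate the *sufficiency of the micro-circuit's mechanism* — that
habituation plus pair-based STDP on the stated topology yields
acquisition, expectation, reversal and extinction under closed-loop
contingencies — not robustness to sensor noise, continuous kinematics,
overlapping multi-modal stimuli or imprecise real-world timing. The
physical-robot embodiment of the sorting task is represented here only by
its simulated world model; hardware drivers are out of scope by design.

## Known limitations

* The habituation decay profile is not monotone at the sparse-ISI end (see
  above); it is a single global profile serving four pacing regimes, and a
  per-synapse override is available in config where that trade-off is
  wrong for a new task.
* Reverse-timing contingencies can only be expressed by scheduling the
  reinforcer against the cue clock, since a contingent reinforcer must
  follow its action by ≥ 1 cycle.
* With reinforcement withheld, behavior fades on stimulus-density time
  scales; rare stimuli fade slowest and may transiently recover.
* No neuromodulation, eligibility traces, distal (beyond-window) reward,
  value systems, or action selection beyond mutual inhibition.
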