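"""Builders for the invariant operant-conditioning micro-circuit.

The inner box is always the same three neurons and three typed links:

    Cue --(strong, habituating)--> Action
    Cue --(weak, STDP)----------> Predictor
    Predictor --(intermediate, static)--> Action

plus a contextual outer box: a cue transducer, a reinforcer transducer
feeding the Predictor through a sensory relay, and a motor relay driving one
actuator.  Operant learning lives entirely in this kernel: the habituating
reflex link fades under the repeated cue while the reinforcer, arriving just
after the self-produced action, drives the Predictor and lets STDP grow the
Cue->Predictor association until the cue alone predicts the outcome.

Compositions: an opposing dual kernel (separate reward and punishment
Predictors on a shared cue path, with mutual inhibition via interneurons)
and multi-cue duplication (one kernel per cue sharing the Action neuron).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .defaults import DEFAULTS
from .lif_core import NeuronParams, NeuronState, PspTable, build_psp_table, integrate_cycle
from .network import (
    EXCITATORY,
    INHIBITORY,
    Actuator,
    ConfigurationError,
    NetworkSpec,
    SynapseSpec,
    Transducer,
)
from .plasticity import AdaptationState, HabituationState, StdpState, build_stdp_curves

REWARD_SEEKING = "reward-seeking"
PUNISHMENT_AVOIDING = "punishment-avoiding"


@dataclass
class OcKernelSpec:
    """Handle on one kernel inside a composed network."""
    cue: str
    action: str
    predictor: str
    cue_action: SynapseSpec
    cue_predictor: SynapseSpec
    predictor_action: SynapseSpec
    reinforcer_input: Transducer
    polarity: str = REWARD_SEEKING

    def validate(self) -> "OcKernelSpec":
        wa, wp, wc = (self.cue_action.weight, self.predictor_action.weight,
                      self.cue_predictor.weight)
        if not wa > wp:
            raise ConfigurationError(
                f"kernel weight ordering violated: weight(cue->action)={wa} "
                f"must exceed weight(predictor->action)={wp}")
        if not wp > wc:
            raise ConfigurationError(
                f"kernel weight ordering violated: weight(predictor->action)={wp} "
                f"must exceed weight(cue->predictor)={wc}")
        if self.cue_action.habituation is None or self.cue_action.stdp is not None:
            raise ConfigurationError("cue->action must carry habituation and no STDP")
        if self.cue_predictor.stdp is None or self.cue_predictor.habituation is not None:
            raise ConfigurationError("cue->predictor must carry STDP and no habituation")
        if self.predictor_action.stdp is not None or self.predictor_action.habituation is not None:
            raise ConfigurationError("predictor->action must be static (no learning rule)")
        return self

    @property
    def neurons(self) -> tuple[str, str, str]:
        return (self.cue, self.action, self.predictor)

    @property
    def inner_synapses(self) -> tuple[SynapseSpec, SynapseSpec, SynapseSpec]:
        return (self.cue_action, self.cue_predictor, self.predictor_action)

    def signature(self) -> frozenset:
        """Typed-edge signature of the inner box, for isomorphism checks."""
        roles = {self.cue: "cue", self.action: "action", self.predictor: "predictor"}
        return frozenset(
            (roles[s.pre], roles[s.post], s.polarity,
             s.habituation is not None, s.stdp is not None)
            for s in self.inner_synapses)


def kernel_census(spec: OcKernelSpec) -> dict:
    return {
        "neurons": len(set(spec.neurons)),
        "inner_synapses": len(spec.inner_synapses),
        "habituation_rules": sum(s.habituation is not None for s in spec.inner_synapses),
        "stdp_rules": sum(s.stdp is not None for s in spec.inner_synapses),
    }


# ---------------------------------------------------------------------------
# Shared parameter helpers
# ---------------------------------------------------------------------------

def _habituation(cfg: dict) -> HabituationState:
    return HabituationState(
        floor=cfg["habituation_floor"],
        decay_buckets=tuple(tuple(b) for b in cfg["habituation_buckets"]),
        recovery_delay=cfg["habituation_recovery_delay"],
        recovery_step=cfg["habituation_recovery_step"],
        recovery_period=cfg["habituation_recovery_period"],
    )


def _stdp(cfg: dict) -> StdpState:
    return StdpState(
        window=cfg["stdp_window"],
        potentiation_curve=build_stdp_curves(
            cfg["stdp_window"], cfg["stdp_peak"], cfg["stdp_slope_cycles"]),
        depression_curve=build_stdp_curves(
            cfg["stdp_window"], cfg["stdp_depression_peak"], cfg["stdp_slope_cycles"]),
        recovery_delay=cfg["stdp_recovery_delay"],
        recovery_period=cfg["stdp_recovery_period"],
    )


def _adaptation(cfg: dict) -> AdaptationState:
    return AdaptationState(
        decay_fraction=cfg["adaptation_decay_fraction"],
        recovery_fraction=cfg["adaptation_recovery_fraction"],
    )


def _config(weights: Optional[dict]) -> dict:
    cfg = dict(DEFAULTS)
    if weights:
        unknown = set(weights) - set(DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown parameter overrides: {sorted(unknown)}")
        cfg.update(weights)
    return cfg


def predictor_fire_weight(psp_table: Optional[PspTable] = None,
                          params: Optional[NeuronParams] = None) -> int:
    """Smallest synaptic weight whose lone PSP fires a resting neuron.

    This is the threshold the Cue->Predictor weight must cross for the cue
    alone to trigger the Predictor; derived from the shipped lookup tables,
    and used by the phase classifier to locate the acquisition point.
    """
    table = psp_table or build_psp_table()
    params = params or NeuronParams()
    for w in range(101):
        state = NeuronState.resting(params)
        for cycle, delta in enumerate(table.curve(w)):
            state = integrate_cycle(state, params, [delta], cycle)
            if state.spiked_this_cycle:
                return w
    raise ConfigurationError("no weight fires a resting neuron; PSP table miscalibrated")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_kernel(
    cue_channel: str,
    reinforcer_channel: str,
    action_name: str,
    polarity: str = REWARD_SEEKING,
    weights: Optional[dict] = None,
    prefix: str = "",
    validate: bool = True,
) -> tuple[NetworkSpec, OcKernelSpec]:
    """The canonical single kernel with its contextual outer box.

    Outer box: cue transducer -> sensory relay -> Cue; reinforcer transducer
    -> sensory relay -> Predictor; Action -> motor relay -> actuator.  With
    ``polarity='punishment-avoiding'`` the Action->motor link is inhibitory,
    so learning decreases rather than increases the overt behavior.
    """
    if polarity not in (REWARD_SEEKING, PUNISHMENT_AVOIDING):
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    cfg = _config(weights)
    p = prefix
    net = NetworkSpec()
    for nid in ("cue_in", "cue", "action", "predictor", "reinf_in", "motor"):
        net.neurons[p + nid] = NeuronParams()

    cue_action = SynapseSpec(p + "cue", p + "action", cfg["cue_action_weight"],
                             habituation=_habituation(cfg))
    cue_predictor = SynapseSpec(p + "cue", p + "predictor", cfg["cue_predictor_weight"],
                                stdp=_stdp(cfg))
    predictor_action = SynapseSpec(p + "predictor", p + "action",
                                   cfg["predictor_action_weight"])
    net.synapses += [
        SynapseSpec(p + "cue_in", p + "cue", cfg["sensor_weight"]),
        cue_action,
        cue_predictor,
        predictor_action,
        SynapseSpec(p + "reinf_in", p + "predictor", cfg["reinforcer_weight"]),
        SynapseSpec(p + "action", p + "motor", cfg["motor_weight"],
                    polarity=INHIBITORY if polarity == PUNISHMENT_AVOIDING else EXCITATORY),
    ]
    reinf_tr = Transducer(reinforcer_channel, p + "reinf_in")
    net.transducers += [Transducer(cue_channel, p + "cue_in"), reinf_tr]
    net.actuators.append(Actuator(p + "motor", action_name))

    kernel = OcKernelSpec(p + "cue", p + "action", p + "predictor",
                          cue_action, cue_predictor, predictor_action,
                          reinf_tr, polarity)
    if validate:
        kernel.validate()
    return net.validate(), kernel


def build_dual_kernel(
    shared_cue_channel: str,
    reward_channel: str,
    punishment_channel: str,
    action_name: str,
    weights: Optional[dict] = None,
    prefix: str = "",
) -> tuple[NetworkSpec, dict[str, OcKernelSpec]]:
    """Two opposing kernels on a shared cue path.

    The reward kernel is the canonical one.  The punishment kernel shares
    Cue and Action; its own Predictor is driven by the punishment reinforcer
    and couples to Action with an inhibitory link of the same intermediate
    strength, so a learned punishment prediction vetoes the behavior.  One
    inhibitory interneuron per direction implements the mutual inhibition
    between the opposing predictions.
    """
    cfg = _config(weights)
    net, kernel_r = build_kernel(shared_cue_channel, reward_channel, action_name,
                                 weights=weights, prefix=prefix)
    p = prefix
    for nid in ("predictor_p", "punish_in", "inhib_r", "inhib_p"):
        net.neurons[p + nid] = NeuronParams()

    cue_predictor_p = SynapseSpec(p + "cue", p + "predictor_p",
                                  cfg["cue_predictor_weight"], stdp=_stdp(cfg))
    predictor_p_action = SynapseSpec(p + "predictor_p", p + "action",
                                     cfg["inhibition_weight"], polarity=INHIBITORY)
    punish_tr = Transducer(punishment_channel, p + "punish_in")
    net.synapses += [
        cue_predictor_p,
        predictor_p_action,
        SynapseSpec(p + "punish_in", p + "predictor_p", cfg["reinforcer_weight"]),
        # mutual inhibition between the opposing predictions
        SynapseSpec(p + "predictor", p + "inhib_r", cfg["interneuron_weight"]),
        SynapseSpec(p + "inhib_r", p + "predictor_p", cfg["mutual_inhibition_weight"],
                    polarity=INHIBITORY),
        SynapseSpec(p + "predictor_p", p + "inhib_p", cfg["interneuron_weight"]),
        SynapseSpec(p + "inhib_p", p + "predictor", cfg["mutual_inhibition_weight"],
                    polarity=INHIBITORY),
    ]
    net.transducers.append(punish_tr)

    kernel_p = OcKernelSpec(p + "cue", p + "action", p + "predictor_p",
                            kernel_r.cue_action, cue_predictor_p, predictor_p_action,
                            punish_tr, PUNISHMENT_AVOIDING)
    kernel_p.validate()
    return net.validate(), {"reward": kernel_r, "punishment": kernel_p}


def build_multicue_kernels(
    cue_channels: list[str],
    shared_action: str,
    reward_channel: str = "light",
    punishment_channel: Optional[str] = None,
    weights: Optional[dict] = None,
) -> tuple[NetworkSpec, dict[str, OcKernelSpec]]:
    """One kernel per cue channel, sharing a single Action neuron.

    Cue transducers attach directly to their sensory Cue neurons and carry
    sensory adaptation, so a constant cue throttles itself.  All kernels
    share the Action/motor path and the reinforcer relays.  When a
    punishment channel is given, each cue gets an opposing predictor pair
    (reward and punishment), as in the dual kernel.
    """
    if len(cue_channels) < 2:
        raise ConfigurationError("multicue composition needs at least two cue channels")
    cfg = _config(weights)
    net = NetworkSpec()
    net.neurons["action"] = NeuronParams()
    net.neurons["motor"] = NeuronParams()
    net.neurons["reward_in"] = NeuronParams()
    net.synapses.append(SynapseSpec("action", "motor", cfg["motor_weight"]))
    net.actuators.append(Actuator("motor", shared_action))
    reward_tr = Transducer(reward_channel, "reward_in")
    net.transducers.append(reward_tr)
    punish_tr = None
    if punishment_channel is not None:
        net.neurons["punish_in"] = NeuronParams()
        punish_tr = Transducer(punishment_channel, "punish_in")
        net.transducers.append(punish_tr)

    kernels: dict[str, OcKernelSpec] = {}
    for ch in cue_channels:
        tag = ch.split("-")[-1]
        cue, pred_r = f"cue_{tag}", f"predictor_r_{tag}"
        net.neurons[cue] = NeuronParams()
        net.neurons[pred_r] = NeuronParams()
        cue_action = SynapseSpec(cue, "action", cfg["cue_action_weight"],
                                 habituation=_habituation(cfg))
        cue_pred_r = SynapseSpec(cue, pred_r, cfg["cue_predictor_weight"], stdp=_stdp(cfg))
        pred_r_action = SynapseSpec(pred_r, "action", cfg["predictor_action_weight"])
        net.synapses += [cue_action, cue_pred_r, pred_r_action,
                         SynapseSpec("reward_in", pred_r, cfg["reinforcer_weight"])]
        net.transducers.append(Transducer(ch, cue, adaptation=_adaptation(cfg)))
        kernels[f"{tag}:reward"] = OcKernelSpec(
            cue, "action", pred_r, cue_action, cue_pred_r, pred_r_action,
            reward_tr, REWARD_SEEKING).validate()

        if punish_tr is not None:
            pred_p = f"predictor_p_{tag}"
            net.neurons[pred_p] = NeuronParams()
            cue_pred_p = SynapseSpec(cue, pred_p, cfg["cue_predictor_weight"], stdp=_stdp(cfg))
            pred_p_action = SynapseSpec(pred_p, "action", cfg["inhibition_weight"],
                                        polarity=INHIBITORY)
            net.synapses += [cue_pred_p, pred_p_action,
                             SynapseSpec("punish_in", pred_p, cfg["reinforcer_weight"])]
            kernels[f"{tag}:punishment"] = OcKernelSpec(
                cue, "action", pred_p, cue_action, cue_pred_p, pred_p_action,
                punish_tr, PUNISHMENT_AVOIDING).validate()
    return net.validate(), kernels
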