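"""Shipped default parameters.

Everything here is config: none of these numbers is hard-wired in the
simulation code.  The kernel weights, habituation steps and STDP shape are
the output of :func:`spikeoc.scenarios.calibrate_defaults`, which searches a
small deterministic grid for the first configuration meeting the timeline
constraints of the reference protocols (reflex cessation near cycle 100,
acquisition complete before reward removal, punishment reversal completing
within its phase).  A regression test asserts that rerunning the calibration
reproduces this bundle exactly.
"""

DEFAULTS = {
    # kernel weights (must satisfy cue_action > predictor_action > cue_predictor)
    "cue_action_weight": 90,
    "predictor_action_weight": 60,
    "cue_predictor_weight": 20,
    # outer-box static weights
    "sensor_weight": 95,
    "reinforcer_weight": 95,
    "motor_weight": 95,
    "inhibition_weight": 60,      # predictor->action on the punishment side
    "interneuron_weight": 95,     # predictor->inhibitory-interneuron drive
    "mutual_inhibition_weight": 90,
    # habituation
    "habituation_buckets": ((3, 8), (10, 5), (12, 3), (None, 4)),
    "habituation_floor": 0,
    "habituation_recovery_delay": 150,
    "habituation_recovery_step": 1,
    "habituation_recovery_period": 6,
    # STDP
    "stdp_window": 15,
    "stdp_peak": 8,
    "stdp_depression_peak": 4,
    "stdp_slope_cycles": 2,
    "stdp_recovery_delay": 250,
    "stdp_recovery_period": 3,
    # sensory adaptation
    "adaptation_decay_fraction": 0.015,
    "adaptation_recovery_fraction": 0.10,
    # scenario pacing
    "cue_period": 12,
    "reinforcer_latency": 2,
    "cycles_per_zone": 100,
    "piece_interval": 50,
    "piece_interval_jitter": 5,
    "piece_visible_cycles": 15,
    "touch_latency_jitter": 3,
}
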