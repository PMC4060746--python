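"""Model configuration.

All tunable parameters live here, each with a provenance tag:

* ``"stated"``   — the value is stated in the source description of the
  model's simulation protocol (scene geometry, background luminance,
  vigilance regime, trial counts, kernel counts);
* ``"default"``  — the governing equations' per-stage coefficients are not
  published at full precision; these are this package's defaults, chosen so
  the model operates in the published regime (0.3 s fixations, ~1.3 s shroud
  epochs, direct searches faster than indirect ones).

One model time unit equals one second, so fixation durations and search
latencies are directly comparable to published values; the global Euler step
is 1 ms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class ModelConfig:
    # -- geometry (desk scale: 100 px scenes, 20 px regions) ----------------
    scene_side: int = 100            # stated (500 full scale; 100 desk scale)
    dt: float = 1e-3                 # default: 1 ms Euler step
    # -- front end ----------------------------------------------------------
    n_orientations: int = 4          # stated: "four orientations"
    scale_half_widths: tuple = (1.0, 2.0, 4.0)  # stated count (3), default widths
    lgn_decay: float = 1.0           # default
    surround_ratio: float = 3.0      # default: surround sigma / center sigma
    boundary_lambda1: float = 0.5    # default: surface-contour feedback gain
    boundary_lambda2: float = 4.0    # default: category-prime feedback gain
    boundary_inh: float = 0.3        # default: feedback off-surround gain
    fill_decay: float = 1e-3         # default: FIDO leak (long diffusion length)
    fill_perm: float = 2.0           # default: baseline diffusion permeability
    fill_mu: float = 2000.0          # default: boundary block of diffusion
    fill_attention_gain: float = 0.3 # default: shroud contrast enhancement
    contour_center_hw: float = 1.0   # default
    contour_surround_hw: float = 3.0 # default
    contour_decay: float = 0.1      # default
    # -- shroud / where stream ---------------------------------------------
    shroud_rate: float = 20.0        # default: 50 ms membrane time constant
    shroud_input_quench: float = 0.3 # default: input quenching threshold
    shroud_input_gain: float = 3.0   # default
    shroud_recurrent_gain: float = 0.8   # default (gain on gated input)
    shroud_recurrent_sigma: float = 2.0  # default
    shroud_hyper: float = 0.5        # default: reset hyperpolarization depth
    shroud_reset_gain: float = 6.0   # default
    shroud_gate_recovery: float = 0.05   # default: slow (multi-second) recovery
    shroud_gate_depletion: float = 1.8   # default: calibrated for ~1.25 s epochs
    shroud_onset_total: float = 10.0 # default: epoch-onset threshold (activity sum)
    reset_epsilon: float = 0.4       # default per design: ratio reset threshold
    reset_rate: float = 80.0         # default: fast disinhibitory burst
    reset_gate_recovery: float = 1.5 # default: replenished before next epoch
    reset_gate_depletion: float = 25.0   # default: burst < 0.3 s
    # -- eye movement map ---------------------------------------------------
    eye_decay: float = 2.0           # default
    eye_contour_gain: float = 2.9    # default: ~0.25 s choice latency
    eye_direct_gain: float = 4.6     # default: ~0.15 s choice latency
    eye_threshold: float = 0.4       # default saccade decision threshold
    eye_global_inh: float = 0.5      # default
    ior_recovery: float = 0.5        # default: ~2 s gate recovery
    ior_radius: float = 3.0          # default: px, neighborhood depleted per fixation
    saccade_refractory: float = 0.05 # default: s, post-saccadic input suppression
    # -- what stream --------------------------------------------------------
    vigilance: float = 0.93          # default (one-trial regime stated)
    art_alpha: float = 0.01          # default choice parameter
    art_beta: float = 1.0            # stated: fast one-trial learning
    feature_grid: int = 10           # default pooling grid per region
    feature_scales: tuple = (0,)     # default: categorize on the finest scale
    category_capacity: int = 512     # default
    integrator_tau: float = 10.0     # default: persists across a shroud epoch
    integrator_threshold: float = 0.35   # default firing threshold
    invariant_capacity: int = 288    # default
    invariant_lambda_slow: float = 0.05  # stated: slow inter-layer learning rate
    direct_route_rate: float = 0.2   # default: category->position Hebb rate
    # -- cognitive-emotional circuit ---------------------------------------
    n_value: int = 3                 # stated: three value categories
    rate_conditioned: float = 0.1    # default per design
    rate_incentive: float = 0.1      # default per design
    rate_ita_orb: float = 0.1        # default per design
    rate_name: float = 0.2           # default per design
    volition_gain_on: float = 1.2    # default: driving top-down efficacy
    volition_gain_off: float = 0.3   # default: modulatory top-down efficacy
    firing_threshold: float = 0.35   # default: category firing threshold
    stage_rate: float = 12.0         # default: category-stage membrane rate (1/s)
    stage_input_gain: float = 3.0    # default: synaptic gain into category stages
    orb_prime_additive: float = 0.4  # default: additive share of ORB primes
    ita_feedback_gain: float = 3.0   # default: ORB->ITa resonant amplification
    surface_reprocess_rate: float = 20.0  # default: V2/V4 re-filtering lag (1/s)
    # -- competition --------------------------------------------------------
    quench_threshold: float = 0.5    # default per design
    winner_margin: float = 1.5       # default per design
    # -- protocol -----------------------------------------------------------
    trials_per_position: int = 40    # stated: 40 training trials per position
    search_timeout: float = 1.5      # default: s, not-found timeout

    @property
    def region_side(self) -> int:
        return self.scene_side // 5

    def to_json(self) -> str:
        d = asdict(self)
        d["provenance"] = PROVENANCE
        return json.dumps(d, indent=1, default=list)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d.pop("provenance", None)
        names = {f.name for f in fields(cls)}
        d = {k: (tuple(v) if isinstance(v, list) else v)
             for k, v in d.items() if k in names}
        return cls(**d)


PROVENANCE = {
    "stated": ["scene_side", "n_orientations", "n_value", "art_beta",
               "invariant_lambda_slow", "trials_per_position"],
    "default": "all remaining coefficients (stage equations unpublished at "
               "full precision); see docs/methods.md",
}
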