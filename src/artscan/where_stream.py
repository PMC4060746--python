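"""Where stream: gain-field coordinate transforms, the attentional shroud,
transient category reset, and the salient-feature eye-movement map with
inhibition of return.

The attentional shroud is a form-fitting distribution of spatial attention
computed in head-centric coordinates.  It is selected by recurrent
on-center off-surround competition over the (gain-field transformed) surface
input, sustained by surface-shroud positive feedback, and slowly undermined
by activity-dependent habituative gates whose depletion eventually lets the
shroud total fall below a ratio threshold of its onset peak.  That event
fires a transient parietal reset burst which collapses the resonance and
frees spatial attention to shift to another object.

Eye movements are chosen on a saccade map driven by shroud-masked surface
contours; habituative gates on recently fixated positions implement
inhibition of return, so successive fixations visit different salient
features (corners, intersections) of the attended surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ModelConfig
from .dynamics import HabituativeGate, habituate_step
from .scene import region_of, translate

__all__ = ["EyeState", "ShroudState", "ResetState", "EyeMovementMap",
           "gain_field_fwd", "gain_field_bwd", "update_shroud", "check_reset",
           "salient_features", "next_saccade", "apply_ior",
           "shroud_retinotopic"]


@dataclass
class EyeState:
    """Current eye position in head-centric pixels plus any planned target.

    ``position`` is where the fovea points in the head-centric (scene-fixed)
    frame; the retinotopic frame is centered on it.  A planned saccade target
    is set strictly before execution so that gain fields can remap
    predictively.
    """

    position: tuple = (0, 0)
    planned: tuple | None = None
    fixation_onset: float = 0.0

    def effective(self):
        """Eye signal used by the gain fields: the planned position once a
        saccade is pending (predictive remapping), else the current one."""
        return self.planned if self.planned is not None else self.position


@dataclass
class ShroudState:
    """Head-centric spatial attention field with per-position habituative
    gates and onset-peak bookkeeping for the ratio reset rule."""

    activity: np.ndarray
    gates: HabituativeGate
    onset_peak: float = 0.0
    epoch_active: bool = False
    epoch_count: int = 0
    winner_mask: np.ndarray | None = None

    @classmethod
    def blank(cls, side: int, cfg: ModelConfig) -> "ShroudState":
        return cls(np.zeros((side, side)),
                   HabituativeGate(np.ones((side, side)),
                                   cfg.shroud_gate_recovery,
                                   cfg.shroud_gate_depletion))

    @property
    def total(self) -> float:
        return float(self.activity.sum())


@dataclass
class ResetState:
    """Tonic reset population, its habituative gate, and the What-stream
    reset latch."""

    activity: float = 0.0
    gate: HabituativeGate = field(
        default_factory=lambda: HabituativeGate(1.0, 1.5, 25.0))
    latch: bool = False          # What-stream reset: persists to next shroud
    events: list = field(default_factory=list)
    firing: bool = False

    @classmethod
    def blank(cls, cfg: ModelConfig) -> "ResetState":
        return cls(gate=HabituativeGate(1.0, cfg.reset_gate_recovery,
                                        cfg.reset_gate_depletion))

    @property
    def where_output(self) -> float:
        """Transient (gated) Where-stream reset burst."""
        return self.activity * float(self.gate.level)


@dataclass
class EyeMovementMap:
    """Saccade-choice field with per-position IOR gates."""

    activity: np.ndarray
    ior: HabituativeGate
    refractory_until: float = 0.0

    @classmethod
    def blank(cls, side: int, cfg: ModelConfig) -> "EyeMovementMap":
        return cls(np.zeros((side, side)),
                   HabituativeGate(np.ones((side, side)), cfg.ior_recovery, 0.0))


def _offset(eye_pos, side):
    cr = cc = (side - 1) // 2
    return int(round(eye_pos[0])) - cr, int(round(eye_pos[1])) - cc


def gain_field_fwd(retinotopic: np.ndarray, eye: EyeState) -> np.ndarray:
    """Retinotopic -> head-centric transform: translate the map by the eye
    position (the planned one if a saccade is pending).  Realized as an exact
    integer-pixel shift; pixels without support are zero."""
    dr, dc = _offset(eye.effective(), retinotopic.shape[0])
    return translate(retinotopic, dr, dc, 0.0)


def gain_field_bwd(head_centric: np.ndarray, eye: EyeState) -> np.ndarray:
    """Head-centric -> retinotopic transform (inverse shift)."""
    dr, dc = _offset(eye.effective(), head_centric.shape[0])
    return translate(head_centric, -dr, -dc, 0.0)


def shroud_retinotopic(s: ShroudState, eye: EyeState) -> np.ndarray:
    return gain_field_bwd(s.activity, eye)


def update_shroud(attention_input: np.ndarray, s: ShroudState,
                  reset_signal: float, cfg: ModelConfig,
                  dt: float | None = None) -> ShroudState:
    """One step of the recurrent shroud competition.

    The long-range off-surround resolves to a choice among candidate
    surfaces: connected components of the (quench-thresholded) surface input
    compete by total gated strength, and the strongest blob wins the shroud
    for the duration of the epoch (the winner-take-all endpoint of the
    recurrent competition, applied algorithmically for robustness).
    Within the winning blob, shunting field dynamics track the gated input
    with short-range recurrent gain; the reset burst inhibits
    nonspecifically; per-position habituative gates deplete under sustained
    shroud activity — the drive traverses a gated pathway on both legs of
    the surface-shroud loop, hence the squared transmitter level — so the
    resonance eventually collapses.
    """
    if np.any(attention_input < 0):
        raise ValueError("attention input must be nonnegative")
    dt = cfg.dt if dt is None else dt
    a = s.activity
    amax = attention_input.max()
    # absolute floor: numerical residue of an empty scene is not signal
    u = attention_input / amax if amax > 1e-6 \
        else np.zeros_like(attention_input)
    # quenching threshold: diffuse sub-threshold surface activity (filling-in
    # leakage) does not recruit spatial attention
    q = cfg.shroud_input_quench
    u = np.maximum(u - q, 0.0) / (1.0 - q)
    drive = u * np.asarray(s.gates.level) ** 2
    mask = s.winner_mask
    if mask is None:
        # new competition: strongest gated blob wins; ties broken toward
        # the lowest row-major position
        labels, nlab = ndimage.label(u > 0)
        if nlab:
            # strength = mean gated drive over the blob: a contrast measure,
            # so a small high-contrast surface can out-compete a large one
            # whose transmitters are depleted
            strengths = ndimage.mean(drive, labels, index=range(1, nlab + 1))
            strengths = np.asarray(strengths) + 1e-9 * np.arange(nlab, 0, -1)
            mask = labels == (int(np.argmax(strengths)) + 1)
        else:
            mask = None
    if mask is None:
        E = np.zeros_like(a)
    else:
        local = ndimage.gaussian_filter(a, cfg.shroud_recurrent_sigma)
        E = cfg.shroud_input_gain * drive * mask \
            * (1.0 + cfg.shroud_recurrent_gain * local)
    I = cfg.shroud_reset_gain * reset_signal
    a = a + dt * cfg.shroud_rate * (-a + (1.0 - a) * E
                                    - (a + cfg.shroud_hyper) * I)
    a = np.clip(a, 0.0, 1.0)
    gates = habituate_step(s.gates, a, dt)
    out = ShroudState(a, gates, s.onset_peak, s.epoch_active, s.epoch_count,
                      mask)
    total = out.total
    if not out.epoch_active and total > cfg.shroud_onset_total:
        out.epoch_active = True
        out.epoch_count += 1
        out.onset_peak = total
    elif out.epoch_active:
        out.onset_peak = max(out.onset_peak, total)
    return out


def check_reset(s: ShroudState, r: ResetState, cfg: ModelConfig,
                t: float, dt: float | None = None) -> ResetState:
    """Ratio reset rule with disinhibitory collapse.

    While the shroud total stays above ``epsilon`` times its onset peak the
    tonic reset population is held off.  Once the ratio drops below
    ``epsilon`` the population is disinhibited and its (habituatively gated)
    output bursts, inhibiting the shroud — which disinhibits the reset
    further until the resonance fully collapses.  The Where output is the
    transient gated burst; the What-stream latch persists until the next
    shroud onset.
    """
    dt = cfg.dt if dt is None else dt
    out = ResetState(r.activity, r.gate, r.latch, list(r.events), r.firing)
    ratio = s.total / s.onset_peak if (s.epoch_active and s.onset_peak > 0) else 1.0
    # disinhibited tonic drive (amplitude 3 so the burst saturates near
    # B*3/4 rather than B/2)
    drive = 3.0 if (s.epoch_active and ratio < cfg.reset_epsilon) else 0.0
    if drive and not out.firing:
        out.firing = True
        out.latch = True
        out.events.append(t)
    if not s.epoch_active:
        out.firing = False
    act = out.activity + dt * cfg.reset_rate * (
        -out.activity + (1.0 - out.activity) * drive)
    out.activity = float(np.clip(act, 0.0, 1.0))
    out.gate = habituate_step(out.gate, out.activity, dt)
    return out


def clear_epoch(s: ShroudState) -> ShroudState:
    """End the current shroud epoch after a completed reset burst."""
    return ShroudState(np.zeros_like(s.activity), s.gates, 0.0, False,
                       s.epoch_count)


def attention_cycle_step(attention_input: np.ndarray, s: ShroudState,
                         r: ResetState, cfg: ModelConfig, t: float):
    """Coupled shroud + reset step implementing the full attention cycle.

    The disinhibitory loop between shroud collapse and reset firing ends
    when the reset burst's transmitter has emptied; at that point the
    residual resonance is extinguished outright and the epoch closes, so a
    fresh competition (biased against the just-attended object by its
    depleted gates) selects the next shroud.  Returns ``(shroud, reset,
    epoch_closed)``.
    """
    s = update_shroud(attention_input, s, r.where_output, cfg)
    r = check_reset(s, r, cfg, t)
    closed = False
    if r.firing and r.activity > 0.5 and float(r.gate.level) < 0.1:
        s = clear_epoch(s)
        r.firing = False
        r.activity = 0.0
        closed = True
    return s, r, closed


def salient_features(contours: np.ndarray, s: ShroudState, eye: EyeState,
                     cfg: ModelConfig) -> np.ndarray:
    """Saccade-target input: surface contours masked by the retinotopically
    back-transformed shroud, normalized to unit maximum.

    Without an active shroud the map stays at a weak baseline so no position
    reaches the saccade threshold; with a shroud, candidate targets lie on
    the attended surface only.
    """
    if not s.epoch_active or s.activity.max() <= 0:
        cmax = contours.max()
        return 0.2 * contours / cmax if cmax > 0 else np.zeros_like(contours)
    mask = shroud_retinotopic(s, eye)
    mask = mask / mask.max() if mask.max() > 0 else mask
    f = contours * mask
    fmax = f.max()
    return f / fmax if fmax > 0 else f


def next_saccade(m: EyeMovementMap, feature_input: np.ndarray,
                 direct_input: np.ndarray | None, t: float,
                 cfg: ModelConfig, dt: float | None = None):
    """One step of the contrast-enhancing saccade choice.

    Inputs are gated by per-position IOR transmitters; a direct
    category-to-position associative readout adds to the contour-driven
    input.  Returns ``(map, target-or-None)``: the most active position is
    returned once it crosses the decision threshold.
    """
    dt = cfg.dt if dt is None else dt
    a = m.activity
    if t < m.refractory_until:
        drive = np.zeros_like(a)
    else:
        drive = cfg.eye_contour_gain * feature_input
        if direct_input is not None:
            drive = drive + cfg.eye_direct_gain * direct_input
        drive = drive * m.ior.level
    a = a + dt * (-cfg.eye_decay * a + (1.0 - a) * drive
                  - a * cfg.eye_global_inh * a.mean() * a.size / 400.0)
    a = np.clip(a, 0.0, 1.0)
    out = EyeMovementMap(a, m.ior, m.refractory_until)
    if a.max() >= cfg.eye_threshold:
        target = np.unravel_index(int(np.argmax(a)), a.shape)
        return out, (int(target[0]), int(target[1]))
    return out, None


def apply_ior(m: EyeMovementMap, target, t: float, cfg: ModelConfig
              ) -> EyeMovementMap:
    """Post-saccadic bookkeeping: deplete IOR gates around the fixated
    position, clear the choice field, and hold inputs off briefly."""
    side = m.activity.shape[0]
    y, x = np.mgrid[0:side, 0:side]
    d2 = (y - target[0]) ** 2 + (x - target[1]) ** 2
    level = np.asarray(m.ior.level, dtype=float).copy()
    level[d2 <= cfg.ior_radius**2] *= 0.02
    ior = HabituativeGate(level, m.ior.recovery_rate, m.ior.depletion_rate)
    return EyeMovementMap(np.zeros_like(m.activity), ior,
                          refractory_until=t + cfg.saccade_refractory)


def step_ior_recovery(m: EyeMovementMap, dt: float) -> EyeMovementMap:
    return EyeMovementMap(m.activity, habituate_step(m.ior, 0.0, dt),
                          m.refractory_until)
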