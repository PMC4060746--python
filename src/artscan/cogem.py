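"""Cognitive-emotional circuit: value categories (amygdala), object-value
categories (orbitofrontal cortex), name categories (prefrontal cortex),
their four families of learned weights, and volitional gating.

Learning is gated Hebbian: conditioned-reinforcer weights (object category
-> value category) and incentive-motivational weights (value -> object-value)
are many-to-one; object-category -> object-value and name <-> object-value
weights are effectively one-to-one after training.  Top-down connections are
modulatory: a prime alone cannot fire its target unless basal-ganglia
volition raises the synaptic efficacy from modulatory to driving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .dynamics import QuenchParams, quench_compete

__all__ = ["VolitionSignal", "CogEMState"]


@dataclass
class VolitionSignal:
    """Basal-ganglia gates for the top-down pathways; all off during passive
    viewing, all on during goal-directed search."""

    orb: bool = False
    ita: bool = False
    integrator: bool = False

    @classmethod
    def all_on(cls):
        return cls(True, True, True)

    @classmethod
    def all_off(cls):
        return cls(False, False, False)


@dataclass
class CogEMState:
    """Activities and adaptive weights of the value / object-value / name
    layers for ``n_objects`` object categories and ``n_value`` drives."""

    cfg: ModelConfig
    n_objects: int = 24
    value: np.ndarray = None
    orb: np.ndarray = None
    name: np.ndarray = None
    w_cond: np.ndarray = None      # object -> value (conditioned reinforcer)
    w_inc: np.ndarray = None       # value -> object-value (incentive)
    w_ita_orb: np.ndarray = None   # object -> object-value
    w_name_orb: np.ndarray = None  # name -> object-value
    w_orb_name: np.ndarray = None  # object-value -> name (ablatable)
    orb_name_ablated: bool = False

    def __post_init__(self):
        n, v = self.n_objects, self.cfg.n_value
        if self.value is None:
            self.value = np.zeros(v)
            self.orb = np.zeros(n)
            self.name = np.zeros(n)
            self.w_cond = np.zeros((n, v))
            self.w_inc = np.zeros((v, n))
            # innate weak one-to-one scaffold: an object category projects
            # to its object-value cell before any conditioning, so
            # bottom-up input alone fires the cell weakly; learning
            # strengthens the pathway
            self.w_ita_orb = 0.7 * np.eye(n)
            self.w_name_orb = np.zeros((n, n))
            self.w_orb_name = np.zeros((n, n))

    def _quench(self):
        return QuenchParams(self.cfg.quench_threshold, 1.0,
                            self.cfg.winner_margin)

    # -- dynamics -----------------------------------------------------------

    def update_value(self, ita: np.ndarray, reinforcer=None, drive=None):
        """Value-category activation: external drive plus reinforcer plus
        conditioned-reinforcer input from active object categories, resolved
        by the normalized quenching competition.  With no input and zero
        learned weights the layer sits at rest."""
        x = self.w_cond.T @ np.asarray(ita, dtype=float)[: self.n_objects]
        if reinforcer is not None:
            x = x + reinforcer
        if drive is not None:
            x = x + drive
        self.value = np.where(x > 1e-12, quench_compete(x, self._quench()), 0.0)
        return self.value

    def update_object_value(self, ita: np.ndarray, volition: VolitionSignal,
                            name_prime: np.ndarray | None = None):
        """Object-value activation.

        Bottom-up object-category input alone fires weakly; bottom-up plus
        incentive fires strongly; a prime (incentive or name) alone fires
        only when the volition gate raises its efficacy to driving.
        """
        cfg = self.cfg
        ita = np.asarray(ita, dtype=float)[: self.n_objects]
        bu = self.w_ita_orb.T @ ita
        g = cfg.volition_gain_on if volition.orb else cfg.volition_gain_off
        top = self.w_inc.T @ self.value
        if name_prime is not None:
            top = top + self.w_name_orb.T @ np.asarray(name_prime)[: self.n_objects]
        # convergent activation: incentive/name primes act chiefly as a
        # gain on the bottom-up object-category input (bottom-up and
        # motivational inputs *together* fire the cell strongly), with a
        # weak additive share that lets a volitionally enhanced prime fire
        # the cell supraliminally on its own
        x = bu * (1.0 + g * top) + cfg.orb_prime_additive * g * top
        fired = np.where(x >= cfg.firing_threshold, x, 0.0)
        self.orb = quench_compete(fired, self._quench()) \
            if fired.any() else np.zeros_like(x)
        self.subliminal = x
        return self.orb

    def update_name(self, prime: np.ndarray | None = None):
        """Name-category activation from an external name prime and/or
        object-value feedback (unless ablated)."""
        x = np.zeros(self.n_objects)
        if prime is not None:
            x = x + np.asarray(prime, dtype=float)[: self.n_objects]
        if not self.orb_name_ablated:
            x = x + self.w_orb_name.T @ self.orb
        self.name = np.where(x > 1e-12, quench_compete(x, self._quench()), 0.0)
        return self.name

    def orb_to_ita_feedback(self, volition: VolitionSignal) -> np.ndarray:
        """Top-down motivated-attention prime from object-value categories
        back to their object-category sources: modulatory without volition,
        driving with it (closing the IT-amygdala-orbitofrontal loop)."""
        g = self.cfg.volition_gain_on if volition.ita \
            else self.cfg.volition_gain_off
        return g * (self.w_ita_orb @ self.orb)

    # -- learning -----------------------------------------------------------

    def learn(self, ita: np.ndarray, what_reset: bool = False,
              pre_thr: float = 0.2, post_thr: float = 0.2):
        """Gated-Hebbian update of all four weight families.

        Weights grow toward 1 only where both pre- and post-synaptic
        activities exceed threshold; no learning while the What-stream reset
        latch is high.
        """
        if what_reset:
            return
        cfg = self.cfg
        ita = np.asarray(ita, dtype=float)[: self.n_objects]
        pre_obj = (ita > pre_thr) * ita

        def hebb(w, pre, post, rate):
            mask = np.outer(pre > 0, post > post_thr)
            w += rate * np.outer(pre, post) * (1.0 - w) * mask

        hebb(self.w_cond, pre_obj, self.value, cfg.rate_conditioned)
        hebb(self.w_inc, (self.value > post_thr) * self.value, self.orb,
             cfg.rate_incentive)
        hebb(self.w_ita_orb, pre_obj, self.orb, cfg.rate_ita_orb)
        hebb(self.w_name_orb, (self.name > post_thr) * self.name, self.orb,
             cfg.rate_name)
        hebb(self.w_orb_name, (self.orb > post_thr) * self.orb, self.name,
             cfg.rate_name)

    # -- priming ------------------------------------------------------------

    def prime_inputs(self, source: str, index: int):
        """External prime vectors for a search trial.

        ``source`` is 'name' (cognitive search: a name category is primed)
        or 'drive' (motivational search: a value category receives an
        internal drive input).  Returns (name_prime, drive_input).
        """
        if source == "name":
            p = np.zeros(self.n_objects)
            p[index] = 1.0
            return p, None
        if source == "drive":
            d = np.zeros(self.cfg.n_value)
            d[index] = 1.0
            return None, d
        raise ValueError(f"unknown prime source {source!r}")
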