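"""What stream: positionally organized view-specific categories (Fuzzy ART),
view category integrators, and view- and positionally-invariant object
categories with reciprocal learned links.

Each of the 25 scene regions owns a bank of view-specific category nodes
trained by Fuzzy ART on complement-coded boundary features pooled from that
region.  A view category's integrator stays active after its category is
reset by a saccade, bridging successive views of the attended object so that
they can all be associated with one emerging invariant object category.
The invariant layer competes via the normalized quenching competition and is
cleared by the What-stream reset latch, which is set by the parietal reset
burst and held until the next shroud forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .dynamics import QuenchParams, quench_compete
from .frontend import BoundaryMap
from .scene import FOVEA_REGION, bounds_of

__all__ = ["ViewCategoryBank", "IntegratorLayer", "InvariantCategoryLayer",
           "WhatResetLatch", "extract_view_vector", "art_classify",
           "learn_direct_route"]


def extract_view_vector(bmap: BoundaryMap, region: int, cfg: ModelConfig
                        ) -> np.ndarray:
    """Pool a region's oriented boundary activities into a complement-coded
    feature vector.

    Each oriented channel of the categorization scales (the finest scale by
    default: its receptive fields stay inside the region, so a neighboring
    object cannot contaminate the view) is block-averaged to a g x g grid
    over the region crop; the stack is flattened, rescaled to [0, 1] by its
    own maximum, and complement coded, so the coded vector's city-block norm
    equals the feature dimension d regardless of the input.
    """
    if not 1 <= region <= 25:
        raise ValueError(f"region {region} out of range")
    r0, r1, c0, c1 = bounds_of(region, bmap.pooled.shape[0])
    g = cfg.feature_grid
    side = r1 - r0
    cell = side // g
    feats = []
    centers = []
    for si in cfg.feature_scales:
        for b in bmap.oriented[si]:
            crop = b[r0 : r0 + g * cell, c0 : c0 + g * cell]
            pooled = crop.reshape(g, cell, g, cell).mean(axis=(1, 3))
            feats.append(pooled.ravel())
            centers.append(pooled[1:-1, 1:-1].ravel())
    v = np.concatenate(feats)
    # normalize by the *central* cells' maximum: boundary spillover from a
    # neighboring object is confined to the crop's outer ring and must not
    # set the gain for a weak object's own features
    vmax = np.concatenate(centers).max() if g > 2 else v.max()
    if vmax > 1e-6:          # guard: don't amplify numerical noise of an
        v = np.minimum(v / vmax, 1.0)   # empty region into features
    else:
        v = np.zeros_like(v)
    return np.concatenate([v, 1.0 - v])


@dataclass
class ViewCategoryBank:
    """Per-region Fuzzy ART modules plus the category->position direct-route
    association weights."""

    cfg: ModelConfig
    weights: dict = field(default_factory=dict)   # region -> (n_j, 2d) array
    position_assoc: dict = field(default_factory=dict)  # (region, j) -> w>0
    winner: dict = field(default_factory=dict)    # region -> current j

    def n_committed(self, region: int) -> int:
        w = self.weights.get(region)
        return 0 if w is None else w.shape[0]

    def total_committed(self) -> int:
        return sum(w.shape[0] for w in self.weights.values())


class CapacityError(RuntimeError):
    pass


def art_classify(I: np.ndarray, bank: ViewCategoryBank, region: int,
                 learn: bool = True):
    """Fuzzy ART choice / match / learning cycle for one coded input.

    Category choice ranks ``T_j = |I ^ w_j| / (alpha + |w_j|)``; resonance
    requires match ``|I ^ w_j| / |I| >= rho``, otherwise the orienting system
    resets the choice and the search continues; if every committed node
    fails, a new node is committed with ``w = I`` (when learning).  Learning
    is the fast Fuzzy ART rule ``w <- beta (I ^ w) + (1 - beta) w``.

    Returns ``(category index or None, resonance flag)``.
    """
    cfg = bank.cfg
    I = np.asarray(I, dtype=float)
    if I.min() < 0 or I.max() > 1:
        raise ValueError("coded input must lie in [0, 1]")
    W = bank.weights.get(region)
    norm_I = I.sum()
    if W is not None and W.shape[0]:
        inter = np.minimum(I[None, :], W).sum(axis=1)
        T = inter / (cfg.art_alpha + W.sum(axis=1))
        order = np.argsort(-T, kind="stable")
        for j in order:
            if norm_I == 0 or inter[j] / norm_I >= cfg.vigilance:
                if learn:
                    W[j] = cfg.art_beta * np.minimum(I, W[j]) \
                        + (1 - cfg.art_beta) * W[j]
                bank.winner[region] = int(j)
                return int(j), True
    if not learn:
        return None, False
    if bank.total_committed() >= cfg.category_capacity:
        raise CapacityError(
            f"view-category capacity {cfg.category_capacity} exhausted "
            f"({bank.total_committed()} nodes committed)")
    W = I[None, :].copy() if W is None else np.vstack([W, I[None, :]])
    bank.weights[region] = W
    j = W.shape[0] - 1
    bank.winner[region] = j
    return j, False


def learn_direct_route(bank: ViewCategoryBank, region: int, j: int) -> None:
    """Hebbian association between an extra-foveally activated view category
    and its region's position node (the ITp -> eye-map direct route).

    Foveal categories represent the currently fixated position and acquire
    no extra-foveal association.
    """
    if region == FOVEA_REGION:
        return
    key = (region, j)
    w = bank.position_assoc.get(key, 0.0)
    bank.position_assoc[key] = w + bank.cfg.direct_route_rate * (1.0 - w)


@dataclass
class WhatResetLatch:
    """What-stream reset: set by the parietal burst, not transmitter-gated,
    held until the next shroud forms."""

    high: bool = False

    def set(self):
        self.high = True

    def clear_on_shroud_onset(self):
        self.high = False


@dataclass
class IntegratorLayer:
    """View category integrators: persistent copies of view-category
    activity, reset only by the What-stream reset."""

    cfg: ModelConfig
    activity: dict = field(default_factory=dict)  # (region, j) -> level

    def drive(self, region: int, j: int, level: float = 1.0):
        key = (region, int(j))
        self.activity[key] = max(self.activity.get(key, 0.0), level)

    def decay(self, dt: float):
        f = np.exp(-dt / self.cfg.integrator_tau)
        for k in list(self.activity):
            self.activity[k] *= f
            if self.activity[k] < 1e-3:
                del self.activity[k]

    def active(self):
        thr = self.cfg.integrator_threshold
        return {k: v for k, v in self.activity.items() if v >= thr}

    def prime_topdown(self, keys, volition: bool):
        """ITa -> integrator priming: modulatory alone, firing with
        volition."""
        level = self.cfg.volition_gain_on if volition \
            else self.cfg.volition_gain_off
        for k in keys:
            self.activity[k] = max(self.activity.get(k, 0.0), min(level, 1.0))

    def clear(self):
        self.activity.clear()


@dataclass
class InvariantCategoryLayer:
    """View- and positionally-invariant object category nodes.

    Bottom-up (integrator -> object) and top-down (object -> integrator)
    adaptive weights are stored per integrator key; both are strengthened
    whenever the integrator and the winning object node are coactive, at the
    slow rate that lets evidence accumulate over many fixations.
    """

    cfg: ModelConfig
    n_committed: int = 0
    w_bu: dict = field(default_factory=dict)  # (region, j) -> vector
    w_td: dict = field(default_factory=dict)
    activity: np.ndarray | None = None

    def _vec(self, d, key):
        if key not in d:
            d[key] = np.zeros(self.cfg.invariant_capacity)
        return d[key]

    def quench(self):
        return QuenchParams(self.cfg.quench_threshold, 1.0,
                            self.cfg.winner_margin)

    def bottom_up_input(self, integrators: dict, orb_feedback=None,
                        volition: bool = False) -> np.ndarray:
        x = np.zeros(self.cfg.invariant_capacity)
        for key, act in integrators.items():
            if key in self.w_bu:
                x += self.w_bu[key] * act
        if orb_feedback is not None:
            g = self.cfg.volition_gain_on if volition \
                else self.cfg.volition_gain_off
            x[: len(orb_feedback)] += g * np.asarray(orb_feedback)
        return x

    def update(self, integrators: dict, orb_feedback=None,
               volition: bool = False, what_reset: bool = False,
               learn: bool = True) -> np.ndarray:
        """One competition/learning event of the invariant layer."""
        if what_reset:
            self.activity = np.zeros(self.cfg.invariant_capacity)
            return self.activity
        x = self.bottom_up_input(integrators, orb_feedback, volition)
        if learn and integrators and x[: max(self.n_committed, 1)].max() \
                < 0.05 and self.n_committed < self.cfg.invariant_capacity:
            # no committed node is supported: recruit a fresh one for the
            # currently active integrators
            jnew = self.n_committed
            self.n_committed += 1
            for key, act in integrators.items():
                self._vec(self.w_bu, key)[jnew] = 0.2 * act
            x = self.bottom_up_input(integrators, orb_feedback, volition)
        self.activity = quench_compete(x, self.quench())
        if learn and integrators:
            lam = self.cfg.invariant_lambda_slow
            for key, act in integrators.items():
                bu = self._vec(self.w_bu, key)
                td = self._vec(self.w_td, key)
                post = self.activity
                bu += lam * post * (act - bu)
                td += lam * act * (post - td) * (post > 0)
        return self.activity

    def response(self, integrators: dict) -> np.ndarray:
        """Read-only bottom-up response (no competition, no learning)."""
        return self.bottom_up_input(integrators)

    def integrator_keys_of(self, obj_node: int, threshold: float = 0.05):
        """Integrator keys with a learned top-down link from an object
        node (the ITa -> integrator priming targets)."""
        return [k for k, v in self.w_td.items() if v[obj_node] > threshold]
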