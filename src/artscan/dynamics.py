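"""Shared neural-field primitives.

Every processing stage in the model is built from four ingredients:

* shunting (cell-membrane) dynamics ``dx/dt = -A*x + (B-x)*E - (C+x)*I``,
  which bound activities to ``[-C, B]`` and give automatic gain control;
* habituative transmitter gates ``dz/dt = r*(1-z) - d*S*z`` that multiply a
  signal pathway and deplete with use (the substrate of inhibition of return
  and of shroud collapse);
* Gaussian / oriented-odd convolution kernels for the on-center off-surround
  and simple-cell receptive fields;
* an algorithmic *normalized quenching competition* that either picks a
  clear winner or lets closely-matched nodes share a normalized total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ShuntingParams",
    "HabituativeGate",
    "Kernel",
    "QuenchParams",
    "shunting_step",
    "shunting_equilibrium",
    "habituate_step",
    "quench_compete",
    "convolve",
    "gaussian_center",
    "gaussian_surround",
    "oriented_odd",
]


class ContractViolation(ValueError):
    """Raised when an operation's preconditions are not met."""


class IntegrationError(RuntimeError):
    """Raised when an Euler step escapes the invariant activity bounds."""


@dataclass(frozen=True)
class ShuntingParams:
    """Coefficients of the shunting membrane equation.

    A: passive decay rate (1/s); B: excitatory saturation (upper bound);
    C: hyperpolarization bound (>= 0); dt: Euler step (s).
    """

    A: float
    B: float
    C: float = 0.0
    dt: float = 1e-3

    def __post_init__(self):
        if not (self.A > 0 and self.B > 0 and self.C >= 0 and self.dt > 0):
            raise ContractViolation(f"invalid shunting parameters: {self}")


def shunting_step(x, E, I, p: ShuntingParams):
    """One explicit Euler step of ``dx/dt = -A x + (B - x) E - (C + x) I``.

    ``E`` and ``I`` are nonnegative total excitatory / inhibitory inputs with
    the same shape as ``x``.  The result stays inside ``[-C, B]`` provided
    ``dt * (A + E + I) < 1`` (checked a posteriori).
    """
    x = np.asarray(x, dtype=float)
    E = np.broadcast_to(np.asarray(E, dtype=float), x.shape)
    I = np.broadcast_to(np.asarray(I, dtype=float), x.shape)
    if np.any(E < 0) or np.any(I < 0):
        raise ContractViolation("shunting inputs must be nonnegative")
    out = x + p.dt * (-p.A * x + (p.B - x) * E - (p.C + x) * I)
    if np.any(out > p.B + 1e-9) or np.any(out < -p.C - 1e-9):
        raise IntegrationError(
            "activity escaped [-C, B]; reduce dt (Euler stability)"
        )
    return out


def shunting_equilibrium(E, I, p: ShuntingParams):
    """Fixed point ``x* = (B E - C I) / (A + E + I)`` of the shunting equation.

    Fast path for feedforward stages whose inputs change slowly compared with
    their membrane time constant.
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    if E.shape != I.shape:
        raise ContractViolation("E and I must have the same shape")
    if np.any(E < 0) or np.any(I < 0):
        raise ContractViolation("shunting inputs must be nonnegative")
    return (p.B * E - p.C * I) / (p.A + E + I)


@dataclass
class HabituativeGate:
    """Activity-dependent transmitter level multiplying a signal pathway.

    ``level`` recovers toward 1 at ``recovery_rate`` and is depleted in
    proportion to the gated signal at ``depletion_rate``.
    """

    level: np.ndarray | float = 1.0
    recovery_rate: float = 1.0
    depletion_rate: float = 1.0

    def output(self, signal):
        """Gated output ``z * S``."""
        return self.level * np.asarray(signal, dtype=float)


def habituate_step(g: HabituativeGate, signal, dt: float) -> HabituativeGate:
    """Euler step of ``dz/dt = r (1 - z) - d S z``; z remains in [0, 1]."""
    S = np.asarray(signal, dtype=float)
    if np.any(S < 0):
        raise ContractViolation("habituative gate signal must be nonnegative")
    z = np.asarray(g.level, dtype=float)
    z = z + dt * (g.recovery_rate * (1.0 - z) - g.depletion_rate * S * z)
    # large S with coarse dt can overshoot below 0; the transmitter level is
    # physically confined to [0, 1]
    z = np.clip(z, 0.0, 1.0)
    if z.ndim == 0:
        z = float(z)
    return replace(g, level=z)


@dataclass(frozen=True)
class QuenchParams:
    """Parameters of the normalized quenching competition.

    quench_threshold: fraction of the layer maximum below which activities
        are suppressed to exactly zero;
    total_norm: normalized total activity of the surviving nodes;
    winner_margin: ratio of best to second-best input above which the
        competition resolves to a winner-take-all choice.
    """

    quench_threshold: float = 0.5
    total_norm: float = 1.0
    winner_margin: float = 1.5

    def __post_init__(self):
        if not (0 <= self.quench_threshold < 1):
            raise ContractViolation("quench_threshold must be in [0, 1)")
        if self.winner_margin <= 1:
            raise ContractViolation("winner_margin must exceed 1")


def quench_compete(inputs, q: QuenchParams = QuenchParams()):
    """Normalized quenching competition over a vector of nonnegative inputs.

    If the largest input exceeds ``winner_margin`` times the second largest,
    the winner (ties broken by lowest flat index) takes the whole normalized
    total ``M``.  Otherwise every node at or above ``quench_threshold`` times
    the maximum survives with activity proportional to its input, the
    survivors summing to ``M``.  An all-zero input stays all-zero.
    """
    v = np.asarray(inputs, dtype=float).ravel()
    if np.any(v < 0):
        raise ContractViolation("competition inputs must be nonnegative")
    out = np.zeros_like(v)
    if v.size == 0 or not np.any(v > 0):
        return out.reshape(np.shape(inputs))
    order = np.argsort(v, kind="stable")
    m1 = v[order[-1]]
    m2 = v[order[-2]] if v.size > 1 else 0.0
    winner = int(np.argmax(v))  # argmax returns the lowest flat index on ties
    if m1 > q.winner_margin * m2:
        out[winner] = q.total_norm
    else:
        keep = v >= q.quench_threshold * m1
        out[keep] = v[keep] * (q.total_norm / v[keep].sum())
    return out.reshape(np.shape(inputs))


@dataclass(frozen=True)
class Kernel:
    """A 2-D receptive-field kernel.

    kind: 'gaussian-center' | 'gaussian-surround' | 'oriented-odd';
    scale: scale index (1..3); orientation: index 1..4 for oriented kernels;
    half_width: Gaussian sigma in pixels; gain: total kernel weight (for the
    antisymmetric oriented-odd kernels, the weight of the positive lobe).
    """

    kind: str
    half_width: float
    gain: float = 1.0
    scale: int = 1
    orientation: int | None = None
    weights: np.ndarray = field(repr=False, default=None)


def _gaussian_patch(sigma: float):
    r = max(1, int(np.ceil(3 * sigma)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    g = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return g, x, y


def gaussian_center(half_width: float, gain: float = 1.0, scale: int = 1) -> Kernel:
    g, _, _ = _gaussian_patch(half_width)
    return Kernel("gaussian-center", half_width, gain, scale,
                  weights=g * (gain / g.sum()))


def gaussian_surround(half_width: float, gain: float = 1.0, scale: int = 1) -> Kernel:
    g, _, _ = _gaussian_patch(half_width)
    return Kernel("gaussian-surround", half_width, gain, scale,
                  weights=g * (gain / g.sum()))


def oriented_odd(orientation: int, half_width: float, gain: float = 1.0,
                 scale: int = 1, n_orientations: int = 4) -> Kernel:
    """Odd-symmetric (edge-detecting) kernel: derivative of a Gaussian along
    the axis perpendicular to the preferred orientation.

    ``orientation`` indexes angles 0, 45, 90, 135 degrees for the default
    four orientations; the kernel is antisymmetric across its preferred axis.
    """
    if orientation is None or not 1 <= orientation <= n_orientations:
        raise ContractViolation("orientation index out of range")
    theta = (orientation - 1) * np.pi / n_orientations
    g, x, y = _gaussian_patch(half_width)
    # orientation 1 prefers vertical edges: the kernel differentiates along
    # x; higher indices rotate the derivative axis by 45-degree steps
    u = x * np.cos(theta) + y * np.sin(theta)
    w = -u * g
    pos = w[w > 0].sum()
    w = w * (gain / pos)
    return Kernel("oriented-odd", half_width, gain, scale, orientation, weights=w)


def convolve(x: np.ndarray, k: Kernel, border: str = "constant") -> np.ndarray:
    """Same-shape correlation of a grid with a kernel.

    ``border='constant'`` zero-pads; retinal stages use ``border='nearest'``
    (edge replication) so that a uniform field produces no spurious contrast
    at the image frame.
    """
    x = np.asarray(x, dtype=float)
    if k.weights.shape[0] > x.shape[0] or k.weights.shape[1] > x.shape[1]:
        raise ContractViolation("kernel larger than grid")
    return ndimage.correlate(x, k.weights, mode=border, cval=0.0)
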