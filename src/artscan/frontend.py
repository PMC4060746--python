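"""Retina/LGN, V1, V2 front end: contrast normalization, oriented simple and
complex cells, boundaries with top-down priming, boundary-gated surface
filling-in (FIDOs), and surface contours.

Stage order and signal flow::

    scene -> ON/OFF (shunting contrast normalization, 3 scales)
          -> simple cells (4 orientations x 2 polarities x 3 scales)
          -> complex cells (polarity pooled)
          -> boundaries (gain-modulated by surface-contour feedback and by
                         top-down category priming)
          -> filling-in domains (boundary-gated diffusion, ON and OFF)
          -> pooled surface  -> surface contours -> (back to boundaries,
                                                     and on to spatial
                                                     attention / eye maps)

Filling-in is solved at equilibrium with a sparse linear solve: diffusion
with permeability ``P / (1 + mu * boundary)`` between 4-neighbors, a small
leak, and the ON/OFF input as source.  A closed boundary therefore encloses
a near-uniform filled compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .config import ModelConfig
from .dynamics import (ShuntingParams, convolve, gaussian_center,
                       gaussian_surround, oriented_odd, shunting_equilibrium)

__all__ = ["OnOffMaps", "BoundaryMap", "SurfaceMap", "FrontendState",
           "lgn_normalize", "simple_cells", "complex_cells", "boundaries",
           "fill_in", "surface_contours", "process_scene"]


@dataclass
class OnOffMaps:
    """Polarity-sensitive contrast-normalized activity, one pair per scale."""

    on: list  # list of 2-D arrays, one per scale
    off: list


@dataclass
class BoundaryMap:
    """Oriented boundary activities b[scale][orientation] plus a pooled map."""

    oriented: list  # oriented[s][o] -> 2-D array
    pooled: np.ndarray


@dataclass
class SurfaceMap:
    """Filled-in ON and OFF surfaces and the pooled attention output."""

    on: np.ndarray
    off: np.ndarray
    pooled: np.ndarray


@dataclass
class FrontendState:
    """All front-end maps for one retinal image.

    ``boundary_bu`` is the pure bottom-up boundary map (no surface-contour
    feedback, no category priming): it is strictly local, hence exactly
    translation-equivariant, and is what the What-stream adaptive filter
    reads; ``boundary`` additionally carries the feedback/priming gain used
    by filling-in and attention.
    """

    scene: np.ndarray
    onoff: OnOffMaps
    complex: list  # complex[s][o]
    boundary: BoundaryMap
    surface: SurfaceMap
    contours: np.ndarray
    boundary_bu: BoundaryMap = None


def _kernels(cfg: ModelConfig):
    ks = []
    for s, hw in enumerate(cfg.scale_half_widths, start=1):
        center = gaussian_center(hw, scale=s)
        surround = gaussian_surround(cfg.surround_ratio * hw, scale=s)
        odd = [oriented_odd(o, hw, scale=s,
                            n_orientations=cfg.n_orientations)
               for o in range(1, cfg.n_orientations + 1)]
        ks.append((center, surround, odd))
    return ks


def lgn_normalize(scene: np.ndarray, cfg: ModelConfig) -> OnOffMaps:
    """Weber-law contrast normalization with ON and OFF channels per scale.

    ON cells respond to local increments, OFF cells to decrements; a uniform
    scene yields (near) zero in both channels — the illuminant is discounted.
    """
    scene = np.asarray(scene, dtype=float)
    p = ShuntingParams(A=cfg.lgn_decay, B=1.0, C=1.0)
    on, off = [], []
    for center, surround, _ in _kernels(cfg):
        E = convolve(scene, center, border="nearest")
        I = convolve(scene, surround, border="nearest")
        x = shunting_equilibrium(E, I, p)
        on.append(np.maximum(x, 0.0))
        off.append(np.maximum(-x, 0.0))
    return OnOffMaps(on, off)


def simple_cells(onoff: OnOffMaps, cfg: ModelConfig):
    """Oriented polarity-sensitive cells.

    The two polarities of a like-oriented pair see mirror-image receptive
    fields: the ON-subregion takes excitatory ON and inhibitory OFF input,
    and conversely.  Returns s[scale][orientation] = (pol_a, pol_b), both
    half-wave rectified.
    """
    out = []
    for s, (_, _, odds) in enumerate(_kernels(cfg)):
        diff = onoff.on[s] - onoff.off[s]
        per_orient = []
        for k in odds:
            resp = convolve(diff, k)
            per_orient.append((np.maximum(resp, 0.0), np.maximum(-resp, 0.0)))
        out.append(per_orient)
    return out


def complex_cells(simple, cfg: ModelConfig):
    """Polarity-insensitive oriented cells: sum of the rectified
    opposite-polarity simple pair at each position."""
    return [[pa + pb for (pa, pb) in per_scale] for per_scale in simple]


def boundaries(complex_maps, cfg: ModelConfig,
               contour_feedback: np.ndarray | None = None,
               itp_prime: np.ndarray | None = None) -> BoundaryMap:
    """V2 boundaries with surface-to-boundary and category-to-boundary gain.

    Boundary gain is ``1 + lambda1 * contour_feedback + lambda2 * itp_prime``
    minus an off-surround term proportional to the total feedback, so the
    attended/primed object's boundaries strengthen while boundaries of
    non-attended surfaces weaken.
    """
    shape = complex_maps[0][0].shape
    fb = np.zeros(shape) if contour_feedback is None else np.asarray(contour_feedback)
    pr = np.zeros(shape) if itp_prime is None else np.asarray(itp_prime)
    total_fb = fb.mean() + pr.mean()
    gain = 1.0 + cfg.boundary_lambda1 * fb + cfg.boundary_lambda2 * pr \
        - cfg.boundary_inh * total_fb
    oriented = [[np.maximum(c * gain, 0.0) for c in per_scale]
                for per_scale in complex_maps]
    pooled = np.zeros(shape)
    for per_scale in oriented:
        for b in per_scale:
            pooled += b
    pooled /= len(oriented)
    return BoundaryMap(oriented, pooled)


def _fill_solve(inputs: np.ndarray, perm_r: np.ndarray, perm_c: np.ndarray,
                decay: float) -> np.ndarray:
    """Equilibrium of leaky boundary-gated diffusion with source ``inputs``.

    perm_r[i, j] couples (i, j) with (i+1, j); perm_c couples (i, j) with
    (i, j+1).  Solves (decay + sum of couplings) x - couplings.x_nb = inputs.
    """
    h, w = inputs.shape
    n = h * w
    idx = np.arange(n).reshape(h, w)
    rows, cols, vals = [], [], []
    diag = np.full(n, decay)

    def couple(a, b, p):
        rows.extend(a)
        cols.extend(b)
        vals.extend(-p)
        np.add.at(diag, a, p)
        np.add.at(diag, b, p)
        rows.extend(b)
        cols.extend(a)
        vals.extend(-p)

    couple(idx[:-1, :].ravel(), idx[1:, :].ravel(), perm_r[:-1, :].ravel())
    couple(idx[:, :-1].ravel(), idx[:, 1:].ravel(), perm_c[:, :-1].ravel())
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    x = spsolve(A, inputs.ravel())
    return x.reshape(h, w)


def fill_in(onoff: OnOffMaps, boundary: BoundaryMap, cfg: ModelConfig,
            attention_feedback: np.ndarray | None = None,
            reset_inhibition: float = 0.0,
            boundary_gain_excess: np.ndarray | None = None) -> SurfaceMap:
    """Boundary-gated surface filling-in (FIDOs) at equilibrium.

    Strong boundaries suppress diffusion between neighbors; spatial-attention
    feedback multiplicatively enhances the attended surface's source input
    (contrast gain); gain-amplified boundaries (surface-contour feedback or
    top-down category priming) likewise raise the contrast of the surface
    they contain; a reset signal subtracts nonspecifically.
    """
    b = boundary.pooled
    bmax = b.max()
    bn = b / bmax if bmax > 0 else b
    perm_r = cfg.fill_perm / (1.0 + cfg.fill_mu * 0.5 * (bn[:-1, :] + bn[1:, :]))
    perm_c = cfg.fill_perm / (1.0 + cfg.fill_mu * 0.5 * (bn[:, :-1] + bn[:, 1:]))
    perm_r = np.vstack([perm_r, np.zeros((1, b.shape[1]))])
    perm_c = np.hstack([perm_c, np.zeros((b.shape[0], 1))])
    att = 0.0 if attention_feedback is None else np.asarray(attention_feedback)
    gain = 1.0 + cfg.fill_attention_gain * att
    if boundary_gain_excess is not None:
        gain = gain * (1.0 + np.maximum(boundary_gain_excess, 0.0))
    filled = []
    for maps in (onoff.on, onoff.off):
        src = np.zeros_like(b)
        for m in maps:
            src = src + m
        src = np.maximum(src * gain - reset_inhibition, 0.0)
        # scale the leak so the filled level is O(source) rather than
        # O(source / decay): equivalently solve with unit-mean sources
        filled.append(_fill_solve(src * cfg.fill_decay * 50, perm_r, perm_c,
                                  cfg.fill_decay) / 50)
    on_f, off_f = filled
    return SurfaceMap(on_f, off_f, on_f + off_f)


def surface_contours(surface: SurfaceMap, cfg: ModelConfig) -> np.ndarray:
    """Contrast-sensitive on-center off-surround readout of the filled
    surface: active only near filled-surface luminance discontinuities, with
    maxima at high-curvature points such as corners."""
    p = ShuntingParams(A=cfg.contour_decay, B=1.0, C=1.0)
    center = gaussian_center(cfg.contour_center_hw)
    surround = gaussian_surround(cfg.contour_surround_hw)
    E = convolve(surface.pooled, center, border="nearest")
    I = convolve(surface.pooled, surround, border="nearest")
    x = shunting_equilibrium(E, I, p)
    return np.abs(x)


def process_scene(scene: np.ndarray, cfg: ModelConfig,
                  itp_prime: np.ndarray | None = None,
                  attention_feedback: np.ndarray | None = None,
                  reset_inhibition: float = 0.0,
                  feedback_passes: int = 1) -> FrontendState:
    """Run the full front end on a retinal image.

    ``feedback_passes`` > 0 closes the surface-contour -> boundary loop that
    many times (one pass suffices for the gain properties used downstream).
    """
    onoff = lgn_normalize(scene, cfg)
    simple = simple_cells(onoff, cfg)
    cmaps = complex_cells(simple, cfg)
    contour_fb = None
    bmap_bu = boundaries(cmaps, cfg)

    def excess(fb, pr):
        e = np.zeros_like(cmaps[0][0])
        if fb is not None:
            e = e + cfg.boundary_lambda1 * fb
        if pr is not None:
            e = e + cfg.boundary_lambda2 * pr
        return e

    bmap = boundaries(cmaps, cfg, None, itp_prime)
    surf = fill_in(onoff, bmap, cfg, attention_feedback, reset_inhibition,
                   excess(None, itp_prime))
    contours = surface_contours(surf, cfg)
    # feedback is scaled against the pure bottom-up contour amplitude, a
    # fixed reference, so attentional/priming enhancement of a surface's
    # contours translates into a net boundary gain rather than being
    # renormalized away
    if attention_feedback is None and itp_prime is None:
        ref = contours.max()
    else:
        surf0 = fill_in(onoff, bmap_bu, cfg)
        ref = surface_contours(surf0, cfg).max()
    for _ in range(feedback_passes):
        contour_fb = contours / ref if ref > 0 else contours
        bmap = boundaries(cmaps, cfg, contour_fb, itp_prime)
        surf = fill_in(onoff, bmap, cfg, attention_feedback, reset_inhibition,
                       excess(contour_fb, itp_prime))
        contours = surface_contours(surf, cfg)
    return FrontendState(np.asarray(scene, dtype=float), onoff, cmaps, bmap,
                         surf, contours, bmap_bu)
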