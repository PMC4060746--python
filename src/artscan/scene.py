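"""Synthetic scene and stimulus generation.

A scene is a square grayscale image (values in [0, 1]) on a homogeneous gray
background of luminance 0.5, partitioned into a 5x5 grid of equal square
regions.  Regions are indexed 1..25 row-major; the geometric center, region
13, is the foveal region.  Objects occupy at most one region each and are
confined to the central nine regions {7, 8, 9, 12, 13, 14, 17, 18, 19} so
that they stay inside the scene after saccadic shifts.

The generator stands in for natural-image exemplars: parametric shapes
(disk, ring, cross, bar pair, blob, polygon) with controllable size and
luminance give mutually distinct boundary signatures while exercising the
same category-learning and search machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID",
    "FOVEA_REGION",
    "CENTRAL_REGIONS",
    "SceneSpec",
    "ObjectImage",
    "region_of",
    "bounds_of",
    "region_center",
    "make_object",
    "object_library",
    "compose_scene",
    "shift_scene",
    "waldo_scene",
]

GRID = 5
FOVEA_REGION = 13
CENTRAL_REGIONS = (7, 8, 9, 12, 13, 14, 17, 18, 19)
BACKGROUND = 0.5
SHAPES = ("disk", "ring", "cross", "bar-pair", "blob", "polygon")


def region_of(row: int, col: int, scene_side: int) -> int:
    """1-based row-major region index containing pixel (row, col)."""
    rs = scene_side // GRID
    r, c = int(row) // rs, int(col) // rs
    if not (0 <= r < GRID and 0 <= c < GRID):
        raise ValueError(f"pixel ({row}, {col}) outside scene")
    return r * GRID + c + 1


def bounds_of(region: int, scene_side: int):
    """Pixel bounds (r0, r1, c0, c1) of a region; r1/c1 exclusive."""
    if not 1 <= region <= GRID * GRID:
        raise ValueError(f"region {region} out of range")
    rs = scene_side // GRID
    r, c = divmod(region - 1, GRID)
    return r * rs, (r + 1) * rs, c * rs, (c + 1) * rs


def region_center(region: int, scene_side: int):
    r0, r1, c0, c1 = bounds_of(region, scene_side)
    return (r0 + r1) // 2, (c0 + c1) // 2


@dataclass(frozen=True)
class ObjectImage:
    """A region-sized grayscale patch containing one object on background."""

    object_id: str
    patch: np.ndarray = field(repr=False)
    shape_kind: str = "disk"
    luminance: float = 0.9

    def __post_init__(self):
        p = self.patch
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("object patch must be square")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("patch values must lie in [0, 1]")


@dataclass
class SceneSpec:
    """Placement plan for one scene: (region, object_id) pairs."""

    scene_side: int = 100
    placements: list = field(default_factory=list)
    background: float = BACKGROUND

    def __post_init__(self):
        if self.scene_side % GRID:
            raise ValueError("scene side must be divisible by the 5x5 grid")
        regions = [r for r, _ in self.placements]
        if len(set(regions)) != len(regions):
            raise ValueError("at most one object per region")
        bad = [r for r in regions if r not in CENTRAL_REGIONS]
        if bad:
            raise ValueError(f"objects confined to central regions; got {bad}")

    def to_json(self) -> str:
        return json.dumps(
            {"scene_side": self.scene_side, "background": self.background,
             "placements": [[int(r), str(o)] for r, o in self.placements]},
            indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        return cls(d["scene_side"],
                   [(int(r), str(o)) for r, o in d["placements"]],
                   d.get("background", BACKGROUND))


def _shape_mask(kind, side, size_frac, rng, variant=0):
    y, x = np.mgrid[0:side, 0:side]
    c = (side - 1) / 2.0
    r = size_frac * side / 2.0
    d = np.hypot(y - c, x - c)
    if kind == "disk":
        return d <= r
    if kind == "ring":
        inner = (0.55, 0.65, 0.45, 0.7)[variant % 4]
        return (d <= r) & (d >= inner * r)
    if kind == "cross":
        theta = (0.0, np.pi / 4)[variant % 2]
        wf = (0.3, 0.15)[(variant // 2) % 2]
        u = np.cos(theta) * (x - c) + np.sin(theta) * (y - c)
        v = -np.sin(theta) * (x - c) + np.cos(theta) * (y - c)
        w = max(1, int(round(wf * r)))
        return ((np.abs(u) <= w) | (np.abs(v) <= w)) & (d <= r)
    if kind == "bar-pair":
        theta = (0.0, np.pi / 2, np.pi / 4, 3 * np.pi / 4)[variant % 4]
        gap = (0.55, 0.9)[(variant // 4) % 2]
        u = np.cos(theta) * (x - c) + np.sin(theta) * (y - c)
        v = -np.sin(theta) * (x - c) + np.cos(theta) * (y - c)
        w = max(1, int(round(0.35 * r)))
        return ((np.abs(u - gap * r) <= w) |
                (np.abs(u + gap * r) <= w)) & (np.abs(v) <= r)
    if kind == "blob":
        from scipy import ndimage
        noise = rng.standard_normal((side, side))
        # variants differ in lobe scale so random blobs stay discriminable
        sigma = side / (14.0, 10.0, 8.0, 12.0)[variant % 4]
        smooth = ndimage.gaussian_filter(noise, sigma)
        target_area = np.pi * (0.55 * r) ** 2 + 6
        mask = smooth >= np.sort(smooth.ravel())[-int(target_area)]
        lab, n = ndimage.label(mask)
        sizes = ndimage.sum(mask, lab, range(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        comp = lab == keep
        # recenter the component so it always lands on the patch
        ys, xs = np.nonzero(comp)
        dy, dx = int(round(c - ys.mean())), int(round(c - xs.mean()))
        comp = np.roll(np.roll(comp, dy, axis=0), dx, axis=1)
        return comp & (d <= 1.1 * r)
    raise ValueError(f"unknown shape kind {kind!r}")


def _polygon_mask(side, size_frac, rng, variant=0):
    c = (side - 1) / 2.0
    r = size_frac * side / 2.0
    k = 3 + variant % 2
    rot = rng.uniform(0, 2 * np.pi)
    ang = rot + np.arange(k) * 2 * np.pi / k
    vy = c + r * np.sin(ang)
    vx = c + r * np.cos(ang)
    from skimage.draw import polygon as sk_polygon

    mask = np.zeros((side, side), dtype=bool)
    rr, cc = sk_polygon(vy, vx, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def make_object(shape_kind: str, size_frac: float, luminance: float,
                seed: int, region_side: int = 20,
                object_id: str | None = None, variant: int = 0) -> ObjectImage:
    """Deterministically draw one object on a region-sized background patch.

    ``size_frac`` is the object diameter as a fraction of the region side and
    must lie in (0.2, 0.9]; ``luminance`` must differ from the 0.5 background
    by at least 0.1 so the object is detectable.
    """
    if not 0.2 < size_frac <= 0.9:
        raise ValueError(f"degenerate object size {size_frac}")
    if abs(luminance - BACKGROUND) < 0.1:
        raise ValueError("object luminance indistinguishable from background")
    if shape_kind not in SHAPES:
        raise ValueError(f"unknown shape kind {shape_kind!r}")
    rng = np.random.default_rng(seed)
    if shape_kind == "polygon":
        mask = _polygon_mask(region_side, size_frac, rng, variant)
    else:
        mask = _shape_mask(shape_kind, region_side, size_frac, rng, variant)
    if mask.sum() < max(10, 0.1 * (size_frac * region_side / 2) ** 2):
        raise ValueError("degenerate object: too few visible pixels")
    patch = np.full((region_side, region_side), BACKGROUND)
    patch[mask] = luminance
    oid = object_id or f"{shape_kind}-{size_frac:.2f}-{luminance:.2f}-{seed}"
    return ObjectImage(oid, patch, shape_kind, luminance)


def _boundary_signature(obj: ObjectImage, g: int = 10) -> np.ndarray:
    """The What-stream view vector of the object's patch, computed locally.

    Runs the categorization front end (finest-scale ON/OFF contrast
    normalization, oriented odd-symmetric filtering, polarity pooling) on
    the background-padded patch, pools to a g x g grid, max-normalizes and
    complement-codes — the same geometry the view categorizer sees, so the
    generator self-test rejects exactly the object pairs the categorizer
    could not tell apart.
    """
    from scipy import ndimage as ndi

    side = obj.patch.shape[0]
    pad = max(6, side // 3)
    img = np.pad(obj.patch, pad, mode="constant", constant_values=BACKGROUND)
    hw = 1.0

    def gauss(sigma):
        r = max(1, int(np.ceil(3 * sigma)))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        return k / k.sum(), xx, yy

    kc, _, _ = gauss(hw)
    ks, _, _ = gauss(3 * hw)
    E = ndi.correlate(img, kc, mode="nearest")
    I = ndi.correlate(img, ks, mode="nearest")
    x = (E - I) / (1.0 + E + I)
    diff = np.maximum(x, 0.0) - np.maximum(-x, 0.0)
    feats = []
    cell = side // g
    for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
        kg, xx, yy = gauss(hw)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        w = -u * np.exp(-(xx**2 + yy**2) / (2 * hw**2))
        w = w / w[w > 0].sum()
        resp = ndi.correlate(diff, w, mode="nearest")
        e = np.abs(resp)[pad : pad + g * cell, pad : pad + g * cell]
        feats.append(e.reshape(g, cell, g, cell).mean((1, 3)).ravel())
    v = np.concatenate(feats)
    vmax = v.max()
    v = v / vmax if vmax > 1e-6 else np.zeros_like(v)
    return np.concatenate([v, 1.0 - v])


def _fuzzy_match(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.minimum(a, b).sum()
    return float(max(inter / a.sum(), inter / b.sum()))


def object_library(n: int = 24, seed: int = 0, region_side: int = 20,
                   max_match: float = 0.90) -> dict:
    """Generate ``n`` mutually distinct objects keyed ``obj00..``.

    Draws from a fixed menu of shape/size/variant combinations chosen so
    that no two entries rely on luminance polarity alone for their identity
    (the boundary-driven categorizer is polarity-blind).  A self-test
    rejects any candidate whose oriented-gradient signature fuzzy-matches a
    previously accepted object above ``max_match``; retries jitter the size
    in both directions, redraw random shapes, and eventually drift the
    structural variant.
    """
    menu = [
        ("disk", 0.8, 0), ("ring", 0.8, 0), ("cross", 0.8, 0),
        ("bar-pair", 0.8, 0), ("blob", 0.8, 0), ("polygon", 0.8, 0),
        ("disk", 0.6, 1), ("ring", 0.64, 1), ("cross", 0.66, 1),
        ("bar-pair", 0.66, 1), ("blob", 0.7, 1), ("polygon", 0.66, 1),
        ("disk", 0.42, 2), ("ring", 0.5, 2), ("cross", 0.8, 2),
        ("bar-pair", 0.52, 2), ("blob", 0.62, 2), ("polygon", 0.52, 2),
        ("blob", 0.75, 3), ("ring", 0.42, 3), ("cross", 0.52, 3),
        ("bar-pair", 0.8, 3), ("bar-pair", 0.66, 4), ("polygon", 0.8, 3),
    ]
    lums = (0.95, 0.05, 0.8, 0.2, 0.75)
    lib, sigs = {}, []
    i = 0
    attempt = 0
    while len(lib) < n:
        shape, size, variant = menu[i % len(menu)]
        lum = lums[i % len(lums)]
        oid = f"obj{len(lib):02d}"
        # two-sided size jitter plus eventual variant drift on retries
        k = (attempt + 1) // 2
        factor = 1.08**k if attempt % 2 else 1.08 ** (-k)
        size_eff = float(np.clip(size * factor, 0.25, 0.9))
        variant_eff = variant + attempt // 12
        try:
            obj = make_object(shape, size_eff, lum,
                              seed * 1009 + i * 31 + attempt,
                              region_side, object_id=oid,
                              variant=variant_eff)
        except ValueError:
            attempt += 1
            if attempt > 60:
                raise RuntimeError("could not generate distinct object set")
            continue
        sig = _boundary_signature(obj)
        if all(_fuzzy_match(sig, s) < max_match for s in sigs):
            lib[oid] = obj
            sigs.append(sig)
            i += 1
            attempt = 0
        else:
            attempt += 1
            if attempt > 60:
                raise RuntimeError("could not generate distinct object set")
    return lib


def compose_scene(spec: SceneSpec, library: dict) -> np.ndarray:
    """Render a SceneSpec to a grayscale array (background everywhere except
    object pixels; region boundaries are implicit)."""
    scene = np.full((spec.scene_side, spec.scene_side), spec.background)
    rs = spec.scene_side // GRID
    for region, oid in spec.placements:
        if oid not in library:
            raise KeyError(f"unknown object id {oid!r}")
        patch = library[oid].patch
        if patch.shape[0] != rs:
            raise ValueError("object patch size does not match region size")
        r0, _, c0, _ = bounds_of(region, spec.scene_side)
        scene[r0 : r0 + rs, c0 : c0 + rs] = patch
    return scene


def shift_scene(scene: np.ndarray, saccade, fill: float = BACKGROUND):
    """Retinotopic scene translation modelling saccade execution.

    ``saccade`` is the (drow, dcol) vector from the current fovea to the
    saccade target; the scene translates by the opposite vector so the target
    lands at the center.  Exposed pixels are background-filled; content
    shifted off-grid is clipped.
    """
    dr, dc = int(round(saccade[0])), int(round(saccade[1]))
    return translate(scene, -dr, -dc, fill)


def translate(arr: np.ndarray, dr: int, dc: int, fill: float = 0.0):
    """Integer-pixel translation with constant fill (content moves by
    (+dr, +dc))."""
    out = np.full_like(np.asarray(arr, dtype=float), fill)
    h, w = arr.shape
    rs0, rs1 = max(0, dr), min(h, h + dr)
    cs0, cs1 = max(0, dc), min(w, w + dc)
    out[rs0:rs1, cs0:cs1] = arr[rs0 - dr : rs1 - dr, cs0 - dc : cs1 - dc]
    return out


def waldo_scene(target_id: str, target_region: int, distractor_ids,
                groups: dict, seed: int, scene_side: int = 100) -> SceneSpec:
    """Build a search scene: the target at a non-foveal central region and
    eight distractors drawn from value groups other than the target's filling
    the remaining central regions."""
    if target_region == FOVEA_REGION or target_region not in CENTRAL_REGIONS:
        raise ValueError("target must occupy a non-foveal central region")
    distractor_ids = list(distractor_ids)
    if len(distractor_ids) != len(CENTRAL_REGIONS) - 1:
        raise ValueError("need exactly eight distractors")
    tgroup = groups[target_id]
    same = [d for d in distractor_ids if groups[d] == tgroup]
    if same:
        raise ValueError(f"distractors {same} share the target's value group")
    rng = np.random.default_rng(seed)
    free = [r for r in CENTRAL_REGIONS if r != target_region]
    order = rng.permutation(len(free))
    placements = [(target_region, target_id)]
    placements += [(free[order[i]], distractor_ids[i])
                   for i in range(len(distractor_ids))]
    return SceneSpec(scene_side, placements)
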