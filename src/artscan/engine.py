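"""Model orchestration: the coupled simulation loop, the learning and
reinforcement protocols, and the six Where's-Waldo search routes.

Stage order per integration step follows the model's signal flow: front end
-> gain fields -> shroud competition -> reset -> What-stream categorization
-> cognitive-emotional circuit -> eye-movement map -> saccade execution.

Three protocols are provided:

* ``integrate`` / ``run_learning_trial`` — free viewing of a (possibly
  multi-object) scene at millisecond resolution; shrouds form and collapse,
  saccades explore salient features, view/invariant categories are learned.
* ``train_positional`` — the positionally-invariant protocol (one object
  per scene, each of the nine central positions, many repeated trials) run
  at fixation-event granularity: the frontend, saccade-target selection and
  all learning rules are the same machinery, but weight equilibration
  trials replay the deterministic fixation-event sequence instead of
  re-integrating the ODEs.
* ``run_search_trial`` / ``run_battery`` — primed or bottom-up search with
  reaction time measured at the eye-movement map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import frontend as fe
from .cogem import CogEMState, VolitionSignal
from .config import ModelConfig
from .scene import (CENTRAL_REGIONS, FOVEA_REGION, SceneSpec, bounds_of,
                    compose_scene, region_center, region_of, shift_scene,
                    translate, waldo_scene)
from .what_stream import (IntegratorLayer, InvariantCategoryLayer,
                          ViewCategoryBank, WhatResetLatch, art_classify,
                          extract_view_vector, learn_direct_route)
from .where_stream import (EyeMovementMap, EyeState, ResetState, ShroudState,
                           apply_ior, attention_cycle_step, gain_field_bwd,
                           gain_field_fwd, next_saccade, salient_features,
                           step_ior_recovery)

__all__ = ["RouteSpec", "SearchResult", "Model", "TrialLog",
           "run_learning_trial", "train_positional",
           "run_reinforcement_schedule", "run_search_trial", "run_battery"]

ROUTE_ORIGINS = ("bottom_up", "cognitive", "motivational")
ROUTE_PATHS = ("direct", "indirect")


@dataclass(frozen=True)
class RouteSpec:
    """One of the six search routes: origin x path."""

    origin: str
    path: str

    def __post_init__(self):
        if self.origin not in ROUTE_ORIGINS or self.path not in ROUTE_PATHS:
            raise ValueError(f"invalid route {self.origin}:{self.path}")

    @classmethod
    def all(cls):
        return [cls(o, p) for o in ROUTE_ORIGINS for p in ROUTE_PATHS]

    def __str__(self):
        return f"{self.origin}:{self.path}"


@dataclass
class SearchResult:
    found: bool
    chosen_region: int | None
    target_region: int
    rt_ms: float | None
    route: RouteSpec
    diagnostic: str = ""


@dataclass
class TrialLog:
    """Time-stamped record of one trial."""

    fixations: list = field(default_factory=list)   # (t, row, col, region)
    resets: list = field(default_factory=list)      # times
    shroud: list = field(default_factory=list)      # (t, total, object_id)
    epochs: list = field(default_factory=list)      # (t, object_id)
    categories: list = field(default_factory=list)  # (t, region, j, new)

    def fixation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fixations,
                            columns=["t", "row", "col", "region"])

    def shroud_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shroud, columns=["t", "total", "object"])


class Model:
    """Complete coupled model state."""

    def __init__(self, cfg: ModelConfig, library: dict, groups: dict | None
                 = None, seed: int = 0):
        self.cfg = cfg
        self.library = library
        self.object_ids = sorted(library)
        self.obj_index = {o: i for i, o in enumerate(self.object_ids)}
        self.groups = groups or {}
        self.rng = np.random.default_rng(seed)
        self.banks = ViewCategoryBank(cfg)
        self.integrators = IntegratorLayer(cfg)
        self.invariant = InvariantCategoryLayer(cfg)
        self.cogem = CogEMState(cfg, n_objects=len(self.object_ids))
        self.latch = WhatResetLatch()
        self.volition = VolitionSignal.all_off()
        self.object_node = {}      # object_id -> invariant node (diagnostic)
        self.ablate_integrators = False
        self.ablate_direct = False
        self.ablate_reinforcement = False

    # -- helpers ------------------------------------------------------------

    def side(self) -> int:
        return self.cfg.scene_side

    def center(self):
        c = (self.side() - 1) // 2
        return (c, c)

    def fresh_where(self):
        side = self.side()
        return (EyeState(position=self.center()),
                ShroudState.blank(side, self.cfg),
                ResetState.blank(self.cfg),
                EyeMovementMap.blank(side, self.cfg))

    # -- fixation-event What-stream update ----------------------------------

    def view_event(self, fs: fe.FrontendState, region: int, learn: bool,
                   reinforcer_group: int | None = None, log: TrialLog | None
                   = None, t: float = 0.0, obj_idx: int | None = None):
        """Process one view: classify it, drive its integrator, update the
        invariant layer, learn the direct route, and (optionally) pair the
        result with a reinforcer."""
        vec = extract_view_vector(fs.boundary_bu, region, self.cfg)
        n_before = self.banks.n_committed(region)
        j, resonant = art_classify(vec, self.banks, region, learn=learn)
        if j is None:
            return None
        if log is not None:
            log.categories.append(
                (t, region, j, self.banks.n_committed(region) > n_before))
        if learn and not self.ablate_direct:
            learn_direct_route(self.banks, region, j)
        if self.ablate_integrators:
            self.integrators.clear()
        self.integrators.drive(region, j)
        acts = self.invariant.update(self.integrators.active(),
                                     what_reset=self.latch.high, learn=learn)
        if reinforcer_group is not None and not self.ablate_reinforcement \
                and acts is not None and acts.max() > 0 and obj_idx is not None:
            reinforcer = np.zeros(self.cfg.n_value)
            reinforcer[reinforcer_group] = 1.0
            # the object-category layer of the emotional circuit is indexed
            # by object; the attended object's node carries the invariant
            # category's activity
            ita = np.zeros(len(self.object_ids))
            ita[obj_idx] = float(acts.max())
            self.cogem.update_value(ita, reinforcer=reinforcer)
            self.cogem.update_object_value(ita, self.volition)
            self.cogem.update_name()
            self.cogem.learn(ita, what_reset=self.latch.high)
        return j

    # -- serialization -------------------------------------------------------

    def save(self, path: str):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config"] = self.cfg.to_json()
            f.attrs["object_ids"] = json.dumps(self.object_ids)
            f.attrs["groups"] = json.dumps(self.groups)
            f.attrs["object_node"] = json.dumps(
                {k: int(v) for k, v in self.object_node.items()})
            g = f.create_group("view_weights")
            for region, w in self.banks.weights.items():
                g.create_dataset(str(region), data=w)
            g = f.create_group("position_assoc")
            for (region, j), w in self.banks.position_assoc.items():
                g.create_dataset(f"{region}_{j}", data=w)
            g = f.create_group("invariant")
            g.attrs["n_committed"] = self.invariant.n_committed
            for name, d in (("bu", self.invariant.w_bu),
                            ("td", self.invariant.w_td)):
                sub = g.create_group(name)
                for (region, j), w in d.items():
                    sub.create_dataset(f"{region}_{j}", data=w)
            g = f.create_group("cogem")
            for name in ("w_cond", "w_inc", "w_ita_orb", "w_name_orb",
                         "w_orb_name"):
                g.create_dataset(name, data=getattr(self.cogem, name))
            g = f.create_group("objects")
            for oid, obj in self.library.items():
                d = g.create_dataset(oid, data=obj.patch)
                d.attrs["shape_kind"] = obj.shape_kind
                d.attrs["luminance"] = obj.luminance

    @classmethod
    def load(cls, path: str) -> "Model":
        import h5py

        from .scene import ObjectImage

        with h5py.File(path, "r") as f:
            cfg = ModelConfig.from_json(f.attrs["config"])
            library = {}
            for oid in f["objects"]:
                d = f["objects"][oid]
                library[oid] = ObjectImage(oid, d[()], d.attrs["shape_kind"],
                                           float(d.attrs["luminance"]))
            groups = {k: int(v) for k, v in
                      json.loads(f.attrs["groups"]).items()}
            m = cls(cfg, library, groups)
            m.object_node = {k: int(v) for k, v in
                             json.loads(f.attrs["object_node"]).items()}
            for region in f["view_weights"]:
                m.banks.weights[int(region)] = f["view_weights"][region][()]
            for key in f["position_assoc"]:
                region, j = key.split("_")
                m.banks.position_assoc[(int(region), int(j))] = \
                    float(f["position_assoc"][key][()])
            m.invariant.n_committed = int(f["invariant"].attrs["n_committed"])
            for name, d in (("bu", m.invariant.w_bu),
                            ("td", m.invariant.w_td)):
                for key in f["invariant"][name]:
                    region, j = key.split("_")
                    d[(int(region), int(j))] = f["invariant"][name][key][()]
            for name in ("w_cond", "w_inc", "w_ita_orb", "w_name_orb",
                         "w_orb_name"):
                setattr(m.cogem, name, f["cogem"][name][()])
        return m


def _translate_frontend(fs: fe.FrontendState, dr: int, dc: int
                        ) -> fe.FrontendState:
    """Shift all front-end maps by (dr, dc).

    Every front-end stage is translation-equivariant away from the image
    frame, so the response to a shifted scene equals the shifted response;
    objects are confined to the central regions, keeping content clear of
    the frame for within-scene saccades.
    """
    t = lambda a: translate(a, dr, dc, 0.0)
    bmap = fe.BoundaryMap([[t(b) for b in per] for per in fs.boundary.oriented],
                          t(fs.boundary.pooled))
    bmap_bu = fe.BoundaryMap(
        [[t(b) for b in per] for per in fs.boundary_bu.oriented],
        t(fs.boundary_bu.pooled))
    surf = fe.SurfaceMap(t(fs.surface.on), t(fs.surface.off),
                         t(fs.surface.pooled))
    onoff = fe.OnOffMaps([t(m) for m in fs.onoff.on],
                         [t(m) for m in fs.onoff.off])
    cmaps = [[t(c) for c in per] for per in fs.complex]
    return fe.FrontendState(translate(fs.scene, dr, dc, 0.5), onoff, cmaps,
                            bmap, surf, t(fs.contours), bmap_bu)


def _attended_region(shroud: ShroudState, eye: EyeState, side: int):
    """Scene region of the currently attended object, in retinotopic
    coordinates (where its view categories live)."""
    if shroud.winner_mask is None or not shroud.winner_mask.any():
        return None
    mask_ret = gain_field_bwd(shroud.winner_mask.astype(float), eye)
    if not mask_ret.any():
        return None
    ys, xs = np.nonzero(mask_ret)
    return region_of(int(ys.mean()), int(xs.mean()), side)


def _object_at(spec: SceneSpec, region: int | None):
    for r, oid in spec.placements:
        if r == region:
            return oid
    return None


def integrate(model: Model, spec: SceneSpec, duration: float,
              learn: bool = True, reinforce: bool = False,
              log: TrialLog | None = None, scene_queue: list | None = None
              ) -> TrialLog:
    """Free-viewing integration of one (or a queued sequence of) scene(s).

    ``scene_queue`` supports the positionally-invariant protocol: on each
    completed reset the next SceneSpec is loaded and the eyes re-center.
    Deterministic given the model state and scene(s).
    """
    cfg = model.cfg
    log = log or TrialLog()
    eye, shroud, reset, eyemap = model.fresh_where()
    # the scene is fixed in head-centric coordinates; every retinotopic
    # map is derived from the head-centric front end by the gain-field
    # translation, so content that leaves the retinal frame during a
    # saccade re-enters when the eyes move back
    head_scene = compose_scene(spec, model.library)
    fs_head = fe.process_scene(head_scene, cfg)
    cr, cc = model.center()
    fs = fs_head
    queue = list(scene_queue or [])
    t = 0.0
    attended_oid = None
    head_spec = spec          # placements in head-centric coordinates
    steps = int(round(duration / cfg.dt))
    log_every = max(1, int(round(0.01 / cfg.dt)))
    for i in range(steps):
        # 1. attention input with surface-shroud contrast enhancement
        mask_ret = gain_field_bwd(shroud.activity, eye)
        att = fs.surface.pooled * (1.0 + cfg.fill_attention_gain * mask_ret)
        head_att = gain_field_fwd(att, eye)
        prev_epoch = shroud.epoch_count
        n_resets = len(reset.events)
        shroud, reset, closed = attention_cycle_step(head_att, shroud, reset,
                                                     cfg, t)
        if shroud.epoch_count > prev_epoch:
            # new shroud: release the What-stream latch, classify the
            # (possibly extra-foveal) view of the newly attended object
            model.latch.clear_on_shroud_onset()
            region = _attended_region(shroud, eye, cfg.scene_side)
            attended_oid = _object_at(head_spec, _attended_region(
                shroud, EyeState(position=model.center()), cfg.scene_side))
            log.epochs.append((t, attended_oid))
            if region is not None:
                group = model.groups.get(attended_oid) if reinforce else None
                model.view_event(fs, region, learn, group, log, t,
                                 model.obj_index.get(attended_oid))
        if len(reset.events) > n_resets:
            log.resets.append(reset.events[-1])
            model.latch.set()
            model.integrators.clear()
            model.invariant.update({}, what_reset=True)
        if closed and queue:
            # positional protocol: next scene, eyes re-center
            head_spec = queue.pop(0)
            head_scene = compose_scene(head_spec, model.library)
            fs_head = fe.process_scene(head_scene, cfg)
            fs = fs_head
            eye, _, _, eyemap = model.fresh_where()
            shroud = ShroudState(np.zeros_like(shroud.activity), shroud.gates,
                                 0.0, False, shroud.epoch_count)
        # 2. saccade choice on shroud-masked surface contours
        feat = salient_features(fs.contours, shroud, eye, cfg)
        eyemap, target = next_saccade(eyemap, feat, None, t, cfg)
        eyemap = step_ior_recovery(eyemap, cfg.dt)
        if target is not None:
            # predictive remapping: plan first, remap, then commit
            eye = replace(eye, planned=(eye.position[0] + target[0] - cr,
                                        eye.position[1] + target[1] - cc))
            dr, dc = cr - target[0], cc - target[1]
            fs = _translate_frontend(fs_head, cr - eye.planned[0],
                                     cc - eye.planned[1])
            eye = EyeState(position=eye.planned, planned=None,
                           fixation_onset=t)
            eyemap = apply_ior(
                EyeMovementMap(translate(eyemap.activity, dr, dc, 0.0),
                               type(eyemap.ior)(
                                   translate(np.asarray(eyemap.ior.level), dr,
                                             dc, 1.0),
                                   eyemap.ior.recovery_rate,
                                   eyemap.ior.depletion_rate)),
                (cr, cc), t, cfg)
            log.fixations.append((t, eye.position[0], eye.position[1],
                                  region_of(min(max(eye.position[0], 0),
                                                cfg.scene_side - 1),
                                            min(max(eye.position[1], 0),
                                                cfg.scene_side - 1),
                                            cfg.scene_side)))
            # the saccade brings the attended object toward the fovea;
            # classify the new view
            region = _attended_region(shroud, eye, cfg.scene_side)
            if region is not None and shroud.epoch_active:
                group = model.groups.get(attended_oid) if reinforce else None
                model.view_event(fs, region, learn, group, log, t,
                                 model.obj_index.get(attended_oid))
        model.integrators.decay(cfg.dt)
        if i % log_every == 0:
            log.shroud.append((t, shroud.total, attended_oid))
        t += cfg.dt
    return log


def run_learning_trial(model: Model, scenes, duration_per_scene: float = 1.6,
                       learn: bool = True, reinforce: bool = False
                       ) -> TrialLog:
    """View- or positionally-invariant learning over a scene sequence.

    A single multi-object scene exercises the view-invariant protocol; a
    sequence of single-object scenes (advanced on reset) exercises the
    positionally-invariant protocol.
    """
    scenes = list(scenes)
    first, rest = scenes[0], scenes[1:]
    return integrate(model, first, duration_per_scene * len(scenes),
                     learn=learn, reinforce=reinforce, scene_queue=rest)


# -- event-level positional training ----------------------------------------


def _hotspots(contours: np.ndarray, mask: np.ndarray, k: int,
              radius: float = 3.0):
    """Successive salient features (IOR-suppressed argmax) on a surface."""
    c = (contours * mask).copy()
    side = contours.shape[0]
    y, x = np.mgrid[0:side, 0:side]
    pts = []
    for _ in range(k):
        if c.max() <= 0:
            break
        p = np.unravel_index(int(np.argmax(c)), c.shape)
        pts.append((int(p[0]), int(p[1])))
        c[(y - p[0]) ** 2 + (x - p[1]) ** 2 <= radius**2] = 0.0
    return pts


def _foveal_frontend(model: Model, oid: str) -> fe.FrontendState:
    """Front end for the single-object scene with the object at the fovea
    (cached: every other position's maps are exact translations)."""
    cache = getattr(model, "_fov_cache", None)
    if cache is None:
        cache = model._fov_cache = {}
    if oid not in cache:
        spec = SceneSpec(model.cfg.scene_side, [(FOVEA_REGION, oid)])
        cache[oid] = fe.process_scene(compose_scene(spec, model.library),
                                      model.cfg)
    return cache[oid]


def _positional_events(model: Model, oid: str, position: int,
                       n_fixations: int = 6):
    """Fixation-event sequence for one object at one position: the
    extra-foveal view, then foveal views at successive salient features."""
    cfg = model.cfg
    fs_fov = _foveal_frontend(model, oid)
    cr, cc = model.center()
    events = []
    if position != FOVEA_REGION:
        # exact region-to-region offset so the translated view aligns with
        # the directly composed scene pixel for pixel
        rp = bounds_of(position, cfg.scene_side)
        rf = bounds_of(FOVEA_REGION, cfg.scene_side)
        events.append((_translate_frontend(fs_fov, rp[0] - rf[0],
                                           rp[2] - rf[2]), position))
    r0, r1, c0, c1 = bounds_of(FOVEA_REGION, cfg.scene_side)
    mask = np.zeros_like(fs_fov.contours)
    mask[r0:r1, c0:c1] = 1.0
    for hy, hx in _hotspots(fs_fov.contours, mask, n_fixations):
        events.append((_translate_frontend(fs_fov, cr - hy, cc - hx),
                       FOVEA_REGION))
    return events


def train_positional(model: Model, object_ids=None, positions=CENTRAL_REGIONS,
                     trials: int | None = None, reinforce: bool = False,
                     n_fixations: int = 6):
    """Positionally-invariant category learning protocol.

    For every object and every central position, the scene containing just
    that object is viewed: the extra-foveal view is categorized (and its
    position association learned), a saccade foveates the object, and
    successive salient features provide foveal views.  All views within one
    scene drive persistent integrators that bind them to one invariant
    object category; a What reset separates scenes.  ``trials`` repetitions
    (default from config) let the slow inter-layer weights equilibrate.
    """
    cfg = model.cfg
    trials = cfg.trials_per_position if trials is None else trials
    object_ids = list(object_ids or model.object_ids)
    for oid in object_ids:
        group = model.groups.get(oid) if reinforce else None
        for position in positions:
            cached = None
            for _ in range(trials):
                if cached is None:
                    cached = _positional_events(model, oid, position,
                                                n_fixations)
                for fs, region in cached:
                    model.view_event(fs, region, learn=True,
                                     reinforcer_group=group,
                                     obj_idx=model.obj_index[oid])
                # scene done: shroud collapse triggers the What reset
                model.latch.set()
                model.integrators.clear()
                model.invariant.update({}, what_reset=True)
                model.latch.clear_on_shroud_onset()
        # record the object's invariant node (argmax response to its views)
        resp = np.zeros(cfg.invariant_capacity)
        for fs, region in _positional_events(model, oid, positions[0], 2):
            vec = extract_view_vector(fs.boundary_bu, region, cfg)
            j, res = art_classify(vec, model.banks, region, learn=False)
            if j is not None:
                resp += model.invariant.response({(region, j): 1.0})
        model.object_node[oid] = int(np.argmax(resp))
    return model


def invariant_response_node(model: Model, oid: str, position: int):
    """Invariant node most activated by the object's view at a position
    (no learning)."""
    cfg = model.cfg
    spec = SceneSpec(cfg.scene_side, [(position, oid)])
    fs = fe.process_scene(compose_scene(spec, model.library), cfg)
    vec = extract_view_vector(fs.boundary, position, cfg)
    j, res = art_classify(vec, model.banks, position, learn=False)
    if j is None:
        return None
    resp = model.invariant.response({(position, j): 1.0})
    if resp.max() <= 0:
        return None
    return int(np.argmax(resp))


def run_reinforcement_schedule(model: Model, groups: dict | None = None,
                               trials: int = 40, record: bool = False):
    """Conditioned-reinforcer / incentive / naming learning.

    Each trial pairs every object's invariant category activation with its
    group's reinforcer while the name input is present, exactly as during
    free viewing with reinforcement on.  Returns per-trial mean activities
    when ``record`` (the learning-curve data)."""
    if groups:
        model.groups = dict(groups)
    cfg = model.cfg
    curves = []
    volition = VolitionSignal.all_off()
    for trial in range(trials):
        acts = {"value": [], "orb": [], "name": [], "ita": []}
        for oid in model.object_ids:
            ita = np.zeros(len(model.object_ids))
            ita[model.obj_index[oid]] = 1.0
            group = model.groups[oid]
            reinforcer = np.zeros(cfg.n_value)
            if not model.ablate_reinforcement:
                reinforcer[group] = 1.0
            name_input = np.zeros(len(model.object_ids))
            name_input[model.obj_index[oid]] = 0.5
            cg = model.cogem
            cg.update_value(ita, reinforcer=reinforcer)
            cg.update_object_value(ita, volition)
            cg.update_name(prime=name_input)
            # motivated-attention feedback amplifies the attended category
            fb = cg.orb_to_ita_feedback(VolitionSignal.all_on()
                                        if not model.ablate_reinforcement
                                        else volition)
            ita_amp = np.clip(ita + fb, 0.0, 1.0)
            cg.learn(ita_amp)
            # re-evaluate with the weights learned this trial, then record
            # raw (pre-competition) activations: the graded levels that
            # grow with the adaptive weights (trial-average proxy)
            cg.update_value(ita_amp, reinforcer=reinforcer)
            cg.update_object_value(ita_amp, volition)
            cg.update_name(prime=name_input)
            i = model.obj_index[oid]
            acts["value"].append(float(reinforcer[group]
                                       + cg.w_cond[:, group] @ ita_amp))
            acts["orb"].append(float(cg.subliminal[i]))
            acts["name"].append(float(name_input[i]
                                      + cg.w_orb_name[:, i] @ cg.orb))
            acts["ita"].append(float(ita_amp[i]))
        if record:
            curves.append({k: float(np.mean(v)) for k, v in acts.items()})
    return curves if record else model


# -- search ------------------------------------------------------------------


def _bottom_up_itp(model: Model, fs: fe.FrontendState, spec: SceneSpec,
                   match_floor: float = 0.85):
    """Bottom-up view-category inputs for a search scene.

    Each occupied region activates its best-choice committed category with
    its match value.  Vigilance gates category *learning*; recognition
    during search reads out the best-matching category subliminally and
    leaves the decision to the primed quenching competition downstream, so
    a clutter-degraded view that narrowly misses vigilance still supports
    its category.  Matches below ``match_floor`` are discarded as noise.
    """
    cfg = model.cfg
    out = {}
    for region, oid in spec.placements:
        W = model.banks.weights.get(region)
        if W is None or not W.shape[0]:
            continue
        vec = extract_view_vector(fs.boundary_bu, region, cfg)
        j, res = art_classify(vec, model.banks, region, learn=False)
        inter = np.minimum(vec[None, :], W).sum(axis=1)
        matches = inter / vec.sum() if vec.sum() > 0 else inter * 0.0
        if j is None:
            # nothing resonates: read out the best-*match* category (the
            # choice function would favour shrunken subset templates of
            # other objects) if it clears the noise floor
            j = int(np.argmax(matches))
            if matches[j] < match_floor:
                continue
        out[(region, int(j))] = float(matches[int(j)])
    return out


def _direct_input_map(model: Model, key, side: int):
    """Direct-route readout: a Gaussian bump at the associated position."""
    w = model.banks.position_assoc.get(key, 0.0)
    grid = np.zeros((side, side))
    if w <= 0:
        return grid
    region = key[0]
    rr, cc = region_center(region, side)
    y, x = np.mgrid[0:side, 0:side]
    grid = w * np.exp(-((y - rr) ** 2 + (x - cc) ** 2) / (2 * 2.0**2))
    return grid


def run_search_trial(model: Model, spec: SceneSpec, route: RouteSpec,
                     target_id: str, volition: bool = True,
                     debug: bool = False) -> SearchResult:
    """Execute one Where's-Waldo search trial.

    The prime (name for cognitive, internal drive for motivational routes)
    and the scene arrive together at t=0; RT is the model time at which the
    eye-movement map first crosses the saccade threshold.  ``found``
    requires the first saccade to land in the target's region.
    """
    cfg = model.cfg
    n_obj = len(model.object_ids)
    target_region = next(r for r, o in spec.placements if o == target_id)
    tgt_idx = model.obj_index[target_id]
    scene = compose_scene(spec, model.library)
    fs = fe.process_scene(scene, cfg)
    b_itp = _bottom_up_itp(model, fs, spec)
    if not b_itp:
        return SearchResult(False, None, target_region, None, route,
                            "no categorizable objects in scene")
    keys = sorted(b_itp)
    vol = VolitionSignal.all_on() if volition else VolitionSignal.all_off()
    g_on = cfg.volition_gain_on if volition else cfg.volition_gain_off

    name_prime = np.zeros(n_obj)
    drive = np.zeros(cfg.n_value)
    if route.origin == "cognitive":
        # phasic name prime (external input amplitude 2: saturates its
        # stage near 2/3 of the activity bound)
        name_prime[tgt_idx] = 2.0
    elif target_id in model.groups:
        # the internal motivational state that defines the desired object:
        # a phasic drive prime for the motivational routes, a weaker tonic
        # drive for the bottom-up routes, whose selection must accumulate
        # conditioned evidence from the recognized scene
        drive[model.groups[target_id]] = 2.0

    # stage activities obey shunting saturation (bounded by 1); competition
    # decisions (normalized quenching) are taken on the instantaneous stage
    # inputs gated by suprathreshold activity, so saturation cannot erase
    # the winner-take-all margins
    x_name = np.zeros(n_obj)
    x_value = np.zeros(cfg.n_value)
    x_orb = np.zeros(n_obj)
    x_ita = np.zeros(cfg.invariant_capacity)
    x_itp = np.zeros(len(keys))
    eye, shroud, reset, eyemap = model.fresh_where()
    rate = cfg.stage_rate
    thr = cfg.firing_threshold
    quench = model.invariant.quench()
    from .dynamics import quench_compete

    gsyn = cfg.stage_input_gain

    def shunt(x, i):
        return np.clip(x + cfg.dt * rate * (-x + (1.0 - x) * gsyn * i),
                       0.0, 1.0)

    def decide(i_stage, x_stage):
        fired = np.where(x_stage > thr, np.maximum(i_stage, 0.0), 0.0)
        return quench_compete(fired, quench) if fired.any() else fired

    itp_selected = None
    fs_primed = None
    ita_quench = np.zeros(cfg.invariant_capacity)
    itp_streak = 0
    itp_candidate = None
    feat = np.zeros_like(fs.contours)
    t = 0.0
    steps = int(round(cfg.search_timeout / cfg.dt))
    node_of = {model.object_node.get(o, -1): i
               for i, o in enumerate(model.object_ids)}
    w_td_mat = np.array([model.invariant.w_td.get(k,
                         np.zeros(cfg.invariant_capacity)) for k in keys])
    for _ in range(steps):
        x_name = shunt(x_name, name_prime)
        name_out = np.where(x_name > thr, x_name, 0.0)
        # object-category output to the emotional circuit: the normalized
        # quenched ITa signal (shared across equally supported categories
        # until the resonance singles one out)
        ita_sig = np.zeros(n_obj)
        for node, i in node_of.items():
            if 0 <= node < x_ita.size:
                ita_sig[i] = ita_quench[node]
        # the bottom-up origin has no phasic prime: its motivational state
        # engages only once the scene has activated object categories
        drive_now = drive
        if route.origin == "bottom_up":
            drive_now = drive * float(np.any(x_ita > thr))
        i_value = drive_now + model.cogem.w_cond.T @ ita_sig
        x_value = shunt(x_value, i_value)
        # the value categories also compete (normalized quenching): the
        # drive-supported category silences the conditioned-reinforcer
        # echo of the distractor groups
        value_out = decide(i_value, x_value)
        orb_bu = model.cogem.w_ita_orb.T @ ita_sig
        orb_top = model.cogem.w_inc.T @ value_out \
            + model.cogem.w_name_orb.T @ name_out
        i_orb = orb_bu * (1.0 + g_on * orb_top) \
            + cfg.orb_prime_additive * g_on * orb_top
        x_orb = shunt(x_orb, i_orb)
        orb_out = decide(i_orb, x_orb)
        # ITa: bottom-up from view categories via integrators + ORB
        # feedback.  Per-node contributions from different positions are
        # max-pooled, not summed: two regions supporting the same invariant
        # object are alternative hypotheses about one thing, and summing
        # them would let a spurious double identification outrun the
        # resonance
        i_ita = np.zeros(cfg.invariant_capacity)
        for i, k in enumerate(keys):
            if k in model.invariant.w_bu:
                np.maximum(i_ita, model.invariant.w_bu[k]
                           * max(x_itp[i], 0.0), out=i_ita)
        fb_gain = cfg.ita_feedback_gain * (1.0 if volition else 0.25)
        fb = fb_gain * (model.cogem.w_ita_orb @ orb_out)
        for node, i in node_of.items():
            if 0 <= node < i_ita.size:
                i_ita[node] += fb[i]
        x_ita = shunt(x_ita, i_ita)
        ita_winner = decide(i_ita, x_ita)
        ita_quench = ita_winner
        # ITp: bottom-up match + top-down prime distributed according to
        # the (possibly shared) invariant category competition, so the
        # prime selects only once the IT-amygdala-orbitofrontal resonance
        # has resolved to a winner
        i_itp = np.array([b_itp[k] for k in keys])
        if ita_winner.any():
            i_itp = i_itp + g_on * (w_td_mat @ ita_winner)
        x_itp = shunt(x_itp, i_itp)
        if debug and int(round(t * 1000)) % 25 == 0:
            print(f"t={t:.3f} val={np.round(x_value,2)} "
                  f"orb_in_top={np.round(np.sort(i_orb)[-3:],2)} "
                  f"orb_out_nz={np.nonzero(orb_out)[0]} "
                  f"ita_w={np.nonzero(ita_winner)[0]} "
                  f"i_itp={np.round(i_itp,2)} x_itp={np.round(x_itp,2)}")
        if itp_selected is None and x_itp.max() > thr:
            # a view-category choice must be stable before it drives action:
            # the winner-take-all state has to persist through transients of
            # the settling resonance
            choice = decide(i_itp, x_itp)
            if choice.max() >= 0.99:
                cand = keys[int(np.argmax(choice))]
                itp_streak = itp_streak + 1 if cand == itp_candidate else 1
                itp_candidate = cand
            else:
                itp_streak = 0
                itp_candidate = None
            if itp_streak >= 15:
                itp_selected = itp_candidate
                t_select = t
                if route.path == "indirect":
                    r0, r1, c0, c1 = bounds_of(itp_selected[0],
                                               cfg.scene_side)
                    prime_map = np.zeros_like(fs.contours)
                    prime_map[r0:r1, c0:c1] = 1.0
                    fs_primed = fe.process_scene(scene, cfg,
                                                 itp_prime=prime_map)
        # Where stream: indirect path forms a shroud on the primed surface
        direct_in = None
        if itp_selected is not None:
            if route.path == "direct":
                direct_in = _direct_input_map(model, itp_selected,
                                              cfg.scene_side)
                if direct_in.max() <= 0:
                    return SearchResult(
                        False, None, target_region, None, route,
                        "direct route untrained (no position association)")
            else:
                # the enhanced surface projects to the spatial attention
                # map to facilitate its competition: the primed position's
                # surface input is additionally amplified at the PPC
                r0, r1, c0, c1 = bounds_of(itp_selected[0], cfg.scene_side)
                att = fs_primed.surface.pooled.copy()
                att[r0:r1, c0:c1] *= (1.0 + 7.0)
                head_att = gain_field_fwd(att, eye)
                shroud, reset, closed = attention_cycle_step(
                    head_att, shroud, reset, cfg, t)
                feat = salient_features(fs_primed.contours, shroud, eye, cfg)
                # the re-filtered boundary/surface signal builds up with
                # its own membrane time constant before it can drive the
                # saccade map
                feat = feat * (1.0 - np.exp(-cfg.surface_reprocess_rate
                                            * (t - t_select)))
        eyemap, target = next_saccade(eyemap, feat, direct_in, t, cfg)
        if target is not None:
            chosen = region_of(target[0], target[1], cfg.scene_side)
            return SearchResult(chosen == target_region, chosen,
                                target_region, t * 1000.0, route)
        t += cfg.dt
    why = "timeout"
    if itp_selected is None:
        why = "no view category selected (prime subthreshold or untrained)"
    return SearchResult(False, None, target_region, None, route, why)


def make_search_scenes(model: Model, seed: int = 0):
    """One search scene per trained object: the object as Waldo at a random
    non-foveal central region, distractors from the other value groups."""
    rng = np.random.default_rng(seed)
    scenes = []
    regions = [r for r in CENTRAL_REGIONS if r != FOVEA_REGION]
    for oid in model.object_ids:
        others = [o for o in model.object_ids
                  if model.groups[o] != model.groups[oid]]
        # small libraries reuse distractors (distinct regions, repeated ids)
        distr = list(rng.choice(others, size=8, replace=len(others) < 8))
        region = int(rng.choice(regions))
        scenes.append((oid, waldo_scene(oid, region, distr, model.groups,
                                        int(rng.integers(2**31)),
                                        model.cfg.scene_side)))
    return scenes


def run_battery(model: Model, scenes=None, routes=None, seed: int = 0
                ) -> pd.DataFrame:
    """Cross every search scene with every route; tabulate accuracy and RT."""
    scenes = scenes or make_search_scenes(model, seed)
    routes = routes or RouteSpec.all()
    rows = []
    for oid, spec in scenes:
        for route in routes:
            res = run_search_trial(model, spec, route, oid)
            rows.append({"object": oid, "route": str(route),
                         "origin": route.origin, "path": route.path,
                         "found": res.found, "chosen": res.chosen_region,
                         "target": res.target_region, "rt_ms": res.rt_ms,
                         "note": res.diagnostic})
    return pd.DataFrame(rows)
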