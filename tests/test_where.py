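"""Where stream: gain fields, shroud competition, reset, eye movements."""

import numpy as np
import pytest

from artscan import frontend as fe
from artscan.scene import SceneSpec, bounds_of, compose_scene, region_of
from artscan.where_stream import (EyeMovementMap, EyeState, ResetState,
                                  ShroudState, apply_ior,
                                  attention_cycle_step, gain_field_bwd,
                                  gain_field_fwd, next_saccade,
                                  salient_features, step_ior_recovery,
                                  update_shroud)


def center_eye(side=100):
    c = (side - 1) // 2
    return EyeState(position=(c, c))


class TestGainFields:
    def test_eye_at_center_is_identity(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0, 1, (100, 100))
        assert np.array_equal(gain_field_fwd(m, center_eye()), m)

    def test_pure_shift_moves_a_peak_by_the_eye_offset(self):
        m = np.zeros((100, 100))
        m[10, 10] = 1.0
        eye = EyeState(position=(49 + 3, 49 - 2))
        out = gain_field_fwd(m, eye)
        assert out[13, 8] == 1.0 and out.sum() == 1.0

    def test_forward_then_backward_is_identity_on_overlap(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (100, 100))
        eye = EyeState(position=(49 + 7, 49 - 4))
        back = gain_field_bwd(gain_field_fwd(m, eye), eye)
        assert np.array_equal(back[10:90, 10:90], m[10:90, 10:90])

    def test_planned_target_drives_predictive_remapping(self):
        m = np.zeros((100, 100))
        m[20, 20] = 1.0
        eye = EyeState(position=(49, 49), planned=(59, 49))
        out = gain_field_fwd(m, eye)
        assert out[30, 20] == 1.0  # shifted by the *planned* offset


@pytest.fixture(scope="module")
def two_object_frontend(cfg, library6):
    spec = SceneSpec(100, [(7, "obj00"), (9, "obj01")])
    return fe.process_scene(compose_scene(spec, library6), cfg)


def run_shroud(att, cfg, steps, shroud=None, reset=None, t0=0.0):
    shroud = shroud or ShroudState.blank(att.shape[0], cfg)
    reset = reset or ResetState.blank(cfg)
    t = t0
    for _ in range(steps):
        shroud, reset, closed = attention_cycle_step(att, shroud, reset,
                                                     cfg, t)
        t += cfg.dt
    return shroud, reset, t


class TestShroud:
    def test_single_object_shroud_fits_the_object(self, cfg, library6):
        spec = SceneSpec(100, [(7, "obj00")])
        fs = fe.process_scene(compose_scene(spec, library6), cfg)
        shroud, _, _ = run_shroud(fs.surface.pooled, cfg, 300)
        support = shroud.activity > 0.5 * shroud.activity.max()
        obj = compose_scene(spec, library6) != 0.5
        inter = (support & obj).sum()
        union = (support | obj).sum()
        assert inter / union >= 0.5
        # nothing suprathreshold outside the object's region
        r0, r1, c0, c1 = bounds_of(7, 100)
        outside = support.copy()
        outside[r0:r1, c0:c1] = False
        assert outside.sum() == 0

    def test_higher_contrast_object_wins_the_competition(self, cfg,
                                                         library6):
        # obj00 (|dL| = 0.45) vs the same shape at lower contrast via obj01
        spec = SceneSpec(100, [(7, "obj01"), (9, "obj00")])
        fs = fe.process_scene(compose_scene(spec, library6), cfg)
        shroud, _, _ = run_shroud(fs.surface.pooled, cfg, 300)
        ys, xs = np.nonzero(shroud.winner_mask)
        region = region_of(int(ys.mean()), int(xs.mean()), 100)
        # winner is the blob with the higher mean drive
        u = fs.surface.pooled / fs.surface.pooled.max()
        strengths = {}
        for r in (7, 9):
            a0, a1, b0, b1 = bounds_of(r, 100)
            crop = np.maximum(u[a0:a1, b0:b1] - cfg.shroud_input_quench, 0)
            strengths[r] = crop[crop > 0].mean()
        assert region == max(strengths, key=strengths.get)

    def test_symmetric_input_resolves_deterministically(self, cfg):
        att = np.zeros((100, 100))
        att[28:32, 28:32] = 1.0
        att[28:32, 68:72] = 1.0
        a, _, _ = run_shroud(att, cfg, 200)
        b, _, _ = run_shroud(att, cfg, 200)
        assert np.array_equal(a.winner_mask, b.winner_mask)
        ys, xs = np.nonzero(a.winner_mask)
        # tie broken toward the lowest row-major position
        assert xs.mean() < 50


class TestReset:
    def test_constant_shroud_total_never_resets(self, cfg):
        att = np.zeros((100, 100))
        att[40:60, 40:60] = 1.0
        shroud = ShroudState.blank(100, cfg)
        # freeze the gates: no habituation, no collapse, no reset
        shroud.gates.recovery_rate = 1.0
        shroud.gates.depletion_rate = 0.0
        shroud, reset, _ = run_shroud(att, cfg, 3000, shroud=shroud)
        assert reset.events == []

    def test_collapse_triggers_exactly_one_transient_reset(self, cfg,
            two_object_frontend):
        att = two_object_frontend.surface.pooled
        shroud, reset, t = run_shroud(att, cfg, 1600)
        assert len(reset.events) == 1
        # the Where-stream burst is transient: gated output near zero again
        # within 0.3 s of the event
        burst, r2 = [], reset
        s2 = shroud
        for i in range(300):
            s2, r2, _ = attention_cycle_step(att, s2, r2, cfg, t + i * cfg.dt)
        assert r2.where_output < 0.05

    def test_three_shrouds_give_three_resets(self, cfg, freeview_log):
        _, log = freeview_log
        assert len(log.resets) == 3
        assert len(log.epochs) >= 3

    def test_what_latch_persists_until_next_shroud(self, cfg, freeview_log):
        model, log = freeview_log
        # the latch was set at each reset and cleared at each following
        # epoch onset; after the trial's final epoch onset it is low
        assert not model.latch.high


class TestEyeMovements:
    def test_no_shroud_no_suprathreshold_choice(self, cfg,
                                                two_object_frontend):
        s = ShroudState.blank(100, cfg)
        feat = salient_features(two_object_frontend.contours, s,
                                center_eye(), cfg)
        m = EyeMovementMap.blank(100, cfg)
        target = None
        for i in range(400):
            m, target = next_saccade(m, feat, None, i * cfg.dt, cfg)
            assert target is None

    def test_candidates_confined_to_attended_surface(self, cfg,
                                                     two_object_frontend):
        att = two_object_frontend.surface.pooled
        shroud, _, _ = run_shroud(att, cfg, 300)
        feat = salient_features(two_object_frontend.contours, shroud,
                                center_eye(), cfg)
        ys, xs = np.nonzero(shroud.winner_mask)
        region = region_of(int(ys.mean()), int(xs.mean()), 100)
        r0, r1, c0, c1 = bounds_of(region, 100)
        outside = feat.copy()
        outside[r0 - 2 : r1 + 2, c0 - 2 : c1 + 2] = 0
        assert outside.max() < 0.5 * feat.max()

    def test_fresh_gates_choose_the_unique_maximum(self, cfg):
        feat = np.zeros((100, 100))
        feat[30, 30] = 1.0
        m = EyeMovementMap.blank(100, cfg)
        target = None
        i = 0
        while target is None and i < 1000:
            m, target = next_saccade(m, feat, None, i * cfg.dt, cfg)
            i += 1
        assert target == (30, 30)

    def test_inhibition_of_return_prevents_immediate_revisit(self, cfg):
        feat = np.zeros((100, 100))
        feat[30, 30] = 1.0
        feat[30, 40] = 0.9
        m = EyeMovementMap.blank(100, cfg)
        t, target = 0.0, None
        while target is None:
            m, target = next_saccade(m, feat, None, t, cfg)
            t += cfg.dt
        first = target
        m = apply_ior(m, first, t, cfg)
        target = None
        while target is None and t < 2.0:
            m, target = next_saccade(m, feat, None, t, cfg)
            m = step_ior_recovery(m, cfg.dt)
            t += cfg.dt
        assert first == (30, 30)
        assert target == (30, 40)

    def test_direct_route_input_alone_elicits_a_saccade(self, cfg):
        direct = np.zeros((100, 100))
        y, x = np.mgrid[0:100, 0:100]
        direct = np.exp(-((y - 30) ** 2 + (x - 50) ** 2) / 8.0)
        m = EyeMovementMap.blank(100, cfg)
        t, target = 0.0, None
        while target is None and t < 1.0:
            m, target = next_saccade(m, np.zeros((100, 100)), direct, t, cfg)
            t += cfg.dt
        assert target is not None
        assert region_of(*target, 100) == region_of(30, 50, 100)


class TestFreeViewingProperties:
    def test_fixations_contained_in_attended_object_region(self, cfg,
                                                           freeview_log):
        """While a shroud is active, saccades land on the attended object
        (spatial attention gates saccade target selection)."""
        _, log = freeview_log
        epochs = log.epochs
        spans = [(epochs[i][0], epochs[i + 1][0] if i + 1 < len(epochs)
                  else np.inf, epochs[i][1]) for i in range(len(epochs))]
        obj_region = {o: r for r, o in
                      [(13, "obj00"), (7, "obj01"), (14, "obj03")]}
        for t, row, col, region in log.fixations:
            oid = next(o for a, b, o in spans if a <= t < b)
            assert region == obj_region[oid]

    def test_no_immediate_refixation_of_the_same_hotspot(self, cfg,
                                                         freeview_log):
        _, log = freeview_log
        pts = [(r, c) for _, r, c, _ in log.fixations]
        for a, b in zip(pts, pts[1:]):
            assert np.hypot(a[0] - b[0], a[1] - b[1]) > cfg.ior_radius

    def test_one_reset_per_shroud_epoch(self, freeview_log):
        _, log = freeview_log
        # each completed epoch ends in exactly one reset; the final epoch
        # may still be running at the end of the trial
        assert len(log.epochs) - len(log.resets) in (0, 1)
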