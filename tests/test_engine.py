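"""Orchestration: the coupled loop, learning protocols, search routes,
ablations, and model serialization."""

import numpy as np
import pytest

from artscan.engine import (Model, RouteSpec, integrate,
                            invariant_response_node, make_search_scenes,
                            run_battery, run_learning_trial,
                            run_reinforcement_schedule, run_search_trial,
                            train_positional)
from artscan.scene import SceneSpec


class TestIntegrate:
    def test_uniform_scene_drives_nothing(self, cfg, library6):
        m = Model(cfg, library6)
        log = integrate(m, SceneSpec(cfg.scene_side, []), 1.0, learn=True)
        assert log.epochs == []
        assert log.fixations == []
        assert log.resets == []
        assert m.banks.total_committed() == 0

    def test_deterministic_given_identical_state(self, cfg, library6):
        logs = []
        for _ in range(2):
            m = Model(cfg, library6)
            spec = SceneSpec(cfg.scene_side, [(7, "obj00"), (13, "obj01")])
            logs.append(integrate(m, spec, 1.2, learn=True))
        assert logs[0].fixations == logs[1].fixations
        assert logs[0].resets == logs[1].resets
        assert logs[0].epochs == logs[1].epochs

    def test_single_object_scene_produces_epoch_with_fixations(self, cfg,
                                                               library6):
        m = Model(cfg, library6)
        log = integrate(m, SceneSpec(cfg.scene_side, [(7, "obj00")]), 1.2,
                        learn=True)
        assert len(log.epochs) >= 1
        assert len(log.fixations) >= 3

    def test_learning_disabled_changes_no_weights(self, cfg, library6):
        m = Model(cfg, library6)
        spec = SceneSpec(cfg.scene_side, [(7, "obj00")])
        integrate(m, spec, 1.0, learn=False)
        assert m.banks.total_committed() == 0
        assert m.invariant.n_committed == 0

    def test_three_objects_three_epochs_three_categories(self, freeview_log):
        model, log = freeview_log
        assert len(log.epochs) >= 3
        assert len({o for _, o in log.epochs[:3]}) == 3
        assert model.invariant.n_committed >= 3


class TestPositionalProtocol:
    def test_object_to_category_map_is_a_bijection(self, trained12):
        nodes = [trained12.object_node[o] for o in trained12.object_ids]
        assert len(set(nodes)) == len(nodes) == 12

    def test_any_position_activates_the_same_invariant_node(self, trained12):
        for oid in trained12.object_ids[:4]:
            nodes = {invariant_response_node(trained12, oid, p)
                     for p in (7, 12, 19)}
            assert nodes == {trained12.object_node[oid]}

    def test_integrator_ablation_reproduces_category_proliferation(
            self, cfg, library6):
        m = Model(cfg, library6, groups={o: 0 for o in library6})
        m.ablate_integrators = True
        train_positional(m, object_ids=["obj00", "obj01"],
                         positions=(7, 9), trials=2)
        per_object = {}
        for oid in ("obj00", "obj01"):
            per_object[oid] = {invariant_response_node(m, oid, p)
                               for p in (7, 9)}
        # without the integrator bridge, fovea and periphery recruit
        # different invariant categories
        assert any(len(v) > 1 for v in per_object.values())

    def test_zero_trials_change_nothing(self, cfg, library6):
        m = Model(cfg, library6)
        train_positional(m, object_ids=["obj00"], positions=(7,), trials=0)
        assert m.invariant.n_committed == 0

    def test_scene_queue_advances_on_reset(self, cfg, library6):
        """The positionally-invariant protocol feeds the next single-object
        scene after each completed reset, with the eyes re-centered."""
        m = Model(cfg, library6)
        scenes = [SceneSpec(cfg.scene_side, [(7, "obj00")]),
                  SceneSpec(cfg.scene_side, [(9, "obj00")])]
        log = run_learning_trial(m, scenes, duration_per_scene=1.6)
        assert len(log.epochs) >= 2
        regions = [r for _, _, _, r in log.fixations]
        assert 7 in regions and 9 in regions


class TestReinforcement:
    def test_selective_many_to_one_weight_structure(self, trained12):
        w = trained12.cogem.w_cond
        for oid in trained12.object_ids:
            i = trained12.obj_index[oid]
            g = trained12.groups[oid]
            assert w[i, g] > 0
            others = [k for k in range(w.shape[1]) if k != g]
            assert np.all(w[i, others] == 0)

    def test_enhancement_of_value_and_object_value_layers(self, cfg,
                                                          library6):
        groups = {o: i % 2 for i, o in enumerate(sorted(library6))}

        def run(ablated):
            m = Model(cfg, library6, groups=groups)
            m.object_node = {o: i for i, o in enumerate(sorted(library6))}
            m.ablate_reinforcement = ablated
            return run_reinforcement_schedule(m, trials=10, record=True)

        with_r = run(False)
        without = run(True)
        for k, strict in (("value", True), ("orb", True), ("name", False),
                          ("ita", False)):
            a = np.array([c[k] for c in with_r])
            b = np.array([c[k] for c in without])
            assert np.all(a > b) if strict else np.all(a >= b)


@pytest.fixture(scope="module")
def scenes(trained12):
    return make_search_scenes(trained12, seed=3)[:4]


class TestSearch:

    def test_all_routes_find_their_target(self, trained12, scenes):
        for oid, spec in scenes:
            for route in RouteSpec.all():
                res = run_search_trial(trained12, spec, route, oid)
                assert res.found, (oid, str(route), res.diagnostic)
                assert res.rt_ms > 0

    def test_direct_routes_are_faster_than_indirect(self, trained12,
                                                    scenes):
        oid, spec = scenes[0]
        for origin in ("bottom_up", "cognitive", "motivational"):
            d = run_search_trial(trained12, spec,
                                 RouteSpec(origin, "direct"), oid)
            i = run_search_trial(trained12, spec,
                                 RouteSpec(origin, "indirect"), oid)
            assert d.rt_ms < i.rt_ms

    def test_volition_off_breaks_top_down_routes(self, trained12, scenes):
        oid, spec = scenes[0]
        for origin in ("cognitive", "motivational"):
            res = run_search_trial(trained12, spec,
                                   RouteSpec(origin, "direct"), oid,
                                   volition=False)
            assert not res.found

    def test_direct_weight_ablation_breaks_only_direct_routes(
            self, trained12, scenes):
        oid, spec = scenes[1]
        saved = dict(trained12.banks.position_assoc)
        trained12.banks.position_assoc = {}
        try:
            d = run_search_trial(trained12, spec,
                                 RouteSpec("cognitive", "direct"), oid)
            i = run_search_trial(trained12, spec,
                                 RouteSpec("cognitive", "indirect"), oid)
        finally:
            trained12.banks.position_assoc = saved
        assert not d.found and "direct route untrained" in d.diagnostic
        assert i.found

    def test_prime_for_untrained_object_reports_not_found(self, cfg,
                                                          library6,
                                                          trained12,
                                                          scenes):
        oid, spec = scenes[2]
        fresh = Model(trained12.cfg, trained12.library,
                      groups=trained12.groups)
        res = run_search_trial(fresh, spec, RouteSpec("cognitive", "direct"),
                               oid)
        assert not res.found

    def test_battery_shape_and_determinism(self, trained12, scenes):
        df1 = run_battery(trained12, scenes[:2])
        df2 = run_battery(trained12, scenes[:2])
        assert len(df1) == 2 * 6
        assert df1.equals(df2)
        assert set(df1.columns) >= {"object", "route", "found", "chosen",
                                    "target", "rt_ms"}


class TestSerialization:
    def test_save_load_roundtrip_preserves_search_behavior(self, trained12,
                                                           tmp_path):
        path = str(tmp_path / "model.h5")
        trained12.save(path)
        again = Model.load(path)
        assert again.object_node == trained12.object_node
        oid, spec = make_search_scenes(trained12, seed=5)[0]
        a = run_search_trial(trained12, spec,
                             RouteSpec("cognitive", "direct"), oid)
        b = run_search_trial(again, spec,
                             RouteSpec("cognitive", "direct"), oid)
        assert (a.found, a.chosen_region, a.rt_ms) \
            == (b.found, b.chosen_region, b.rt_ms)
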