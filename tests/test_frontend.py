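"""Retina/LGN, V1/V2 and filling-in front end."""

import numpy as np
import pytest

from artscan import frontend as fe
from artscan.config import ModelConfig
from artscan.dynamics import gaussian_center
from artscan.scene import SceneSpec, bounds_of, compose_scene


@pytest.fixture(scope="module")
def uniform_state(cfg):
    return fe.process_scene(np.full((100, 100), 0.5), cfg)


@pytest.fixture(scope="module")
def disk_scene(cfg):
    scene = np.full((100, 100), 0.5)
    y, x = np.mgrid[0:100, 0:100]
    scene[(y - 50) ** 2 + (x - 50) ** 2 <= 8**2] = 0.9
    return scene


class TestLGN:
    def test_uniform_scene_discounts_the_illuminant(self, cfg):
        maps = fe.lgn_normalize(np.full((100, 100), 0.5), cfg)
        for m in maps.on + maps.off:
            assert np.allclose(m, 0.0, atol=1e-9)

    def test_bright_disk_drives_on_inside_and_off_outside(self, cfg,
                                                          disk_scene):
        maps = fe.lgn_normalize(disk_scene, cfg)
        on, off = maps.on[0], maps.off[0]
        assert on[50, 50 + 6] > 0          # just inside the rim
        assert off[50, 50 + 10] > 0        # just outside the rim
        assert on[50, 50 + 10] == 0.0

    def test_weber_law_compresses_doubled_contrast(self, cfg, disk_scene):
        maps1 = fe.lgn_normalize(disk_scene, cfg)
        doubled = 0.5 + 2.0 * (disk_scene - 0.5)
        maps2 = fe.lgn_normalize(np.clip(doubled, 0, 1), cfg)
        r1 = maps1.on[0].max()
        r2 = maps2.on[0].max()
        assert r1 < r2 < 2.0 * r1


class TestSimpleComplex:
    def test_vertical_step_maximally_drives_vertical_orientation(self, cfg):
        scene = np.full((100, 100), 0.3)
        scene[:, 50:] = 0.7
        onoff = fe.lgn_normalize(scene, cfg)
        simple = fe.simple_cells(onoff, cfg)
        cmaps = fe.complex_cells(simple, cfg)
        # orientation index 0 is 0 deg (vertical edge: derivative along x)
        totals = [cm.sum() for cm in cmaps[0]]
        assert np.argmax(totals) == 0

    def test_opposite_polarities_are_mirror_images_across_a_step(self, cfg):
        scene = np.full((100, 100), 0.3)
        scene[:, 50:] = 0.7
        flipped = scene[:, ::-1]
        s1 = fe.simple_cells(fe.lgn_normalize(scene, cfg), cfg)
        s2 = fe.simple_cells(fe.lgn_normalize(flipped, cfg), cfg)
        a = s1[0][0][0][:, 1:-1]
        b = s2[0][0][1][:, 1:-1][:, ::-1]
        assert np.allclose(a, b, atol=1e-9)

    def test_complex_cells_are_polarity_insensitive(self, cfg):
        # a dark-to-light step and the reversed light-to-dark step evoke
        # identical (mirrored) complex-cell responses
        scene = np.full((100, 100), 0.3)
        scene[:, 50:] = 0.7
        reverse = scene[:, ::-1]
        c1 = fe.complex_cells(fe.simple_cells(fe.lgn_normalize(scene, cfg),
                                              cfg), cfg)
        c2 = fe.complex_cells(fe.simple_cells(fe.lgn_normalize(reverse, cfg),
                                              cfg), cfg)
        assert np.allclose(c1[0][0][:, 1:-1], c2[0][0][:, 1:-1][:, ::-1],
                           atol=1e-9)

    def test_complex_equals_sum_of_rectified_simple_pair(self, cfg):
        rng = np.random.default_rng(7)
        scene = rng.uniform(0, 1, (100, 100))
        simple = fe.simple_cells(fe.lgn_normalize(scene, cfg), cfg)
        cmaps = fe.complex_cells(simple, cfg)
        for s in range(3):
            for o in range(4):
                pa, pb = simple[s][o]
                assert np.allclose(cmaps[s][o], pa + pb)


class TestBoundariesAndFilling:
    def test_uniform_scene_has_no_boundaries_surfaces_or_contours(
            self, uniform_state):
        assert uniform_state.boundary.pooled.max() < 1e-9
        assert uniform_state.surface.pooled.max() < 1e-9
        assert uniform_state.contours.max() < 1e-12

    def test_category_prime_strengthens_only_the_primed_region(self, cfg,
                                                               library6):
        spec = SceneSpec(100, [(7, "obj00"), (9, "obj01")])
        scene = compose_scene(spec, library6)
        base = fe.process_scene(scene, cfg)
        prime = np.zeros_like(scene)
        r0, r1, c0, c1 = bounds_of(9, 100)
        prime[r0:r1, c0:c1] = 1.0
        primed = fe.process_scene(scene, cfg, itp_prime=prime)

        def region_total(state, region):
            a0, a1, b0, b1 = bounds_of(region, 100)
            return state.boundary.pooled[a0:a1, b0:b1].sum()

        assert region_total(primed, 9) > region_total(base, 9)
        assert region_total(primed, 7) <= region_total(base, 7) + 1e-9

    def test_closed_square_fills_uniformly_inside(self, cfg):
        # oracle configuration: an explicit closed square boundary and a
        # uniform interior source; the filled compartment is uniform
        side = 20
        b = np.zeros((side, side))
        b[4:6, 4:16] = b[14:16, 4:16] = 1.0
        b[4:16, 4:6] = b[4:16, 14:16] = 1.0
        bmap = fe.BoundaryMap([[b]], b)
        src = np.zeros((side, side))
        src[8:12, 8:12] = 0.3
        onoff = fe.OnOffMaps([src], [np.zeros_like(src)])
        surf = fe.fill_in(onoff, bmap, cfg)
        interior = surf.on[7:13, 7:13]
        exterior = surf.on.copy()
        exterior[4:16, 4:16] = 0
        assert interior.std() / interior.mean() < 0.01
        assert exterior.max() < 0.05 * interior.mean()

    def test_no_boundaries_and_uniform_input_fill_uniformly(self, cfg):
        side = 20
        src = np.full((side, side), 0.2)
        bmap = fe.BoundaryMap([[np.zeros((side, side))]],
                              np.zeros((side, side)))
        surf = fe.fill_in(fe.OnOffMaps([src], [np.zeros_like(src)]),
                          bmap, cfg)
        assert surf.on.std() / surf.on.mean() < 0.01

    def test_attention_feedback_raises_attended_surface_activity(self, cfg,
                                                                 library6):
        spec = SceneSpec(100, [(7, "obj00"), (9, "obj00")])
        scene = compose_scene(spec, library6)
        att = np.zeros_like(scene)
        r0, r1, c0, c1 = bounds_of(7, 100)
        att[r0:r1, c0:c1] = 1.0
        base = fe.process_scene(scene, cfg)
        boosted = fe.process_scene(scene, cfg, attention_feedback=att)
        a0, a1, b0, b1 = bounds_of(7, 100)
        c0_, c1_, d0, d1 = bounds_of(9, 100)
        assert boosted.surface.pooled[a0:a1, b0:b1].sum() \
            > base.surface.pooled[a0:a1, b0:b1].sum()
        assert boosted.surface.pooled[c0_:c1_, d0:d1].sum() \
            > 0.5 * base.surface.pooled[c0_:c1_, d0:d1].sum()


class TestSurfaceContours:
    def test_filled_disk_yields_ring_of_contour_activity(self, cfg,
                                                         disk_scene):
        state = fe.process_scene(disk_scene, cfg)
        c = state.contours
        # contour activity concentrates on the rim: the global maximum lies
        # at disk-radius distance from the center, well above the interior
        y, x = np.unravel_index(np.argmax(c), c.shape)
        assert 3 <= np.hypot(y - 50, x - 50) <= 11
        assert c.max() > 5 * c[50, 50]

    def test_filled_square_contours_peak_at_corners(self, cfg):
        scene = np.full((100, 100), 0.5)
        scene[40:61, 40:61] = 0.9
        state = fe.process_scene(scene, cfg)
        c = state.contours
        corner = max(c[40, 40], c[40, 60], c[60, 40], c[60, 60])
        edge_mid = max(c[40, 50], c[50, 40], c[60, 50], c[50, 60])
        assert corner > edge_mid

    def test_contour_total_monotone_in_surface_contrast(self, cfg):
        totals = []
        for lum in (0.7, 0.8, 0.95):
            scene = np.full((100, 100), 0.5)
            scene[45:56, 45:56] = lum
            totals.append(fe.process_scene(scene, cfg).contours.sum())
        assert totals[0] < totals[1] < totals[2]


class TestContrastGainChain:
    def test_attention_increases_contour_then_boundary_totals(self, cfg,
                                                              library6):
        """Spatial attention on one of two identical objects raises its
        surface contours and thence its boundary total (the resonance's
        contrast-gain chain)."""
        spec = SceneSpec(100, [(7, "obj00"), (9, "obj00")])
        scene = compose_scene(spec, library6)
        att = np.zeros_like(scene)
        r0, r1, c0, c1 = bounds_of(7, 100)
        att[r0:r1, c0:c1] = 1.0
        base = fe.process_scene(scene, cfg)
        boosted = fe.process_scene(scene, cfg, attention_feedback=att)

        def totals(state, region):
            a0, a1, b0, b1 = bounds_of(region, 100)
            return (state.contours[a0:a1, b0:b1].sum(),
                    state.boundary.pooled[a0:a1, b0:b1].sum())

        c_base, b_base = totals(base, 7)
        c_boost, b_boost = totals(boosted, 7)
        assert c_boost > c_base
        assert b_boost > b_base
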