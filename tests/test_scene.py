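"""Stimulus construction: backgrounds, sphere sprites, composition,
occlusion-controlled placement."""

import numpy as np
import pytest

from camopt.scene import (
    DEFAULT_ENVIRONMENTS,
    EnvironmentConfig,
    PlacementError,
    PlacementInfeasibleError,
    SPHERE_DIAMETER,
    StimulusScene,
    compose,
    disc_mask,
    generate_background,
    occlusion_fraction_at,
    sample_placement,
    shade_sphere,
    _inside_frame_mask,
)

SMALL = (480, 320)  # (width, height) used for desk-scale scene tests


def make_scene(occluder, diameter=41, environment="forest"):
    h, w = occluder.shape
    return StimulusScene(
        background=np.zeros((h, w, 3), dtype=np.uint8),
        occluder_mask=occluder,
        permissible_mask=_inside_frame_mask((h, w), diameter),
        environment=environment,
        sphere_diameter=diameter,
    )


class TestBackgrounds:
    def test_deterministic_given_environment_and_seed(self):
        a = generate_background("forest", 7, size=SMALL)
        b = generate_background("forest", 7, size=SMALL)
        assert np.array_equal(a.background, b.background)
        assert np.array_equal(a.occluder_mask, b.occluder_mask)
        c = generate_background("forest", 8, size=SMALL)
        assert not np.array_equal(a.background, c.background)

    def test_unknown_environment_rejected(self):
        with pytest.raises(ValueError, match="unknown environment"):
            generate_background("tundra", 0, size=SMALL)

    def test_single_colour_palette_gives_uniform_background(self):
        envs = {
            "flat": EnvironmentConfig(name="flat", palette=((10, 20, 30),))
        }
        sc = generate_background("flat", 0, size=SMALL, environments=envs)
        assert (sc.background == np.array([10, 20, 30], dtype=np.uint8)).all()

    def test_permissible_mask_matches_brute_force_centre_scan(self):
        d = 41
        sc = generate_background("desert", 1, size=(100, 90), sphere_diameter=d)
        off_lo = (d - 1) // 2
        off_hi = d // 2
        h, w = sc.permissible_mask.shape
        brute = np.zeros((h, w), dtype=bool)
        for y in range(h):
            for x in range(w):
                brute[y, x] = (
                    y - off_lo >= 0
                    and x - off_lo >= 0
                    and y + off_hi <= h - 1
                    and x + off_hi <= w - 1
                )
        assert np.array_equal(sc.permissible_mask, brute)
        assert sc.permissible_mask.any()

    def test_occluder_cover_near_configured_mean(self):
        sc = generate_background("forest", 3, size=(640, 480))
        cover = sc.occluder_mask.mean()
        assert cover == pytest.approx(
            DEFAULT_ENVIRONMENTS["forest"].occluder_cover, abs=0.02
        )


class TestSphere:
    def test_widest_row_spans_exactly_the_diameter(self):
        sp = shade_sphere((34, 68, 17), SPHERE_DIAMETER)
        assert sp.alpha.sum(axis=1).max() == SPHERE_DIAMETER

    @pytest.mark.parametrize("d", [3, 5, 40, 41, 128])
    def test_widest_row_for_various_diameters(self, d):
        sp = shade_sphere((200, 10, 10), d)
        assert sp.alpha.sum(axis=1).max() == d
        assert sp.alpha.sum(axis=0).max() == d

    def test_bounding_square_corners_transparent(self):
        sp = shade_sphere((1, 2, 3), 64)
        for y, x in [(0, 0), (0, 63), (63, 0), (63, 63)]:
            assert not sp.alpha[y, x]
            assert sp.rgba[y, x, 3] == 0

    def test_shading_peaks_at_one_and_stays_positive(self):
        sp = shade_sphere((100, 100, 100), 129)
        inside = sp.shading[sp.alpha]
        assert inside.max() == pytest.approx(1.0, abs=1e-6)
        assert inside.min() > 0.0

    def test_diameter_below_three_rejected(self):
        with pytest.raises(ValueError):
            shade_sphere((0, 0, 0), 2)


class TestCompose:
    def test_no_occluders_gives_zero_occlusion(self):
        occ = np.zeros((120, 160), dtype=bool)
        sc = make_scene(occ)
        stim = compose(sc, shade_sphere((250, 40, 40), 41), (80, 60))
        assert stim.occlusion_fraction == 0.0

    def test_half_plane_occluder_covers_half_the_disc(self):
        d = 41
        occ = np.zeros((120, 160), dtype=bool)
        occ[:, :80] = True  # left half of the image
        sc = make_scene(occ, diameter=d)
        # disc centred on the boundary: left half occluded
        stim = compose(sc, shade_sphere((250, 40, 40), d), (80, 60))
        disc = disc_mask(d)
        # exact half up to the one-pixel column containing the centre
        quantum = disc.sum(axis=0).max() / disc.sum()
        assert stim.occlusion_fraction == pytest.approx(0.5, abs=quantum)

    def test_changes_confined_to_unoccluded_disc_pixels(self):
        rng = np.random.default_rng(1)
        occ = rng.random((120, 160)) < 0.4
        sc = make_scene(occ)
        d = sc.sphere_diameter
        stim = compose(sc, shade_sphere((250, 250, 10), d), (70, 65))
        diff = (stim.image != sc.background).any(axis=-1)
        allowed = np.zeros_like(diff)
        off = (d - 1) // 2
        allowed[65 - off : 65 - off + d, 70 - off : 70 - off + d] = (
            disc_mask(d) & ~occ[65 - off : 65 - off + d, 70 - off : 70 - off + d]
        )
        assert not (diff & ~allowed).any()

    def test_occlusion_agrees_with_recount_from_composed_image(self):
        # black background, bright sphere: visible sphere pixels are
        # exactly the changed pixels, so the fraction can be recounted
        rng = np.random.default_rng(2)
        occ = rng.random((120, 160)) < 0.35
        sc = make_scene(occ)
        d = sc.sphere_diameter
        stim = compose(sc, shade_sphere((255, 255, 255), d), (75, 60))
        visible = (stim.image != sc.background).any(axis=-1).sum()
        total = disc_mask(d).sum()
        assert stim.occlusion_fraction == pytest.approx(1 - visible / total)

    def test_determinism(self):
        occ = np.zeros((120, 160), dtype=bool)
        occ[50:70, :] = True
        sc = make_scene(occ)
        s1 = compose(sc, shade_sphere((1, 2, 3), 41), (80, 60))
        s2 = compose(sc, shade_sphere((1, 2, 3), 41), (80, 60))
        assert np.array_equal(s1.image, s2.image)
        assert s1.occlusion_fraction == s2.occlusion_fraction

    def test_centre_outside_permissible_mask_rejected(self):
        sc = make_scene(np.zeros((120, 160), dtype=bool))
        with pytest.raises(PlacementError):
            compose(sc, shade_sphere((1, 2, 3), 41), (5, 5))

    def test_side_follows_midline(self):
        sc = make_scene(np.zeros((120, 160), dtype=bool))
        sp = shade_sphere((9, 9, 9), 41)
        assert compose(sc, sp, (30, 60)).side == "left"
        assert compose(sc, sp, (130, 60)).side == "right"


class TestPlacement:
    def test_full_range_accepts_first_draw(self):
        sc = make_scene(np.zeros((120, 160), dtype=bool))
        centre, frac = sample_placement(sc, (0.0, 1.0), seed=0, max_tries=1)
        assert sc.permissible_mask[centre[1], centre[0]]
        assert frac == 0.0

    def test_no_occluders_makes_nonzero_range_infeasible(self):
        sc = make_scene(np.zeros((120, 160), dtype=bool))
        with pytest.raises(PlacementInfeasibleError):
            sample_placement(sc, (0.25, 0.50), seed=0, max_tries=50)

    def test_accepted_fractions_always_inside_range(self):
        sc = generate_background("forest", 11, size=SMALL, sphere_diameter=41)
        rng = np.random.default_rng(3)
        for _ in range(50):
            _, frac = sample_placement(sc, (0.25, 0.50), seed=rng)
            assert 0.25 <= frac <= 0.50

    def test_mean_accepted_occlusion_is_37_5_percent(self):
        # occluder: iid pixel noise whose density rises linearly across
        # x, symmetric about 0.375, so accepted fractions are close to
        # uniform on [0.25, 0.50]
        d = 41
        h, w = 160, 600
        rng = np.random.default_rng(4)
        density = np.linspace(0.20, 0.55, w)[None, :]
        occ = rng.random((h, w)) < density
        sc = make_scene(occ, diameter=d)
        gen = np.random.default_rng(5)
        fracs = np.array(
            [sample_placement(sc, (0.25, 0.50), seed=gen)[1] for _ in range(10_000)]
        )
        assert fracs.min() >= 0.25 and fracs.max() <= 0.50
        assert abs(fracs.mean() - 0.375) <= 0.00375  # 1% of 37.5%

    def test_realised_fraction_matches_mask_recount(self):
        sc = generate_background("desert", 2, size=SMALL, sphere_diameter=41)
        centre, frac = sample_placement(sc, (0.25, 0.50), seed=9)
        assert frac == occlusion_fraction_at(sc, centre)
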