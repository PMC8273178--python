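"""Stimulus rendering: geometry, textures, scrambling, grating contrast."""

import numpy as np
import pytest

from chromasupp.munsell import D65_WHITE, chip_set, white_luminance_for_value5
from chromasupp.stimuli import (
    BLACK_LEVEL,
    GratingSpec,
    PatchPatternSpec,
    TextureSpec,
    load_stimulus,
    measure_michelson,
    render_grating,
    render_patch_pattern,
    render_texture,
    save_stimulus,
    scramble,
)


def test_degree_pixel_conversion_is_invertible(small_display):
    X, Y = small_display.pixel_grid_deg()
    ppx, ppy = small_display.px_per_deg
    w, h = small_display.resolution
    cols = X[0] * ppx + w / 2 - 0.5
    assert np.allclose(cols, np.arange(w))
    rows = h / 2 - Y[:, 0] * ppy - 0.5
    assert np.allclose(rows, np.arange(h))


class TestPatchPattern:
    def test_ring_geometry_equal_arc(self, small_display):
        img = render_patch_pattern(PatchPatternSpec(), 7, small_display)
        centers = np.asarray(img.provenance["patch_centers_deg"])
        radii = np.hypot(centers[:, 0], centers[:, 1])
        assert np.allclose(radii, 12.4 / 2)
        angles = np.rad2deg(np.arctan2(centers[:, 1], centers[:, 0]))
        steps = np.diff(np.sort(angles % 360))
        assert np.allclose(steps, 36.0, atol=1e-9)

    def test_jitter_from_allowed_set_and_whole_ring(self, small_display):
        seen = set()
        for seed in range(12):
            img = render_patch_pattern(PatchPatternSpec(), seed, small_display)
            seen.add(img.provenance["ring_jitter_deg"])
        assert seen <= {-12.0, 0.0, 12.0}
        assert len(seen) > 1

    def test_patch_luminance_matches_chip(self, small_display):
        spec = PatchPatternSpec(chroma_condition="/4", background="black")
        img = render_patch_pattern(spec, 3, small_display)
        chips = chip_set("/4", white_luminance_for_value5(16.0))
        inside = img.masks["patches"] & (img.luminance > BLACK_LEVEL)
        vals = np.unique(img.luminance[inside])
        assert np.allclose(vals, chips[0].luminance)
        # colored disks carry chip chromaticities, background stays neutral
        assert set(np.round(img.chroma_x[inside], 5)) <= {
            round(c.chromaticity[0], 5) for c in chips}
        outside = ~img.masks["patches"] & ~img.masks["fixation"]
        assert np.all(img.chroma_x[outside] == D65_WHITE[0])

    def test_rendering_is_deterministic(self, small_display):
        a = render_patch_pattern(PatchPatternSpec(), 11, small_display)
        b = render_patch_pattern(PatchPatternSpec(), 11, small_display)
        assert np.array_equal(a.luminance, b.luminance)
        assert np.array_equal(a.chroma_x, b.chroma_x)

    def test_oversized_ring_raises(self, small_display):
        spec = PatchPatternSpec(circle_diameter_deg=40.0)
        with pytest.raises(ValueError, match="screen"):
            render_patch_pattern(spec, 0, small_display)


class TestTexture:
    def test_ellipse_texture_levels_and_range(self, small_display):
        img = render_texture(TextureSpec.fmri_background(), 5, small_display)
        levels = np.unique(img.luminance)
        assert levels.size == 8
        assert levels.min() == pytest.approx(0.23)
        assert levels.max() == pytest.approx(30.24)

    def test_square_mask_is_axis_aligned_tiling(self, small_display):
        img = render_texture(TextureSpec.psycho_mask(), 5, small_display)
        assert np.unique(img.luminance).size == 8
        # every row crossing a tile boundary changes value at the same columns
        ppx = small_display.px_per_deg[0]
        tile_px = 1.5 * ppx
        changes = np.flatnonzero(np.diff(img.luminance[0]) != 0)
        assert np.all(np.diff(changes) % round(tile_px) <= 1)

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError, match="8 luminance levels"):
            TextureSpec(luminance_levels=(1.0, 2.0, 3.0))


class TestScramble:
    def test_full_scramble_preserves_histogram(self, small_display):
        img = render_patch_pattern(PatchPatternSpec(chroma_condition="/6"),
                                   2, small_display)
        scr = scramble(img, 9, mode="full", protect_fixation=False)
        assert np.array_equal(np.sort(img.luminance.ravel()),
                              np.sort(scr.luminance.ravel()))
        assert not np.array_equal(img.luminance, scr.luminance)

    def test_fixation_rectangle_protected(self, small_display):
        img = render_patch_pattern(PatchPatternSpec(), 2, small_display)
        scr = scramble(img, 9, mode="full", protect_fixation=True)
        fix = img.masks["fixation"]
        assert np.array_equal(scr.luminance[fix], img.luminance[fix])

    def test_patches_only_scramble_leaves_black_surround(self, small_display):
        spec = PatchPatternSpec(chroma_condition="/2", background="black")
        img = render_patch_pattern(spec, 2, small_display)
        scr = scramble(img, 9, mode="patches_only")
        outside = ~img.masks["patches"] & ~img.masks["fixation"]
        assert np.all(scr.luminance[outside] == BLACK_LEVEL)
        patches = img.masks["patches"] & ~img.masks["fixation"]
        assert np.array_equal(np.sort(img.luminance[patches]),
                              np.sort(scr.luminance[patches]))


class TestGrating:
    @pytest.mark.parametrize("contrast", [0.34, 0.50, 0.66])
    def test_measured_michelson_matches_nominal(self, contrast):
        # default resolution: discretisation keeps the error under 1%
        img = render_grating(GratingSpec(max_michelson_contrast=contrast,
                                         overlay=None))
        measured = measure_michelson(img, "grating")
        assert measured == pytest.approx(contrast, rel=0.01)

    def test_center_is_a_luminance_trough(self):
        img = render_grating(GratingSpec(), seed=1)
        h, w = img.luminance.shape
        assert img.luminance[h // 2, w // 2] < 19.8

    def test_zero_contrast_gives_uniform_field(self):
        img = render_grating(GratingSpec(max_michelson_contrast=0.0,
                                         overlay=None))
        assert np.allclose(img.luminance, 19.8)

    def test_overlay_patches_at_mean_luminance(self):
        img = render_grating(GratingSpec(), seed=0)
        inside = img.masks["patches"] & (img.luminance > 0)
        assert np.allclose(np.unique(img.luminance[inside]), 19.8)

    def test_out_of_range_contrast_rejected(self):
        with pytest.raises(ValueError):
            GratingSpec(max_michelson_contrast=1.2)


class TestMeasureMichelson:
    def test_uniform_region_is_zero(self, small_display):
        img = render_grating(GratingSpec(max_michelson_contrast=0.0,
                                         overlay=None), geometry=small_display)
        assert measure_michelson(img) == 0.0

    def test_two_level_closed_form(self, small_display):
        img = render_texture(TextureSpec.fmri_background(), 1, small_display)
        img.luminance = np.where(img.luminance > 15, 30.0, 10.0)
        assert measure_michelson(img) == pytest.approx(0.5)

    def test_all_zero_region_raises(self, small_display):
        img = render_texture(TextureSpec.fmri_background(), 1, small_display)
        img.luminance[:] = 0.0
        with pytest.raises(ValueError, match="undefined"):
            measure_michelson(img)


def test_save_load_roundtrip(tmp_path, small_display):
    img = render_patch_pattern(PatchPatternSpec(chroma_condition="/6"),
                               4, small_display)
    save_stimulus(img, tmp_path / "stim")
    back = load_stimulus(tmp_path / "stim")
    # chromaticity is palette-exact; luminance is 16-bit quantised
    assert np.array_equal(back.chroma_x, img.chroma_x)
    assert np.array_equal(back.chroma_y, img.chroma_y)
    assert np.allclose(back.luminance, img.luminance,
                       atol=img.luminance.max() / 65535)
    assert back.provenance["seed"] == 4
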