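"""Phantom generator: determinism, point-process statistics, tiling truth."""

import numpy as np
import pytest

import musemargin as mm
from musemargin.stitch import Placement, blend

from conftest import three_class_spec


class TestGenerateScene:
    def test_deterministic_under_fixed_seed(self):
        spec_a = three_class_spec(seed=5, width=256, height=128)
        spec_b = three_class_spec(seed=5, width=256, height=128)
        scene_a, truth_a = mm.generate_scene(spec_a)
        scene_b, truth_b = mm.generate_scene(spec_b)
        assert np.array_equal(scene_a, scene_b)
        assert np.array_equal(truth_a.nuclear_mask, truth_b.nuclear_mask)
        assert np.array_equal(truth_a.label_map, truth_b.label_map)

    def test_zero_density_yields_empty_mask(self):
        regions = mm.vertical_strip_layout(128, 128, ["stroma"])
        spec = mm.PhantomSpec(
            width_px=128,
            height_px=128,
            regions=regions,
            nuclei_density_per_mm2={c: 0.0 for c in mm.TISSUE_CLASSES},
            seed=0,
        )
        _, truth = mm.generate_scene(spec)
        assert not truth.nuclear_mask.any()

    def test_nucleus_count_matches_poisson_oracle(self):
        # stroma at 500/mm^2 over ~2 mm^2: realized count within 3 SD of the
        # Poisson count implied by density x area
        side = 1120  # 1120 px * 1.2626 um = 1.414 mm -> area ~2.0 mm^2
        regions = mm.vertical_strip_layout(side, side, ["stroma"])
        spec = mm.PhantomSpec(
            width_px=side,
            height_px=side,
            regions=regions,
            nuclei_density_per_mm2={**mm.phantom.DEFAULT_DENSITY_PER_MM2, "stroma": 500.0},
            seed=9,
        )
        _, truth = mm.generate_scene(spec)
        area_mm2 = side * side * spec.mm2_per_px
        lam = 500.0 * area_mm2
        count = truth.nuclear_fraction_per_region[0]["n_nuclei"]
        assert abs(count - lam) <= 3.0 * np.sqrt(lam)

    def test_truth_fraction_is_exact_pixel_ratio(self, small_phantom):
        _, truth = small_phantom
        for frac in truth.nuclear_fraction_per_region:
            region = truth.label_map == mm.LABEL_CODES[frac["tissue_class"]]
            n_nuc = int((truth.nuclear_mask & region).sum())
            assert frac["nuclear_px"] == n_nuc
            assert frac["nuclear_fraction"] == n_nuc / region.sum()

    def test_tumor_fraction_exceeds_stroma_exceeds_adipose(self, small_phantom):
        _, truth = small_phantom
        by_class = {
            f["tissue_class"]: f["nuclear_fraction"]
            for f in truth.nuclear_fraction_per_region
        }
        assert by_class["IDC"] > by_class["stroma"] > by_class["adipose"]

    def test_overlapping_regions_rejected(self):
        m = np.ones((64, 64), dtype=bool)
        regions = [
            mm.Region(tissue_class="stroma", mask=m),
            mm.Region(tissue_class="adipose", mask=m),
        ]
        spec = mm.PhantomSpec(width_px=64, height_px=64, regions=regions, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            mm.generate_scene(spec)

    def test_polygon_outside_bounds_rejected(self):
        poly = np.array([[0, 0], [200, 0], [200, 50], [0, 50]], dtype=float)
        reg = mm.Region(tissue_class="stroma", polygon=poly)
        with pytest.raises(ValueError, match="bounds"):
            reg.rasterize(64, 64)

    def test_tumor_density_must_exceed_stroma(self):
        regions = mm.vertical_strip_layout(64, 64, ["IDC", "stroma"])
        dens = {**mm.phantom.DEFAULT_DENSITY_PER_MM2, "IDC": 100.0}
        with pytest.raises(ValueError, match="density"):
            mm.PhantomSpec(
                width_px=64, height_px=64, regions=regions,
                nuclei_density_per_mm2=dens,
            )


class TestShadingField:
    def test_zero_strength_is_uniform(self):
        f = mm.make_shading_field((41, 61), 0.0)
        assert np.allclose(f.gain, 1.0)

    @pytest.mark.parametrize("strength", [0.1, 0.3, 0.6])
    def test_center_corner_ratio_matches_closed_form(self, strength):
        # profile 1 - s (r/rmax)^2 -> center/corner gain ratio 1/(1-s),
        # independent of the mean-1 normalisation
        f = mm.make_shading_field((101, 101), strength)
        center = f.gain[50, 50]
        corner = f.gain[0, 0]
        assert center / corner == pytest.approx(1.0 / (1.0 - strength), rel=1e-12)

    def test_mean_is_one(self):
        f = mm.make_shading_field((64, 96), 0.3)
        assert abs(f.gain.mean() - 1.0) < 1e-6

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError):
            mm.make_shading_field((32, 32), 1.0)


class TestRenderTiles:
    def test_identity_shading_zero_noise_tiles_equal_crops(self, small_phantom):
        scene, _ = small_phantom
        tiles, manifest = mm.render_tiles(
            scene, tile_w_px=256, tile_h_px=128,
            overlap_x_um=120.0, overlap_y_um=60.0,
        )
        for t, rec in zip(tiles, manifest):
            crop = scene[
                rec["y0_px"] : rec["y0_px"] + 128,
                rec["x0_px"] : rec["x0_px"] + 256,
            ]
            assert np.array_equal(t.image, crop)

    def test_manifest_offsets_are_tile_minus_overlap(self, small_phantom):
        scene, _ = small_phantom
        pitch = mm.phantom.DEFAULT_PIXEL_PITCH_UM
        tiles, manifest = mm.render_tiles(
            scene, tile_w_px=256, tile_h_px=128,
            overlap_x_um=120.0, overlap_y_um=60.0, pixel_pitch_um=pitch,
        )
        step_x = 256 - round(120.0 / pitch)
        step_y = 128 - round(60.0 / pitch)
        for rec in manifest:
            assert rec["x0_px"] == rec["grid_col"] * step_x
            assert rec["y0_px"] == rec["grid_row"] * step_y

    def test_vignette_dims_corners_by_gain_ratio(self):
        flat = np.full((300, 300, 3), 200, dtype=np.uint8)
        shading = mm.make_shading_field((128, 128), 0.3)
        tiles, _ = mm.render_tiles(
            flat, tile_w_px=128, tile_h_px=128,
            overlap_x_um=40.0, overlap_y_um=40.0, shading=shading,
        )
        img = tiles[0].image[:, :, 1].astype(float)
        ratio = img[64, 64] / img[0, 0]
        expected = shading.gain[64, 64] / shading.gain[0, 0]
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_overlap_must_be_smaller_than_tile(self, small_phantom):
        scene, _ = small_phantom
        with pytest.raises(ValueError, match="overlap"):
            mm.render_tiles(
                scene, tile_w_px=64, tile_h_px=64,
                overlap_x_um=100.0, overlap_y_um=10.0,
                pixel_pitch_um=1.0,
            )

    def test_recomposite_at_true_offsets_reproduces_scene(self, small_phantom):
        # tiles cut with identity shading and zero noise, re-blended at the
        # manifest offsets, must reproduce the covered scene bit-exactly
        scene, _ = small_phantom
        tiles, manifest = mm.render_tiles(
            scene, tile_w_px=256, tile_h_px=128,
            overlap_x_um=120.0, overlap_y_um=60.0,
        )
        placement = Placement(
            offsets_px=[(float(r["x0_px"]), float(r["y0_px"])) for r in manifest]
        )
        mosaic = blend(tiles, placement)
        h, w = mosaic.shape[:2]
        assert np.array_equal(mosaic, scene[:h, :w])
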