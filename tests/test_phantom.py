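import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from pals import phantom
from pals.core_io import ABLATED, NON_ABLATED, UNLABELED, ValidationError, make_grid
from tests.conftest import tiny_config


class TestConfig:
    def test_ratio_peak_must_lie_in_window(self):
        grid = make_grid(690, 950, 65)
        bad = np.ones(5)
        bad[-1] = 10.0  # ratio peak at 950 nm
        with pytest.raises(ValidationError, match="ratio peaks"):
            tiny_config(mu_abs_ablated=bad * phantom.nonablated_spectrum(grid))

    def test_default_spectra_ratio_peaks_near_780(self):
        grid = make_grid(690, 950, 5)
        ratio = phantom.ablated_spectrum(grid) / phantom.nonablated_spectrum(grid)
        peak = grid.to_array()[np.argmax(ratio)]
        assert 720 <= peak <= 790

    def test_spectra_strictly_positive(self):
        grid = make_grid(690, 950, 5)
        assert np.all(phantom.nonablated_spectrum(grid) > 0)
        assert np.all(phantom.ablated_spectrum(grid) > 0)

    def test_default_fluence_matches_reported_extremes(self):
        grid = make_grid(690, 950, 5)
        fluence = phantom.default_fluence(grid)
        assert fluence.energy_mJ.max() == pytest.approx(14.74, abs=0.01)
        assert fluence.energy_mJ.min() == pytest.approx(7.93, abs=0.7)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            tiny_config(noise_sigma=-1.0)


class TestBuildScene:
    def test_no_lesions(self, config):
        scene = phantom.build_scene(config, 0)
        assert not np.any(scene.tissue_map >= phantom.LESION_BASE)

    def test_three_lesions_at_configured_offsets(self, config):
        scene = phantom.build_scene(config, 3)
        centers = sorted(c for _, c, _, _ in scene.lesions)
        mid = config.width_px / 2.0
        offsets_px = [
            round(mid + o / config.pitch_mm) for o in sorted(config.lesion_offsets_mm)
        ]
        assert centers == offsets_px

    def test_first_lesion_is_left_of_centerline(self, config):
        scene = phantom.build_scene(config, 1)
        assert scene.lesions[0][1] < config.width_px / 2.0

    def test_overlapping_lesions_merge(self):
        cfg = tiny_config(lesion_offsets_mm=(-1.0, 0.0, 1.0), boundary_band_px=0)
        scene = phantom.build_scene(cfg, 3)
        mask = phantom.make_mask(cfg, scene)
        _, n_components = ndimage.label(mask.codes == ABLATED)
        assert n_components < 3  # overlapping ellipses merge

    def test_lesion_exceeding_frame_rejected(self):
        cfg = tiny_config(lesion_axes_mm=(30.0, 1.8))
        with pytest.raises(ValidationError, match="exceeds frame"):
            phantom.build_scene(cfg, 1)

    def test_water_above_tissue(self, config):
        scene = phantom.build_scene(config, 0)
        assert np.all(scene.tissue_map[0] == phantom.WATER)
        assert np.all(scene.tissue_map[-1] != phantom.WATER)


class TestRenderMWPA:
    def test_unit_factor_render_reproduces_absorption(self, clean_config):
        """With E=1, Gamma=1, mu_eff=0, F=1, no noise/jitter the pixel
        spectrum equals its tissue-class absorption spectrum exactly."""
        cfg = dataclasses.replace(
            clean_config,
            fluence=dataclasses.replace(
                clean_config.fluence, energy_mJ=np.ones(5)
            ),
        )
        scene = phantom.build_scene(cfg, 1)
        cube = phantom.render_mwpa(cfg, scene)
        tissue = scene.tissue_map == phantom.TISSUE
        np.testing.assert_allclose(
            cube.intensities[tissue],
            np.broadcast_to(
                cfg.mu_abs_nonablated, (tissue.sum(), 5)
            ).astype(np.float32),
            rtol=1e-6,
        )
        lesion = scene.tissue_map >= phantom.LESION_BASE
        np.testing.assert_allclose(
            cube.intensities[lesion],
            np.broadcast_to(cfg.mu_abs_ablated, (lesion.sum(), 5)).astype(np.float32),
            rtol=1e-6,
        )

    def test_doubling_fluence_at_one_channel_doubles_that_channel(self, clean_config):
        scene = phantom.build_scene(clean_config, 1)
        cube1 = phantom.render_mwpa(clean_config, scene)
        doubled = clean_config.fluence.energy_mJ.copy()
        doubled[2] *= 2
        cfg2 = dataclasses.replace(
            clean_config,
            fluence=dataclasses.replace(clean_config.fluence, energy_mJ=doubled),
        )
        cube2 = phantom.render_mwpa(cfg2, scene)
        np.testing.assert_allclose(
            cube2.intensities[:, :, 2], 2 * cube1.intensities[:, :, 2], rtol=1e-6
        )
        for ch in (0, 1, 3, 4):
            np.testing.assert_array_equal(
                cube2.intensities[:, :, ch], cube1.intensities[:, :, ch]
            )

    def test_fluence_division_matches_unit_fluence_render(self, clean_config):
        """Oracle: independently evaluate the forward model both ways."""
        scene = phantom.build_scene(clean_config, 2)
        cube = phantom.render_mwpa(clean_config, scene)
        divided = cube.intensities / clean_config.fluence.energy_mJ.astype(
            np.float32
        )
        cfg_unit = dataclasses.replace(
            clean_config,
            fluence=dataclasses.replace(clean_config.fluence, energy_mJ=np.ones(5)),
        )
        reference = phantom.render_mwpa(cfg_unit, scene)
        np.testing.assert_allclose(divided, reference.intensities, rtol=1e-5)

    def test_depth_monotonicity(self):
        cfg = tiny_config(
            noise_sigma=0.0,
            spectrum_jitter_cv=0.0,
            sensitivity_amplitude=0.0,
            mu_eff=np.full(5, 2.0),
        )
        scene = phantom.build_scene(cfg, 0)
        cube = phantom.render_mwpa(cfg, scene)
        col = cube.intensities[scene.surface_row :, 5, 0]
        assert np.all(np.diff(col) < 0)

    def test_deterministic_given_seed(self, config):
        scene = phantom.build_scene(config, 1)
        c1 = phantom.render_mwpa(config, scene)
        c2 = phantom.render_mwpa(config, scene)
        np.testing.assert_array_equal(c1.intensities, c2.intensities)

    def test_state_is_raw_and_nonnegative(self, config):
        scene = phantom.build_scene(config, 1)
        cube = phantom.render_mwpa(config, scene)
        assert cube.state == "raw"
        assert np.all(cube.intensities >= 0)


class TestRenderUS:
    def test_tissue_brighter_than_water(self, config):
        scene = phantom.build_scene(config, 0)
        us = phantom.render_us(config, scene)
        water = us.intensities[scene.tissue_map == phantom.WATER]
        tissue = us.intensities[scene.tissue_map != phantom.WATER]
        assert water.mean() < tissue.mean()

    def test_deterministic(self, config):
        scene = phantom.build_scene(config, 0)
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        np.testing.assert_array_equal(
            phantom.render_us(config, scene, rng1).intensities,
            phantom.render_us(config, scene, rng2).intensities,
        )

    def test_shape_matches_scene(self, config):
        scene = phantom.build_scene(config, 0)
        us = phantom.render_us(config, scene)
        assert us.intensities.shape == scene.tissue_map.shape


class TestMakeMask:
    def test_no_lesions_no_ablated(self, config):
        scene = phantom.build_scene(config, 0)
        mask = phantom.make_mask(config, scene)
        assert mask.count(ABLATED) == 0

    def test_zero_band_covers_whole_tissue(self):
        cfg = tiny_config(boundary_band_px=0)
        scene = phantom.build_scene(cfg, 2)
        mask = phantom.make_mask(cfg, scene)
        tissue = scene.tissue_map != phantom.WATER
        labeled = mask.codes != UNLABELED
        np.testing.assert_array_equal(labeled, tissue)

    def test_axial_band_wider_than_lateral(self, config):
        """The unlabeled gap is thicker axially than laterally."""
        scene = phantom.build_scene(config, 1)
        mask = phantom.make_mask(config, scene)
        rc, cc, _, _ = scene.lesions[0]
        col = mask.codes[:, cc]
        row = mask.codes[rc, :]
        axial_band = np.count_nonzero(col == UNLABELED) - np.count_nonzero(
            scene.tissue_map[:, cc] == phantom.WATER
        )
        lateral_band = np.count_nonzero(row == UNLABELED)
        assert axial_band > lateral_band

    def test_partition_disjoint_exhaustive(self, config):
        scene = phantom.build_scene(config, 3)
        mask = phantom.make_mask(config, scene)
        total = mask.count(ABLATED) + mask.count(NON_ABLATED) + mask.count(UNLABELED)
        assert total == config.height_px * config.width_px

    def test_water_unlabeled(self, config):
        scene = phantom.build_scene(config, 1)
        mask = phantom.make_mask(config, scene)
        assert np.all(mask.codes[scene.tissue_map == phantom.WATER] == UNLABELED)


class TestMakeStudy:
    def test_19_blocks_4_frames_yields_76(self):
        cfg = tiny_config(height_px=16, width_px=24, pixel_pitch_um=1576.96)
        frames = phantom.make_study(cfg, 19, 4)
        assert len(frames) == 76

    def test_lesion_schedule_0_to_3(self, config):
        frames = phantom.make_study(config, 1, 4)
        assert [f.n_lesions for f in frames] == [0, 1, 2, 3]

    def test_determinism(self, config):
        f1 = phantom.make_study(config, 2, 1)
        f2 = phantom.make_study(config, 2, 1)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.cube.intensities, b.cube.intensities)
            np.testing.assert_array_equal(a.mask.codes, b.mask.codes)

    def test_n_lesions_matches_connected_components(self, config):
        for f in phantom.make_study(config, 2, 4):
            _, n = ndimage.label(f.mask.codes == ABLATED)
            assert n == f.n_lesions

    def test_block_ids_distinct(self, config):
        frames = phantom.make_study(config, 3, 2)
        assert len({f.block_id for f in frames}) == 3

    def test_blocks_differ(self, config):
        frames = phantom.make_study(config, 2, 1)
        assert not np.array_equal(
            frames[0].cube.intensities, frames[1].cube.intensities
        )


class TestSideLobes:
    def test_sidelobes_present_and_outside_lesion(self):
        cfg = tiny_config(side_lobes=True)
        scene = phantom.build_scene(cfg, 1)
        assert scene.sidelobe_map.any()
        assert not np.any(scene.sidelobe_map & (scene.tissue_map >= phantom.LESION_BASE))

    def test_sidelobe_spectrum_is_blend(self):
        cfg = tiny_config(
            side_lobes=True, spectrum_jitter_cv=0.0, sidelobe_blend=0.75
        )
        scene = phantom.build_scene(cfg, 1)
        expected = 0.75 * cfg.mu_abs_ablated + 0.25 * cfg.mu_abs_nonablated
        got = scene.mu_abs_field[scene.sidelobe_map][0]
        np.testing.assert_allclose(got, expected.astype(np.float32), rtol=1e-6)
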