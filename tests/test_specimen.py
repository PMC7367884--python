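"""Medium segmentation/removal and stack alignment."""

import numpy as np
import pytest

from cryostack import (
    PhantomSpec,
    RasterVolume,
    align_stack,
    estimate_medium_color,
    estimate_shift,
    make_phantom,
    remove_medium,
    specimen_mask,
)

MEDIUM = (200, 200, 210)


def disc_volume(noise_sigma=0.0, seed=5, radius_um=80.0, canvas=(96, 96)):
    spec = PhantomSpec(shape="sphere", shape_params={"radius_um": radius_um},
                       canvas=canvas, medium_color=MEDIUM,
                       noise_sigma=noise_sigma, seed=seed)
    return make_phantom(spec)


def textured_slab(seed, jitter_px=0, noise_sigma=0.0, canvas=(96, 96)):
    spec = PhantomSpec(
        shape="slab",
        shape_params={"thickness_um": 232.0, "y_outer_um": 200.0},
        canvas=canvas, n_layers=6, medium_color=MEDIUM,
        jitter_px=jitter_px, noise_sigma=noise_sigma,
        texture_amplitude=60, texture_scale_px=2, seed=seed,
    )
    return make_phantom(spec)


class TestMediumColor:
    def test_uniform_medium_recovered_exactly(self):
        vol, _ = disc_volume()
        assert estimate_medium_color(vol) == MEDIUM

    def test_noisy_medium_within_two_levels(self):
        vol, _ = disc_volume(noise_sigma=3.0)
        got = estimate_medium_color(vol)
        assert all(abs(g - m) <= 2 for g, m in zip(got, MEDIUM))

    def test_specimen_touching_one_corner_tolerated(self):
        vol, _ = disc_volume()
        stack = vol.as_array().copy()
        stack[:, :12, :12] = (10, 10, 10)  # specimen occupies a corner
        vol2 = RasterVolume.from_array(stack, vol.step_um, vol.pitch_um)
        assert estimate_medium_color(vol2) == MEDIUM


class TestSpecimenMask:
    def test_disc_area_within_perimeter_bound(self):
        vol, truth = disc_volume()
        sm = specimen_mask(vol, medium_color=MEDIUM, threshold=30)
        k0 = int(np.argmax(truth.masks.sum(axis=(1, 2))))
        r_px = truth.params["radius_um"] / vol.pitch_um
        area = sm.masks[k0].sum()
        assert abs(area - np.pi * r_px**2) <= 2 * np.pi * r_px

    def test_pure_medium_layer_is_empty(self):
        vol, truth = disc_volume()
        sm = specimen_mask(vol, medium_color=MEDIUM, threshold=30)
        assert not sm.masks[0].any()  # margin layer holds no specimen

    def test_zero_threshold_selects_all_non_medium_pixels(self):
        vol, truth = disc_volume()
        sm = specimen_mask(vol, medium_color=MEDIUM, threshold=0)
        np.testing.assert_array_equal(sm.masks, truth.masks)

    def test_cleanup_removes_speckle(self):
        vol, truth = disc_volume()
        stack = vol.as_array().copy()
        stack[2, 2, 2] = (0, 0, 0)  # isolated non-medium pixel
        vol2 = RasterVolume.from_array(stack, vol.step_um, vol.pitch_um)
        raw = specimen_mask(vol2, MEDIUM, 30)
        cleaned = specimen_mask(vol2, MEDIUM, 30, min_area=4)
        assert raw.masks[2, 2, 2] and not cleaned.masks[2, 2, 2]
        largest = specimen_mask(vol2, MEDIUM, 30, keep_largest=True)
        assert not largest.masks[2, 2, 2]

    def test_negative_threshold_rejected(self):
        vol, _ = disc_volume()
        with pytest.raises(ValueError, match="threshold"):
            specimen_mask(vol, MEDIUM, threshold=-1)


class TestRemoveMedium:
    def test_all_true_mask_is_identity(self):
        vol, _ = disc_volume()
        masks = np.ones((vol.n_layers, *vol.layer_shape), dtype=bool)
        out = remove_medium(vol, masks, fill_color=(0, 0, 0))
        assert out == RasterVolume.from_array(vol.as_array(), vol.step_um,
                                              vol.pitch_um, vol.fill_color)

    def test_all_false_mask_gives_uniform_fill(self):
        vol, _ = disc_volume()
        masks = np.zeros((vol.n_layers, *vol.layer_shape), dtype=bool)
        out = remove_medium(vol, masks, fill_color=(9, 9, 9))
        assert np.all(out.as_array() == (9, 9, 9))

    def test_only_medium_pixels_altered(self):
        vol, truth = disc_volume()
        sm = specimen_mask(vol, MEDIUM, threshold=0)
        out = remove_medium(vol, sm, fill_color=(0, 0, 0))
        src = vol.as_array()
        res = out.as_array()
        np.testing.assert_array_equal(res[truth.masks], src[truth.masks])
        assert np.all(res[~truth.masks] == (0, 0, 0))

    def test_dimension_mismatch_rejected(self):
        vol, _ = disc_volume()
        with pytest.raises(ValueError, match="mask shape"):
            remove_medium(vol, np.ones((2, 3, 3), dtype=bool))

    def test_masking_is_idempotent_after_removal(self):
        vol, _ = disc_volume()
        sm = specimen_mask(vol, MEDIUM, threshold=30)
        cleaned = remove_medium(vol, sm)  # default fill = medium color
        again = specimen_mask(cleaned, MEDIUM, threshold=30)
        np.testing.assert_array_equal(again.masks, sm.masks)


class TestEstimateShift:
    def test_identical_images_give_zero(self):
        vol, _ = textured_slab(seed=1)
        img = vol.layer(2)
        assert estimate_shift(img, img) == (0.0, 0.0)

    def test_known_injected_shift_recovered(self):
        vol, _ = textured_slab(seed=2)
        ref = vol.layer(2)
        from cryostack.specimen import _shift_image

        moving = _shift_image(ref, 3, -2, np.asarray(MEDIUM, np.uint8))
        assert estimate_shift(ref, moving) == (3.0, -2.0)

    def test_shift_recovered_under_noise(self, rng):
        vol, _ = textured_slab(seed=3, noise_sigma=5.0)
        from cryostack.specimen import _shift_image

        ref = vol.layer(2)
        moving = _shift_image(vol.layer(3), 3, -2, np.asarray(MEDIUM, np.uint8))
        assert estimate_shift(ref, moving) == (3.0, -2.0)

    def test_constant_images_warn_and_return_zero(self):
        flat = np.full((16, 16, 3), 100, np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_shift(flat, flat) == (0.0, 0.0)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            estimate_shift(np.zeros((4, 4)), np.zeros((4, 5)))


class TestAlignStack:
    def test_jitter_free_stack_is_noop(self):
        vol, _ = textured_slab(seed=4)
        aligned, log = align_stack(vol, max_shift_px=4)
        assert log.shifts == [(0.0, 0.0)] * vol.n_layers
        np.testing.assert_array_equal(aligned.as_array(), vol.as_array())

    def test_injected_jitter_recovered_exactly(self):
        vol, truth = textured_slab(seed=6, jitter_px=2)
        aligned, log = align_stack(vol, max_shift_px=4)
        applied = np.asarray(log.shifts)
        np.testing.assert_array_equal(applied, -truth.shifts_px)
        # aligned content matches the jitter-free reference away from borders
        ref, _ = textured_slab(seed=6, jitter_px=0)
        j = 2
        np.testing.assert_array_equal(
            aligned.as_array()[:, j:-j, j:-j], ref.as_array()[:, j:-j, j:-j])

    def test_shift_recovery_over_seeds(self):
        # integer jitter in [-3, 3]^2 at noise sigma=5 recovered exactly
        for seed in range(8):
            vol, truth = textured_slab(seed=100 + seed, jitter_px=3,
                                       noise_sigma=5.0)
            _, log = align_stack(vol, max_shift_px=6)
            np.testing.assert_array_equal(np.asarray(log.shifts),
                                          -truth.shifts_px)

    def test_large_jitter_clamped_with_warning(self):
        vol, truth = textured_slab(seed=7, jitter_px=3)
        assert np.abs(truth.shifts_px).max() > 1
        with pytest.warns(UserWarning, match="clamped"):
            _, log = align_stack(vol, max_shift_px=1)
        assert any(log.clamped)
        assert np.abs(np.asarray(log.shifts)).max() <= 1

    def test_single_layer_rejected(self):
        vol = RasterVolume.from_array(np.zeros((1, 8, 8, 3), np.uint8), 10, 8)
        with pytest.raises(ValueError, match="2 layers"):
            align_stack(vol)


def test_shift_log_csv_round_trip(tmp_path):
    vol, _ = textured_slab(seed=8, jitter_px=2)
    _, log = align_stack(vol, max_shift_px=4)
    path = log.to_csv(tmp_path / "shifts.csv")
    rows = path.read_text().strip().splitlines()
    assert rows[0] == "k,dx_px,dy_px,clamped"
    assert len(rows) == vol.n_layers + 1
    assert rows[1].startswith("1,0.0,0.0")
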