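"""Degradation, normalization, patch extraction, augmentation, tiling."""

import numpy as np
import pytest

from carn.data import (NormStats, PatchPair, apply_normalization,
                       augment_rot90, bicubic_resize, compute_norm_stats,
                       extract_training_patch, invert_normalization,
                       load_image, lr_patch_size, make_pair, save_image,
                       tile_image)


def smooth_image(size=64):
    x = np.linspace(0, 1, size)
    g = 0.5 + 0.25 * np.outer(np.sin(2 * np.pi * x), np.cos(2 * np.pi * x))
    return np.stack([g, g * 0.8 + 0.1, 1 - g], axis=2)


# ------------------------------------------------------------------ bicubic

def test_bicubic_preserves_constants():
    img = np.full((32, 32, 3), 0.37)
    for factor in (0.5, 2, 4):
        out = bicubic_resize(img, factor)
        np.testing.assert_allclose(out, 0.37, atol=1e-6)


def test_bicubic_shapes_and_validation():
    img = np.zeros((64, 64, 3))
    assert bicubic_resize(img, 0.5).shape == (32, 32, 3)
    assert bicubic_resize(img, 3).shape == (192, 192, 3)
    with pytest.raises(ValueError, match="non-integer"):
        bicubic_resize(np.zeros((5, 5, 3)), 0.5)
    with pytest.raises(ValueError):
        bicubic_resize(img, -1)


def test_bicubic_down_up_error_small_on_smooth_gradient():
    img = smooth_image(64)
    rec = bicubic_resize(bicubic_resize(img, 0.5), 2)
    assert np.abs(rec - img).max() <= 0.02


def test_bicubic_output_stays_in_unit_range(rng):
    # sharp edges cause cubic overshoot; outputs must be clipped
    img = (rng.random((32, 32, 3)) > 0.5).astype(float)
    out = bicubic_resize(img, 2)
    assert out.min() >= 0.0 and out.max() <= 1.0


# ------------------------------------------------------------- normalization

def test_norm_stats_of_uniform_image():
    img = np.full((16, 16, 3), 0.5)
    stats = compute_norm_stats([img])
    assert (stats.mean_r, stats.mean_g, stats.mean_b) == (0.5, 0.5, 0.5)
    np.testing.assert_array_equal(apply_normalization(img, stats), 0.0)


def test_norm_stats_empty_manifest_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        compute_norm_stats([])


def test_reference_default_means_are_the_training_set_values():
    from carn.model import DEFAULT_RGB_MEANS
    assert DEFAULT_RGB_MEANS == (0.7204, 0.4298, 0.6397)


def test_normalization_round_trip_is_bit_exact_on_png_grid(tmp_path, rng):
    save_image(tmp_path / "img.png", rng.random((32, 32, 3)))
    img = load_image(tmp_path / "img.png")
    stats = NormStats(0.7204, 0.4298, 0.6397)
    back = invert_normalization(apply_normalization(img, stats), stats)
    assert np.array_equal(back, img)


def test_dataset_means_vanish_after_normalization(fixture_dir):
    directory, rows = fixture_dir
    images = [load_image(directory / r["path"]) for r in rows]
    stats = compute_norm_stats(images)
    normalized = np.concatenate(
        [apply_normalization(im, stats).reshape(-1, 3) for im in images]
    )
    assert np.abs(normalized.mean(axis=0)).max() < 1e-6


# ----------------------------------------------------------------- PNG round trip

def test_png_round_trip_is_exact_on_8bit_grid(tmp_path, rng):
    img = rng.integers(0, 256, size=(16, 16, 3)) / 255.0
    save_image(tmp_path / "x.png", img)
    np.testing.assert_array_equal(load_image(tmp_path / "x.png"), img)


# ------------------------------------------------------------------- pairs

def test_pair_alignment_whole_image(rng):
    hr = smooth_image(64)
    pair = make_pair(hr, 2)
    assert pair.lr.shape == (32, 32, 3)
    # lr is by construction the bicubic degradation of hr
    np.testing.assert_allclose(pair.lr, bicubic_resize(hr, 0.5), atol=1e-6)
    with pytest.raises(ValueError):
        PatchPair(lr=pair.lr, hr=hr[:-2], scale=2)


@pytest.mark.parametrize("scale,expected_lr,expected_hr",
                         [(2, 64, 128), (3, 48, 144), (4, 64, 256)])
def test_training_patch_sizes_per_scale(rng, scale, expected_lr, expected_hr):
    assert lr_patch_size(scale) == expected_lr
    pair = make_pair(smooth_image(expected_hr * 2), scale)
    crop = extract_training_patch(pair, rng)
    assert crop.lr.shape == (expected_lr, expected_lr, 3)
    assert crop.hr.shape == (expected_hr, expected_hr, 3)


def test_patch_extraction_is_seeded_and_aligned(rng):
    hr = rng.random((128, 128, 3))  # unique pixels make crops locatable
    pair = make_pair(hr, 2)
    a = extract_training_patch(pair, np.random.default_rng(99), patch_size=32)
    b = extract_training_patch(pair, np.random.default_rng(99), patch_size=32)
    np.testing.assert_array_equal(a.lr, b.lr)
    np.testing.assert_array_equal(a.hr, b.hr)
    # locate the LR crop in the parent by exact match, then check the HR
    # window sits at exactly scale x the LR coordinates
    matches = [
        (y, x)
        for y in range(33)
        for x in range(33)
        if np.array_equal(pair.lr[y:y + 32, x:x + 32], a.lr)
    ]
    assert len(matches) == 1
    y, x = matches[0]
    np.testing.assert_array_equal(pair.hr[2 * y:2 * y + 64, 2 * x:2 * x + 64], a.hr)


def test_patch_extraction_rejects_small_images(rng):
    pair = make_pair(smooth_image(64), 2)  # lr is 32x32
    with pytest.raises(ValueError, match="smaller"):
        extract_training_patch(pair, rng, patch_size=48)


# -------------------------------------------------------------- augmentation

def test_rot90_applies_same_rotation_to_both_members(rng):
    pair = make_pair(smooth_image(64), 2)
    for _ in range(8):
        rot = augment_rot90(pair, rng)
        # undo by rotating further: some k in 0..3 restores both at once
        restored = False
        for k in range(4):
            if np.array_equal(np.rot90(rot.lr, k), pair.lr):
                restored = np.array_equal(np.rot90(rot.hr, k), pair.hr)
                break
        assert restored


def test_rot90_matches_index_permutation_oracle():
    pair = make_pair(smooth_image(64), 2)

    class FixedRng:
        def integers(self, lo, hi):
            return 1

    rot = augment_rot90(pair, FixedRng())
    h, w = pair.lr.shape[:2]
    # a single 90-degree rotation is the coordinate permutation
    # out[i, j] = in[j, W-1-i]
    for i in (0, 3, h - 1):
        for j in (0, 5, w - 1):
            np.testing.assert_array_equal(rot.lr[i, j], pair.lr[j, w - 1 - i])


def test_four_rotations_are_identity():
    pair = make_pair(smooth_image(64), 2)

    class FixedRng:
        def integers(self, lo, hi):
            return 1

    out = pair
    for _ in range(4):
        out = augment_rot90(out, FixedRng())
    np.testing.assert_array_equal(out.lr, pair.lr)
    np.testing.assert_array_equal(out.hr, pair.hr)


# ------------------------------------------------------------------- tiling

def test_tiling_1024_into_64_tiles_and_reassembly():
    rng = np.random.default_rng(3)
    img = rng.random((1024, 1024, 3))
    tiles = tile_image(img, 128)
    assert len(tiles) == 64
    rows = [np.concatenate(tiles[i * 8:(i + 1) * 8], axis=1) for i in range(8)]
    np.testing.assert_array_equal(np.concatenate(rows, axis=0), img)


def test_tiling_identity_and_validation():
    img = np.zeros((128, 128, 3))
    tiles = tile_image(img, 128)
    assert len(tiles) == 1
    np.testing.assert_array_equal(tiles[0], img)
    with pytest.raises(ValueError, match="divisible"):
        tile_image(np.zeros((100, 128, 3)), 128)
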