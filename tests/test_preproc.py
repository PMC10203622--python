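"""Padding/cropping conventions, augmentations and dataset layouts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselseg import (
    AugmentSpec,
    DataLayoutError,
    DimensionError,
    FundusSample,
    PadSpec,
    augment,
    crop_back,
    load_dataset,
    pad_to,
    save_dataset,
    split_dataset,
    SyntheticSpec,
    generate_dataset,
    generate_sample,
)
from vesselseg.preproc import _rotate_sample

RNG = np.random.default_rng(0)


@pytest.mark.parametrize(
    "original,expected",
    [((584, 565), (592, 592)), ((999, 960), (1008, 1008))],
)
def test_default_pad_targets_for_fundus_resolutions(original, expected):
    pad = PadSpec.square16(original)
    assert (pad.target_height, pad.target_width) == expected
    arr = RNG.random(original)
    padded = pad_to(arr, pad)
    assert padded.shape == expected


def test_padding_is_zero_and_centred():
    pad = PadSpec.square16((584, 565))
    arr = RNG.random((584, 565)) + 1.0  # strictly positive content
    padded = pad_to(arr, pad)
    top, left = pad.offsets
    assert top == (592 - 584) // 2 and left == (592 - 565) // 2
    content = padded[top : top + 584, left : left + 565]
    assert np.array_equal(content, arr)
    outside = padded.sum() - content.sum()
    assert outside == 0.0


def test_pad_identity_when_already_at_target():
    arr = RNG.random((64, 64))
    pad = PadSpec.centered((64, 64), (64, 64))
    assert np.array_equal(pad_to(arr, pad), arr)


def test_pad_rejects_oversized_input():
    with pytest.raises(DimensionError):
        PadSpec.centered((100, 100), (64, 64))
    pad = PadSpec.centered((32, 32), (64, 64))
    with pytest.raises(DimensionError):
        pad_to(RNG.random((64, 64)), pad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    oh=st.integers(1, 40),
    ow=st.integers(1, 40),
    extra_h=st.integers(0, 17),
    extra_w=st.integers(0, 17),
    data=st.data(),
)
def test_pad_crop_roundtrip_is_exact(oh, ow, extra_h, extra_w, data):
    top = data.draw(st.integers(0, extra_h))
    left = data.draw(st.integers(0, extra_w))
    pad = PadSpec(oh + extra_h, ow + extra_w, oh, ow, (top, left))
    arr = np.random.default_rng(oh * 41 + ow).random((oh, ow, 3))
    assert np.array_equal(crop_back(pad_to(arr, pad), pad), arr)


def test_crop_back_of_zeros_is_zeros():
    pad = PadSpec.square16((584, 565))
    out = crop_back(np.zeros((592, 592)), pad)
    assert out.shape == (584, 565) and out.sum() == 0


def test_identity_augmentation(sample):
    spec = AugmentSpec(
        hflip_prob=0.0, vflip_prob=0.0, rotation_range=0.0,
        jitter_brightness=0.0, jitter_contrast=0.0, jitter_saturation=0.0,
    )
    out = augment(sample, spec)
    np.testing.assert_allclose(out.image, sample.image, atol=1e-6)
    assert np.array_equal(out.mask, sample.mask)


def test_forced_hflip_mirrors_image_and_mask(sample):
    spec = AugmentSpec(
        hflip_prob=1.0, vflip_prob=0.0, rotation_range=0.0,
        jitter_brightness=0.0, jitter_contrast=0.0, jitter_saturation=0.0,
    )
    out = augment(sample, spec)
    assert np.array_equal(out.mask, sample.mask[:, ::-1])
    np.testing.assert_allclose(out.image, sample.image[:, ::-1], atol=1e-6)
    # flipping twice is the identity and preserves vessel count
    again = augment(out, spec)
    assert np.array_equal(again.mask, sample.mask)
    assert out.mask.sum() == sample.mask.sum()


def test_rotation_by_90_maps_vertical_line_to_horizontal():
    mask = np.zeros((33, 33), dtype=np.uint8)
    mask[:, 16] = 1
    image = np.repeat(mask[:, :, None] * 0.5, 3, axis=2).astype(np.float32)
    _, rotated, _ = _rotate_sample(image, mask, None, 90.0)
    expected = np.zeros_like(mask)
    expected[16, :] = 1
    assert np.array_equal(rotated, expected)


def test_augmented_mask_stays_binary_under_arbitrary_rotation(sample):
    spec = AugmentSpec(rotation_range=180.0, seed=5)
    out = augment(sample, spec)
    assert set(np.unique(out.mask)) <= {0, 1}
    assert out.image.min() >= 0.0 and out.image.max() <= 1.0


def test_jitter_changes_image_not_mask(sample):
    spec = AugmentSpec(hflip_prob=0.0, vflip_prob=0.0, rotation_range=0.0, seed=2)
    out = augment(sample, spec)
    assert np.array_equal(out.mask, sample.mask)
    assert not np.allclose(out.image, sample.image)


def test_flat_layout_loads_in_lexicographic_order(tmp_path):
    spec = SyntheticSpec(seed=9)
    tr, _ = generate_dataset(spec, 5, 0)
    save_dataset(tr, tmp_path)
    loaded1 = load_dataset(tmp_path, layout="flat")
    loaded2 = load_dataset(tmp_path, layout="flat")
    assert len(loaded1) == 5
    for a, b in zip(loaded1, loaded2):
        assert np.array_equal(a.mask, b.mask)
        assert set(np.unique(a.mask)) <= {0, 1}


def test_missing_mask_raises_with_stem(tmp_path):
    s = generate_sample(SyntheticSpec(seed=1))
    save_dataset([s], tmp_path)
    (tmp_path / "mask_000.png").unlink()
    with pytest.raises(DataLayoutError, match="000"):
        load_dataset(tmp_path, layout="flat")


def _write_chase_like(root, n):
    import imageio.v3 as iio

    root.mkdir(exist_ok=True)
    for i in range(n):
        img = (np.random.default_rng(i).random((16, 16, 3)) * 255).astype(np.uint8)
        mask = (np.random.default_rng(100 + i).random((16, 16)) > 0.8).astype(np.uint8) * 255
        iio.imwrite(root / f"Image_{i:02d}.jpg", img)
        iio.imwrite(root / f"Image_{i:02d}_1stHO.png", mask)


def test_chase_layout_split_20_8(tmp_path):
    _write_chase_like(tmp_path, 28)
    samples = load_dataset(tmp_path, layout="chase")
    assert len(samples) == 28
    train, test = split_dataset(samples, "chase")
    assert (len(train), len(test)) == (20, 8)


def test_drive_layout_split_20_20(tmp_path):
    import imageio.v3 as iio

    for sub in ("training", "test"):
        for d in ("images", "1st_manual", "mask"):
            (tmp_path / sub / d).mkdir(parents=True)
    k = 0
    for sub in ("training", "test"):
        for i in range(20):
            stem = f"{k:02d}"
            img = (np.random.default_rng(k).random((16, 16, 3)) * 255).astype(np.uint8)
            mask = (np.random.default_rng(50 + k).random((16, 16)) > 0.8).astype(np.uint8) * 255
            iio.imwrite(tmp_path / sub / "images" / f"{stem}_training.png", img)
            iio.imwrite(tmp_path / sub / "1st_manual" / f"{stem}_manual1.png", mask)
            iio.imwrite(tmp_path / sub / "mask" / f"{stem}_mask.png", np.full((16, 16), 255, np.uint8))
            k += 1
    samples = load_dataset(tmp_path, layout="drive")
    assert len(samples) == 40
    train, test = split_dataset(samples, "drive")
    assert (len(train), len(test)) == (20, 20)
    assert all(s.fov is not None for s in samples)
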