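"""Label schema, mask serialization, split arithmetic and augmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image

from mvdnet import (
    AugmentationConfig,
    LabelSchema,
    SceneSample,
    augment,
    read_mask,
    split_manifest,
    write_mask,
)
from mvdnet.errors import InvalidInputError, SchemaError

SCHEMA = LabelSchema.default()


def test_schema_has_ten_distinct_classes():
    assert len(SCHEMA) == 10
    assert SCHEMA.abbreviations == [
        "background", "cn5", "cn7", "cn9", "cn10",
        "aica", "pica", "aica+cn7", "pica+cn7", "pv",
    ]
    assert len({e[3] for e in SCHEMA.entries}) == 10


def test_schema_yaml_roundtrip(tmp_path):
    path = tmp_path / "classes.yaml"
    SCHEMA.to_yaml(path)
    assert LabelSchema.from_yaml(path) == SCHEMA


def test_mask_roundtrip_is_identity(tmp_path):
    rng = np.random.default_rng(0)
    mask = rng.integers(0, 10, size=(64, 64))
    path = tmp_path / "m.png"
    write_mask(mask, SCHEMA, path)
    np.testing.assert_array_equal(read_mask(path, SCHEMA), mask)


def test_out_of_schema_mask_value_rejected(tmp_path):
    mask = np.full((8, 8), 11)
    with pytest.raises(SchemaError, match="11"):
        write_mask(mask, SCHEMA, tmp_path / "bad.png")


def test_rgb_mask_decoding_and_unknown_color(tmp_path):
    mask = np.random.default_rng(1).integers(0, 10, size=(16, 16))
    rgb = SCHEMA.colorize(mask)
    path = tmp_path / "rgb.png"
    Image.fromarray(rgb).save(path)
    np.testing.assert_array_equal(read_mask(path, SCHEMA), mask)
    rgb[0, 0] = (12, 34, 56)
    Image.fromarray(rgb).save(path)
    with pytest.raises(SchemaError, match=r"\(12, 34, 56\)"):
        read_mask(path, SCHEMA)


def test_split_counts_match_corpus_arithmetic():
    splits = split_manifest(3087, 973, 308, seed=1)
    assert len(splits["train"]) == 1806
    assert len(splits["val"]) == 973
    assert len(splits["test"]) == 308


@given(st.integers(0, 2 ** 31 - 1))
def test_splits_partition_the_index_set(seed):
    splits = split_manifest(50, 13, 7, seed)
    all_ids = splits["train"] + splits["val"] + splits["test"]
    assert sorted(all_ids) == list(range(50))


def test_split_determinism_across_seeds():
    base = split_manifest(200, 60, 20, seed=3)
    assert split_manifest(200, 60, 20, seed=3) == base
    others = [split_manifest(200, 60, 20, seed=s) for s in range(4, 9)]
    assert any(o != base for o in others)


def test_degenerate_and_invalid_splits():
    assert split_manifest(10, 0, 0, seed=0)["train"] == list(range(10))
    with pytest.raises(InvalidInputError):
        split_manifest(10, 8, 5, seed=0)


def _coordinate_sample(h=20, w=24):
    """Image channels encode (col, row, 0) so augmented pixels reveal
    their source coordinates."""
    img = np.zeros((h, w, 3))
    img[..., 0] = np.arange(w)
    img[..., 1] = np.arange(h)[:, None]
    mask = np.random.default_rng(5).integers(0, 10, size=(h, w))
    return SceneSample(image=img, mask=mask)


def test_flip_is_an_involution():
    sample = _coordinate_sample(20, 20)
    cfg = AugmentationConfig(flip_probability=1.0, blur_probability=0.0, crop_size=20)
    once = augment(sample, cfg, np.random.default_rng(0))
    twice = augment(SceneSample(image=once.image, mask=once.mask),
                    cfg, np.random.default_rng(0))
    np.testing.assert_allclose(twice.image, sample.image)
    np.testing.assert_array_equal(twice.mask, sample.mask)


def test_hand_computed_flip():
    img = np.stack([np.arange(9).reshape(3, 3)] * 3, axis=-1).astype(float)
    mask = np.array([[1, 0, 0], [0, 0, 0], [0, 0, 0]])
    cfg = AugmentationConfig(flip_probability=1.0, blur_probability=0.0, crop_size=3)
    out = augment(SceneSample(image=img, mask=mask), cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(out.mask[0], [0, 0, 1])
    np.testing.assert_array_equal(out.image[..., 0], img[:, ::-1, 0])


@given(st.integers(0, 10_000))
def test_augmentation_preserves_pixel_correspondence(seed):
    """After any flip/crop combination every surviving pixel's encoded
    source coordinates still index its own mask value."""
    sample = _coordinate_sample()
    cfg = AugmentationConfig(blur_probability=0.0, crop_size=12)
    out = augment(sample, cfg, np.random.default_rng(seed))
    cols = np.rint(out.image[..., 0]).astype(int)
    rows = np.rint(out.image[..., 1]).astype(int)
    np.testing.assert_array_equal(out.mask, sample.mask[rows, cols])
    assert out.mask.shape == (12, 12)


def test_mask_value_set_invariant_under_augmentation():
    sample = _coordinate_sample(16, 16)
    cfg = AugmentationConfig(crop_size=16)
    out = augment(sample, cfg, np.random.default_rng(9))
    assert set(np.unique(out.mask)) <= set(np.unique(sample.mask))


def test_crop_output_size_and_reflect_padding():
    small = SceneSample(image=np.zeros((10, 10, 3)), mask=np.zeros((10, 10), dtype=int))
    cfg = AugmentationConfig(blur_probability=0.0, crop_size=16)
    out = augment(small, cfg, np.random.default_rng(0))
    assert out.mask.shape == (16, 16)
    with pytest.raises(InvalidInputError):
        augment(SceneSample(image=np.zeros((4, 4, 3)), mask=np.zeros((4, 4), dtype=int)),
                AugmentationConfig(crop_size=16), np.random.default_rng(0))


def test_standardization_uses_channel_statistics():
    img = np.full((6, 6, 3), 100.0)
    cfg = AugmentationConfig(flip_probability=0.0, blur_probability=0.0,
                             mean=(100.0, 50.0, 0.0), std=(10.0, 50.0, 1.0),
                             crop_size=6)
    out = augment(SceneSample(image=img, mask=np.zeros((6, 6), dtype=int)),
                  cfg, np.random.default_rng(0))
    np.testing.assert_allclose(out.image[..., 0], 0.0)
    np.testing.assert_allclose(out.image[..., 1], 1.0)
    np.testing.assert_allclose(out.image[..., 2], 100.0)
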