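import numpy as np
import pytest

from polypseg import (AugmentationSpec, SegmentationSample, augment_subset,
                      fit_hsv_jitter, jitter_pair, rescale_and_crop,
                      rotate_pair, scale_pair, tps_deform_pair)


def _disc_sample(h=80, w=80, r=20):
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r * r).astype(np.uint8)
    rng = np.random.default_rng(0)
    image = rng.integers(40, 200, (h, w, 3), dtype=np.uint8)
    image[mask.astype(bool)] = (210, 140, 130)
    return SegmentationSample(image=image, mask=mask, sequence_id="s0", frame_id="f0")


# -- rescale + crop ---------------------------------------------------------

def test_rescale_halves_double_resolution_exactly():
    rng = np.random.default_rng(1)
    big = SegmentationSample(image=rng.integers(0, 255, (500, 574, 3), dtype=np.uint8),
                             mask=(rng.random((500, 574)) > 0.7).astype(np.uint8),
                             sequence_id="s", frame_id="f")
    out = rescale_and_crop(big, (250, 287), seed=0)
    assert out.mask.shape == (250, 287)
    assert set(np.unique(out.mask)) <= {0, 1}


def test_rescale_identity_when_already_target():
    s = _disc_sample(64, 64)
    out = rescale_and_crop(s, (64, 64), seed=5)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_rescale_crops_overhang_isotropically():
    rng = np.random.default_rng(2)
    s = SegmentationSample(image=rng.integers(0, 255, (288, 384, 3), dtype=np.uint8),
                           mask=(rng.random((288, 384)) > 0.5).astype(np.uint8),
                           sequence_id="s", frame_id="f")
    out = rescale_and_crop(s, (250, 287), seed=1)
    assert out.image.shape == (250, 287, 3)
    assert set(np.unique(out.mask)) <= {0, 1}


def test_rescale_upscales_small_inputs():
    s = _disc_sample(40, 40, 10)
    out = rescale_and_crop(s, (64, 64), seed=0)
    assert out.mask.shape == (64, 64)


# -- rotation ---------------------------------------------------------------

@pytest.mark.parametrize("angle", [0.0, 360.0])
def test_rotation_identity_angles(angle):
    s = _disc_sample()
    out = rotate_pair(s, angle)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_rotation_preserves_centered_disc_area():
    s = _disc_sample()
    out = rotate_pair(s, 90.0)
    assert out.mask.sum() == pytest.approx(s.mask.sum(), rel=0.02)
    assert set(np.unique(out.mask)) <= {0, 1}


# -- TPS --------------------------------------------------------------------

def test_tps_zero_displacement_is_identity():
    s = _disc_sample()
    out = tps_deform_pair(s, (10, 10), 0.0, seed=0)
    assert np.array_equal(out.image, s.image)
    assert np.array_equal(out.mask, s.mask)


def test_tps_seeded_determinism_and_binarity():
    s = _disc_sample()
    a = tps_deform_pair(s, (10, 10), 4.0, seed=9)
    b = tps_deform_pair(s, (10, 10), 4.0, seed=9)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    assert set(np.unique(a.mask)) <= {0, 1}


def test_tps_displacement_stays_moderate():
    # with 4 px control displacements the warped disc's area changes little
    s = _disc_sample()
    out = tps_deform_pair(s, (10, 10), 4.0, seed=3)
    assert out.mask.sum() == pytest.approx(s.mask.sum(), rel=0.15)


# -- HSV jitter -------------------------------------------------------------

def test_jitter_on_identical_corpus_is_degenerate():
    s = _disc_sample()
    model = fit_hsv_jitter([s] * 5)
    assert np.allclose(model.hue_shifts, 0)
    assert np.allclose(model.val_shifts, 0)
    out = jitter_pair(s, model, seed=0)
    assert np.abs(out.image.astype(int) - s.image.astype(int)).max() <= 1


def test_jitter_shift_support_bounded_by_corpus_spread():
    dark = _disc_sample()
    bright = SegmentationSample(image=np.clip(dark.image.astype(int) + 60, 0, 255).astype(np.uint8),
                                mask=dark.mask, sequence_id="s", frame_id="g")
    model = fit_hsv_jitter([dark, bright])
    d = np.abs(np.mean(bright.image / 255.0) - np.mean(dark.image / 255.0))
    assert np.abs(model.val_shifts).max() <= d + 1e-9


def test_jitter_handles_gray_frame_without_nans():
    gray = SegmentationSample(image=np.full((32, 32, 3), 128, np.uint8),
                              mask=np.zeros((32, 32), np.uint8),
                              sequence_id="s", frame_id="f")
    model = fit_hsv_jitter([gray, _disc_sample(32, 32, 8)])
    out = jitter_pair(gray, model, seed=1)
    assert out.image.dtype == np.uint8
    assert np.isfinite(out.image).all()


def test_fit_jitter_empty_corpus_rejected():
    with pytest.raises(ValueError):
        fit_hsv_jitter([])


# -- pair consistency (shared geometric transform) --------------------------

@pytest.mark.parametrize("transform", [
    lambda s: rotate_pair(s, 37.0),
    lambda s: scale_pair(s, 1.15),
    lambda s: tps_deform_pair(s, (6, 6), 3.0, seed=4),
])
def test_mask_transform_is_shared_with_image(transform):
    s = _disc_sample()
    # feeding the mask as a second 'mask' must give the identical result
    twin = SegmentationSample(image=s.image, mask=s.mask.copy(),
                              sequence_id=s.sequence_id, frame_id=s.frame_id)
    a, b = transform(s), transform(twin)
    assert np.array_equal(a.mask, b.mask)
    assert set(np.unique(a.mask)) <= {0, 1}


# -- subset augmentation ----------------------------------------------------

def test_augment_subset_count_and_coverage(tiny_corpus):
    originals = tiny_corpus[:10]
    spec = AugmentationSpec(target_size=(64, 64), augmented_count_per_subset=100, seed=0)
    out = augment_subset(originals, spec)
    assert len(out) == 100
    produced = {s.frame_id for s in out}
    assert produced == {s.frame_id for s in originals}
    assert all(s.mask.shape == (64, 64) for s in out)


def test_augment_subset_determinism(tiny_corpus):
    spec = AugmentationSpec(target_size=(64, 64), augmented_count_per_subset=8, seed=11)
    a = augment_subset(tiny_corpus[:4], spec)
    b = augment_subset(tiny_corpus[:4], spec)
    for x, y in zip(a, b):
        assert np.array_equal(x.image, y.image)
        assert np.array_equal(x.mask, y.mask)


def test_all_disabled_reduces_to_rescale_crop(tiny_corpus):
    spec = AugmentationSpec(target_size=(64, 64), augmented_count_per_subset=4,
                            enable_rotation=False, enable_scale=False,
                            enable_tps=False, enable_jitter=False, seed=2)
    out = augment_subset(tiny_corpus[:4], spec)
    # inputs are already 64x64: rescale+crop alone is the identity here
    for o, s in zip(out, tiny_corpus[:4]):
        assert np.array_equal(o.image, s.image)


def test_count_below_originals_rejected(tiny_corpus):
    spec = AugmentationSpec(target_size=(64, 64), augmented_count_per_subset=2)
    with pytest.raises(ValueError):
        augment_subset(tiny_corpus[:5], spec)


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        AugmentationSpec(scale_range=(1.2, 0.8))
    with pytest.raises(ValueError):
        AugmentationSpec(tps_max_displacement=-1)
    with pytest.raises(ValueError):
        AugmentationSpec(tps_grid=(1, 10))
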