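"""Training-time augmentation with paired image/mask consistency.

The pipeline mirrors how limited endoscopy training corpora are enlarged:
every frame is first rescaled (aspect preserved) and randomly cropped to the
common working size, then an independently sampled composition of the
enabled transforms is applied — rotation (0-360 deg), scaling (0.8-1.2),
thin-plate-spline deformation on a 10x10 control grid with displacements of
at most 4 px, and HSV color jitter with shifts drawn from the empirical
distribution of per-image channel statistics of the training corpus.

Every geometric transform is applied identically to the image (bilinear,
reflect border) and to the mask (nearest neighbour, zero border), so masks
stay binary and paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage import color as skcolor
from skimage import transform as sktransform

from .phantoms import SegmentationSample


@dataclass
class AugmentationSpec:
    target_size: tuple[int, int] = (250, 287)
    rotation_range: tuple[float, float] = (0.0, 360.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    tps_grid: tuple[int, int] = (10, 10)
    tps_max_displacement: float = 4.0
    enable_rotation: bool = True
    enable_scale: bool = True
    enable_tps: bool = True
    enable_jitter: bool = True
    augmented_count_per_subset: int | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo < hi):
            raise ValueError("scale_range must satisfy 0 < min < max")
        if self.tps_max_displacement < 0:
            raise ValueError("tps_max_displacement must be >= 0")
        if min(self.tps_grid) < 2:
            raise ValueError("tps_grid must be at least 2x2")
        lo, hi = self.rotation_range
        if not (0 <= lo <= hi <= 360):
            raise ValueError("rotation_range must lie within [0, 360]")

    def to_dict(self) -> dict:
        return asdict(self)


def _warp_pair(image, mask, inverse_map, output_shape=None):
    """Shared geometric warp: bilinear/reflect for image, nearest/zero for mask."""
    img = sktransform.warp(image.astype(np.float64) / 255.0, inverse_map,
                           order=1, mode="reflect", output_shape=output_shape)
    msk = sktransform.warp(mask.astype(np.float64), inverse_map,
                           order=0, mode="constant", cval=0.0,
                           output_shape=output_shape)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), (msk > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Rescale + random crop (translation augmentation)


def rescale_and_crop(sample: SegmentationSample, target_size: tuple[int, int],
                     seed: int = 0) -> SegmentationSample:
    """Isotropic rescale to cover the target, then a random crop of the overhang.

    The scale factor is the larger of the two per-axis ratios, so aspect
    ratio is preserved and both axes cover the target; the residual extent in
    the looser axis is removed by a uniformly random crop offset (this is the
    translation component of the augmentation).  A 500x574 frame maps onto
    250x287 with factor 0.5 and no residual.
    """
    th, tw = target_size
    if th < 1 or tw < 1:
        raise ValueError("target_size must be positive")
    h, w = sample.mask.shape
    rng = np.random.default_rng(seed)
    s = max(th / h, tw / w)
    nh = max(th, int(round(h * s)))
    nw = max(tw, int(round(w * s)))
    if (nh, nw) == (h, w):
        img, msk = sample.image.copy(), sample.mask.copy()
    else:
        img = sktransform.resize(sample.image.astype(np.float64) / 255.0,
                                 (nh, nw), order=1, mode="reflect",
                                 anti_aliasing=s < 1)
        img = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        msk = sktransform.resize(sample.mask.astype(np.float64), (nh, nw),
                                 order=0, anti_aliasing=False)
        msk = (msk > 0.5).astype(np.uint8)
    oy = int(rng.integers(0, nh - th + 1))
    ox = int(rng.integers(0, nw - tw + 1))
    return SegmentationSample(image=img[oy:oy + th, ox:ox + tw],
                              mask=msk[oy:oy + th, ox:ox + tw],
                              sequence_id=sample.sequence_id,
                              frame_id=sample.frame_id)


# ---------------------------------------------------------------------------
# Rotation / scale / TPS


def rotate_pair(sample: SegmentationSample, angle: float) -> SegmentationSample:
    """Rotate image (bilinear, reflect) and mask (nearest, zero) about the center."""
    if not 0 <= angle < 360:
        angle = angle % 360.0
    if angle == 0.0:
        return SegmentationSample(sample.image.copy(), sample.mask.copy(),
                                  sample.sequence_id, sample.frame_id)
    h, w = sample.mask.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (sktransform.EuclideanTransform(translation=-center)
             + sktransform.EuclideanTransform(rotation=np.deg2rad(angle))
             + sktransform.EuclideanTransform(translation=center))
    img, msk = _warp_pair(sample.image, sample.mask, tform.inverse)
    return SegmentationSample(img, msk, sample.sequence_id, sample.frame_id)


def scale_pair(sample: SegmentationSample, factor: float) -> SegmentationSample:
    """Scale about the center keeping the frame size fixed."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return SegmentationSample(sample.image.copy(), sample.mask.copy(),
                                  sample.sequence_id, sample.frame_id)
    h, w = sample.mask.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (sktransform.SimilarityTransform(translation=-center)
             + sktransform.SimilarityTransform(scale=factor)
             + sktransform.SimilarityTransform(translation=center))
    img, msk = _warp_pair(sample.image, sample.mask, tform.inverse)
    return SegmentationSample(img, msk, sample.sequence_id, sample.frame_id)


def tps_deform_pair(sample: SegmentationSample, grid: tuple[int, int] = (10, 10),
                    max_displacement: float = 4.0, seed: int = 0) -> SegmentationSample:
    """Thin-plate-spline warp from a regular control grid.

    Each control point is displaced by an independent uniform vector with
    sup-norm <= max_displacement; the TPS interpolant of the displaced grid
    warps the image and mask identically.
    """
    if min(grid) < 2:
        raise ValueError("grid must be at least 2x2")
    if max_displacement < 0:
        raise ValueError("max_displacement must be >= 0")
    if max_displacement == 0:
        return SegmentationSample(sample.image.copy(), sample.mask.copy(),
                                  sample.sequence_id, sample.frame_id)
    h, w = sample.mask.shape
    rng = np.random.default_rng(seed)
    gy = np.linspace(0, h - 1, grid[0])
    gx = np.linspace(0, w - 1, grid[1])
    src = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)  # (x, y)
    disp = rng.uniform(-max_displacement, max_displacement, src.shape)
    dst = src + disp
    # warp() needs the inverse (output->input) map: estimate dst -> src
    tps = sktransform.ThinPlateSplineTransform.from_estimate(dst, src)
    img, msk = _warp_pair(sample.image, sample.mask, tps)
    return SegmentationSample(img, msk, sample.sequence_id, sample.frame_id)


# ---------------------------------------------------------------------------
# HSV jitter fitted to corpus statistics


@dataclass
class HsvJitterModel:
    """Empirical per-channel shift distributions from a training corpus.

    The model records each training image's mean hue/saturation/value; a
    jitter shift is the deviation of one (resampled) image's channel mean
    from the corpus grand mean, so sampled shifts always lie within the
    spread observed in the corpus and a corpus of identical images yields a
    degenerate (all-zero) distribution.
    """

    hue_shifts: np.ndarray
    sat_shifts: np.ndarray
    val_shifts: np.ndarray

    def sample_shifts(self, rng: np.random.Generator) -> tuple[float, float, float]:
        i = int(rng.integers(0, len(self.hue_shifts)))
        j = int(rng.integers(0, len(self.sat_shifts)))
        k = int(rng.integers(0, len(self.val_shifts)))
        return (float(self.hue_shifts[i]), float(self.sat_shifts[j]),
                float(self.val_shifts[k]))

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        dh, ds, dv = self.sample_shifts(rng)
        hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + ds, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] + dv, 0.0, 1.0)
        rgb = skcolor.hsv2rgb(hsv)
        return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def fit_hsv_jitter(corpus) -> HsvJitterModel:
    """Fit the jitter model from per-image HSV channel means."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot fit HSV jitter on an empty corpus")
    means = []
    for s in corpus:
        image = s.image if isinstance(s, SegmentationSample) else s
        hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
        means.append(hsv.reshape(-1, 3).mean(axis=0))
    means = np.asarray(means)
    shifts = means - means.mean(axis=0, keepdims=True)
    return HsvJitterModel(hue_shifts=shifts[:, 0], sat_shifts=shifts[:, 1],
                          val_shifts=shifts[:, 2])


def jitter_pair(sample: SegmentationSample, model: HsvJitterModel,
                seed: int = 0) -> SegmentationSample:
    rng = np.random.default_rng(seed)
    return SegmentationSample(model.apply(sample.image, rng), sample.mask.copy(),
                              sample.sequence_id, sample.frame_id)


# ---------------------------------------------------------------------------
# Subset augmentation


def augment_subset(samples, spec: AugmentationSpec,
                   jitter_model: HsvJitterModel | None = None) -> list[SegmentationSample]:
    """Produce an augmented subset of exactly ``augmented_count_per_subset``.

    Every output is rescale+crop followed by an independently sampled
    composition of the enabled transforms, applied in the fixed order
    rotation -> scale -> TPS -> color jitter.  Every original is represented
    at least once; the originals' sequence ids are retained.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot augment an empty subset")
    count = spec.augmented_count_per_subset
    if count is None:
        count = len(samples)
    if count < len(samples):
        raise ValueError("augmented count must be >= the number of originals")
    if spec.enable_jitter and jitter_model is None:
        jitter_model = fit_hsv_jitter(samples)
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    # each original at least once, remainder drawn uniformly
    order = list(range(len(samples))) + [
        int(rng.integers(0, len(samples))) for _ in range(count - len(samples))]
    out = []
    for draw_seed, idx in zip(root.spawn(count), order):
        drng = np.random.default_rng(draw_seed)
        s = rescale_and_crop(samples[idx], spec.target_size,
                             seed=int(drng.integers(0, 2 ** 31)))
        if spec.enable_rotation:
            lo, hi = spec.rotation_range
            s = rotate_pair(s, float(drng.uniform(lo, hi)) % 360.0)
        if spec.enable_scale:
            s = scale_pair(s, float(drng.uniform(*spec.scale_range)))
        if spec.enable_tps:
            s = tps_deform_pair(s, spec.tps_grid, spec.tps_max_displacement,
                                seed=int(drng.integers(0, 2 ** 31)))
        if spec.enable_jitter:
            s = jitter_pair(s, jitter_model, seed=int(drng.integers(0, 2 ** 31)))
        out.append(s)
    return out
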