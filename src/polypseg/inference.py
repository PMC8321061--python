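"""Inference: probability maps, rotation test-time augmentation, and
threshold + morphology post-processing.

Rotation test-time augmentation presents the input at ``360/angle_step``
orientations (24 views at the default 15-degree step), predicts each, maps
every output back into the original frame, and averages.  Because the
network is not rotation invariant, the averaged response is more stable
than any single view.  Non-square frames are reflect-padded to the
enclosing square before rotating; per-pixel normalization by the number of
views whose un-padded region covers the pixel handles the corners.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph
from skimage import transform as sktransform

from .training import to_network_input


@dataclass
class ProbabilityMap:
    """Per-pixel polyp probability with TTA provenance."""

    prob: np.ndarray
    tta: bool = False
    n_views: int = 1

    def __post_init__(self):
        p = np.asarray(self.prob)
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TTASpec:
    angle_step: float = 15.0
    aggregation: str = "binary_mean"
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.angle_step <= 0 or 360.0 % self.angle_step != 0:
            raise ValueError("360 must be divisible by angle_step")
        if self.aggregation not in ("binary_mean", "probability_mean"):
            raise ValueError("aggregation must be binary_mean or probability_mean")

    @property
    def n_views(self) -> int:
        return int(round(360.0 / self.angle_step))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PostprocessSpec:
    threshold: float = 0.5
    opening_radius: float = 2.0
    fill_holes: bool = True
    # if set, opening radius is scaled by min(H,W)/reference_size so the
    # element keeps its relative size on other resolutions
    reference_size: int | None = None

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Forward pass


def predict(network, image: np.ndarray, allow_any_size: bool = False) -> ProbabilityMap:
    """Softmax forward pass; returns the polyp-class probability plane.

    ``image`` is (H, W, 3) uint8 at the network's input size.  The network
    is fully convolutional; ``allow_any_size`` lifts the size check (used by
    test-time augmentation, which feeds padded squares).
    """
    from . import nn
    hw = tuple(image.shape[:2])
    if not allow_any_size and hw != tuple(network.spec.input_size):
        raise ValueError(f"image size {hw} does not match network input "
                         f"{tuple(network.spec.input_size)}")
    x = to_network_input(image, network.input_stats)
    scores = network.forward(x, training=False)
    prob = nn.softmax(scores, axis=1)[0, 1]
    return ProbabilityMap(prob=prob.astype(np.float64), tta=False, n_views=1)


# ---------------------------------------------------------------------------
# Rotation TTA


def _rotate(arr: np.ndarray, angle: float, order: int, mode: str) -> np.ndarray:
    """Rotate about the center keeping shape; exact for multiples of 90."""
    if angle % 360 == 0:
        return arr.copy()
    if angle % 90 == 0 and arr.shape[0] == arr.shape[1]:
        return np.ascontiguousarray(np.rot90(arr, int(angle // 90) % 4, axes=(0, 1)))
    return sktransform.rotate(arr, angle, order=order, mode=mode,
                              cval=0.0, preserve_range=True)


def predict_tta(network_or_fn, image: np.ndarray, tta: TTASpec | None = None) -> ProbabilityMap:
    """Rotation test-time augmentation.

    ``network_or_fn`` is either a trained network or any callable mapping an
    (H, W, 3) uint8 image to an (H, W) probability array (useful for
    analysis with hand-built predictors).  Each view is rotated, predicted,
    inverse-rotated into the original frame and aggregated; with
    ``binary_mean`` the per-view outputs are binarized before averaging,
    with ``probability_mean`` the raw probabilities are averaged.
    """
    tta = tta or TTASpec()
    if callable(network_or_fn):
        fn = network_or_fn
    else:
        fn = lambda img: predict(network_or_fn, img, allow_any_size=True).prob

    if tta.n_views == 1:
        prob = np.asarray(fn(image), dtype=np.float64)
        if tta.aggregation == "binary_mean":
            prob = (prob >= tta.binarize_threshold).astype(np.float64)
        return ProbabilityMap(prob=prob, tta=True, n_views=1)

    h, w = image.shape[:2]
    side = max(h, w)
    py, px = (side - h) // 2, (side - w) // 2
    padded = np.pad(image, ((py, side - h - py), (px, side - w - px), (0, 0)),
                    mode="reflect")
    valid = np.zeros((side, side))
    valid[py:py + h, px:px + w] = 1.0

    acc = np.zeros((side, side))
    cover = np.zeros((side, side))
    for v in range(tta.n_views):
        angle = v * tta.angle_step
        view = _rotate(padded.astype(np.float64), angle, order=1, mode="reflect")
        out = np.asarray(fn(np.clip(view, 0, 255).round().astype(np.uint8)),
                         dtype=np.float64)
        if tta.aggregation == "binary_mean":
            out = (out >= tta.binarize_threshold).astype(np.float64)
        back = _rotate(out, -angle, order=1, mode="constant")
        vmask = _rotate(_rotate(valid, angle, order=0, mode="constant"),
                        -angle, order=0, mode="constant")
        acc += back * vmask
        cover += vmask
    prob = np.divide(acc, cover, out=np.zeros_like(acc), where=cover > 0)
    prob = np.clip(prob[py:py + h, px:px + w], 0.0, 1.0)
    return ProbabilityMap(prob=prob, tta=True, n_views=tta.n_views)


# ---------------------------------------------------------------------------
# Post-processing


def postprocess(pmap: ProbabilityMap | np.ndarray, spec: PostprocessSpec | None = None) -> np.ndarray:
    """Threshold, morphological opening (disc element), hole filling.

    Opening removes small spurious responses; hole filling closes interior
    gaps in the polyp response.  Idempotent: applying it to its own output
    changes nothing.
    """
    spec = spec or PostprocessSpec()
    prob = pmap.prob if isinstance(pmap, ProbabilityMap) else np.asarray(pmap)
    mask = prob >= spec.threshold
    radius = spec.opening_radius
    if spec.reference_size:
        radius = radius * min(mask.shape) / spec.reference_size
    radius = int(round(radius))
    if radius > 0:
        mask = skmorph.opening(mask, skmorph.disk(radius))
    if spec.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask.astype(np.uint8)
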