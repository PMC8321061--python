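"""Seeded synthetic colonoscopy-like phantoms with exact ground-truth masks.

Each phantom frame shows a single raised polyp-like blob on a mucosa-like
textured background, with the confounders typical of endoscopy optics:
multiplicative vignetting, small saturated specular highlights, and additive
Gaussian sensor noise.  Frames are grouped into "videos": all frames of a
sequence share one polyp identity (size, eccentricity, boundary roughness,
color) and differ by pose and illumination, emulating correlated views
selected from a colonoscopy sequence.  No claim of photorealism is made —
the generator exists so the segmentation pipeline is testable end to end
with known ground truth.

The blob support is analytic (a star-convex polar region), so the mask is
exact: a pixel is foreground iff its center lies inside the region.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio


@dataclass
class PhantomSpec:
    """Parameters of a synthetic corpus.

    Defaults emulate the structure of the standard-definition polyp training
    corpus: 15 video sequences with ~20 correlated frames each (300 frames),
    at the 250x287 working resolution.
    """

    image_height: int = 250
    image_width: int = 287
    n_sequences: int = 15
    frames_per_sequence: int = 20
    polyp_radius_range: tuple[float, float] = (18.0, 60.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    boundary_roughness_range: tuple[float, float] = (0.0, 0.5)
    highlight_count_range: tuple[int, int] = (0, 4)
    vignette_strength: float = 0.35
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("canvas must be at least 16x16")
        if self.n_sequences < 1 or self.frames_per_sequence < 1:
            raise ValueError("need at least one sequence and one frame")
        for name in ("polyp_radius_range", "eccentricity_range",
                     "boundary_roughness_range", "highlight_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        if self.polyp_radius_range[0] < 3:
            raise ValueError("polyp radius must be >= 3 px")
        e_lo, e_hi = self.eccentricity_range
        if not (0.0 <= e_lo and e_hi < 1.0):
            raise ValueError("eccentricity must lie in [0, 1)")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SegmentationSample:
    """One RGB frame with its binary polyp mask and sequence identity."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    sequence_id: str
    frame_id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("mask shape must equal image spatial shape")


# ---------------------------------------------------------------------------
# Blob geometry


def _radial_profile(eccentricity: float, roughness: float, rng: np.random.Generator):
    """Return a function r(theta)/r0 describing the blob boundary."""
    n_harm = 4
    amps = rng.uniform(-1.0, 1.0, n_harm) / np.arange(2, 2 + n_harm)
    phases = rng.uniform(0.0, 2 * np.pi, n_harm)
    orient = rng.uniform(0.0, np.pi)
    # eccentricity e: axis ratio b/a = sqrt(1 - e^2), area preserved
    ratio = np.sqrt(1.0 - eccentricity ** 2)
    a = 1.0 / np.sqrt(ratio)
    b = np.sqrt(ratio)

    def boundary(theta):
        t = theta - orient
        ell = (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        rough = 1.0 + roughness * sum(
            amp * np.cos((k + 2) * t + ph)
            for k, (amp, ph) in enumerate(zip(amps, phases)))
        return ell * np.maximum(rough, 0.2)

    return boundary


def _rasterize_blob(shape, center, radius, boundary):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - center[0]
    dx = xx - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return (rho <= radius * boundary(theta)).astype(np.uint8)


def generate_polyp_mask(radius: float, eccentricity: float = 0.0,
                        boundary_roughness: float = 0.0, seed: int = 0,
                        shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize one star-convex blob; returns a binary (H, W) mask.

    Area scales as radius^2 and circularity decreases monotonically as
    eccentricity or boundary roughness grows, which is what lets downstream
    size/circularity stratification produce non-degenerate groups.
    """
    if radius < 3:
        raise ValueError("radius must be >= 3 px")
    if not 0.0 <= eccentricity < 1.0:
        raise ValueError("eccentricity must lie in [0, 1)")
    if boundary_roughness < 0:
        raise ValueError("boundary_roughness must be non-negative")
    rng = np.random.default_rng(seed)
    boundary = _radial_profile(eccentricity, boundary_roughness, rng)
    if shape is None:
        side = int(np.ceil(2 * radius * 2.2)) + 4
        shape = (side, side)
    if min(shape) < 2 * radius * 0.5:
        raise ValueError("grid too small for the requested radius")
    center = (shape[0] / 2.0, shape[1] / 2.0)
    return _rasterize_blob(shape, center, radius, boundary)


# ---------------------------------------------------------------------------
# Appearance


def _smooth_field(shape, rng, scale=8, lo=0.0, hi=1.0):
    """Low-frequency random field in [lo, hi] via bilinear upsampling."""
    coarse = rng.random((scale, scale))
    ys = np.linspace(0, scale - 1, shape[0])
    xs = np.linspace(0, scale - 1, shape[1])
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, scale - 1)
    x1 = np.minimum(x0 + 1, scale - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    f = (coarse[np.ix_(y0, x0)] * (1 - fy) * (1 - fx)
         + coarse[np.ix_(y1, x0)] * fy * (1 - fx)
         + coarse[np.ix_(y0, x1)] * (1 - fy) * fx
         + coarse[np.ix_(y1, x1)] * fy * fx)
    return lo + (hi - lo) * f


def _render_frame(spec: PhantomSpec, identity: dict, rng: np.random.Generator):
    h, w = spec.image_height, spec.image_width
    base = np.array(identity["bg_color"], dtype=np.float64)
    texture = _smooth_field((h, w), rng, scale=9, lo=0.85, hi=1.15)
    img = base[None, None, :] * texture[:, :, None]

    # polyp placement: jittered around the sequence's home position
    margin = identity["radius"] * 1.3
    cy = np.clip(identity["cy"] + rng.normal(0, 6), margin, h - margin)
    cx = np.clip(identity["cx"] + rng.normal(0, 6), margin, w - margin)
    mask = _rasterize_blob((h, w), (cy, cx), identity["radius"], identity["boundary"])

    # raised-blob shading: radial gradient, brighter dome center
    yy, xx = np.mgrid[0:h, 0:w]
    rho = np.hypot(yy - cy, xx - cx) / max(identity["radius"], 1.0)
    dome = np.clip(1.25 - 0.45 * rho ** 2, 0.6, 1.3)
    polyp_col = np.array(identity["polyp_color"], dtype=np.float64)
    inside = mask.astype(bool)
    img[inside] = (polyp_col[None, :] * dome[inside, None])

    # illumination: per-frame gain and vignette
    gain = rng.uniform(0.92, 1.08)
    img *= gain
    if spec.vignette_strength > 0:
        d2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        img *= (1.0 - spec.vignette_strength * d2 / 2.0)[:, :, None]

    # specular highlights: small saturated ellipses
    n_hi = int(rng.integers(spec.highlight_count_range[0],
                            spec.highlight_count_range[1] + 1))
    for _ in range(n_hi):
        hy, hx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(1.5, 5.0, 2)
        ang = rng.uniform(0, np.pi)
        dy, dx = yy - hy, xx - hx
        u = dy * np.cos(ang) + dx * np.sin(ang)
        v = -dy * np.sin(ang) + dx * np.cos(ang)
        spot = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        img[spot] = 250.0

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def generate_corpus(spec: PhantomSpec) -> list[SegmentationSample]:
    """Generate the full seeded corpus: n_sequences x frames_per_sequence."""
    root = np.random.SeedSequence(spec.seed)
    seq_seeds = root.spawn(spec.n_sequences)
    samples = []
    r_lo, r_hi = spec.polyp_radius_range
    for s, seq_seed in enumerate(seq_seeds):
        rng = np.random.default_rng(seq_seed)
        # log-uniform radius so the 25th/75th-percentile strata are non-empty
        radius = float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
        ecc = float(rng.uniform(*spec.eccentricity_range))
        rough = float(rng.uniform(*spec.boundary_roughness_range))
        identity = {
            "radius": radius,
            "boundary": _radial_profile(ecc, rough, rng),
            "cy": rng.uniform(0.3, 0.7) * spec.image_height,
            "cx": rng.uniform(0.3, 0.7) * spec.image_width,
            "bg_color": (rng.uniform(150, 190), rng.uniform(85, 120), rng.uniform(75, 110)),
            "polyp_color": (rng.uniform(195, 230), rng.uniform(120, 160), rng.uniform(110, 150)),
        }
        seq_id = f"seq{s:03d}"
        for f in range(spec.frames_per_sequence):
            image, mask = _render_frame(spec, identity, rng)
            samples.append(SegmentationSample(
                image=image, mask=mask,
                sequence_id=seq_id, frame_id=f"{seq_id}_f{f:03d}"))
    return samples


# ---------------------------------------------------------------------------
# Disk I/O: PNG images/masks + manifest CSV

MANIFEST_COLUMNS = ("frame_id", "sequence_id", "image_path", "mask_path")


def write_corpus(samples, out_dir) -> Path:
    """Write images/ and masks/ PNGs plus manifest.csv; returns manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for s in samples:
            ipath = f"images/{s.frame_id}.png"
            mpath = f"masks/{s.frame_id}.png"
            iio.imwrite(out_dir / ipath, s.image)
            iio.imwrite(out_dir / mpath, (s.mask * 255).astype(np.uint8))
            writer.writerow([s.frame_id, s.sequence_id, ipath, mpath])
    return manifest


def read_corpus(manifest_path) -> list[SegmentationSample]:
    """Load a corpus from a manifest CSV written by :func:`write_corpus`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    samples = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(iio.imread(root / row["image_path"]))
            mask = np.asarray(iio.imread(root / row["mask_path"]))
            if mask.ndim == 3:
                mask = mask[..., 0]
            samples.append(SegmentationSample(
                image=image[..., :3].astype(np.uint8),
                mask=(mask > 127).astype(np.uint8),
                sequence_id=row["sequence_id"], frame_id=row["frame_id"]))
    return samples
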