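"""Seeded synthetic fundus-like images with paired vessel masks.

Real fundus photographs pose two well-known difficulties for vessel
segmentation: thin (1-2 px) vessels with low contrast against the
background, and an over-illuminated optic-disc region that washes out the
vessels crossing it.  The generator reproduces exactly these features on
a textured background — branching curvilinear trees stroked at thick and
thin widths, thin branches at reduced contrast, one bright disc placed on
top of a vessel — together with the strong class imbalance (vessels are a
small minority of pixels) that motivates pixel-importance reweighting of
the training loss.

All randomness flows from the single integer seed in :class:`SyntheticSpec`
through ``numpy.random.SeedSequence`` counters, so identical specs produce
bit-identical samples with no global RNG state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "FundusSample", "generate_sample", "generate_dataset", "save_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic image generator.

    Heights and widths must be divisible by 4 because the segmentation
    network downsamples twice by a factor of 2.
    """

    height: int = 64
    width: int = 64
    n_trees: int = 3
    thick_width_range: tuple[int, int] = (3, 6)
    thin_width_range: tuple[int, int] = (1, 2)
    thin_contrast_factor: float = 0.5
    vessel_contrast: float = 0.35
    disc_brightness: float = 0.25
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ConfigurationError("height and width must be positive")
        if self.height % 4 or self.width % 4:
            raise ConfigurationError(
                f"height and width must be divisible by 4, got {self.height}x{self.width}"
            )
        for lo, hi in (self.thick_width_range, self.thin_width_range):
            if lo < 1 or hi < lo:
                raise ConfigurationError("width ranges must satisfy 1 <= lo <= hi")
        if not (0.0 < self.thin_contrast_factor <= 1.0):
            raise ConfigurationError("thin_contrast_factor must be in (0, 1]")
        if self.disc_brightness < 0 or self.noise_sd < 0:
            raise ConfigurationError("disc_brightness and noise_sd must be >= 0")


@dataclass
class FundusSample:
    """An RGB image in [0,1] (H, W, 3) with a binary vessel mask (H, W).

    ``fov`` marks the circular field of view of the camera; ``width_map``
    records the stroke width each vessel pixel was drawn with, letting
    evaluations stratify performance by vessel calibre.
    """

    image: np.ndarray
    mask: np.ndarray
    fov: np.ndarray | None = None
    width_map: np.ndarray | None = None

    def validate(self) -> "FundusSample":
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match image")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        return self


def _stamp_branch(canvas, width_map, points, widths):
    """Stroke a polyline of centerline points with per-point disk radii."""
    h, w = canvas.shape
    for (y, x), bw in zip(points, widths):
        r = max(0.0, (bw - 1) / 2.0)
        ri = int(np.ceil(r))
        y0, y1 = max(0, int(y) - ri), min(h, int(y) + ri + 1)
        x0, x1 = max(0, int(x) - ri), min(w, int(x) + ri + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - y) ** 2 + (xx - x) ** 2 <= r**2 + 0.25
        canvas[y0:y1, x0:x1] |= disk
        region = width_map[y0:y1, x0:x1]
        np.maximum(region, np.where(disk, bw, 0.0), out=region)


def _walk(rng, start, angle, n_steps, h, w, wobble=0.18):
    """Meandering unit-step walk; returns the visited float coordinates."""
    pts = []
    y, x = start
    for _ in range(n_steps):
        pts.append((y, x))
        angle += rng.normal(0.0, wobble)
        y += np.sin(angle)
        x += np.cos(angle)
        if not (-2 <= y < h + 2 and -2 <= x < w + 2):
            break
    return pts


def _draw_tree(rng, spec, thick_canvas, thin_canvas, width_map, span_full: bool):
    h, w = spec.height, spec.width
    side = rng.integers(0, 4)
    along = rng.uniform(0.2, 0.8)
    if side == 0:
        start, angle = (along * h, 0.0), 0.0
    elif side == 1:
        start, angle = (along * h, w - 1.0), np.pi
    elif side == 2:
        start, angle = (0.0, along * w), np.pi / 2
    else:
        start, angle = (h - 1.0, along * w), -np.pi / 2
    angle += rng.normal(0.0, 0.25)
    n_steps = int(1.2 * max(h, w)) if span_full else int(rng.uniform(0.5, 1.0) * max(h, w))
    trunk = _walk(rng, start, angle, n_steps, h, w)
    wmax = rng.integers(spec.thick_width_range[0], spec.thick_width_range[1] + 1)
    # taper the trunk towards its distal end
    widths = np.linspace(wmax, max(1.0, wmax - 2.0), len(trunk))
    _stamp_branch(thick_canvas, width_map, trunk, widths)

    n_children = int(rng.integers(1, 4)) if span_full else int(rng.integers(0, 3))
    for _ in range(max(1, n_children) if span_full else n_children):
        if len(trunk) < 8:
            break
        idx = int(rng.integers(len(trunk) // 4, len(trunk)))
        by, bx = trunk[idx]
        branch_angle = np.arctan2(
            trunk[min(idx + 1, len(trunk) - 1)][0] - trunk[idx - 1][0],
            trunk[min(idx + 1, len(trunk) - 1)][1] - trunk[idx - 1][1],
        ) + rng.choice((-1.0, 1.0)) * rng.uniform(0.5, 1.1)
        child = _walk(rng, (by, bx), branch_angle, int(rng.uniform(0.25, 0.6) * max(h, w)), h, w)
        bw = int(rng.integers(spec.thin_width_range[0], spec.thin_width_range[1] + 1))
        _stamp_branch(thin_canvas, width_map, child, np.full(len(child), float(bw)))


def _sample_rng(spec: SyntheticSpec, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stream, index)))


def generate_sample(spec: SyntheticSpec, _stream: int = 0, _index: int = 0) -> FundusSample:
    """Generate one synthetic fundus image with its ground-truth mask.

    Deterministic for a fixed spec.  The first vessel tree is forced to span
    at least half the image; at least one branch is drawn thin at reduced
    contrast; a bright disc is placed on a vessel (when vessels exist).
    """
    rng = _sample_rng(spec, _stream, _index)
    h, w = spec.height, spec.width

    thick = np.zeros((h, w), dtype=bool)
    thin = np.zeros((h, w), dtype=bool)
    width_map = np.zeros((h, w), dtype=np.float32)
    for t in range(spec.n_trees):
        _draw_tree(rng, spec, thick, thin, width_map, span_full=(t == 0))

    # field of view: inscribed circle, as produced by a fundus camera
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0 - 1.0
    fov = ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2).astype(np.uint8)

    thick &= fov.astype(bool)
    thin &= fov.astype(bool)
    thin &= ~thick  # thick stroke wins where they overlap
    mask = (thick | thin).astype(np.uint8)
    width_map *= mask

    # smooth textured background, reddish like a retina
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(4, h // 12))
    texture = 0.05 * texture / max(1e-8, np.abs(texture).max())
    base = 0.55 + texture
    gains = np.array([1.05, 1.0, 0.75])
    image = base[:, :, None] * gains[None, None, :]

    # vessels absorb light: darken, thin branches at reduced contrast
    vessel_field = spec.vessel_contrast * (
        ndimage.gaussian_filter(thick.astype(float), 0.5)
        + spec.thin_contrast_factor * ndimage.gaussian_filter(thin.astype(float), 0.5)
    )
    image -= vessel_field[:, :, None] * np.array([0.9, 1.0, 0.6])[None, None, :]

    # over-bright disc centred on a vessel pixel
    if mask.any() and spec.disc_brightness > 0:
        ys, xs = np.nonzero(mask)
        pick = int(rng.integers(len(ys)))
        dy, dx = ys[pick], xs[pick]
        sigma = max(3.0, h / 10.0)
        blob = np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * sigma**2)))
        image += spec.disc_brightness * blob[:, :, None]

    image += rng.normal(0.0, spec.noise_sd, (h, w, 3))
    image *= np.where(fov[:, :, None] > 0, 1.0, 0.0)
    image += (1 - fov[:, :, None]) * 0.02
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return FundusSample(image=image, mask=mask, fov=fov, width_map=width_map).validate()


def generate_dataset(
    spec: SyntheticSpec, n_train: int, n_test: int
) -> tuple[list[FundusSample], list[FundusSample]]:
    """Generate disjoint train/test sample lists with per-sample derived seeds."""
    if n_train < 0 or n_test < 0:
        raise ConfigurationError("n_train and n_test must be >= 0")
    train = [generate_sample(spec, _stream=0, _index=i) for i in range(n_train)]
    test = [generate_sample(spec, _stream=1, _index=i) for i in range(n_test)]
    return train, test


def save_dataset(samples: list[FundusSample], out_dir: str | Path, prefix: str = "") -> list[Path]:
    """Write samples as ``img_XXX.png`` / ``mask_XXX.png`` / ``fov_XXX.png`` pairs."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, s in enumerate(samples):
        stem = f"{prefix}{i:03d}"
        img_path = out_dir / f"img_{stem}.png"
        iio.imwrite(img_path, (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8))
        iio.imwrite(out_dir / f"mask_{stem}.png", (s.mask * 255).astype(np.uint8))
        if s.fov is not None:
            iio.imwrite(out_dir / f"fov_{stem}.png", (s.fov * 255).astype(np.uint8))
        written.append(img_path)
    return written


def spec_with(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Return a copy of ``spec`` with the given fields replaced."""
    return dataclasses.replace(spec, **overrides)
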