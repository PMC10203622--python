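"""Dataset loading, zero padding / crop-back, and training augmentations.

Whole images are fed to the network, zero-padded to a square whose side is
the largest dimension rounded up to a multiple of 16 (DRIVE's 584x565
becomes 592x592, CHASE_DB1's 999x960 becomes 1008x1008); predictions are
cropped back to the original size before evaluation.  Padding is centred,
with any odd remainder pixel going to the bottom/right, and the exact
offsets are carried in :class:`PadSpec` so the crop inverts the pad
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DataLayoutError, DimensionError
from .synthetic import FundusSample

__all__ = [
    "PadSpec",
    "AugmentSpec",
    "pad_to",
    "crop_back",
    "augment",
    "load_dataset",
    "split_dataset",
]


@dataclass(frozen=True)
class PadSpec:
    """Zero-padding geometry: original size, target size and content offsets."""

    target_height: int
    target_width: int
    original_height: int
    original_width: int
    offsets: tuple[int, int]  # (top, left)

    def __post_init__(self):
        th, tw = self.target_height, self.target_width
        oh, ow = self.original_height, self.original_width
        top, left = self.offsets
        if th < oh or tw < ow:
            raise DimensionError("target size must be >= original size")
        if top < 0 or left < 0 or top + oh > th or left + ow > tw:
            raise DimensionError("offsets place the image outside the target")

    @classmethod
    def centered(cls, original_hw: tuple[int, int], target_hw: tuple[int, int]) -> "PadSpec":
        """Symmetric padding; odd remainder goes to the bottom/right."""
        oh, ow = original_hw
        th, tw = target_hw
        return cls(th, tw, oh, ow, ((th - oh) // 2, (tw - ow) // 2))

    @classmethod
    def square16(cls, original_hw: tuple[int, int]) -> "PadSpec":
        """Default rule: square target, side = max(H, W) rounded up to 16k."""
        side = -(-max(original_hw) // 16) * 16
        return cls.centered(original_hw, (side, side))


def pad_to(arr: np.ndarray, pad: PadSpec) -> np.ndarray:
    """Zero-pad a (H, W) or (H, W, C) array to the PadSpec target size."""
    if arr.shape[0] != pad.original_height or arr.shape[1] != pad.original_width:
        raise DimensionError(
            f"input is {arr.shape[0]}x{arr.shape[1]}, PadSpec expects "
            f"{pad.original_height}x{pad.original_width}"
        )
    top, left = pad.offsets
    bottom = pad.target_height - pad.original_height - top
    right = pad.target_width - pad.original_width - left
    widths = [(top, bottom), (left, right)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, widths)


def crop_back(padded: np.ndarray, pad: PadSpec) -> np.ndarray:
    """Exact inverse of :func:`pad_to`."""
    if padded.shape[0] != pad.target_height or padded.shape[1] != pad.target_width:
        raise DimensionError(
            f"input is {padded.shape[0]}x{padded.shape[1]}, PadSpec expects "
            f"{pad.target_height}x{pad.target_width}"
        )
    top, left = pad.offsets
    return padded[top : top + pad.original_height, left : left + pad.original_width]


@dataclass(frozen=True)
class AugmentSpec:
    """Training-time augmentation: flips, rotation, colour jitter.

    Geometric transforms are applied identically to image, mask and FOV
    (nearest-neighbour for the binary maps); jitter touches the image only.
    """

    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_range: float = 180.0
    jitter_brightness: float = 0.2
    jitter_contrast: float = 0.2
    jitter_saturation: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("flip probabilities must be in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")


def _rotate_sample(image, mask, fov, angle: float):
    """Rotate about the image centre; bilinear image, nearest binary maps."""
    img = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1, mode="constant")
    msk = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False, order=0, mode="constant")
    f = None
    if fov is not None:
        f = ndimage.rotate(fov, angle, axes=(1, 0), reshape=False, order=0, mode="constant")
    return np.clip(img, 0.0, 1.0), (msk > 0.5).astype(mask.dtype), f


def augment(
    sample: FundusSample, spec: AugmentSpec, rng: np.random.Generator | None = None
) -> FundusSample:
    """Randomly transformed copy of ``sample``.

    Pass a persistent ``rng`` for a stream of different augmentations;
    without one, the spec's seed makes the call deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    image = sample.image.copy()
    mask = sample.mask.copy()
    fov = None if sample.fov is None else sample.fov.copy()

    if rng.random() < spec.hflip_prob:
        image, mask = image[:, ::-1], mask[:, ::-1]
        fov = None if fov is None else fov[:, ::-1]
    if rng.random() < spec.vflip_prob:
        image, mask = image[::-1], mask[::-1]
        fov = None if fov is None else fov[::-1]
    if spec.rotation_range > 0:
        angle = rng.uniform(-spec.rotation_range, spec.rotation_range)
        image, mask, fov = _rotate_sample(image, mask, fov, angle)

    # photometric jitter (image only)
    if spec.jitter_brightness > 0:
        image = image * rng.uniform(1 - spec.jitter_brightness, 1 + spec.jitter_brightness)
    if spec.jitter_contrast > 0:
        c = rng.uniform(1 - spec.jitter_contrast, 1 + spec.jitter_contrast)
        image = (image - image.mean()) * c + image.mean()
    if spec.jitter_saturation > 0:
        s = rng.uniform(1 - spec.jitter_saturation, 1 + spec.jitter_saturation)
        gray = image.mean(axis=2, keepdims=True)
        image = gray + (image - gray) * s
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return FundusSample(
        image=np.ascontiguousarray(image),
        mask=np.ascontiguousarray(mask),
        fov=None if fov is None else np.ascontiguousarray(fov),
    )


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def _to_float_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    arr = arr.astype(np.float32)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def _to_binary(arr: np.ndarray) -> np.ndarray:
    # annotations are near-binary rasters; threshold at mid-range for
    # robustness to antialiased or 16-bit files
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    threshold = 127 if arr.max() > 1 else 0.5
    return (arr > threshold).astype(np.uint8)


_IMG_EXTS = (".png", ".tif", ".tiff", ".gif", ".jpg", ".jpeg", ".ppm", ".bmp")


def _find_with_stem(directory: Path, stem_part: str) -> Path | None:
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in _IMG_EXTS and stem_part in p.stem:
            return p
    return None


def _load_flat(root: Path) -> list[FundusSample]:
    samples = []
    for img_path in sorted(root.glob("img_*")):
        if img_path.suffix.lower() not in _IMG_EXTS:
            continue
        stem = img_path.stem[len("img_") :]
        mask_path = _find_with_stem(root, f"mask_{stem}")
        if mask_path is None:
            raise DataLayoutError(f"no mask found for image stem {stem!r}")
        fov_path = _find_with_stem(root, f"fov_{stem}")
        samples.append(
            FundusSample(
                image=_to_float_rgb(_read_image(img_path)),
                mask=_to_binary(_read_image(mask_path)),
                fov=None if fov_path is None else _to_binary(_read_image(fov_path)),
            ).validate()
        )
    return samples


def _load_drive_like(root: Path) -> list[FundusSample]:
    images_dir = root / "images"
    manual_dir = root / "1st_manual"
    fov_dir = root / "mask"
    if not images_dir.is_dir() or not manual_dir.is_dir():
        raise DataLayoutError(f"{root} lacks images/ and 1st_manual/ directories")
    samples = []
    for img_path in sorted(p for p in images_dir.iterdir() if p.suffix.lower() in _IMG_EXTS):
        stem = img_path.stem.split("_")[0]
        mask_path = _find_with_stem(manual_dir, stem)
        if mask_path is None:
            raise DataLayoutError(f"no manual annotation for image stem {stem!r}")
        fov_path = _find_with_stem(fov_dir, stem) if fov_dir.is_dir() else None
        samples.append(
            FundusSample(
                image=_to_float_rgb(_read_image(img_path)),
                mask=_to_binary(_read_image(mask_path)),
                fov=None if fov_path is None else _to_binary(_read_image(fov_path)),
            ).validate()
        )
    return samples


def _load_chase(root: Path, annotator: str = "1stHO") -> list[FundusSample]:
    samples = []
    img_paths = sorted(
        p
        for p in root.iterdir()
        if p.suffix.lower() in _IMG_EXTS and annotator not in p.stem and "2ndHO" not in p.stem
    )
    if not img_paths:
        raise DataLayoutError(f"{root} contains no CHASE-style images")
    for img_path in img_paths:
        mask_path = _find_with_stem(root, f"{img_path.stem}_{annotator}")
        if mask_path is None:
            raise DataLayoutError(f"no {annotator} annotation for image stem {img_path.stem!r}")
        samples.append(
            FundusSample(
                image=_to_float_rgb(_read_image(img_path)),
                mask=_to_binary(_read_image(mask_path)),
            ).validate()
        )
    return samples


def load_dataset(root: str | Path, layout: str = "flat", annotator: str = "1stHO") -> list[FundusSample]:
    """Load image/mask(/FOV) triples from a dataset directory.

    ``layout='drive'`` reads ``images/``, ``1st_manual/`` and ``mask/``
    subdirectories (applied to a DRIVE ``training/`` or ``test/`` folder, or
    to a merged folder of all 40 stems); ``layout='chase'`` reads flat
    ``Image_*.jpg`` files with ``*_1stHO.png`` annotations (first human
    observer by default); ``layout='flat'`` reads the generator's
    ``img_/mask_/fov_`` triples.  Files are consumed in lexicographic order.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataLayoutError(f"dataset directory {root} does not exist")
    if layout == "flat":
        return _load_flat(root)
    if layout == "drive":
        if (root / "training").is_dir() and (root / "test").is_dir():
            return _load_drive_like(root / "training") + _load_drive_like(root / "test")
        return _load_drive_like(root)
    if layout == "chase":
        return _load_chase(root, annotator=annotator)
    raise ValueError(f"unknown layout {layout!r}")


def split_dataset(samples: list[FundusSample], layout: str) -> tuple[list[FundusSample], list[FundusSample]]:
    """Official train/test split: DRIVE first-20/last-20, CHASE first-20/last-8."""
    if layout == "drive":
        if len(samples) != 40:
            raise DataLayoutError(f"DRIVE split expects 40 stems, got {len(samples)}")
        return samples[:20], samples[20:]
    if layout == "chase":
        if len(samples) != 28:
            raise DataLayoutError(f"CHASE_DB1 split expects 28 stems, got {len(samples)}")
        return samples[:20], samples[20:]
    raise ValueError(f"no canonical split for layout {layout!r}")
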