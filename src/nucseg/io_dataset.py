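"""Reading DSB/BBBC038-style sample folders and splitting datasets.

Each sample lives in its own directory::

    <id>/
      images/<id>.png          # one RGB (or grayscale) image
      masks/*.png              # zero or more per-nucleus binary masks

Instance masks are unioned into a single binary semantic mask: the task
is nucleus-vs-background, not instance segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


class InputError(ValueError):
    """Missing or malformed input files."""


class ValidationError(ValueError):
    """Inputs present but mutually inconsistent."""


@dataclass
class ImageRecord:
    """One sample: an RGB image and its binary nucleus mask.

    ``mask`` uses 1 for nucleus (positive class) and 0 for background.
    """

    id: str
    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray   # H x W, uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(
                f"{self.id}: image must be HxWx3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise ValidationError(
                f"{self.id}: mask shape {self.mask.shape} does not match "
                f"image {self.image.shape[:2]}")
        vals = np.unique(self.mask)
        if not np.isin(vals, [0, 1]).all():
            raise ValidationError(
                f"{self.id}: mask values must be 0/1, got {vals[:10]}")
        self.mask = self.mask.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of a record list."""

    train: list[ImageRecord]
    validation: list[ImageRecord]
    test: list[ImageRecord]
    seed: int = 42

    def __post_init__(self) -> None:
        ids = [r.id for part in (self.train, self.validation, self.test) for r in part]
        if len(ids) != len(set(ids)):
            raise ValidationError("split parts share sample ids")

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def _to_rgb(image: np.ndarray) -> np.ndarray:
    """Coerce any loaded image to HxWx3 uint8.

    Grayscale is replicated to 3 channels; RGBA drops alpha.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        # 16-bit TIFFs and friends: rescale to the 8-bit range
        image = image.astype(np.float64)
        hi = image.max()
        if hi > 0:
            image = image / hi * 255.0
        image = image.astype(np.uint8)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    elif image.shape[2] == 4:
        image = image[:, :, :3]
    elif image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    return image


def _read_mask(path: Path) -> np.ndarray:
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[:, :, 0]
    return (m > 0).astype(np.uint8)


def load_sample(sample_dir: str | Path) -> ImageRecord:
    """Load one sample directory, merging its instance masks.

    The returned mask is the pixelwise logical OR of every file under
    ``masks/``, each binarized at intensity > 0. A sample with no mask
    files yields an all-zero mask (valid: some fields contain no nuclei).
    """
    sample_dir = Path(sample_dir)
    img_dir = sample_dir / "images"
    image_files = sorted(
        p for p in (img_dir.glob("*") if img_dir.is_dir() else [])
        if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if len(image_files) != 1:
        raise InputError(
            f"{sample_dir}: expected exactly one image under images/, "
            f"found {len(image_files)}")
    image = _to_rgb(iio.imread(image_files[0]))

    mask = np.zeros(image.shape[:2], dtype=np.uint8)
    mask_dir = sample_dir / "masks"
    for mf in sorted(mask_dir.glob("*")) if mask_dir.is_dir() else []:
        if mf.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        inst = _read_mask(mf)
        if inst.shape != mask.shape:
            raise ValidationError(
                f"mask {mf.name} has shape {inst.shape}, image is "
                f"{mask.shape}")
        mask |= inst

    return ImageRecord(id=sample_dir.name, image=image, mask=mask)


def load_dataset(data_dir: str | Path) -> list[ImageRecord]:
    """Load every sample directory under ``data_dir``, sorted by id."""
    data_dir = Path(data_dir)
    dirs = sorted(p for p in data_dir.iterdir() if p.is_dir())
    if not dirs:
        raise InputError(f"no sample directories under {data_dir}")
    return [load_sample(d) for d in dirs]


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))


def split_sizes(n: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> tuple[int, int, int]:
    """Partition sizes: floor(r_train*n), floor(r_val*n), remainder.

    Deterministic and sums exactly to ``n``.
    """
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return n_train, n_val, n - n_train - n_val


def split_dataset(
    records: Sequence[ImageRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 42,
) -> DatasetSplit:
    """Reproducible 80:10:10 split by whole image.

    Records are ordered by id before shuffling, so the split does not
    depend on the order the caller discovered the files in.
    """
    if len(records) < 3:
        raise InputError(f"need >= 3 records to split, got {len(records)}")
    if not np.isclose(sum(ratios), 1.0):
        raise InputError(f"ratios must sum to 1, got {ratios}")
    ordered = sorted(records, key=lambda r: r.id)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ordered))
    shuffled = [ordered[i] for i in perm]
    n_train, n_val, _ = split_sizes(len(records), ratios)
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed,
    )
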