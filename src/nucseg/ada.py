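"""Balanced patch extraction (adaptive augmentation).

Microscopy nucleus datasets are dominated by background pixels. Instead
of resizing heterogeneous images to a fixed shape, each image is cut
into fixed-size patches by sliding a k x k window with stride s (zero
padding, unit dilation); the per-axis window count uses a ceiling so the
grid always covers the full extent:

    ph = ceil((h - k) / s) + 1
    pl = ceil((w - k) / s) + 1
    N  = ph * pl

Because the ceiling can push the last window origin past the border,
the final origin per axis is clamped to h - k (resp. w - k), producing
extra overlap rather than padding; clamped origins are kept even when
they coincide, so the patch count always equals N.

Patches whose foreground-pixel count does not EXCEED ``alpha_threshold``
are discarded. The number removed is the improper-class-distribution
count alpha, leaving N_alpha = N - alpha patches — a simple, effective
rebalancing of the foreground/background pixel ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from nucseg.io_dataset import DatasetSplit, ImageRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ADAParams:
    """Patch-extraction geometry and filter settings.

    k: patch side length (pixels); s: stride; p: padding (fixed 0);
    d: dilation (fixed 1). ``alpha_threshold`` is the foreground-pixel
    count a patch must strictly exceed to be kept. ``aug_fraction`` is
    the fraction of kept *training* patches that additionally receive a
    randomly composed basic augmentation.
    """

    k: int = 128
    s: int = 64
    p: int = 0
    d: int = 1
    alpha_threshold: int = 9
    aug_fraction: float = 0.25
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1 or self.s < 1:
            raise ValueError(f"k and s must be >= 1 (k={self.k}, s={self.s})")
        if self.p != 0:
            raise ValueError("padding is fixed at 0")
        if self.d != 1:
            raise ValueError("dilation is fixed at 1")
        if self.alpha_threshold < 0:
            raise ValueError("alpha_threshold must be >= 0")
        if not 0.0 <= self.aug_fraction <= 1.0:
            raise ValueError("aug_fraction must be in [0, 1]")


@dataclass
class PatchGrid:
    """Window-grid bookkeeping for one image.

    ``alpha`` / ``n_alpha`` are filled in by the balance filter.
    """

    ph: int
    pl: int
    N: int
    alpha: int | None = None
    n_alpha: int | None = None


@dataclass
class Patch:
    """One k x k window cut from a source image."""

    image: np.ndarray       # k x k x 3
    mask: np.ndarray        # k x k, {0, 1}
    source_id: str
    row0: int
    col0: int
    foreground_count: int

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_count / self.mask.size


def compute_patch_grid(h: int, w: int, params: ADAParams) -> PatchGrid:
    """Window counts for an h x w image: ph = ceil((h-k)/s) + 1, etc."""
    k, s = params.k, params.s
    if h < k or w < k:
        raise ValueError(
            f"image {h}x{w} smaller than patch size {k}; pad first "
            "(extract_patches handles this)")
    ph = math.ceil((h - k) / s) + 1
    pl = math.ceil((w - k) / s) + 1
    return PatchGrid(ph=ph, pl=pl, N=ph * pl)


def _axis_origins(extent: int, k: int, s: int, count: int) -> list[int]:
    # last origin clamped inside the image; duplicates intentionally kept
    return [min(i * s, extent - k) for i in range(count)]


def _pad_to_k(record: ImageRecord, k: int) -> ImageRecord:
    """Reflect-pad an undersized image (and mask) up to k per axis."""
    h, w = record.mask.shape
    ph, pw = max(0, k - h), max(0, k - w)
    mode = "reflect" if min(h, w) > 1 else "edge"
    logger.info("padding %s from %dx%d to >= %d (%s)", record.id, h, w, k, mode)
    image = np.pad(record.image, ((0, ph), (0, pw), (0, 0)), mode=mode)
    mask = np.pad(record.mask, ((0, ph), (0, pw)), mode=mode)
    return ImageRecord(id=record.id, image=image, mask=mask)


def extract_patches(record: ImageRecord, params: ADAParams) -> list[Patch]:
    """Cut the full window grid out of one image, row-major.

    Returns exactly ``N = ph * pl`` patches; every patch lies fully
    inside the image. Undersized images are reflect-padded up to k.
    """
    if record.height < params.k or record.width < params.k:
        record = _pad_to_k(record, params.k)
    h, w, k = record.height, record.width, params.k
    grid = compute_patch_grid(h, w, params)
    rows = _axis_origins(h, k, params.s, grid.ph)
    cols = _axis_origins(w, k, params.s, grid.pl)
    patches = []
    for r0 in rows:
        for c0 in cols:
            m = record.mask[r0:r0 + k, c0:c0 + k]
            patches.append(Patch(
                image=record.image[r0:r0 + k, c0:c0 + k],
                mask=m,
                source_id=record.id,
                row0=r0,
                col0=c0,
                foreground_count=int(m.sum()),
            ))
    return patches


def filter_patches(
    patches: Sequence[Patch], alpha_threshold: int
) -> tuple[list[Patch], int, int]:
    """Keep patches whose foreground count strictly exceeds the threshold.

    Returns ``(kept, alpha, n_alpha)`` where alpha is the number
    discarded and n_alpha = N - alpha. Order of kept patches preserved.
    """
    kept = [p for p in patches if p.foreground_count > alpha_threshold]
    alpha = len(patches) - len(kept)
    return kept, alpha, len(kept)


# --- basic augmentations ------------------------------------------------

def hflip_patch(patch: Patch) -> Patch:
    return replace(patch, image=patch.image[:, ::-1].copy(),
                   mask=patch.mask[:, ::-1].copy())


def vflip_patch(patch: Patch) -> Patch:
    return replace(patch, image=patch.image[::-1].copy(),
                   mask=patch.mask[::-1].copy())


def rot90_patch(patch: Patch, turns: int) -> Patch:
    return replace(patch,
                   image=np.rot90(patch.image, turns, axes=(0, 1)).copy(),
                   mask=np.rot90(patch.mask, turns).copy())


def blur_patch(patch: Patch, sigma: float) -> Patch:
    """Gaussian blur on the image channels only; the mask is untouched."""
    blurred = gaussian_filter(patch.image.astype(np.float32),
                              sigma=(sigma, sigma, 0))
    return replace(patch, image=np.clip(blurred, 0, 255).astype(np.uint8))


def augment_patch(patch: Patch, rng_seed: int) -> Patch:
    """Apply a randomly chosen subset of the basic augmentations.

    Candidates: vertical flip, horizontal flip, rotation by a random
    multiple of 90 degrees, Gaussian blur (image only). Geometric
    transforms hit image and mask identically, so the mask stays binary
    and its foreground count is preserved; blur never touches the mask.
    """
    rng = np.random.default_rng(rng_seed)
    out = patch
    if rng.random() < 0.5:
        out = vflip_patch(out)
    if rng.random() < 0.5:
        out = hflip_patch(out)
    if rng.random() < 0.5:
        out = rot90_patch(out, int(rng.integers(1, 4)))
    if rng.random() < 0.5:
        out = blur_patch(out, float(rng.uniform(0.5, 1.5)))
    return out


# --- dataset-level preparation ------------------------------------------

REPORT_COLUMNS = ["id", "subset", "h", "w", "ph", "pl", "N", "alpha",
                  "n_alpha", "fg_fraction_before", "fg_fraction_after"]


def _fg_fraction(patches: Iterable[Patch]) -> float:
    patches = list(patches)
    if not patches:
        return float("nan")
    total = sum(p.mask.size for p in patches)
    return sum(p.foreground_count for p in patches) / total


def prepare_patch_dataset(
    split: DatasetSplit, params: ADAParams
) -> tuple[dict[str, list[Patch]], pd.DataFrame]:
    """Run extract -> filter -> (augment) over a whole split.

    Augmentation adds transformed copies of a random ``aug_fraction``
    subset of the kept training patches; validation and test patches are
    never augmented. Returns per-subset patch lists plus a per-image
    balance report (grid counts and foreground fractions before/after
    the filter). Per-image failures are logged and skipped so one bad
    file cannot sink the run.
    """
    rng = np.random.default_rng(params.seed)
    ensembles: dict[str, list[Patch]] = {}
    rows = []
    for subset, records in (("train", split.train),
                            ("validation", split.validation),
                            ("test", split.test)):
        collected: list[Patch] = []
        for rec in records:
            try:
                patches = extract_patches(rec, params)
                kept, alpha, n_alpha = filter_patches(patches, params.alpha_threshold)
            except (ValueError, ValidationError) as exc:
                logger.error("skipping %s: %s", rec.id, exc)
                continue
            grid = compute_patch_grid(max(rec.height, params.k),
                                      max(rec.width, params.k), params)
            rows.append({
                "id": rec.id, "subset": subset,
                "h": rec.height, "w": rec.width,
                "ph": grid.ph, "pl": grid.pl, "N": grid.N,
                "alpha": alpha, "n_alpha": n_alpha,
                "fg_fraction_before": _fg_fraction(patches),
                "fg_fraction_after": _fg_fraction(kept),
            })
            collected.extend(kept)
        if subset == "train" and params.aug_fraction > 0 and collected:
            n_aug = int(len(collected) * params.aug_fraction)
            chosen = rng.choice(len(collected), size=n_aug, replace=False)
            for idx in sorted(chosen):
                seed = int(rng.integers(0, 2**31 - 1))
                collected.append(augment_patch(collected[idx], seed))
        ensembles[subset] = collected
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ensembles, report
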