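"""Patch grid math, extraction, the balance filter, and augmentations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucseg.ada import (ADAParams, augment_patch, blur_patch, compute_patch_grid,
                        extract_patches, filter_patches, hflip_patch,
                        prepare_patch_dataset, rot90_patch, vflip_patch)
from nucseg.io_dataset import DatasetSplit
from tests.conftest import make_record


def brute_force_origins(extent, k, s):
    """Oracle: enumerate clamped window origins directly (no dedup)."""
    origins = []
    i = 0
    while True:
        start = i * s
        if start + k >= extent:
            origins.append(min(start, extent - k))
            break
        origins.append(start)
        i += 1
    return origins


class TestGrid:
    @pytest.mark.parametrize("h,w,k,s,ph,pl", [
        (128, 128, 128, 64, 1, 1),            # single exact-fit window
        (256, 256, 128, 128, 2, 2),           # exact tiling
        (250, 250, 128, 64, 3, 3),            # ceil(122/64)+1 = 3
    ])
    def test_examples(self, h, w, k, s, ph, pl):
        grid = compute_patch_grid(h, w, ADAParams(k=k, s=s))
        assert (grid.ph, grid.pl, grid.N) == (ph, pl, ph * pl)

    @given(h=st.integers(1, 64), w=st.integers(1, 64),
           k=st.integers(1, 64), s=st.integers(1, 64))
    @settings(max_examples=300, derandomize=True)
    def test_grid_count_matches_brute_force_enumeration(self, h, w, k, s):
        if k > min(h, w) or s > k:
            return
        grid = compute_patch_grid(h, w, ADAParams(k=k, s=s))
        assert grid.ph == len(brute_force_origins(h, k, s))
        assert grid.pl == len(brute_force_origins(w, k, s))

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError):
            compute_patch_grid(100, 200, ADAParams(k=128, s=64))


class TestExtract:
    def test_exact_tiling_origins(self):
        rec = make_record(h=256, w=256)
        patches = extract_patches(rec, ADAParams(k=128, s=128))
        assert [(p.row0, p.col0) for p in patches] == [
            (0, 0), (0, 128), (128, 0), (128, 128)]

    def test_clamped_final_origin(self):
        rec = make_record(h=250, w=250)
        patches = extract_patches(rec, ADAParams(k=128, s=64))
        assert len(patches) == 9
        assert sorted({p.row0 for p in patches}) == [0, 64, 122]
        assert sorted({p.col0 for p in patches}) == [0, 64, 122]

    def test_exact_tiling_partitions_foreground(self):
        rec = make_record(h=256, w=256, blobs=[(10, 10, 30, 40), (200, 100, 20, 20)])
        patches = extract_patches(rec, ADAParams(k=128, s=128))
        assert sum(p.foreground_count for p in patches) == rec.mask.sum()

    def test_patches_lie_inside_image(self):
        rec = make_record(h=200, w=170)
        for p in extract_patches(rec, ADAParams(k=128, s=64)):
            assert 0 <= p.row0 <= 200 - 128
            assert 0 <= p.col0 <= 170 - 128
            assert p.image.shape == (128, 128, 3)

    def test_undersized_image_reflect_padded(self):
        rec = make_record(h=100, w=140, blobs=[(0, 0, 10, 10)])
        patches = extract_patches(rec, ADAParams(k=128, s=64))
        assert all(p.image.shape == (128, 128, 3) for p in patches)
        # reflected content preserves the original top-left corner
        np.testing.assert_array_equal(patches[0].mask[:100, :100],
                                      rec.mask[:, :100])


class TestFilter:
    def test_all_background_all_filtered(self):
        rec = make_record(h=192, w=192)
        patches = extract_patches(rec, ADAParams(k=64, s=64))
        kept, alpha, n_alpha = filter_patches(patches, 9)
        assert kept == [] and alpha == 9 and n_alpha == 0

    def test_strict_inequality_at_boundary(self):
        rec = make_record(h=64, w=256)
        patches = extract_patches(rec, ADAParams(k=64, s=64))
        for p, count in zip(patches, (0, 9, 10, 500)):
            p.mask[:] = 0
            p.mask.ravel()[:count] = 1
            p.foreground_count = count
        kept, alpha, n_alpha = filter_patches(patches, 9)
        assert [p.foreground_count for p in kept] == [10, 500]
        assert (alpha, n_alpha) == (2, 2)

    def test_alpha_identity_over_random_images(self):
        rng = np.random.default_rng(7)
        params = ADAParams(k=32, s=16, alpha_threshold=9)
        for i in range(100):
            h, w = rng.integers(32, 80, size=2)
            rec = make_record(id=f"r{i}", h=int(h), w=int(w))
            rec.mask[:] = (rng.random((int(h), int(w))) < 0.02)
            patches = extract_patches(rec, params)
            for p in patches:
                p.foreground_count = int(p.mask.sum())
            grid = compute_patch_grid(int(h), int(w), params)
            kept, alpha, n_alpha = filter_patches(patches, 9)
            assert alpha + n_alpha == grid.N == len(patches)

    def test_kept_patches_are_foreground_enriched(self):
        rec = make_record(h=256, w=256, blobs=[(0, 0, 40, 40)])
        patches = extract_patches(rec, ADAParams(k=64, s=64))
        kept, _, _ = filter_patches(patches, 9)
        mean_all = np.mean([p.foreground_fraction for p in patches])
        mean_kept = np.mean([p.foreground_fraction for p in kept])
        assert mean_kept >= mean_all


class TestAugment:
    def _patch(self):
        rec = make_record(h=64, w=64, blobs=[(5, 10, 12, 9)])
        return extract_patches(rec, ADAParams(k=64, s=64))[0]

    def test_hflip_is_an_involution(self):
        p = self._patch()
        back = hflip_patch(hflip_patch(p))
        np.testing.assert_array_equal(back.image, p.image)
        np.testing.assert_array_equal(back.mask, p.mask)

    @pytest.mark.parametrize("seed", range(5))
    def test_geometric_ops_preserve_foreground_count(self, seed):
        p = self._patch()
        out = augment_patch(p, rng_seed=seed)
        assert out.mask.sum() == p.mask.sum()
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_blur_never_touches_mask(self):
        p = self._patch()
        out = blur_patch(p, sigma=1.2)
        np.testing.assert_array_equal(out.mask, p.mask)
        assert not np.array_equal(out.image, p.image)

    def test_rotation_consistency_between_image_and_mask(self):
        p = self._patch()
        out = rot90_patch(p, 1)
        np.testing.assert_array_equal(out.mask, np.rot90(p.mask, 1))
        np.testing.assert_array_equal(out.image, np.rot90(p.image, 1, axes=(0, 1)))


class TestPrepare:
    def _split(self, train, val=None, test=None):
        return DatasetSplit(train=train, validation=val or [], test=test or [])

    def test_two_images_no_filter_no_aug(self):
        recs = [make_record(id=f"a{i}", h=256, w=256, blobs=[(60, 60, 130, 130)])
                for i in range(2)]
        split = DatasetSplit(train=[recs[0]], validation=[recs[1]], test=[])
        params = ADAParams(k=128, s=128, alpha_threshold=0, aug_fraction=0.0)
        ensembles, report = prepare_patch_dataset(split, params)
        assert len(ensembles["train"]) + len(ensembles["validation"]) == 8

    def test_all_background_image_contributes_nothing(self):
        fg = make_record(id="fg", h=256, w=256, blobs=[(0, 0, 256, 256)])
        bg = make_record(id="bg", h=256, w=256)
        split = DatasetSplit(train=[fg, bg], validation=[], test=[])
        params = ADAParams(k=128, s=128, alpha_threshold=9, aug_fraction=0.0)
        ensembles, _ = prepare_patch_dataset(split, params)
        assert len(ensembles["train"]) == 4

    def test_report_totals_match_ensemble_size_before_augmentation(self):
        recs = [make_record(id=f"b{i}", h=200, w=180, blobs=[(20, 20, 60, 60)])
                for i in range(4)]
        split = DatasetSplit(train=recs[:2], validation=[recs[2]], test=[recs[3]])
        params = ADAParams(k=128, s=64, alpha_threshold=9, aug_fraction=0.0)
        ensembles, report = prepare_patch_dataset(split, params)
        for subset in ("train", "validation", "test"):
            assert report.loc[report.subset == subset, "n_alpha"].sum() == \
                len(ensembles[subset])

    def test_augmentation_adds_copies_only_to_training(self):
        recs = [make_record(id=f"c{i}", h=256, w=256, blobs=[(60, 60, 130, 130)])
                for i in range(3)]
        split = DatasetSplit(train=[recs[0]], validation=[recs[1]], test=[recs[2]])
        base = ADAParams(k=128, s=128, alpha_threshold=0, aug_fraction=0.0)
        aug = ADAParams(k=128, s=128, alpha_threshold=0, aug_fraction=0.5)
        plain, _ = prepare_patch_dataset(split, base)
        boosted, _ = prepare_patch_dataset(split, aug)
        assert len(boosted["train"]) == len(plain["train"]) + 2  # 4 * 0.5
        assert len(boosted["validation"]) == len(plain["validation"])
        assert len(boosted["test"]) == len(plain["test"])

    def test_determinism_under_fixed_seed(self):
        recs = [make_record(id=f"d{i}", h=200, w=200, blobs=[(30, 30, 50, 50)])
                for i in range(3)]
        split = DatasetSplit(train=recs, validation=[], test=[])
        params = ADAParams(k=128, s=64, alpha_threshold=9, aug_fraction=0.5, seed=11)
        e1, _ = prepare_patch_dataset(split, params)
        e2, _ = prepare_patch_dataset(split, params)
        assert len(e1["train"]) == len(e2["train"])
        for p1, p2 in zip(e1["train"], e2["train"]):
            np.testing.assert_array_equal(p1.image, p2.image)
            np.testing.assert_array_equal(p1.mask, p2.mask)
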