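import numpy as np
import pytest

from nucseg.io_dataset import ImageRecord


def make_record(id="rec", h=64, w=64, blobs=(), fill=0):
    """Build an ImageRecord with rectangular foreground blobs.

    ``blobs`` is a sequence of (r0, c0, height, width) rectangles.
    """
    rng = np.random.default_rng(abs(hash(id)) % 2**31)
    image = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    mask = np.full((h, w), fill, dtype=np.uint8)
    for r0, c0, bh, bw in blobs:
        mask[r0:r0 + bh, c0:c0 + bw] = 1
    return ImageRecord(id=id, image=image, mask=mask)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def sample_dir_factory(tmp_path):
    """Write a DSB-style sample directory and return its path."""
    import imageio.v3 as iio

    def _make(sample_id, image, instance_masks, image_name=None):
        d = tmp_path / sample_id
        (d / "images").mkdir(parents=True)
        (d / "masks").mkdir()
        iio.imwrite(d / "images" / (image_name or f"{sample_id}.png"), image)
        for i, m in enumerate(instance_masks):
            iio.imwrite(d / "masks" / f"m{i}.png",
                        (np.asarray(m, dtype=np.uint8) * 255))
        return d

    return _make
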