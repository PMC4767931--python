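"""Input datasets: synthetic bar patterns, MNIST IDX files, batch streaming.

The bar dataset is the classic sparse-coding benchmark: binary ``size x size``
images, each the union of a few full-row (horizontal) or full-column
(vertical) bars.  With 16 hidden units on 8x8 images the ideal sparse code
assigns one unit to each of the 16 possible bars.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["ImageDataset", "generate_bar_patterns", "read_mnist_idx", "batch_stream"]

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


@dataclass
class ImageDataset:
    """A stack of images (count x height x width, values in [0, 1])."""

    images: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.images.ndim != 3:
            raise ValueError("images must be a count x height x width array")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def flattened(self) -> np.ndarray:
        """Row-major flattening to count x (height*width)."""
        return self.images.reshape(len(self.images), -1)


def generate_bar_patterns(
    count: int = 5000,
    size: int = 8,
    max_bars: int = 4,
    rng: np.random.Generator | None = None,
) -> ImageDataset:
    """Binary images each containing 1..max_bars random bars.

    The number of bars is drawn uniformly from {1, ..., max_bars}; each bar
    is chosen uniformly without replacement among the ``2*size`` candidates
    (``size`` rows plus ``size`` columns), so horizontal and vertical bars
    may co-occur.  Overlapping pixels saturate at 1.
    """
    if size < 1:
        raise ValueError("size must be at least 1")
    if not 1 <= max_bars <= 2 * size:
        raise ValueError(f"max_bars must lie in [1, {2 * size}], got {max_bars}")
    rng = rng if rng is not None else np.random.default_rng()
    images = np.zeros((count, size, size))
    for i in range(count):
        n_bars = int(rng.integers(1, max_bars + 1))
        for pick in rng.choice(2 * size, size=n_bars, replace=False):
            if pick < size:
                images[i, pick, :] = 1.0
            else:
                images[i, :, pick - size] = 1.0
    return ImageDataset(images=images)


def read_mnist_idx(images_path, labels_path=None) -> ImageDataset:
    """Read IDX-format image (and optionally label) files.

    Parses the big-endian IDX header (magic 0x00000803 for images,
    0x00000801 for labels) and scales pixels by 1/255.  Raises a format
    error on a wrong magic number and an I/O error on truncation.
    """
    with open(images_path, "rb") as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise IOError(f"truncated IDX header in {images_path}")
        magic, count, rows, cols = struct.unpack(">IIII", header)
        if magic != _IDX_IMAGES_MAGIC:
            raise ValueError(
                f"{images_path}: magic 0x{magic:08x} is not an IDX image file "
                f"(expected 0x{_IDX_IMAGES_MAGIC:08x})"
            )
        raw = fh.read(count * rows * cols)
        if len(raw) < count * rows * cols:
            raise IOError(f"truncated IDX image data in {images_path}")
    images = np.frombuffer(raw, dtype=np.uint8).reshape(count, rows, cols) / 255.0

    labels = None
    if labels_path is not None:
        with open(labels_path, "rb") as fh:
            header = fh.read(8)
            if len(header) < 8:
                raise IOError(f"truncated IDX header in {labels_path}")
            magic, lcount = struct.unpack(">II", header)
            if magic != _IDX_LABELS_MAGIC:
                raise ValueError(
                    f"{labels_path}: magic 0x{magic:08x} is not an IDX label file"
                )
            raw = fh.read(lcount)
            if len(raw) < lcount:
                raise IOError(f"truncated IDX label data in {labels_path}")
        labels = np.frombuffer(raw, dtype=np.uint8).copy()
    return ImageDataset(images=images, labels=labels)


def write_mnist_idx(images: np.ndarray, images_path) -> None:
    """Write a count x h x w uint8-compatible array as an IDX image file."""
    arr = np.asarray(images)
    if arr.ndim != 3:
        raise ValueError("need a count x height x width array")
    data = np.clip(np.round(arr * 255 if arr.dtype != np.uint8 else arr), 0, 255).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, *data.shape))
        fh.write(data.tobytes())


def batch_stream(
    dataset: ImageDataset | np.ndarray,
    bt: int,
    shuffle: bool = False,
    rng: np.random.Generator | None = None,
):
    """Yield flattened minibatches of ``bt`` patterns (final short batch kept).

    Accepts an :class:`ImageDataset` or an already-flattened array.  With
    ``shuffle`` a fresh permutation is drawn from ``rng`` for the pass.
    """
    if bt < 1:
        raise ValueError("batch size must be at least 1")
    X = dataset.flattened() if isinstance(dataset, ImageDataset) else np.asarray(dataset)
    if len(X) == 0:
        raise ValueError("empty dataset")
    order = np.arange(len(X))
    if shuffle:
        if rng is None:
            rng = np.random.default_rng()
        order = rng.permutation(len(X))
    for start in range(0, len(X), bt):
        yield X[order[start : start + bt]]
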