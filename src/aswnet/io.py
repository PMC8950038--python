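"""Core raster data types and TIFF/PNG reading and writing.

All arrays are 2-D, row-major, indexed ``(row, col)`` with 0-based
coordinates.  Intensity images keep their original bit depth (8, 16 or
float); instance label maps are non-negative integer arrays where 0 is
background and every positive label is one nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import IOFailure, NotFound, ShapeError, UnsupportedFormat

__all__ = [
    "GrayImage",
    "InstanceMask",
    "ThreeClassLabel",
    "ProbMap",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "read_prob_map",
    "write_prob_map",
]

BACKGROUND, INTERIOR, BOUNDARY = 0, 1, 2


@dataclass
class GrayImage:
    """Single-channel intensity image.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite intensities.
    dtype_bits
        8, 16 or the string ``"float"``; recorded so writers can
        round-trip the original bit depth.
    """

    pixels: np.ndarray
    dtype_bits: int | str = "float"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError("GrayImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.dtype_bits not in (8, 16, "float"):
            raise ValueError("dtype_bits must be 8, 16 or 'float'")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class InstanceMask:
    """Instance label map: 0 = background, each positive label one nucleus."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ShapeError("InstanceMask requires a non-empty 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise UnsupportedFormat("instance labels must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("instance labels must be non-negative")

    @property
    def n_instances(self) -> int:
        return int(np.count_nonzero(np.unique(self.labels)))

    @property
    def instance_labels(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ThreeClassLabel:
    """Per-pixel class in {0 background, 1 interior, 2 boundary}."""

    classes: np.ndarray

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ShapeError("ThreeClassLabel requires a non-empty 2-D array")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise UnsupportedFormat("class labels must be integer-typed")
        if self.classes.min() < 0 or self.classes.max() > 2:
            raise ValueError("classes must lie in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


@dataclass
class ProbMap:
    """Per-pixel probability triple (background, interior, boundary).

    Stored channel-first as a ``(3, H, W)`` float array; each pixel's
    triple must sum to 1 within 1e-5.
    """

    probs: np.ndarray
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3 or self.probs.shape[0] != 3:
            raise ShapeError("ProbMap requires a (3, H, W) array")
        if self._validate:
            if np.any(self.probs < -1e-6):
                raise ValueError("probabilities must be non-negative")
            sums = self.probs.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-5):
                raise ValueError("per-pixel probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]

    @property
    def p_background(self) -> np.ndarray:
        return self.probs[BACKGROUND]

    @property
    def p_interior(self) -> np.ndarray:
        return self.probs[INTERIOR]

    @property
    def p_boundary(self) -> np.ndarray:
        return self.probs[BOUNDARY]

    def argmax_classes(self) -> np.ndarray:
        return self.probs.argmax(axis=0).astype(np.int8)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_raw(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Accept multi-channel input only when all channels are identical."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        # channel-last (H, W, C) or channel-first (C, H, W) with small C
        if arr.shape[-1] in (2, 3, 4):
            chans = np.moveaxis(arr, -1, 0)
        elif arr.shape[0] in (2, 3, 4):
            chans = arr
        else:
            raise UnsupportedFormat(f"cannot interpret shape {arr.shape}")
        if all(np.array_equal(chans[0], c) for c in chans[1:]):
            return np.array(chans[0])
        raise UnsupportedFormat("multi-channel image with distinct channels")
    raise UnsupportedFormat(f"unsupported array dimensionality {arr.ndim}")


def _bits_of(dtype: np.dtype) -> int | str:
    if np.issubdtype(dtype, np.floating):
        return "float"
    if dtype.itemsize == 1:
        return 8
    return 16


def read_image(path) -> GrayImage:
    """Read a single-channel 8/16-bit or float TIFF/PNG intensity image.

    Multi-channel files are accepted only if every channel is identical
    (they are collapsed to one); otherwise :class:`UnsupportedFormat`.
    Intensities are never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise NotFound(str(path))
    arr = _collapse_channels(_read_raw(path))
    return GrayImage(pixels=arr, dtype_bits=_bits_of(arr.dtype))


def write_image(image: GrayImage, path) -> None:
    """Write a GrayImage losslessly at its recorded bit depth."""
    path = Path(path)
    if image.dtype_bits == 8:
        arr = image.pixels.astype(np.uint8)
    elif image.dtype_bits == 16:
        arr = image.pixels.astype(np.uint16)
    else:
        arr = image.pixels.astype(np.float32)
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise UnsupportedFormat("float images must be written as TIFF")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
    except (OSError, FileNotFoundError) as exc:  # pragma: no cover - passthrough
        raise IOFailure(str(exc)) from exc


def read_label_map(path) -> InstanceMask:
    """Read an integer-typed instance label TIFF/PNG."""
    path = Path(path)
    if not path.exists():
        raise NotFound(str(path))
    arr = _collapse_channels(_read_raw(path))
    if np.issubdtype(arr.dtype, np.floating):
        raise UnsupportedFormat("label maps must be integer-typed")
    return InstanceMask(labels=arr.astype(np.int64))


def write_label_map(mask: InstanceMask, path) -> None:
    """Write an instance label map as 16-bit TIFF (32-bit when labels overflow)."""
    path = Path(path)
    max_label = int(mask.labels.max(initial=0))
    dtype = np.uint16 if max_label < 65536 else np.uint32
    try:
        tifffile.imwrite(path, mask.labels.astype(dtype))
    except (OSError, FileNotFoundError) as exc:
        raise IOFailure(str(exc)) from exc


def read_prob_map(path) -> ProbMap:
    """Read a 3-page float32 TIFF (pages: background, interior, boundary)."""
    path = Path(path)
    if not path.exists():
        raise NotFound(str(path))
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise UnsupportedFormat("probability maps must be 3-page TIFFs")
    return ProbMap(probs=arr.astype(np.float32))


def write_prob_map(prob: ProbMap, path) -> None:
    try:
        tifffile.imwrite(Path(path), prob.probs.astype(np.float32),
                         photometric="minisblack")
    except (OSError, FileNotFoundError) as exc:
        raise IOFailure(str(exc)) from exc
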