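"""Pre-processing: grayscale normalization, 3-class label derivation,
class weighting and rotation/flip augmentation.

Instance masks are recast as a per-pixel classification problem with
three classes -- background, nucleus interior and nucleus boundary.  The
boundary class is the *inner* morphological boundary of each instance
(instance pixels within ``boundary_width`` of the instance's complement),
so the interface between touching nuclei is labelled boundary on both
sides, which is what lets a semantic network separate clumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import MissingClass, ShapeError
from .io import BOUNDARY, INTERIOR, GrayImage, InstanceMask, ThreeClassLabel

__all__ = [
    "PreprocessConfig",
    "ClassWeights",
    "normalize_grayscale",
    "instance_to_three_class",
    "compute_class_weights",
    "augment",
    "list_transforms",
    "apply_transform",
]


@dataclass
class PreprocessConfig:
    """Normalization percentiles, boundary width and augmentation group.

    Percentile normalization (default 0.1/99.9) is robust to the hot
    pixels common in fluorescence data.  Rotations are restricted to
    multiples of 90 degrees so categorical labels never need
    interpolation.
    """

    norm_low_percentile: float = 0.1
    norm_high_percentile: float = 99.9
    boundary_width: int = 2
    augment_rotations: Sequence[int] = (0, 90, 180, 270)
    augment_flips: Sequence[str] = ("horizontal", "vertical")

    def __post_init__(self):
        if not 0 <= self.norm_low_percentile < self.norm_high_percentile <= 100:
            raise ValueError("need 0 <= low < high <= 100")
        if self.boundary_width < 1:
            raise ValueError("boundary_width must be >= 1")
        for r in self.augment_rotations:
            if r % 90 != 0:
                raise ValueError("rotations must be multiples of 90 degrees")
        for f in self.augment_flips:
            if f not in ("horizontal", "vertical"):
                raise ValueError(f"unknown flip {f!r}")


@dataclass
class ClassWeights:
    """Positive per-class weights for the weighted cross-entropy loss."""

    w_background: float = 1.0
    w_interior: float = 1.0
    w_boundary: float = 1.0

    def __post_init__(self):
        if min(self.w_background, self.w_interior, self.w_boundary) <= 0:
            raise ValueError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_background, self.w_interior, self.w_boundary],
                        dtype=np.float64)


def normalize_grayscale(image: GrayImage,
                        config: PreprocessConfig | None = None) -> GrayImage:
    """Linearly map the low/high intensity percentiles to [0, 1] and clip.

    Constant images map to all zeros.
    """
    config = config or PreprocessConfig()
    px = image.pixels.astype(np.float64)
    lo, hi = np.percentile(px, [config.norm_low_percentile,
                                config.norm_high_percentile])
    if hi <= lo:
        return GrayImage(pixels=np.zeros_like(px), dtype_bits="float")
    out = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return GrayImage(pixels=out, dtype_bits="float")


def instance_to_three_class(mask: InstanceMask, boundary_width: int = 2) -> ThreeClassLabel:
    """Derive the background/interior/boundary label from an instance mask.

    Per instance, pixels whose Euclidean distance to the instance's
    complement is <= ``boundary_width`` become boundary; the rest of the
    instance is interior.  An instance so small that this empties its
    interior keeps its innermost pixel (maximum distance to complement,
    ties broken by smallest row then column) as interior, so every
    instance retains at least one interior seed.
    """
    if boundary_width < 1:
        raise ValueError("boundary_width must be >= 1")
    classes = np.zeros(mask.shape, dtype=np.int8)
    objects = ndimage.find_objects(mask.labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, mask.shape[0])
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, mask.shape[1])
        box = (slice(r0, r1), slice(c0, c1))
        inst = mask.labels[box] == lab
        # zero-pad so the image frame counts as complement: instance pixels
        # on the border are boundary
        padded = np.pad(inst, 1)
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        interior = inst & (dist > boundary_width)
        if not interior.any():
            flat = np.where(inst.ravel(), dist.ravel(), -1.0)
            keep = int(np.argmax(flat))  # argmax returns first max: smallest row, col
            interior = np.zeros_like(inst)
            interior[np.unravel_index(keep, inst.shape)] = True
        boundary = inst & ~interior
        classes[box][interior] = INTERIOR
        classes[box][boundary] = BOUNDARY
    return ThreeClassLabel(classes=classes)


def compute_class_weights(labels: Iterable[ThreeClassLabel]) -> ClassWeights:
    """Inverse-frequency weights: w_c = total_pixels / (3 * pixels_of_c)."""
    counts = np.zeros(3, dtype=np.int64)
    for lab in labels:
        counts += np.bincount(lab.classes.ravel(), minlength=3)[:3]
    if np.any(counts == 0):
        missing = [name for name, c in
                   zip(("background", "interior", "boundary"), counts) if c == 0]
        raise MissingClass(f"classes absent from collection: {missing}")
    total = counts.sum()
    w = total / (3.0 * counts)
    return ClassWeights(*w.tolist())


def list_transforms(config: PreprocessConfig) -> list[tuple[int, str | None]]:
    """Enumerate the configured rotation x flip group as (degrees, flip)."""
    flips: list[str | None] = [None] + list(config.augment_flips)
    return [(rot, flip) for rot in config.augment_rotations for flip in flips]


def apply_transform(arr: np.ndarray, rot: int, flip: str | None) -> np.ndarray:
    """Apply a rotation (multiple of 90 degrees) then an optional flip."""
    out = np.rot90(arr, k=(rot // 90) % 4)
    if flip == "horizontal":
        out = np.flip(out, axis=1)
    elif flip == "vertical":
        out = np.flip(out, axis=0)
    return np.ascontiguousarray(out)


def augment(image: GrayImage, label: ThreeClassLabel,
            config: PreprocessConfig | None = None,
            rng_seed: int | np.random.Generator = 0) -> tuple[GrayImage, ThreeClassLabel]:
    """Apply one transform sampled uniformly from the configured group.

    Image and label receive the identical transform; deterministic for a
    given seed.
    """
    config = config or PreprocessConfig()
    if image.shape != label.shape:
        raise ShapeError("image and label must share shape")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    transforms = list_transforms(config)
    rot, flip = transforms[rng.integers(len(transforms))]
    return (
        GrayImage(pixels=apply_transform(image.pixels, rot, flip),
                  dtype_bits=image.dtype_bits),
        ThreeClassLabel(classes=apply_transform(label.classes, rot, flip)),
    )
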