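"""Synthetic fluorescence-microscopy nucleus images with ground truth.

Emulates single-DNA-channel screens: rounded-but-irregular nuclei
(randomly oriented ellipses with a low-order Fourier perturbation of the
boundary), radial intensity falloff, a flat background level and additive
Gaussian read noise scaled to a target signal-to-noise ratio, with an
optional Poisson shot-noise component.  Two regimes matter in practice:
clean, fairly dense fields (BBBC039-like) and low-SNR fields
(ganglioneuroblastoma-like); both are reachable through ``snr`` and the
density presets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import IOFailure
from .io import GrayImage, InstanceMask, write_image, write_label_map

__all__ = [
    "SynthConfig",
    "SynthSample",
    "generate_nuclei_image",
    "generate_dataset",
    "measure_snr",
    "preset",
    "PRESET_SPLITS",
]

#: nuclei per 1000 pixels for the density presets (§ density case study)
_DENSITY_PER_KPX = {"low": 0.08, "medium": 0.20, "high": 0.40}


@dataclass
class SynthConfig:
    """Parameters of one synthetic field of view.

    ``snr`` is the target ratio of mean in-nucleus signal (above
    background) to the standard deviation of the background noise.
    ``clump_fraction`` is the fraction of nuclei deliberately placed
    touching an already-placed neighbour.
    """

    image_height: int = 256
    image_width: int = 256
    n_nuclei: int = 20
    density_mode: str | None = None  # overrides n_nuclei when set
    radius_range: tuple[float, float] = (12.0, 22.0)
    eccentricity_range: tuple[float, float] = (1.0, 1.8)
    clump_fraction: float = 0.15
    snr: float = 8.0
    background_level: float = 200.0
    noise_sigma: float = 60.0
    poisson_noise: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.radius_range[0] < 2:
            raise ValueError("minimum radius must be at least 2 px")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.density_mode is not None:
            if self.density_mode not in _DENSITY_PER_KPX:
                raise ValueError(f"unknown density_mode {self.density_mode!r}")
            area_kpx = self.image_height * self.image_width / 1000.0
            self.n_nuclei = max(1, round(_DENSITY_PER_KPX[self.density_mode] * area_kpx))


@dataclass
class SynthSample:
    """One generated image with its ground-truth instance mask."""

    image: GrayImage
    truth: InstanceMask
    config: SynthConfig
    placement_shortfall: bool = False  # fewer nuclei placed than requested


def _nucleus_stamp(rng: np.random.Generator, a: float, b: float):
    """Rasterize one wobbly ellipse; returns (binary mask, intensity, extent)."""
    theta = rng.uniform(0, np.pi)
    amps = rng.uniform(0.0, 0.08, size=3)          # Fourier orders 2..4
    phases = rng.uniform(0, 2 * np.pi, size=3)
    half = int(np.ceil(max(a, b) * 1.15)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ct, st = np.cos(theta), np.sin(theta)
    xr = ct * xx + st * yy
    yr = -st * xx + ct * yy
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    phi = np.arctan2(yr, xr)
    wobble = 1.0
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        wobble = wobble + amp * np.cos(k * phi + ph)
    inside = rho <= wobble
    rho_n = np.where(inside, rho / np.maximum(wobble, 1e-6), 1.0)
    profile = np.where(inside, 1.0 - 0.35 * rho_n**2, 0.0)
    return inside, profile, half


def generate_nuclei_image(config: SynthConfig) -> SynthSample:
    """Generate one field of view; deterministic given ``config.rng_seed``.

    Non-clumped nuclei are rejection-placed so that no two touch (their
    3x3-dilations are disjoint); clumped nuclei are placed adjacent to an
    existing one, with any overlapping pixels ceded to the earlier nucleus
    so that instances touch but never share pixels.  If placement fails
    after bounded retries the sample carries fewer nuclei and
    ``placement_shortfall`` is set.
    """
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.image_height, config.image_width
    labels = np.zeros((H, W), dtype=np.int32)
    signal = np.zeros((H, W), dtype=np.float64)
    struct = np.ones((3, 3), bool)

    placed_centers: list[tuple[float, float, float]] = []  # (row, col, radius)
    shortfall = False
    next_label = 1
    for i in range(config.n_nuclei):
        clumped = placed_centers and rng.random() < config.clump_fraction
        a = rng.uniform(*config.radius_range)
        ecc = rng.uniform(*config.eccentricity_range)
        b = a / ecc
        stamp, profile, half = _nucleus_stamp(rng, a, b)
        brightness = rng.uniform(0.75, 1.2)
        placed = False
        for _attempt in range(60):
            if clumped:
                r0, c0, r_prev = placed_centers[rng.integers(len(placed_centers))]
                ang = rng.uniform(0, 2 * np.pi)
                dist = (r_prev + 0.5 * (a + b)) * rng.uniform(0.80, 0.95)
                cy = int(round(r0 + dist * np.sin(ang)))
                cx = int(round(c0 + dist * np.cos(ang)))
            else:
                cy = int(round(rng.uniform(half, H - 1 - half))) if H > 2 * half else H // 2
                cx = int(round(rng.uniform(half, W - 1 - half))) if W > 2 * half else W // 2
            top, left = cy - half, cx - half
            if top < 0 or left < 0 or top + stamp.shape[0] > H or left + stamp.shape[1] > W:
                continue
            sl = (slice(top, top + stamp.shape[0]), slice(left, left + stamp.shape[1]))
            occupied = labels[sl] > 0
            cand = stamp & ~occupied
            if not cand.any():
                continue
            if clumped:
                # keep the largest connected piece after ceding overlap
                cc, n_cc = ndimage.label(cand, structure=struct)
                if n_cc > 1:
                    sizes = ndimage.sum_labels(np.ones_like(cc), cc, index=range(1, n_cc + 1))
                    cand = cc == (1 + int(np.argmax(sizes)))
                touching = (ndimage.binary_dilation(cand, struct) & occupied).any()
                if not touching:
                    continue
            else:
                if (ndimage.binary_dilation(cand, struct) & (labels > 0)[sl]).any():
                    continue
            labels[sl][cand] = next_label
            signal[sl][cand] = brightness * profile[cand]
            placed_centers.append((cy, cx, 0.5 * (a + b)))
            next_label += 1
            placed = True
            break
        if not placed:
            shortfall = True

    # scale the unit-profile signal so mean in-nucleus signal = snr * sigma
    sigma = config.noise_sigma
    if labels.any():
        signal *= config.snr * sigma / signal[labels > 0].mean()
    image = config.background_level + signal
    if config.poisson_noise:
        image = rng.poisson(np.maximum(image, 0)).astype(np.float64)
    image = image + rng.normal(0.0, sigma, size=image.shape)
    image = np.clip(image, 0.0, None)

    return SynthSample(
        image=GrayImage(pixels=image, dtype_bits="float"),
        truth=InstanceMask(labels=labels),
        config=config,
        placement_shortfall=shortfall,
    )


def measure_snr(sample: SynthSample) -> float:
    """Empirical SNR: (mean in-nucleus - mean background) / background SD."""
    fg = sample.truth.foreground()
    img = sample.image.pixels
    if not fg.any() or fg.all():
        raise ValueError("sample must contain both nucleus and background pixels")
    return float((img[fg].mean() - img[~fg].mean()) / img[~fg].std())


def _sample_seed(master: int, split_index: int, i: int) -> int:
    ss = np.random.SeedSequence([int(master), split_index, i])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(config: SynthConfig, n_train: int, n_val: int, n_test: int,
                     out_dir) -> Path:
    """Write a train/val/test dataset and return the manifest path.

    Per-sample seeds are derived deterministically from ``config.rng_seed``
    and the sample's split and index, so the same master seed reproduces
    the dataset bit for bit.  Images are stored as 16-bit TIFF, masks via
    the standard label-map writer, and a tab-separated manifest
    (``split  image_path  mask_path  seed``) indexes all pairs.
    """
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise IOFailure(f"parent of {out_dir} does not exist")
    out_dir.mkdir(exist_ok=True)
    rows = []
    for split_index, (split, n) in enumerate(
            [("train", n_train), ("val", n_val), ("test", n_test)]):
        if n < 0:
            raise ValueError("split counts must be non-negative")
        sub = out_dir / split
        sub.mkdir(exist_ok=True)
        for i in range(n):
            seed = _sample_seed(config.rng_seed, split_index, i)
            sample = generate_nuclei_image(dataclasses.replace(config, rng_seed=seed))
            img16 = GrayImage(
                pixels=np.clip(np.round(sample.image.pixels), 0, 65535).astype(np.uint16),
                dtype_bits=16)
            image_path = sub / f"image_{i:04d}.tif"
            mask_path = sub / f"mask_{i:04d}.tif"
            write_image(img16, image_path)
            write_label_map(sample.truth, mask_path)
            rows.append((split, str(image_path), str(mask_path), seed))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("split\timage_path\tmask_path\tseed\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest


#: split sizes of the emulated benchmark partition (train, val, test)
PRESET_SPLITS = {
    "bbbc039-like": (100, 50, 50),
    "low-snr": (7, 0, 3),
}


def preset(name: str) -> tuple[SynthConfig, tuple[int, int, int]]:
    """Named generation presets for the two emulated data regimes."""
    if name == "bbbc039-like":
        cfg = SynthConfig(image_height=520, image_width=696,
                          density_mode="medium", snr=8.0)
        return cfg, PRESET_SPLITS[name]
    if name == "low-snr":
        cfg = SynthConfig(image_height=256, image_width=256,
                          density_mode="low", snr=2.0)
        return cfg, PRESET_SPLITS[name]
    raise ValueError(f"unknown preset {name!r}")
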