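"""Convert 3-class probability maps into instance label maps.

The main method is *interior expansion*, a synchronized seeded region
growing on the probability field: connected components of
p_interior > 0.5 are seeds; every iteration each seed's frontier may
claim adjacent pixels while climbing the boundary-probability ridge
(candidate boundary probability non-decreasing relative to the claiming
pixel, or the candidate is interior-dominant); a pixel claimable by two
different seeds in the same iteration is a contested ridge pixel and
stays unassigned forever; and once a seed stops growing, the pixels it
claimed in its final (ridge-top) iteration are discarded, which leaves a
one-pixel-wide gap along the true boundary ridge.  Marker-controlled
watershed and plain argmax thresholding are provided as ablation
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import ShapeError
from .io import BACKGROUND, INTERIOR, InstanceMask, ProbMap

__all__ = [
    "PostprocessConfig",
    "seed_from_interior",
    "interior_expansion",
    "watershed_postprocess",
    "threshold_labeling",
    "run_postprocess",
]

_EPS_RIDGE = 1e-6  # plateau tolerance for the non-decreasing ridge climb


@dataclass
class PostprocessConfig:
    seed_threshold: float = 0.5
    connectivity: int = 8
    max_iterations: int | None = None  # default: image diagonal
    method: str = "interior_expansion"

    def __post_init__(self):
        if not 0.0 < self.seed_threshold < 1.0:
            raise ValueError("seed_threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.method not in ("interior_expansion", "watershed", "threshold"):
            raise ValueError(f"unknown method {self.method!r}")


def _structure(connectivity: int) -> np.ndarray:
    return (np.ones((3, 3), bool) if connectivity == 8
            else ndimage.generate_binary_structure(2, 1))


def _offsets(connectivity: int) -> list[tuple[int, int]]:
    if connectivity == 4:
        return [(-1, 0), (1, 0), (0, -1), (0, 1)]
    return [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)]


def seed_from_interior(prob: ProbMap,
                       config: PostprocessConfig | None = None) -> InstanceMask:
    """Label connected components of p_interior strictly above threshold."""
    config = config or PostprocessConfig()
    seeds = prob.p_interior > config.seed_threshold  # strict
    labels, _ = ndimage.label(seeds, structure=_structure(config.connectivity))
    return InstanceMask(labels=labels.astype(np.int32))


def interior_expansion(prob: ProbMap, seeds: InstanceMask | None = None,
                       config: PostprocessConfig | None = None) -> InstanceMask:
    """Grow interior seeds to the boundary-probability ridge.

    See the module docstring for the growth rules.  The output is the
    union of the original seed pixels and the retained expansion pixels;
    instances are pairwise disjoint and connected under the configured
    connectivity.
    """
    config = config or PostprocessConfig()
    if seeds is None:
        seeds = seed_from_interior(prob, config)
    if seeds.shape != prob.shape:
        raise ShapeError("seeds and probability map must share shape")
    H, W = prob.shape
    max_iter = config.max_iterations or int(np.ceil(np.hypot(H, W)))

    labels = seeds.labels.astype(np.int32).copy()
    n_labels = int(labels.max(initial=0))
    if n_labels == 0:
        return InstanceMask(labels=labels)
    pb = prob.p_boundary.astype(np.float64)
    arg = prob.argmax_classes()
    expandable = arg != BACKGROUND           # background-dominant pixels are never claimed
    interior_dom = arg == INTERIOR
    blocked = np.zeros((H, W), dtype=bool)   # contested ridge pixels
    claim_iter = np.zeros((H, W), dtype=np.int32)
    last_claim = np.zeros(n_labels + 1, dtype=np.int32)  # per label

    frontier = labels > 0
    offsets = _offsets(config.connectivity)
    for it in range(1, max_iter + 1):
        new_label = np.zeros((H, W), dtype=np.int32)
        contested = np.zeros((H, W), dtype=bool)
        open_pix = (labels == 0) & ~blocked & expandable
        for dr, dc in offsets:
            # q = p + (dr, dc): source slice (p) and destination slice (q)
            src = (slice(max(-dr, 0), H - max(dr, 0)),
                   slice(max(-dc, 0), W - max(dc, 0)))
            dst = (slice(max(dr, 0), H + min(dr, 0)),
                   slice(max(dc, 0), W + min(dc, 0)))
            p_is_front = frontier[src]
            q_open = open_pix[dst]
            ridge_ok = (pb[dst] >= pb[src] - _EPS_RIDGE) | interior_dom[dst]
            claim = p_is_front & q_open & ridge_ok
            if not claim.any():
                continue
            src_lab = labels[src]
            nl = new_label[dst]
            ct = contested[dst]
            newly = claim & (nl == 0) & ~ct
            conflict = claim & (nl != 0) & (nl != src_lab)
            nl[newly] = src_lab[newly]
            ct[conflict] = True
            new_label[dst] = nl
            contested[dst] = ct
        new_label[contested] = 0
        blocked |= contested
        claimed = new_label > 0
        if not claimed.any() and not contested.any():
            break
        labels[claimed] = new_label[claimed]
        claim_iter[claimed] = it
        for lab in np.unique(new_label[claimed]):
            last_claim[lab] = it
        frontier = claimed

    # discard each label's final (ridge-top) claiming layer
    ridge_top = (labels > 0) & (claim_iter > 0) & (claim_iter == last_claim[labels])
    labels[ridge_top] = 0
    return InstanceMask(labels=labels)


def watershed_postprocess(prob: ProbMap,
                          config: PostprocessConfig | None = None) -> InstanceMask:
    """Marker-controlled watershed on the boundary-minus-interior elevation.

    Markers are the interior seeds; flooding is restricted to pixels
    where background is not the dominant class.
    """
    config = config or PostprocessConfig()
    seeds = seed_from_interior(prob, config)
    if seeds.n_instances == 0:
        return InstanceMask(labels=np.zeros(prob.shape, dtype=np.int32))
    elevation = prob.p_boundary - prob.p_interior
    mask = prob.argmax_classes() != BACKGROUND
    out = watershed(elevation, markers=seeds.labels, mask=mask,
                    connectivity=2 if config.connectivity == 8 else 1)
    return InstanceMask(labels=out.astype(np.int32))


def threshold_labeling(prob: ProbMap,
                       config: PostprocessConfig | None = None) -> InstanceMask:
    """Connected components of the argmax-interior class.

    Boundary-dominant pixels are excluded, which is what separates
    clumped nuclei in this baseline.
    """
    config = config or PostprocessConfig()
    interior = prob.argmax_classes() == INTERIOR
    labels, _ = ndimage.label(interior, structure=_structure(config.connectivity))
    return InstanceMask(labels=labels.astype(np.int32))


def run_postprocess(prob: ProbMap, config: PostprocessConfig) -> InstanceMask:
    """Dispatch on ``config.method``."""
    if config.method == "interior_expansion":
        return interior_expansion(prob, config=config)
    if config.method == "watershed":
        return watershed_postprocess(prob, config=config)
    return threshold_labeling(prob, config=config)
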