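import numpy as np
import pytest
from scipy import ndimage

from aswnet.errors import ShapeError
from aswnet.io import InstanceMask, ProbMap
from aswnet.metrics import aji
from aswnet.postprocess import (PostprocessConfig, interior_expansion,
                                run_postprocess, seed_from_interior,
                                threshold_labeling, watershed_postprocess)
from aswnet.synthetic import SynthConfig, generate_nuclei_image
from conftest import ideal_prob_map
from oracles import flood_fill_count


def prob_from_interior(p_int: np.ndarray) -> ProbMap:
    """Probability map with the remaining mass on background."""
    probs = np.zeros((3,) + p_int.shape, np.float32)
    probs[1] = p_int
    probs[0] = 1.0 - p_int
    return ProbMap(probs=probs)


class TestSeeding:
    def test_all_below_threshold_gives_empty(self):
        pm = prob_from_interior(np.full((8, 8), 0.4, np.float32))
        assert seed_from_interior(pm).n_instances == 0

    def test_threshold_is_strict(self):
        pm = prob_from_interior(np.full((8, 8), 0.5, np.float32))
        assert seed_from_interior(pm).n_instances == 0

    def test_two_blobs_match_flood_fill_oracle(self):
        p = np.zeros((16, 16), np.float32)
        p[2:5, 2:5] = 0.9
        p[10:13, 10:14] = 0.9
        pm = prob_from_interior(p)
        seeds = seed_from_interior(pm)
        assert seeds.n_instances == flood_fill_count(p > 0.5) == 2


class TestInteriorExpansion:
    def test_no_admissible_expansion_returns_seeds(self):
        p = np.zeros((12, 12), np.float32)
        p[4:8, 4:8] = 1.0
        pm = prob_from_interior(p)  # background certain elsewhere
        out = interior_expansion(pm)
        np.testing.assert_array_equal(out.labels > 0, p > 0.5)

    def test_single_disk_recovered_with_high_iou(self):
        """Ideal probability map of one disk: output IoU vs truth >= 0.9."""
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2)
        truth = InstanceMask(disk.astype(np.int32))
        out = interior_expansion(ideal_prob_map(truth, 2))
        assert out.n_instances == 1
        pred = out.labels > 0
        iou = (pred & disk).sum() / (pred | disk).sum()
        assert iou >= 0.9

    def test_contested_ridge_stays_unassigned(self):
        """Two nuclei abutting a 1-px boundary ridge: both seeds reach the
        ridge in the same iteration, so it is contested and left unlabeled."""
        probs = np.zeros((3, 10, 13), np.float32)
        probs[1, 2:8, 2:6] = 1.0    # interior of nucleus A
        probs[1, 2:8, 7:11] = 1.0   # interior of nucleus B
        probs[2, 2:8, 6] = 1.0      # shared boundary ridge, one pixel wide
        probs[0] = 1.0 - probs[1] - probs[2]
        out = interior_expansion(ProbMap(probs=probs))
        assert out.n_instances == 2
        assert np.all(out.labels[2:8, 6] == 0)  # ridge unassigned
        a = out.labels[2:8, 2:6]
        b = out.labels[2:8, 7:11]
        assert len(np.unique(a)) == 1 and len(np.unique(b)) == 1
        assert a[0, 0] != b[0, 0]

    def test_clumped_truth_recovered_as_distinct_instances(self):
        cfg = SynthConfig(image_height=128, image_width=128, n_nuclei=2,
                          clump_fraction=1.0, radius_range=(12, 16), rng_seed=21)
        sample = generate_nuclei_image(cfg)
        assert sample.truth.n_instances == 2
        out = interior_expansion(ideal_prob_map(sample.truth, 2))
        assert out.n_instances == 2
        # each output instance overlaps exactly one ground-truth nucleus
        for lab in out.instance_labels:
            covered = sample.truth.labels[out.labels == lab]
            assert len(np.unique(covered[covered > 0])) == 1

    def test_instances_connected_and_contain_seeds(self, small_sample):
        pm = ideal_prob_map(small_sample.truth, 2)
        seeds = seed_from_interior(pm)
        out = interior_expansion(pm, seeds)
        struct = np.ones((3, 3), bool)
        for lab in out.instance_labels:
            inst = out.labels == lab
            _, n = ndimage.label(inst, structure=struct)
            assert n == 1
        # original seed pixels keep their labels
        seeded = seeds.labels > 0
        np.testing.assert_array_equal(out.labels[seeded], seeds.labels[seeded])

    def test_beats_threshold_labeling_on_ideal_maps(self, small_sample):
        pm = ideal_prob_map(small_sample.truth, 2)
        truth = small_sample.truth
        assert aji(interior_expansion(pm), truth) >= aji(threshold_labeling(pm), truth)

    def test_terminates_on_random_fields(self, rng):
        raw = rng.random((3, 32, 32)).astype(np.float32)
        pm = ProbMap(probs=raw / raw.sum(0, keepdims=True))
        cfg = PostprocessConfig(max_iterations=64)
        out = interior_expansion(pm, config=cfg)
        assert out.labels.shape == (32, 32)

    def test_shape_mismatch_raises(self):
        pm = prob_from_interior(np.zeros((8, 8), np.float32))
        seeds = InstanceMask(np.zeros((6, 6), np.int32))
        with pytest.raises(ShapeError):
            interior_expansion(pm, seeds)


class TestWatershed:
    def test_single_blob_covers_foreground(self):
        p = np.zeros((16, 16), np.float32)
        p[5:10, 5:10] = 0.9
        out = watershed_postprocess(prob_from_interior(p))
        assert out.n_instances == 1
        np.testing.assert_array_equal(out.labels > 0, p > 0.4)

    def test_two_nuclei_disjoint(self, small_sample):
        out = watershed_postprocess(ideal_prob_map(small_sample.truth, 2))
        assert out.n_instances == small_sample.truth.n_instances

    def test_empty_seeds_empty_output(self):
        pm = prob_from_interior(np.zeros((8, 8), np.float32))
        assert watershed_postprocess(pm).n_instances == 0


class TestThresholdLabeling:
    def test_all_background_empty(self):
        pm = prob_from_interior(np.zeros((8, 8), np.float32))
        assert threshold_labeling(pm).n_instances == 0

    def test_boundary_ridge_separates_components(self):
        probs = np.zeros((3, 8, 12), np.float32)
        probs[1, 2:6, 2:5] = 1.0
        probs[1, 2:6, 7:10] = 1.0
        probs[2, 2:6, 5:7] = 1.0  # boundary-dominant ridge
        probs[0] = 1.0 - probs[1] - probs[2]
        out = threshold_labeling(ProbMap(probs=probs))
        assert out.n_instances == 2

    def test_agrees_with_seeding_when_sets_coincide(self):
        p = np.zeros((10, 10), np.float32)
        p[3:7, 3:7] = 0.9
        pm = prob_from_interior(p)
        np.testing.assert_array_equal(
            threshold_labeling(pm).labels, seed_from_interior(pm).labels)


def test_run_postprocess_dispatch(small_sample):
    pm = ideal_prob_map(small_sample.truth, 2)
    for method in ("interior_expansion", "watershed", "threshold"):
        out = run_postprocess(pm, PostprocessConfig(method=method))
        assert out.shape == pm.shape
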