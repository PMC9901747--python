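import numpy as np
import pytest

from calscreen.evaluation import (
    iom,
    match_regions,
    metric_sweep,
    precision_recall_fscore,
)
from calscreen.types import LabelImage

from oracles import iom_sets, optimal_matching


def label_image(shape, masks: dict):
    lbl = np.zeros(shape, dtype=np.int32)
    for k, pix in masks.items():
        for y, x in pix:
            lbl[y, x] = k
    return LabelImage(lbl)


def random_label_image(rng, shape, n_blobs, radius=2.5):
    lbl = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for k in range(1, n_blobs + 1):
        cy, cx = rng.uniform(0, shape[0] - 1), rng.uniform(0, shape[1] - 1)
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= rng.uniform(1, radius) ** 2
        lbl[m] = k  # later blobs may overwrite earlier ones
    return LabelImage(lbl)


def masks_as_sets(lbl: LabelImage):
    d = lbl.data
    return {
        int(k): {(int(y), int(x)) for y, x in zip(*np.nonzero(d == k))}
        for k in np.unique(d)
        if k > 0
    }


class TestIoM:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:4] = True
        assert iom(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = b[4, 4] = True
        assert iom(a, b) == 0.0

    def test_containment_saturates(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2:4, 2:4] = True  # 4 px
        b[1:6, 1:6] = True  # 25 px, contains a
        assert iom(a, b) == 1.0

    def test_half_overlap_count(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5, :20] = True  # 100 px
        b[2:12, :20] = True  # 200 px
        # intersection rows 2..4 -> 60 px; by construction scale to 50/100
        a2 = np.zeros((30, 30), bool)
        b2 = np.zeros((30, 30), bool)
        a2[0:10, 0:10] = True  # 100
        b2[5:25, 0:10] = True  # 200
        assert iom(a2, b2) == 0.5  # intersection 50 / min(100, 200)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            iom(np.zeros((3, 3), bool), np.ones((3, 3), bool))

    def test_matches_set_oracle_on_random_masks(self, rng):
        for _ in range(100):
            a = rng.random((6, 6)) < 0.4
            b = rng.random((6, 6)) < 0.4
            if not a.any() or not b.any():
                continue
            sa = {(int(y), int(x)) for y, x in zip(*np.nonzero(a))}
            sb = {(int(y), int(x)) for y, x in zip(*np.nonzero(b))}
            assert iom(a, b) == pytest.approx(iom_sets(sa, sb))


class TestMatchRegions:
    def test_perfect_segmentation(self, rng):
        gt = random_label_image(rng, (16, 16), 3)
        rep = match_regions(gt, gt, 0.5)
        assert (rep.precision, rep.recall, rep.fscore) == (1.0, 1.0, 1.0)

    def test_two_matches_one_extra_segment(self):
        gts = {1: {(0, 0), (0, 1)}, 2: {(5, 5), (5, 6)}}
        segs = dict(gts)
        segs[3] = {(10, 10), (10, 11)}
        rep = match_regions(
            label_image((16, 16), segs), label_image((16, 16), gts), 0.5
        )
        assert (rep.tp, rep.fp, rep.fn) == (2, 1, 0)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == 1.0
        assert rep.fscore == pytest.approx(0.8)

    def test_straddling_segment_gives_one_tp(self):
        # one segment covering two ground truths: one-to-one allows one TP
        seg = {1: {(0, x) for x in range(10)}}
        gts = {1: {(0, x) for x in range(4)}, 2: {(0, x) for x in range(6, 10)}}
        rep = match_regions(
            label_image((4, 12), seg), label_image((4, 12), gts), 0.5
        )
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 1)

    def test_strict_inequality_at_threshold(self):
        # IoM exactly 0.5 is NOT a true positive ("larger than")
        seg = {1: {(0, 0), (0, 1)}}
        gt = {1: {(0, 1), (0, 2)}}
        at = match_regions(label_image((2, 4), seg), label_image((2, 4), gt), 0.5)
        below = match_regions(label_image((2, 4), seg), label_image((2, 4), gt), 0.49)
        assert at.tp == 0 and below.tp == 1

    def test_counts_partition_segments_and_truths(self, rng):
        for _ in range(30):
            seg = random_label_image(rng, (14, 14), int(rng.integers(0, 5)))
            gt = random_label_image(rng, (14, 14), int(rng.integers(0, 5)))
            rep = match_regions(seg, gt, 0.3)
            assert rep.tp + rep.fp == seg.n_rois
            assert rep.tp + rep.fn == gt.n_rois

    def test_greedy_equals_exhaustive_optimal(self, rng):
        for _ in range(100):
            seg = random_label_image(rng, (8, 8), int(rng.integers(1, 4)))
            gt = random_label_image(rng, (8, 8), int(rng.integers(1, 4)))
            for thr in (0.1, 0.5):
                rep = match_regions(seg, gt, thr)
                tp, fp, fn, _ = optimal_matching(
                    masks_as_sets(seg), masks_as_sets(gt), thr
                )
                assert (rep.tp, rep.fp, rep.fn) == (tp, fp, fn)


class TestMetricSweep:
    LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.7)

    def test_perfect_segmentation_all_levels(self, rng):
        gt = random_label_image(rng, (16, 16), 4)
        reps = metric_sweep(gt, gt, self.LEVELS)
        assert [r.fscore for r in reps] == [1.0] * 6

    def test_intermediate_overlap_flips_at_threshold(self):
        # segment/GT pairs built with IoM exactly 0.45
        seg = {1: {(0, x) for x in range(20)}}  # 20 px
        gt = {1: {(0, x) for x in range(9)} | {(1, x) for x in range(11)}}  # 20 px
        # intersection = 9 px -> IoM = 0.45
        reps = metric_sweep(
            label_image((4, 24), seg), label_image((4, 24), gt), self.LEVELS
        )
        for rep in reps:
            if rep.iom_threshold <= 0.4:
                assert rep.tp == 1
            else:
                assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)

    def test_fscore_non_increasing(self, rng):
        for _ in range(20):
            seg = random_label_image(rng, (16, 16), int(rng.integers(1, 5)))
            gt = random_label_image(rng, (16, 16), int(rng.integers(1, 5)))
            fs = [r.fscore for r in metric_sweep(seg, gt, self.LEVELS)]
            assert all(a >= b - 1e-12 for a, b in zip(fs, fs[1:]))


class TestConventions:
    def test_fscore_between_min_and_max_of_p_r(self):
        p, r, f = precision_recall_fscore(3, 1, 2)
        assert min(p, r) <= f <= max(p, r)

    def test_zero_conventions(self):
        assert precision_recall_fscore(0, 0, 0) == (0.0, 0.0, 0.0)
        assert precision_recall_fscore(0, 2, 3)[2] == 0.0
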