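import numpy as np
import pytest

from calscreen.features import (
    FeatureImage,
    build_dataset,
    extract_traces,
    resize_bicubic,
    resize_flatten,
    shuffle_rows,
    split_by_video,
    to_arrays,
)
from calscreen.types import LabelImage, VideoStack

from oracles import trace_loop


def make_stack(arr):
    return VideoStack(np.asarray(arr, dtype=np.uint16))


class TestExtractTraces:
    def test_constant_stack(self):
        stack = make_stack(np.full((5, 6, 6), 321))
        lbl = LabelImage(np.kron(np.array([[1, 2], [0, 0]]), np.ones((3, 3), int)))
        tm = extract_traces(stack, lbl)
        assert tm.values.shape == (2, 5)
        assert np.all(tm.values == 321)

    def test_single_pixel_roi_equals_pixel_series(self, rng):
        data = rng.integers(0, 65536, size=(8, 4, 4)).astype(np.uint16)
        lbl = np.zeros((4, 4), int)
        lbl[2, 3] = 1
        tm = extract_traces(make_stack(data), LabelImage(lbl))
        assert np.array_equal(tm.values[0], data[:, 2, 3].astype(float))

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            data = rng.integers(0, 65536, size=(6, 8, 8)).astype(np.uint16)
            lbl = rng.integers(0, 3, size=(8, 8))
            if lbl.max() == 0:
                continue
            tm = extract_traces(make_stack(data), LabelImage(lbl))
            ids, rows = trace_loop(data.tolist(), lbl.tolist())
            assert tm.roi_ids == ids
            assert np.allclose(tm.values, rows)

    def test_shape_mismatch_rejected(self, rng):
        stack = make_stack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            extract_traces(stack, LabelImage(np.ones((5, 5), int)))

    def test_empty_label_image_rejected(self):
        stack = make_stack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            extract_traces(stack, LabelImage(np.zeros((4, 4), int)))


class TestShuffleRows:
    def test_preserves_row_multiset_and_sums(self, rng):
        fi = FeatureImage(rng.random((7, 20)), class_label=1)
        outs = shuffle_rows(fi, 200, seed=5)
        assert len(outs) == 200
        base = sorted(map(tuple, fi.values))
        for out in outs[:10]:
            assert sorted(map(tuple, out.values)) == base
            assert out.class_label == 1
        assert np.allclose(
            sorted(outs[3].values.sum(axis=1)), sorted(fi.values.sum(axis=1))
        )

    def test_single_row_invariant(self, rng):
        fi = FeatureImage(rng.random((1, 10)))
        for out in shuffle_rows(fi, 5, seed=0):
            assert np.array_equal(out.values, fi.values)

    def test_seed_determinism(self, rng):
        fi = FeatureImage(rng.random((9, 12)))
        a = shuffle_rows(fi, 6, seed=42)
        b = shuffle_rows(fi, 6, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)


class TestResizeFlatten:
    def test_identity_resize_reproduces_input(self, rng):
        arr = rng.random((10, 14))
        assert np.allclose(resize_bicubic(arr, 10, 14), arr)

    def test_constant_image_stays_constant(self):
        fi = FeatureImage(np.full((32, 128), 5.0), class_label=0)
        out = resize_flatten(fi)
        assert out.vector.shape == (4096,)
        assert np.allclose(out.vector, 0.0)  # constant -> normalized to zero
        raw = resize_flatten(fi, normalize=False)
        assert np.allclose(raw.vector, 5.0)

    def test_linear_ramp_preserved_in_interior(self):
        # cubic convolution has linear precision away from clamped edges
        ramp = np.tile(np.arange(40.0), (6, 1))
        out = resize_bicubic(ramp, 6, 20)
        interior = out[:, 2:-2]
        diffs = np.diff(interior, axis=1)
        assert np.allclose(diffs, diffs[0, 0])

    def test_default_output_length(self, rng):
        fi = FeatureImage(rng.random((23, 310)), class_label=1)
        assert resize_flatten(fi).vector.shape == (4096,)

    def test_row_permutation_changes_vector(self, rng):
        values = rng.random((12, 60))
        a = resize_flatten(FeatureImage(values, class_label=0))
        b = resize_flatten(FeatureImage(values[::-1], class_label=0))
        assert not np.allclose(a.vector, b.vector)


class TestBuildDataset:
    def _images(self, rng, n_disease, n_control, T=30):
        out = []
        for i in range(n_disease + n_control):
            out.append(
                FeatureImage(
                    rng.random((int(rng.integers(4, 9)), T)),
                    class_label=1 if i < n_disease else 0,
                    video_id=f"video_{i:03d}",
                )
            )
        return out

    def test_size_and_provenance(self, rng):
        samples = build_dataset(self._images(rng, 2, 2), 3, shuffle_seed=0)
        assert len(samples) == 12
        prov = {(s.video_id, s.shuffle_index) for s in samples}
        assert len(prov) == 12

    def test_class_balance_scales_with_shuffles(self, rng):
        samples = build_dataset(self._images(rng, 3, 2), 4, shuffle_seed=1)
        labels = [s.class_label for s in samples]
        assert labels.count(1) == 12 and labels.count(0) == 8

    def test_unlabeled_input_rejected(self, rng):
        fis = self._images(rng, 1, 1)
        fis[0].class_label = None
        with pytest.raises(ValueError):
            build_dataset(fis, 2, shuffle_seed=0)


class TestSplitByVideo:
    def _samples(self, rng, n_disease=6, n_control=4, n_shuffles=5):
        fis = TestBuildDataset()._images(rng, n_disease, n_control)
        return build_dataset(fis, n_shuffles, shuffle_seed=0)

    def test_no_video_leakage(self, rng):
        train, test = split_by_video(self._samples(rng), {1: 4, 0: 3}, seed=7)
        assert {s.video_id for s in train} & {s.video_id for s in test} == set()

    def test_train_fraction(self, rng):
        samples = self._samples(rng)
        train, test = split_by_video(samples, {1: 4, 0: 3}, seed=7)
        assert len(train) == 7 * 5 and len(test) == 3 * 5

    def test_impossible_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            split_by_video(self._samples(rng), {1: 7, 0: 1}, seed=0)

    def test_deterministic_given_seed(self, rng):
        samples = self._samples(rng)
        a = split_by_video(samples, {1: 4, 0: 2}, seed=3)
        b = split_by_video(samples, {1: 4, 0: 2}, seed=3)
        assert [s.video_id for s in a[0]] == [s.video_id for s in b[0]]

    def test_to_arrays_shapes(self, rng):
        samples = self._samples(rng)
        X, y, vids = to_arrays(samples)
        assert X.shape == (50, 4096) and y.shape == (50,) and vids.shape == (50,)
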