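"""From ROIs to classifier-ready vectors.

Each detected ROI yields a fluorescence trace (mean raw 16-bit intensity per
frame); stacking the traces of one recording row-wise gives its *feature
image*, a K×T matrix carrying the video's class label.  Because every ROI in
a recording shares the same treatment, randomly permuting the rows produces
additional class-preserving samples; each shuffled matrix is resized to a
fixed 32×128 raster with bicubic interpolation and flattened to a length-4096
vector.  Samples are split into train and test at the *video* level so that
shuffled copies of one recording never appear on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LabelImage, VideoStack


@dataclass
class TraceMatrix:
    """K×T matrix of per-ROI mean intensities on the raw 16-bit scale."""

    values: np.ndarray
    roi_ids: list[int]
    video_id: str | None = None
    class_label: int | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (ROIs x time)")
        if values.min() < 0:
            raise ValueError("trace intensities must be non-negative")
        self.values = values


@dataclass
class FeatureImage:
    """Rows = ROI traces, columns = time points; one per recording."""

    values: np.ndarray
    class_label: int | None = None
    video_id: str | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("feature image must be a non-empty 2-D matrix")
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AugmentedSample:
    """One flattened, resized, shuffled feature image."""

    vector: np.ndarray
    class_label: int
    video_id: str | None = None
    shuffle_index: int = 0


def extract_traces(stack: VideoStack, labels: LabelImage) -> TraceMatrix:
    """Mean raw intensity inside each ROI, per frame."""
    lbl = labels.data
    if lbl.shape != stack.frame_shape:
        raise ValueError("label image shape does not match the stack frames")
    ids = np.unique(lbl)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label image contains no ROIs")
    flat = lbl.ravel()
    counts = np.bincount(flat, minlength=int(ids.max()) + 1)
    T = stack.n_frames
    values = np.empty((ids.size, T), dtype=np.float64)
    for t in range(T):
        sums = np.bincount(
            flat, weights=stack.data[t].ravel(), minlength=int(ids.max()) + 1
        )
        values[:, t] = sums[ids] / counts[ids]
    return TraceMatrix(values, roi_ids=[int(i) for i in ids])


def feature_image(
    traces: TraceMatrix,
    class_label: int | None = None,
    video_id: str | None = None,
) -> FeatureImage:
    return FeatureImage(
        traces.values.copy(),
        class_label=class_label if class_label is not None else traces.class_label,
        video_id=video_id if video_id is not None else traces.video_id,
    )


def shuffle_rows(fi: FeatureImage, n: int, seed: int) -> list[FeatureImage]:
    """``n`` independent row permutations of one feature image."""
    if n < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        perm = rng.permutation(fi.values.shape[0])
        out.append(
            FeatureImage(fi.values[perm], class_label=fi.class_label, video_id=fi.video_id)
        )
    return out


def _cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic-convolution (Catmull-Rom for a = -0.5) interpolation kernel."""
    x = np.abs(x)
    return np.where(
        x <= 1,
        (a + 2) * x**3 - (a + 3) * x**2 + 1,
        np.where(x < 2, a * (x**3 - 5 * x**2 + 8 * x - 4), 0.0),
    )


def _resample_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
    """4-tap indices and weights mapping n_in samples to n_out (edge-clamped)."""
    scale = n_in / n_out
    x = (np.arange(n_out) + 0.5) * scale - 0.5  # pixel-centre alignment
    base = np.floor(x).astype(np.int64)
    idx = base[:, None] + np.array([-1, 0, 1, 2])[None, :]
    w = _cubic_kernel(x[:, None] - idx)
    w /= w.sum(axis=1, keepdims=True)
    return np.clip(idx, 0, n_in - 1), w


def resize_bicubic(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable cubic-convolution resize, no antialias prefilter."""
    arr = np.asarray(arr, dtype=np.float64)
    idx_r, w_r = _resample_weights(arr.shape[0], out_h)
    tmp = np.einsum("ok,okw->ow", w_r, arr[idx_r, :])
    idx_c, w_c = _resample_weights(arr.shape[1], out_w)
    return np.einsum("ok,hok->ho", w_c, tmp[:, idx_c])


def resize_flatten(
    fi: FeatureImage,
    width: int = 128,
    height: int = 32,
    normalize: bool = True,
) -> AugmentedSample:
    """Resize a feature image to height×width and flatten it row-major.

    When ``normalize`` is set (the default) the matrix is min-max scaled to
    [0, 1] before resizing and clipped back to [0, 1] afterwards (bicubic
    interpolation can overshoot); a constant matrix maps to all zeros.
    """
    values = fi.values
    if normalize:
        lo, hi = values.min(), values.max()
        values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    out = resize_bicubic(values, height, width)
    if normalize:
        out = np.clip(out, 0.0, 1.0)
    return AugmentedSample(
        vector=out.ravel(),
        class_label=fi.class_label if fi.class_label is not None else -1,
        video_id=fi.video_id,
    )


def build_dataset(
    feature_images: list[FeatureImage],
    n_shuffles: int,
    shuffle_seed: int,
    width: int = 128,
    height: int = 32,
    normalize: bool = True,
) -> list[AugmentedSample]:
    """videos × n_shuffles augmented samples with (video, shuffle) provenance."""
    for fi in feature_images:
        if fi.class_label is None:
            raise ValueError(f"feature image {fi.video_id!r} has no class label")
    seeds = np.random.SeedSequence(shuffle_seed).spawn(len(feature_images))
    samples: list[AugmentedSample] = []
    for fi, seq in zip(feature_images, seeds):
        rng_seed = int(seq.generate_state(1)[0] % (2**31))
        for j, shuffled in enumerate(shuffle_rows(fi, n_shuffles, rng_seed)):
            s = resize_flatten(shuffled, width=width, height=height, normalize=normalize)
            s.shuffle_index = j
            samples.append(s)
    return samples


def split_by_video(
    samples: list[AugmentedSample],
    train_counts: dict[int, int],
    seed: int,
) -> tuple[list[AugmentedSample], list[AugmentedSample]]:
    """Video-level train/test split: all samples of a video land together.

    ``train_counts`` maps class label -> number of *videos* of that class to
    place in training (the published split is {1: 15, 0: 7} for a 21 + 12
    video study).
    """
    by_class: dict[int, list[str]] = {}
    video_class: dict[str, int] = {}
    for s in samples:
        if s.video_id is None:
            raise ValueError("samples need video ids for a video-level split")
        if s.video_id in video_class:
            if video_class[s.video_id] != s.class_label:
                raise ValueError(f"video {s.video_id} has inconsistent labels")
        else:
            video_class[s.video_id] = s.class_label
            by_class.setdefault(s.class_label, []).append(s.video_id)

    rng = np.random.default_rng(seed)
    train_videos: set[str] = set()
    for label, count in sorted(train_counts.items()):
        vids = sorted(by_class.get(label, []))
        if not (0 < count <= len(vids)):
            raise ValueError(
                f"cannot place {count} training videos for class {label} "
                f"(have {len(vids)})"
            )
        train_videos.update(rng.choice(vids, size=count, replace=False).tolist())

    train = [s for s in samples if s.video_id in train_videos]
    test = [s for s in samples if s.video_id not in train_videos]
    return train, test


def to_arrays(samples: list[AugmentedSample]):
    """Stack samples into (X, y, video_ids) arrays for the classifiers."""
    X = np.stack([s.vector for s in samples])
    y = np.array([s.class_label for s in samples], dtype=np.int64)
    vids = np.array([s.video_id for s in samples])
    return X, y, vids
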