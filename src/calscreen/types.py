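"""Core in-memory containers: video stacks, label images, run configuration.

A recording is a T×H×W stack of 16-bit fluorescence frames.  ROI sets —
both researcher-drawn ground truths and the segmenter's output — are carried
as dense integer label images (0 = background, k > 0 = ROI k).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import U16_MAX

#: canonical projection method names (row labels of the benchmark grid)
PROJECTION_METHODS = ("maxint", "std", "stdscale")


@dataclass
class VideoStack:
    """A time-lapse recording: ``data[t, y, x]`` 16-bit intensities.

    Parameters
    ----------
    data
        T×H×W array of non-negative integers in [0, 65535].
    frame_interval
        Seconds per frame (metadata only; recordings here are 1 Hz).
    """

    data: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"stack must be T x H x W, got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("stack needs at least 2 frames")
        if data.size == 0:
            raise ValueError("stack has empty frames")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("stack intensities must be integers")
        if data.min() < 0 or data.max() > U16_MAX:
            raise ValueError("stack intensities must lie in [0, 65535]")
        self.data = data.astype(np.uint16)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class LabelImage:
    """Integer ROI raster: 0 = background, k in 1..K = ROI k.

    ``id_map`` records the original-id -> new-id mapping when the image was
    re-indexed to a contiguous range on load.
    """

    data: np.ndarray
    id_map: dict[int, int] | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError(f"label image must be 2-D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("label image must be integer-valued")
        if data.min() < 0:
            raise ValueError("label ids must be non-negative")
        self.data = data.astype(np.int32)

    @property
    def n_rois(self) -> int:
        ids = np.unique(self.data)
        return int((ids > 0).sum())

    @property
    def is_contiguous(self) -> bool:
        ids = np.unique(self.data)
        ids = ids[ids > 0]
        return ids.size == 0 or (ids[0] == 1 and ids[-1] == ids.size)

    def relabel(self) -> "LabelImage":
        """Re-index ids to 1..K preserving their order; record the mapping."""
        ids = np.unique(self.data)
        ids = ids[ids > 0]
        lut = np.zeros(int(self.data.max()) + 1, dtype=np.int32)
        id_map: dict[int, int] = {}
        for new, old in enumerate(ids, start=1):
            lut[old] = new
            id_map[int(old)] = new
        return LabelImage(lut[self.data], id_map=id_map)

    def mask(self, roi_id: int) -> np.ndarray:
        m = self.data == roi_id
        if not m.any():
            raise KeyError(f"no ROI with id {roi_id}")
        return m


@dataclass
class RunConfig:
    """Every knob of the screening pipeline, JSON-serialisable.

    Defaults are the published operating point: junction/stopping/elimination
    500/3000/500 px, IoM levels (0.1, 0.2, 0.3, 0.4, 0.5, 0.7), 200 shuffles,
    128×32 feature images, and 15 disease + 7 control training videos.
    """

    projection_method: str = "maxint"
    junction: int = 500
    stopping: int = 3000
    elimination: int = 500
    filter_size: int = 5
    connectivity: int = 8
    iom_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.7)
    n_shuffles: int = 200
    feature_width: int = 128
    feature_height: int = 32
    normalize_features: bool = True
    train_disease: int | None = 15
    train_control: int | None = 7
    split_seed: int = 0
    shuffle_seed: int = 0
    classifier_names: tuple[str, ...] = ()  # empty = full panel
    cv_folds: int = 5
    classify: bool = True

    def __post_init__(self):
        if self.projection_method not in PROJECTION_METHODS:
            raise ValueError(f"unknown projection method {self.projection_method!r}")
        for name in ("junction", "stopping", "elimination"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.filter_size < 1 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be an odd positive integer")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if any(not (0 < t <= 1) for t in self.iom_thresholds):
            raise ValueError("IoM thresholds must lie in (0, 1]")
        self.iom_thresholds = tuple(float(t) for t in self.iom_thresholds)
        self.classifier_names = tuple(self.classifier_names)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
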