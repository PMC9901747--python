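"""Multi-level-thresholding (MLT) segmentation of cell somas.

The 8-bit projection image is swept with a descending threshold, 255 down
to 0.  Connected bright components seed candidate cell regions, which then
grow as the threshold drops.  Three area criteria (in pixels) govern the
sweep:

* ``junction`` — when two or more growing regions meet inside one component,
  they merge only if the sum of their current areas is at most this value;
  otherwise every involved region freezes at its current pixels.
* ``stopping`` — a region never grows past this area; a growth step that
  would exceed it freezes the region at its last conforming mask.
* ``elimination`` — after the sweep, any region smaller than this is
  discarded as noise.

The update rules, per threshold t (B_t = pixels >= t, components under the
configured connectivity; c' = component minus all frozen pixels; G = growing
regions inside the component):

a. G empty, component disjoint from frozen regions -> birth a region = c'.
b. G empty but the component touches a frozen region -> nothing is born
   (the component is the halo of a finished cell).
c. G = {r}: grow r to c', unless |c'| > stopping, in which case r freezes.
d. |G| >= 2: if the members' current areas sum past ``junction`` they all
   freeze; otherwise they merge into the smallest id (earliest birth kept)
   and the merged region takes c', subject to the same stopping rule (a
   candidate past ``stopping`` freezes the merged region at the union of its
   members' current pixels).

The result is a pure function of (image, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import LabelImage

_GROWING = 0
_FROZEN = 1


@dataclass
class MLTParams:
    """Area criteria (pixels) and pre-processing knobs for the MLT sweep."""

    junction: int = 500
    stopping: int = 3000
    elimination: int = 500
    filter_size: int = 5
    connectivity: int = 8

    def __post_init__(self):
        for name in ("junction", "stopping", "elimination"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.filter_size < 1 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be odd and >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class RegionInfo:
    """Bookkeeping for one final ROI."""

    id: int
    area: int
    birth_threshold: int
    centroid: tuple[float, float]


@dataclass
class SegmentationResult:
    label_image: LabelImage
    regions: list[RegionInfo] = field(default_factory=list)
    params: MLTParams = field(default_factory=MLTParams)

    @property
    def n_rois(self) -> int:
        return len(self.regions)


def mean_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Box mean over a size×size window, reflected borders, half-up rounding.

    The window sum is computed in exact integer arithmetic so the rounded
    result is bit-identical across platforms.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("filter size must be odd and >= 1")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    n = size * size
    kernel = np.ones((size, size), dtype=np.int64)
    sums = ndimage.correlate(img.astype(np.int64), kernel, mode="reflect")
    out = (2 * sums + n) // (2 * n)  # floor(sum/n + 1/2) exactly
    return out.astype(img.dtype)


def binarize(img: np.ndarray, level: int) -> np.ndarray:
    """Pixels at or above ``level`` are foreground (value 1)."""
    return np.asarray(img) >= level


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    return ndimage.generate_binary_structure(2, 1)


def mlt_segment(
    image: np.ndarray,
    params: MLTParams | None = None,
    presmooth: bool = False,
) -> SegmentationResult:
    """Run the descending-threshold sweep on an 8-bit projection image.

    Parameters
    ----------
    image
        8-bit single-channel image (already mean-filtered, or pass
        ``presmooth=True`` to apply ``mean_filter(params.filter_size)``).
    """
    params = params or MLTParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("mlt_segment expects an 8-bit image")
    if presmooth:
        img = mean_filter(img, params.filter_size)

    structure = _structure(params.connectivity)
    owner = np.zeros(img.shape, dtype=np.int32)
    status: dict[int, int] = {}
    area: dict[int, int] = {}
    birth: dict[int, int] = {}
    next_id = 1

    for t in range(255, -1, -1):
        lab, n = ndimage.label(binarize(img, t), structure=structure)
        if n == 0:
            continue
        slices = ndimage.find_objects(lab)
        for ci, sl in enumerate(slices, start=1):
            comp = lab[sl] == ci
            own = owner[sl]
            ids = np.unique(own[comp])
            ids = ids[ids > 0]
            growing = [int(i) for i in ids if status[int(i)] == _GROWING]
            frozen = [int(i) for i in ids if status[int(i)] == _FROZEN]

            if frozen:
                frozen_mask = np.isin(own, frozen)
                cprime = comp & ~frozen_mask
            else:
                cprime = comp
            c_size = int(cprime.sum())

            if not growing:
                if not frozen and c_size > 0:
                    own[cprime] = next_id
                    status[next_id] = _GROWING
                    area[next_id] = c_size
                    birth[next_id] = t
                    next_id += 1
                # touching only frozen regions: halo of a finished cell
                continue

            if len(growing) == 1:
                r = growing[0]
                if c_size > params.stopping:
                    status[r] = _FROZEN
                else:
                    own[cprime] = r
                    area[r] = c_size
                continue

            # two or more growing regions meet
            total = sum(area[g] for g in growing)
            if total > params.junction:
                for g in growing:
                    status[g] = _FROZEN
                continue
            target = min(growing)
            birth[target] = max(birth[g] for g in growing)
            others = [g for g in growing if g != target]
            if c_size > params.stopping:
                # merge but freeze at the union of current member pixels
                for g in others:
                    own[own == g] = target
                    del status[g], area[g], birth[g]
                area[target] = total
                status[target] = _FROZEN
            else:
                own[cprime] = target
                for g in others:
                    del status[g], area[g], birth[g]
                area[target] = c_size

    # sweep done: everything freezes, then small regions are eliminated
    survivors = sorted(i for i in status if area[i] >= params.elimination)
    lut = np.zeros(next_id, dtype=np.int32)
    for new, old in enumerate(survivors, start=1):
        lut[old] = new
    final = lut[owner]

    regions: list[RegionInfo] = []
    if survivors:
        centroids = ndimage.center_of_mass(
            np.ones_like(final), final, list(range(1, len(survivors) + 1))
        )
        for new, old in enumerate(survivors, start=1):
            cy, cx = centroids[new - 1]
            regions.append(
                RegionInfo(
                    id=new,
                    area=area[old],
                    birth_threshold=birth[old],
                    centroid=(float(cy), float(cx)),
                )
            )
    return SegmentationResult(LabelImage(final), regions, params)
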