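"""Temporal projection of a video stack onto a single image.

Three per-pixel statistics summarise a T×H×W recording as one H×W image:

* ``maxint`` — maximum intensity over time,
* ``std`` — population standard deviation over time,
* ``stdscale`` — the std image linearly stretched to the full 16-bit range.

Each variant is finally quantised to 8 bits (``round(v * 255 / 65535)``)
before segmentation.  Only the std image receives the contrast stretch; the
maximum-intensity image is converted to 8 bits directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import U8_MAX, U16_MAX, round_half_up
from .types import PROJECTION_METHODS, VideoStack


@dataclass
class ProjectionImage:
    data: np.ndarray
    bit_depth: int
    method: str | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError("projection image must be 2-D")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        hi = U8_MAX if self.bit_depth == 8 else U16_MAX
        if data.min() < 0 or data.max() > hi:
            raise ValueError(f"values exceed {self.bit_depth}-bit range")
        self.data = data.astype(np.uint8 if self.bit_depth == 8 else np.uint16)


def project_max(stack: VideoStack) -> ProjectionImage:
    """Per-pixel maximum over time (16-bit)."""
    return ProjectionImage(stack.data.max(axis=0), bit_depth=16, method="maxint")


def project_std(stack: VideoStack) -> ProjectionImage:
    """Per-pixel population standard deviation over time, rounded (16-bit)."""
    sd = stack.data.astype(np.float64).std(axis=0)  # divide-by-T convention
    out = np.clip(round_half_up(sd), 0, U16_MAX).astype(np.uint16)
    return ProjectionImage(out, bit_depth=16, method="std")


def linear_scale(img: ProjectionImage) -> ProjectionImage:
    """Stretch a 16-bit image so min -> 0 and max -> 65535.

    A constant image is returned unchanged with a warning: the stretch is
    undefined when there is no dynamic range.
    """
    if img.bit_depth != 16:
        raise ValueError("linear_scale expects a 16-bit image")
    data = img.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        warnings.warn("constant image: linear scaling is undefined, returning input")
        return ProjectionImage(img.data.copy(), bit_depth=16, method=img.method)
    out = round_half_up((data - lo) * (U16_MAX / (hi - lo))).astype(np.uint16)
    return ProjectionImage(out, bit_depth=16, method=img.method)


def to_8bit(img: ProjectionImage) -> ProjectionImage:
    """Quantise a 16-bit image to 8 bits via round(v * 255 / 65535)."""
    if img.bit_depth != 16:
        raise ValueError("to_8bit expects a 16-bit image")
    out = round_half_up(img.data.astype(np.float64) * (U8_MAX / U16_MAX))
    return ProjectionImage(out.astype(np.uint8), bit_depth=8, method=img.method)


def project(stack: VideoStack, method: str, keep_16bit: bool = False):
    """Run one named projection end-to-end to its 8-bit image.

    Returns the 8-bit ProjectionImage, or ``(8-bit, 16-bit intermediate)``
    when ``keep_16bit`` is set.
    """
    if method not in PROJECTION_METHODS:
        raise ValueError(f"unknown projection method {method!r}")
    if method == "maxint":
        inter = project_max(stack)
    elif method == "std":
        inter = project_std(stack)
    else:  # stdscale
        inter = linear_scale(project_std(stack))
        inter.method = "stdscale"
    final = to_8bit(inter)
    final.method = method
    return (final, inter) if keep_16bit else final
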