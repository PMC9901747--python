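"""Reading and writing the on-disk artifacts.

Stacks are multi-page 16-bit grayscale TIFFs, one page per frame (time-
major).  Projections and label images are single-page TIFF (or PNG for
labels).  8-bit stacks are accepted and up-scaled by 257 to the 16-bit
range.  Label images are re-indexed to a contiguous 1..K range on load, with
the original-id mapping recorded on the returned object.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from ._util import U16_MAX
from .projection import ProjectionImage
from .types import LabelImage, VideoStack


def read_stack(path) -> VideoStack:
    """Read a multi-page grayscale TIFF as a T×H×W stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        raise ValueError(f"{path}: single page; a stack needs >= 2 frames")
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages of one size, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        data = data.astype(np.uint16) * 257  # 255 -> 65535
    elif data.dtype != np.uint16:
        raise ValueError(f"{path}: unsupported bit depth {data.dtype}; need 8 or 16")
    return VideoStack(data)


def write_stack(stack: VideoStack, path) -> None:
    tifffile.imwrite(Path(path), stack.data, photometric="minisblack")


def read_label_image(path, expected_shape=None) -> LabelImage:
    """Read a single-page integer label image (TIFF or PNG), re-indexed 1..K."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        data = np.asarray(Image.open(path))
    else:
        data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: label image must be single-page grayscale")
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path}: shape {data.shape} does not match expected {expected_shape}"
        )
    lbl = LabelImage(data.astype(np.int64))
    return lbl if lbl.is_contiguous else lbl.relabel()


def write_label_image(label: LabelImage, path) -> None:
    path = Path(path)
    data = label.data
    if data.max() > U16_MAX:
        raise ValueError("more ROI ids than a 16-bit label image can hold")
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(data.astype(np.uint16)).save(path)
    else:
        tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")


def write_projection(img: ProjectionImage, path) -> None:
    tifffile.imwrite(Path(path), img.data, photometric="minisblack")


def read_projection(path, bit_depth: int | None = None) -> ProjectionImage:
    data = tifffile.imread(Path(path))
    if bit_depth is None:
        bit_depth = 8 if data.dtype == np.uint8 else 16
    return ProjectionImage(data, bit_depth=bit_depth)
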