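"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np

U8_MAX = 255
U16_MAX = 65535


def round_half_up(x):
    """Round to the nearest integer with ties going up (0.5 -> 1).

    numpy's default rounds ties to even; the pipeline specifies half-up
    everywhere so that quantisation is bit-reproducible across platforms.
    Returns float64; callers cast to the target integer dtype.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)
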