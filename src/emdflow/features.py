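"""Scene feature maps: local RMS contrast and contrast-weighted nearness.

Local contrast at a receptor is the standard deviation of the 3x3
neighborhood brightness (the receptor and its eight orthogonal/diagonal
neighbors) divided by the neighborhood mean; it is therefore
dimensionless and invariant under global brightness scaling.  The
contrast-weighted nearness map is the pointwise product of the contrast
map and the nearness map -- the environmental feature the motion-energy
profile is compared against.
"""

from __future__ import annotations

import numpy as np


def _box3(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sums and counts over 3x3 windows; azimuth wraps, rows truncate."""
    padded = np.pad(img, ((1, 1), (0, 0)), mode="constant", constant_values=0.0)
    cnt = np.pad(np.ones_like(img), ((1, 1), (0, 0)), mode="constant")
    padded = np.pad(padded, ((0, 0), (1, 1)), mode="wrap")
    cnt = np.pad(cnt, ((0, 0), (1, 1)), mode="wrap")
    k = np.lib.stride_tricks.sliding_window_view
    s = k(padded, (3, 3)).sum(axis=(-2, -1))
    n = k(cnt, (3, 3)).sum(axis=(-2, -1))
    return s, n


def local_rms_contrast(frame: np.ndarray) -> np.ndarray:
    """Per-receptor RMS contrast (std / mean of the 3x3 neighborhood).

    Azimuth neighbors wrap around the panorama; top and bottom rows use
    their valid neighbors only.  Regions with non-positive mean come out
    NaN (invalid).
    """
    frame = np.asarray(frame, dtype=np.float64)
    s, n = _box3(frame)
    s2, _ = _box3(frame * frame)
    mean = s / n
    var = np.maximum(s2 / n - mean ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var) / mean
    return np.where(mean > 0, out, np.nan)


def contrast_sequence(stack: np.ndarray) -> np.ndarray:
    """Contrast map per frame of a (T, rows, cols) brightness stack."""
    return np.stack([local_rms_contrast(f) for f in stack])


def contrast_weighted_nearness(contrast: np.ndarray,
                               nearness: np.ndarray) -> np.ndarray:
    """Pointwise product of the contrast and nearness maps.

    Invalid (NaN) nearness stays invalid; zero contrast gives zero.
    """
    contrast = np.asarray(contrast)
    nearness = np.asarray(nearness)
    if contrast.shape != nearness.shape:
        raise ValueError("contrast and nearness maps are not co-registered")
    return contrast * nearness
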