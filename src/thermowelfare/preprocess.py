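"""Per-frame segmentation and contrast normalization of thermograms.

A rodent is the warmest object in the scene, so foreground extraction
reduces to multilevel Otsu thresholding with the warmest class taken as
the animal. Three classes (background / warm halo at the body edge /
body core) are the default because the thermal point-spread function
smears the body boundary into an intermediate-temperature ring.

All operations act on intensity rank order only, so radiometric (deg C)
and raw gray frames flow through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu


@dataclass
class SegmentationResult:
    """Thresholds (ascending) and the warmest-class foreground mask."""

    thresholds: np.ndarray
    mask: np.ndarray
    n_foreground: int

    @property
    def is_empty(self) -> bool:
        return self.n_foreground == 0


def multilevel_otsu(frame: np.ndarray, n_classes: int = 3, nbins: int = 256) -> np.ndarray:
    """Optimal multilevel thresholds by maximizing between-class variance.

    The frame is histogrammed into ``nbins`` bins over its min-max range and
    the ``n_classes - 1`` cut points that maximize the between-class variance
    of the histogram are returned (in frame intensity units, ascending).
    """
    frame = np.asarray(frame)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    finite = frame[np.isfinite(frame)]
    if finite.size == 0 or finite.min() == finite.max():
        raise ValueError("cannot threshold a constant frame")
    thresholds = threshold_multiotsu(frame, classes=n_classes, nbins=nbins)
    return np.asarray(thresholds, dtype=float)


def segment_animal(frame: np.ndarray, thresholds: np.ndarray) -> SegmentationResult:
    """Foreground mask: pixels strictly warmer than the top threshold.

    An empty mask is allowed (no animal in view) and flagged via
    ``n_foreground == 0`` rather than raised.
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    mask = np.asarray(frame) > thresholds[-1]
    return SegmentationResult(
        thresholds=thresholds, mask=mask, n_foreground=int(mask.sum())
    )


def _percentiles(frame: np.ndarray, lo_pct: float, hi_pct: float) -> tuple[float, float]:
    """Exact linear-interpolated percentiles via a single float32 partition."""
    flat = frame.reshape(-1).astype(np.float32, copy=True)
    n = flat.size
    out = []
    kth = []
    for pct in (lo_pct, hi_pct):
        pos = pct / 100.0 * (n - 1)
        kth.extend([int(np.floor(pos)), min(int(np.floor(pos)) + 1, n - 1)])
    flat.partition(sorted(set(kth)))
    for pct in (lo_pct, hi_pct):
        pos = pct / 100.0 * (n - 1)
        k = int(np.floor(pos))
        frac = pos - k
        lo_v = flat[k]
        hi_v = flat[min(k + 1, n - 1)]
        out.append(float(lo_v + frac * (hi_v - lo_v)))
    return out[0], out[1]


def stretch_contrast(
    frame: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> np.ndarray:
    """Linear percentile contrast stretch to 8 bits.

    Intensities at/below the ``lo_pct`` percentile map to 0, at/above
    ``hi_pct`` to 255, linearly in between. Percentile clipping keeps hot
    spots (e.g. urine marks) from compressing the body's dynamic range.
    """
    if not (0.0 <= lo_pct < hi_pct <= 100.0):
        raise ValueError("need 0 <= lo_pct < hi_pct <= 100")
    frame = np.asarray(frame, dtype=np.float32)
    lo, hi = _percentiles(frame, lo_pct, hi_pct)
    if hi <= lo:
        warnings.warn("constant frame: contrast stretch yields all zeros")
        return np.zeros(frame.shape, dtype=np.uint8)
    out = (frame - lo) * (255.0 / (hi - lo))
    np.clip(out, 0.0, 255.0, out=out)
    return (out + 0.5).astype(np.uint8)


def stretch_video(frames: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Per-frame contrast stretch of a whole stack (frame, row, col)."""
    frames = np.asarray(frames)
    out = np.empty(frames.shape, dtype=np.uint8)
    for i in range(frames.shape[0]):
        out[i] = stretch_contrast(frames[i], lo_pct, hi_pct)
    return out
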