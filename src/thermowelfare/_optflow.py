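"""Sparse pyramidal Lucas-Kanade point tracking.

Implements the classic iterative Lucas-Kanade step on a window around each
feature point, coarse-to-fine over an image pyramid, vectorized across all
points with bilinear sampling. Sub-pixel accuracy is what matters here:
respiratory chest motion is on the order of one pixel.
"""

from __future__ import annotations

import numpy as np


def _bilinear(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``img`` at float coordinates (clipped to bounds)."""
    h, w = img.shape
    ys = np.clip(ys, 0.0, h - 1.001)
    xs = np.clip(xs, 0.0, w - 1.001)
    y0 = ys.astype(np.int32)
    x0 = xs.astype(np.int32)
    wy = ys - y0
    wx = xs - x0
    flat = img.ravel()
    idx = y0 * w + x0
    ia = flat.take(idx)
    ib = flat.take(idx + 1)
    ic = flat.take(idx + w)
    id_ = flat.take(idx + w + 1)
    top = ia + (ib - ia) * wx
    bot = ic + (id_ - ic) * wx
    return top + (bot - top) * wy


def _downsample(img: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsampling (crops to even size)."""
    h, w = img.shape
    img = img[: h - h % 2, : w - w % 2]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def build_pyramid(frame: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(frame, dtype=np.float32)]
    for _ in range(levels - 1):
        pyr.append(_downsample(pyr[-1]))
    return pyr


def lk_pair(
    pyr_prev: list[np.ndarray],
    pyr_next: list[np.ndarray],
    pts: np.ndarray,
    win: int = 15,
    max_iter: int = 8,
    eps: float = 0.02,
    min_det: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Track points (x, y) from the previous to the next frame.

    Returns the new positions and a per-point validity flag; points whose
    tracking window leaves the frame or whose normal matrix is singular are
    marked invalid.
    """
    pts = np.asarray(pts, dtype=np.float32)
    n = pts.shape[0]
    half = win // 2
    offs = np.arange(-half, half + 1, dtype=np.float32)
    uy, ux = np.meshgrid(offs, offs, indexing="ij")
    ux = ux.ravel()[None, :]  # (1, win*win)
    uy = uy.ravel()[None, :]
    valid = np.ones(n, dtype=bool)
    d = np.zeros((n, 2), dtype=np.float32)  # accumulated displacement (x, y)

    levels = len(pyr_prev)
    for lev in range(levels - 1, -1, -1):
        prev = pyr_prev[lev]
        nxt = pyr_next[lev]
        h, w = prev.shape
        scale = 2.0**lev
        px = pts[:, 0:1] / scale
        py = pts[:, 1:2] / scale
        # in-bounds check for the template window (+1 margin for gradients)
        inb = (
            (px[:, 0] - half - 1 >= 0)
            & (px[:, 0] + half + 1 <= w - 2)
            & (py[:, 0] - half - 1 >= 0)
            & (py[:, 0] + half + 1 <= h - 2)
        )
        valid &= inb
        gx = px + ux
        gy = py + uy
        t = _bilinear(prev, gy, gx)
        # spatial gradients from the sampled window itself (unit grid spacing)
        tw = t.reshape(-1, win, win)
        iy3, ix3 = np.gradient(tw, axis=(1, 2))
        ix = ix3.reshape(t.shape)
        iy = iy3.reshape(t.shape)
        a11 = np.einsum("ij,ij->i", ix, ix)
        a12 = np.einsum("ij,ij->i", ix, iy)
        a22 = np.einsum("ij,ij->i", iy, iy)
        det = a11 * a22 - a12 * a12
        ok = det > min_det
        valid &= ok
        det_safe = np.where(ok, det, 1.0)
        dl = d / scale  # displacement at this level
        for _ in range(max_iter):
            e = _bilinear(nxt, gy + dl[:, 1:2], gx + dl[:, 0:1]) - t
            b1 = np.einsum("ij,ij->i", ix, e)
            b2 = np.einsum("ij,ij->i", iy, e)
            step_x = -(a22 * b1 - a12 * b2) / det_safe
            step_y = -(a11 * b2 - a12 * b1) / det_safe
            dl[:, 0] += np.where(valid, step_x, 0.0)
            dl[:, 1] += np.where(valid, step_y, 0.0)
            if max(np.abs(step_x[valid]).max(initial=0.0),
                   np.abs(step_y[valid]).max(initial=0.0)) < eps:
                break
        d = dl * scale

    new_pts = pts + d
    h0, w0 = pyr_prev[0].shape
    valid &= (
        (new_pts[:, 0] >= half)
        & (new_pts[:, 0] <= w0 - 1 - half)
        & (new_pts[:, 1] >= half)
        & (new_pts[:, 1] <= h0 - 1 - half)
    )
    valid &= np.all(np.isfinite(new_pts), axis=1)
    return new_pts, valid


def track_points(
    frames: np.ndarray,
    pts0: np.ndarray,
    win: int = 15,
    levels: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Track points through a frame stack.

    Returns ``(x, y, alive)`` where ``x``/``y`` are (n_frames, n_points)
    position arrays (NaN once a point is lost) and ``alive`` is the
    per-point flag of surviving the full stack.
    """
    frames = np.asarray(frames)
    n_frames = frames.shape[0]
    pts = np.asarray(pts0, dtype=np.float64).copy()
    n = pts.shape[0]
    x = np.full((n_frames, n), np.nan)
    y = np.full((n_frames, n), np.nan)
    alive = np.ones(n, dtype=bool)
    x[0], y[0] = pts[:, 0], pts[:, 1]
    pyr_prev = build_pyramid(frames[0], levels)
    for f in range(1, n_frames):
        pyr_next = build_pyramid(frames[f], levels)
        new_pts, ok = lk_pair(pyr_prev, pyr_next, pts, win=win)
        alive &= ok
        pts[alive] = new_pts[alive]
        x[f, alive] = pts[alive, 0]
        y[f, alive] = pts[alive, 1]
        pyr_prev = pyr_next
    return x, y, alive
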