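"""Sparse-representation particle-filter tracking of a rodent in thermal video.

Each candidate window is scored by how well it can be reconstructed as a
non-negative sparse combination of target templates plus trivial (positive
and negative identity) templates:

    min_c ||y - [T, I, -I] c||^2 + lambda ||c||_1,   c >= 0

The reconstruction error using only the target-template coefficients,
||y - T c_T||^2, ranks the candidates; the smallest-error candidate is the
tracking result. The particle filter propagates (cx, cy, log sx, log sy)
states with Gaussian noise and resamples systematically when the effective
sample size degenerates. Templates adapt: when no template resembles the
current result (max cosine similarity < tau), the least important template
is replaced.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig, TrackerConfig
from .io import RectROI, ThermalVideo
from .preprocess import stretch_video


@dataclass
class TrackerState:
    particles: np.ndarray          # (n, 4): cx, cy, log_sx, log_sy
    weights: np.ndarray            # (n,), sum 1
    templates: np.ndarray          # (m, D), zero-mean unit-norm rows
    template_weights: np.ndarray   # (m,) importance, sum 1
    base_size: tuple[float, float]  # (w, h) of the ROI at unit scale
    patch_shape: tuple[int, int]
    frame_shape: tuple[int, int]
    rng: np.random.Generator
    config: TrackerConfig
    frame_index: int = 0
    error_history: deque = field(default_factory=lambda: deque(maxlen=50))


def extract_patches(
    frame: np.ndarray,
    centers: np.ndarray,
    sizes: np.ndarray,
    patch_shape: tuple[int, int],
) -> np.ndarray:
    """Bilinear resampling of axis-aligned windows into the template space.

    ``centers`` is (n, 2) in (x, y); ``sizes`` is (n, 2) box (width, height).
    Returns (n, ph*pw) float32 row vectors.
    """
    frame = np.asarray(frame, dtype=np.float32)
    h, w = frame.shape
    ph, pw = patch_shape
    gy, gx = np.mgrid[0:ph, 0:pw]
    gx = (gx / (pw - 1.0) - 0.5).ravel()[None, :]  # normalized offsets in [-0.5, 0.5]
    gy = (gy / (ph - 1.0) - 0.5).ravel()[None, :]
    xs = centers[:, 0:1] + gx * sizes[:, 0:1]
    ys = centers[:, 1:2] + gy * sizes[:, 1:2]
    xs = np.clip(xs, 0.0, w - 1.001)
    ys = np.clip(ys, 0.0, h - 1.001)
    x0 = xs.astype(np.int32)
    y0 = ys.astype(np.int32)
    wx = (xs - x0).astype(np.float32)
    wy = (ys - y0).astype(np.float32)
    top = frame[y0, x0] * (1 - wx) + frame[y0, x0 + 1] * wx
    bot = frame[y0 + 1, x0] * (1 - wx) + frame[y0 + 1, x0 + 1] * wx
    return top * (1 - wy) + bot * wy


def normalize_patches(patches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean, unit-norm rows; returns (normalized, row_is_degenerate)."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 1:
        patches = patches[None]
    out = patches - patches.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(out, axis=1)
    degenerate = norms < 1e-9
    out[~degenerate] /= norms[~degenerate, None]
    return out, degenerate


def sparse_reconstruct(
    candidates: np.ndarray,
    templates: np.ndarray,
    lam: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-negative l1-regularized reconstruction over [T, I, -I].

    Solves, for each candidate row y,
    ``min ||y - T' c_T - e||^2 + lam (sum c_T + ||e||_1)`` with ``c_T >= 0``
    (``e = e+ - e-`` absorbs the trivial templates), by block coordinate
    descent: closed-form soft-thresholding for ``e`` alternating with
    coordinate descent over the target coefficients.

    Returns ``(c_T, e, errors)`` where ``errors[i] = ||y_i - T' c_T_i||^2``
    uses only the target-template part.
    """
    y = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    t = np.asarray(templates, dtype=np.float64)
    m, n = t.shape[0], y.shape[0]
    gram = t @ t.T
    diag = np.where(np.diag(gram) > 0, np.diag(gram), 1.0)
    c = np.zeros((n, m))
    e = np.zeros_like(y)
    # block coordinate descent: exact soft-threshold for the trivial part e,
    # Gram-space coordinate descent for the target coefficients. Each block
    # update decreases the objective, so the per-candidate objective is
    # monotone; a candidate is frozen once its decrease falls below tol.
    active = np.arange(n)
    prev_obj = np.full(n, np.inf)
    converged = False
    for _ in range(max_iter):
        ya = y[active]
        ea = e[active]
        ca = c[active]
        b = (ya - ea) @ t.T
        for _ in range(3):
            for j in range(m):
                g = b[:, j] - ca @ gram[:, j] + ca[:, j] * diag[j]
                ca[:, j] = np.maximum(0.0, (g - lam / 2.0) / diag[j])
        r0 = ya - ca @ t
        ea = np.sign(r0) * np.maximum(np.abs(r0) - lam / 2.0, 0.0)
        resid = r0 - ea
        obj = (
            np.einsum("ij,ij->i", resid, resid)
            + lam * ca.sum(axis=1)
            + lam * np.abs(ea).sum(axis=1)
        )
        c[active] = ca
        e[active] = ea
        done = prev_obj[active] - obj < tol * np.maximum(1.0, np.abs(obj))
        prev_obj[active] = obj
        active = active[~done]
        if active.size == 0:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"l1 solver did not converge in {max_iter} iterations")
    resid_target = y - c @ t
    errors = np.einsum("ij,ij->i", resid_target, resid_target)
    return c, e, errors


def reconstruction_objective(y, templates, c, e, lam) -> np.ndarray:
    """Value of the optimization objective (for verification)."""
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    r = y - np.atleast_2d(c) @ templates - np.atleast_2d(e)
    return (
        np.einsum("ij,ij->i", r, r)
        + lam * np.atleast_2d(c).sum(axis=1)
        + lam * np.abs(np.atleast_2d(e)).sum(axis=1)
    )


_TEMPLATE_SHIFTS = [
    (0, 0), (1, 0), (-1, 0), (0, 1), (0, -1),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
    (2, 0), (-2, 0), (0, 2), (0, -2),
]


def init_tracker(
    frame8: np.ndarray,
    roi: RectROI,
    config: TrackerConfig | None = None,
    seed: int = 0,
) -> TrackerState:
    """Initialize templates and particles from the first-frame ROI.

    Templates are the ROI patch plus one-pixel-shifted copies, resampled to
    the template patch size, zero-meaned and unit-normed.
    """
    config = config or TrackerConfig()
    frame8 = np.asarray(frame8)
    roi.validate_within(frame8.shape)
    if roi.area < 64:
        raise ValueError("ROI patch too small for tracking (area must be >= 64 px)")
    cx, cy = roi.center
    size = np.array([[roi.width, roi.height]], dtype=float)
    shifts = _TEMPLATE_SHIFTS[: config.n_templates]
    centers = np.array([[cx + sx, cy + sy] for sx, sy in shifts], dtype=float)
    raw = extract_patches(frame8, centers, np.repeat(size, len(shifts), axis=0), config.patch_size)
    templates, degenerate = normalize_patches(raw)
    if degenerate[0]:
        raise ValueError("zero-variance ROI patch: cannot build templates")
    templates = templates[~degenerate]
    if templates.shape[0] < 2:
        raise ValueError("need >= 2 usable templates")
    rng = np.random.default_rng(seed)
    n = config.n_particles
    particles = np.zeros((n, 4))
    particles[:, 0] = cx + config.sigma_xy * rng.standard_normal(n)
    particles[:, 1] = cy + config.sigma_xy * rng.standard_normal(n)
    particles[:, 2] = config.sigma_log_scale * rng.standard_normal(n)
    particles[:, 3] = config.sigma_log_scale * rng.standard_normal(n)
    m = templates.shape[0]
    return TrackerState(
        particles=particles,
        weights=np.full(n, 1.0 / n),
        templates=templates,
        template_weights=np.full(m, 1.0 / m),
        base_size=(float(roi.width), float(roi.height)),
        patch_shape=config.patch_size,
        frame_shape=frame8.shape,
        rng=rng,
        config=config,
    )


def propagate(state: TrackerState, rng: np.random.Generator | None = None) -> np.ndarray:
    """Candidate states: particles perturbed by Gaussian transition noise."""
    rng = rng or state.rng
    cfg = state.config
    cand = state.particles.copy()
    n = cand.shape[0]
    cand[:, 0] += cfg.sigma_xy * rng.standard_normal(n)
    cand[:, 1] += cfg.sigma_xy * rng.standard_normal(n)
    cand[:, 2] += cfg.sigma_log_scale * rng.standard_normal(n)
    cand[:, 3] += cfg.sigma_log_scale * rng.standard_normal(n)
    h, w = state.frame_shape
    cand[:, 0] = np.clip(cand[:, 0], 0.0, w - 1.0)
    cand[:, 1] = np.clip(cand[:, 1], 0.0, h - 1.0)
    cand[:, 2:] = np.clip(cand[:, 2:], -0.7, 0.7)
    return cand


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def step(state: TrackerState, frame8: np.ndarray) -> tuple[TrackerState, dict]:
    """One tracking step: propagate, score, select, reweight, resample.

    Returns the updated state and a result row dict with the selected
    center, scales, target-reconstruction error and a low-confidence flag
    (error above ``error_spike_factor`` x the running median error).
    """
    cfg = state.config
    frame8 = np.asarray(frame8)
    if frame8.shape != state.frame_shape:
        raise ValueError("frame geometry changed mid-track")
    cand = propagate(state)
    sizes = np.column_stack(
        [state.base_size[0] * np.exp(cand[:, 2]), state.base_size[1] * np.exp(cand[:, 3])]
    )
    raw = extract_patches(frame8, cand[:, :2], sizes, state.patch_shape)
    patches, degenerate = normalize_patches(raw)
    _, _, errors = sparse_reconstruct(
        patches, state.templates, cfg.lam, cfg.solver_tol, cfg.solver_max_iter
    )
    errors = np.where(degenerate, np.inf, errors)
    if not np.isfinite(errors).any():
        raise RuntimeError("all candidate patches degenerate")
    best = int(np.argmin(errors))
    best_error = float(errors[best])
    running_median = (
        float(np.median(state.error_history)) if state.error_history else np.inf
    )
    low_confidence = bool(
        state.error_history and best_error > cfg.error_spike_factor * max(running_median, 1e-12)
    )
    state.error_history.append(best_error)

    finite = np.isfinite(errors)
    logw = np.where(finite, -cfg.alpha * errors, -np.inf)
    logw = logw - logw[finite].max()
    w = state.weights * np.exp(logw)
    total = w.sum()
    weights = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
    ess = 1.0 / np.sum(weights**2)
    particles = cand
    if ess < cfg.n_particles / 2.0:
        idx = _systematic_resample(weights, state.rng)
        particles = cand[idx]
        weights = np.full(cand.shape[0], 1.0 / cand.shape[0])
    state.particles = particles
    state.weights = weights
    state.frame_index += 1
    row = {
        "x_px": float(cand[best, 0]),
        "y_px": float(cand[best, 1]),
        "sx": float(np.exp(cand[best, 2])),
        "sy": float(np.exp(cand[best, 3])),
        "error": best_error,
        "low_confidence": low_confidence,
        "_best_patch": patches[best],
    }
    return state, row


def update_templates(state: TrackerState, result_patch: np.ndarray) -> TrackerState:
    """Adapt the template set to the current appearance.

    If the result patch resembles an existing template (max cosine
    similarity >= tau), that template's importance increases; otherwise the
    least important template is replaced by the result patch.
    """
    patch, degenerate = normalize_patches(result_patch)
    if degenerate[0]:
        return state
    patch = patch[0]
    sims = state.templates @ patch
    tw = state.template_weights.copy()
    if sims.max() < state.config.tau:
        j = int(np.argmin(tw))
        state.templates = state.templates.copy()
        state.templates[j] = patch
        tw[j] = float(np.median(tw))
    else:
        tw[int(np.argmax(sims))] *= 1.1
    state.template_weights = tw / tw.sum()
    return state


def track_video(video: ThermalVideo, roi: RectROI, config: RunConfig) -> pd.DataFrame:
    """Track the animal through a whole video.

    Returns a per-frame table: ``frame, time_s, x_px, y_px, sx, sy, error,
    low_confidence``.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames to track")
    video8 = stretch_video(video.frames, config.stretch_lo_pct, config.stretch_hi_pct)
    state = init_tracker(video8[0], roi, config.tracker, seed=config.rng_seed)
    cx, cy = roi.center
    rows = [
        {"x_px": cx, "y_px": cy, "sx": 1.0, "sy": 1.0, "error": 0.0, "low_confidence": False}
    ]
    for f in range(1, video.n_frames):
        state, row = step(state, video8[f])
        state = update_templates(state, row.pop("_best_patch"))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "time_s", np.arange(video.n_frames) / video.fps)
    out.insert(0, "frame", np.arange(video.n_frames))
    return out
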