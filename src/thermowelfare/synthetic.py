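"""Ground-truthed synthetic thermal scenes.

Emulates the acquisition setup the pipelines target: a warm rodent body
(~35 deg C) on a cool background (~22 deg C), recorded top-down/frontal at
up to 640 x 480 px and 60 fps. Two scene families:

* breathing scenes - a static textured body whose chest sub-region
  translates vertically following a commanded breaths/min profile, for the
  RR pipeline;
* Open Field scenes - the body follows a bounded correlated random walk
  across an arena, optionally wall-biased (thigmotaxis), for the tracker.

The texture is a frozen smoothed random field advected rigidly with the
body so that corner detection has gradients to work with; the body edge is
Gaussian-blurred to mimic the thermal point-spread halo. Chest displacement
uses bilinear sub-pixel shifting so amplitudes below one pixel remain
detectable. Per-frame sensor noise is i.i.d. Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import RectROI, ThermalVideo

RRProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclass
class BreathSceneConfig:
    """Parameters of a synthetic breathing scene."""

    frame_shape: Tuple[int, int] = (480, 640)  # (rows, cols)
    fps: float = 60.0
    duration_s: float = 120.0
    background_c: float = 22.0
    body_c: float = 35.0
    noise_sigma_c: float = 0.3
    body_center: Optional[Tuple[float, float]] = None  # (x, y), default frame center
    body_axes: Optional[Tuple[float, float]] = None    # semi-axes (x, y) px
    chest_rect: Optional[Tuple[int, int, int, int]] = None  # (x0, y0, x1, y1)
    breath_amplitude_px: float = 1.5
    rr_profile: RRProfile = 54.0  # breaths/min, constant or callable of time
    texture_strength_c: float = 1.0
    texture_corr_px: float = 3.0
    edge_blur_px: float = 1.5
    truth_hop_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_shape
        if self.body_center is None:
            self.body_center = (w / 2.0, h / 2.0)
        if self.body_axes is None:
            self.body_axes = (0.20 * w, 0.18 * h)
        if self.chest_rect is None:
            cx, cy = self.body_center
            ax, ay = self.body_axes
            self.chest_rect = (
                int(round(cx - 0.45 * ax)),
                int(round(cy - 0.35 * ay)),
                int(round(cx + 0.45 * ax)),
                int(round(cy + 0.35 * ay)),
            )
        if self.breath_amplitude_px <= 0:
            raise ValueError("breath amplitude must be > 0")
        if self.texture_strength_c <= 0:
            raise ValueError("texture_strength_c must be > 0 (features need texture)")
        x0, y0, x1, y1 = self.chest_rect
        margin = self.breath_amplitude_px + 2.0
        cx, cy = self.body_center
        ax, ay = self.body_axes
        for x, y in ((x0, y0), (x1, y0), (x0, y1), (x1, y1)):
            if ((x - cx) / ax) ** 2 + ((y - cy + np.sign(y - cy) * margin) / ay) ** 2 >= 1.0:
                raise ValueError("chest_rect (plus breathing margin) must lie inside the body ellipse")

    @property
    def chest_roi(self) -> RectROI:
        return RectROI(*self.chest_rect)


def _rr_at(profile: RRProfile, t: np.ndarray) -> np.ndarray:
    if callable(profile):
        return np.asarray(profile(t), dtype=float)
    return np.full(t.shape, float(profile))


def ramp_profile(bpm_start: float, bpm_end: float, duration_s: float) -> Callable:
    """Linear RR ramp over the scene duration."""

    def profile(t: np.ndarray) -> np.ndarray:
        frac = np.clip(np.asarray(t) / duration_s, 0.0, 1.0)
        return bpm_start + (bpm_end - bpm_start) * frac

    return profile


def step_profile(bpm_before: float, bpm_after: float, t_step_s: float) -> Callable:
    """RR step change at ``t_step_s``."""

    def profile(t: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(t) < t_step_s, bpm_before, bpm_after)

    return profile


def _body_scene(
    frame_shape: Tuple[int, int],
    center: Tuple[float, float],
    axes: Tuple[float, float],
    background_c: float,
    body_c: float,
    texture: np.ndarray,
    edge_blur_px: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free base frame and the hard (commanded) body mask."""
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    ax, ay = axes
    hard = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    soft = hard.astype(np.float32)
    if edge_blur_px > 0:
        soft = gaussian_filter(soft, edge_blur_px)
    scene = background_c + soft * (body_c - background_c + texture)
    return scene.astype(np.float32), hard


def _make_texture(shape, corr_px, strength, rng) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal(shape), corr_px)
    sd = field.std()
    if sd > 0:
        field *= strength / sd
    return field.astype(np.float32)


def make_breathing_video(cfg: BreathSceneConfig) -> Tuple[ThermalVideo, pd.DataFrame]:
    """Render a breathing scene and its commanded-RR truth trace.

    The chest rectangle translates vertically by
    ``a * sin(2 pi integral f(t) dt)``; the truth trace samples the
    commanded profile every ``truth_hop_s`` (columns ``time_s, rr_bpm``).
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.fps))
    if n_frames < 2:
        raise ValueError("scene must span at least 2 frames")
    texture = _make_texture(cfg.frame_shape, cfg.texture_corr_px, cfg.texture_strength_c, rng)
    scene0, _ = _body_scene(
        cfg.frame_shape,
        cfg.body_center,
        cfg.body_axes,
        cfg.background_c,
        cfg.body_c,
        texture,
        cfg.edge_blur_px,
    )
    t = np.arange(n_frames) / cfg.fps
    freq_hz = _rr_at(cfg.rr_profile, t) / 60.0
    if np.any(freq_hz <= 0) or np.any(freq_hz >= cfg.fps / 2.0):
        raise ValueError("rr_profile must stay within (0, 30*fps) breaths/min")
    phase = 2.0 * np.pi * np.cumsum(freq_hz) / cfg.fps
    disp = cfg.breath_amplitude_px * np.sin(phase)

    x0, y0, x1, y1 = cfg.chest_rect
    frames = np.empty((n_frames,) + cfg.frame_shape, dtype=np.float32)
    frames[:] = scene0[None]
    for i in range(n_frames):
        d = disp[i]
        k = int(np.floor(d))
        wfrac = np.float32(d - k)
        top = scene0[y0 + k : y1 + k, x0:x1]
        bot = scene0[y0 + k + 1 : y1 + k + 1, x0:x1]
        frames[i, y0:y1, x0:x1] = top * (1.0 - wfrac) + bot * wfrac
    if cfg.noise_sigma_c > 0:
        chunk = max(1, int(2**24 // scene0.size))  # ~64 MB of noise at a time
        for a in range(0, n_frames, chunk):
            b = min(a + chunk, n_frames)
            frames[a:b] += cfg.noise_sigma_c * rng.standard_normal(
                (b - a,) + cfg.frame_shape, dtype=np.float32
            )
    video = ThermalVideo(frames=frames, fps=cfg.fps, intensity_kind="radiometric_celsius")
    t_truth = np.arange(cfg.truth_hop_s, cfg.duration_s + 1e-9, cfg.truth_hop_s)
    truth = pd.DataFrame({"time_s": t_truth, "rr_bpm": _rr_at(cfg.rr_profile, t_truth)})
    return video, truth


def body_mask(cfg: BreathSceneConfig) -> np.ndarray:
    """The commanded (hard) body mask of a breathing scene."""
    h, w = cfg.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = cfg.body_center
    ax, ay = cfg.body_axes
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


@dataclass
class OFTSceneConfig:
    """Parameters of a synthetic Open Field scene."""

    frame_shape: Tuple[int, int] = (480, 640)
    fps: float = 30.0
    duration_s: float = 30.0
    arena_rect: Optional[Tuple[int, int, int, int]] = None  # (x0, y0, x1, y1) px
    arena_w_mm: float = 720.0
    arena_h_mm: float = 720.0
    background_c: float = 22.0
    body_c: float = 35.0
    noise_sigma_c: float = 0.3
    body_axes: Tuple[float, float] = (22.0, 14.0)  # semi-axes (x, y) px
    speed_mean_px_s: float = 60.0
    speed_sigma_px_s: float = 30.0
    speed_tau_s: float = 1.0
    turn_sigma_rad_s: float = 1.5
    thigmotaxis_bias: float = 0.0
    texture_strength_c: float = 1.0
    texture_corr_px: float = 3.0
    edge_blur_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.frame_shape
        if self.arena_rect is None:
            m = int(0.05 * min(h, w))
            self.arena_rect = (m, m, w - m, h - m)
        x0, y0, x1, y1 = self.arena_rect
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError("arena rect must lie inside the frame")
        ax, ay = self.body_axes
        if 2 * ax >= (x1 - x0) or 2 * ay >= (y1 - y0):
            raise ValueError("body must fit inside the arena")
        if not (0.0 <= self.thigmotaxis_bias <= 1.0):
            raise ValueError("thigmotaxis_bias must lie in [0, 1]")


def simulate_walk(cfg: OFTSceneConfig) -> np.ndarray:
    """Correlated random walk of the body center, reflected at the walls.

    Returns per-frame (x, y) positions in px. ``thigmotaxis_bias`` steers
    the heading toward the nearest wall, reproducing wall-hugging behavior.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fps))
    dt = 1.0 / cfg.fps
    x0, y0, x1, y1 = cfg.arena_rect
    ax, ay = cfg.body_axes
    lo = np.array([x0 + ax, y0 + ay])
    hi = np.array([x1 - ax, y1 - ay])
    pos = np.empty((n, 2))
    p = (lo + hi) / 2.0
    theta = rng.uniform(0.0, 2.0 * np.pi)
    speed = max(cfg.speed_mean_px_s, 0.0)
    for i in range(n):
        pos[i] = p
        theta += cfg.turn_sigma_rad_s * np.sqrt(dt) * rng.standard_normal()
        if cfg.thigmotaxis_bias > 0:
            # steer toward the nearest wall point
            d_wall = np.array([p[0] - lo[0], hi[0] - p[0], p[1] - lo[1], hi[1] - p[1]])
            side = int(np.argmin(d_wall))
            target_theta = (np.pi, 0.0, 3 * np.pi / 2, np.pi / 2)[side]
            dth = (target_theta - theta + np.pi) % (2.0 * np.pi) - np.pi
            theta += 4.0 * cfg.thigmotaxis_bias * dth * dt
        speed += (
            (cfg.speed_mean_px_s - speed) * dt / cfg.speed_tau_s
            + cfg.speed_sigma_px_s * np.sqrt(dt) * rng.standard_normal()
        )
        speed = max(speed, 0.0)
        p = p + speed * dt * np.array([np.cos(theta), np.sin(theta)])
        # reflect into the admissible box
        for k in range(2):
            if p[k] < lo[k]:
                p[k] = 2 * lo[k] - p[k]
                theta = np.pi - theta if k == 0 else -theta
            elif p[k] > hi[k]:
                p[k] = 2 * hi[k] - p[k]
                theta = np.pi - theta if k == 0 else -theta
            p[k] = np.clip(p[k], lo[k], hi[k])
    return pos


def make_oft_video(cfg: OFTSceneConfig) -> Tuple[ThermalVideo, pd.DataFrame]:
    """Render an Open Field scene and its ground-truth trajectory.

    Truth columns: ``frame, time_s, x_px, y_px, x_mm, y_mm`` (mm coordinates
    relative to the arena's top-left corner).
    """
    rng = np.random.default_rng(cfg.seed)
    pos = simulate_walk(cfg)
    n = pos.shape[0]
    h, w = cfg.frame_shape
    ax, ay = cfg.body_axes
    # body patch rendered once in body-centric coordinates, pasted per frame
    pr = int(np.ceil(ay + 3 * cfg.edge_blur_px)) + 2
    pc = int(np.ceil(ax + 3 * cfg.edge_blur_px)) + 2
    py, px = np.mgrid[-pr : pr + 1, -pc : pc + 1]
    hard = (px / ax) ** 2 + (py / ay) ** 2 <= 1.0
    soft = gaussian_filter(hard.astype(np.float32), cfg.edge_blur_px)
    tex = _make_texture(hard.shape, cfg.texture_corr_px, cfg.texture_strength_c, rng)
    patch = soft * (cfg.body_c - cfg.background_c + tex)

    frames = np.empty((n, h, w), dtype=np.float32)
    for i in range(n):
        frame = np.full((h, w), cfg.background_c, dtype=np.float32)
        cx, cy = pos[i]
        ix, iy = int(np.floor(cx)), int(np.floor(cy))
        fx, fy = np.float32(cx - ix), np.float32(cy - iy)
        # bilinear sub-pixel placement of the patch
        shifted = (
            (1 - fy) * ((1 - fx) * patch[1:, 1:] + fx * patch[1:, :-1])
            + fy * ((1 - fx) * patch[:-1, 1:] + fx * patch[:-1, :-1])
        )
        r0, c0 = iy - pr + 1, ix - pc + 1
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r0 + shifted.shape[0], h)
        cc1 = min(c0 + shifted.shape[1], w)
        frame[rr0:rr1, cc0:cc1] += shifted[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        if cfg.noise_sigma_c > 0:
            frame += cfg.noise_sigma_c * rng.standard_normal((h, w), dtype=np.float32)
        frames[i] = frame
    video = ThermalVideo(frames=frames, fps=cfg.fps, intensity_kind="radiometric_celsius")
    x0, y0, x1, y1 = cfg.arena_rect
    sx = cfg.arena_w_mm / (x1 - x0)
    sy = cfg.arena_h_mm / (y1 - y0)
    truth = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / cfg.fps,
            "x_px": pos[:, 0],
            "y_px": pos[:, 1],
            "x_mm": (pos[:, 0] - x0) * sx,
            "y_mm": (pos[:, 1] - y0) * sy,
        }
    )
    return video, truth
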