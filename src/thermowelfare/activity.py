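"""Locomotor-activity readouts from a track: velocity, occupancy heat maps
and Open Field zone metrics.

Conventions: the arena is calibrated by its physical size (mm) and its
pixel rectangle in the frame; the center zone is the concentric rectangle
whose sides are ``center_frac`` of the arena sides (the classic Open Field
center/periphery split); immobility is any maximal run of sub-threshold
speed lasting at least ``immobility_min_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .config import ActivityConfig


@dataclass(frozen=True)
class ArenaCalibration:
    """Physical arena size and its pixel footprint in the frame."""

    arena_w_mm: float
    arena_h_mm: float
    x0_px: float
    y0_px: float
    x1_px: float
    y1_px: float

    def __post_init__(self) -> None:
        if self.arena_w_mm <= 0 or self.arena_h_mm <= 0:
            raise ValueError("arena dimensions must be positive")
        if not (self.x0_px < self.x1_px and self.y0_px < self.y1_px):
            raise ValueError("arena pixel rectangle is degenerate")

    @property
    def mm_per_px_x(self) -> float:
        return self.arena_w_mm / (self.x1_px - self.x0_px)

    @property
    def mm_per_px_y(self) -> float:
        return self.arena_h_mm / (self.y1_px - self.y0_px)

    def to_mm(self, x_px: np.ndarray, y_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            (np.asarray(x_px, dtype=float) - self.x0_px) * self.mm_per_px_x,
            (np.asarray(y_px, dtype=float) - self.y0_px) * self.mm_per_px_y,
        )


@dataclass
class OccupancyMap:
    """Cumulative dwell time (seconds) on a grid over the arena."""

    grid: np.ndarray
    cell_w_mm: float
    cell_h_mm: float

    @property
    def total_s(self) -> float:
        return float(self.grid.sum())


@dataclass
class ActivitySummary:
    total_distance_mm: float
    mean_speed_mm_s: float
    max_speed_mm_s: float
    time_center_s: float
    time_periphery_s: float
    distance_center_mm: float
    distance_periphery_mm: float
    immobility_time_s: float
    duration_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _positions_mm(track: pd.DataFrame, calib: ArenaCalibration) -> tuple[np.ndarray, np.ndarray]:
    return calib.to_mm(track["x_px"].to_numpy(), track["y_px"].to_numpy())


def velocity(
    track: pd.DataFrame,
    calib: ArenaCalibration,
    fps: float,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Smoothed speed series in mm/s.

    Central finite differences of the mm-converted centers (one-sided at
    the endpoints), then a moving average over ``smooth_s`` seconds.
    """
    x, y = _positions_mm(track, calib)
    if x.size < 3:
        raise ValueError("need >= 3 frames for a velocity estimate")
    dt = 1.0 / fps
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    win = max(1, int(round(smooth_s * fps)))
    if win > 1:
        # average the vector components, not the magnitudes: jitter of a
        # stationary animal then cancels instead of rectifying
        vx = uniform_filter1d(vx, size=win, mode="nearest")
        vy = uniform_filter1d(vy, size=win, mode="nearest")
    return np.hypot(vx, vy)


def occupancy_heatmap(
    track: pd.DataFrame,
    calib: ArenaCalibration,
    fps: float,
    grid_n: int = 32,
) -> OccupancyMap:
    """Dwell-time grid: each frame adds 1/fps s to its cell.

    Positions outside the arena are clipped into the border cells (with a
    warning), so the total mass always equals the track duration.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    x, y = _positions_mm(track, calib)
    ix = np.floor(x / calib.arena_w_mm * grid_n).astype(int)
    iy = np.floor(y / calib.arena_h_mm * grid_n).astype(int)
    outside = (ix < 0) | (ix >= grid_n) | (iy < 0) | (iy >= grid_n)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} track positions outside the arena were clipped")
        ix = np.clip(ix, 0, grid_n - 1)
        iy = np.clip(iy, 0, grid_n - 1)
    grid = np.zeros((grid_n, grid_n))
    np.add.at(grid, (iy, ix), 1.0 / fps)
    return OccupancyMap(
        grid=grid,
        cell_w_mm=calib.arena_w_mm / grid_n,
        cell_h_mm=calib.arena_h_mm / grid_n,
    )


def log_heatmap(occupancy: OccupancyMap) -> OccupancyMap:
    """Order-preserving log compression: cell -> ln(1 + seconds)."""
    return OccupancyMap(
        grid=np.log1p(occupancy.grid),
        cell_w_mm=occupancy.cell_w_mm,
        cell_h_mm=occupancy.cell_h_mm,
    )


def zone_metrics(
    track: pd.DataFrame,
    calib: ArenaCalibration,
    fps: float,
    config: ActivityConfig | None = None,
) -> ActivitySummary:
    """Open Field summary metrics.

    Total and per-zone distance, per-zone dwell time, mean/max speed and
    immobility time. Per-step distance is assigned to the zone of the
    segment midpoint, which makes the split invariant under time reversal.
    """
    config = config or ActivityConfig()
    x, y = _positions_mm(track, calib)
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 frames")
    dt = 1.0 / fps
    duration = n * dt

    fx = config.center_frac
    cx_lo = calib.arena_w_mm * (1.0 - fx) / 2.0
    cx_hi = calib.arena_w_mm * (1.0 + fx) / 2.0
    cy_lo = calib.arena_h_mm * (1.0 - fx) / 2.0
    cy_hi = calib.arena_h_mm * (1.0 + fx) / 2.0

    def in_center(px, py):
        return (px >= cx_lo) & (px <= cx_hi) & (py >= cy_lo) & (py <= cy_hi)

    center_frames = in_center(x, y)
    time_center = float(center_frames.sum() * dt)
    time_periphery = duration - time_center

    steps = np.hypot(np.diff(x), np.diff(y))
    mid_center = in_center((x[:-1] + x[1:]) / 2.0, (y[:-1] + y[1:]) / 2.0)
    distance_center = float(steps[mid_center].sum())
    distance_periphery = float(steps[~mid_center].sum())

    speed = velocity(track, calib, fps, config.speed_smooth_s) if n >= 3 else np.zeros(n)
    slow = speed < config.immobility_speed_mm_s
    immobility = 0.0
    run = 0
    for flag in np.append(slow, False):
        if flag:
            run += 1
        else:
            if run * dt >= config.immobility_min_s:
                immobility += run * dt
            run = 0

    return ActivitySummary(
        total_distance_mm=float(steps.sum()),
        mean_speed_mm_s=float(speed.mean()),
        max_speed_mm_s=float(speed.max()),
        time_center_s=time_center,
        time_periphery_s=time_periphery,
        distance_center_mm=distance_center,
        distance_periphery_mm=distance_periphery,
        immobility_time_s=immobility,
        duration_s=duration,
    )
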