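"""Reading and writing of thermal video stacks, RR traces and occupancy maps.

The first-class on-disk video format is a multipage TIFF: float32 frames for
radiometric (degrees Celsius per pixel) data, uint8/uint16 for grayscale.
Frame rate is stored in the TIFF ImageDescription as JSON when written by
this package; an explicit ``fps`` argument always takes precedence because
thermal stacks in the wild usually carry no timing metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

INTENSITY_KINDS = ("radiometric_celsius", "gray8", "gray16")


@dataclass
class ThermalVideo:
    """An ordered stack of thermal frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Per-pixel intensity: temperature in degrees Celsius for radiometric
        data, raw gray levels otherwise.
    fps : float
        Acquisition frame rate (> 0).
    intensity_kind : {"radiometric_celsius", "gray8", "gray16"}
    pixel_pitch_mm : float, optional
        Physical size of one pixel on the object plane, when known.
    """

    frames: np.ndarray
    fps: float
    intensity_kind: str = "radiometric_celsius"
    pixel_pitch_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (frame, row, col) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a thermal video needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"intensity_kind must be one of {INTENSITY_KINDS}")
        if self.intensity_kind == "radiometric_celsius" and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("radiometric frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class RectROI:
    """Half-open rectangular region [x0, x1) x [y0, y1), 0-based, x = column."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("ROI must satisfy x0 < x1 and y0 < y1")
        if self.area < 16:
            raise ValueError("ROI area must be >= 16 px")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1 - 1) / 2.0, (self.y0 + self.y1 - 1) / 2.0)

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} outside frame of shape {shape}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    @classmethod
    def from_string(cls, text: str) -> "RectROI":
        parts = [int(p) for p in text.replace(" ", "").split(",")]
        if len(parts) != 4:
            raise ValueError("ROI string must be 'x0,y0,x1,y1'")
        return cls(*parts)


def write_thermal_video(video: ThermalVideo, path) -> None:
    """Write a video as a multipage TIFF, embedding fps metadata as JSON."""
    meta = {"fps": video.fps, "intensity_kind": video.intensity_kind}
    if video.pixel_pitch_mm is not None:
        meta["pixel_pitch_mm"] = video.pixel_pitch_mm
    frames = video.frames
    if video.intensity_kind == "radiometric_celsius":
        frames = frames.astype(np.float32, copy=False)
    tifffile.imwrite(
        path, frames, photometric="minisblack", description=json.dumps(meta)
    )


def _read_tiff(path, fps, intensity_kind, pixel_pitch_mm):
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        raise ValueError(f"{path}: no fps metadata found; pass fps explicitly")
    if intensity_kind is None:
        intensity_kind = meta.get("intensity_kind")
    if intensity_kind is None:
        intensity_kind = _infer_kind(frames)
    if pixel_pitch_mm is None:
        pixel_pitch_mm = meta.get("pixel_pitch_mm")
    return frames, float(fps), intensity_kind, pixel_pitch_mm


def _infer_kind(frames: np.ndarray) -> str:
    if np.issubdtype(frames.dtype, np.floating):
        return "radiometric_celsius"
    if frames.dtype == np.uint8:
        return "gray8"
    return "gray16"


def read_thermal_video(
    path,
    intensity_kind: Optional[str] = None,
    fps: Optional[float] = None,
    pixel_pitch_mm: Optional[float] = None,
) -> ThermalVideo:
    """Read a thermal video from a multipage TIFF or a grayscale video file.

    Radiometric TIFF values are passed through unmodified. An explicit
    ``fps`` overrides any value found in the container metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames, fps, intensity_kind, pixel_pitch_mm = _read_tiff(
            path, fps, intensity_kind, pixel_pitch_mm
        )
    else:
        frames, fps = _read_video_container(path, fps)
        if intensity_kind is None:
            intensity_kind = _infer_kind(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # collapse RGB from generic containers to grayscale
        frames = frames[..., :3].mean(axis=-1)
    return ThermalVideo(
        frames=frames,
        fps=fps,
        intensity_kind=intensity_kind,
        pixel_pitch_mm=pixel_pitch_mm,
    )


def _read_video_container(path, fps):
    try:
        import imageio.v3 as iio

        frames = np.stack(list(iio.imiter(path)))
        if fps is None:
            meta = iio.immeta(path)
            fps = meta.get("fps")
    except Exception as exc:  # plugin missing or unreadable file
        raise ValueError(f"cannot read video container {path}: {exc}") from exc
    if fps is None:
        raise ValueError(f"{path}: container carries no fps; pass fps explicitly")
    return frames, float(fps)


RR_TRACE_COLUMNS = ["time_s", "rr_bpm", "rr_bpm_median", "periodicity", "pc_index"]


def write_rr_trace(trace: pd.DataFrame, path) -> None:
    """Write an RR trace as CSV (6 significant digits, lossless round trip)."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty RR trace")
    missing = [c for c in RR_TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"RR trace missing columns: {missing}")
    trace[RR_TRACE_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_rr_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_heatmap(grid: np.ndarray, path_csv=None, path_png=None, log: bool = False) -> None:
    """Write an occupancy grid: CSV of raw dwell seconds, PNG rendering.

    The PNG uses a blue-to-yellow colormap (low to high dwell time). With
    ``log=True`` the rendered image is computed from the log1p-transformed
    grid; the CSV always holds the raw seconds.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("occupancy grid must be 2-D")
    if not np.all(np.isfinite(grid)):
        raise ValueError("occupancy grid must be finite")
    if np.any(grid < 0):
        raise ValueError("occupancy grid cells must be non-negative")
    if path_csv is not None:
        np.savetxt(path_csv, grid, delimiter=",", fmt="%.6g")
    if path_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = np.log1p(grid) if log else grid
        vmax = img.max() if img.max() > 0 else 1.0
        plt.imsave(path_png, img, cmap="cividis", vmin=0.0, vmax=vmax)


def read_heatmap_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
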