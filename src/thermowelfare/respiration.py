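"""Respiratory-rate estimation from chest motion in thermal video.

Pipeline: Shi-Tomasi feature detection inside a thorax ROI (first frame
only) -> pyramidal Lucas-Kanade trajectory tracking -> pruning of the most
erratic quartile of trajectories -> selection of the dominant motion axis
-> species band-pass FIR filtering -> PCA blind source separation ->
selection of the most periodic component by peak-to-total spectral ratio
-> RR = 60 x dominant frequency, median-smoothed over the trailing 5 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from skimage.feature import corner_shi_tomasi
from sklearn.decomposition import PCA

from . import _optflow
from .config import RunConfig
from .io import RectROI, ThermalVideo
from .preprocess import multilevel_otsu, segment_animal, stretch_video


@dataclass
class TrajectoryMatrix:
    """Feature-point positions over time: one row per frame, one column per point."""

    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    t0_frame: int = 0

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must share one shape")
        if self.valid.shape != (self.x.shape[1],):
            raise ValueError("valid must have one flag per point")
        if not self.valid.any():
            raise ValueError("trajectory matrix needs >= 1 valid point")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def window(self, start: int, stop: int) -> "TrajectoryMatrix":
        """Sub-matrix over [start, stop); points with any non-finite position
        inside the window are dropped from the valid set."""
        xs = self.x[start:stop]
        ys = self.y[start:stop]
        ok = self.valid & np.all(np.isfinite(xs), axis=0) & np.all(np.isfinite(ys), axis=0)
        return TrajectoryMatrix(x=xs, y=ys, valid=ok, t0_frame=self.t0_frame + start)


@dataclass
class ComponentSet:
    """PCA score time series ordered by descending explained variance."""

    scores: np.ndarray      # (frames, k)
    variances: np.ndarray   # (k,) descending

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class AgreementMetrics:
    """Agreement statistics between an estimated and a reference RR trace."""

    rmse_bpm: float
    mean_rel_err_pct: float
    p90_rel_err_pct: float
    pearson_r: float
    bland_altman_bias_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float
    n_pairs: int


def detect_features(
    frame8: np.ndarray,
    roi: RectROI,
    mask: Optional[np.ndarray] = None,
    n: int = 100,
    min_distance: int = 3,
) -> np.ndarray:
    """Detect up to ``n`` Shi-Tomasi corners inside ``roi`` (and ``mask``).

    Points are ranked by the minimum eigenvalue of the local gradient
    structure matrix, with a minimum mutual distance enforced. Returns an
    (n_points, 2) array of (x, y) positions; raises if fewer than 4 corners
    are found (insufficient texture).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    frame8 = np.asarray(frame8)
    roi.validate_within(frame8.shape)
    response = corner_shi_tomasi(frame8.astype(np.float64), sigma=1.0)
    allowed = np.zeros(frame8.shape, dtype=bool)
    allowed[roi.slices()] = True
    if mask is not None:
        allowed &= mask
    response = np.where(allowed, response, 0.0)
    peak = response.max()
    if peak <= 0:
        raise ValueError("insufficient texture in ROI: no corner response")
    # greedy ranked selection: best-scoring candidates first, enforcing the
    # minimum mutual distance against already accepted points
    ys, xs = np.nonzero(response > 1e-3 * peak)
    scores = response[ys, xs]
    order = np.argsort(scores, kind="stable")[::-1]
    accepted_x: list[int] = []
    accepted_y: list[int] = []
    min_d2 = float(min_distance) ** 2
    for k in order:
        x, y = int(xs[k]), int(ys[k])
        if accepted_x:
            d2 = (np.array(accepted_x) - x) ** 2 + (np.array(accepted_y) - y) ** 2
            if d2.min() <= min_d2:
                continue
        accepted_x.append(x)
        accepted_y.append(y)
        if len(accepted_x) == n:
            break
    if len(accepted_x) < 4:
        raise ValueError(
            f"insufficient texture in ROI: only {len(accepted_x)} corners found"
        )
    return np.column_stack([accepted_x, accepted_y]).astype(np.float64)


def track_features(
    video8: np.ndarray,
    points: np.ndarray,
    win: int = 15,
    pyramid_levels: int = 2,
) -> TrajectoryMatrix:
    """Propagate feature points through the stack with pyramidal Lucas-Kanade."""
    x, y, alive = _optflow.track_points(video8, points, win=win, levels=pyramid_levels)
    # a point is useful even if it dies late; validity per window is handled
    # by TrajectoryMatrix.window. Globally valid = survived at least 2 frames.
    valid = np.all(np.isfinite(x[:2]), axis=0)
    if not valid.any():
        raise ValueError("all feature points lost immediately")
    return TrajectoryMatrix(x=x, y=y, valid=valid)


def prune_unstable(traj: TrajectoryMatrix, percentile: float = 25.0) -> TrajectoryMatrix:
    """Discard the most erratic trajectories.

    Instability of a point is its mean inter-frame displacement magnitude;
    the top ``percentile`` % most-displaced points are invalidated, keeping
    exactly ``ceil((1 - p/100) * n_valid)`` points. Ties break by point index.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    idx = np.flatnonzero(traj.valid)
    if idx.size < 4:
        raise ValueError(f"need >= 4 valid points to prune, have {idx.size}")
    dx = np.diff(traj.x[:, idx], axis=0)
    dy = np.diff(traj.y[:, idx], axis=0)
    instability = np.hypot(dx, dy).mean(axis=0)
    n_keep = math.ceil((1.0 - percentile / 100.0) * idx.size)
    if n_keep < 4:
        raise ValueError(f"pruning would leave {n_keep} < 4 points")
    order = np.argsort(instability, kind="stable")
    keep = idx[order[:n_keep]]
    valid = np.zeros_like(traj.valid)
    valid[keep] = True
    return TrajectoryMatrix(x=traj.x, y=traj.y, valid=valid, t0_frame=traj.t0_frame)


def select_axis(traj: TrajectoryMatrix) -> Tuple[np.ndarray, str]:
    """Pick the axis (x or y) carrying the main chest motion.

    The axis whose summed per-point variance (after mean removal) is larger
    wins; ties break toward y. Returns a zero-mean (frames x points) matrix
    of the selected coordinate and the axis name.
    """
    idx = np.flatnonzero(traj.valid)
    xs = traj.x[:, idx]
    ys = traj.y[:, idx]
    var_x = np.nansum(np.nanvar(xs, axis=0))
    var_y = np.nansum(np.nanvar(ys, axis=0))
    sig = xs if var_x > var_y else ys
    axis = "x" if var_x > var_y else "y"
    return sig - np.nanmean(sig, axis=0, keepdims=True), axis


def _remez_order(delta_p: float, delta_s: float, transition_norm: float) -> int:
    """Herrmann/Rabiner equiripple order estimate (firpmord-style)."""
    lp, ls = math.log10(delta_p), math.log10(delta_s)
    d_inf = (0.005309 * lp**2 + 0.07114 * lp - 0.4761) * ls - (
        0.00266 * lp**2 + 0.5941 * lp + 0.4278
    )
    f = 11.01217 + 0.51244 * (lp - ls)
    n = d_inf / transition_norm - f * transition_norm + 1.0
    return max(8, int(math.ceil(n)))


def design_bandpass(
    passband_hz: Tuple[float, float],
    fs: float,
    transition_hz: float = 0.2,
    ripple_db: float = 0.4,
    atten_db: float = 40.0,
) -> np.ndarray:
    """Linear-phase equiripple (Parks-McClellan) band-pass FIR taps.

    The design is verified on a dense grid (passband within +-ripple_db of
    unity, stopbands below -atten_db) and the order is increased until the
    verification passes. The default 0.4 dB ripple keeps the *applied*
    response within 1 dB, because filtering is forward-backward (the
    effective magnitude response is the square of the design).
    """
    lo, hi = passband_hz
    nyq = fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"passband {passband_hz} infeasible at fs={fs}")
    if lo - transition_hz <= 0 or hi + transition_hz >= nyq:
        raise ValueError(
            f"passband {passband_hz} leaves no room for a {transition_hz} Hz transition at fs={fs}"
        )
    delta_p = (10 ** (ripple_db / 20.0) - 1.0) / (10 ** (ripple_db / 20.0) + 1.0)
    delta_s = 10 ** (-atten_db / 20.0)
    numtaps = _remez_order(delta_p, delta_s, transition_hz / fs)
    numtaps += 1 - numtaps % 2  # force odd (type I) for a band-pass
    bands = [0.0, lo - transition_hz, lo, hi, hi + transition_hz, nyq]
    weight = [delta_p / delta_s, 1.0, delta_p / delta_s]
    for _ in range(10):
        taps = sps.remez(numtaps, bands, [0.0, 1.0, 0.0], weight=weight, fs=fs)
        if _meets_design_targets(taps, bands, fs, ripple_db, atten_db):
            return taps
        numtaps = int(numtaps * 1.15) + 2
        numtaps += 1 - numtaps % 2
    raise RuntimeError("band-pass design failed to meet its ripple/attenuation targets")


def _meets_design_targets(taps, bands, fs, ripple_db, atten_db) -> bool:
    w, h = sps.freqz(taps, worN=8192, fs=fs)
    mag = np.abs(h)
    stop = ((w <= bands[1]) | (w >= bands[4])) & (w > 0)
    passb = (w >= bands[2]) & (w <= bands[3])
    with np.errstate(divide="ignore"):
        gain_db = 20.0 * np.log10(np.maximum(mag, 1e-12))
    return bool(
        np.all(gain_db[stop] <= -atten_db)
        and np.all(np.abs(gain_db[passb]) <= ripple_db)
    )


def apply_filter(signals: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-net-delay band-pass: forward-backward FIR application, per column."""
    signals = np.asarray(signals, dtype=np.float64)
    n = signals.shape[0]
    if n <= 3 * taps.size:
        raise ValueError(
            f"signal length {n} too short for filter of {taps.size} taps "
            f"(need > {3 * taps.size} samples)"
        )
    return sps.filtfilt(taps, [1.0], signals, axis=0)


def pca_decompose(signals: np.ndarray, k: int = 6) -> ComponentSet:
    """Blind source separation of trajectory signals via PCA.

    Columns are mean-centered; the first ``min(k, n_points)`` principal
    component score time series are returned with descending variance.
    """
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2 or signals.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if signals.shape[0] < 8:
        raise ValueError("need >= 8 time samples")
    n_comp = min(k, signals.shape[1], signals.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(signals)
    if pca.explained_variance_[0] <= 0:
        raise ValueError("signals have zero variance (rank < 1)")
    return ComponentSet(scores=scores, variances=pca.explained_variance_)


def periodicity_score(
    component: np.ndarray,
    fs: float,
    passband_hz: Tuple[float, float],
    peak_halfwidth_hz: float = 0.05,
    harmonic_halfwidth_hz: float = 0.05,
    max_resolution_hz: float = 0.01,
) -> Tuple[float, float]:
    """Peak-to-total spectral ratio of a component.

    The component is Hamming-windowed and zero-padded to a frequency
    resolution of at most ``max_resolution_hz``; the dominant frequency f0
    is the power-spectrum argmax inside the passband, and the score is the
    fraction of total power (over (0, fs/2]) lying within
    ``peak_halfwidth_hz`` of f0 or ``harmonic_halfwidth_hz`` of 2 f0.
    """
    component = np.asarray(component, dtype=np.float64)
    n = component.size
    if n < 4 * fs:
        raise ValueError("component must span at least 4 s")
    component = component - component.mean()
    if not np.any(component):
        raise ValueError("zero-power component")
    windowed = component * np.hamming(n)
    nfft = 1
    while nfft < max(n, fs / max_resolution_hz):
        nfft *= 2
    spec = np.fft.rfft(windowed, nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    positive = freqs > 0
    total = power[positive].sum()
    if total <= 0:
        raise ValueError("zero-power component")
    lo, hi = passband_hz
    band = positive & (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError(f"passband {passband_hz} contains no frequency bins")
    f0 = freqs[band][np.argmax(power[band])]
    sel = positive & (
        (np.abs(freqs - f0) <= peak_halfwidth_hz)
        | (np.abs(freqs - 2.0 * f0) <= harmonic_halfwidth_hz)
    )
    score = float(power[sel].sum() / total)
    return score, float(f0)


def estimate_rr_window(
    components: ComponentSet,
    fs: float,
    passband_hz: Tuple[float, float],
    peak_halfwidth_hz: float = 0.05,
    harmonic_halfwidth_hz: float = 0.05,
) -> Tuple[float, int, float]:
    """RR (breaths/min) from the most periodic component.

    Returns ``(rr_bpm, pc_index, score)`` where ``pc_index`` is the 0-based
    index of the selected component (ties break toward the lower index).
    """
    scores = np.empty(components.k)
    f0s = np.empty(components.k)
    for j in range(components.k):
        scores[j], f0s[j] = periodicity_score(
            components.scores[:, j],
            fs,
            passband_hz,
            peak_halfwidth_hz,
            harmonic_halfwidth_hz,
        )
    best = int(np.argmax(scores))
    return 60.0 * f0s[best], best, float(scores[best])


def rr_trace(video: ThermalVideo, roi: RectROI, config: RunConfig) -> pd.DataFrame:
    """Full RR pipeline over sliding windows.

    Feature detection happens once on the first frame; tracking runs over
    the whole video; the band-pass is applied once to the full-length
    trajectories; pruning, axis selection, PCA and spectral estimation run
    per sliding window of ``rr_window_s`` hopped every ``rr_hop_s``.
    ``rr_bpm_median`` is the median of the estimates in the trailing
    ``median_s`` seconds. Windows where the chain fails yield gap rows
    flagged invalid.
    """
    config.validate_for_fps(video.fps)
    fps = video.fps
    win_frames = int(round(config.rr_window_s * fps))
    hop_frames = max(1, int(round(config.rr_hop_s * fps)))
    if video.n_frames < win_frames:
        raise ValueError(
            f"video ({video.duration_s:.1f} s) shorter than one "
            f"{config.rr_window_s} s window"
        )
    thresholds = multilevel_otsu(video.frames[0], config.n_otsu_classes)
    seg = segment_animal(video.frames[0], thresholds)
    video8 = stretch_video(video.frames, config.stretch_lo_pct, config.stretch_hi_pct)
    roi.validate_within(video.shape)
    mask = None if seg.is_empty else seg.mask
    points = detect_features(video8[0], roi, mask, n=config.n_features)
    traj = track_features(
        video8, points, win=config.lk_window, pyramid_levels=config.lk_pyramid_levels
    )
    # full-length band-pass of both axes (NaN tails are frozen at the last
    # tracked position so lost points contribute no spurious band power)
    taps = design_bandpass(config.passband_hz, fps, config.filter_transition_hz)
    xf = apply_filter(_fill_nan(traj.x), taps)
    yf = apply_filter(_fill_nan(traj.y), taps)

    rows = []
    for start in range(0, video.n_frames - win_frames + 1, hop_frames):
        stop = start + win_frames
        time_s = stop / fps
        try:
            sub = traj.window(start, stop)
            pruned = prune_unstable(sub, config.prune_percentile)
            _, axis = select_axis(pruned)
            cols = np.flatnonzero(pruned.valid)
            filt = (xf if axis == "x" else yf)[start:stop, cols]
            comps = pca_decompose(filt, config.n_pcs)
            rr, pc_index, score = estimate_rr_window(
                comps,
                fps,
                config.passband_hz,
                config.peak_halfwidth_hz,
                config.harmonic_halfwidth_hz,
            )
            rows.append((time_s, rr, score, pc_index, True))
        except ValueError:
            rows.append((time_s, np.nan, np.nan, -1, False))
    trace = pd.DataFrame(
        rows, columns=["time_s", "rr_bpm", "periodicity", "pc_index", "valid"]
    )
    medians = np.full(len(trace), np.nan)
    t = trace["time_s"].to_numpy()
    rr = trace["rr_bpm"].to_numpy()
    ok = trace["valid"].to_numpy()
    for i in range(len(trace)):
        sel = ok & (t > t[i] - config.median_s) & (t <= t[i])
        if sel.any():
            medians[i] = np.median(rr[sel])
    trace["rr_bpm_median"] = medians
    return trace[["time_s", "rr_bpm", "rr_bpm_median", "periodicity", "pc_index", "valid"]]


def _fill_nan(arr: np.ndarray) -> np.ndarray:
    """Forward/backward-fill NaNs per column (constant extension)."""
    out = np.array(arr, dtype=np.float64)
    for j in range(out.shape[1]):
        col = out[:, j]
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        if bad.all():
            out[:, j] = 0.0
            continue
        good = np.flatnonzero(~bad)
        out[bad, j] = np.interp(np.flatnonzero(bad), good, col[good])
    return out


def evaluate_against_reference(
    est_trace: pd.DataFrame,
    ref_trace: pd.DataFrame,
    est_col: str = "rr_bpm_median",
    ref_col: str = "rr_bpm",
    max_dt_s: Optional[float] = None,
) -> AgreementMetrics:
    """Agreement metrics between an estimated and a reference RR trace.

    Reference samples are matched to estimate timestamps by nearest
    neighbor within ``max_dt_s`` (default: half the median estimate hop).
    Computes RMSE, mean and 90th-percentile relative error, Pearson r, and
    Bland-Altman bias with 95% limits of agreement.
    """
    est_t = est_trace["time_s"].to_numpy(dtype=float)
    est_v = est_trace[est_col].to_numpy(dtype=float)
    ref_t = ref_trace["time_s"].to_numpy(dtype=float)
    ref_v = ref_trace[ref_col].to_numpy(dtype=float)
    if np.any(ref_v <= 0):
        raise ValueError("reference RR values must be positive")
    if max_dt_s is None:
        hops = np.diff(np.sort(est_t))
        max_dt_s = (np.median(hops) / 2.0) if hops.size else np.inf
    order = np.argsort(ref_t)
    ref_t, ref_v = ref_t[order], ref_v[order]
    pos = np.searchsorted(ref_t, est_t)
    pos = np.clip(pos, 1, len(ref_t) - 1) if len(ref_t) > 1 else np.zeros_like(pos)
    left = np.maximum(pos - 1, 0)
    choose_left = np.abs(est_t - ref_t[left]) <= np.abs(est_t - ref_t[pos])
    nearest = np.where(choose_left, left, pos)
    dt = np.abs(est_t - ref_t[nearest])
    pair = (dt <= max_dt_s) & np.isfinite(est_v)
    est_p = est_v[pair]
    ref_p = ref_v[nearest[pair]]
    if est_p.size < 3:
        raise ValueError(f"need >= 3 matched pairs, have {est_p.size}")
    diff = est_p - ref_p
    rel = 100.0 * np.abs(diff) / ref_p
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    if np.ptp(est_p) == 0 or np.ptp(ref_p) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(est_p, ref_p).statistic)
    return AgreementMetrics(
        rmse_bpm=float(np.sqrt(np.mean(diff**2))),
        mean_rel_err_pct=float(rel.mean()),
        p90_rel_err_pct=float(np.percentile(rel, 90)),
        pearson_r=r,
        bland_altman_bias_bpm=bias,
        loa_low_bpm=bias - 1.96 * sd,
        loa_high_bpm=bias + 1.96 * sd,
        n_pairs=int(est_p.size),
    )
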