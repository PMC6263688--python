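"""Run configuration for the RR and Open Field pipelines.

Species presets encode the resting-to-anesthetized respiratory frequency
ranges used to band-limit chest-motion signals: mice breathe roughly
60-276 breaths/min and rats 36-198 breaths/min under anesthesia, which
maps to passbands of [1, 4.6] Hz and [0.6, 3.3] Hz respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

#: Band-pass limits (Hz) per species preset.
SPECIES_BANDS: dict[str, Tuple[float, float]] = {
    "rat": (0.6, 3.3),
    "mouse": (1.0, 4.6),
}


@dataclass
class TrackerConfig:
    """Parameters of the sparse-representation particle-filter tracker."""

    n_particles: int = 300
    patch_size: Tuple[int, int] = (16, 16)  # (rows, cols) of template space
    n_templates: int = 10
    lam: float = 0.01          # l1 penalty weight
    alpha: float = 50.0        # weight sharpness: w ~ exp(-alpha * error)
    tau: float = 0.7           # template-update similarity threshold
    sigma_xy: float = 3.0      # particle position noise, px / frame
    sigma_log_scale: float = 0.01
    solver_tol: float = 1e-5
    solver_max_iter: int = 2000
    error_spike_factor: float = 5.0  # low-confidence if error > factor * running median


@dataclass
class ActivityConfig:
    """Occupancy-map and zone-metric parameters."""

    grid_n: int = 32
    center_frac: float = 0.5           # linear fraction of arena sides forming the center zone
    immobility_speed_mm_s: float = 5.0
    immobility_min_s: float = 1.0
    speed_smooth_s: float = 0.5


@dataclass
class RunConfig:
    """Global configuration shared by the CLI and library pipelines."""

    species: str = "custom"                       # "rat", "mouse" or "custom"
    passband_hz: Optional[Tuple[float, float]] = None
    rr_window_s: float = 10.0
    rr_hop_s: float = 1.0
    median_s: float = 5.0
    n_features: int = 100
    prune_percentile: float = 25.0
    n_pcs: int = 6
    peak_halfwidth_hz: float = 0.05
    harmonic_halfwidth_hz: float = 0.05
    n_otsu_classes: int = 3
    stretch_lo_pct: float = 1.0
    stretch_hi_pct: float = 99.0
    lk_window: int = 15
    lk_pyramid_levels: int = 2
    filter_transition_hz: float = 0.2
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("rat", "mouse", "custom"):
            raise ValueError(f"unknown species preset: {self.species!r}")
        if self.species != "custom" and self.passband_hz is None:
            self.passband_hz = SPECIES_BANDS[self.species]
        if self.passband_hz is None:
            raise ValueError("custom species requires an explicit passband_hz")
        lo, hi = self.passband_hz
        if not (0.0 < lo < hi):
            raise ValueError(f"passband must satisfy 0 < low < high, got {self.passband_hz}")
        if not (0.0 < self.prune_percentile < 100.0):
            raise ValueError("prune_percentile must lie in (0, 100)")
        if self.n_features < 4:
            raise ValueError("n_features must be >= 4")

    def validate_for_fps(self, fps: float) -> None:
        """Raise if the passband is infeasible at the given frame rate."""
        lo, hi = self.passband_hz
        if hi >= fps / 2.0:
            raise ValueError(
                f"passband upper edge {hi} Hz is not below Nyquist ({fps / 2.0} Hz)"
            )

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def preset(species: str, **kwargs) -> RunConfig:
    """Convenience constructor: ``preset("rat")`` or ``preset("mouse")``."""
    return RunConfig(species=species, **kwargs)
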