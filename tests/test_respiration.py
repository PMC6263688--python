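import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from oracles import agreement_oracle, dft_argmax
from thermowelfare.config import preset
from thermowelfare.io import RectROI, ThermalVideo
from thermowelfare.preprocess import stretch_video
from thermowelfare.respiration import (
    ComponentSet,
    TrajectoryMatrix,
    apply_filter,
    design_bandpass,
    detect_features,
    estimate_rr_window,
    evaluate_against_reference,
    pca_decompose,
    periodicity_score,
    prune_unstable,
    rr_trace,
    select_axis,
    track_features,
)
from thermowelfare.synthetic import BreathSceneConfig, make_breathing_video, step_profile

RAT_BAND = (0.6, 3.3)
MOUSE_BAND = (1.0, 4.6)


def _textured_frame(shape=(120, 160), seed=0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(0, 1, shape), 2.0)
    f = (f - f.min()) / np.ptp(f) * 255.0
    return f.astype(np.uint8)


class TestDetectFeatures:
    def test_checkerboard_corners_found_at_intersections(self):
        board = np.kron((np.indices((8, 8)).sum(axis=0) % 2) * 255, np.ones((12, 12)))
        frame = board.astype(np.uint8)
        pts = detect_features(frame, RectROI(10, 10, 86, 86), n=100)
        assert 4 <= len(pts) <= 100
        # every detected point sits near a block intersection (multiple of 12)
        near = np.abs((pts % 12) - 6)  # distance from block centers
        assert np.all(near.max(axis=1) >= 3)

    def test_uniform_roi_raises(self):
        frame = np.full((64, 64), 128, dtype=np.uint8)
        with pytest.raises(ValueError, match="texture"):
            detect_features(frame, RectROI(8, 8, 56, 56), n=50)

    def test_returned_points_dominate_excluded_candidates(self):
        """Exhaustive score-map oracle: every returned corner's Shi-Tomasi
        response is >= that of any non-returned candidate lying outside the
        spacing radius of all returned points."""
        from skimage.feature import corner_shi_tomasi

        frame = _textured_frame(seed=3)
        roi = RectROI(20, 20, 140, 100)
        n = 25
        pts = detect_features(frame, roi, n=n, min_distance=3)
        response = corner_shi_tomasi(frame.astype(np.float64), sigma=1.0)
        allowed = np.zeros(frame.shape, dtype=bool)
        allowed[roi.slices()] = True
        min_returned = min(response[int(y), int(x)] for x, y in pts)
        ys, xs = np.nonzero(allowed)
        dist2 = (
            (xs[:, None] - pts[None, :, 0]) ** 2 + (ys[:, None] - pts[None, :, 1]) ** 2
        ).min(axis=1)
        outside = dist2 > 3**2
        if outside.any():
            assert response[ys[outside], xs[outside]].max() <= min_returned + 1e-9


class TestTrackFeatures:
    def test_static_scene_total_drift_below_half_pixel(self):
        frame = _textured_frame(seed=1)
        video8 = np.repeat(frame[None], 100, axis=0)
        pts = detect_features(frame, RectROI(20, 20, 140, 100), n=40)
        traj = track_features(video8, pts)
        drift = np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0])
        assert np.nanmax(drift[traj.valid]) < 0.5

    def test_uniform_translation_tracked_at_one_pixel_per_frame(self):
        big = _textured_frame(shape=(120, 260), seed=2)
        video8 = np.stack([big[:, s : s + 160] for s in range(60)])
        pts = detect_features(video8[0], RectROI(40, 20, 120, 100), n=40)
        traj = track_features(video8, pts)
        # scene content moves left 1 px/frame as the crop window slides right
        steps = np.diff(traj.x[:, traj.valid], axis=0)
        assert np.abs(np.nanmean(steps) + 1.0) < 0.2
        assert np.abs(np.nanmedian(traj.y[-1] - traj.y[0])) < 0.5

    def test_chest_oscillation_amplitude_recovered(self):
        cfg = BreathSceneConfig(
            frame_shape=(240, 320), fps=30.0, duration_s=10.0,
            rr_profile=60.0, breath_amplitude_px=1.5, noise_sigma_c=0.1, seed=7,
        )
        video, _ = make_breathing_video(cfg)
        video8 = stretch_video(video.frames)
        pts = detect_features(video8[0], cfg.chest_roi, n=60)
        traj = track_features(video8, pts)
        # points whose tracking window lies fully inside the moving chest
        # rectangle carry the unattenuated displacement
        x0, y0, x1, y1 = cfg.chest_rect
        interior = (
            traj.valid
            & (traj.x[0] >= x0 + 8) & (traj.x[0] <= x1 - 8)
            & (traj.y[0] >= y0 + 8) & (traj.y[0] <= y1 - 8)
        )
        assert interior.sum() >= 5
        y = traj.y[:, interior] - np.nanmean(traj.y[:, interior], axis=0)
        t = np.arange(video.n_frames) / 30.0
        # least-squares sinusoid fit at the commanded 1 Hz
        basis = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        coef, *_ = np.linalg.lstsq(basis, np.nanmean(y, axis=1), rcond=None)
        amp = np.hypot(*coef)
        assert abs(amp - 1.5) <= 0.3


def _make_traj(x, y, valid=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.ones(x.shape[1], dtype=bool)
    return TrajectoryMatrix(x=x, y=y, valid=valid)


class TestPruneUnstable:
    def test_hundred_points_keep_exactly_seventy_five(self, rng):
        x = np.cumsum(rng.normal(0, 0.1, (50, 100)), axis=0)
        y = np.cumsum(rng.normal(0, 0.1, (50, 100)), axis=0)
        pruned = prune_unstable(_make_traj(x, y), 25.0)
        assert pruned.n_valid == 75

    @pytest.mark.parametrize("n,expected", [(10, 8), (11, 9), (100, 75), (7, 6)])
    def test_ceil_rule_under_ties(self, n, expected):
        x = np.zeros((20, n))
        y = np.zeros((20, n))
        pruned = prune_unstable(_make_traj(x, y), 25.0)
        assert pruned.n_valid == expected
        # ties break by point index: the lowest-index points survive
        assert np.all(np.flatnonzero(pruned.valid) == np.arange(expected))

    def test_erratic_trajectories_removed_first(self, rng):
        n = 12
        x = np.cumsum(rng.normal(0, 0.05, (40, n)), axis=0)
        y = np.cumsum(rng.normal(0, 0.05, (40, n)), axis=0)
        x[::2, 3] += 20.0  # jumps of 20 px
        y[::2, 8] -= 20.0
        pruned = prune_unstable(_make_traj(x, y), 25.0)
        assert not pruned.valid[3] and not pruned.valid[8]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            prune_unstable(_make_traj(np.zeros((10, 3)), np.zeros((10, 3))))


class TestSelectAxis:
    def _oscillating(self, axis):
        t = np.linspace(0, 4 * np.pi, 60)[:, None]
        osc = np.sin(t) * np.ones((1, 5))
        flat = np.zeros_like(osc)
        return _make_traj(osc if axis == "x" else flat, flat if axis == "x" else osc)

    def test_vertical_motion_selects_y(self):
        sig, axis = select_axis(self._oscillating("y"))
        assert axis == "y"
        assert np.allclose(sig.mean(axis=0), 0.0, atol=1e-12)

    def test_horizontal_motion_selects_x(self):
        _, axis = select_axis(self._oscillating("x"))
        assert axis == "x"

    def test_tie_breaks_toward_y(self):
        t = np.linspace(0, 4 * np.pi, 60)[:, None]
        osc = np.sin(t) * np.ones((1, 5))
        _, axis = select_axis(_make_traj(osc, osc.copy()))
        assert axis == "y"


class TestBandpassDesign:
    def test_rat_band_response_at_sixty_fps(self):
        taps = design_bandpass(RAT_BAND, fs=60.0)
        w, h = sps.freqz(taps, worN=4096, fs=60.0)
        gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
        assert abs(gain_db[np.argmin(np.abs(w - 1.5))]) <= 1.0
        assert gain_db[np.argmin(np.abs(w - 0.2))] <= -40.0

    def test_mouse_band_passes_two_hertz(self):
        taps = design_bandpass(MOUSE_BAND, fs=60.0)
        w, h = sps.freqz(taps, worN=4096, fs=60.0)
        gain_db = 20 * np.log10(np.maximum(np.abs(h), 1e-12))
        assert abs(gain_db[np.argmin(np.abs(w - 2.0))]) <= 1.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_bandpass((1.0, 20.0), fs=30.0)


class TestApplyFilter:
    @pytest.fixture(scope="class")
    def rat_taps(self):
        return design_bandpass(RAT_BAND, fs=30.0)

    def test_dc_column_suppressed(self, rat_taps):
        sig = np.full((3400, 2), 7.0)
        out = apply_filter(sig, rat_taps)
        assert np.abs(out).max() < 7.0e-3

    def test_in_band_sinusoid_preserved_with_zero_delay(self, rat_taps):
        fs = 30.0
        t = np.arange(3400) / fs
        sig = np.sin(2 * np.pi * 1.5 * t)[:, None]
        out = apply_filter(sig, rat_taps)[:, 0]
        core = slice(500, -500)
        basis = np.column_stack([np.sin(2 * np.pi * 1.5 * t), np.cos(2 * np.pi * 1.5 * t)])
        coef, *_ = np.linalg.lstsq(basis[core], out[core], rcond=None)
        amp = np.hypot(*coef)
        phase_cycles = abs(np.arctan2(coef[1], coef[0])) / (2 * np.pi)
        assert abs(amp - 1.0) < 0.05
        assert phase_cycles < 0.01

    def test_out_of_band_sinusoid_attenuated_forty_db(self, rat_taps):
        fs = 30.0
        t = np.arange(3400) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)[:, None]
        out = apply_filter(sig, rat_taps)[:, 0]
        assert np.abs(out[500:-500]).max() < 10 ** (-40 / 20)

    def test_short_signal_rejected(self, rat_taps):
        with pytest.raises(ValueError, match="too short"):
            apply_filter(np.zeros((100, 1)), rat_taps)


class TestPCADecompose:
    def test_rank_one_data_recovered_by_first_component(self, rng):
        t = np.linspace(0, 6 * np.pi, 200)
        source = np.sin(t)
        signals = source[:, None] * rng.uniform(0.5, 2.0, 10)[None, :]
        signals += rng.normal(0, 1e-4, signals.shape)
        comps = pca_decompose(signals, k=6)
        var_frac = comps.variances[0] / comps.variances.sum()
        r = np.corrcoef(comps.scores[:, 0], source)[0, 1]
        assert var_frac >= 0.99
        assert abs(r) >= 0.999

    def test_two_orthogonal_sources_span_leading_components(self, rng):
        t = np.linspace(0, 8 * np.pi, 400)
        s1, s2 = np.sin(t), np.sin(2.5 * t)
        signals = np.column_stack([s1, s1, 3 * s2, s2, 2 * s1, s2])
        signals += rng.normal(0, 1e-3, signals.shape)
        comps = pca_decompose(signals, k=6)
        # subspace angle between span(PC1, PC2) and span(s1, s2) < 5 degrees
        from scipy.linalg import subspace_angles

        ang = subspace_angles(comps.scores[:, :2], np.column_stack([s1, s2]))
        assert np.degrees(ang.max()) < 5.0

    def test_component_count_capped_by_columns(self, rng):
        signals = rng.normal(0, 1, (50, 3))
        assert pca_decompose(signals, k=6).k == 3


class TestPeriodicityScore:
    def test_pure_sinusoid_scores_high_with_exact_frequency(self):
        # the +-0.05 Hz score windows capture the Hamming main lobe (half
        # width 2/T Hz) once the segment is about a minute long
        fs = 30.0
        t = np.arange(int(60 * fs)) / fs
        score, f0 = periodicity_score(np.sin(2 * np.pi * 1.0 * t), fs, RAT_BAND)
        assert abs(f0 - 1.0) <= 0.01
        assert score >= 0.9

    def test_pure_sinusoid_dominates_noise_at_short_window(self, rng):
        # at a 10-s window the absolute score is leakage-limited, but the
        # periodic component still separates cleanly from noise
        fs = 30.0
        t = np.arange(int(10 * fs)) / fs
        s_sine, f0 = periodicity_score(np.sin(2 * np.pi * 1.0 * t), fs, RAT_BAND)
        s_noise, _ = periodicity_score(rng.normal(0, 1, t.size), fs, RAT_BAND)
        assert abs(f0 - 1.0) <= 0.01
        assert s_sine > 0.5 > 2 * s_noise

    def test_white_noise_scores_low(self):
        fs = 30.0
        scores = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            score, _ = periodicity_score(rng.normal(0, 1, int(10 * fs)), fs, RAT_BAND)
            scores.append(score)
        assert np.median(scores) < 0.2

    def test_harmonic_content_raises_score_over_noisy_control(self):
        fs = 30.0
        t = np.arange(int(10 * fs)) / fs
        rng = np.random.default_rng(0)
        squareish = np.sin(2 * np.pi * t) + 0.5 * np.sin(4 * np.pi * t)
        noisy_sine = np.sin(2 * np.pi * t) + 0.5 * rng.normal(0, 1, t.size)
        s_sq, _ = periodicity_score(squareish, fs, RAT_BAND)
        s_ns, _ = periodicity_score(noisy_sine, fs, RAT_BAND)
        assert s_sq > s_ns

    @pytest.mark.parametrize("f_true", [0.75, 1.1, 2.3])
    def test_argmax_matches_brute_force_dft(self, f_true, rng):
        """Spectral argmax equals a brute-force DFT evaluation on a 0.005 Hz
        grid within one resolution bin."""
        fs = 30.0
        t = np.arange(int(12 * fs)) / fs
        x = np.sin(2 * np.pi * f_true * t) + 0.3 * rng.normal(0, 1, t.size)
        _, f0 = periodicity_score(x, fs, RAT_BAND)
        f_oracle = dft_argmax(x, fs, *RAT_BAND)
        assert abs(f0 - f_oracle) <= 0.01

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            periodicity_score(np.zeros(400), 30.0, RAT_BAND)

    def test_too_short_component_rejected(self):
        with pytest.raises(ValueError, match="4 s"):
            periodicity_score(np.ones(50), 30.0, RAT_BAND)


class TestEstimateRRWindow:
    def _components(self, cols):
        arr = np.column_stack(cols)
        variances = arr.var(axis=0)
        return ComponentSet(scores=arr - arr.mean(axis=0), variances=variances)

    def test_sine_component_wins_over_noise(self, rng):
        fs = 30.0
        t = np.arange(int(10 * fs)) / fs
        comps = self._components([np.sin(2 * np.pi * 0.9 * t), rng.normal(0, 1, t.size)])
        rr, idx, score = estimate_rr_window(comps, fs, RAT_BAND)
        assert idx == 0
        assert abs(rr - 54.0) <= 0.6

    def test_breathing_on_third_component_found(self, rng):
        fs = 30.0
        t = np.arange(int(10 * fs)) / fs
        comps = self._components(
            [rng.normal(0, 1, t.size), rng.normal(0, 1, t.size), np.sin(2 * np.pi * 1.2 * t)]
        )
        rr, idx, _ = estimate_rr_window(comps, fs, RAT_BAND)
        assert idx == 2
        assert abs(rr - 72.0) <= 0.72

    def test_all_noise_returns_max_score_component_with_low_score(self, rng):
        fs = 30.0
        cols = [rng.normal(0, 1, int(10 * fs)) for _ in range(3)]
        comps = self._components(cols)
        rr, idx, score = estimate_rr_window(comps, fs, RAT_BAND)
        assert 60 * RAT_BAND[0] <= rr <= 60 * RAT_BAND[1]
        assert 0 <= idx < 3
        assert score < 0.5


class TestEvaluateAgainstReference:
    def _frame(self, t, v, col):
        return pd.DataFrame({"time_s": t, col: v})

    def test_identical_traces_give_zero_errors(self):
        t = np.arange(1.0, 11.0)
        v = np.full(10, 52.0) + np.sin(t)
        m = evaluate_against_reference(
            self._frame(t, v, "rr_bpm_median"), self._frame(t, v, "rr_bpm")
        )
        assert m.rmse_bpm == 0.0
        assert m.mean_rel_err_pct == 0.0
        assert m.p90_rel_err_pct == 0.0
        assert m.bland_altman_bias_bpm == 0.0

    def test_constant_offset_closed_form(self):
        t = np.arange(1.0, 9.0)
        ref = np.full(8, 50.0)
        m = evaluate_against_reference(
            self._frame(t, ref + 1.0, "rr_bpm_median"), self._frame(t, ref, "rr_bpm")
        )
        assert m.rmse_bpm == pytest.approx(1.0)
        assert m.mean_rel_err_pct == pytest.approx(2.0)
        assert m.bland_altman_bias_bpm == pytest.approx(1.0)
        assert m.loa_low_bpm == pytest.approx(1.0)
        assert m.loa_high_bpm == pytest.approx(1.0)

    def test_random_pairs_match_independent_recomputation(self, rng):
        t = np.arange(1.0, 41.0)
        ref = rng.uniform(40, 70, 40)
        est = ref + rng.normal(0, 1.5, 40)
        m = evaluate_against_reference(
            self._frame(t, est, "rr_bpm_median"), self._frame(t, ref, "rr_bpm")
        )
        o = agreement_oracle(est, ref)
        assert m.rmse_bpm == pytest.approx(o["rmse"])
        assert m.mean_rel_err_pct == pytest.approx(o["mean_rel"])
        assert m.p90_rel_err_pct == pytest.approx(o["p90_rel"])
        assert m.pearson_r == pytest.approx(o["r"])
        assert m.bland_altman_bias_bpm == pytest.approx(o["bias"])
        assert m.loa_low_bpm == pytest.approx(o["loa_low"])
        assert m.loa_high_bpm == pytest.approx(o["loa_high"])

    def test_nonpositive_reference_rejected(self):
        t = np.arange(1.0, 5.0)
        with pytest.raises(ValueError, match="positive"):
            evaluate_against_reference(
                self._frame(t, t + 50, "rr_bpm_median"),
                self._frame(t, [50, 50, 0, 50], "rr_bpm"),
            )

    def test_too_few_pairs_rejected(self):
        t = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="pairs"):
            evaluate_against_reference(
                self._frame(t, [50, 50], "rr_bpm_median"), self._frame(t, [50, 50], "rr_bpm")
            )


class TestRRTraceEndToEnd:
    def test_constant_rate_recovered_within_one_bpm(self, breath_scene, rat_config):
        cfg, video, truth = breath_scene
        trace = rr_trace(video, cfg.chest_roi, rat_config)
        valid = trace[trace["valid"]]
        assert len(valid) >= 30
        assert np.all(np.abs(valid["rr_bpm_median"] - 54.0) <= 1.0)
        assert np.all(np.diff(trace["time_s"]) > 0)

    def test_estimates_confined_to_passband(self, breath_scene, rat_config):
        cfg, video, _ = breath_scene
        trace = rr_trace(video, cfg.chest_roi, rat_config)
        valid = trace[trace["valid"]]
        lo, hi = rat_config.passband_hz
        assert valid["rr_bpm"].between(60 * lo, 60 * hi).all()

    def test_step_change_settles_within_window_plus_median(self):
        cfg = BreathSceneConfig(
            frame_shape=(120, 160), fps=30.0, duration_s=60.0,
            rr_profile=step_profile(50.0, 60.0, 30.0), noise_sigma_c=0.3, seed=13,
        )
        video, _ = make_breathing_video(cfg)
        config = preset("rat")
        trace = rr_trace(video, cfg.chest_roi, config)
        settle_after = 30.0 + config.rr_window_s + config.median_s
        tail = trace[(trace["time_s"] >= settle_after) & trace["valid"]]
        # pre-step windows must also be clear of the band-pass impulse
        # response (~4 s half-width), which smears the step backwards
        head = trace[(trace["time_s"] <= 25.0) & trace["valid"]]
        assert np.all(np.abs(tail["rr_bpm_median"] - 60.0) <= 1.0)
        assert np.all(np.abs(head["rr_bpm_median"] - 50.0) <= 1.0)

    @pytest.mark.parametrize(
        "rr_bpm,species",
        [(42.0, "rat"), (54.0, "rat"), (66.0, "rat"),
         (90.0, "mouse"), (130.0, "mouse"), (200.0, "mouse")],
    )
    def test_parameter_recovery_across_both_species_regimes(self, rr_bpm, species):
        """Textured scenes at noise sigma 0.3 C: the commanded rate is
        recovered with mean relative error <= 2 % in every condition."""
        cfg = BreathSceneConfig(
            frame_shape=(240, 320), fps=30.0, duration_s=45.0,
            rr_profile=rr_bpm, noise_sigma_c=0.3, seed=int(rr_bpm),
        )
        video, truth = make_breathing_video(cfg)
        trace = rr_trace(video, cfg.chest_roi, preset(species))
        m = evaluate_against_reference(trace, truth)
        assert m.mean_rel_err_pct <= 2.0

    def test_video_shorter_than_window_rejected(self, rat_config, rng):
        frames = rng.normal(25, 1, (30, 32, 32)).astype(np.float32)
        video = ThermalVideo(frames, fps=30.0)
        with pytest.raises(ValueError, match="window"):
            rr_trace(video, RectROI(4, 4, 28, 28), rat_config)
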