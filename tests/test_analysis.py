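"""Analysis toolchain: PIV, density/ROI statistics, fronts, MSD, activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swarmconvect import analysis as an
from swarmconvect import synth


def texture(shape=(128, 128), seed=0, smooth=2.0):
    """Smooth random texture with enough structure for correlation peaks."""
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.uniform(0, 100, size=shape), smooth)


class TestPIV:
    def test_identity_pair_gives_zero_displacement(self):
        img = texture()
        fieldv = an.piv_pair(img, img)
        assert fieldv.mask.any()
        assert np.abs(fieldv.u[fieldv.mask]).max() <= 0.05
        assert np.abs(fieldv.v[fieldv.mask]).max() <= 0.05

    def test_integer_shift_recovered_within_tolerance(self):
        img = texture(seed=1)
        a, b = synth.shifted_pair(img, 3, 5)
        fieldv = an.piv_pair(a, b)
        assert abs(np.median(fieldv.u[fieldv.mask]) - 3) <= 0.2
        assert abs(np.median(fieldv.v[fieldv.mask]) - 5) <= 0.2

    def test_default_window_and_overlap_follow_protocol(self):
        import inspect
        sig = inspect.signature(an.piv_pair)
        assert sig.parameters["window"].default == 32
        assert sig.parameters["overlap"].default == 16
        img = texture((96, 96))
        fieldv = an.piv_pair(img, img)
        # 96px with 32px windows at 16px steps -> 5 window centres per axis
        assert fieldv.u.shape == (5, 5)

    def test_shape_mismatch_rejected_constant_windows_masked(self):
        img = texture()
        with pytest.raises(ValueError):
            an.piv_pair(img, img[:64, :64])
        flat = np.zeros((64, 64))
        fieldv = an.piv_pair(flat, flat)
        assert not fieldv.mask.any()

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(dx=st.integers(min_value=-8, max_value=8),
           dy=st.integers(min_value=-8, max_value=8))
    def test_pure_translations_within_quarter_window(self, dx, dy):
        img = texture(seed=7)
        a, b = synth.shifted_pair(img, dx, dy)
        fieldv = an.piv_pair(a, b)
        assert abs(np.median(fieldv.u[fieldv.mask]) - dx) <= 0.2
        assert abs(np.median(fieldv.v[fieldv.mask]) - dy) <= 0.2

    def test_subpixel_shift_lands_in_known_bias_envelope(self):
        img = texture(seed=3, smooth=3.0)
        a, b = synth.shifted_pair(img, 0.5, 0.0)
        fieldv = an.piv_pair(a, b)
        med = np.median(fieldv.u[fieldv.mask])
        assert 0.3 <= med <= 0.7

    def test_velocity_scale_arithmetic_and_roundtrip(self):
        x = np.arange(3.0)
        ones = np.ones((3, 3))
        fieldv = an.VelocityField(x=x, y=x, u=ones.copy(), v=0 * ones,
                                  mask=ones.astype(bool))
        phys = an.velocity_scale(fieldv, fps=3.33, px_size=10.0)
        assert phys.u[0, 0] == pytest.approx(33.3)
        assert phys.units == "length/s"
        back = an.VelocityField(x=x, y=x, u=phys.u / (3.33 * 10.0),
                                v=phys.v / (3.33 * 10.0), mask=phys.mask)
        assert np.allclose(back.u, fieldv.u, rtol=1e-12)
        zero = an.velocity_scale(
            an.VelocityField(x=x, y=x, u=0 * ones, v=0 * ones,
                             mask=ones.astype(bool)), fps=3.33, px_size=10.0)
        assert np.all(zero.u == 0)
        with pytest.raises(ValueError):
            an.velocity_scale(fieldv, fps=3.33, px_size=0.0)


class TestDensityMap:
    def test_constant_frames_sum_and_average(self):
        seq = an.ImageSequence(frames=np.full((1000, 8, 8), 3.0), fps=25.0)
        maps = an.density_map(seq, segment_frames=1000)
        assert len(maps) == 1
        assert np.allclose(maps[0]["cumulative"], 3000.0)
        assert np.allclose(maps[0]["average"], 3.0)

    def test_default_segment_is_forty_seconds_at_25fps(self):
        import inspect
        assert inspect.signature(an.density_map).parameters[
            "segment_frames"].default == 1000
        assert 1000 / 25.0 == 40.0

    def test_moving_spot_leaves_connected_streak(self):
        from scipy.ndimage import label
        n = 40
        ys = np.linspace(10, 50, n)
        table = pd.DataFrame({"id": 0, "time": np.arange(n) / 25.0,
                              "x": np.full(n, 32.0), "y": ys})
        traj = an.TrajectorySet(table=table)
        spec = synth.RenderSpec(height=64, width=64, spot_sigma=2.0,
                                background=0.0, noise_sigma=0.0)
        seq = synth.render_frames(traj, spec, fps=25.0)
        maps = an.density_map(seq, segment_frames=n)
        level = maps[0]["cumulative"] > 0.5 * maps[0]["cumulative"].max()
        _, n_components = label(level)
        assert n_components == 1
        rows_hit = np.nonzero(level.any(axis=1))[0]
        assert rows_hit.min() <= 12 and rows_hit.max() >= 48

    def test_permutation_invariance_within_segment(self, rng):
        frames = rng.uniform(0, 10, size=(50, 16, 16))
        seq = an.ImageSequence(frames=frames, fps=25.0)
        shuffled = an.ImageSequence(frames=frames[rng.permutation(50)],
                                    fps=25.0)
        a = an.density_map(seq, segment_frames=50)[0]["cumulative"]
        b = an.density_map(shuffled, segment_frames=50)[0]["cumulative"]
        assert np.allclose(a, b)

    def test_empty_sequence_rejected(self):
        seq = an.ImageSequence(frames=np.zeros((5, 8, 8)), fps=25.0)
        with pytest.raises(ValueError):
            an.density_map(seq, segment_frames=10)


class TestRoiIntensity:
    def test_constant_frames_have_zero_dispersion(self):
        seq = an.ImageSequence(frames=np.full((10, 320, 320), 7.0), fps=25.0)
        out = an.roi_intensity_distribution(seq, roi_origin=(0, 0),
                                            roi_size=300)
        assert out[0]["std"] == 0.0
        assert out[0]["iqr"] == 0.0

    def test_checkerboard_dispersion_is_analytic(self):
        tile = np.indices((300, 300)).sum(axis=0) % 2
        frames = (100.0 * tile)[None, :, :]
        seq = an.ImageSequence(frames=frames, fps=1.0)
        out = an.roi_intensity_distribution(seq, roi_size=300, interval_s=1.0)
        assert out[0]["std"] == pytest.approx(50.0)

    def test_broad_blob_disperses_more_than_tight_blob(self):
        x = np.arange(300)
        xx, yy = np.meshgrid(x, x)

        def blob(sig):
            img = 100 * np.exp(-((xx - 150) ** 2 + (yy - 150) ** 2)
                               / (2 * sig ** 2))
            return an.ImageSequence(frames=img[None], fps=1.0)

        broad = an.roi_intensity_distribution(blob(80), roi_size=300)[0]
        tight = an.roi_intensity_distribution(blob(10), roi_size=300)[0]
        assert broad["std"] > tight["std"]

    def test_roi_outside_image_rejected(self):
        seq = an.ImageSequence(frames=np.zeros((2, 100, 100)), fps=25.0)
        with pytest.raises(ValueError):
            an.roi_intensity_distribution(seq, roi_origin=(0, 0),
                                          roi_size=300)


class TestFrontTrack:
    def _rising_blob_sequence(self, v=2.0, fps=10.0, n=30):
        h, w = 100, 40
        rows = np.arange(h)
        frames = []
        for k in range(n):
            z = 10 + v * k / fps          # physical height, z-up
            row = (h - 1) - z             # image row (top = row 0)
            img = np.exp(-0.5 * ((rows - row) / 6.0) ** 2)[:, None] \
                * np.ones(w)[None, :]
            frames.append(100 * img)
        return an.ImageSequence(frames=np.stack(frames), fps=fps, px_size=1.0)

    def test_rising_blob_front_speed_recovered(self):
        v = 2.0
        seq = self._rising_blob_sequence(v=v)
        frame = an.front_track(seq, threshold_frac=0.5)
        mid = frame["speed"].to_numpy()[5:-5]
        assert np.median(mid) == pytest.approx(v, rel=0.02)

    def test_static_field_has_zero_speed(self):
        seq = self._rising_blob_sequence(v=0.0)
        frame = an.front_track(seq, threshold_frac=0.5)
        assert np.allclose(frame["speed"].dropna(), 0.0, atol=1e-9)

    def test_speed_at_requested_heights_reported(self):
        seq = self._rising_blob_sequence(v=2.0)
        _, at_h = an.front_track(seq, threshold_frac=0.5,
                                 report_heights=[20.0, 999.0])
        assert at_h.loc[0, "speed"] == pytest.approx(2.0, rel=0.1)
        assert np.isnan(at_h.loc[1, "speed"])

    def test_threshold_never_exceeded_raises(self):
        seq = an.ImageSequence(frames=np.zeros((3, 50, 20)), fps=10.0)
        with pytest.raises(ValueError):
            an.front_track(seq, threshold_frac=0.5)
        with pytest.raises(ValueError):
            an.front_track(seq, threshold_frac=1.5)

    def test_front_stays_above_com_for_bottom_release(self, short_run):
        from swarmconvect.sideview import center_of_mass_height
        frame = an.front_track(short_run, threshold_frac=0.1)
        com = short_run.com_heights()
        assert np.all(frame["front_height"].to_numpy() >= com - 1e-9)


class TestMSD:
    def test_stationary_tracks_give_zero(self):
        traj = synth.brownian_trajectories(0.0, 0.1, 20, 5, seed=1)
        msd = an.compute_msd(traj)
        assert np.allclose(msd["msd"], 0.0)

    def test_ballistic_tracks_exact_closed_form(self):
        v = (1.5, -2.0)
        traj = synth.ballistic_trajectories(v, dt=0.2, n_steps=30)
        msd = an.compute_msd(traj)
        v2 = v[0] ** 2 + v[1] ** 2
        assert np.allclose(msd["msd"], v2 * msd["lag"] ** 2, rtol=1e-12)

    def test_matches_brute_force_pairwise_oracle(self, rng):
        n_tracks, n_pts, dt = 4, 12, 0.5
        rows = []
        for tid in range(n_tracks):
            xy = rng.normal(size=(n_pts, 2)).cumsum(axis=0)
            for k in range(n_pts):
                rows.append({"id": tid, "time": k * dt,
                             "x": xy[k, 0], "y": xy[k, 1]})
        table = pd.DataFrame(rows)
        traj = an.TrajectorySet(table=table)
        msd = an.compute_msd(traj)
        # independent O(n^2) oracle: explicit loop over all ordered pairs
        for row in msd.itertuples():
            lag_steps = int(round(row.lag / dt))
            acc, cnt = 0.0, 0
            for tid in range(n_tracks):
                g = table[table["id"] == tid].reset_index()
                for i in range(len(g) - lag_steps):
                    ddx = g.loc[i + lag_steps, "x"] - g.loc[i, "x"]
                    ddy = g.loc[i + lag_steps, "y"] - g.loc[i, "y"]
                    acc += ddx ** 2 + ddy ** 2
                    cnt += 1
            assert row.msd == pytest.approx(acc / cnt, rel=1e-12)

    def test_nonuniform_sampling_rejected(self):
        table = pd.DataFrame({"id": 0, "time": [0.0, 0.1, 0.3],
                              "x": [0, 1, 2], "y": [0, 0, 0]})
        with pytest.raises(ValueError):
            an.compute_msd(an.TrajectorySet(table=table))

    def test_track_times_must_increase(self):
        table = pd.DataFrame({"id": 0, "time": [0.0, 0.2, 0.2],
                              "x": [0, 1, 2], "y": [0, 0, 0]})
        with pytest.raises(ValueError):
            an.TrajectorySet(table=table)


class TestDiffusionFit:
    def test_exact_line_recovers_d_to_machine_precision(self):
        d0 = 0.37
        lag = np.arange(1, 20) * 0.1
        msd = pd.DataFrame({"lag": lag, "msd": 4 * d0 * lag,
                            "n_pairs": np.full(lag.size, 100)})
        fit = an.fit_diffusion_coefficient(msd)
        assert fit["D"] == pytest.approx(d0, rel=1e-12)

    def test_brownian_ensemble_recovers_d_within_5_percent(self):
        d0 = 1.0
        traj = synth.brownian_trajectories(d0, dt=0.04, n_steps=500,
                                           n_particles=1000, seed=1)
        msd = an.compute_msd(traj, max_lag=25)
        fit = an.fit_diffusion_coefficient(msd)
        assert fit["D"] == pytest.approx(d0, rel=0.05)

    def test_ballistic_contamination_biases_short_lag_fit_high(self):
        # MSD = 4 D lag + v^2 lag^2: short-window fit must exceed D less
        # than a long-window fit exceeds it (bias grows with the window)
        d0, v2 = 1.0, 0.5
        lag = np.arange(1, 101) * 0.1
        msd = pd.DataFrame({"lag": lag, "msd": 4 * d0 * lag + v2 * lag ** 2,
                            "n_pairs": np.full(lag.size, 100)})
        short = an.fit_diffusion_coefficient(msd, fit_lags=10)["D"]
        long = an.fit_diffusion_coefficient(msd, fit_lags=100)["D"]
        assert d0 < short < long

    def test_negative_slope_reported_as_zero_with_flag(self):
        lag = np.arange(1, 10) * 0.1
        msd = pd.DataFrame({"lag": lag, "msd": -lag,
                            "n_pairs": np.full(lag.size, 10)})
        fit = an.fit_diffusion_coefficient(msd)
        assert fit["D"] == 0.0
        assert fit["negative_slope"]


class TestSpecificActivity:
    def _series(self, slope, k=25.0, l_cm=0.5, mass=1.0):
        t = np.linspace(0, 30, 31)
        return an.AbsorbanceSeries(time_min=t, absorbance=k * l_cm * slope * t,
                                   enzyme_mass_mg=mass, k=k, l_cm=l_cm)

    def test_zero_slope_gives_zero_activity(self):
        out = an.specific_activity(self._series(0.0))
        assert out["activity_U_per_mg"] == 0.0

    def test_linear_series_recovers_rate_exactly(self):
        r = 0.002   # concentration change per minute
        out = an.specific_activity(self._series(r, mass=2.0),
                                   conversion_factor=1.0, volume_ml=1.0)
        assert out["dc_dt_per_min"] == pytest.approx(r, rel=1e-12)
        assert out["activity_U_per_mg"] == pytest.approx(r / 2.0, rel=1e-12)

    def test_path_length_defaults_to_half_centimetre(self):
        t = np.array([0.0, 1.0])
        series = an.AbsorbanceSeries(time_min=t, absorbance=t,
                                     enzyme_mass_mg=1.0, k=1.0)
        assert series.l_cm == 0.5

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            an.AbsorbanceSeries(time_min=np.array([0.0]),
                                absorbance=np.array([0.1]),
                                enzyme_mass_mg=1.0, k=1.0)
        series = an.AbsorbanceSeries(time_min=np.array([1.0, 1.0]),
                                     absorbance=np.array([0.1, 0.2]),
                                     enzyme_mass_mg=1.0, k=1.0)
        with pytest.raises(ValueError):
            an.specific_activity(series)
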