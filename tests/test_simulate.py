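"""Simulator: interference contrast, Brownian trajectories, optical
rendering, parametric background noise and kymograph composition."""

import numpy as np
import pytest

from nanokymo.simulate import (
    ChannelGeometry,
    Kymograph,
    NoiseParams,
    OpticalParams,
    TrajectoryParams,
    differential_contrast,
    embed_in_measured_background,
    render_molecule_response,
    sample_background,
    sample_trajectory,
    synthesize_kymograph,
)


class TestDifferentialContrast:
    @pytest.mark.parametrize("i_c,i_m,expected", [
        (1.0, 0.0, 0.0),
        (1.0, 0.5, -0.5),       # 0.5 - sqrt(2*1*0.5) = -0.5
        (2.0, 1.0, 1.0 - 2.0),  # 1 - sqrt(4)
    ])
    def test_closed_form(self, i_c, i_m, expected):
        assert differential_contrast(i_c, i_m) == pytest.approx(expected)

    def test_interference_term_dominates_for_weak_scatterers(self):
        """|sqrt(2 Ic Im)| / Im = sqrt(2 Ic/Im) >> 1 across the weak-signal
        regime, which justifies dropping the molecular self-scattering."""
        i_c = 1.0
        i_m = i_c * np.logspace(-8, -2, 25)
        ratio = np.sqrt(2.0 * i_c * i_m) / i_m
        assert np.all(ratio > 10.0)
        assert ratio.min() == pytest.approx(np.sqrt(2.0 / 1e-2), rel=1e-12)

    def test_negative_between_zero_and_twice_channel(self):
        vals = differential_contrast(1.0, np.linspace(1e-6, 1.999, 50))
        assert np.all(vals < 0)

    def test_rejects_invalid_intensities(self):
        with pytest.raises(ValueError):
            differential_contrast(0.0, 1.0)
        with pytest.raises(ValueError):
            differential_contrast(1.0, -0.1)


class TestSampleTrajectory:
    def test_frozen_molecule_stays_put(self, small_geometry):
        p = TrajectoryParams(D=0.0, v=0.0, x0=100.0, k=10)
        t = sample_trajectory(p, small_geometry)
        assert np.all(t.positions == 100.0)
        assert t.n_in_view == 10

    def test_pure_drift_advances_v_dt_per_frame(self, small_geometry):
        p = TrajectoryParams(D=0.0, v=1.0, dt=0.005, x0=0.0, k=3)
        t = sample_trajectory(p, small_geometry)
        np.testing.assert_allclose(t.positions, [0.0, 5.0, 10.0])

    def test_increment_statistics_match_theory(self, small_geometry, rng):
        """Mean and variance of increments within 5 SE of v*dt and 2*D*dt."""
        d_um2, v_um, dt, k = 40.0, 2.0, 0.005, 100_000
        p = TrajectoryParams(D=d_um2, v=v_um, dt=dt, k=k)
        t = sample_trajectory(p, small_geometry, rng=rng)
        inc = np.diff(t.positions)
        var_true = 2.0 * d_um2 * 1e6 * dt
        mean_true = v_um * 1e3 * dt
        se_mean = np.sqrt(var_true / inc.size)
        se_var = var_true * np.sqrt(2.0 / (inc.size - 1))
        assert abs(inc.mean() - mean_true) < 5 * se_mean
        assert abs(inc.var(ddof=1) - var_true) < 5 * se_var

    def test_msd_is_linear_in_lag(self, small_geometry):
        """For v = 0 the mean-squared displacement fits 2*D*tau with a
        relative slope error below 5%."""
        d_um2, dt, k = 10.0, 0.005, 100_000
        rng = np.random.default_rng(7)
        lags = np.array([1, 2, 4, 8, 16])
        msd = np.zeros(len(lags))
        n_rep = 100
        for _ in range(n_rep):
            t = sample_trajectory(TrajectoryParams(D=d_um2, v=0.0, dt=dt, k=k // n_rep),
                                  small_geometry, rng=rng)
            for i, lag in enumerate(lags):
                dx = t.positions[lag:] - t.positions[:-lag]
                msd[i] += np.mean(dx**2) / n_rep
        slope = np.polyfit(lags * dt, msd, 1)[0]
        assert slope == pytest.approx(2.0 * d_um2 * 1e6, rel=0.05)

    def test_positions_not_clipped_to_view(self, small_geometry):
        p = TrajectoryParams(D=0.0, v=10.0, dt=0.005, x0=0.0, k=1000)
        t = sample_trajectory(p, small_geometry)
        assert t.positions.max() > small_geometry.view_length_nm
        assert t.n_in_view < t.params.k

    def test_determinism_under_seed(self, small_geometry):
        p = TrajectoryParams(D=5.0, v=0.0, k=100, seed=42)
        t1 = sample_trajectory(p, small_geometry)
        t2 = sample_trajectory(p, small_geometry)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_rejects_empty_trajectory(self):
        with pytest.raises(ValueError):
            TrajectoryParams(D=1.0, k=0)


class TestRenderMoleculeResponse:
    def test_zero_contrast_gives_unity_field(self, small_geometry):
        t = sample_trajectory(TrajectoryParams(D=0.0, x0=500.0, k=5), small_geometry)
        resp = render_molecule_response(t, OpticalParams(ioc=0.0, s=300.0),
                                        small_geometry)
        np.testing.assert_array_equal(resp, 1.0)

    def test_integrated_contrast_deficit_equals_ioc(self, small_geometry):
        centre = small_geometry.view_length_nm / 2
        t = sample_trajectory(TrajectoryParams(D=0.0, x0=centre, k=1), small_geometry)
        resp = render_molecule_response(t, OpticalParams(ioc=10.0, s=300.0),
                                        small_geometry)
        integral = small_geometry.pixel_size_nm * (1.0 - resp).sum()
        assert integral == pytest.approx(10.0, abs=0.01)

    def test_contrast_conservation_along_diffusing_track(self, small_geometry, rng):
        """Every in-view frame of a moving molecule conserves the deficit."""
        t = sample_trajectory(
            TrajectoryParams(D=1.0, x0=small_geometry.view_length_nm / 2, k=50),
            small_geometry, rng=rng)
        resp = render_molecule_response(t, OpticalParams(ioc=5.0, s=200.0),
                                        small_geometry)
        margin = 5 * 200.0
        inside = ((t.positions > margin)
                  & (t.positions < small_geometry.view_length_nm - margin))
        integrals = small_geometry.pixel_size_nm * (1.0 - resp[inside]).sum(axis=1)
        np.testing.assert_allclose(integrals, 5.0, rtol=1e-3)

    def test_far_out_of_view_leaves_no_trace(self, small_geometry):
        t = sample_trajectory(
            TrajectoryParams(D=0.0, x0=-10 * 300.0, k=3), small_geometry)
        resp = render_molecule_response(t, OpticalParams(ioc=10.0, s=300.0),
                                        small_geometry)
        assert np.max(np.abs(1.0 - resp)) < 1e-6


class TestSampleBackground:
    def test_deterministic_skeleton(self, small_geometry, quiet_noise):
        """With every stochastic amplitude zeroed the field is exactly the
        static Gaussian envelope."""
        bg = sample_background(quiet_noise, (4, 128), small_geometry)
        x = small_geometry.pixel_centers_nm()
        expected = np.exp(-((x - 1500.0) ** 2) / 800.0**2)
        np.testing.assert_allclose(bg, np.broadcast_to(expected, (4, 128)))

    def test_zero_noise_level_reduces_to_b0(self, small_geometry, rng):
        """N_theta = 0 removes both final noise terms, leaving b0."""
        n = NoiseParams(n_theta=0.0, amp_A=0.0, d_x=0.0, dirt_amp=0.0,
                        x0_bg=1000.0, lambda_bg=700.0)
        bg1 = sample_background(n, (6, 128), small_geometry,
                                rng=np.random.default_rng(3))
        bg2 = sample_background(n, (6, 128), small_geometry,
                                rng=np.random.default_rng(4))
        np.testing.assert_array_equal(bg1, bg2)  # nothing stochastic remains

    def test_additive_term_variance(self, small_geometry):
        """With b0 frozen at 0 the additive term has variance (0.4*N_theta)^2
        (checked within 5 SE over ~1e5 draws)."""
        n_theta = 2.0e-3
        n = NoiseParams(n_theta=n_theta, amp_A=0.0, d_x=0.0, dirt_amp=0.0,
                        x0_bg=-1e9, lambda_bg=1.0)  # envelope ~ 0 everywhere
        bg = sample_background(n, (800, 128), small_geometry,
                               rng=np.random.default_rng(5))
        draws = bg.ravel()
        var_true = (0.4 * n_theta) ** 2
        se = var_true * np.sqrt(2.0 / (draws.size - 1))
        assert abs(draws.var(ddof=1) - var_true) < 5 * se

    def test_seeded_reproducibility(self, small_geometry):
        n = NoiseParams(seed=11)
        bg1 = sample_background(n, (10, 128), small_geometry)
        bg2 = sample_background(n, (10, 128), small_geometry)
        np.testing.assert_array_equal(bg1, bg2)

    def test_rejects_empty_shape(self, small_geometry, quiet_noise):
        with pytest.raises(ValueError):
            sample_background(quiet_noise, (0, 128), small_geometry)

    def test_draw_respects_sampling_ranges(self, rng):
        n = NoiseParams()
        drawn = n.draw(rng)
        lo, hi = n.sampling_ranges["n_theta"]
        assert lo <= drawn.n_theta <= hi
        lo, hi = n.sampling_ranges["C"]
        assert lo <= drawn.C <= hi


class TestSynthesizeKymograph:
    def test_unity_response_returns_background(self, small_geometry, quiet_noise):
        bg = sample_background(quiet_noise, (6, 128), small_geometry)
        kymo = synthesize_kymograph([np.ones_like(bg)], bg, small_geometry, 0.005)
        np.testing.assert_array_equal(kymo.values, bg)

    def test_unit_background_returns_response(self, small_geometry, rng):
        t = sample_trajectory(TrajectoryParams(D=1.0, x0=1000.0, k=6),
                              small_geometry, rng=rng)
        resp = render_molecule_response(t, OpticalParams(ioc=5.0, s=300.0),
                                        small_geometry)
        kymo = synthesize_kymograph([resp], np.ones_like(resp),
                                    small_geometry, 0.005)
        np.testing.assert_array_equal(kymo.values, resp)

    def test_matches_bruteforce_product(self, small_geometry, rng):
        shape = (5, 128)
        bg = rng.uniform(0.5, 1.5, shape)
        r1 = rng.uniform(0.9, 1.0, shape)
        r2 = rng.uniform(0.9, 1.0, shape)
        kymo = synthesize_kymograph([r1, r2], bg, small_geometry, 0.005)
        expected = np.empty(shape)
        for i in range(shape[0]):
            for j in range(shape[1]):
                expected[i, j] = bg[i, j] * r1[i, j] * r2[i, j]
        np.testing.assert_allclose(kymo.values, expected)

    def test_scalar_homogeneity_in_background(self, small_geometry, rng):
        shape = (4, 128)
        bg = rng.uniform(0.5, 1.5, shape)
        resp = rng.uniform(0.9, 1.0, shape)
        k1 = synthesize_kymograph([resp], 3.0 * bg, small_geometry, 0.005)
        k2 = synthesize_kymograph([resp], bg, small_geometry, 0.005)
        np.testing.assert_allclose(k1.values, 3.0 * k2.values)

    def test_shape_mismatch_rejected(self, small_geometry, rng):
        bg = rng.uniform(0.5, 1.5, (4, 128))
        with pytest.raises(ValueError):
            synthesize_kymograph([np.ones((3, 128))], bg, small_geometry, 0.005)


class TestEmbedInMeasuredBackground:
    def _recording(self, geometry, rng, shape=(50, 128)):
        values = rng.uniform(0.8, 1.2, shape)
        return Kymograph(values=values, geometry=geometry, dt=0.005,
                         provenance="measured")

    def test_no_responses_returns_crop(self, small_geometry, rng):
        rec = self._recording(small_geometry, rng)
        out = embed_in_measured_background([], rec, shape=(10, 64),
                                           rng=np.random.default_rng(0))
        assert out.values.shape == (10, 64)
        # the crop must be a contiguous block of the recording
        found = any(
            np.array_equal(rec.values[i : i + 10, j : j + 64], out.values)
            for i in range(41) for j in range(65)
        )
        assert found

    def test_seeded_crop_is_reproducible(self, small_geometry, rng):
        rec = self._recording(small_geometry, rng)
        resp = rng.uniform(0.95, 1.0, (10, 64))
        o1 = embed_in_measured_background([resp], rec, rng=np.random.default_rng(9))
        o2 = embed_in_measured_background([resp], rec, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(o1.values, o2.values)

    def test_product_composition_matches_bruteforce(self, small_geometry, rng):
        rec = self._recording(small_geometry, rng)
        resp = rng.uniform(0.9, 1.0, (50, 128))
        out = embed_in_measured_background([resp], rec,
                                           rng=np.random.default_rng(2))
        np.testing.assert_allclose(out.values, rec.values * resp)

    def test_too_small_recording_rejected(self, small_geometry, rng):
        rec = self._recording(small_geometry, rng, shape=(5, 128))
        with pytest.raises(ValueError):
            embed_in_measured_background([], rec, shape=(10, 128))


class TestGeometry:
    def test_area_defaults_to_width_times_depth(self):
        g = ChannelGeometry(width_nm=63.0, depth_nm=30.0)
        assert g.area_nm2 == 63.0 * 30.0

    def test_area_override(self):
        g = ChannelGeometry(width_nm=63.0, depth_nm=30.0, area_nm2=1891.0)
        assert g.area_nm2 == 1891.0

    @pytest.mark.parametrize("kwargs", [
        dict(width_nm=-1.0, depth_nm=30.0),
        dict(width_nm=63.0, depth_nm=0.0),
        dict(width_nm=63.0, depth_nm=30.0, n_pixels=0),
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ChannelGeometry(**kwargs)
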