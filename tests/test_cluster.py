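"""Nanocluster arm: consolidation, drift, rendering, g(r), model fit,
Ripley's K."""

import numpy as np
import pandas as pd
import pytest

from synaptrack import (
    ClusterSimParams,
    LocalizationTable,
    NanoclusterModel,
    autocorrelation,
    consolidate,
    correct_drift,
    fit_cluster_model,
    molecules_per_cluster,
    render_image,
    ripley_k,
    simulate_clustered_localizations,
    simulate_csr,
)
from synaptrack.cluster import (
    ClusterFit,
    RadialAutocorrelation,
    _model_g,
    _smeared_exponential,
)


class TestConsolidation:
    def test_single_record_unchanged(self):
        df = pd.DataFrame({"frame": [3], "x": [50.0], "y": [60.0]})
        locs = LocalizationTable(df=df, fov=(0, 100, 0, 100),
                                 pixel_size_camera=100)
        out = consolidate(locs)
        assert len(out) == 1
        assert out.df["x"].iloc[0] == 50.0

    def test_transitive_chain_merged_to_hand_mean(self, five_record_blinks):
        out = consolidate(five_record_blinks, frame_gap=1, distance=1.0)
        assert len(out) == 3
        merged = out.df.sort_values("x").iloc[1]
        # records 1-3 chained: mean of (100,100),(140,90),(120,115)
        assert merged["x"] == pytest.approx(120.0)
        assert merged["y"] == pytest.approx(101.666666, abs=1e-6)
        assert merged["frame"] == 0
        assert merged["intensity"] == pytest.approx(6.0)

    def test_idempotent(self, five_record_blinks):
        once = consolidate(five_record_blinks)
        twice = consolidate(once)
        pd.testing.assert_frame_equal(
            once.df[["frame", "x", "y"]], twice.df[["frame", "x", "y"]])

    def test_far_frames_not_linked(self):
        df = pd.DataFrame({"frame": [0, 3], "x": [10.0, 10.0],
                           "y": [10.0, 10.0]})
        locs = LocalizationTable(df=df, fov=(0, 100, 0, 100),
                                 pixel_size_camera=100)
        assert len(consolidate(locs, frame_gap=1)) == 2

    def test_missing_pixel_size_rejected(self):
        df = pd.DataFrame({"frame": [0], "x": [1.0], "y": [1.0]})
        locs = LocalizationTable(df=df, fov=(0, 10, 0, 10),
                                 pixel_size_camera=100)
        locs.pixel_size_camera = None
        with pytest.raises(ValueError, match="pixel"):
            consolidate(locs)


class TestDriftCorrection:
    @staticmethod
    def _locs(rng, n=200, frames=100):
        df = pd.DataFrame({
            "frame": rng.integers(0, frames, n),
            "x": rng.uniform(0, 5000, n),
            "y": rng.uniform(0, 5000, n),
        })
        return LocalizationTable(df=df, fov=(0, 5000, 0, 5000))

    def test_zero_drift_noop(self, rng):
        locs = self._locs(rng)
        fid = pd.DataFrame({"fiducial_id": 0, "frame": np.arange(100),
                            "x": 1000.0, "y": 2000.0})
        out = correct_drift(locs, fid)
        np.testing.assert_allclose(out.df["x"], locs.df["x"], atol=1e-9)

    def test_linear_drift_removed(self, rng):
        locs = self._locs(rng, frames=200)
        rate = 0.5  # nm per frame
        frames = locs.df["frame"].to_numpy()
        drifted = locs.df.copy()
        drifted["x"] = drifted["x"] + rate * frames
        drifted = LocalizationTable(df=drifted, fov=None)
        fid_frames = np.arange(200)
        fid = pd.DataFrame({"fiducial_id": 0, "frame": fid_frames,
                            "x": 800.0 + rate * fid_frames, "y": 500.0})
        out = correct_drift(drifted, fid)
        resid = out.df["x"].to_numpy() - locs.df["x"].to_numpy()
        assert np.abs(resid - resid.mean()).max() < 2.0

    def test_translation_only_preserves_in_frame_geometry(self, rng):
        df = pd.DataFrame({"frame": [5, 5, 5], "x": [0.0, 100.0, 200.0],
                           "y": [0.0, 50.0, 150.0]})
        locs = LocalizationTable(df=df, fov=(-10000, 10000, -10000, 10000))
        fid = pd.DataFrame({"fiducial_id": 0, "frame": np.arange(10),
                            "x": np.linspace(0, 30, 10), "y": 0.0})
        out = correct_drift(locs, fid)
        d_before = np.hypot(100.0, 50.0)
        d_after = np.hypot(out.df["x"][1] - out.df["x"][0],
                           out.df["y"][1] - out.df["y"][0])
        assert d_after == pytest.approx(d_before, abs=1e-9)

    def test_insufficient_coverage_warns_noop(self, rng):
        locs = self._locs(rng, frames=100)
        fid = pd.DataFrame({"fiducial_id": 0, "frame": [0, 1, 2],
                            "x": [0.0, 5.0, 10.0], "y": 0.0})
        out = correct_drift(locs, fid)
        np.testing.assert_array_equal(out.df["x"], locs.df["x"])


class TestRender:
    def test_single_localization_single_pixel(self):
        df = pd.DataFrame({"frame": [0], "x": [25.0], "y": [35.0]})
        locs = LocalizationTable(df=df, fov=(0, 100, 0, 100))
        img, _ = render_image(locs, pixel=10.0)
        assert img.sum() == 1
        assert img[2, 3] == 1

    def test_counts_match_brute_force_binning(self, rng):
        n = 1000
        df = pd.DataFrame({"frame": np.zeros(n, dtype=int),
                           "x": rng.uniform(0, 1000, n),
                           "y": rng.uniform(0, 1000, n)})
        locs = LocalizationTable(df=df, fov=(0, 1000, 0, 1000))
        img, _ = render_image(locs, pixel=10.0)
        assert img.sum() == n
        brute = np.zeros_like(img)
        for x, y in df[["x", "y"]].to_numpy():
            ix = min(int(x // 10), img.shape[0] - 1)
            iy = min(int(y // 10), img.shape[1] - 1)
            brute[ix, iy] += 1
        np.testing.assert_array_equal(img, brute)


class TestAutocorrelation:
    def test_csr_flat_near_one(self):
        locs = simulate_csr(50.0, (0, 10_000, 0, 10_000), rng_seed=0)
        for est in ("fft_image", "direct_pairs"):
            ac = autocorrelation(locs, r_max=1000, bin_width=20,
                                 estimator=est)
            sel = (ac.r >= 50) & (ac.r <= 500)
            assert np.all(np.abs(ac.g[sel] - 1.0) < 0.05), est

    def test_two_points_single_elevated_bin(self):
        n_bg = 200  # sparse background so the pair histogram is meaningful
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "frame": np.zeros(2, dtype=int),
            "x": [2000.0, 2100.0],
            "y": [2000.0, 2000.0],
        })
        locs = LocalizationTable(df=df, fov=(0, 4000, 0, 4000))
        ac = autocorrelation(locs, r_max=400, bin_width=20,
                             estimator="direct_pairs", min_points=2)
        peak = np.argmax(ac.g)
        assert ac.r[peak] == pytest.approx(110.0)  # bin containing 100 nm
        others = np.delete(ac.g, peak)
        assert np.all(others == 0)

    def test_estimators_agree_on_random_points(self, rng):
        df = pd.DataFrame({"frame": np.zeros(500, dtype=int),
                           "x": rng.uniform(0, 1500, 500),
                           "y": rng.uniform(0, 1500, 500)})
        locs = LocalizationTable(df=df, fov=(0, 1500, 0, 1500))
        a_fft = autocorrelation(locs, r_max=520, bin_width=40,
                                estimator="fft_image", pixel=3.0)
        a_dir = autocorrelation(locs, r_max=520, bin_width=40,
                                estimator="direct_pairs")
        sel = (a_fft.r >= 20) & (a_fft.r <= 500)
        rel = np.abs(a_fft.g[sel] - a_dir.g[sel]) / a_dir.g[sel]
        assert np.nanmax(rel) < 0.02

    def test_rmax_beyond_half_extent_rejected(self):
        locs = simulate_csr(100.0, (0, 1000, 0, 1000), rng_seed=1)
        with pytest.raises(ValueError, match="r_max"):
            autocorrelation(locs, r_max=600, bin_width=10)


class TestClusterModelFit:
    @staticmethod
    def _curve_from_model(rho_um2, sigma, xi, amp, noise=0.0, seed=0):
        r = np.arange(10.0, 1000.0, 10.0) + 5.0
        g = _model_g(r, rho_um2 * 1e-6, sigma, xi, amp)
        if noise:
            g = g + np.random.default_rng(seed).normal(0, noise, len(r))
        return RadialAutocorrelation(r=r, g=g, n_pairs=np.full(len(r), 1000),
                                     estimator="fft_image", bin_width=10,
                                     density_um2=rho_um2)

    def test_flat_curve_zero_amplitude(self):
        r = np.arange(15.0, 800.0, 10.0)
        ac = RadialAutocorrelation(r=r, g=np.ones(len(r)),
                                   n_pairs=np.full(len(r), 100),
                                   estimator="fft_image", bin_width=10,
                                   density_um2=50.0)
        fit = fit_cluster_model(ac)
        assert abs(fit.amplitude_A * np.exp(-ac.r[0] / fit.xi)) < 0.05

    def test_noiseless_self_consistency_within_1pct(self):
        truth = dict(rho_um2=50.0, sigma=20.0, xi=80.0, amp=5.0)
        ac = self._curve_from_model(**truth)
        fit = fit_cluster_model(ac)
        assert abs(fit.rho - 50.0) / 50.0 < 0.01
        assert abs(fit.sigma - 20.0) / 20.0 < 0.01
        assert abs(fit.xi - 80.0) / 80.0 < 0.01
        assert abs(fit.amplitude_A - 5.0) / 5.0 < 0.01

    def test_resolution_is_sigma_over_sqrt2_exact(self):
        fit = ClusterFit(rho=50.0, sigma=22.0, xi=80.0, amplitude_A=3.0,
                         fit_rms=0.0)
        assert fit.resolution == pytest.approx(22.0 / np.sqrt(2), rel=1e-12)

    def test_molecules_per_cluster_quadrature_oracle(self):
        fit = ClusterFit(rho=50.0, sigma=20.0, xi=80.0, amplitude_A=5.0,
                         fit_rms=0.0)
        n = molecules_per_cluster(fit)
        # numerical integration of rho·A·exp(−r/ξ)·2πr dr
        r = np.linspace(0, 5000, 200_000)
        oracle = np.trapezoid(50e-6 * 5.0 * np.exp(-r / 80.0) * 2 * np.pi * r,
                              r)
        assert n == pytest.approx(oracle, rel=1e-4)
        assert n == pytest.approx(2 * np.pi * 50e-6 * 5.0 * 80.0 ** 2,
                                  rel=1e-9)

    def test_zero_amplitude_zero_molecules(self):
        fit = ClusterFit(rho=50.0, sigma=20.0, xi=80.0, amplitude_A=0.0,
                         fit_rms=0.0)
        assert molecules_per_cluster(fit) == 0.0

    def test_smeared_exponential_limits(self):
        r = np.array([20.0, 80.0, 250.0])
        nearly_plain = _smeared_exponential(r, 80.0, 2.0)
        np.testing.assert_allclose(nearly_plain, np.exp(-r / 80.0), atol=5e-3)
        # convolution preserves the integral (hence molecules per cluster)
        rr = np.linspace(0.01, 6000, 12_000)
        total = np.trapezoid(rr * _smeared_exponential(rr, 80.0, 25.0), rr)
        assert total == pytest.approx(80.0 ** 2, rel=1e-3)


class TestEndToEndRecovery:
    def test_xi_recovered_at_rest_preset_scale(self):
        p = ClusterSimParams(cluster_center_density=1.4,
                             molecules_per_cluster_mean=40,
                             cluster_radius_xi=83.5, background_density=5.0,
                             rng_seed=10)
        table, gt = simulate_clustered_localizations(p)
        res = NanoclusterModel(table, r_max=1000, bin_width=10).fit()
        assert abs(res.xi - 83.5) / 83.5 < 0.15

    def test_overcounting_separated_from_clustering(self):
        """More blinks per molecule inflates the short-range term but
        leaves the fitted cluster radius within tolerance."""
        fits = {}
        for blinks in (1.0, 3.0):
            p = ClusterSimParams(cluster_center_density=1.4,
                                 molecules_per_cluster_mean=40,
                                 cluster_radius_xi=80.0,
                                 background_density=5.0,
                                 blinks_per_molecule_mean=blinks, rng_seed=11)
            table, _ = simulate_clustered_localizations(p)
            res = NanoclusterModel(table, r_max=1000, bin_width=10).fit()
            fits[blinks] = res.fit
        over_1 = 1.0 / (4 * np.pi * fits[1.0].rho * 1e-6 * fits[1.0].sigma ** 2)
        over_3 = 1.0 / (4 * np.pi * fits[3.0].rho * 1e-6 * fits[3.0].sigma ** 2)
        assert over_3 > over_1
        assert abs(fits[3.0].xi - 80.0) / 80.0 < 0.2


class TestRipley:
    def test_brute_force_four_corner_fixture(self):
        df = pd.DataFrame({"frame": [0] * 4, "x": [0.0, 1000, 0, 1000],
                           "y": [0.0, 0, 1000, 1000]})
        locs = LocalizationTable(df=df, fov=(0, 1000, 0, 1000))
        res = ripley_k(locs, radii=np.array([1500.0]), edge_correction=False)
        # all 12 ordered pairs lie within 1.5 μm: K = A·12/(n(n−1))
        assert res.K[0] == pytest.approx(1000 * 1000 * 12 / (4 * 3))

    def test_k_non_decreasing(self, rng):
        locs = simulate_csr(80.0, (0, 4000, 0, 4000), rng_seed=4)
        res = ripley_k(locs, radii=np.arange(50.0, 1500.0, 50.0))
        assert np.all(np.diff(res.K) >= 0)

    def test_csr_l_matches_r(self):
        locs = simulate_csr(100.0, (0, 5000, 0, 5000), rng_seed=5)
        radii = np.arange(100.0, 1000.0, 100.0)
        res = ripley_k(locs, radii)
        assert np.abs(res.L_minus_r).max() < 30.0

    def test_radii_beyond_half_extent_rejected(self):
        locs = simulate_csr(100.0, (0, 1000, 0, 1000), rng_seed=6)
        with pytest.raises(ValueError):
            ripley_k(locs, radii=np.array([600.0]))

    def test_local_l_elevated_inside_cluster(self, rng):
        cluster = rng.normal(2000, 30, (100, 2))
        bg = rng.uniform(0, 4000, (100, 2))
        xy = np.vstack([cluster, bg])
        df = pd.DataFrame({"frame": np.zeros(len(xy), dtype=int),
                           "x": xy[:, 0], "y": xy[:, 1]})
        locs = LocalizationTable(df=df, fov=(0, 4000, 0, 4000))
        res = ripley_k(locs, radii=np.array([100.0, 200.0]), map_radius=100.0)
        assert res.local_l[:100].mean() > res.local_l[100:].mean()
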