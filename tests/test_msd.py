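"""MSD, diffusion-fit and mobility-classification tests.

Expected values come from independent oracles: a brute-force double loop
for the MSD, closed forms for ballistic motion, and direct counting for
the classification summaries.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp_st

from synaptrack import (
    MobilityModel,
    Trajectory,
    classify_mobility,
    compute_msd,
    ensemble_msd,
    filter_tracks,
    fit_diffusion,
    remove_outlier_fields,
    summarize_field,
)
from synaptrack.msd import DiffusionEstimate

from conftest import random_tracks


def brute_force_msd(track, n_max):
    """Independent double-loop MSD oracle over frame-lag pairs."""
    out = {}
    frames = list(track.frames)
    for n in range(1, n_max + 1):
        vals = []
        for i, fi in enumerate(frames):
            for j, fj in enumerate(frames):
                if fj - fi == n:
                    vals.append((track.x[j] - track.x[i]) ** 2
                                + (track.y[j] - track.y[i]) ** 2)
        if vals:
            out[n] = sum(vals) / len(vals)
    return out


class TestComputeMSD:
    def test_stationary_track_zero_msd(self, stationary_track):
        curve = compute_msd(stationary_track)
        assert np.all(curve.msd == 0.0)

    def test_hand_computed_three_point_track(self, simple_track):
        curve = compute_msd(simple_track)
        # lag 1: mean of (0.1² + 0²) and (0.2² + 0.1²) = 0.03
        # lag 2: 0.3² + 0.1² = 0.10
        np.testing.assert_allclose(curve.msd, [0.03, 0.10], atol=1e-15)
        np.testing.assert_allclose(curve.lags, [0.03, 0.06])
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_ballistic_track_exact_quadratic(self):
        v, dt = 2.0, 0.03
        n = 12
        track = Trajectory("b", np.arange(n), v * dt * np.arange(n),
                           np.zeros(n), dt=dt)
        curve = compute_msd(track)
        expected = v ** 2 * curve.lags ** 2
        np.testing.assert_allclose(curve.msd, expected, rtol=1e-12)

    def test_matches_brute_force_on_random_tracks(self, rng):
        tracks = random_tracks(rng, n=100, min_len=3, max_len=25)
        for track in tracks:
            n_max = len(track) - 1
            curve = compute_msd(track, n_max)
            oracle = brute_force_msd(track, n_max)
            np.testing.assert_allclose(
                curve.msd, [oracle[n] for n in sorted(oracle)], atol=1e-12)

    def test_gap_lags_without_pairs_are_omitted(self):
        track = Trajectory("g", [0, 1, 3, 4], [0, 1, 2, 3.0],
                           [0, 0, 0, 0.0], dt=0.03)
        curve = compute_msd(track, 4)
        oracle = brute_force_msd(track, 4)
        assert set(np.rint(curve.lags / 0.03).astype(int)) == set(oracle)

    def test_n_max_truncated_with_warning(self, simple_track):
        curve = compute_msd(simple_track, n_max=10)
        assert len(curve) == 2


class TestEnsembleMSD:
    def test_identical_curves_unchanged(self, simple_track):
        c = compute_msd(simple_track)
        ens = ensemble_msd([c, c], n_points=2)
        np.testing.assert_allclose(ens.msd, c.msd)

    def test_arithmetic_mean_of_two_curves(self):
        t1 = Trajectory("a", [0, 1], [0, 1.0], [0, 0.0], dt=1.0)
        t2 = Trajectory("b", [0, 1], [0, np.sqrt(3)], [0, 0.0], dt=1.0)
        ens = ensemble_msd([compute_msd(t1), compute_msd(t2)], n_points=1)
        np.testing.assert_allclose(ens.msd, [2.0])

    def test_ragged_curves_contribute_available_lags(self):
        t1 = Trajectory("a", [0, 1, 2, 3], [0, 1, 2, 3.0], [0] * 4, dt=1.0)
        t2 = Trajectory("b", [0, 1], [0, 5.0], [0, 0.0], dt=1.0)
        ens = ensemble_msd([compute_msd(t1), compute_msd(t2)], n_points=3)
        np.testing.assert_array_equal(ens.n_tracks, [2, 1, 1])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([], n_points=4)

    def test_brownian_ensemble_slope_near_4d(self, rng):
        d, dt = 0.1, 1 / 33
        tracks = random_tracks(rng, n=300, min_len=10, max_len=10, d=d, dt=dt)
        curves = [compute_msd(t, 8) for t in tracks]
        ens = ensemble_msd(curves, n_points=8)
        est = fit_diffusion(ens, 4)
        se = np.sqrt(np.mean(ens.sem[:4] ** 2))  # scale of per-lag error
        assert abs(4 * est.D - 4 * d) < 3 * 4 * se / dt


class TestFitDiffusion:
    def test_exact_linear_curve(self):
        from synaptrack.msd import MSDCurve
        lags = 0.03 * np.arange(1, 9)
        curve = MSDCurve(lags=lags, msd=4 * 0.05 * lags,
                         n_pairs=np.full(8, 10))
        est = fit_diffusion(curve, 4)
        assert est.D == pytest.approx(0.05, abs=1e-12)
        assert est.offset_a == pytest.approx(0.0, abs=1e-12)

    def test_offset_identity(self):
        from synaptrack.msd import MSDCurve
        lags = 0.03 * np.arange(1, 9)
        curve = MSDCurve(lags=lags, msd=4 * 0.05 * lags + 0.02,
                         n_pairs=np.full(8, 10))
        est = fit_diffusion(curve, 4)
        assert est.D == pytest.approx(0.05, abs=1e-12)
        assert est.offset_a == pytest.approx(0.02, abs=1e-12)

    def test_negative_slope_clamped_and_flagged(self):
        from synaptrack.msd import MSDCurve
        lags = 0.03 * np.arange(1, 5)
        curve = MSDCurve(lags=lags, msd=np.array([0.4, 0.3, 0.2, 0.1]),
                         n_pairs=np.full(4, 5))
        est = fit_diffusion(curve, 4)
        assert est.D == 0.0
        assert est.clamped
        assert est.slope_raw < 0

    def test_single_lag_rejected(self, simple_track):
        curve = compute_msd(simple_track, 1)
        with pytest.raises(ValueError):
            fit_diffusion(curve, 4)

    def test_mean_d_unbiased_no_noise(self, rng):
        """Monte-Carlo unbiasedness of the 4-point fit (mean over tracks)."""
        d, dt = 0.1, 1 / 33
        tracks = random_tracks(rng, n=3000, min_len=12, max_len=12, d=d, dt=dt)
        slopes = [fit_diffusion(compute_msd(t, 8), 4).slope_raw
                  for t in tracks]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - d) < 3 * se


class TestClassification:
    def test_zero_d_immobile(self):
        est = DiffusionEstimate(D=0.0, offset_a=0.0, n_fit_points=4,
                                track_id="a")
        assert classify_mobility(est) == "immobile"

    def test_threshold_tie_is_immobile(self):
        assert classify_mobility(0.021) == "immobile"
        assert classify_mobility(0.0211) == "mobile"

    def test_mixture_fraction_matches_counting_oracle(self, rng):
        ds = np.where(rng.random(200) < 0.7,
                      rng.normal(0.005, 0.001, 200),
                      rng.normal(0.2, 0.02, 200))
        labels = [classify_mobility(max(d, 0.0), 0.021) for d in ds]
        assert sum(l == "mobile" for l in labels) == int((ds > 0.021).sum())


class TestSummaries:
    @staticmethod
    def _estimates(ds, field="f0"):
        return [DiffusionEstimate(D=d, offset_a=0.0, n_fit_points=4,
                                  track_id=str(i), field_id=field)
                for i, d in enumerate(ds)]

    def test_counts_and_ratio(self):
        s = summarize_field(self._estimates([0.001, 0.01, 0.3, 0.5]), 0.021)
        assert (s.n_mobile, s.n_immobile) == (2, 2)
        assert s.mobile_immobile_ratio == pytest.approx(1.0)

    def test_all_immobile_ratio_zero(self):
        s = summarize_field(self._estimates([0.001, 0.052]), 0.1)
        assert s.mobile_immobile_ratio == 0.0

    def test_no_immobile_ratio_flagged_undefined(self):
        s = summarize_field(self._estimates([0.5, 0.9]), 0.021)
        assert not s.ratio_defined
        assert np.isnan(s.mobile_immobile_ratio)

    def test_histogram_sums_to_one(self, rng):
        s = summarize_field(self._estimates(rng.lognormal(-3, 1, 500)), 0.021)
        assert s.hist_rel_freq.sum() == pytest.approx(1.0, abs=1e-12)


class TestFilterAndOutliers:
    def test_boundary_length_kept(self):
        tracks = [Trajectory(str(n), np.arange(n), np.zeros(n), np.zeros(n))
                  for n in (5, 8, 12)]
        kept = filter_tracks(tracks, 8)
        assert sorted(len(t) for t in kept) == [8, 12]

    def test_empty_input(self):
        assert filter_tracks([], 8) == []

    def test_filter_matches_comprehension_oracle(self, rng):
        tracks = random_tracks(rng, n=100, min_len=2, max_len=20)
        kept = filter_tracks(tracks, 8)
        oracle = [t for t in tracks if len(t) >= 8]
        assert [t.track_id for t in kept] == [t.track_id for t in oracle]

    def test_identical_values_none_removed(self):
        vals, flags = remove_outlier_fields([2.0] * 6, q=0.01)
        assert not flags.any()

    def test_gross_outlier_flagged(self):
        vals, flags = remove_outlier_fields([1.0, 1.1, 0.9, 1.05, 15.0],
                                            q=0.01)
        np.testing.assert_array_equal(flags,
                                      [False, False, False, False, True])
        assert 15.0 not in vals

    def test_permutation_invariant(self, rng):
        data = np.array([1.0, 1.1, 0.9, 1.05, 15.0, 0.95])
        _, f1 = remove_outlier_fields(data, 0.01)
        perm = rng.permutation(len(data))
        _, f2 = remove_outlier_fields(data[perm], 0.01)
        np.testing.assert_array_equal(f1[perm], f2)

    def test_too_few_values_noop(self):
        vals, flags = remove_outlier_fields([1.0, 99.0], 0.01)
        assert not flags.any()


@settings(max_examples=25, deadline=None)
@given(hyp_st.integers(min_value=3, max_value=20),
       hyp_st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_msd_nonnegative_and_pairs_decrease(n, seed):
    """MSD invariants hold for arbitrary gap-free Brownian tracks."""
    r = np.random.default_rng(seed)
    pos = np.cumsum(r.normal(0, 0.1, (n, 2)), axis=0)
    track = Trajectory("h", np.arange(n), pos[:, 0], pos[:, 1], dt=1 / 33)
    curve = compute_msd(track)
    assert np.all(curve.msd >= 0)
    assert np.all(np.diff(curve.n_pairs) <= 0)
    assert np.all(np.diff(curve.lags) > 0)


def test_mobility_model_end_to_end(rng):
    """Two-population mixture: recovered mobile fraction matches the
    injected mixing proportion within binomial error."""
    import synaptrack as st
    p_fast = 0.3
    tracks = []
    for i in range(400):
        d = 0.2 if rng.random() < p_fast else 0.005
        npts = 12
        steps = rng.normal(0, np.sqrt(2 * d / 33), (npts - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        tracks.append(Trajectory(f"m{i}", np.arange(npts), pos[:, 0],
                                 pos[:, 1], dt=1 / 33))
    res = MobilityModel(tracks).fit()
    frac = res.pooled_summary().mobile_fraction
    assert abs(frac - p_fast) < 3 * np.sqrt(p_fast * (1 - p_fast) / 400)
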