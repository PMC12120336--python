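"""Geolocation engine: emission likelihoods, movement kernel, smoothing,
diffusion estimation and track diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tagtrack import GridSpec
from tagtrack.hmm import (InfeasibleTrackError, LikelihoodStack,
                          acoustic_likelihood, combine_likelihoods,
                          daily_mean_track, depth_likelihood, estimate_sigma,
                          extract_track, forward_backward, movement_kernel,
                          temperature_likelihood, track_distance,
                          track_sensitivity, PosteriorStack, Track, _Stepper)


def _obs(hours, z_max, z_mean=None, t_mean=14.0):
    n = len(hours)
    return pd.DataFrame({
        "hour": pd.DatetimeIndex(hours),
        "z_max": np.broadcast_to(z_max, n).astype(float),
        "z_mean": np.broadcast_to(z_mean if z_mean is not None else z_max, n
                                  ).astype(float),
        "t_mean": np.broadcast_to(t_mean, n).astype(float),
        "n_records": np.full(n, 40)})


def _uniform_stack(grid, T=4, start="2022-06-01"):
    times = pd.date_range(start, periods=T, freq="h")
    vals = np.repeat(grid.sea_mask[None].astype(float), T, axis=0)
    return LikelihoodStack(grid=grid, times=times, values=vals)


class TestDepthLikelihood:
    def test_deep_cell_is_fully_feasible(self, tiny_fields):
        L = depth_likelihood(_obs(["2022-06-01 00:00"], 50.0), tiny_fields, 5.0)
        assert L.values[0, 2, 2] == 1.0  # 100 m water column

    def test_shoal_cell_penalised_by_shortfall(self, tiny_fields):
        L = depth_likelihood(_obs(["2022-06-01 00:00"], 50.0), tiny_fields, 5.0)
        # 10 m shoal: shortfall 40 m -> exp(-40^2 / (2*25)) = exp(-32)
        assert L.values[0, 0, 0] == pytest.approx(np.exp(-32.0), rel=1e-12)

    def test_land_cells_are_zero(self, tiny_fields):
        L = depth_likelihood(_obs(["2022-06-01 00:00"], 5.0), tiny_fields, 5.0)
        assert L.values[0, 1, 1] == 0.0

    def test_missing_hour_raises_naming_it(self, tiny_fields):
        with pytest.raises(KeyError, match="2023"):
            depth_likelihood(_obs(["2023-01-01 00:00"], 5.0), tiny_fields, 5.0)


class TestTemperatureLikelihood:
    def test_exact_match_has_weight_one(self, tiny_fields):
        # shallow obs: surface level, western column is 14.0 C
        L = temperature_likelihood(_obs(["2022-06-01 00:00"], 1.0, 0.0, 14.0),
                                   tiny_fields, 1.0)
        assert L.values[0, 1, 0] == pytest.approx(1.0)

    def test_one_sigma_mismatch(self, tiny_fields):
        L = temperature_likelihood(_obs(["2022-06-01 00:00"], 1.0, 0.0, 13.0),
                                   tiny_fields, 1.0)
        # western column reference is 14.0 -> |dT| = sigma -> exp(-1/2)
        assert L.values[0, 1, 0] == pytest.approx(np.exp(-0.5))

    def test_shoal_uses_deepest_available_level(self, tiny_fields):
        # z_mean = 40 m but the shoal has only the surface level (14.0 C)
        L = temperature_likelihood(_obs(["2022-06-01 00:00"], 40.0, 40.0, 14.0),
                                   tiny_fields, 0.5)
        assert L.values[0, 0, 0] == pytest.approx(1.0)

    def test_unreachable_temperature_raises_with_diagnostic(self, tiny_fields):
        with pytest.raises(InfeasibleTrackError, match="min \\|dT\\|"):
            temperature_likelihood(_obs(["2022-06-01 00:00"], 1.0, 0.0, 50.0),
                                   tiny_fields, 0.1)


class TestAcousticLikelihood:
    def _recv(self, lon, lat, range_m=3000.0, start="2022-05-01",
              end="2022-09-01", rid="R1"):
        return pd.DataFrame({
            "receiver_id": [rid], "station": [rid], "lon": [lon], "lat": [lat],
            "start": [pd.Timestamp(start)], "end": [pd.Timestamp(end)],
            "detection_range_m": [range_m], "protocol": ["OPi"]})

    def test_detection_pins_to_receiver_cells(self, tiny_grid):
        recv = self._recv(0.02, 50.04)
        dets = pd.DataFrame({"tag_id": ["F"], "receiver_id": ["R1"],
                             "timestamp": [pd.Timestamp("2022-06-01 00:30:00")]})
        times = pd.date_range("2022-06-01", periods=2, freq="h")
        L = acoustic_likelihood(dets, recv, tiny_grid, times)
        assert L.values[0, 2, 1] > 0              # the receiver's cell
        assert L.values[0, 0, :].sum() == 0.0     # far row excluded
        # non-detection hour: fully covered receiver cell excluded
        assert L.values[1, 2, 1] == 0.0
        assert L.values[1, 0, 0] == 1.0

    def test_no_active_receivers_gives_uniform_slice(self, tiny_grid):
        recv = self._recv(0.02, 50.04, end="2022-05-02")
        times = pd.date_range("2022-06-01", periods=2, freq="h")
        L = acoustic_likelihood(pd.DataFrame(columns=["tag_id", "receiver_id",
                                                      "timestamp"]),
                                recv, tiny_grid, times)
        np.testing.assert_array_equal(L.values[0], tiny_grid.sea_mask.astype(float))

    def test_conflicting_simultaneous_detections_raise(self):
        sea = np.ones((2, 30), dtype=bool)
        grid = GridSpec(lon=np.linspace(-5.0, -4.0, 30),
                        lat=np.array([48.0, 48.02]), sea_mask=sea)
        recv = pd.concat([self._recv(-4.98, 48.0, rid="R1", range_m=400),
                          self._recv(-4.05, 48.0, rid="R2", range_m=400)],
                         ignore_index=True)  # ~70 km apart
        dets = pd.DataFrame({
            "tag_id": ["F", "F"], "receiver_id": ["R1", "R2"],
            "timestamp": pd.to_datetime(["2022-06-01 00:10:00",
                                         "2022-06-01 00:40:00"])})
        times = pd.date_range("2022-06-01", periods=1, freq="h")
        with pytest.raises(InfeasibleTrackError, match="conflict"):
            acoustic_likelihood(dets, recv, grid, times)

    def test_detection_outside_deployment_is_an_error(self, tiny_grid):
        recv = self._recv(0.02, 50.04, end="2022-05-02")
        dets = pd.DataFrame({"tag_id": ["F"], "receiver_id": ["R1"],
                             "timestamp": [pd.Timestamp("2022-06-01 00:30:00")]})
        times = pd.date_range("2022-06-01", periods=1, freq="h")
        with pytest.raises(ValueError, match="deployment"):
            acoustic_likelihood(dets, recv, tiny_grid, times)


class TestCombine:
    def test_product_with_all_ones_is_identity(self, tiny_grid):
        rng = np.random.default_rng(0)
        a = _uniform_stack(tiny_grid)
        a.values *= rng.uniform(0.1, 1.0, a.values.shape)
        ones = _uniform_stack(tiny_grid)
        out = combine_likelihoods(a, ones)
        np.testing.assert_allclose(out.values, a.values)

    def test_release_anchor_makes_first_slice_one_hot(self, tiny_grid):
        a = _uniform_stack(tiny_grid)
        out = combine_likelihoods(a, release=(0.0, 50.0))
        assert out.values[0].sum() == 1.0
        assert out.values[0, 0, 0] == 1.0

    def test_combination_is_commutative_and_associative(self, tiny_grid):
        rng = np.random.default_rng(1)
        stacks = []
        for _ in range(3):
            s = _uniform_stack(tiny_grid)
            s.values *= rng.uniform(0.1, 1.0, s.values.shape)
            stacks.append(s)
        a, b, c = stacks
        ab_c = combine_likelihoods(combine_likelihoods(a, b), c)
        a_bc = combine_likelihoods(a, combine_likelihoods(b, c))
        cba = combine_likelihoods(c, b, a)
        np.testing.assert_allclose(ab_c.values, a_bc.values, rtol=1e-12)
        np.testing.assert_allclose(ab_c.values, cba.values, rtol=1e-12)

    def test_all_zero_slice_raises_with_index(self, tiny_grid):
        a = _uniform_stack(tiny_grid)
        a.values[2] = 0.0
        with pytest.raises(InfeasibleTrackError, match="index 2"):
            combine_likelihoods(a)


class TestMovementKernel:
    def test_vanishing_sigma_is_identity(self):
        k = movement_kernel(1e-4)
        assert k.array[k.radius, k.radius] == pytest.approx(1.0)

    def test_unit_mass(self):
        for s in (0.3, 1.0, 2.5):
            assert movement_kernel(s).array.sum() == pytest.approx(1.0, abs=1e-12)

    def test_one_step_variance_matches_sigma(self):
        sigma = 1.3
        n = 61
        sea = np.ones((n, n), dtype=bool)
        grid = GridSpec(lon=np.linspace(0, 1, n), lat=np.linspace(40, 41, n),
                        sea_mask=sea)
        step = _Stepper(movement_kernel(sigma), sea)
        p = np.zeros((n, n))
        p[n // 2, n // 2] = 1.0
        q = step.predict(p)
        idx = np.arange(n) - n // 2
        var_x = (q.sum(axis=0) * idx ** 2).sum()
        var_y = (q.sum(axis=1) * idx ** 2).sum()
        assert var_x == pytest.approx(sigma ** 2, rel=0.01)
        assert var_y == pytest.approx(sigma ** 2, rel=0.01)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            movement_kernel(0.0)


class TestForwardBackward:
    def test_single_step_posterior_is_prior_times_likelihood(self, tiny_grid):
        rng = np.random.default_rng(2)
        L = _uniform_stack(tiny_grid, T=1)
        L.values *= rng.uniform(0.1, 1.0, L.values.shape)
        prior = tiny_grid.sea_mask / tiny_grid.sea_mask.sum()
        post, ll = forward_backward(L, movement_kernel(1.0), prior)
        expect = prior * L.values[0]
        np.testing.assert_allclose(post.probs[0], expect / expect.sum(),
                                   rtol=1e-12)
        assert np.isfinite(ll)

    @pytest.mark.parametrize("shape,T,sigma", [((3, 3), 4, 0.8),
                                               ((4, 4), 3, 1.2)])
    def test_matches_exhaustive_path_enumeration(self, shape, T, sigma):
        rng = np.random.default_rng(shape[0] * 10 + T)
        sea = np.ones(shape, dtype=bool)
        sea[1, 1] = False
        ny, nx = shape
        grid = GridSpec(lon=np.linspace(0, 0.1, nx),
                        lat=np.linspace(50, 50.1, ny), sea_mask=sea)
        K = movement_kernel(sigma)
        vals = rng.uniform(0.05, 1.0, (T,) + shape) * sea
        L = LikelihoodStack(grid=grid,
                            times=pd.date_range("2022-01-01", periods=T,
                                                freq="h"),
                            values=vals)
        post, ll = forward_backward(L, K)

        cells = [c for c in itertools.product(range(ny), range(nx)) if sea[c]]
        r = K.radius

        def kval(a, b):
            di, dj = b[0] - a[0], b[1] - a[1]
            if abs(di) > r or abs(dj) > r:
                return 0.0
            return K.array[di + r, dj + r]

        trans = np.array([[kval(a, b) for b in cells] for a in cells])
        trans /= trans.sum(axis=1, keepdims=True)
        prior = np.full(len(cells), 1.0 / len(cells))
        lc = np.array([[vals[t][c] for c in cells] for t in range(T)])
        marg = np.zeros((T, len(cells)))
        tot = 0.0
        for path in itertools.product(range(len(cells)), repeat=T):
            w = prior[path[0]] * lc[0, path[0]]
            for t in range(1, T):
                w *= trans[path[t - 1], path[t]] * lc[t, path[t]]
            tot += w
            for t in range(T):
                marg[t, path[t]] += w
        marg /= tot
        mine = np.array([[post.probs[t][c] for c in cells] for t in range(T)])
        np.testing.assert_allclose(mine, marg, atol=1e-10)
        assert ll == pytest.approx(np.log(tot), abs=1e-10)

    def test_slices_normalised_and_land_zero(self, tiny_grid):
        rng = np.random.default_rng(3)
        L = _uniform_stack(tiny_grid, T=8)
        L.values *= rng.uniform(0.05, 1.0, L.values.shape)
        post, _ = forward_backward(L, movement_kernel(0.7))
        sums = post.probs.reshape(8, -1).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert np.all(post.probs[:, 1, 1] == 0.0)

    def test_anchors_pin_first_and_last_slices(self, tiny_grid):
        L = _uniform_stack(tiny_grid, T=5)
        combined = combine_likelihoods(L, release=(0.0, 50.0),
                                       recapture=(0.04, 50.04))
        post, _ = forward_backward(combined, movement_kernel(1.0))
        assert post.probs[0, 0, 0] == pytest.approx(1.0)
        assert post.probs[-1, 2, 2] == pytest.approx(1.0)


class TestEstimateSigma:
    def test_flat_profile_warns_and_returns_boundary(self, tiny_grid):
        L = _uniform_stack(tiny_grid, T=6)
        with pytest.warns(UserWarning, match="flat"):
            est = estimate_sigma(L, bounds=(0.2, 2.0))
        assert est.at_boundary
        assert est.sigma_hat == 0.2

    def test_invariant_to_likelihood_scaling(self, tiny_grid):
        rng = np.random.default_rng(4)
        L = _uniform_stack(tiny_grid, T=20)
        L.values *= rng.uniform(0.05, 1.0, L.values.shape)
        L2 = LikelihoodStack(grid=tiny_grid, times=L.times,
                             values=7.0 * L.values)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = estimate_sigma(L, bounds=(0.2, 2.0))
            e2 = estimate_sigma(L2, bounds=(0.2, 2.0))
        assert e1.sigma_hat == pytest.approx(e2.sigma_hat, abs=1e-6)


class TestTrackExtraction:
    def _post(self, grid, probs):
        return PosteriorStack(grid=grid,
                              times=pd.date_range("2022-06-01",
                                                  periods=len(probs), freq="h"),
                              probs=np.asarray(probs, dtype=float))

    def test_one_hot_posterior_gives_cell_centre_and_zero_sd(self, tiny_grid):
        p = np.zeros((1, 3, 3))
        p[0, 2, 0] = 1.0
        tr = extract_track(self._post(tiny_grid, p))
        assert tr.data["lon_mean"].iloc[0] == 0.0
        assert tr.data["lat_mean"].iloc[0] == 50.04
        assert tr.data["sd_km"].iloc[0] == 0.0

    def test_symmetric_posterior_mean_midpoint_mode_tiebreak(self, tiny_grid):
        p = np.zeros((1, 3, 3))
        p[0, 0, 0] = 0.5
        p[0, 0, 2] = 0.5
        tr = extract_track(self._post(tiny_grid, p))
        assert tr.data["lon_mean"].iloc[0] == pytest.approx(0.02)
        assert tr.data["lon_mode"].iloc[0] == 0.0  # lowest (lat, lon) index

    def test_stationary_track_travels_zero_km(self, tiny_grid):
        p = np.zeros((30, 3, 3))
        p[:, 2, 0] = 1.0
        tr = extract_track(self._post(tiny_grid, p))
        assert track_distance(tr, "hourly") == 0.0
        assert track_distance(tr, "daily") == 0.0

    def test_hourly_distance_at_least_daily(self, scenario):
        # zig-zag posterior across two cells
        p = np.zeros((48, 3, 3))
        for t in range(48):
            p[t, 2, t % 2] = 1.0
        grid = GridSpec(lon=np.array([0.0, 0.02, 0.04]),
                        lat=np.array([50.0, 50.02, 50.04]),
                        sea_mask=np.ones((3, 3), dtype=bool))
        tr = extract_track(self._post(grid, p))
        assert track_distance(tr, "hourly") >= track_distance(tr, "daily")

    def test_daily_track_averages_hourly_means(self, tiny_grid):
        p = np.zeros((24, 3, 3))
        p[:12, 2, 0] = 1.0
        p[12:, 2, 2] = 1.0
        tr = extract_track(self._post(tiny_grid, p))
        daily = daily_mean_track(tr)
        assert len(daily) == 1
        assert daily["lon"].iloc[0] == pytest.approx(0.02)


class TestTrackSensitivity:
    def _track(self, lons, lats):
        n = len(lons)
        return Track(data=pd.DataFrame({
            "time": pd.date_range("2022-06-01", periods=n, freq="h"),
            "lon_mean": lons, "lat_mean": lats,
            "lon_mode": lons, "lat_mode": lats, "sd_km": np.zeros(n)}))

    def test_identical_tracks_have_zero_sensitivity(self):
        t = self._track([0.0, 0.1, 0.2], [48.0, 48.0, 48.0])
        assert track_sensitivity(t, t) == (0.0, 0.0, 0.0)

    def test_mismatched_time_axes_raise(self):
        a = self._track([0.0, 0.1], [48.0, 48.0])
        b = self._track([0.0, 0.1, 0.2], [48.0, 48.0, 48.0])
        with pytest.raises(ValueError, match="time axes"):
            track_sensitivity(a, b)

    def test_summary_is_mean_min_max_of_stepwise_distance(self):
        a = self._track([0.0, 0.0, 0.0], [48.0, 48.0, 48.0])
        b = self._track([0.0, 1.0, 2.0], [48.0, 48.0, 48.0])
        mean_d, min_d, max_d = track_sensitivity(a, b)
        assert min_d == 0.0
        assert max_d == pytest.approx(148.8, rel=1e-2)
        assert mean_d == pytest.approx((0 + 74.4 + 148.8) / 3, rel=1e-2)
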