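import numpy as np
import pytest

import focimap as fm
from focimap.localize import MeshGeometry, PlanarGeometry, _closed_form_objective


def _single_source_chain(layout, mat, n_resamples=10, sigma=0.0, seed=0):
    cfg = fm.StatsConfig(n_resamples_M=n_resamples, trials_T=30, lat_sd_sigma=sigma, seed=seed)
    est_f = fm.estimate_probabilities(mat, cfg, "first")
    est_l = fm.estimate_probabilities(mat, cfg, "last")
    (path,) = fm.extract_probable_paths(est_f, est_l, 1)
    matched = fm.filter_path_matched(mat, path, "full")
    return path, matched


class TestEstimateCv:
    def test_six_pairwise_values(self, layout, noiseless_single_source, planar_geometry):
        mat, _ = noiseless_single_source
        path, matched = _single_source_chain(layout, mat)
        cve = fm.estimate_cv(mat, path, matched, planar_geometry, rel_dt_frac=0.0)
        assert len(cve.pairwise_values) == 6
        assert cve.mean_mu > 0

    def test_collinear_sensors_planar_wave_exact(self):
        """Sensors on a line, wave travelling along it: all 6 CVs exact, sd 0."""
        pos = {11: [0.0, 0.0, 0.0], 1: [10.0, 0.0, 0.0], 9: [20.0, 0.0, 0.0], 19: [30.0, 0.0, 0.0]}
        geom = PlanarGeometry(pos)
        cv_true = 0.8
        lat = np.zeros((5, 10))
        mat_cols = {p: fm.ActivationMatrix(np.zeros((1, 10))).column_of(p) for p in pos}
        for p, xyz in pos.items():
            lat[:, mat_cols[p]] = 100.0 * np.arange(1, 6)[:, None].squeeze() + xyz[0] / cv_true
        for k in range(5):
            lat[k, :] += 0.0
        mat = fm.ActivationMatrix(lat + 1.0)  # keep untouched channels finite
        path = fm.ProbablePath(source_rank=1, FO=11, FI=1, LI=9, LO=19)
        matched = fm.PathMatchedSample(path=path, activation_ids=mat.activation_ids)
        cve = fm.estimate_cv(mat, path, matched, geom, rel_dt_frac=0.0)
        np.testing.assert_allclose(cve.pairwise_values, cv_true, rtol=1e-9)
        assert cve.sd_sigma_c == pytest.approx(0.0, abs=1e-9)

    def test_focal_wave_mean_within_ten_percent(self, layout, planar_geometry):
        """A distant source roughly aligned with the path: the geodesic
        chord approximates the wavepath and the CV bias stays small."""
        src = fm.SourceSpec(np.array([60.0, 6.0, 0.0]), np.arange(1, 41) * 400.0)
        mat = fm.simulate_lat_matrix([src], layout.pair_midpoints, fm.CVModel(1.0, 0.0), fm.NoiseModel(0.2), seed=4)
        path, matched = _single_source_chain(layout, mat, sigma=0.2, seed=4)
        cve = fm.estimate_cv(mat, path, matched, planar_geometry)
        assert cve.mean_mu == pytest.approx(1.0, rel=0.10)

    def test_too_few_usable_pairs_rejected(self):
        pos = {11: [0.0, 0.0, 0.0], 1: [1.0, 0.0, 0.0], 9: [2.0, 0.0, 0.0], 19: [3.0, 0.0, 0.0]}
        geom = PlanarGeometry(pos)
        mat = fm.ActivationMatrix(np.full((4, 10), 50.0))  # all simultaneous
        path = fm.ProbablePath(source_rank=1, FO=11, FI=1, LI=9, LO=19)
        matched = fm.PathMatchedSample(path=path, activation_ids=mat.activation_ids)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than two usable"):
                fm.estimate_cv(mat, path, matched, geom)


class TestFitSourceLocation:
    def test_planar_noiseless_recovery(self, layout, noiseless_single_source, planar_geometry):
        mat, src = noiseless_single_source
        path, matched = _single_source_chain(layout, mat)
        fit = fm.fit_source_location(mat, path, matched, 1.0, planar_geometry, fm.LocalizationConfig())
        assert np.linalg.norm(fit.s0 - src.location) <= 0.1

    def test_mesh_fit_equals_brute_force(self, icosphere):
        """Exhaustive (vertex, closed-form onset) enumeration is the oracle."""
        rng = np.random.default_rng(2)
        sensor_vertices = {11: 0, 1: 25, 9: 80, 19: 140}
        geom = MeshGeometry(icosphere, sensor_vertices)
        true_vertex = 60
        onsets = np.arange(1, 11) * 300.0
        lat = np.zeros((10, 10))
        mat_proto = fm.ActivationMatrix(np.ones((1, 10)))
        for p, v in sensor_vertices.items():
            d = fm.geodesic_field(icosphere, true_vertex).distance_per_vertex[v]
            lat[:, mat_proto.column_of(p)] = onsets + d / 1.0
        lat += rng.normal(0.0, 0.3, size=lat.shape)
        lat = np.abs(lat)
        mat = fm.ActivationMatrix(lat)
        path = fm.ProbablePath(source_rank=1, FO=11, FI=1, LI=9, LO=19)
        matched = fm.PathMatchedSample(path=path, activation_ids=mat.activation_ids)
        config = fm.LocalizationConfig(rho_max=200.0)
        fit = fm.fit_source_location(mat, path, matched, 1.0, geom, config)

        # independent brute force: loop over every vertex, profile onsets
        cols = [mat.column_of(p) for p in path.as_tuple]
        sub = lat[:, cols]
        best_v, best_sse = None, np.inf
        for v in range(icosphere.n_vertices):
            d = np.array([fm.geodesic_field(icosphere, sv).distance_per_vertex[v] for sv in sensor_vertices.values()])
            t = np.clip((sub - d[None, :]).mean(axis=1), 0.0, sub[:, 0] - config.onset_tol)
            sse = float(np.sum((d[None, :] + t[:, None] - sub) ** 2))
            if sse < best_sse:
                best_v, best_sse = v, sse
        assert fit.vertex == best_v
        assert fit.sse == pytest.approx(best_sse, rel=1e-12)

    def test_source_at_sensor_site(self, layout, planar_geometry):
        """Source placed on a path sensor: zero distance term, feasible fit."""
        src_loc = layout.midpoint_of(11).copy()
        src = fm.SourceSpec(src_loc, np.arange(1, 31) * 400.0)
        mat = fm.simulate_lat_matrix([src], layout.pair_midpoints, fm.CVModel(1.0, 0.0), fm.NoiseModel(0.0), seed=0)
        path, matched = _single_source_chain(layout, mat)
        fit = fm.fit_source_location(mat, path, matched, 1.0, planar_geometry, fm.LocalizationConfig())
        assert np.linalg.norm(fit.s0 - src_loc) <= 0.1
        assert fit.sse == pytest.approx(0.0, abs=1e-6)

    def test_onset_constraint_holds(self, layout, make_single_source, planar_geometry):
        mat, _ = make_single_source(sigma=1.0, cv_sd=0.05, seed=21)
        path, matched = _single_source_chain(layout, mat, sigma=1.0, seed=21)
        fit = fm.fit_source_location(mat, path, matched, 1.1, planar_geometry, fm.LocalizationConfig())
        sub = mat.subset_by_ids(matched.activation_ids)
        lat_fo = sub.lat[:, sub.column_of(path.FO)]
        assert np.all(fit.onsets >= 0.0)
        assert np.all(fit.onsets < lat_fo)

    def test_sse_not_worse_than_truth(self, layout, make_single_source, planar_geometry):
        mat, src = make_single_source(sigma=0.5, seed=33)
        path, matched = _single_source_chain(layout, mat, sigma=0.5, seed=33)
        cfg = fm.LocalizationConfig()
        fit = fm.fit_source_location(mat, path, matched, 1.0, planar_geometry, cfg)
        sub = mat.subset_by_ids(matched.activation_ids)
        cols = [sub.column_of(p) for p in path.as_tuple]
        lat = sub.lat[:, cols]
        d_true = np.linalg.norm(planar_geometry.sensor_array(path.as_tuple) - src.location, axis=1)
        sse_true, _ = _closed_form_objective(d_true[None, :], lat, lat[:, 0], 1.0, cfg.onset_tol)
        assert fit.sse <= sse_true[0] + 1e-9


class TestMonteCarloLocalize:
    def test_deterministic_and_zero_dispersion_without_noise(self, layout, noiseless_single_source, planar_geometry):
        mat, src = noiseless_single_source
        path, matched = _single_source_chain(layout, mat)
        cve = fm.CVEstimate(mean_mu=1.0, sd_sigma_c=0.0, pairwise_values=np.ones(6))
        cfg = fm.LocalizationConfig(n_mc_replicates_M=8, seed=5)
        a = fm.monte_carlo_localize(mat, path, matched, cve, planar_geometry, cfg)
        b = fm.monte_carlo_localize(mat, path, matched, cve, planar_geometry, cfg)
        np.testing.assert_array_equal(a.point_estimate, b.point_estimate)
        assert a.dispersion["mean_spread"] == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.norm(a.point_estimate - src.location) <= 0.1

    def test_dispersion_grows_with_cv_uncertainty(self, layout, noiseless_single_source, planar_geometry):
        from scipy.stats import kendalltau

        mat, _ = noiseless_single_source
        path, matched = _single_source_chain(layout, mat)
        spreads = []
        for sd in (0.0, 0.02, 0.05, 0.1):
            cve = fm.CVEstimate(mean_mu=1.0, sd_sigma_c=sd, pairwise_values=np.ones(6))
            res = fm.monte_carlo_localize(
                mat, path, matched, cve, planar_geometry, fm.LocalizationConfig(n_mc_replicates_M=15, seed=7, bootstrap=False)
            )
            spreads.append(res.dispersion["mean_spread"])
        tau, _ = kendalltau(range(len(spreads)), spreads)
        assert tau > 0


class TestAggregation:
    def test_identical_placements_agree(self, layout, noiseless_single_source, planar_geometry):
        mat, src = noiseless_single_source
        path, matched = _single_source_chain(layout, mat)
        cve = fm.CVEstimate(mean_mu=1.0, sd_sigma_c=0.0, pairwise_values=np.ones(6))
        res = fm.monte_carlo_localize(
            mat, path, matched, cve, planar_geometry, fm.LocalizationConfig(n_mc_replicates_M=3, seed=0)
        )
        pooled = fm.aggregate_placements([res, res, res], truth=src.location)
        np.testing.assert_allclose(pooled["centroid"], res.point_estimate)
        assert pooled["spread_rms"] == pytest.approx(0.0, abs=1e-9)
        assert pooled["centroid_error"] <= 0.1

    def test_closer_catheters_localize_better(self):
        """Rank correlation between catheter-source distance and error."""
        from scipy.stats import kendalltau

        src_loc = np.array([0.0, 0.0, 0.0])
        errors, dists = [], []
        for k, dist in enumerate((6.0, 12.0, 20.0, 30.0)):
            lay = fm.build_pentaray_layout(center=(dist, 3.0, 0.0), orientation=0.3 * k)
            src = fm.SourceSpec(src_loc, np.arange(1, 41) * 400.0)
            mat = fm.simulate_lat_matrix([src], lay.pair_midpoints, fm.CVModel(1.0, 0.02), fm.NoiseModel(0.3), seed=k)
            path, matched = _single_source_chain(lay, mat, sigma=0.3, seed=k)
            geom = fm.PlanarGeometry.from_layout(lay)
            cve = fm.estimate_cv(mat, path, matched, geom)
            res = fm.monte_carlo_localize(
                mat, path, matched, cve, geom, fm.LocalizationConfig(n_mc_replicates_M=10, rho_max=60.0, seed=k)
            )
            errors.append(np.linalg.norm(res.point_estimate - src_loc))
            dists.append(dist)
        tau, _ = kendalltau(dists, errors)
        assert tau > 0
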