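"""Kernel home ranges: isopleth areas, overlap, centroids, monthly fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

import vultrack as vt
from vultrack.homerange import DegenerateInputError, isopleth_mask, _fit_on_grid

from conftest import hourly_times, make_traj

CENTER = vt.GeoPoint(-8.0, 16.0)


def gaussian_cloud(n, sigma_km, center=CENTER, seed=0, offset_km=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    proj = vt.EqualAreaProjection(center)
    xy = rng.normal(0.0, sigma_km, size=(n, 2)) + np.asarray(offset_km)
    return proj.inverse(xy[:, 0], xy[:, 1])


class TestFitKde:
    def test_gaussian_isopleth_area_matches_analytic(self):
        # KDE of N(0, sigma^2 I) with kernel SD h estimates N(0, (sigma^2+h^2) I),
        # whose 95% region has area pi * chi2(0.95, 2) * (sigma^2 + h^2)
        lon, lat = gaussian_cloud(4000, 100.0, seed=1)
        est = vt.fit_kde(lon, lat, bandwidth=20.0, cell_km=5.0)
        expected = math.pi * chi2.ppf(0.95, 2) * (100.0 ** 2 + 20.0 ** 2)
        assert est.area_km2 == pytest.approx(expected, rel=0.05)

    def test_density_mass_is_one(self):
        lon, lat = gaussian_cloud(500, 50.0, seed=2)
        est = vt.fit_kde(lon, lat, bandwidth=15.0)
        assert est.density.sum() * est.cell_km ** 2 == pytest.approx(1.0, abs=1e-6)
        assert est.mass_inside() >= est.level

    def test_isopleth_levels_nested_and_monotone(self):
        lon, lat = gaussian_cloud(1000, 80.0, seed=3)
        est = vt.fit_kde(lon, lat, bandwidth=20.0)
        m50 = isopleth_mask(est, 0.50)
        m99 = isopleth_mask(est, 0.99)
        assert np.all(m50 <= est.mask) and np.all(est.mask <= m99)
        area = est.cell_km ** 2
        assert m50.sum() * area < est.area_km2 < m99.sum() * area

    def test_grid_refinement_stability(self):
        lon, lat = gaussian_cloud(3000, 100.0, seed=4)
        a5 = vt.fit_kde(lon, lat, bandwidth=20.0, cell_km=5.0).area_km2
        a10 = vt.fit_kde(lon, lat, bandwidth=20.0, cell_km=10.0).area_km2
        assert abs(a10 - a5) / a5 < 0.03

    def test_matches_sklearn_density_cross_check(self):
        from sklearn.neighbors import KernelDensity

        lon, lat = gaussian_cloud(800, 60.0, seed=5)
        h = 25.0
        est = vt.fit_kde(lon, lat, bandwidth=h, cell_km=4.0)
        x, y = est.projection.forward(lon, lat)
        kd = KernelDensity(bandwidth=h).fit(np.c_[x, y])
        # compare at the grid cell centres of a central slice
        iy, ix = np.nonzero(est.mask)
        pick = slice(0, len(ix), max(1, len(ix) // 50))
        cx = est.x0 + ix[pick] * est.cell_km
        cy = est.y0 + iy[pick] * est.cell_km
        ref = np.exp(kd.score_samples(np.c_[cx, cy]))
        ours = est.density[iy[pick], ix[pick]]
        assert np.allclose(ours, ref, rtol=0.05, atol=ref.max() * 0.02)

    def test_silverman_reference_bandwidth(self):
        lon, lat = gaussian_cloud(1000, 100.0, seed=6)
        est = vt.fit_kde(lon, lat, bandwidth="reference")
        x, y = est.projection.forward(lon, lat)
        sigma = np.sqrt(0.5 * (np.var(x, ddof=1) + np.var(y, ddof=1)))
        assert est.bandwidth_km == pytest.approx(sigma * 1000 ** (-1 / 6.0))

    def test_error_on_too_few_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            vt.fit_kde(np.zeros(5), np.zeros(5))

    def test_error_on_identical_points(self):
        with pytest.raises(DegenerateInputError):
            vt.fit_kde(np.full(20, -8.0), np.full(20, 16.0), bandwidth=10.0)

    def test_error_on_bad_bandwidth(self):
        lon, lat = gaussian_cloud(50, 10.0, seed=7)
        with pytest.raises(ValueError):
            vt.fit_kde(lon, lat, bandwidth=-1.0)


class TestOverlap:
    def test_identical_point_sets_full_overlap(self):
        lon, lat = gaussian_cloud(600, 80.0, seed=8)
        a = vt.fit_kde(lon, lat, bandwidth=20.0)
        b = vt.fit_kde(lon, lat, bandwidth=20.0)
        assert vt.overlap_pct(a, b) == pytest.approx(100.0, abs=0.5)

    def test_distant_ranges_zero_overlap(self):
        lon1, lat1 = gaussian_cloud(300, 60.0, seed=9)
        far = vt.GeoPoint(40.0, 10.0)   # ~5000 km away
        lon2, lat2 = gaussian_cloud(300, 60.0, center=far, seed=10)
        a = vt.fit_kde(lon1, lat1, bandwidth=20.0)
        b = vt.fit_kde(lon2, lat2, bandwidth=20.0)
        assert vt.overlap_pct(a, b) == 0.0

    def test_symmetry_in_arguments(self):
        lon1, lat1 = gaussian_cloud(400, 70.0, seed=11)
        lon2, lat2 = gaussian_cloud(400, 70.0, seed=12, offset_km=(60.0, 0.0))
        a = vt.fit_kde(lon1, lat1, bandwidth=20.0)
        b = vt.fit_kde(lon2, lat2, bandwidth=20.0)
        assert vt.overlap_pct(a, b) == pytest.approx(vt.overlap_pct(b, a), abs=1e-9)

    def test_offset_gaussians_match_finer_grid_oracle(self):
        # overlap recomputed on a 4x finer lattice agrees within 2 points
        rng = np.random.default_rng(13)
        for trial in range(5):
            sigma = rng.uniform(60, 120)
            off = rng.uniform(0.3, 1.5) * sigma
            lon1, lat1 = gaussian_cloud(700, sigma, seed=100 + trial)
            lon2, lat2 = gaussian_cloud(700, sigma, seed=200 + trial,
                                        offset_km=(off, 0.0))
            a = vt.fit_kde(lon1, lat1, bandwidth=20.0, cell_km=5.0)
            b = vt.fit_kde(lon2, lat2, bandwidth=20.0, cell_km=5.0)
            coarse = vt.overlap_pct(a, b)
            af = vt.fit_kde(lon1, lat1, bandwidth=20.0, cell_km=1.25)
            bf = vt.fit_kde(lon2, lat2, bandwidth=20.0, cell_km=1.25)
            fine = vt.overlap_pct(af, bf)
            assert abs(coarse - fine) <= 2.0

    def test_directed_overlaps_bracket_symmetric(self):
        lon1, lat1 = gaussian_cloud(500, 60.0, seed=14)
        lon2, lat2 = gaussian_cloud(500, 120.0, seed=15, offset_km=(50.0, 0.0))
        a = vt.fit_kde(lon1, lat1, bandwidth=20.0)
        b = vt.fit_kde(lon2, lat2, bandwidth=20.0)
        res = vt.pairwise_overlap(a, b, "a", "b")
        lo, hi = sorted([res.directed_a_pct, res.directed_b_pct])
        assert lo <= res.overlap_pct <= hi


class TestCentroids:
    def test_identical_estimates_zero_distance(self):
        lon, lat = gaussian_cloud(400, 50.0, seed=16)
        a = vt.fit_kde(lon, lat, bandwidth=15.0)
        assert vt.centroid_distance_km(a, a) == 0.0

    def test_offset_by_400km_recovered(self):
        lon1, lat1 = gaussian_cloud(2000, 60.0, seed=17)
        lon2, lat2 = gaussian_cloud(2000, 60.0, seed=18, offset_km=(400.0, 0.0))
        a = vt.fit_kde(lon1, lat1, bandwidth=20.0)
        b = vt.fit_kde(lon2, lat2, bandwidth=20.0)
        assert vt.centroid_distance_km(a, b) == pytest.approx(400.0, abs=10.0)


@pytest.fixture(scope="module")
def resident(small_cohort_clean):
    _, clean, segs, truths = small_cohort_clean
    for traj, seg in zip(clean, segs):
        if (truths[traj.individual_id].strategy == "non_migrant"
                and truths[traj.individual_id].death_time is None):
            start = [iv for iv in seg.intervals if iv.stage == "residency"][0].start
            fixes = traj.fixes[traj.fixes["timestamp"] >= start]
            return vt.Trajectory(traj.deployment, fixes.reset_index(drop=True))
    pytest.skip("no surviving resident in fixture cohort")


class TestMonthlyKde:

    def test_seasonal_two_core_pattern(self, resident):
        from shapely.geometry import Point

        cfg = vt.SimulationConfig()
        cores = {"south": Point(*cfg.resident_core_south).buffer(0.5),
                 "north": Point(*cfg.resident_core_north).buffer(0.5)}
        _, occ = vt.monthly_kde(resident, core_polygons=cores)
        occ = occ[occ["n_fixes"] >= 100].copy()
        occ["m"] = occ["month"].map(lambda p: p.month)
        month_mean = occ.groupby("m")[["pct_in_south", "pct_in_north"]].mean()
        south_months = [9, 10, 11, 12, 1, 2, 3]
        for m in south_months:
            assert month_mean.loc[m, "pct_in_south"] > 80.0
        for m in [5, 6, 7]:   # well inside the northern season
            assert month_mean.loc[m, "pct_in_north"] > month_mean.loc[m, "pct_in_south"]

    def test_sparse_month_skipped(self):
        times = list(hourly_times("2021-07-30 12:00", 3, 1.0))
        times += list(hourly_times("2021-08-01", 200, 1.0))
        rng = np.random.default_rng(19)
        traj = make_traj(times, -6 + rng.normal(0, 0.1, 203),
                         40 + rng.normal(0, 0.1, 203))
        ests, occ = vt.monthly_kde(traj, min_fixes=10)
        months = {str(m) for m in ests}
        assert "2021-07" not in months and "2021-08" in months

    def test_monthly_masks_do_not_union_to_pooled(self, resident):
        ests, _ = vt.monthly_kde(resident)
        pooled = vt.fit_kde(resident.fixes["lon"], resident.fixes["lat"])
        total_monthly = sum(e.area_km2 for e in ests.values())
        assert total_monthly != pytest.approx(pooled.area_km2, rel=0.01)


class TestAreaContrast:
    def test_migrant_sahel_ranges_dwarf_resident_ranges(self, small_cohort_clean):
        _, clean, segs, truths = small_cohort_clean
        sahel_areas, resident_areas = [], []
        for traj, seg in zip(clean, segs):
            label = {"migrant": "sahel_stay", "non_migrant": "residency"}.get(seg.strategy)
            if label is None:
                continue
            spans = [iv for iv in seg.intervals if iv.stage == label]
            if not spans:
                continue
            m = np.zeros(len(traj.fixes), dtype=bool)
            for iv in spans:
                m |= ((traj.fixes["timestamp"] >= iv.start)
                      & (traj.fixes["timestamp"] <= iv.end)).to_numpy()
            if m.sum() < 10:
                continue
            est = vt.fit_kde(traj.fixes["lon"][m], traj.fixes["lat"][m])
            (sahel_areas if label == "sahel_stay" else resident_areas).append(est.area_km2)
        assert sahel_areas and resident_areas
        assert np.mean(sahel_areas) >= 5.0 * np.mean(resident_areas)
        assert np.mean(sahel_areas) > 5e4   # order 1e5 km2
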