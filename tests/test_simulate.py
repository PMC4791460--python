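import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alcatrack import simulate as sim
from alcatrack.simulate import ROIBox, SimConfig


class TestLevySteps:
    def test_closed_form_median(self):
        # Pareto median is l_min * 2**(1/(mu-1)) = 2 for mu = 2, l_min = 1
        l = sim.gen_levy_steps(100_000, 2.0, 1.0, 0)
        assert np.median(l) == pytest.approx(2.0, rel=0.03)

    def test_support_bound(self):
        assert sim.gen_levy_steps(10_000, 2.0, 1.0, 1).min() >= 1.0

    def test_ccdf_matches_analytic_law(self):
        # empirical CCDF at l is (l/l_min)^(1-mu); KS against the exact CDF
        l = sim.gen_levy_steps(100_000, 2.0, 1.0, 2)
        p = stats.kstest(l, lambda v: 1.0 - v ** -1.0).pvalue
        assert p > 0.01

    def test_ks_calibration_across_seeds(self):
        # distributional correctness: alpha = 0.01 KS passes in >= 95% of seeds
        ok = sum(
            stats.kstest(sim.gen_levy_steps(2000, 1.7, 1.0, s),
                         lambda v: 1.0 - v ** (1 - 1.7)).pvalue > 0.01
            for s in range(40))
        assert ok >= 38

    @pytest.mark.parametrize("mu", [1.0, 0.5, -2.0])
    def test_invalid_exponent_rejected(self, mu):
        with pytest.raises(ValueError):
            sim.gen_levy_steps(10, mu, 1.0, 0)


class TestExponentialSteps:
    def test_means(self):
        assert sim.gen_exponential_steps(100_000, 1.0, 0.0, 0).mean() == pytest.approx(1.0, rel=0.02)
        assert sim.gen_exponential_steps(100_000, 0.5, 1.0, 1).mean() == pytest.approx(3.0, rel=0.02)

    def test_single_draw_respects_floor(self):
        assert sim.gen_exponential_steps(1, 2.0, 5.0, 0)[0] >= 5.0

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_exponential_steps(10, 0.0, 1.0, 0)


class TestCentralPlaceTrip:
    def test_timestamps_strictly_increasing(self):
        cfg = SimConfig(seed=0)
        fixes, _ = sim.gen_central_place_trip(cfg, 45.0, 1)
        assert (np.diff(fixes["t_s"]) > 0).all()

    def test_noise_free_max_range_matches_truth(self):
        cfg = SimConfig(seed=0, gps_noise_sd=0.0)
        fixes, truth = sim.gen_central_place_trip(cfg, 120.0, 2, distal_distance=20_000.0)
        r = np.hypot(fixes["x"], fixes["y"])
        assert r.max() == pytest.approx(truth["max_range_m"], rel=1e-9)
        assert truth["max_range_m"] >= 20_000.0

    def test_endpoints_at_colony(self):
        cfg = SimConfig(seed=0)
        fixes, _ = sim.gen_central_place_trip(cfg, -60.0, 3)
        assert fixes[["x", "y"]].iloc[0].abs().max() == 0.0
        assert fixes[["x", "y"]].iloc[-1].abs().max() == 0.0

    def test_true_steps_follow_the_powerlaw(self):
        # realized (untethered, untruncated) step lengths pass the CCDF check
        cfg = SimConfig(seed=0, mu_true=2.0, l_min=1000.0)
        fixes, truth = sim.gen_central_place_trip(cfg, 90.0, 4, n_ars_steps=600,
                                                  distal_distance=30_000.0)
        l = np.asarray(truth["step_lengths_m"])
        keep = ~(np.asarray(truth["steps_truncated"]) | np.asarray(truth["steps_clipped"]))
        p = stats.kstest(l[keep] / 1000.0, lambda v: 1.0 - v ** -1.0).pvalue
        assert p > 0.01


class TestRouteFamilies:
    def test_zero_jitter_collapses_families(self, rng):
        from alcatrack.routes import nna_distance
        paths, labels = sim.gen_route_families(2, 3, jitter_m=0.0, seed=0)
        a, b = [p for p, l in zip(paths, labels) if l == 0][:2]
        assert nna_distance(a, b) == 0.0

    def test_between_family_exceeds_within(self):
        from alcatrack.routes import nna_distance
        paths, labels = sim.gen_route_families(2, 3, jitter_m=200.0, seed=1,
                                               separation_m=10_000.0)
        fam0 = [p for p, l in zip(paths, labels) if l == 0]
        fam1 = [p for p, l in zip(paths, labels) if l == 1]
        within = nna_distance(fam0[0], fam0[1])
        between = nna_distance(fam0[0], fam1[0])
        assert between > 5 * within

    def test_single_track(self):
        paths, labels = sim.gen_route_families(1, 1, jitter_m=0.0, seed=0)
        assert len(paths) == 1 and labels.tolist() == [0]


class TestTdrTrace:
    def test_empty_plan_is_flat_zero(self):
        tr = sim.gen_tdr_trace([], 100, surface_noise_sd=0.0, drift_rate=0.0)
        assert (tr["depth_m"] == 0.0).all()

    def test_single_dive_reaches_planned_depth(self):
        tr = sim.gen_tdr_trace([(30.0, 40.0, 10.0)], 120, surface_noise_sd=0.0)
        assert tr["depth_m"].max() == pytest.approx(10.0, abs=0.01)

    def test_linear_drift_magnitude(self):
        tr = sim.gen_tdr_trace([], 3600, surface_noise_sd=0.0, drift_rate=0.001)
        assert tr["depth_m"].iloc[-1] == pytest.approx(3.6, abs=0.01)

    def test_overlapping_dives_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_tdr_trace([(0.0, 50.0, 5.0), (30.0, 50.0, 5.0)], 200)


class TestPPRaster:
    def test_zero_delta_means_equal(self):
        box = ROIBox(-5.6, -5.4, 51.68, 51.78)
        ds = sim.gen_pp_raster(np.arange(-6, -5, 0.02), np.arange(51.4, 52, 0.02),
                               np.arange(3), noise_sd=0.5, hotspot_box=box,
                               hotspot_delta=0.0, seed=0)
        from alcatrack.environment import in_roi
        lon2, lat2 = np.meshgrid(ds.lon, ds.lat)
        mask = in_roi(lon2, lat2, box)
        field = ds.chl.mean("time").to_numpy()
        assert abs(field[mask].mean() - field[~mask].mean()) < 0.1

    def test_hotspot_delta_recovered(self):
        box = ROIBox(-5.6, -5.4, 51.68, 51.78)
        ds = sim.gen_pp_raster(np.arange(-6, -5, 0.02), np.arange(51.4, 52, 0.02),
                               np.arange(3), background_mean=5.0, noise_sd=1.0,
                               hotspot_box=box, hotspot_delta=5.0, seed=1)
        from alcatrack.environment import in_roi
        lon2, lat2 = np.meshgrid(ds.lon, ds.lat)
        mask = in_roi(lon2, lat2, box)
        field = ds.chl.mean("time").to_numpy()
        assert field[mask].mean() - field[~mask].mean() == pytest.approx(5.0, abs=0.15)

    def test_monotone_coordinates(self):
        ds = sim.gen_pp_raster([-5.5, -5.6, -5.4], [51.7, 51.6], [0], seed=0)
        assert (np.diff(ds.lon) > 0).all() and (np.diff(ds.lat) > 0).all()


class TestCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=5, n_birds=3)
        p1, _ = sim.gen_cohort(cfg, tmp_path / "a")
        p2, _ = sim.gen_cohort(cfg, tmp_path / "b")
        for rel in ["truth.json", "chl.nc", "gps/bird_00.csv", "tdr/bird_02.csv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_default_scale_near_study_size(self):
        _, data = sim.gen_cohort(SimConfig(seed=2))
        n = len(data["truth"]["trips"])
        assert 18 * 1 <= n <= 18 * 7
        assert 35 <= n <= 85  # ~3.1 trips per bird on average

    def test_truth_rows_match_generated_trips(self, small_cohort):
        cfg, data = small_cohort
        from alcatrack import trips as tp
        n_seg = sum(len(tp.segment_trips(d["gps_xy"])) for d in data["birds"].values())
        assert len(data["truth"]["trips"]) == n_seg
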