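import numpy as np
import pandas as pd
import pytest

from alcatrack import environment as env
from alcatrack import simulate as sim
from alcatrack.simulate import ROIBox

COLONY = (-5.30, 51.74)


class TestBearing:
    def test_cardinal_conventions(self):
        assert env.bearing(COLONY, COLONY[0], COLONY[1] + 0.1) == pytest.approx(0.0, abs=0.01)
        assert env.bearing(COLONY, COLONY[0] + 0.1, COLONY[1]) == pytest.approx(90.0, abs=0.1)
        assert env.bearing(COLONY, COLONY[0], COLONY[1] - 0.1) == pytest.approx(180.0, abs=0.01)

    def test_origin_offset_rotates_convention(self):
        east = env.bearing(COLONY, COLONY[0] + 0.1, COLONY[1], origin_offset=90.0)
        assert east == pytest.approx(0.0, abs=0.1)

    def test_colony_itself_flagged(self):
        assert np.isnan(env.bearing(COLONY, *COLONY))


class TestKsCompare:
    def test_identical_samples(self, rng):
        a = rng.normal(size=200)
        assert env.ks_compare(a, a)["D"] == 0.0

    def test_disjoint_supports(self, rng):
        out = env.ks_compare(rng.uniform(0, 1, 100), rng.uniform(5, 6, 100))
        assert out["D"] == 1.0
        assert out["p"] < 1e-10

    def test_matches_brute_force_ecdf(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(20, 200))
            b = rng.normal(0.3, 1.2, size=rng.integers(20, 200))
            grid = np.concatenate([a, b])
            fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
            fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
            assert env.ks_compare(a, b)["D"] == pytest.approx(np.abs(fa - fb).max(),
                                                              abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a, b = rng.normal(size=150), rng.normal(0.5, 1, size=120)
        d1 = env.ks_compare(a, b)["D"]
        d2 = env.ks_compare(np.exp(a), np.exp(b))["D"]
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestInRoi:
    ROI = ROIBox()

    def test_printed_box_membership(self):
        assert env.in_roi(-5.5, 51.73, self.ROI) is True
        assert env.in_roi(-6.0, 51.73, self.ROI) is False

    def test_boundary_closed(self):
        assert env.in_roi(self.ROI.lon_min, self.ROI.lat_min, self.ROI) is True
        assert env.in_roi(self.ROI.lon_max, self.ROI.lat_max, self.ROI) is True

    def test_vectorised(self):
        res = env.in_roi(np.array([-5.5, -6.0]), np.array([51.73, 51.73]), self.ROI)
        assert res.tolist() == [True, False]


@pytest.fixture(scope="module")
def raster():
    return sim.gen_pp_raster(np.arange(-6.0, -5.0, 0.05),
                             np.arange(51.4, 52.0, 0.05),
                             np.array([0.0, 43200.0, 86400.0]),
                             noise_sd=0.5, seed=4)


class TestSamplePP:

    def test_exact_cell_and_slice(self, raster):
        lon, lat = float(raster.lon[3]), float(raster.lat[5])
        got = env.sample_pp(raster, 43200.0, lon, lat)
        assert got == pytest.approx(float(raster.chl[1, 5, 3]))

    def test_outside_grid_missing(self, raster):
        assert np.isnan(env.sample_pp(raster, 0.0, -7.0, 51.7))
        assert np.isnan(env.sample_pp(raster, 1e9, -5.5, 51.7, max_time_offset=3600.0))

    def test_missing_plus_returned_covers_queries(self, raster, rng):
        lon = rng.uniform(-7.0, -4.5, 200)
        lat = rng.uniform(51.0, 52.4, 200)
        vals = env.sample_pp(raster, np.zeros(200), lon, lat)
        assert np.isnan(vals).sum() + np.isfinite(vals).sum() == 200
        assert np.isnan(vals).sum() > 0  # some queries fall off the grid


class TestStageRoiTests:
    @staticmethod
    def _pp(rng, roi_boost_chick=0.0, roi_boost_inc=0.0, n=120):
        rows = []
        for stage, boost in (("incubation", roi_boost_inc),
                             ("chick_rearing", roi_boost_chick)):
            for flag in (True, False):
                mu = 5.0 + (boost if flag else 0.0)
                for v in rng.normal(mu, 1.0, n):
                    rows.append({"stage": stage, "in_roi": flag, "chl": v})
        return pd.DataFrame(rows)

    def test_adjustment_is_exactly_bonferroni(self, rng):
        out = env.stage_roi_tests(self._pp(rng))
        assert np.allclose(out["p_adj"], np.minimum(1.0, 3.0 * out["p"]))

    def test_null_mostly_non_significant(self):
        hits = 0
        for s in range(30):
            out = env.stage_roi_tests(self._pp(np.random.default_rng(s)))
            hits += int((out["p_adj"] < 0.05).any())
        assert hits <= 6  # three Bonferroni-corrected tests at alpha 0.05

    def test_constructed_hotspot_detected(self, rng):
        out = env.stage_roi_tests(self._pp(rng, roi_boost_chick=5.0)).set_index("comparison")
        assert out.loc["chick_rearing_in_vs_out", "p_adj"] < 0.05
        assert out.loc["in_roi_incubation_vs_chick", "p_adj"] < 0.05
        assert out.loc["incubation_in_vs_out", "p_adj"] > 0.05


class TestBootstrapRoiEnrichment:
    ROI = ROIBox(-5.65, -5.35, 51.67, 51.80)

    def _raster(self, delta, seed, noise=1.0):
        return sim.gen_pp_raster(np.arange(-6.4, -4.6, 0.02),
                                 np.arange(51.0, 52.4, 0.02), np.arange(3),
                                 background_mean=5.0, noise_sd=noise,
                                 hotspot_box=self.ROI, hotspot_delta=delta,
                                 seed=seed)

    def test_uniform_field_mean_p_near_half(self):
        # a single bootstrap p on an exchangeable field is Uniform(0,1);
        # its mean across independent fields is the calibrated quantity
        ps = [env.bootstrap_roi_enrichment(self._raster(0.0, s), self.ROI,
                                           n_boot=100, seed=s)["p"]
              for s in range(12)]
        assert 0.25 <= float(np.mean(ps)) <= 0.75

    def test_hotspot_detected(self):
        out = env.bootstrap_roi_enrichment(self._raster(5.0, 0), self.ROI,
                                           n_boot=200, seed=0)
        assert out["p"] < 0.01
        assert out["observed"] > float(np.mean(out["null"])) + 3.0

    def test_null_size_and_p_range(self):
        out = env.bootstrap_roi_enrichment(self._raster(1.0, 1), self.ROI,
                                           n_boot=150, seed=1)
        assert out["null"].shape == (150,)
        assert 0.0 <= out["p"] <= 1.0

    def test_roi_larger_than_raster_rejected(self):
        small = sim.gen_pp_raster(np.arange(-5.6, -5.4, 0.02),
                                  np.arange(51.7, 51.8, 0.02), [0], seed=0)
        with pytest.raises(ValueError):
            env.bootstrap_roi_enrichment(small, self.ROI, n_boot=10, seed=0)
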