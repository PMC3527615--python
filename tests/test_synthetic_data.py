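"""Generator structure, calibration to the published moments, and the
latent response surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from arcann.stats import two_sample_t
from arcann.synthetic_data import (
    ABUNDANCE_COLUMNS,
    SEASONAL_DEPTHS,
    SEASONAL_TARGETS,
    SPATIAL_TARGETS,
    GeneratorConfig,
    calibrate_moments,
    generate_seasonal,
    generate_spatial,
    true_response,
)


class TestTableStructure:
    def test_seasonal_has_156_rows_at_fixed_depths(self, seasonal42):
        assert len(seasonal42) == 156
        assert set(seasonal42["depth_m"]) <= set(SEASONAL_DEPTHS)
        assert seasonal42["date"].nunique() == 21

    def test_spatial_has_37_rows_above_80m(self, spatial7):
        assert len(spatial7) == 37
        assert spatial7["depth_m"].max() <= 80
        assert spatial7["station"].nunique() == 7

    @pytest.mark.parametrize("seed", [0, 42])
    def test_sum_columns_additive(self, seed):
        t = generate_seasonal(GeneratorConfig(seed=seed))
        np.testing.assert_array_equal(
            t["prokaryotes_1e5_ml"], t["hna_1e5_ml"] + t["lna_1e5_ml"]
        )
        np.testing.assert_array_equal(
            t["viruses_1e6_ml"], t["v1_1e6_ml"] + t["v2_1e6_ml"]
        )

    def test_strictly_positive_and_day_length_bounded(self, seasonal42):
        for col in ("chl_a_ug_l", *ABUNDANCE_COLUMNS.values()):
            assert (seasonal42[col] > 0).all()
        assert seasonal42["day_length_h"].between(0, 24).all()

    def test_same_seed_bit_identical(self):
        a = generate_seasonal(GeneratorConfig(seed=5))
        b = generate_seasonal(GeneratorConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_seasonal(GeneratorConfig(seed=5))
        b = generate_seasonal(GeneratorConfig(seed=6))
        assert not a["hna_1e5_ml"].equals(b["hna_1e5_ml"])


class TestMomentCalibration:
    def test_seasonal_means_and_sds_match_targets(self, seasonal42):
        for col, (mean, sd) in SEASONAL_TARGETS.items():
            x = seasonal42[col]
            assert x.mean() == pytest.approx(mean, rel=1e-9)
            assert x.std(ddof=1) == pytest.approx(sd, rel=1e-9)

    def test_spatial_means_match_targets(self, spatial7):
        for col, (mean, _) in SPATIAL_TARGETS.items():
            assert spatial7[col].mean() == pytest.approx(mean, rel=1e-9)

    def test_seasonal_ranges_bracket_published_extremes(self, seasonal42):
        # published min/max: chl 0.01-0.61, hna 0.44-9.49, v2 0.90-16.11
        for col, (lo, hi) in {
            "chl_a_ug_l": (0.01, 0.61),
            "hna_1e5_ml": (0.44, 9.49),
            "v2_1e6_ml": (0.90, 16.11),
        }.items():
            x = seasonal42[col]
            assert 0.5 * lo <= x.min() <= 2 * lo or x.min() <= lo
            assert 0.5 * hi <= x.max() <= 2 * hi

    def test_calibrate_moments_hits_targets_and_preserves_ranks(self, seasonal42):
        targets = {"hna_1e5_ml": (3.0, 1.0), "v2_1e6_ml": (10.0, 2.0)}
        out = calibrate_moments(seasonal42, targets)
        for col, (m, s) in targets.items():
            assert out[col].mean() == pytest.approx(m, abs=1e-9)
            assert out[col].std(ddof=1) == pytest.approx(s, rel=1e-9)
            rho = spearmanr(seasonal42[col], out[col]).statistic
            assert rho == pytest.approx(1.0)
        # sum columns recomputed, additivity kept exactly
        np.testing.assert_array_equal(
            out["prokaryotes_1e5_ml"], out["hna_1e5_ml"] + out["lna_1e5_ml"]
        )

    def test_identity_when_already_on_target(self, seasonal42):
        col = "hna_1e5_ml"
        x = seasonal42[col]
        out = calibrate_moments(
            seasonal42, {col: (float(x.mean()), float(x.std(ddof=1)))}
        )
        np.testing.assert_allclose(out[col], x, rtol=1e-9)

    def test_constant_column_with_nonzero_target_sd_errors(self, seasonal42):
        t = seasonal42.copy()
        t["hna_1e5_ml"] = 2.0
        with pytest.raises(ValueError, match="constant"):
            calibrate_moments(t, {"hna_1e5_ml": (2.0, 1.0)})


class TestResponseSurfaces:
    cfg = GeneratorConfig()

    @staticmethod
    def _cov(**overrides):
        base = {
            "temperature_c": np.array([-0.8]),
            "depth_m": np.array([10.0]),
            "chl_a_ug_l": np.array([0.1]),
            "day_length_h": np.array([12.0]),
        }
        base.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
        return base

    def test_hna_temperature_optimum_in_published_window(self):
        grid = np.linspace(-1.8, 2.8, 2000)
        resp = true_response(self._cov(temperature_c=grid,
                                       depth_m=np.full_like(grid, 10.0),
                                       chl_a_ug_l=np.full_like(grid, 0.1),
                                       day_length_h=np.full_like(grid, 12.0)),
                             "hna", self.cfg)
        assert -1.3 <= grid[np.argmax(resp)] <= -0.3

    def test_hna_unimodal_around_optimum(self):
        r = lambda t: true_response(self._cov(temperature_c=[t]), "hna", self.cfg)[0]
        assert r(-0.8) >= r(-1.8) and r(-0.8) >= r(2.8)

    def test_v2_decreases_with_depth(self):
        shallow = true_response(self._cov(depth_m=[5.0]), "v2", self.cfg)[0]
        deep = true_response(self._cov(depth_m=[200.0]), "v2", self.cfg)[0]
        assert shallow > deep

    def test_lna_increases_with_temperature_and_chl(self):
        r = lambda **kw: true_response(self._cov(**kw), "lna", self.cfg)[0]
        assert r(temperature_c=[2.0]) > r(temperature_c=[-1.5])
        assert r(chl_a_ug_l=[0.5]) > r(chl_a_ug_l=[0.02])

    def test_v1_increases_with_chl_and_day_length(self):
        r = lambda **kw: true_response(self._cov(**kw), "v1", self.cfg)[0]
        assert r(chl_a_ug_l=[0.5]) > r(chl_a_ug_l=[0.02])
        assert r(day_length_h=[24.0]) > r(day_length_h=[2.0])

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError, match="unknown population"):
            true_response(self._cov(), "archaea", self.cfg)


class TestSeasonalVsSpatialContrast:
    def test_every_parameter_differs_significantly(self, seasonal42, spatial7):
        """The summer survey is warmer, fresher, shallower, better lit and
        more productive than the seasonal series; a pooled t-test rejects
        equality for every modelled variable."""
        cols = [
            "depth_m", "temperature_c", "salinity_psu", "day_length_h",
            "chl_a_ug_l", *ABUNDANCE_COLUMNS.values(),
            "prokaryotes_1e5_ml", "viruses_1e6_ml",
        ]
        for col in cols:
            _, p = two_sample_t(seasonal42[col], spatial7[col])
            assert p <= 0.05, col
        for col in ("temperature_c", "chl_a_ug_l", "day_length_h",
                    "hna_1e5_ml", "viruses_1e6_ml"):
            assert spatial7[col].mean() > seasonal42[col].mean()
        assert spatial7["salinity_psu"].mean() < seasonal42["salinity_psu"].mean()
        assert spatial7["depth_m"].mean() < seasonal42["depth_m"].mean()
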