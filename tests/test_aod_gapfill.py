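"""Satellite-view merging and AOD gap filling."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaplesspm import aod_gapfill, synthworld
from gaplesspm.aod_gapfill import (
    GaplessField,
    InsufficientOverlapError,
    fill_gaps,
    merge_terra_aqua,
    read_field,
    train_gapfill,
    validate_points,
    write_field,
)
from gaplesspm.features import bundle_gapfill_table
from gaplesspm.stet_model import StetConfig


def masked_pair(seed=0, shape=(5, 8, 10), slope=1.0, intercept=0.0, frac=0.3):
    rng = np.random.default_rng(seed)
    terra = rng.uniform(0.1, 1.5, size=shape)
    aqua = (terra - intercept) / slope  # so terra = slope*aqua + intercept
    terra = terra.copy()
    m1 = rng.random(shape) < frac
    m2 = rng.random(shape) < frac
    terra[m1] = np.nan
    aqua[m2] = np.nan
    return terra, aqua


class TestMergeTerraAqua:
    def test_identical_views_give_identity_line_and_union(self):
        terra, aqua = masked_pair(seed=1)
        aqua_same = terra.copy()
        merged, coeffs = merge_terra_aqua(terra, aqua_same)
        assert coeffs["slope"] == pytest.approx(1.0, abs=1e-12)
        assert coeffs["intercept"] == pytest.approx(0.0, abs=1e-12)
        union = np.isfinite(terra) | np.isfinite(aqua_same)
        assert np.array_equal(np.isfinite(merged), union)

    def test_terra_only_cell_passes_through(self):
        terra, aqua = masked_pair(seed=2)
        only_terra = np.isfinite(terra) & ~np.isfinite(aqua)
        merged, _ = merge_terra_aqua(terra, aqua)
        np.testing.assert_array_equal(merged[only_terra], terra[only_terra])

    def test_exact_linear_relation_recovered_against_ols_oracle(self):
        # aqua = 0.9*terra + 0.05 exactly -> conversion recovers the inverse
        rng = np.random.default_rng(4)
        terra = rng.uniform(0.1, 1.5, size=(4, 6, 6))
        aqua = 0.9 * terra + 0.05
        merged, coeffs = merge_terra_aqua(terra, aqua)
        oracle = stats.linregress(aqua.ravel(), terra.ravel())
        assert coeffs["slope"] == pytest.approx(oracle.slope, abs=1e-10)
        assert coeffs["intercept"] == pytest.approx(oracle.intercept, abs=1e-10)
        assert coeffs["slope"] == pytest.approx(1 / 0.9, abs=1e-10)
        assert coeffs["intercept"] == pytest.approx(-0.05 / 0.9, abs=1e-10)
        np.testing.assert_allclose(merged, terra, atol=1e-10)

    def test_random_pairs_match_linregress_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            terra = rng.uniform(0.05, 2.0, size=(3, 5, 5))
            aqua = 0.8 * terra + 0.1 + rng.normal(0, 0.05, terra.shape)
            _, coeffs = merge_terra_aqua(terra, aqua)
            oracle = stats.linregress(aqua.ravel(), terra.ravel())
            assert coeffs["slope"] == pytest.approx(oracle.slope, abs=1e-10)
            assert coeffs["intercept"] == pytest.approx(oracle.intercept, abs=1e-10)

    def test_insufficient_overlap_rejected(self):
        terra = np.full((2, 3, 3), np.nan)
        aqua = np.full((2, 3, 3), 0.5)
        terra[0, 0, 0] = 0.4
        with pytest.raises(InsufficientOverlapError):
            merge_terra_aqua(terra, aqua)


class TestFillGaps:
    def test_observed_values_pass_through_bit_exact(self, small_world,
                                                    small_gapless):
        gapless, _ = small_gapless
        merged, _ = merge_terra_aqua(small_world.terra_aod,
                                     small_world.aqua_aod)
        obs = np.isfinite(merged)
        assert np.array_equal(gapless.values[obs], merged[obs])
        assert (gapless.origin[obs] == aod_gapfill.ORIGIN_OBSERVED).all()
        assert (gapless.origin[~obs] == aod_gapfill.ORIGIN_PREDICTED).all()

    def test_full_coverage_from_64_percent_input(self, small_world,
                                                 small_gapless):
        _, report = small_gapless
        assert report["coverage_before_percent"] == pytest.approx(64.0, abs=3.0)
        assert report["coverage_after_percent"] == 100.0

    def test_zero_missing_input_identity(self, tiny_world):
        table = bundle_gapfill_table(tiny_world)
        full = tiny_world.true_aod.copy()
        model = train_gapfill(full, table,
                              config=StetConfig(n_trees=10, min_leaf=5),
                              max_train_rows=5000)
        out = fill_gaps(model, full, table)
        np.testing.assert_array_equal(out.values, full)
        assert (out.origin == aod_gapfill.ORIGIN_OBSERVED).all()

    def test_gapless_field_rejects_nan(self):
        with pytest.raises(ValueError, match="missing"):
            GaplessField(values=np.array([[np.nan]]),
                         origin=np.array([[0]], dtype=np.int8))


class TestTrainGapfill:
    def test_noiseless_proportional_world_recovered(self, tiny_world):
        # construct a world where observed AOD = 2 * ctm_aod exactly
        table = bundle_gapfill_table(tiny_world)
        truth = 2.0 * tiny_world.ctm_aod
        masked = truth.copy()
        masked[tiny_world.cloud_mask] = np.nan
        model = train_gapfill(masked, table,
                              config=StetConfig(n_trees=30, min_leaf=2))
        out = fill_gaps(model, masked, table)
        miss = tiny_world.cloud_mask
        r = np.corrcoef(truth[miss], out.values[miss])[0, 1]
        assert r * r >= 0.95

    def test_shuffling_key_predictor_destroys_skill(self, tiny_world):
        table = bundle_gapfill_table(tiny_world)
        truth = 2.0 * tiny_world.ctm_aod
        masked = truth.copy()
        masked[tiny_world.cloud_mask] = np.nan
        model = train_gapfill(masked, table,
                              config=StetConfig(n_trees=30, min_leaf=2))
        rng = np.random.default_rng(0)
        broken = table.copy()
        broken["ctm_aod"] = rng.permutation(broken["ctm_aod"].to_numpy())
        out_good = fill_gaps(model, masked, table)
        out_bad = fill_gaps(model, masked, broken)
        miss = tiny_world.cloud_mask
        r2_good = np.corrcoef(truth[miss], out_good.values[miss])[0, 1] ** 2
        r2_bad = np.corrcoef(truth[miss], out_bad.values[miss])[0, 1] ** 2
        assert r2_good - r2_bad > 0.3

    def test_trains_at_ten_percent_coverage(self, tiny_world):
        rng = np.random.default_rng(1)
        table = bundle_gapfill_table(tiny_world)
        masked = tiny_world.true_aod.copy()
        masked[rng.random(masked.shape) < 0.9] = np.nan
        model = train_gapfill(masked, table,
                              config=StetConfig(n_trees=10, min_leaf=5))
        out = fill_gaps(model, masked, table)
        assert out.coverage_percent == 100.0

    def test_skill_and_graceful_degradation_with_missingness(self):
        """Held-out-cell skill >= 0.7 and monotone decrease, not collapse."""
        r2s = []
        for frac in (0.2, 0.5, 0.8):
            cfg = synthworld.WorldConfig(
                n_lat=10, n_lon=14, n_stations=8, n_countries=4,
                seed=21, missing_frac=frac,
            )
            w = synthworld.generate_world(cfg)
            gapless, _ = aod_gapfill.run_gapfill(
                w, config=StetConfig(n_trees=30, min_leaf=3)
            )
            miss = w.cloud_mask
            r = np.corrcoef(w.true_aod[miss], gapless.values[miss])[0, 1]
            r2s.append(r * r)
        assert r2s[0] >= 0.7
        assert r2s[0] >= r2s[1] >= r2s[2]
        assert r2s[2] > 0.2  # degraded, not collapsed


class TestValidatePoints:
    def _points_from_truth(self, world, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            i = rng.integers(world.grid.shape[0])
            j = rng.integers(world.grid.shape[1])
            d = rng.integers(len(world.dates))
            rows.append(
                {
                    "lat": world.grid.lats[i],
                    "lon": world.grid.lons[j],
                    "date": world.dates[d],
                    "aod": world.true_aod[d, i, j],
                }
            )
        return pd.DataFrame(rows)

    def test_perfect_field_gives_r_one(self, tiny_world):
        field = GaplessField(
            values=tiny_world.true_aod,
            origin=np.zeros_like(tiny_world.true_aod, dtype=np.int8),
        )
        pts = self._points_from_truth(tiny_world)
        res = validate_points(field, pts, tiny_world.grid, tiny_world.dates)
        assert res["overall"]["r"] == pytest.approx(1.0, abs=1e-12)
        assert res["overall"]["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_field_reports_nan_with_warning(self, tiny_world):
        field = GaplessField(
            values=np.full_like(tiny_world.true_aod, 0.5),
            origin=np.zeros_like(tiny_world.true_aod, dtype=np.int8),
        )
        pts = self._points_from_truth(tiny_world)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = validate_points(field, pts, tiny_world.grid, tiny_world.dates)
        assert np.isnan(res["overall"]["r"])

    def test_observed_at_least_as_good_as_predicted(self, small_world,
                                                    small_gapless):
        gapless, _ = small_gapless
        pts = self._points_from_truth(small_world, n=400, seed=3)
        res = validate_points(gapless, pts, small_world.grid, small_world.dates)
        assert res["observed"]["r"] >= res["predicted"]["r"]

    def test_too_few_matches_rejected(self, tiny_world):
        field = GaplessField(
            values=tiny_world.true_aod,
            origin=np.zeros_like(tiny_world.true_aod, dtype=np.int8),
        )
        pts = self._points_from_truth(tiny_world, n=2)
        with pytest.raises(ValueError, match="3 matched"):
            validate_points(field, pts, tiny_world.grid, tiny_world.dates)


class TestFieldIO:
    def test_roundtrip(self, tiny_world, tmp_path):
        field = GaplessField(
            values=tiny_world.true_aod,
            origin=np.zeros_like(tiny_world.true_aod, dtype=np.int8),
            units="AOD",
        )
        path = tmp_path / "field.nc"
        write_field(field, path, tiny_world.grid, tiny_world.dates)
        back, dates = read_field(path)
        np.testing.assert_array_equal(back.values, field.values)
        np.testing.assert_array_equal(back.origin, field.origin)
        assert back.units == "AOD"
        assert dates.equals(tiny_world.dates)
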