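import numpy as np
import pandas as pd
import pytest

from udsnet.gridfit import (GridSpec, GridLibrary, build_grid_library,
                            fit_cell, exponential_trend, predict_delays,
                            group_compare, rate_distance, FitResult)
from udsnet.stats import SpaSpiSummary


def _summary(spa, spi, sk_d=None, sk_u=None):
    return SpaSpiSummary(phi_SPA=spa, phi_SPI=spi,
                         skipped_down_frac=sk_d if sk_d is not None else spa,
                         skipped_up_frac=sk_u if sk_u is not None else spi,
                         n_up=50, n_down=50)


@pytest.fixture(scope="module")
def tiny_library(tmp_path_factory):
    spec = GridSpec.linspace(n_ext=4, n_int=4)
    cache = tmp_path_factory.mktemp("lib")
    return build_grid_library(spec, n_seeds=1, duration=150.0, seed0=3,
                              cache_dir=cache), cache


class TestBuild:
    def test_structure(self, tiny_library):
        lib, _ = tiny_library
        assert len(lib.table) == 16
        assert {"W_EXT", "W_INT", "xi_SPA", "xi_SPI", "delay_down_up",
                "xi_SPA_s0"} <= set(lib.table.columns)
        assert lib.table[["xi_SPA", "xi_SPI"]].dropna().ge(0).all().all()

    def test_cache_round_trip_is_identical(self, tiny_library):
        lib, cache = tiny_library
        reloaded = GridLibrary.load(cache)
        pd.testing.assert_frame_equal(lib.table, reloaded.table)
        assert reloaded.spec == lib.spec

    def test_cache_hit_skips_resimulation(self, tiny_library):
        import time
        lib, cache = tiny_library
        t0 = time.time()
        again = build_grid_library(lib.spec, n_seeds=1, duration=150.0,
                                   seed0=3, cache_dir=cache)
        assert time.time() - t0 < 2.0
        pd.testing.assert_frame_equal(again.table, lib.table)

    def test_deterministic_given_seed(self):
        spec = GridSpec(w_ext=(0.15,), w_int=(1.05,))
        a = build_grid_library(spec, n_seeds=1, duration=120.0, seed0=9)
        b = build_grid_library(spec, n_seeds=1, duration=120.0, seed0=9)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestFitCell:
    def test_exact_library_rates_recover_their_entry(self, tiny_library):
        lib, _ = tiny_library
        row = lib.table.dropna(subset=["xi_SPA", "xi_SPI"]).iloc[5]
        fit = fit_cell(_summary(row["xi_SPA"], row["xi_SPI"]), lib)
        assert fit.distance == pytest.approx(0.0, abs=1e-12)
        assert fit.W_EXT == row["W_EXT"]
        assert fit.W_INT == row["W_INT"]

    def test_distance_arithmetic(self):
        assert rate_distance((0.2, 0.0), (0.17, 0.04)) \
            == pytest.approx(0.05)

    def test_distance_is_a_metric(self):
        pts = [(0.1, 0.2), (0.3, 0.05), (0.0, 0.0)]
        for a in pts:
            assert rate_distance(a, a) == 0.0
            for b in pts:
                assert rate_distance(a, b) == rate_distance(b, a)
                for c in pts:
                    assert rate_distance(a, c) <= \
                        rate_distance(a, b) + rate_distance(b, c) + 1e-15
    def test_out_of_coverage_warns(self, tiny_library):
        lib, _ = tiny_library
        with pytest.warns(UserWarning, match="coverage"):
            fit_cell(_summary(0.9, 0.9), lib)

    def test_empty_library_rejected(self, tiny_library):
        lib, _ = tiny_library
        empty = GridLibrary(spec=lib.spec, table=lib.table.iloc[:0],
                            n_seeds=1, duration=1.0, dt=0.2, seed0=0,
                            params=lib.params)
        with pytest.raises(ValueError):
            fit_cell(_summary(0.1, 0.1), empty)


class TestExponentialTrend:
    def test_exact_exponential_recovered(self):
        x = np.linspace(0, 0.1, 20)
        y = np.exp(x / 0.01)
        scale, r = exponential_trend(x, y)
        assert scale == pytest.approx(0.01, rel=1e-9)
        assert r == pytest.approx(1.0)

    def test_decaying_exponential_has_negative_scale(self):
        x = np.linspace(0, 0.1, 20)
        scale, r = exponential_trend(x, np.exp(-x / 0.004))
        assert scale == pytest.approx(-0.004, rel=1e-9)
        assert r == pytest.approx(-1.0)

    def test_constant_rates_give_flat_slope(self):
        x = np.linspace(0, 1, 15)
        scale, r = exponential_trend(x, np.full(15, 0.2))
        assert abs(1.0 / scale) < 1e-9

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            exponential_trend([1, 2, 3], [0, 0, 0])


class TestPredictDelays:
    def test_predictions_come_from_matched_entry(self, tiny_library):
        lib, _ = tiny_library
        row = lib.table.dropna(subset=["xi_SPA"]).iloc[3]
        fit = fit_cell(_summary(row["xi_SPA"], row["xi_SPI"]), lib)
        pred_du, pred_ud, (rdu, rud) = predict_delays(
            fit, lib, observed_down_up=row["delay_down_up"],
            observed_up_down=row["delay_up_down"])
        assert pred_du == row["delay_down_up"]
        assert pred_ud == row["delay_up_down"]
        assert rdu == pytest.approx(0.0)
        assert rud == pytest.approx(0.0)


class TestGroupCompare:
    def _fits(self, w_ints, group, rng):
        return [FitResult(cell_id=f"{group}{i}", phi_SPA=0.1, phi_SPI=0.1,
                          W_EXT=0.2 + 0.01 * rng.standard_normal(),
                          W_INT=w, distance=0.0,
                          predicted_delay_down_up=0.1,
                          predicted_delay_up_down=0.5, group=group)
                for i, w in enumerate(w_ints)]

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(0)
        n_sig = 0
        for rep in range(20):
            a = self._fits(1.05 + 0.02 * rng.standard_normal(10), "a", rng)
            b = self._fits(1.05 + 0.02 * rng.standard_normal(10), "b", rng)
            table = group_compare(a + b)
            p = table[table.parameter == "W_INT"].p_value.iloc[0]
            n_sig += p < 0.05
        assert n_sig <= 2

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        a = self._fits(1.04 + 0.005 * rng.standard_normal(10), "a", rng)
        b = self._fits(1.08 + 0.005 * rng.standard_normal(10), "b", rng)
        table = group_compare(a + b)
        p = table[table.parameter == "W_INT"].p_value.iloc[0]
        assert p < 0.05

    def test_single_group_gives_empty_table(self):
        rng = np.random.default_rng(2)
        table = group_compare(self._fits([1.0, 1.1, 1.2], "only", rng))
        assert len(table) == 0

    def test_small_groups_flagged(self):
        rng = np.random.default_rng(3)
        a = self._fits([1.0, 1.1], "a", rng)
        b = self._fits([1.05, 1.15, 1.1], "b", rng)
        table = group_compare(a + b)
        assert table.flagged.all()
        assert table.p_value.isna().all()
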