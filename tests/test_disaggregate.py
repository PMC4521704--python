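"""Suitability masking, allocation and the conservation machinery."""

import numpy as np
import pytest

from livesysmap.curves import SystemShares
from livesysmap.disaggregate import (
    allocate_extensive,
    build_mask,
    disaggregate_species,
    intensive_by_difference,
    rescale_totals,
    rural_population,
    split_pig_intensive,
)
from livesysmap.rasters import RasterBundle, RasterGrid


def grid(values, nodata=-1.0):
    return RasterGrid(values=np.atleast_2d(np.asarray(values, float)), nodata=nodata)


class TestBuildMask:
    def base(self, shape=(1, 1)):
        z = np.zeros(shape)
        return dict(
            elevation=grid(z + 100.0), slope=grid(z + 5.0),
            urban=np.zeros(shape, bool), snow_ice=np.zeros(shape, bool),
        )

    def test_high_elevation_unsuitable(self):
        layers = self.base()
        layers["elevation"] = grid([[5000.0]])
        assert not build_mask(**layers)[0, 0]

    def test_steep_slope_unsuitable(self):
        layers = self.base()
        layers["slope"] = grid([[45.0]])
        assert not build_mask(**layers)[0, 0]

    def test_thresholds_inclusive(self):
        # "higher than" is strict: exactly 4,750 m and 40 % remain suitable
        layers = self.base()
        layers["elevation"] = grid([[4750.0]])
        layers["slope"] = grid([[40.0]])
        assert build_mask(**layers)[0, 0]

    def test_urban_and_snow_unsuitable(self):
        layers = self.base((1, 2))
        layers["urban"][0, 0] = True
        layers["snow_ice"][0, 1] = True
        assert not build_mask(**layers).any()

    def test_nodata_unsuitable(self):
        layers = self.base()
        layers["elevation"] = grid([[-1.0]])
        assert not build_mask(**layers)[0, 0]

    def test_shape_mismatch_errors(self):
        layers = self.base()
        layers["urban"] = np.zeros((2, 2), bool)
        with pytest.raises(ValueError):
            build_mask(**layers)


class TestRuralPopulation:
    def test_urban_masked_out(self):
        pop = grid([[10.0, 20.0]])
        out = rural_population(pop, np.array([[False, True]]), np.ones((1, 2), bool))
        assert out.values.tolist() == [[10.0, 0.0]]

    def test_all_urban_gives_zero(self):
        pop = grid([[10.0, 20.0]])
        out = rural_population(pop, np.ones((1, 2), bool), np.ones((1, 2), bool))
        assert not out.values.any()

    def test_nodata_contributes_zero(self):
        pop = grid([[-1.0, 5.0]])
        out = rural_population(pop, np.zeros((1, 2), bool), np.ones((1, 2), bool))
        assert out.values.tolist() == [[0.0, 5.0]]


UNITS = np.array([[1, 1, 1]])


class TestRescaleTotals:
    def test_doubling(self):
        out = rescale_totals(grid([[50.0, 150.0]]), np.array([[1, 1]]), {1: 400.0})
        assert out.values.tolist() == [[100.0, 300.0]]

    def test_identity_when_total_matches(self):
        out = rescale_totals(grid([[50.0, 150.0]]), np.array([[1, 1]]), {1: 200.0})
        assert out.values.tolist() == [[50.0, 150.0]]

    def test_zero_total_zeroes_unit(self):
        out = rescale_totals(grid([[50.0, 150.0]]), np.array([[1, 1]]), {1: 0.0})
        assert not out.values.any()

    def test_zero_grid_with_positive_total_errors(self):
        with pytest.raises(ValueError, match="unit 1"):
            rescale_totals(grid([[0.0, 0.0]]), np.array([[1, 1]]), {1: 5.0})

    def test_idempotent(self):
        g0 = grid([[3.0, 9.0, 1.0]])
        once = rescale_totals(g0, UNITS, {1: 42.0})
        twice = rescale_totals(once, UNITS, {1: 42.0})
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-14)


class TestAllocateExtensive:
    def test_worked_example(self):
        out = allocate_extensive(grid([[10.0, 30.0, 60.0]]), UNITS, {1: 0.4}, {1: 1000.0})
        assert out.values.tolist() == [[40.0, 120.0, 240.0]]
        assert out.values.sum() == 400.0

    def test_zero_share_gives_zero_grid(self):
        out = allocate_extensive(grid([[10.0, 30.0]]), np.array([[1, 1]]), {1: 0.0}, {1: 500.0})
        assert not out.values.any()

    def test_single_rural_pixel_gets_all(self):
        out = allocate_extensive(grid([[0.0, 7.0, 0.0]]), UNITS, {1: 0.5}, {1: 100.0})
        assert out.values.tolist() == [[0.0, 50.0, 0.0]]

    def test_no_rural_population_errors(self):
        with pytest.raises(ValueError, match="unit 1"):
            allocate_extensive(grid([[0.0, 0.0]]), np.array([[1, 1]]), {1: 0.5}, {1: 100.0})

    def test_proportional_to_rural_population(self):
        rng = np.random.default_rng(0)
        rural = rng.uniform(0, 100, (5, 5))
        out = allocate_extensive(
            RasterGrid(values=rural), np.ones((5, 5), int), {1: 0.3}, {1: 1234.5}
        )
        m = 0.3 * 1234.5 / rural.sum()
        np.testing.assert_allclose(out.values, rural * m, rtol=1e-12)


def intensive_by_difference_oracle(total, extensive, unit_map):
    """Independent scalar-loop implementation of the overflow correction.

    Per-cell logic is a plain Python loop; the two per-unit reductions
    use row-major np.sum so results are bit-comparable with any
    correct implementation using the same summation order.
    """
    total = np.array(total, float)
    extensive = np.array(extensive, float)
    intensive = np.zeros_like(total)
    corrected = total.copy()
    for u in sorted(set(unit_map.ravel()) - {0}):
        cells = [(i, j) for i in range(total.shape[0]) for j in range(total.shape[1])
                 if unit_map[i, j] == u]
        shortfalls = []
        for i, j in cells:
            raw = total[i, j] - extensive[i, j]
            if raw < 0:
                shortfalls.append(-raw)
                corrected[i, j] = extensive[i, j]
                intensive[i, j] = 0.0
            else:
                intensive[i, j] = raw
        deficit = float(np.sum(shortfalls)) if shortfalls else 0.0
        s_pos = float(np.sum([intensive[i, j] for i, j in cells]))
        if deficit > 0:
            if deficit > s_pos:
                raise ValueError("deficit exceeds commercial stock")
            factor = (s_pos - deficit) / s_pos
            for i, j in cells:
                intensive[i, j] *= factor
    return intensive, corrected


class TestIntensiveByDifference:
    def test_overflow_worked_example(self):
        total = grid([[10.0, 140.0, 250.0]])
        ext = grid([[20.0, 60.0, 120.0]])
        inten, corrected, ledger = intensive_by_difference(total, ext, UNITS)
        np.testing.assert_allclose(
            inten.values, [[0.0, 80.0 * 200 / 210, 130.0 * 200 / 210]], rtol=1e-12
        )
        assert corrected.values[0, 0] == 20.0
        # grand total conserved
        assert (ext.values + inten.values).sum() == pytest.approx(400.0, rel=1e-12)
        row = ledger.iloc[0]
        assert row["overflow_deficit"] == 10.0 and row["pixels_overflowed"] == 1

    def test_no_overflow_is_plain_difference(self):
        total = grid([[10.0, 20.0]])
        ext = grid([[4.0, 5.0]])
        inten, corrected, _ = intensive_by_difference(total, ext, np.array([[1, 1]]))
        assert inten.values.tolist() == [[6.0, 15.0]]
        assert corrected.values.tolist() == [[10.0, 20.0]]

    def test_zero_extensive_identity(self):
        total = grid([[3.0, 4.0]])
        inten, _, _ = intensive_by_difference(total, grid([[0.0, 0.0]]), np.array([[1, 1]]))
        assert inten.values.tolist() == [[3.0, 4.0]]

    def test_deficit_exceeding_commercial_errors(self):
        total = grid([[1.0, 2.0]])
        ext = grid([[10.0, 0.0]])
        with pytest.raises(ValueError, match="unit 1"):
            intensive_by_difference(total, ext, np.array([[1, 1]]))

    def test_matches_scalar_oracle_on_random_grids(self):
        rng = np.random.default_rng(12345)
        for _ in range(500):
            h, w = rng.integers(1, 11, 2)
            unit_map = rng.integers(0, 4, (h, w))
            total = rng.uniform(0, 100, (h, w))
            # extensive below per-unit totals so conservation is feasible
            ext = total * rng.uniform(0, 1.0, (h, w)) * rng.uniform(0.5, 1.5)
            for u in set(unit_map.ravel()) - {0}:
                sel = unit_map == u
                if ext[sel].sum() > total[sel].sum():
                    ext[sel] *= 0.9 * total[sel].sum() / ext[sel].sum()
            inten, corrected, _ = intensive_by_difference(
                RasterGrid(values=total), RasterGrid(values=ext), unit_map
            )
            oracle_int, oracle_tot = intensive_by_difference_oracle(total, ext, unit_map)
            np.testing.assert_array_equal(inten.values, oracle_int)
            np.testing.assert_array_equal(corrected.values, oracle_tot)


class TestSplitPigIntensive:
    SHARES = {1: SystemShares(p_ext=0.25, p_sint=0.25, p_int=0.5)}

    def test_ratio_split(self):
        semi, inten = split_pig_intensive(grid([[90.0]]), np.array([[1]]), self.SHARES)
        assert semi.values[0, 0] == pytest.approx(30.0)
        assert inten.values[0, 0] == pytest.approx(60.0)

    def test_zero_semi_share(self):
        shares = {1: SystemShares(p_ext=0.4, p_sint=0.0, p_int=0.6)}
        semi, inten = split_pig_intensive(grid([[10.0, 5.0]]), np.array([[1, 1]]), shares)
        assert not semi.values.any()

    def test_split_sums_back(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 50, (4, 4))
        semi, inten = split_pig_intensive(RasterGrid(values=v), np.ones((4, 4), int), self.SHARES)
        np.testing.assert_allclose(semi.values + inten.values, v, rtol=1e-12)

    def test_zero_commercial_share_with_pixels_errors(self):
        shares = {1: SystemShares(p_ext=1.0, p_sint=0.0, p_int=0.0)}
        with pytest.raises(ValueError, match="unit 1"):
            split_pig_intensive(grid([[5.0]]), np.array([[1]]), shares)


def tiny_bundle(rng, n_units=3, shape=(6, 6)):
    """A hand-rolled multi-unit bundle, independent of the generator."""
    h, w = shape
    unit_map = np.repeat(np.arange(1, n_units + 1), h * w // n_units).reshape(h, w)
    pop = rng.uniform(1, 50, shape)
    urban = rng.random(shape) < 0.15
    elevation = np.where(rng.random(shape) < 0.1, 5000.0, 200.0)
    livestock = rng.uniform(0, 100, shape)
    g = lambda v: RasterGrid(values=np.asarray(v, float))
    return RasterBundle(
        livestock=g(livestock), population=g(pop), urban=urban,
        elevation=g(elevation), slope=g(np.full(shape, 3.0)),
        snow_ice=np.zeros(shape, bool), unit_map=unit_map,
    )


class TestDisaggregateSpecies:
    def test_chicken_extensive_sums_exact(self):
        rng = np.random.default_rng(8)
        bundle = tiny_bundle(rng)
        shares = {u: SystemShares(0.3 + 0.1 * u, 0.0, 0.7 - 0.1 * u) for u in (1, 2, 3)}
        res = disaggregate_species(bundle, shares, species="chicken")
        for _, row in res.ledger.iterrows():
            assert row["extensive_sum"] == pytest.approx(
                row["p_ext"] * row["stock_total"], rel=1e-9
            )

    def test_pig_three_rasters_sum_to_total(self):
        rng = np.random.default_rng(9)
        bundle = tiny_bundle(rng)
        shares = {u: SystemShares(0.4, 0.2, 0.4) for u in (1, 2, 3)}
        res = disaggregate_species(bundle, shares, species="pig")
        assert res.semi_intensive is not None
        assert res.check_conservation()

    def test_fully_extensive_unit_has_no_intensive(self):
        rng = np.random.default_rng(10)
        bundle = tiny_bundle(rng)
        shares = {1: SystemShares(1.0, 0.0, 0.0),
                  2: SystemShares(0.5, 0.0, 0.5),
                  3: SystemShares(0.5, 0.0, 0.5)}
        res = disaggregate_species(bundle, shares, species="chicken")
        assert not res.intensive.values[bundle.unit_map == 1].any()

    def test_unsuitable_pixels_zero_everywhere(self):
        rng = np.random.default_rng(11)
        bundle = tiny_bundle(rng)
        shares = {u: SystemShares(0.5, 0.0, 0.5) for u in (1, 2, 3)}
        res = disaggregate_species(bundle, shares, species="chicken")
        for grid_ in res.system_grids().values():
            assert not grid_.values[~res.mask].any()

    def test_missing_shares_errors(self):
        rng = np.random.default_rng(12)
        bundle = tiny_bundle(rng)
        with pytest.raises(KeyError):
            disaggregate_species(bundle, {1: SystemShares(0.5, 0.0, 0.5)}, species="chicken")
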