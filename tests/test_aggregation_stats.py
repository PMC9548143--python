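"""Diagnostics against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temcn import aggregation_stats as agg
from temcn.synthetic_forcing import GridSpec


class TestCellArea:
    def test_equator_square_degree(self):
        a = agg.cell_area(-0.5, 0.5, 0.0, 1.0)
        assert a == pytest.approx(1.2364e10, rel=1e-4)

    def test_zonal_symmetry(self):
        assert agg.cell_area(30, 31, 0, 1) == agg.cell_area(30, 31, 170, 171)
        assert agg.cell_area(-31, -30, 0, 1) == pytest.approx(
            agg.cell_area(30, 31, 0, 1))

    def test_whole_sphere(self):
        a = agg.cell_area(-90, 90, 0, 360)
        assert a == pytest.approx(4 * np.pi * agg.EARTH_RADIUS_M ** 2,
                                  rel=1e-9)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            agg.cell_area(31, 30, 0, 1)


class TestDecadalMeans:
    def test_constant(self):
        np.testing.assert_allclose(agg.decadal_means(np.full(101, 3.5)), 3.5)

    def test_year_index_series(self):
        got = agg.decadal_means(np.arange(1900, 2001, dtype=float))
        np.testing.assert_allclose(got, 1904.5 + 10 * np.arange(10))

    def test_matches_grouped_mean(self, rng):
        x = rng.normal(size=101)
        expected = [np.mean([x[d * 10 + i] for i in range(10)])
                    for d in range(10)]
        np.testing.assert_allclose(agg.decadal_means(x), expected, atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            agg.decadal_means(np.zeros(100))


class TestLinearTrend:
    def test_exact_line(self):
        years = np.arange(1900, 1931)
        slope, r2, _ = agg.linear_trend(0.03 * years + 2.0, years)
        assert slope == pytest.approx(0.30)
        assert r2 == pytest.approx(1.0)

    def test_flat_series(self):
        slope, r2, p = agg.linear_trend(np.full(31, 7.0))
        assert (slope, r2, p) == (0.0, 0.0, 1.0)

    def test_matches_independent_regression(self, rng):
        """Hand-rolled normal-equation OLS with the classic t-test
        reproduces slope, R^2 and p to 1e-9."""
        years = np.arange(1970, 2001, dtype=float)
        y = 0.02 * years + rng.normal(0, 0.3, size=31)
        slope, r2, p = agg.linear_trend(y, years)
        n = len(years)
        xm, ym = years.mean(), y.mean()
        sxx = np.sum((years - xm) ** 2)
        sxy = np.sum((years - xm) * (y - ym))
        b = sxy / sxx
        resid = y - (ym + b * (years - xm))
        sse = np.sum(resid ** 2)
        sst = np.sum((y - ym) ** 2)
        r2_o = 1 - sse / sst
        se = np.sqrt(sse / (n - 2) / sxx)
        from scipy.stats import t as tdist
        p_o = 2 * tdist.sf(abs(b / se), n - 2)
        assert slope == pytest.approx(10 * b, abs=1e-9)
        assert r2 == pytest.approx(r2_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_window_selection(self):
        years = np.arange(1900, 2001)
        y = np.where(years < 1970, 0.0, (years - 1970) * 0.1)
        slope, _, _ = agg.linear_trend(y, years, window=(1971, 2000))
        assert slope == pytest.approx(1.0)


class TestStripAnomalies:
    def test_stationary_field_zero(self, small_grid):
        field = np.ones((20, small_grid.n_cells)) * 4.2
        out = agg.strip_anomalies(field, small_grid, "latitude",
                                  np.arange(1900, 1920), (1900, 1919))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_full_baseline_centers_each_strip(self, small_grid, rng):
        field = rng.normal(size=(20, small_grid.n_cells))
        out = agg.strip_anomalies(field, small_grid, "longitude",
                                  np.arange(1900, 1920), (1900, 1919))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)

    def test_matches_two_loop_oracle(self, small_grid, rng):
        field = rng.normal(size=(15, small_grid.n_cells))
        years = np.arange(1900, 1915)
        base = (1902, 1906)
        areas = agg.grid_cell_areas(small_grid)
        got = agg.strip_anomalies(field, small_grid, "latitude", years, base)
        lat_idx = np.repeat(np.arange(small_grid.n_lat), small_grid.n_lon)
        for s in range(small_grid.n_lat):
            cells = np.where(lat_idx == s)[0]
            series = []
            for t in range(15):
                num = den = 0.0
                for c in cells:
                    num += field[t, c] * areas[c]
                    den += areas[c]
                series.append(num / den)
            series = np.array(series)
            ref = series - series[2:7].mean()
            np.testing.assert_allclose(got[s], ref, atol=1e-9)


class TestHuLine:
    def test_endpoints_on_line_are_southeast(self):
        assert agg.hu_line_side(50.25, 127.5) == "southeast"
        assert agg.hu_line_side(25.0, 98.5) == "southeast"

    def test_known_cities(self):
        assert agg.hu_line_side(31.2, 121.5) == "southeast"   # Shanghai
        assert agg.hu_line_side(43.8, 87.6) == "northwest"    # Urumqi

    def test_reflection_flips_label(self, rng):
        ax, ay = agg.HU_HEIHE
        bx, by = agg.HU_TENGCHONG
        d = np.array([bx - ax, by - ay])
        d = d / np.linalg.norm(d)
        for _ in range(20):
            p = np.array([rng.uniform(80, 130), rng.uniform(20, 50)])
            v = p - np.array([ax, ay])
            refl = np.array([ax, ay]) + 2 * (v @ d) * d - v
            s1 = agg.hu_line_side(p[1], p[0])
            s2 = agg.hu_line_side(refl[1], refl[0])
            if abs((v - (v @ d) * d) @ np.array([-d[1], d[0]])) > 1e-9:
                assert s1 != s2

    def test_partition_is_total(self, china):
        lat, lon = china.cell_latlon()
        sides = agg.hu_line_side(lat, lon)
        assert set(np.unique(sides)) <= {"northwest", "southeast"}
        assert len(sides) == china.n_cells


class TestCountSourceYears:
    def test_all_positive(self):
        assert agg.count_source_years(np.ones(101)) == 0

    def test_zero_is_not_a_source(self):
        assert agg.count_source_years(np.array([-1.0, 0.0, 2.0])) == 1

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=101)
        assert agg.count_source_years(x) == sum(1 for v in x if v < 0)


def _rank_avg(v):
    """Average ranks, brute force."""
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        eq = np.sum(v == x)
        out[i] = less + (eq + 1) / 2.0
    return out


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert agg.spearman(x, x ** 3)[0] == pytest.approx(1.0)
        assert agg.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [3.0, 1.0, 2.0, 4.0]
        rho, _ = agg.spearman(x, y)
        rx, ry = _rank_avg(x), _rank_avg(y)
        expected = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (rx.std() * ry.std())
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            agg.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    # keep magnitudes away from the underflow range so cubing cannot
    # collapse distinct values into ties
    _vals = st.floats(-100, 100).filter(lambda v: v == 0 or abs(v) > 1e-3)

    @given(st.lists(_vals, min_size=5, max_size=30, unique=True),
           st.lists(_vals, min_size=30, max_size=30, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, xs, ys):
        x = np.array(xs)
        y = np.array(ys)[: len(x)]
        if len(y) < len(x):
            return
        r1, _ = agg.spearman(x, y)
        r2, _ = agg.spearman(np.exp(x / 100.0), y ** 3)
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestPartialCorrelation:
    def test_no_controls_reduces_to_spearman(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert agg.partial_correlation(x, y) == pytest.approx(
            agg.spearman(x, y))

    def test_perfect_confounder_removed(self, rng):
        z = rng.normal(size=60)
        y = 3.0 * z
        x = rng.normal(size=60)
        rho, _ = agg.partial_correlation(x, y, [z])
        assert abs(rho) < 0.05

    def test_matches_recursion_formula(self):
        """Trivariate Gaussian, n=500: partial rho agrees with
        (rxy - rxz*ryz)/sqrt((1-rxz^2)(1-ryz^2)) within 0.05."""
        rng = np.random.default_rng(7)
        z = rng.normal(size=500)
        x = 0.6 * z + rng.normal(size=500)
        y = 0.5 * z + 0.4 * x + rng.normal(size=500)
        rho, _ = agg.partial_correlation(x, y, [z])
        rxy = agg.spearman(x, y)[0]
        rxz = agg.spearman(x, z)[0]
        ryz = agg.spearman(y, z)[0]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert rho == pytest.approx(expected, abs=0.05)

    def test_collinear_controls_signalled(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValueError):
            agg.partial_correlation(x, y, [z, 2 * z])


class TestAggregateRegion:
    def test_unit_arithmetic(self, small_world, monkeypatch):
        """Uniform 10 g C m-2 yr-1 over 1e12 m2 of land is 10 Tg C yr-1."""

        class Arch:
            grid = small_world["grid"]
            land_fraction = np.ones(small_world["grid"].n_cells)
            years = np.arange(1900, 1902)
            frac = np.tile(
                np.array([1.0, 0, 0, 0, 0, 0]),
                (2, small_world["grid"].n_cells, 1))
            annual_by_type = {"nep": np.full(
                (2, small_world["grid"].n_cells, 6), 10.0)}

            def annual(self, name):
                return np.full((2, self.grid.n_cells), 10.0)

        areas = np.full(small_world["grid"].n_cells,
                        1e12 / small_world["grid"].n_cells)
        s = agg.aggregate_region(Arch(), areas=areas)
        np.testing.assert_allclose(s.national_nep, 10.0)

    def test_matches_double_loop_oracle(self, small_world, rng):
        grid = small_world["grid"]
        n = grid.n_cells

        class Arch:
            years = np.arange(1900, 1903)
            land_fraction = rng.uniform(0.5, 1.0, n)
            frac = rng.dirichlet(np.ones(6), size=(3, n))
            annual_by_type = {"nep": rng.normal(size=(3, n, 6))}
            _fields = {k: rng.normal(size=(3, n))
                       for k in ("nep", "npp", "rh", "gpp", "c_soil", "c_veg")}

            def annual(self, name):
                return self._fields[name]

        Arch.grid = grid
        arch = Arch()
        areas = agg.grid_cell_areas(grid)
        s = agg.aggregate_region(arch, areas=areas)
        for year in range(3):
            tot = 0.0
            for c in range(n):
                tot += arch._fields["nep"][year, c] * areas[c] \
                    * arch.land_fraction[c]
            assert s.national_nep[year] == pytest.approx(tot * 1e-12, rel=1e-9)
        # linearity: aggregated NPP - aggregated RH == aggregated (NPP-RH)
        diff = s.national_npp - s.national_rh
        class Arch2(Arch):
            def annual(self, name):
                if name == "nep":
                    return self._fields["npp"] - self._fields["rh"]
                return self._fields[name]
        arch2 = Arch2()
        arch2._fields = arch._fields
        s2 = agg.aggregate_region(arch2, areas=areas)
        np.testing.assert_allclose(s2.national_nep, diff, atol=1e-9)

    def test_empty_mask_rejected(self, small_world):
        class Arch:
            grid = small_world["grid"]
            land_fraction = np.ones(small_world["grid"].n_cells)
        with pytest.raises(ValueError):
            agg.aggregate_region(Arch(), mask=np.zeros(
                small_world["grid"].n_cells, bool))
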