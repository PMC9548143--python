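"""Equilibrium, spin-up and transient protocol: convergence, analytic
steady state, determinism, and factorial separation."""

import numpy as np
import pytest

import temcn
from temcn import carbon_core as cc
from temcn import protocol as proto
from temcn import aggregation_stats as agg
from temcn.synthetic_forcing import (COVER_TYPES, CO2Series, ClimateForcing,
                                     GridSpec, SoilProperties)


def _constant_world(tair=20.0, precip=300.0, cloud=0.2):
    """One equatorial cell under truly constant forcing: day length is 12 h
    year-round and the saturated bucket pins WFPS at 100%, so every
    environmental scalar is a constant and the steady state has a closed
    form."""
    grid = GridSpec(-1.0, 1.0, 100.0, 102.0, 2.0)
    clim = {"tair": np.full((12, 1), tair),
            "precip": np.full((12, 1), precip),
            "cloud": np.full((12, 1), cloud)}
    props = SoilProperties(sand=np.array([0.4]), silt=np.array([0.35]),
                           clay=np.array([0.25]), elevation=np.array([100.0]),
                           water_capacity=np.array([162.5]))
    return grid, clim, props


@pytest.fixture(scope="module")
def small_eq(small_world):
    w = small_world
    clim = proto._climatology(w["forcing"], 1900, 2000)
    co2_ref = float(np.mean(w["co2"].ppm))
    return proto.run_equilibrium(clim, co2_ref, w["soil"], w["grid"]), clim, co2_ref


class TestEquilibrium:
    def test_converges_and_is_flagged(self, small_eq):
        eq, _, _ = small_eq
        assert eq.converged.all()
        assert eq.metadata["n_unconverged"] == 0
        assert eq.metadata["equilibrium_years"] < proto.DEFAULT_MAX_ITER

    def test_null_ecosystem(self):
        """A cover type with zero photosynthetic capacity equilibrates to
        empty pools."""
        grid, clim, props = _constant_world()
        table = cc.BiomeTable({t: (cc.default_biome_table()[t] if t != "bare"
                                   else cc.BiomeParams(c_max=0.0, t_min=-5,
                                                       t_opt=15, t_max=40))
                               for t in COVER_TYPES})
        eq = proto.run_equilibrium(clim, 340.0, props, grid, table)
        j = COVER_TYPES.index("bare")
        assert eq.c_veg[0, j] == pytest.approx(0.0, abs=1e-6)
        assert eq.c_soil[0, j] == pytest.approx(0.0, abs=1e-6)

    def test_matches_analytic_steady_state(self):
        """Closed-form fixed point under constant forcing: NPP balances
        litterfall (Cv* = NPP/l_f) and litter input balances
        decomposition (Cs* = l_f Cv* / (k_d q10^((T-10)/10) f_w)),
        each within 1%."""
        grid, clim, props = _constant_world(tair=20.0)
        eq = proto.run_equilibrium(clim, 340.0, props, grid)
        table = cc.default_biome_table()
        for j, cover in enumerate(COVER_TYPES):
            p = table[cover]
            t = 20.0
            num = (t - p.t_min) * (p.t_max - t)
            f_temp = min(max(num / (num - (t - p.t_opt) ** 2), 0.0), 1.0)
            f_light = 1.0 - p.cloud_ext * 0.2
            f_w = 0.6  # WFPS pinned at 100%
            gpp = p.c_max * f_temp * 1.0 * f_light * f_w
            q_veg = p.q10_veg ** ((t - 10.0) / 10.0)
            cv_star = (1 - p.r_g) * gpp / (p.l_f + (1 - p.r_g) * p.r_m * q_veg)
            q_soil = p.q10_soil ** ((t - 10.0) / 10.0)
            cs_star = p.l_f * cv_star / (p.k_d * q_soil * f_w)
            assert eq.c_veg[0, j] == pytest.approx(cv_star, rel=0.01), cover
            assert eq.c_soil[0, j] == pytest.approx(cs_star, rel=0.01), cover

    def test_rejects_bad_tolerance(self, small_world):
        clim = proto._climatology(small_world["forcing"], 1900, 2000)
        with pytest.raises(ValueError):
            proto.run_equilibrium(clim, 340.0, small_world["soil"],
                                  small_world["grid"], tol=-1.0)


def _stationary_forcing(grid, clim, n_years=5):
    return ClimateForcing(grid, 1900, 1900 + n_years - 1,
                          np.tile(clim["tair"], (n_years, 1)),
                          np.tile(clim["precip"], (n_years, 1)),
                          np.tile(clim["cloud"], (n_years, 1)))


class TestSpinup:
    def test_zero_years_is_noop(self, small_world, small_eq):
        eq, _, _ = small_eq
        out = proto.run_spinup(eq, small_world["forcing"], 296.0,
                               small_world["soil"], years=0)
        np.testing.assert_array_equal(out.c_veg, eq.c_veg)
        np.testing.assert_array_equal(out.c_soil, eq.c_soil)

    def test_constant_block_preserves_equilibrium(self, small_world, small_eq):
        """Spinning up on a repeat of the climatology leaves the
        equilibrium pools in place to within the convergence tolerance
        per year."""
        eq, clim, co2_ref = small_eq
        f = _stationary_forcing(small_world["grid"], clim, 10)
        out = proto.run_spinup(eq, f, co2_ref, small_world["soil"],
                               years=10, block=(1900, 1909))
        drift = np.abs((out.c_veg - eq.c_veg) + (out.c_soil - eq.c_soil))
        assert drift.max() < 10 * 2 * proto.DEFAULT_TOL

    def test_deterministic(self, small_world, small_eq):
        eq, _, _ = small_eq
        a = proto.run_spinup(eq, small_world["forcing"], 296.0,
                             small_world["soil"], years=20)
        b = proto.run_spinup(eq, small_world["forcing"], 296.0,
                             small_world["soil"], years=20)
        np.testing.assert_array_equal(a.c_veg, b.c_veg)
        np.testing.assert_array_equal(a.c_soil, b.c_soil)

    def test_block_outside_forcing_rejected(self, small_world, small_eq):
        eq, _, _ = small_eq
        with pytest.raises(ValueError):
            proto.run_spinup(eq, small_world["forcing"], 296.0,
                             small_world["soil"], block=(1890, 1949))


class TestTransient:
    def test_bit_identical_reruns(self, small_world, small_eq):
        eq, _, _ = small_eq
        w = small_world
        a = proto.run_transient(eq.copy(), w["forcing"], w["co2"], w["land"],
                                proto.EXPERIMENTS["S1"], props=w["soil"])
        b = proto.run_transient(eq.copy(), w["forcing"], w["co2"], w["land"],
                                proto.EXPERIMENTS["S1"], props=w["soil"])
        for k in proto.MONTHLY_FIELDS:
            np.testing.assert_array_equal(a.monthly[k], b.monthly[k])

    def test_s1_equals_s2_under_constant_co2(self, small_world, small_eq):
        eq, _, _ = small_eq
        w = small_world
        co2c = temcn.generate_co2_series(296.0, 296.0)
        a = proto.run_transient(eq.copy(), w["forcing"], co2c, w["land"],
                                proto.EXPERIMENTS["S1"], props=w["soil"])
        b = proto.run_transient(eq.copy(), w["forcing"], co2c, w["land"],
                                proto.EXPERIMENTS["S2"], props=w["soil"])
        np.testing.assert_array_equal(a.monthly["nep"], b.monthly["nep"])

    def test_co2_separation_sign(self, small_world, small_eq):
        """With CO2 the only trending driver, S1 outgrows S2 in NPP by the
        1990s while the two start together."""
        eq, clim, co2_ref = small_eq
        w = small_world
        f = _stationary_forcing(w["grid"], clim, 101)
        s1 = proto.run_transient(eq.copy(), f, w["co2"], w["land_static"],
                                 proto.EXPERIMENTS["S1"], props=w["soil"])
        s2 = proto.run_transient(eq.copy(), f, w["co2"], w["land_static"],
                                 proto.EXPERIMENTS["S2"], props=w["soil"])
        npp1 = s1.annual("npp").sum(axis=1)
        npp2 = s2.annual("npp").sum(axis=1)
        assert npp1[0] == pytest.approx(npp2[0], rel=1e-6)
        assert np.all(npp1[90:] > npp2[90:])

    def test_missing_climatology_years_rejected(self, small_world, small_eq):
        eq, clim, _ = small_eq
        w = small_world
        f = _stationary_forcing(w["grid"], clim, 5)  # ends 1904 < 1919
        with pytest.raises(ValueError):
            proto.run_transient(eq.copy(), f, w["co2"], w["land_static"],
                                proto.EXPERIMENTS["S3"], props=w["soil"])


class TestFactorialAndAttribution:
    def test_degenerate_equality_under_stationary_drivers(self, small_world,
                                                          small_eq):
        """All four experiments coincide when nothing trends."""
        eq, clim, co2_ref = small_eq
        w = small_world
        f = _stationary_forcing(w["grid"], clim, 101)
        co2c = CO2Series(1900, np.full(101, co2_ref))
        archives = proto.run_factorial(eq, f, co2c, w["land_static"],
                                       w["soil"])
        ref = archives["S1"].monthly["nep"]
        for name in ("S2", "S3", "S4"):
            np.testing.assert_allclose(archives[name].monthly["nep"], ref,
                                       atol=1e-9)
        att = proto.attribution_effects(archives, w["areas"])
        for eff in (att.effect_co2, att.effect_climate, att.effect_luc):
            np.testing.assert_allclose(eff, 0.0, atol=1e-9)

    def test_attribution_requires_all_archives(self, small_world):
        with pytest.raises(KeyError):
            proto.attribution_effects({"S1": None}, small_world["areas"])

    def test_experiment_spec_validation(self):
        with pytest.raises(ValueError):
            proto.ExperimentSpec(co2_mode="frozen")
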