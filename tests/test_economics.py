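"""Open-access fleet economics: catch, price, costs, adaptation, exit."""

import numpy as np
import pytest

from fishweb.config import EconConfig, RunConfig
from fishweb.dynamics import CommunityState, EcoParams, derivatives, simulate
from fishweb.economics import (
    FleetSet,
    catch_rate,
    cost_per_vessel,
    fleet_derivatives,
    fleet_profit,
    init_fleets,
    market_price,
    revenue_from_catch,
    species_price_scale,
)
from fishweb.webs import SpeciesPool, build_topology

PED = -1.15


def make_fleet(p_base_i=1.0, catch_max=1.0, clearance=0.5, maintenance=1.0,
               scaling=0.01, gear=1.0, n=1, targets=None):
    return FleetSet(
        target=np.array(targets if targets is not None else list(range(n))),
        catch_max=np.full(n, catch_max),
        maintenance=np.full(n, maintenance),
        gear=np.full(n, gear),
        scaling=np.full(n, scaling),
        p_base_i=np.full(n, p_base_i),
        ped=PED,
        mu_vessel=0.01,
        mu_clearance=0.3,
        V0=np.full(n, 1e-3),
        clearance0=np.full(n, clearance),
        exit_threshold=1e-10,
    )


class TestCatchRate:
    def test_no_stock_no_catch(self):
        assert catch_rate(0.0, 1.0, 0.5, 2.0) == 0.0

    def test_half_saturation_point(self):
        cm, cl, V = 2.0, 0.4, 3.0
        B = cm / cl
        assert catch_rate(B, cm, cl, V) == pytest.approx(cm * V / 2, rel=1e-12)

    def test_saturation_limit(self):
        assert catch_rate(1e12, 2.0, 0.4, 3.0) == pytest.approx(6.0, rel=1e-6)

    def test_negative_stock_rejected(self):
        with pytest.raises(ValueError):
            catch_rate(-0.1, 1.0, 0.5, 1.0)

    def test_zero_clearance_gives_zero(self):
        assert catch_rate(5.0, 1.0, 0.0, 1.0) == 0.0

    def test_hyperstability(self):
        """Catch per vessel falls less than proportionally with stock:
        (catch/V)/B increases as B decreases."""
        Bs = np.linspace(5.0, 0.01, 40)
        cpue_per_b = catch_rate(Bs, 1.0, 0.5, 1.0) / Bs
        assert np.all(np.diff(cpue_per_b) > 0)


class TestPrice:
    def test_unit_ratio(self):
        assert market_price(0.37, 0.37, PED) == pytest.approx(1.0)

    def test_doubling_factor(self):
        p1 = market_price(0.1, 1.0, PED)
        p2 = market_price(0.2, 1.0, PED)
        assert p2 / p1 == pytest.approx(0.5473117682173594, rel=1e-12)

    def test_zero_catch_price_undefined_but_revenue_zero(self):
        with pytest.raises(ValueError):
            market_price(0.0, 1.0, PED)
        assert revenue_from_catch(0.0, 1.0, PED) == 0.0

    def test_revenue_increasing_for_elastic_demand(self):
        catches = np.linspace(1e-6, 2.0, 200)
        rev = revenue_from_catch(catches, 0.8, PED)
        assert np.all(np.diff(rev) > 0)

    def test_revenue_decreasing_for_inelastic_demand(self):
        catches = np.linspace(1e-6, 2.0, 200)
        rev = revenue_from_catch(catches, 0.8, -0.85)
        assert np.all(np.diff(rev) < 0)

    def test_revenue_equals_price_times_catch(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = rng.uniform(1e-8, 10.0)
            pb = rng.uniform(0.01, 10.0)
            assert revenue_from_catch(c, pb, PED) == pytest.approx(
                market_price(c, pb, PED) * c, rel=1e-12
            )


class TestPriceScale:
    def test_mean_mass_gives_base(self):
        assert species_price_scale(5.0, 5.0, 2.0) == pytest.approx(2.0)

    def test_linear_in_mass(self):
        assert species_price_scale(10.0, 5.0, 2.0) == pytest.approx(4.0)

    def test_uniform_switch(self):
        assert species_price_scale(1e9, 5.0, 2.0, uniform_price=True) == 2.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            species_price_scale(-1.0, 5.0, 2.0)


class TestProfit:
    def test_break_even(self):
        fl = make_fleet(p_base_i=1.0)
        catch = 0.3
        rev = revenue_from_catch(catch, 1.0, PED)
        cost = cost_per_vessel(1.0, 0.01, 0.5, 1.0)
        V = rev / cost
        assert fleet_profit(catch, fl, 0.5, V) == pytest.approx(0.0, abs=1e-12)

    def test_empty_fleet_zero_profit_at_zero_catch(self):
        fl = make_fleet()
        assert fleet_profit(0.0, fl, 0.5, 0.0) == pytest.approx(0.0)

    def test_termwise_oracle(self):
        fl = make_fleet(p_base_i=0.7, maintenance=1.3, scaling=0.02,
                        clearance=0.9, gear=2.0)
        catch, V = 0.45, 0.12
        rev = 0.7 ** (-1 / PED) * catch ** (1 + 1 / PED)
        cost = 1.3 + 0.02 * 0.9 / 2.0
        assert fleet_profit(catch, fl, 0.9, V) == pytest.approx(
            rev - cost * V, rel=1e-12
        )


class TestFleetDerivatives:
    def test_zero_profit_equilibrium(self):
        fl = make_fleet()
        dV, dC = fleet_derivatives(np.array([0.0]), fl)
        assert dV[0] == 0.0 and dC[0] == 0.0

    def test_adaptation_speeds(self):
        fl = make_fleet()
        dV, dC = fleet_derivatives(np.array([1.0]), fl)
        assert dV[0] == pytest.approx(0.01)
        assert dC[0] == pytest.approx(0.3)

    def test_sign_follows_profit(self):
        fl = make_fleet()
        for pi in (-2.0, -1e-9, 1e-9, 2.0):
            dV, _ = fleet_derivatives(np.array([pi]), fl)
            assert np.sign(dV[0]) == np.sign(pi)


class TestInitFleets:
    def setup_method(self):
        pool = SpeciesPool(
            np.array([0, 1, 2, 2, 2]), np.array([1.0, 3.0, 5.0, 6.0, 7.0])
        )
        self.web = build_topology(pool, 100.0, 2.0)

    def test_vessels_in_range(self):
        fl = init_fleets(
            [2, 3, 4], self.web.pool.mass, self.web.pool.is_plant,
            self.web.pool.is_consumer, EconConfig(), np.random.default_rng(0),
        )
        assert fl.n == 3
        assert np.all((fl.V0 >= 1e-4) & (fl.V0 <= 1e-3))

    def test_deterministic_under_seed(self):
        args = (
            [2, 3], self.web.pool.mass, self.web.pool.is_plant,
            self.web.pool.is_consumer, EconConfig(),
        )
        a = init_fleets(*args, np.random.default_rng(5))
        b = init_fleets(*args, np.random.default_rng(5))
        np.testing.assert_array_equal(a.V0, b.V0)

    def test_plant_target_rejected(self):
        with pytest.raises(ValueError):
            init_fleets(
                [0], self.web.pool.mass, self.web.pool.is_plant,
                self.web.pool.is_consumer, EconConfig(),
                np.random.default_rng(0),
            )

    def test_duplicate_targets_rejected(self):
        with pytest.raises(ValueError):
            init_fleets(
                [2, 2], self.web.pool.mass, self.web.pool.is_plant,
                self.web.pool.is_consumer, EconConfig(),
                np.random.default_rng(0),
            )

    def test_price_scales_with_target_mass(self):
        fl = init_fleets(
            [2, 4], self.web.pool.mass, self.web.pool.is_plant,
            self.web.pool.is_consumer, EconConfig(), np.random.default_rng(0),
        )
        ratio = self.web.pool.mass[4] / self.web.pool.mass[2]
        assert fl.p_base_i[1] / fl.p_base_i[0] == pytest.approx(ratio, rel=1e-12)


class TestCalibration:
    def test_breakeven_density_is_zero_profit(self):
        from fishweb.calibration import breakeven_vessel_density, profit_at
        cfg = EconConfig()
        for B, ratio in [(2.0, 0.1), (0.5, 0.02), (8.0, 3.0)]:
            V = breakeven_vessel_density(B, ratio, cfg)
            assert V > 0
            assert profit_at(B, V, ratio, cfg) == pytest.approx(0.0, abs=1e-10)

    def test_breakeven_p_base_inverts_defaults(self):
        from fishweb.calibration import breakeven_p_base, breakeven_vessel_density
        cfg = EconConfig()
        V = breakeven_vessel_density(2.0, 0.1, cfg)
        assert breakeven_p_base(2.0, V, 0.1, cfg) == pytest.approx(
            cfg.p_base, rel=1e-9
        )

    def test_mid_trophic_fishery_breaks_even_at_positive_fleet(self):
        # the shipped defaults let a mid-trophic-level fish (mass ~ a tenth
        # of the mean consumer mass, stock ~ 2) support a fleet
        from fishweb.calibration import breakeven_vessel_density
        assert breakeven_vessel_density(2.0, 0.1, EconConfig()) > 1e-3


class TestCouplingAndExit:
    @pytest.fixture()
    def harvested_system(self):
        pool = SpeciesPool(np.array([0, 2]), np.array([2.0, 4.0]))
        web = build_topology(pool, 100.0, 2.0)
        from fishweb.config import EcoConfig

        params = EcoParams.from_web(web, EcoConfig(), np.random.default_rng(0))
        fleet = make_fleet(targets=[1])
        return web, params, fleet

    def test_catch_removed_exactly_from_target(self, harvested_system):
        """Biomass removed from the harvested species equals the catch."""
        web, params, fleet = harvested_system
        N = np.array([5.0, 5.0])
        B = np.array([4.0, 1.7])
        state = CommunityState(N, B, np.ones(2, dtype=bool))
        V, C = np.array([0.05]), np.array([0.6])
        _, dB_no, _, _ = derivatives(state, params)
        _, dB_yes, _, _ = derivatives(state, params, fleet, V, C)
        removed = dB_no[1] - dB_yes[1]
        assert removed == pytest.approx(
            catch_rate(B[1], fleet.catch_max[0], C[0], V[0]), rel=1e-12
        )
        assert dB_yes[0] == pytest.approx(dB_no[0], rel=1e-12)

    def test_exit_threshold_semantics(self):
        fl = make_fleet()
        assert 1e-11 < fl.exit_threshold
        assert 1e-9 > fl.exit_threshold

    def test_exited_fleet_contributes_nothing(self, harvested_system):
        web, params, fleet = harvested_system
        fleet = fleet.copy()
        fleet.active[0] = False
        state = CommunityState(
            np.array([5.0, 5.0]), np.array([4.0, 1.7]), np.ones(2, dtype=bool)
        )
        _, dB, dV, dC = derivatives(
            state, params, fleet, np.array([0.5]), np.array([0.6])
        )
        _, dB_free, _, _ = derivatives(state, params)
        assert dB[1] == pytest.approx(dB_free[1], rel=1e-12)
        assert dV[0] == 0.0 and dC[0] == 0.0

    def test_exit_event_is_absorbing(self, harvested_system):
        """A fleet pushed into losses exits at V < 1e-10 and never catches
        again; its exit is recorded."""
        web, params, fleet = harvested_system
        # the target stock is extinct: zero catch, pure losses
        fleet.maintenance[:] = 10.0
        fleet.V0[:] = 1e-9
        state = CommunityState(
            np.array([5.0, 5.0]),
            np.array([4.0, 0.0]),
            np.array([True, False]),
        )
        res = simulate(
            params, state, (0.0, 200.0), fleets=fleet,
            run_config=RunConfig(n_save=21, steady_tolerance=None),
            rtol=1e-8, atol=1e-14,
        )
        assert len(res.exits) == 1
        assert not res.fleets.active[0]
        t_exit = res.exits[0][0]
        after = res.trajectory.t > t_exit
        assert np.all(res.trajectory.catch[after, 0] == 0.0)
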