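"""Unit and property tests for the compartmental PK core."""

import numpy as np
import pytest

from tcisim.pk import (
    CompartmentTrajectory,
    InfusionProfile,
    PKParameters,
    StatePropagator,
    amounts_to_concentrations,
    analytic_constant_infusion,
    derive_rate_constants,
    pk_rhs,
    simulate,
)

from conftest import random_pk_parameters


def make_params(**overrides) -> PKParameters:
    base = dict(CL=1.0, V1=10.0, V2=20.0, V3=100.0, Q2=0.5, Q3=0.3, ke0=0.2)
    base.update(overrides)
    return PKParameters(**base)


class TestRateConstants:
    def test_elimination_is_clearance_over_central_volume(self):
        rc = derive_rate_constants(make_params(CL=1.0, V1=10.0))
        assert rc.k10 == pytest.approx(0.1)

    def test_effect_site_constants(self):
        rc = derive_rate_constants(make_params(ke0=0.2))
        assert rc.k41 == 0.2
        assert rc.k14 == pytest.approx(2e-5)

    def test_peripheral_mammillary_convention(self):
        rc = derive_rate_constants(make_params(Q2=0.5, V1=10.0, V2=20.0))
        assert rc.k12 == pytest.approx(0.05)
        assert rc.k21 == pytest.approx(0.025)

    @pytest.mark.parametrize("field", ["CL", "V1", "V2", "V3", "Q2", "Q3", "ke0"])
    def test_nonpositive_parameter_rejected_naming_field(self, field):
        with pytest.raises(ValueError, match=field):
            make_params(**{field: -1.0})

    def test_peripheral_constants_consistent_with_steady_state_volume(self):
        # at steady state dA2/dt = 0 forces A2/A1 = k12/k21 = V2/V1, i.e. the
        # peripheral compartment equilibrates at the same concentration
        p = make_params()
        state = analytic_constant_infusion(p, 10.0, 40000.0)
        c = state[:3] / np.array([p.V1, p.V2, p.V3])
        assert c == pytest.approx(np.full(3, c[0]), rel=1e-5)


class TestRHS:
    def test_origin_is_fixed_point(self):
        rc = derive_rate_constants(make_params())
        assert pk_rhs(np.zeros(4), rc, 0.0, 10.0) == pytest.approx(np.zeros(4))

    def test_central_amount_feeds_first_peripheral(self):
        rc = derive_rate_constants(make_params())
        d = pk_rhs([10.0, 0.0, 0.0, 0.0], rc, 0.0, 10.0)
        assert d[1] == pytest.approx(10.0 * rc.k12)

    def test_only_loss_is_elimination(self, rng):
        p = make_params()
        rc = derive_rate_constants(p)
        for _ in range(20):
            state = rng.uniform(0, 50, 4)
            U = rng.uniform(0, 30)
            d = pk_rhs(state, rc, U, p.V1)
            assert d[:3].sum() == pytest.approx(U - state[0] * rc.k10)


class TestSimulate:
    def test_zero_input_zero_state_stays_zero(self):
        traj = simulate(make_params(), InfusionProfile([0.0], [0.0]), np.linspace(0, 10, 11))
        assert np.all(traj.states() == 0)

    def test_matches_analytic_oracle_constant_rate(self, ref_params):
        grid = np.linspace(0, 30, 61)
        traj = simulate(ref_params, InfusionProfile([0.0], [25.0]), grid)
        ana = analytic_constant_infusion(ref_params, 25.0, grid)
        scale = np.abs(ana).max(axis=0)
        rel = np.abs(traj.states() - ana) / np.maximum(np.abs(ana), 1e-9 * scale)
        assert np.nanmax(rel[1:]) < 1e-6

    def test_steady_state_c1_is_rate_over_clearance(self):
        p = make_params()
        traj = simulate(p, InfusionProfile([0.0], [5.0]), np.array([0.0, 5000.0]))
        assert traj.A1[-1] / p.V1 == pytest.approx(5.0 / p.CL, rel=1e-4)
        assert traj.C4[-1] == pytest.approx(5.0 / p.CL, rel=1e-4)

    def test_linearity_doubling_rate_doubles_trajectory(self, ref_params):
        grid = np.linspace(0, 20, 21)
        prof = InfusionProfile([0.0, 5.0], [40.0, 10.0])
        t1 = simulate(ref_params, prof, grid)
        t2 = simulate(ref_params, prof.scaled(2.0), grid)
        assert t2.states()[1:] == pytest.approx(2.0 * t1.states()[1:], rel=1e-7)

    def test_mass_balance_piecewise_profile(self, ref_params):
        prof = InfusionProfile([0.0, 2.0, 6.0], [120.0, 0.0, 15.0])
        grid = np.linspace(0, 20, 81)
        traj = simulate(ref_params, prof, grid)
        infused = prof.cumulative_infused(grid)
        retained = traj.A1 + traj.A2 + traj.A3
        residual = infused - retained - traj.eliminated
        assert np.abs(residual[1:] / infused[1:]).max() < 1e-6

    def test_non_negative_trajectories(self, ref_params):
        prof = InfusionProfile([0.0, 1.0], [200.0, 0.0])
        traj = simulate(ref_params, prof, np.linspace(0, 60, 121))
        assert np.all(traj.states() >= -1e-9)

    def test_grid_beyond_profile_rejected(self, ref_params):
        prof = InfusionProfile([0.0], [10.0], duration=5.0)
        with pytest.raises(ValueError):
            simulate(ref_params, prof, np.linspace(0, 10, 11))

    def test_negative_initial_state_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate(
                ref_params,
                InfusionProfile([0.0], [0.0]),
                np.array([0.0, 1.0]),
                init=[-1.0, 0.0, 0.0, 0.0],
            )


class TestOracle:
    def test_zero_time_zero_init_is_zero(self, ref_params):
        assert analytic_constant_infusion(ref_params, 30.0, 0.0) == pytest.approx(
            np.zeros(4)
        )

    def test_long_time_limit_is_steady_state(self):
        p = make_params()
        state = analytic_constant_infusion(p, 8.0, 1e5)
        assert state[0] / p.V1 == pytest.approx(8.0 / p.CL, rel=1e-9)
        assert state[3] == pytest.approx(8.0 / p.CL, rel=1e-9)

    def test_agreement_with_solver_over_random_draws(self):
        # dual-route check: adaptive ODE integration vs matrix-exponential
        # closed form on 100 random parameter/rate draws
        rng = np.random.default_rng(777)
        worst = 0.0
        check_times = np.array([0.5, 2.0, 10.0, 40.0])
        for _ in range(100):
            p = random_pk_parameters(rng)
            U = float(rng.uniform(1.0, 100.0))
            traj = simulate(p, InfusionProfile([0.0], [U]), np.concatenate([[0.0], check_times]))
            ana = analytic_constant_infusion(p, U, check_times)
            scale = np.abs(ana).max(axis=0)
            rel = np.abs(traj.states()[1:] - ana) / np.maximum(np.abs(ana), 1e-9 * scale)
            worst = max(worst, float(np.nanmax(rel)))
        assert worst < 1e-6


class TestStatePropagator:
    def test_matches_oracle_on_random_draws(self):
        rng = np.random.default_rng(31)
        times = np.array([0.0, 0.5, 3.0, 12.0])
        for _ in range(25):
            p = random_pk_parameters(rng)
            U = float(rng.uniform(0.0, 80.0))
            tr = StatePropagator(p).run(InfusionProfile([0.0], [U]), times)
            ana = analytic_constant_infusion(p, U, times)
            assert tr.states() == pytest.approx(ana, rel=1e-9, abs=1e-12)

    def test_step_composition(self, ref_params):
        sp = StatePropagator(ref_params)
        x = np.array([50.0, 10.0, 2.0, 1.0])
        one = sp.step(sp.step(x, 0.5, 20.0), 0.5, 20.0)
        two = sp.step(x, 1.0, 20.0)
        assert one == pytest.approx(two, rel=1e-12)


class TestConcentrations:
    def test_amounts_divided_by_volumes(self):
        p = make_params(V1=10.0)
        traj = CompartmentTrajectory(
            times=np.array([0.0, 1.0]),
            A1=np.array([0.0, 5.0]),
            A2=np.array([0.0, 4.0]),
            A3=np.array([0.0, 10.0]),
            C4=np.array([0.0, 0.3]),
        )
        df = amounts_to_concentrations(traj, p)
        assert df["C1_mg_per_L"].iloc[1] == pytest.approx(0.5)
        assert df["C2_mg_per_L"].iloc[1] == pytest.approx(4.0 / 20.0)
        assert df["C3_mg_per_L"].iloc[1] == pytest.approx(0.1)
        # C4 passes through unchanged and the round trip C_i * V_i recovers A_i
        assert df["C4_mg_per_L"].iloc[1] == 0.3
        assert df["C1_mg_per_L"].to_numpy() * p.V1 == pytest.approx(traj.A1)


class TestInfusionProfile:
    def test_validation(self):
        with pytest.raises(ValueError):
            InfusionProfile([1.0], [5.0])  # must start at 0
        with pytest.raises(ValueError):
            InfusionProfile([0.0, 0.0], [5.0, 1.0])  # non-increasing
        with pytest.raises(ValueError):
            InfusionProfile([0.0], [-1.0])  # negative rate

    def test_rate_lookup_and_cumulative_dose(self):
        prof = InfusionProfile([0.0, 2.0, 4.0], [10.0, 0.0, 5.0])
        assert prof.rate_at(0.0) == 10.0
        assert prof.rate_at(1.999) == 10.0
        assert prof.rate_at(2.0) == 0.0
        assert prof.rate_at(100.0) == 5.0
        assert prof.cumulative_infused([3.0])[0] == pytest.approx(20.0)
        assert prof.cumulative_infused([6.0])[0] == pytest.approx(30.0)

    def test_csv_round_trip(self, tmp_path):
        prof = InfusionProfile([0.0, 1.25], [33.5, 0.0])
        path = tmp_path / "profile.csv"
        prof.to_csv(path)
        back = InfusionProfile.from_csv(path)
        assert back.times == pytest.approx(prof.times)
        assert back.rates == pytest.approx(prof.rates)
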