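"""Core plant: exact propagation, state-space form, transfer functions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thyrodose import (
    DoseSchedule,
    PlantState,
    ThyroidParams,
    TshSignal,
    continuous_tf,
    simulate_plant,
    system_matrices,
)


def _ode_oracle(params, doses, tsh_values, t_grid, x0=(0.0, 0.0)):
    """Adaptive-step integration of the plant between impulse events.

    Independent of the exact-propagation path: integrates the right-hand
    side numerically with tight tolerances, adding each absorbed dose to
    x1 at its event time and holding TSH constant per grid interval.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    tsh = TshSignal(tsh_values).on_grid(t_grid.size)
    amounts = dict(zip(doses.times_h, doses.amounts_umol))
    x = np.array(x0, dtype=float)
    out = np.empty((t_grid.size, 2))
    x[0] += amounts.get(t_grid[0], 0.0)
    out[0] = x
    for k in range(t_grid.size - 1):
        u = params.vmax * tsh[k] / (params.km + tsh[k])

        def rhs(_t, s):
            return [
                -params.kexc * s[0],
                u + params.kreac * s[0] - params.ksec * s[1],
            ]

        sol = solve_ivp(
            rhs,
            (t_grid[k], t_grid[k + 1]),
            x,
            rtol=1e-11,
            atol=1e-14,
            dense_output=False,
        )
        x = sol.y[:, -1]
        x[0] += amounts.get(t_grid[k + 1], 0.0)
        out[k + 1] = x
    return out


def staircase_schedule(days=90, levels=(50.0, 80.0, 110.0)):
    daily = np.concatenate(
        [np.full(30, levels[0]), np.full(30, levels[1]), np.full(days - 60, levels[2])]
    )
    return DoseSchedule.daily(daily)


class TestSimulatePlant:
    def test_null_input_stays_zero(self, params):
        t = np.arange(0.0, 200.0)
        traj = simulate_plant(
            params, DoseSchedule.empty(), TshSignal.constant(0.0), PlantState(), t
        )
        assert np.all(traj.x1 == 0.0)
        assert np.all(traj.x2 == 0.0)

    def test_constant_rate_equilibrium(self, params):
        """x1* = dbar/kexc, x2* = (vmax TSH/(km+TSH) + kreac x1*)/ksec."""
        tsh = 40.0
        daily = 100.0
        t = np.arange(0.0, 24.0 * 600 + 1.0)
        doses = DoseSchedule.daily(np.full(600, daily))
        traj = simulate_plant(
            params, doses, TshSignal.constant(tsh), PlantState(), t,
            dosing_mode="rate",
        )
        dbar = doses.amounts_umol[0] / 24.0
        x1_star = dbar / params.kexc
        x2_star = (
            params.vmax * tsh / (params.km + tsh) + params.kreac * x1_star
        ) / params.ksec
        assert traj.x1[-1] == pytest.approx(x1_star, rel=1e-6)
        assert traj.x2[-1] == pytest.approx(x2_star, rel=1e-6)

    def test_staircase_matches_adaptive_integrator(self, params):
        """Exact propagation vs a dense Runge-Kutta oracle, 1e-6 relative."""
        days = 90
        doses = staircase_schedule(days)
        t = np.arange(0.0, days * 24 + 1.0)
        tsh = 30.0 + 20.0 * np.sin(2 * np.pi * t / (30 * 24.0))
        traj = simulate_plant(params, doses, TshSignal(tsh), PlantState(), t)
        ref = _ode_oracle(params, doses, tsh, t)
        scale1, scale2 = np.max(ref[:, 0]), np.max(ref[:, 1])
        assert np.max(np.abs(traj.x1 - ref[:, 0])) / scale1 < 1e-6
        assert np.max(np.abs(traj.x2 - ref[:, 1])) / scale2 < 1e-6

    def test_random_draws_match_adaptive_integrator(self, rng):
        """Oracle equivalence on random parameters, schedules and grids."""
        for _ in range(10):
            p = ThyroidParams(
                kexc=rng.uniform(0.1, 0.5),
                ksec=rng.uniform(1e-3, 1e-2),
                vmax=10 ** rng.uniform(-5, -3),
                km=10 ** rng.uniform(2, 4),
                kreac=rng.uniform(1.0, 20.0),
            )
            days = 10
            doses = DoseSchedule.daily(rng.uniform(0, 150, days))
            t = np.arange(0.0, days * 24 + 1.0)
            tsh = rng.uniform(0.0, 100.0, t.size)
            x0 = PlantState(rng.uniform(0, 0.1), rng.uniform(0, 50))
            traj = simulate_plant(p, doses, TshSignal(tsh), x0, t)
            ref = _ode_oracle(p, doses, tsh, t, (x0.x1, x0.x2))
            denom = 1.0 + np.max(np.abs(ref), axis=0)
            err = np.max(np.abs(np.column_stack([traj.x1, traj.x2]) - ref), axis=0)
            assert np.all(err / denom < 1e-6)

    def test_superposition_in_dose(self, params, rng):
        """x1 response to summed schedules is the sum of responses."""
        days = 20
        t = np.arange(0.0, days * 24 + 1.0)
        tsh = TshSignal.constant(10.0)
        d1 = rng.uniform(0, 100, days)
        d2 = rng.uniform(0, 100, days)
        run = lambda d: simulate_plant(
            params, DoseSchedule.daily(d), tsh, PlantState(), t
        )
        np.testing.assert_allclose(
            run(d1 + d2).x1, run(d1).x1 + run(d2).x1, rtol=1e-12, atol=1e-18
        )

    def test_monotonicity_and_positivity(self, params, rng):
        days = 30
        t = np.arange(0.0, days * 24 + 1.0)
        tsh = TshSignal(rng.uniform(0, 80, t.size))
        base = rng.uniform(0, 100, days)
        lo = simulate_plant(params, DoseSchedule.daily(base), tsh, PlantState(), t)
        hi = simulate_plant(
            params, DoseSchedule.daily(base + rng.uniform(0, 50, days)),
            tsh, PlantState(), t,
        )
        assert np.all(lo.x1 >= 0) and np.all(lo.x2 >= 0)
        assert np.all(hi.x2 >= lo.x2 - 1e-15)

    def test_dose_off_grid_rejected(self, params):
        t = np.arange(0.0, 48.0)
        doses = DoseSchedule(np.array([13.5]), np.array([50.0]))
        with pytest.raises(ValueError, match="not on the simulation grid"):
            simulate_plant(params, doses, TshSignal.constant(0.0), PlantState(), t)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ThyroidParams(kexc=-0.2, ksec=3e-3, vmax=1e-4, km=1e3, kreac=7.0)
        with pytest.raises(ValueError, match="kexc must differ"):
            ThyroidParams(kexc=0.01, ksec=0.01, vmax=1e-4, km=1e3, kreac=7.0)


class TestSystemMatrices:
    def test_eigenvalues_are_minus_rates(self, params):
        A, b, V, c, eig, _ = system_matrices(params)
        np.testing.assert_allclose(sorted(eig), sorted([-params.kexc, -params.ksec]))
        np.testing.assert_allclose(sorted(np.linalg.eigvals(A).real), sorted(eig))

    def test_structure_matches_state_space_form(self, params):
        A, b, V, c, _, _ = system_matrices(params)
        np.testing.assert_allclose(
            A, [[-params.kexc, 0.0], [params.kreac, -params.ksec]]
        )
        np.testing.assert_allclose(b, [1.0, 0.0])
        np.testing.assert_allclose(V, [0.0, params.vmax])
        np.testing.assert_allclose(c, [0.0, 1.0])

    def test_controllability_reduces_to_kreac(self, params):
        assert system_matrices(params)[-1] is True
        degenerate = ThyroidParams(
            kexc=params.kexc, ksec=params.ksec, vmax=params.vmax,
            km=params.km, kreac=0.0, check=False,
        )
        assert system_matrices(degenerate)[-1] is False


class TestContinuousTF:
    def test_denominator_factors_into_rate_poles(self, params):
        G, _ = continuous_tf(params)
        roots = np.roots(G.den)
        np.testing.assert_allclose(
            sorted(roots), sorted([-params.kexc, -params.ksec]), rtol=1e-12
        )

    def test_dc_gains(self, params):
        G, S = continuous_tf(params)
        assert G(0.0) == pytest.approx(params.kreac / (params.ksec * params.kexc))
        assert S(0.0) == pytest.approx(params.vmax / params.ksec)


class TestIO:
    def test_trajectory_csv_round_trip(self, params, tmp_path):
        t = np.arange(0.0, 100.0)
        traj = simulate_plant(
            params, DoseSchedule.daily([75.0] * 4), TshSignal.constant(5.0),
            PlantState(), t,
        )
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = type(traj).from_csv(path)
        np.testing.assert_allclose(back.x2, traj.x2)
        np.testing.assert_allclose(back.x1, traj.x1)

    def test_dose_schedule_csv_round_trip(self, tmp_path):
        sched = DoseSchedule.daily([50.0, 80.0, 110.0])
        path = tmp_path / "doses.csv"
        sched.to_csv(path)
        back = DoseSchedule.from_csv(path)
        np.testing.assert_allclose(back.times_h, sched.times_h)
        np.testing.assert_allclose(back.doses, sched.doses)
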