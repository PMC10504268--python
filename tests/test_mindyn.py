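"""Unit and property tests for the 1-d Min reaction-diffusion simulator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from minsize.mindyn import (Grid1D, MinFields, MinModelParams, detect_period,
                            initialize_fields, rhs, simulate,
                            time_average_profile)


class TestInitializeFields:
    def test_zero_perturbation_is_mirror_symmetric_with_exact_totals(self):
        params = MinModelParams()
        grid = Grid1D.for_length(4.0, dx=0.1)
        f = initialize_fields(params, grid, seed=0, perturbation=0.0)
        for arr in (f.c_DD, f.c_DT, f.c_E):
            assert np.array_equal(arr, arr[::-1])
        assert f.total_D(grid.dx) == pytest.approx(params.dens_D * grid.L,
                                                   rel=1e-14)
        assert f.total_E(grid.dx) == pytest.approx(params.dens_E * grid.L,
                                                   rel=1e-14)

    def test_same_seed_bit_identical(self):
        params = MinModelParams()
        grid = Grid1D.for_length(3.0, dx=0.05)
        a = initialize_fields(params, grid, seed=11, perturbation=0.01)
        b = initialize_fields(params, grid, seed=11, perturbation=0.01)
        assert np.array_equal(a.stack(), b.stack())

    def test_perturbed_totals_conserved_to_machine_precision(self):
        params = MinModelParams()
        grid = Grid1D.for_length(5.0, dx=0.05)
        f = initialize_fields(params, grid, seed=3, perturbation=0.01)
        assert abs(f.total_D(grid.dx) - params.dens_D * grid.L) < 1e-9
        assert not np.array_equal(f.c_DT, f.c_DT[::-1])   # asymmetric kick

    def test_invalid_perturbation_rejected(self):
        with pytest.raises(ValueError):
            initialize_fields(MinModelParams(), Grid1D.for_length(4.0),
                              seed=0, perturbation=1.5)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            MinModelParams(dens_D=-5.0)
        with pytest.raises(ValueError):
            MinModelParams(dens_E=0.0)


class TestRhs:
    def test_no_reaction_channels_gives_zero_derivative(self):
        params = MinModelParams(k_exchange=0.0, sigma_D=0.0)
        grid = Grid1D.for_length(4.0, dx=0.1)
        f = initialize_fields(params, grid, seed=0, perturbation=0.0)
        d = rhs(f, params, grid)
        assert np.allclose(d.stack(), 0.0, atol=1e-12)

    def test_reactions_conserve_both_totals(self, rng):
        params = MinModelParams()
        grid = Grid1D.for_length(4.0, dx=0.1)
        y = rng.uniform(0.0, 300.0, size=(5, grid.n_x))
        d = rhs(MinFields.from_stack(y), params, grid)
        dD = (d.c_DD + d.c_DT + d.m_d + d.m_de).sum() * grid.dx
        dE = (d.c_E + d.m_de).sum() * grid.dx
        scale = params.dens_D * grid.L
        assert abs(dD) < 1e-9 * scale
        assert abs(dE) < 1e-9 * scale

    def test_single_interval_matches_hand_computed_mass_action(self):
        """On a 1-cell grid the derivative is the bare mass-action system."""
        p = MinModelParams()
        grid = Grid1D(L=1.0, n_x=1)
        cDD, cDT, cE, md, mde = 120.0, 310.0, 140.0, 55.0, 30.0
        f = MinFields(*(np.array([v]) for v in (cDD, cDT, cE, md, mde)))
        d = rhs(f, p, grid)
        bind = (p.sigma_D + p.sigma_dD * (md + mde)) * cDT
        hyd = p.sigma_E * md * cE
        rel = p.sigma_de * mde
        exch = p.k_exchange * cDD
        assert d.c_DD[0] == pytest.approx(-exch + rel, rel=1e-14)
        assert d.c_DT[0] == pytest.approx(exch - bind, rel=1e-14)
        assert d.c_E[0] == pytest.approx(-hyd + rel, rel=1e-14)
        assert d.m_d[0] == pytest.approx(bind - hyd, rel=1e-14)
        assert d.m_de[0] == pytest.approx(hyd - rel, rel=1e-14)


class TestSimulate:
    def test_absorbing_state_stays_static(self):
        params = MinModelParams(k_exchange=0.0, sigma_D=0.0)
        grid = Grid1D.for_length(4.0, dx=0.1)
        out = simulate(params, grid, t_end=20.0, seed=0, perturbation=0.0)
        assert np.allclose(out.midcell_signal, 0.0, atol=1e-12)
        assert np.allclose(out.membrane_occupancy, 0.0, atol=1e-12)

    def test_mirror_symmetric_start_stays_symmetric(self):
        """A symmetric bump must evolve symmetrically (equations commute
        with the mirror); asymmetry can only come from roundoff."""
        params = MinModelParams()
        grid = Grid1D.for_length(4.0, dx=0.1)
        f = initialize_fields(params, grid, seed=0, perturbation=0.0)
        bump = 1.0 + 0.2 * np.exp(-0.5 * ((grid.x - grid.L / 2) / 0.4) ** 2)
        f.c_DT[:] = f.c_DT * bump
        f.c_DD[:] = params.dens_D - f.c_DT
        out = simulate(params, grid, t_end=200.0, fields=f)
        u = out.membrane_occupancy
        denom = max(np.abs(u).max(), 1e-30)
        asym = np.abs(u - u[:, ::-1]).max() / denom
        assert asym <= 1e-8

    def test_conservation_and_positivity(self, wt_sim_600s):
        out = wt_sim_600s
        assert out.conservation_drift <= 1e-6
        assert out.membrane_occupancy.min() >= -1e-12 * out.params.dens_D

    def test_wild_type_oscillates_near_40s(self, wt_sim_600s):
        period = detect_period(wt_sim_600s.pole_signal, 1.0, burn_in=200.0)
        assert period is not None
        assert 20.0 <= period <= 80.0

    def test_period_grid_converged(self, wt_params):
        """Halving dx changes the detected period by < 2%."""
        periods = {}
        for dx in (0.1, 0.05):
            out = simulate(wt_params, Grid1D.for_length(4.0, dx=dx),
                           t_end=400.0, seed=0)
            periods[dx] = detect_period(out.pole_signal, 1.0, burn_in=200.0)
        assert periods[0.05] is not None and periods[0.1] is not None
        assert abs(periods[0.05] - periods[0.1]) / periods[0.05] < 0.02

    def test_split_integrator_agrees_with_rk4(self, wt_params):
        grid = Grid1D.for_length(3.0, dx=0.1)
        kw = dict(t_end=30.0, sample_dt=1.0, seed=0, perturbation=0.01)
        a = simulate(wt_params, grid, method="numpy", **kw)
        b = simulate(wt_params, grid, method="split", **kw)
        scale = np.abs(a.membrane_occupancy).max() + wt_params.dens_D
        assert np.abs(a.membrane_occupancy - b.membrane_occupancy).max() \
            / scale < 1e-3

    def test_invalid_run_arguments(self, wt_params):
        grid = Grid1D.for_length(4.0, dx=0.1)
        with pytest.raises(ValueError):
            simulate(wt_params, grid, t_end=0.0)
        with pytest.raises(ValueError):
            simulate(wt_params, grid, t_end=10.0, sample_dt=-1.0)


class TestReactionOnlyOracle:
    def test_integrator_matches_adaptive_ode_solution(self):
        """On a single-interval grid the PDE stepper reduces to the
        five-species mass-action ODE; compare against an independently
        coded adaptive (LSODA) solution."""
        p = MinModelParams()
        grid = Grid1D(L=1.0, n_x=1)
        y0 = np.array([200.0, 300.0, 150.0, 80.0, 55.0])

        def odes(_t, y):
            cDD, cDT, cE, md, mde = y
            bind = (p.sigma_D + p.sigma_dD * (md + mde)) * cDT
            hyd = p.sigma_E * md * cE
            rel = p.sigma_de * mde
            exch = p.k_exchange * cDD
            return [-exch + rel, exch - bind, -hyd + rel,
                    bind - hyd, hyd - rel]

        t_end = 20.0
        ref = solve_ivp(odes, (0.0, t_end), y0, method="LSODA",
                        rtol=1e-11, atol=1e-9).y[:, -1]
        fields = MinFields(*(np.array([v]) for v in y0))
        out = simulate(p, grid, t_end=t_end, sample_dt=1.0, fields=fields)
        got = out.final_fields.stack()[:, 0]
        assert np.abs(got - ref).max() / np.abs(ref).max() <= 1e-6


class TestDetectPeriod:
    def test_pure_sinusoid_recovered(self):
        t = np.arange(0.0, 400.0, 1.0)
        sig = 10.0 + np.sin(2 * np.pi * t / 40.0)
        period = detect_period(sig, 1.0, burn_in=50.0)
        assert period == pytest.approx(40.0, abs=1.0)

    def test_constant_signal_returns_none(self):
        assert detect_period(np.full(400, 7.0), 1.0, burn_in=50.0) is None

    def test_dominant_component_wins_over_weak_fast_one(self):
        t = np.arange(0.0, 400.0, 1.0)
        sig = 10.0 + np.sin(2 * np.pi * t / 40.0) \
            + 0.1 * np.sin(2 * np.pi * t / 13.0)
        period = detect_period(sig, 1.0, burn_in=50.0)
        assert period == pytest.approx(40.0, abs=1.0)

    def test_burn_in_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_period(np.ones(100), 1.0, burn_in=200.0)


class TestTimeAverageProfile:
    def test_static_output_average_equals_any_frame(self):
        params = MinModelParams(k_exchange=0.0, sigma_D=0.0)
        grid = Grid1D.for_length(4.0, dx=0.1)
        out = simulate(params, grid, t_end=20.0, seed=0, perturbation=0.0)
        avg = time_average_profile(out, burn_in=5.0)
        assert np.allclose(avg, out.membrane_occupancy[-1], atol=1e-12)

    def test_symmetric_dynamics_average_is_symmetric(self, wt_params):
        grid = Grid1D.for_length(4.0, dx=0.1)
        f = initialize_fields(wt_params, grid, seed=0, perturbation=0.0)
        out = simulate(wt_params, grid, t_end=100.0, fields=f)
        avg = time_average_profile(out, burn_in=10.0)
        assert np.abs(avg - avg[::-1]).max() <= 1e-8 * np.abs(avg).max() + 1e-12

    def test_polar_gradient_at_wild_type(self, wt_sim_600s):
        """Time-averaged membrane occupancy is maximal at the poles and
        depleted around mid-cell in an oscillating wild-type cell."""
        avg = time_average_profile(wt_sim_600s, burn_in=200.0)
        n = len(avg)
        outer = max(avg[:n // 5].max(), avg[-(n // 5):].max())
        central = avg[2 * n // 5: 3 * n // 5 + 1].mean()
        assert central < outer
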