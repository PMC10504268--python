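"""Tests for induction kinetics, dose-response fitting and the
generational size recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minsize.sizemodel import (DoseResponseParams, FitFailure, GrowthParams,
                               InductionParams, dose_response,
                               fit_dose_response, minE_at, ratio_trajectory,
                               run_generations, sister_delta, time_to_ring)

FIG2 = DoseResponseParams()      # printed dose-response constants


class TestInductionSigmoid:
    def test_midpoint_identity(self):
        p = InductionParams(minE_initial=1.0, minE_final=5.0, t_c=10.0, t_s=2.0)
        assert minE_at(10.0, p) == pytest.approx(3.0, rel=1e-14)

    def test_plateau_limit(self):
        p = InductionParams(minE_initial=1.0, minE_final=5.0, t_c=10.0, t_s=2.0)
        assert minE_at(10.0 + 50 * 2.0, p) == pytest.approx(5.0, abs=1e-9)

    def test_one_timescale_past_midpoint(self):
        p = InductionParams(minE_initial=2.0, minE_final=6.0, t_c=3.0, t_s=1.5)
        expected = 2.0 + 4.0 / (1.0 + math.exp(-1.0))
        assert minE_at(3.0 + 1.5, p) == pytest.approx(expected, rel=1e-14)

    def test_ratio_trajectory_baseline_and_midpoint(self):
        p = InductionParams(minE_initial=1.0, minE_final=3.0, t_c=5.0, t_s=1.0)
        r = ratio_trajectory(p, minD_const=10.0, times=[-50.0, 5.0])
        assert r[0] == pytest.approx(1.0, abs=1e-9)
        assert r[1] == pytest.approx(2.0, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 40), min_size=2, max_size=20))
    def test_ratio_trajectory_monotone(self, times):
        p = InductionParams(minE_initial=1.0, minE_final=4.0, t_c=6.0, t_s=2.0)
        r = ratio_trajectory(p, 1.0, np.sort(np.asarray(times)))
        assert np.all(np.diff(r) >= -1e-12)

    def test_zero_initial_rejected(self):
        p = InductionParams(minE_initial=0.0, minE_final=1.0, t_c=1.0, t_s=1.0)
        with pytest.raises(ValueError):
            ratio_trajectory(p, 1.0, [0.0])


class TestDoseResponse:
    def test_value_at_inflection(self):
        # offset + amplitude/2 with the printed constants
        assert dose_response(0.182, FIG2) == pytest.approx(
            2.878 + 179.63 / 2.0, rel=1e-12)

    def test_value_at_zero_concentration(self):
        expected = 2.878 + 179.63 / (1.0 + math.exp(0.182 / 0.158))
        assert dose_response(0.0, FIG2) == pytest.approx(expected, rel=1e-12)

    def test_zero_amplitude_is_flat(self):
        p = DoseResponseParams(offset=3.0, amplitude=0.0, inflection=0.2,
                               scale=0.1)
        c = np.linspace(0, 1, 7)
        assert np.allclose(dose_response(c, p), 3.0)

    def test_strictly_increasing(self):
        c = np.linspace(0.0, 1.0, 50)
        assert np.all(np.diff(dose_response(c, FIG2)) > 0)


class TestFitDoseResponse:
    def test_noiseless_roundtrip_recovers_printed_constants(self):
        c = np.linspace(0.0, 1.0, 8)
        pts = np.column_stack([c, dose_response(c, FIG2)])
        fit, diag = fit_dose_response(pts)
        assert fit.amplitude == pytest.approx(FIG2.amplitude, rel=1e-6)
        assert fit.inflection == pytest.approx(FIG2.inflection, rel=1e-6)
        assert fit.offset == pytest.approx(FIG2.offset, rel=1e-4)
        assert fit.scale == pytest.approx(FIG2.scale, rel=1e-6)
        assert not diag["unidentifiable"]

    def test_flat_data_flagged_unidentifiable(self):
        c = np.linspace(0.0, 1.0, 8)
        pts = np.column_stack([c, np.full(8, 5.0)])
        fit, diag = fit_dose_response(pts)
        assert abs(fit.amplitude) < 1e-6
        assert diag["unidentifiable"]

    def test_noisy_coverage_of_generating_parameters(self):
        """With sigma = 2 noise the generating amplitude/inflection fall
        within 3 reported standard errors in >= 95% of replicates."""
        c = np.linspace(0.0, 1.0, 12)
        truth = dose_response(c, FIG2)
        hits = 0
        n_rep = 100
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            pts = np.column_stack([c, truth + rng.normal(0, 2.0, c.size)])
            try:
                fit, diag = fit_dose_response(pts)
            except FitFailure:
                continue
            se = diag["stderr"]
            ok = (abs(fit.amplitude - FIG2.amplitude) <= 3 * se["amplitude"]
                  and abs(fit.inflection - FIG2.inflection) <= 3 * se["inflection"])
            hits += ok
        assert hits >= 0.95 * n_rep

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([(0.0, 1.0), (0.1, 2.0), (0.2, 3.0)])


class TestTimeToRing:
    def test_already_at_stable_length(self):
        assert time_to_ring(3.0, 3.0, 0.02) == 0.0

    def test_doubling(self):
        assert time_to_ring(2.0, 4.0, math.log(2)) == pytest.approx(1.0,
                                                                    rel=1e-12)

    def test_clamped_when_past_stable(self):
        assert time_to_ring(5.0, 3.0, 0.02) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            time_to_ring(-1.0, 3.0, 0.02)
        with pytest.raises(ValueError):
            time_to_ring(1.0, 3.0, 0.0)


class TestGenerationRecursion:
    growth = GrowthParams(alpha=math.log(2) / 25.0, tau=18.0,
                          lopt_a=1.5, lopt_b=1.0)

    def test_fixed_point_is_stationary_with_doubling_cycle(self):
        g = self.growth
        L_fp = 0.5 * g.L_stable(1.0) * math.exp(g.alpha * g.tau)
        traj = run_generations(6, g, induction=None, L_0_init=L_fp)
        assert np.allclose(traj.L_0, L_fp, rtol=1e-12)
        assert np.allclose(traj.cycle_time, math.log(2) / g.alpha, rtol=1e-12)
        # alpha * (T_z + tau) = ln 2 at steady state
        assert g.alpha * (traj.T_z[0] + g.tau) == pytest.approx(math.log(2),
                                                                abs=1e-12)

    def test_fixed_point_reached_in_one_generation(self):
        g = self.growth
        L_fp = 0.5 * g.L_stable(1.0) * math.exp(g.alpha * g.tau)
        traj = run_generations(4, g, induction=None, L_0_init=0.6 * L_fp)
        assert traj.L_0[1] == pytest.approx(L_fp, rel=1e-12)
        assert np.allclose(traj.L_0[1:], L_fp, rtol=1e-12)

    def test_recursion_identity_holds_exactly(self):
        g = self.growth
        ind = InductionParams(minE_initial=1.0, minE_final=3.0, t_c=4.0,
                              t_s=1.5)
        traj = run_generations(15, g, induction=ind)
        for i in range(15):
            expected = 0.5 * traj.L_0[i] * math.exp(
                g.alpha * (traj.T_z[i] + g.tau))
            assert traj.L_0[i + 1] == pytest.approx(expected, rel=1e-12)
            if traj.T_z[i] > 0:
                alt = 0.5 * traj.L_stable[i] * math.exp(g.alpha * g.tau)
                assert traj.L_0[i + 1] == pytest.approx(alt, rel=1e-12)

    def test_induction_transient_rises_then_returns(self):
        """T_z spikes after induction and relaxes to baseline; birth length
        climbs monotonically to a higher plateau."""
        g = self.growth
        ind = InductionParams(minE_initial=1.0, minE_final=3.0, t_c=4.0,
                              t_s=1.0)
        traj = run_generations(25, g, induction=ind)
        # the uninduced steady state has alpha*(T_z + tau) = ln 2; the
        # sigmoid's nonzero offset at t = 0 puts T_z(0) slightly above it
        Tz_base = math.log(2) / g.alpha - g.tau
        assert traj.T_z[0] >= Tz_base
        assert traj.T_z.max() > traj.T_z[0]
        settled = traj.ratio_rel >= 0.99 * 3.0
        assert settled.any()
        assert np.allclose(traj.T_z[-3:], Tz_base, rtol=0.01)
        assert np.all(np.diff(traj.L_0) >= -1e-12)
        assert traj.L_0[-1] > traj.L_0[0]

    def test_constant_ratio_with_zero_amplitude_induction(self):
        g = self.growth
        ind = InductionParams(minE_initial=2.0, minE_final=2.0, t_c=4.0,
                              t_s=1.0)
        traj = run_generations(8, g, induction=ind)
        assert np.allclose(traj.ratio_rel, 1.0, rtol=1e-12)
        assert np.allclose(traj.T_z[1:], traj.T_z[1], rtol=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            run_generations(0, self.growth)
        with pytest.raises(ValueError):
            run_generations(3, self.growth, L_0_init=-1.0)


class TestSisterDelta:
    growth = GrowthParams(alpha=math.log(2) / 25.0, tau=18.0,
                          lopt_a=1.5, lopt_b=1.0)

    def test_symmetric_division_equal_deltas(self):
        dA, dB = sister_delta(0.5, 4.0, self.growth)
        assert dA == pytest.approx(dB, rel=1e-14)

    def test_closed_form_difference(self):
        # f_A - f_B = 0.2 with a 5 um mother -> Delta_A - Delta_B = -1 um
        dA, dB = sister_delta(0.6, 5.0, self.growth)
        assert dA - dB == pytest.approx(-1.0, rel=1e-12)

    def test_slope_over_pair_set_is_minus_mother_length(self):
        L_m = 4.2
        fs = np.linspace(0.3, 0.7, 9)
        diffs = [np.subtract(*sister_delta(f, L_m, self.growth)) for f in fs]
        slope = np.polyfit(2 * fs - 1.0, diffs, 1)[0]
        assert slope == pytest.approx(-L_m, rel=1e-10)

    def test_matches_generation_recursion_per_sister(self):
        """Each sister run through the recursion adds the same length the
        closed form predicts (oracle equivalence)."""
        g = self.growth
        L_m = 4.0
        for f in (0.4, 0.55):
            S0 = f * L_m
            traj = run_generations(1, g, induction=None, L_0_init=S0)
            S_div = S0 * math.exp(g.alpha * traj.cycle_time[0])
            dA, _ = sister_delta(f, L_m, g)
            assert S_div - S0 == pytest.approx(dA, rel=1e-12)
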