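"""Rate terms and the forward-Euler simulator: limits, invariants, oracle."""

import math

import numpy as np
import pytest

import fracrad as fr
from fracrad.dynamics import late_grid


@pytest.fixture(scope="module")
def rad_params():
    return fr.default_truth().cell_lines["9L"].radiation


class TestUntreatedGrowth:
    def test_fixed_point_at_carrying_capacity(self, growth_9l):
        assert fr.untreated_rhs(growth_9l.theta, growth_9l) == 0.0

    def test_zero_proliferation_rate(self):
        growth = fr.GrowthParams(k_p=0.0, theta=0.9, A=1.0)
        for n in [0.0, 0.1, 0.5, 0.9]:
            assert fr.untreated_rhs(n, growth) == 0.0

    def test_half_capacity_without_allee(self):
        growth = fr.GrowthParams(k_p=0.04, theta=0.8, A=0.0)
        expected = 0.04 * growth.theta / 8
        assert fr.untreated_rhs(growth.theta / 2, growth) == pytest.approx(expected)


class TestDeathRates:
    def test_inactive_forms_give_zero(self, kinetics):
        spec4 = fr.model_family()[3]  # no early death
        params = fr.RadiationParams(
            alpha_accum_N=1.0, k_accum_D=1e-4, r=0.02, k_ps={16.0: 0.0, 20.0: 0.0}
        )
        sched = fr.get_schedule("16x2")
        assert fr.early_death_rate(30.0, spec4, params, sched, 0.1, kinetics) == 0.0
        spec3 = fr.model_family()[2]
        zero = fr.RadiationParams(
            k_acute_N=0.0, alpha_accum_N=1.0, k_accum_D=1e-4, r=0.02,
            k_ps={16.0: 0.0, 20.0: 0.0},
        )
        for t in [0.0, 10.0, 50.0]:
            assert fr.early_death_rate(t, spec3, zero, sched, 0.1, kinetics) == 0.0

    def test_single_fraction_early_death_hand_value(self):
        """One fraction at t=0 with 20% DSBs left at 24 h: the rate is
        k_acute_N * N0 * 0.2 * tanh(0.2)."""
        k_rep = math.log(5) / 24.0  # f_DSB(24) = 0.2 exactly
        kin = fr.RepairKinetics((4.0, 8.0), (k_rep, k_rep))
        sched = fr.DoseSchedule((0.0,), 8.0, 8.0, "single")
        spec3 = fr.model_family((8.0,))[2]
        params = fr.RadiationParams(
            k_acute_N=0.25, alpha_accum_N=1.0, k_accum_D=1e-4, r=0.02,
            k_ps={8.0: 0.0},
        )
        got = fr.early_death_rate(24.0, spec3, params, sched, 0.1, kin)
        assert got == pytest.approx(0.25 * 0.1 * 0.2 * math.tanh(0.2), rel=1e-12)

    def test_late_death_zero_at_delivery(self, rad_params):
        sched = fr.DoseSchedule((0.0,), 8.0, 8.0, "single")
        spec = fr.model_family((8.0,))[0]
        params = fr.RadiationParams(
            alpha_acute_N=1.0, k_acute_D=1e-3, alpha_accum_N=1.0, k_accum_D=2e-4,
            r=0.02, k_ps={8.0: 0.0},
        )
        assert fr.late_death_rate(0.0, spec, params, sched, 0.1) == 0.0

    def test_late_death_peaks_at_inverse_decay_rate(self):
        """Grid-search oracle: single-fraction late death is maximal at t = 1/r."""
        sched = fr.DoseSchedule((0.0,), 8.0, 8.0, "single")
        spec = fr.model_family((8.0,))[0]
        r = 0.025
        params = fr.RadiationParams(
            alpha_acute_N=0.0, k_acute_D=0.0, alpha_accum_N=1.0, k_accum_D=2e-4,
            r=r, k_ps={8.0: 0.0},
        )
        ts = np.linspace(0.0, 300.0, 6001)
        vals = [fr.late_death_rate(t, spec, params, sched, 0.1) for t in ts]
        assert ts[int(np.argmax(vals))] == pytest.approx(1.0 / r, abs=0.1)

    def test_plus_one_convention_at_zero_density_scale(self):
        """alpha_accum_N = 0 leaves the pure dose term k_accum_D * D * sum."""
        sched = fr.get_schedule("16x2")
        spec = fr.model_family()[0]
        params = fr.RadiationParams(
            alpha_acute_N=0.0, k_acute_D=0.0, alpha_accum_N=0.0, k_accum_D=2e-4,
            r=0.02, k_ps={16.0: 0.0, 20.0: 0.0},
        )
        t = 60.0
        direct = sum(
            2e-4 * 8.0 * (t - ft) * math.exp(-0.02 * (t - ft))
            for ft in sched.fraction_times
            if t > ft
        )
        assert fr.late_death_rate(t, spec, params, sched, 0.2) == pytest.approx(direct)

    def test_death_rate_time_courses_have_expected_shape(self, kinetics, rad_params):
        """Early death is maximal right after delivery and decays; late death
        starts at zero, peaks near 1/r, then decays."""
        sched = fr.DoseSchedule((0.0,), 8.0, 8.0, "single")
        spec = fr.model_family((8.0,))[0]
        params = fr.RadiationParams(
            alpha_acute_N=1.0, k_acute_D=1e-3, alpha_accum_N=1.0, k_accum_D=2e-4,
            r=0.02, k_ps={8.0: 0.0},
        )
        ts = np.linspace(0.0, 300.0, 601)
        early = np.array(
            [fr.early_death_rate(t, spec, params, sched, 0.1, kinetics) for t in ts]
        )
        late = np.array([fr.late_death_rate(t, spec, params, sched, 0.1) for t in ts])
        assert early.argmax() == 0 and np.all(np.diff(early) <= 1e-15)
        assert late[0] == 0.0
        peak = late.argmax()
        assert 0 < peak < len(ts) - 1
        assert ts[peak] == pytest.approx(1.0 / 0.02, abs=1.0)
        assert np.all(np.diff(late[peak:]) <= 1e-15)


class TestTreatedRhs:
    def test_zero_radiation_reduces_to_untreated_growth(self, growth_9l, kinetics):
        spec = fr.model_family()[0]
        zero = fr.RadiationParams(
            alpha_acute_N=0.0, k_acute_D=0.0, alpha_accum_N=0.0, k_accum_D=0.0,
            r=0.02, k_ps={16.0: 0.0, 20.0: 0.0},
        )
        sched = fr.get_schedule("16x2")
        for n in [0.05, 0.3, 0.7]:
            dnp, dns = fr.treated_rhs(
                (n, 0.0), 40.0, spec, growth_9l, zero, sched, 0.1, kinetics
            )
            assert dnp == pytest.approx(fr.untreated_rhs(n, growth_9l), rel=1e-12)
            assert dns == 0.0

    def test_pure_conversion_conserves_total(self, kinetics):
        growth = fr.GrowthParams(k_p=0.0, theta=0.9, A=1.0)
        spec = fr.model_family()[2]
        params = fr.RadiationParams(
            k_acute_N=0.0, alpha_accum_N=0.0, k_accum_D=0.0, r=0.02,
            k_ps={16.0: 0.05, 20.0: 0.05},
        )
        sched = fr.get_schedule("16x2")
        dnp, dns = fr.treated_rhs(
            (0.2, 0.1), 30.0, spec, growth, params, sched, 0.2, kinetics
        )
        assert dnp + dns == pytest.approx(0.0, abs=1e-15)
        assert dns > 0

    def test_saturated_population_only_dies(self, growth_9l, kinetics):
        """At N_p + N_s = theta the growth/late term vanishes:
        dN_p/dt = -(k_ed + k_ps N0) N_p."""
        spec = fr.model_family()[2]
        params = fr.RadiationParams(
            k_acute_N=0.3, alpha_accum_N=1.0, k_accum_D=2e-4, r=0.02,
            k_ps={16.0: 0.05, 20.0: 0.05},
        )
        sched = fr.get_schedule("16x2")
        n0, t = 0.2, 30.0
        n_p = growth_9l.theta - 0.1
        dnp, dns = fr.treated_rhs(
            (n_p, 0.1), t, spec, growth_9l, params, sched, n0, kinetics
        )
        k_ed = fr.early_death_rate(t, spec, params, sched, n0, kinetics)
        expected = -(k_ed + 0.05 * n0) * n_p
        assert dnp == pytest.approx(expected, rel=1e-12)


class TestSimulate:
    def test_without_growth_or_radiation_state_is_constant(self, kinetics):
        growth = fr.GrowthParams(k_p=0.0, theta=0.9, A=1.0)
        spec = fr.model_family()[2]
        params = fr.RadiationParams(
            k_acute_N=0.0, alpha_accum_N=0.0, k_accum_D=0.0, r=0.02,
            k_ps={16.0: 0.0, 20.0: 0.0},
        )
        traj = fr.simulate(
            spec, growth, params, fr.get_schedule("16x2"), 0.1, horizon=100,
            output_times=np.linspace(0, 100, 11), kinetics=kinetics,
        )
        np.testing.assert_allclose(traj.N_p, 0.1, rtol=1e-12)
        np.testing.assert_array_equal(traj.N_s, 0.0)

    def test_senescence_inactive_keeps_second_compartment_empty(
        self, growth_9l, kinetics, rad_params
    ):
        spec8 = fr.model_family()[7]
        traj = fr.simulate(
            spec8, growth_9l, rad_params, fr.get_schedule("20x2"), 0.1,
            horizon=200, output_times=np.linspace(0, 200, 21), kinetics=kinetics,
        )
        np.testing.assert_array_equal(traj.N_s, 0.0)

    def test_nonnegative_bounded_and_monotone_senescence(self, kinetics, rng):
        """Random admissible parameters: state stays in [0, theta(1+eps)] and
        the senescent compartment never shrinks."""
        fam = fr.model_family((16.0, 20.0))
        for i in range(12):
            spec = fam[i % 8]
            growth = fr.GrowthParams(
                k_p=rng.uniform(0.01, 0.05),
                theta=rng.uniform(0.5, 1.0),
                A=rng.uniform(0.0, 2.0),
            )
            params = fr.RadiationParams(
                alpha_acute_N=rng.uniform(0, 5),
                k_acute_D=rng.uniform(0, 5e-3),
                k_acute_N=rng.uniform(0, 0.5),
                alpha_accum_N=rng.uniform(0, 5),
                k_accum_D=rng.uniform(0, 4e-4),
                k_accum_N=rng.uniform(0, 0.04),
                r=rng.uniform(5e-3, 0.05),
                k_ps={16.0: rng.uniform(0, 0.1), 20.0: rng.uniform(0, 0.1)},
            )
            sched = fr.get_schedule(list(fr.SCHEDULE_PRESETS)[i % 6])
            n0 = rng.uniform(0.03, 0.3) * growth.theta
            traj = fr.simulate(
                spec, growth, params, sched, n0, horizon=330,
                output_times=np.linspace(0, 330, 67), kinetics=kinetics, dt=0.01,
            )
            eps = 10 * 0.01 * growth.k_p
            assert np.all(traj.N_p >= 0) and np.all(traj.N_s >= 0)
            assert np.all(traj.N_total <= growth.theta * (1 + eps) + 1e-12)
            assert np.all(np.diff(traj.N_s) >= -1e-15)

    def test_early_exponential_growth_slope(self, kinetics):
        """With A=1, no radiation and N0 << theta, log N grows at rate k_p."""
        growth = fr.GrowthParams(k_p=0.03, theta=0.9, A=1.0)
        spec = fr.model_family()[2]
        zero = fr.RadiationParams(
            k_acute_N=0.0, alpha_accum_N=0.0, k_accum_D=0.0, r=0.02,
            k_ps={16.0: 0.0, 20.0: 0.0},
        )
        ts = np.linspace(0, 200, 201)
        traj = fr.simulate(
            spec, growth, zero, fr.get_schedule("16x2"), 1e-3, horizon=200,
            output_times=ts, kinetics=kinetics,
        )
        window = traj.N_p < 0.05 * growth.theta
        slope = np.polyfit(ts[window], np.log(traj.N_p[window]), 1)[0]
        assert slope == pytest.approx(growth.k_p, rel=0.02)

    def test_euler_agrees_with_adaptive_integrator(self, growth_9l, kinetics,
                                                   rad_params):
        ts = np.linspace(0, 330, 34)
        for sched_name in ("16x4", "20x2"):
            sched = fr.get_schedule(sched_name)
            eul = fr.simulate(
                fr.model_family()[2], growth_9l, rad_params, sched, 0.1,
                horizon=330, dt=0.01, output_times=ts, kinetics=kinetics,
            )
            ref = fr.simulate_reference(
                fr.model_family()[2], growth_9l, rad_params, sched, 0.1, ts,
                kinetics=kinetics,
            )
            err = np.max(np.abs(eul.N_total - ref.N_total)) / np.max(ref.N_total)
            assert err < 5e-3

    def test_bad_arguments_rejected(self, growth_9l, kinetics, rad_params):
        spec = fr.model_family()[2]
        sched = fr.get_schedule("16x2")
        with pytest.raises(ValueError):
            fr.simulate(spec, growth_9l, rad_params, sched, 0.0, horizon=100,
                        kinetics=kinetics)
        with pytest.raises(ValueError):
            fr.simulate(spec, growth_9l, rad_params, sched, 0.1, horizon=50,
                        output_times=np.array([0.0, 100.0]), kinetics=kinetics)


def test_late_grid_matches_scalar_rate(kinetics):
    """The vectorized late-death grid equals the scalar rate function."""
    sched = fr.get_schedule("20x3")
    spec = fr.model_family()[0]
    params = fr.RadiationParams(
        alpha_acute_N=0.0, k_acute_D=0.0, alpha_accum_N=2.0, k_accum_D=2e-4,
        r=0.03, k_ps={16.0: 0.0, 20.0: 0.0},
    )
    from fracrad.dynamics import accum_coefficient, death_rate_grids

    dt = 0.5
    n_steps = 400
    _, ti = death_rate_grids(sched, kinetics, n_steps, dt)
    coeff = accum_coefficient(spec, params, sched.dose_per_fraction, 0.15)
    grid = coeff * late_grid(ti, params.r)
    for k in [0, 10, 47, 120, 399]:
        scalar = fr.late_death_rate(k * dt, spec, params, sched, 0.15)
        assert grid[k] == pytest.approx(scalar, rel=1e-12, abs=1e-15)
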