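"""Core dynamics: logistic homeostasis, pulse limits, bookkeeping and
cross-integrator agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secancer.model_core import (
    CellState,
    ChemoCourse,
    ConcurrentCourse,
    OrganParams,
    RadiationCourse,
    RiskEstimate,
    Trajectory,
    chemo_rhs,
    concurrent_rhs,
    dose_response_curve,
    relative_risk,
    risk,
    rt_rhs,
    simulate_course,
)


class TestRhs:
    def test_homeostatic_fixed_point(self, lung):
        """At n = N, m = 0 and no pulse, the system does not move."""
        dn, dm = rt_rhs(CellState(0.5, lung.N, 0.0), lung, RadiationCourse(5))
        assert dn == 0.0 and dm == 0.0

    def test_logistic_growth_off_pulse(self, lung):
        dn, dm = rt_rhs(CellState(0.5, lung.N / 2, 10.0), lung, RadiationCourse(5))
        assert dn == pytest.approx(0.4 * (lung.N / 2) * 0.5)
        assert dm == pytest.approx(lung.r * 0.4 * 10.0 * 0.5)

    def test_on_pulse_kill_and_mutation_flux(self, lung):
        course = RadiationCourse(1, tau=1.0)
        s = CellState(1e-5, lung.N, 5.0)  # inside the 1-minute pulse at t=0
        dn, dm = rt_rhs(s, lung, course)
        rate = course.d_R / (course.tau / 1440.0)
        assert dn == pytest.approx(-(lung.alpha_R + lung.gamma_R) * rate * lung.N)
        assert dm == pytest.approx(
            -lung.alpha_R * rate * 5.0 + lung.gamma_R * rate * lung.N
        )

    def test_chemo_kill_decays_with_cycle_clock(self, lung):
        """One clearance time into a cycle the kill is e^-1 of its start."""
        course = ChemoCourse(1)
        k0, _ = _chemo_kill(lung, course, t=0.0)
        k1, _ = _chemo_kill(lung, course, t=1.0 / lung.alpha_d)
        assert k1 / k0 == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_mutation_flux_conserved_between_compartments(self, lung):
        """With no kill, whatever mutation takes from n appears in m."""
        p = lung.with_updates(alpha_C=0.0)
        dn, dm = chemo_rhs(CellState(1.0, p.N, 0.0), p, ChemoCourse(1))
        growth = 0.0  # n = N
        assert dm > 0
        assert dn + dm == pytest.approx(growth, abs=1e-12)

    def test_negative_state_rejected(self, lung):
        with pytest.raises(ValueError, match="negative"):
            rt_rhs(CellState(0.0, -1.0, 0.0), lung, RadiationCourse(1))
        with pytest.raises(ValueError, match="negative"):
            chemo_rhs(CellState(0.0, 1.0, -2.0), lung, ChemoCourse(1))

    def test_concurrent_rhs_superposition_without_interaction(self, lung):
        """epsilon-neutral concurrent derivative = RT + chemo - logistic."""
        rt = RadiationCourse(2)
        ch = ChemoCourse(2)
        conc = ConcurrentCourse(rt, ch, epsilon=1.0)
        s = CellState(0.2, 0.7 * lung.N, 3.0)  # off-pulse, inside cycle 1
        dn_c, dm_c = concurrent_rhs(s, lung, conc)
        dn_r, dm_r = rt_rhs(s, lung, rt)
        dn_ch, dm_ch = chemo_rhs(s, lung, ch)
        growth_n = lung.lam * s.n * (1 - s.n / lung.N)
        growth_m = lung.r * lung.lam * s.m * (1 - s.n / lung.N)
        assert dn_c == pytest.approx(dn_r + dn_ch - growth_n, rel=1e-12)
        assert dm_c == pytest.approx(dm_r + dm_ch - growth_m, rel=1e-12)


def _chemo_kill(params, course, t):
    """Kill hazard probe via the public rhs (m-compartment, zero growth)."""
    s = CellState(t, params.N, 1.0)
    dn, dm = chemo_rhs(s, params, course)
    mut = params.gamma_C * course.d_C / course.cycle_length
    kill = -(dm - mut * params.N)  # m = 1, growth term vanishes at n = N
    return kill, mut


class TestSimulate:
    def test_untreated_tissue_is_stationary(self, lung):
        traj = simulate_course(lung, ChemoCourse(0), t_end=365.0)
        assert np.all(traj.n == lung.N)
        assert np.all(traj.m == 0.0)

    def test_untreated_recovery_follows_logistic_closed_form(self, lung):
        n0 = lung.N / 2
        traj = simulate_course(
            lung, ChemoCourse(0), t_end=10.0, initial=CellState(0.0, n0, 0.0)
        )
        expected = lung.N / (1.0 + math.exp(-lung.lam * 10.0))
        assert traj.n[-1] == pytest.approx(expected, rel=1e-9)

    def test_single_fraction_impulse_yield(self, lung):
        """A 2 Gy impulse converts ~ gamma_R * d * N cells, reduced by the
        same pulse's kill; the finite-pulse integration agrees."""
        course = RadiationCourse(1)
        traj = simulate_course(lung, course, regrow=False)
        m_post = traj.m[1]  # state right after the fraction
        first_order = lung.gamma_R * 2.0 * lung.N  # = 2 premalignant cells
        assert m_post == pytest.approx(first_order * math.exp(-0.36), rel=1e-9)
        assert m_post == pytest.approx(first_order, rel=0.5)
        fine = simulate_course(lung, course, regrow=False, mode="continuous")
        assert fine.m[-1] == pytest.approx(traj.m[-1], rel=1e-4)
        assert fine.n[-1] == pytest.approx(traj.n[-1], rel=1e-4)

    @pytest.mark.parametrize("organ_name", ["breast", "lung", "thyroid"])
    @pytest.mark.parametrize(
        "course",
        [
            RadiationCourse(20),
            ChemoCourse(3),
            ConcurrentCourse(RadiationCourse(10), ChemoCourse(3), epsilon=2.6),
        ],
        ids=["rt", "chemo", "concurrent"],
    )
    def test_impulse_map_matches_finite_pulse_integration(self, organs, organ_name, course):
        """Discrete per-fraction map vs 1-minute pulse ODE: < 0.5% on M."""
        p = organs[organ_name]
        m_map = risk(p, simulate_course(p, course, mode="discrete")).M
        m_ode = risk(p, simulate_course(p, course, mode="continuous")).M
        assert m_ode == pytest.approx(m_map, rel=5e-3)

    def test_t_end_before_course_rejected(self, lung):
        with pytest.raises(ValueError, match="before the last treatment"):
            simulate_course(lung, ChemoCourse(3), t_end=10.0)

    def test_trajectory_strictly_increasing_and_exportable(self, lung):
        traj = simulate_course(lung, ChemoCourse(2))
        assert np.all(np.diff(traj.t) > 0)
        df = traj.to_frame()
        assert list(df.columns) == ["t", "n", "m", "event"]
        assert (df["event"] == "chemo_cycle_start").sum() >= 1

    def test_additivity_limit_is_exact(self, thyroid):
        """A concurrent course with one modality absent equals the
        single-modality model bit for bit."""
        rt = RadiationCourse(10)
        ch = ChemoCourse(5)
        m_rt = risk(thyroid, simulate_course(thyroid, rt)).M
        m_rt_conc = risk(
            thyroid,
            simulate_course(thyroid, ConcurrentCourse(rt, ChemoCourse(0), epsilon=2.6)),
        ).M
        assert m_rt_conc == m_rt
        m_ch = risk(thyroid, simulate_course(thyroid, ch)).M
        m_ch_conc = risk(
            thyroid,
            simulate_course(thyroid, ConcurrentCourse(RadiationCourse(0), ch, epsilon=2.6)),
        ).M
        assert m_ch_conc == m_ch

    def test_interaction_modes_reduce_risk(self, thyroid):
        """Any active interaction adds cell kill, so risk drops."""
        rt, ch = RadiationCourse(10), ChemoCourse(5)
        base = relative_risk(thyroid, ConcurrentCourse(rt, ch, epsilon=1.0)).RR
        mult = relative_risk(thyroid, ConcurrentCourse(rt, ch, epsilon=2.6)).RR
        extra = relative_risk(
            thyroid,
            ConcurrentCourse(rt, ch, epsilon=0.5, interaction_mode="extra_kill_rate"),
        ).RR
        assert mult < base
        assert extra < base


class TestRisk:
    def test_no_treatment_means_no_excess_risk(self, lung):
        est = relative_risk(lung, ChemoCourse(0))
        assert est.ERR == 0.0 and est.RR == 1.0

    def test_err_is_g_times_m(self, thyroid):
        traj = Trajectory([0.0, 1.0], [thyroid.N, thyroid.N], [0.0, 3.61])
        est = risk(thyroid, traj)
        assert est.M == pytest.approx(3.61)
        assert est.ERR == pytest.approx(thyroid.g * 3.61)
        assert est.RR == pytest.approx(1.0 + thyroid.g * 3.61)

    def test_rr_consistency_enforced(self):
        with pytest.raises(ValueError):
            RiskEstimate(ERR=1.0, RR=2.5, M=1.0, organ="lung")
        with pytest.raises(ValueError):
            RiskEstimate(ERR=-0.1, RR=0.9, M=0.0, organ="lung")

    def test_end_of_treatment_rule_gives_smaller_m(self, thyroid):
        traj = simulate_course(thyroid, RadiationCourse(10))
        plateau = risk(thyroid, traj, eval_rule="plateau").M
        end = risk(thyroid, traj, eval_rule="end_of_treatment").M
        assert end < plateau

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1.0, max_value=10.0))
    def test_err_monotone_in_mutation_induction(self, scale):
        """ERR never decreases when gamma_C grows, everything else fixed."""
        base = OrganParams(
            "custom", lam=0.4, r=0.8, N=1e6, alpha_C=0.2, gamma_C=1e-7, alpha_d=0.1333, g=1.0
        )
        course = ChemoCourse(3)
        low = relative_risk(base, course).ERR
        high = relative_risk(base.with_updates(gamma_C=scale * 1e-7), course).ERR
        assert high >= low
        assert low >= 0.0 and 1.0 + low >= 1.0


class TestDoseResponse:
    def test_zero_dose_means_zero_err(self, thyroid):
        curve = dose_response_curve(thyroid, [0.0, 10.0])
        assert curve["ERR"][0] == 0.0

    def test_thyroid_bell_shape(self, thyroid):
        """Cell kill (alpha_R = 0.25/Gy) eventually beats repopulation:
        the thyroid curve rises then falls, with one interior maximum."""
        curve = dose_response_curve(thyroid, np.arange(0.0, 41.0, 1.0))
        err = curve["ERR"].to_numpy()
        peak = int(np.argmax(err))
        assert 0 < peak < len(err) - 1
        d = np.diff(err)
        d = d[d != 0]
        assert int(np.sum(np.diff(np.sign(d)) != 0)) == 1

    def test_breast_monotone_over_therapeutic_doses(self, breast):
        curve = dose_response_curve(breast, np.arange(0.0, 31.0, 1.0))
        assert np.all(np.diff(curve["ERR"].to_numpy()) >= 0)

    def test_negative_dose_rejected(self, breast):
        with pytest.raises(ValueError):
            dose_response_curve(breast, [-1.0])


class TestValidation:
    def test_organ_params_invariants(self):
        with pytest.raises(ValueError):
            OrganParams(lam=0.0)
        with pytest.raises(ValueError):
            OrganParams(r=-0.5)
        with pytest.raises(ValueError):
            OrganParams(alpha_R=-0.1)
        with pytest.warns(UserWarning, match="rare outcome"):
            OrganParams(alpha_R=0.2, gamma_R=0.1)

    def test_course_invariants(self):
        with pytest.raises(ValueError):
            RadiationCourse(-1)
        with pytest.raises(ValueError):
            ChemoCourse(1, cycle_length=0.0)
        with pytest.raises(ValueError):
            ConcurrentCourse(RadiationCourse(1), ChemoCourse(1), epsilon=-1.0)
        with pytest.raises(ValueError):
            ConcurrentCourse(RadiationCourse(1), ChemoCourse(1), interaction_mode="bogus")
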