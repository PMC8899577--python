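"""Multi-site Langmuir kinetics: schedules, forward model, fits, selectivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from bclscreen.datasets import BCL2_KD_UM, BCLXL_KD_UM, MCL1_KD_UM
from bclscreen.exceptions import InputError
from bclscreen.sprkin import (
    InjectionSchedule,
    KineticParams,
    Sensorgram,
    build_schedule,
    fit_sensorgram,
    selectivity_index,
    simulate_sensorgram,
)


class TestSchedules:
    def test_faststep_preset_encodes_six_doubling_steps(self, faststep):
        assert len(faststep.segments) == 6
        concs = [c for _, _, c in faststep.segments]
        assert concs[0] == pytest.approx(0.625e-6)
        assert concs[-1] == pytest.approx(20e-6)
        for lo, hi in zip(concs, concs[1:]):
            assert hi == pytest.approx(2 * lo)
        t0, t1, c = faststep.segments[-1]
        assert (t1, c) == (165.0, 20e-6)
        assert faststep.t_end == 165.0

    @pytest.mark.parametrize(
        "include_low, n_cycles", [(False, 4), (True, 5)],
        ids=["bclxl", "mcl1_with_0.3uM"],
    )
    def test_titration_preset_cycle_count(self, include_low, n_cycles):
        sched = build_schedule(
            "titration_bclxl_mcl1", include_low_concentration=include_low
        )
        assoc = [(t0, t1, c) for t0, t1, c in sched.segments if c > 0]
        assert len(assoc) == n_cycles
        assert all(t1 - t0 == 180.0 for t0, t1, c in assoc)
        top = [c for _, _, c in assoc]
        assert top[-1] == pytest.approx(30e-6)
        if include_low:
            assert top[0] == pytest.approx(0.3e-6)

    def test_custom_single_segment(self):
        sched = build_schedule("custom", segments=((0.0, 100.0, 1e-6),))
        assert sched.segments == ((0.0, 100.0, 1e-6),)

    def test_non_contiguous_segments_rejected(self):
        with pytest.raises(InputError):
            InjectionSchedule(segments=((0.0, 30.0, 1e-6), (31.0, 60.0, 2e-6)))

    def test_overlapping_segments_rejected(self):
        with pytest.raises(InputError):
            InjectionSchedule(segments=((0.0, 30.0, 1e-6), (20.0, 60.0, 2e-6)))


class TestForwardModel:
    def test_constant_injection_reaches_langmuir_plateau(self):
        # C = KD held to steady state -> plateau Rmax/2
        ka, kd, rmax = 1e5, 0.01, 100.0
        kD = kd / ka
        sched = build_schedule(
            "custom", segments=((0.0, 5000.0, kD),), dissociation_s=0.0
        )
        sg = simulate_sensorgram(KineticParams((ka,), (kd,), (rmax,)), sched, 1.0)
        assert sg.response[-1] == pytest.approx(rmax / 2, rel=1e-6)
        # general isotherm at C = 3 KD
        sched3 = build_schedule(
            "custom", segments=((0.0, 5000.0, 3 * kD),), dissociation_s=0.0
        )
        sg3 = simulate_sensorgram(KineticParams((ka,), (kd,), (rmax,)), sched3, 1.0)
        assert sg3.response[-1] == pytest.approx(rmax * 3 / 4, rel=1e-6)

    def test_dissociation_phase_is_pure_exponential(self):
        ka, kd, rmax = 1e5, 0.02, 90.0
        sched = build_schedule(
            "custom", segments=((0.0, 600.0, 1e-5),), dissociation_s=200.0
        )
        sg = simulate_sensorgram(KineticParams((ka,), (kd,), (rmax,)), sched, 0.5)
        mask = sg.times >= 600.0
        t_rel = sg.times[mask] - 600.0
        r0 = sg.response[mask][0]
        np.testing.assert_allclose(sg.response[mask], r0 * np.exp(-kd * t_rel), rtol=1e-9)

    def test_two_site_response_is_superposition(self, faststep, two_site_params):
        p = two_site_params
        total = simulate_sensorgram(p, faststep, 1.0)
        parts = [
            simulate_sensorgram(
                KineticParams((p.ka[i],), (p.kd[i],), (p.rmax[i],)), faststep, 1.0
            )
            for i in range(2)
        ]
        np.testing.assert_allclose(
            total.response, parts[0].response + parts[1].response, rtol=1e-12
        )

    def test_analytic_solution_matches_ode_integration(self, faststep, two_site_params):
        """Independent oracle: integrate dR_i/dt numerically per segment."""
        p = two_site_params
        sg = simulate_sensorgram(p, faststep, 1.0)

        def rhs(t, r, conc):
            return [
                p.ka[i] * conc * (p.rmax[i] - r[i]) - p.kd[i] * r[i] for i in range(2)
            ]

        state = [0.0, 0.0]
        ode_resp = np.empty_like(sg.times)
        for t0, t1, conc in faststep.with_dissociation():
            mask = (sg.times >= t0) & (
                sg.times <= t1 if t1 >= faststep.total_time else sg.times < t1
            )
            t_eval = np.unique(np.append(sg.times[mask], t1))
            sol = solve_ivp(
                rhs,
                (t0, t1),
                state,
                t_eval=t_eval,
                args=(conc,),
                rtol=1e-11,
                atol=1e-13,
                method="LSODA",
            )
            vals = sol.y.sum(axis=0)
            ode_resp[mask] = vals[np.searchsorted(t_eval, sg.times[mask])]
            state = sol.y[:, -1]
        scale = np.max(np.abs(ode_resp))
        np.testing.assert_allclose(sg.response, ode_resp, atol=1e-6 * scale)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        log_ka=st.floats(3.5, 6.5),
        log_kd=st.floats(-3.5, -0.5),
        rmax=st.floats(5.0, 200.0),
    )
    def test_response_bounded_by_capacity(self, faststep, log_ka, log_kd, rmax):
        p = KineticParams((10**log_ka,), (10**log_kd,), (rmax,))
        sg = simulate_sensorgram(p, faststep, 2.0)
        assert np.all(sg.response >= -1e-9)
        assert np.all(sg.response <= rmax + 1e-9)

    def test_response_monotone_in_concentration_single_site(self):
        ka, kd, rmax = 1e5, 0.02, 90.0
        responses = []
        for conc in (0.5e-6, 1e-6, 2e-6, 4e-6):
            sched = build_schedule(
                "custom", segments=((0.0, 120.0, conc),), dissociation_s=0.0
            )
            sg = simulate_sensorgram(KineticParams((ka,), (kd,), (rmax,)), sched, 1.0)
            responses.append(sg.response[60])
        assert np.all(np.diff(responses) > 0)


class TestFitting:
    def test_noiseless_two_site_recovery_within_1pct(self, faststep, two_site_params):
        sg = simulate_sensorgram(two_site_params, faststep, 1.0)
        fit = fit_sensorgram(sg, faststep, n_sites=2)
        truth = two_site_params.sorted_by_affinity()
        for got, want in zip(
            fit.params.ka + fit.params.kd + fit.params.rmax,
            truth.ka + truth.kd + truth.rmax,
        ):
            assert got == pytest.approx(want, rel=0.01)
        assert fit.kd_report == pytest.approx(min(truth.kD), rel=0.01)
        # no spurious optimum: objective at the fit is no worse than at truth
        assert fit.rss <= 1e-6

    def test_one_site_truth_fitted_with_two_sites_keeps_kd1(self, faststep, one_site_params):
        import warnings

        sg = simulate_sensorgram(one_site_params, faststep, 1.0)
        with warnings.catch_warnings():
            # a degenerate second site is expected and warned about
            warnings.simplefilter("ignore")
            fit = fit_sensorgram(sg, faststep, n_sites=2)
        true_kd = one_site_params.kD[0]
        assert fit.kd_report == pytest.approx(true_kd, rel=0.05)

    def test_fit_is_deterministic_given_seed(self, faststep, two_site_params):
        sg = simulate_sensorgram(two_site_params, faststep, 1.0)
        f1 = fit_sensorgram(sg, faststep, n_sites=2, seed=9)
        f2 = fit_sensorgram(sg, faststep, n_sites=2, seed=9)
        assert f1.params == f2.params and f1.rss == f2.rss

    def test_too_few_points_rejected(self, faststep):
        with pytest.raises(InputError):
            fit_sensorgram(
                Sensorgram(np.arange(5.0), np.ones(5)), faststep, n_sites=1
            )


class TestSelectivity:
    def test_is21_selectivity_for_bcl2(self):
        """Measured KDs: Bcl-xL/Bcl-2 ~2.7-fold, Mcl-1/Bcl-2 ~6-fold."""
        si_xl = selectivity_index(BCL2_KD_UM["IS21"], BCLXL_KD_UM["IS21"])
        si_mcl1 = selectivity_index(BCL2_KD_UM["IS21"], MCL1_KD_UM["IS21"])
        assert round(si_xl, 1) == 2.7
        assert round(si_mcl1) == 6

    def test_is20_mcl1_selectivity(self):
        si = selectivity_index(BCL2_KD_UM["IS20"], MCL1_KD_UM["IS20"])
        assert round(si) == 12

    def test_equal_kds_give_unity(self):
        assert selectivity_index(0.5, 0.5) == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InputError):
            selectivity_index(0.0, 1.0)
        with pytest.raises(InputError):
            selectivity_index(1.0, -2.0)
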