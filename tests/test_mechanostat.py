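"""Mechanostat rate laws and forward-Euler surface evolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoadapt import beam, mechanostat
from osteoadapt.contours import ENDOSTEAL, PERIOSTEAL, circle_contour
from osteoadapt.mechanostat import (
    MechanostatError,
    MechanostatParams,
    SimulationSchedule,
    SimulationState,
    normalized_strain,
    simulate,
    step,
    surface_rate,
)

TBL_RATES = dict(k_pt=2.148, k_pc=0.981, k_et=7.055, k_ec=0.794)


class TestNormalizedStrain:
    def test_twice_threshold_gives_one(self):
        assert normalized_strain(2 * 2785.0, 2785.0) == pytest.approx(1.0)
        assert normalized_strain(-2 * 1100.0, 1100.0) == pytest.approx(1.0)

    def test_three_times_threshold_gives_two(self):
        assert normalized_strain(3 * 1100.0, 1100.0) == pytest.approx(2.0)

    def test_lazy_zone_is_a_caller_error(self):
        with pytest.raises(MechanostatError):
            normalized_strain(1000.0, 1100.0)
        with pytest.raises(MechanostatError):
            normalized_strain(1100.0, 1100.0)  # boundary belongs to the lazy zone


class TestSurfaceRate:
    def test_periosteum_zero_strain_no_response(self):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        assert surface_rate(0.0, p, PERIOSTEAL) == 0.0

    def test_endosteum_zero_strain_resorbs_at_k_sn(self):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        assert surface_rate(0.0, p, ENDOSTEAL) == pytest.approx(-1.398)

    def test_periosteal_tension_at_twice_threshold(self):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        assert surface_rate(2 * 2785.0, p, PERIOSTEAL) == pytest.approx(2.148)

    def test_threshold_boundary_in_lazy_zone(self):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        assert surface_rate(2785.0, p, PERIOSTEAL) == 0.0
        assert surface_rate(-2785.0, p, PERIOSTEAL) == 0.0

    def test_endosteal_branches(self):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        # compression at 3× threshold: ε_norm = 2
        assert surface_rate(-3 * 1100.0, p, ENDOSTEAL) == pytest.approx(2 * 0.794 - 1.398)
        assert surface_rate(+3 * 1100.0, p, ENDOSTEAL) == pytest.approx(2 * 7.055 - 1.398)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(eps=st.floats(-10000, 10000))
    def test_rate_total_and_lazy_zone_flat(self, eps):
        p = MechanostatParams(model_id="M4", **TBL_RATES)
        rate_p = surface_rate(eps, p, PERIOSTEAL)
        rate_e = surface_rate(eps, p, ENDOSTEAL)
        assert np.isfinite(rate_p) and np.isfinite(rate_e)
        if abs(eps) <= 2785.0:
            assert rate_p == 0.0
        else:
            assert rate_p > 0.0
        if abs(eps) <= 1100.0:
            assert rate_e == pytest.approx(-1.398)


class TestModelConstraints:
    def test_m1_requires_single_rate(self):
        with pytest.raises(MechanostatError):
            MechanostatParams(model_id="M1", k_pt=1.0, k_pc=2.0, k_et=1.0, k_ec=1.0,
                              eps_hom_p=1100.0, eps_hom_e=1100.0)

    def test_m1_requires_single_threshold(self):
        with pytest.raises(MechanostatError):
            MechanostatParams(model_id="M1", k_pt=1.0, k_pc=1.0, k_et=1.0, k_ec=1.0)

    def test_from_free_rates_round_trip(self):
        for model, rates in [("M1", (0.5,)), ("M2", (0.4, 0.6)), ("M3", (1.0, 1.1)),
                             ("M4", (1.0, 2.0, 3.0, 4.0))]:
            p = MechanostatParams.from_free_rates(model, rates)
            assert p.free_rates() == rates

    def test_m1_m2_share_the_low_threshold(self):
        p = MechanostatParams.from_free_rates("M2", (0.4, 0.6))
        assert p.eps_hom_p == p.eps_hom_e == 1100.0
        p4 = MechanostatParams.from_free_rates("M4", (1, 1, 1, 1))
        assert (p4.eps_hom_p, p4.eps_hom_e) == (2785.0, 1100.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(MechanostatError):
            MechanostatParams(model_id="M4", k_pt=-0.1)


class TestStepAndSimulate:
    def test_homeostasis_zero_rates_zero_strain(self, circle_pair):
        peri, endo = circle_pair
        params = MechanostatParams(model_id="M4", k_sn=0.0)
        state = step(SimulationState(peri, endo), params, load=None)
        np.testing.assert_array_equal(state.periosteal.xy, peri.xy)
        np.testing.assert_array_equal(state.endosteal.xy, endo.xy)

    def test_disuse_step_enlarges_marrow(self, circle_pair):
        peri, endo = circle_pair
        params = MechanostatParams(model_id="M4", k_sn=1.398)
        state = step(SimulationState(peri, endo), params, load=None)
        r_new = np.hypot(state.endosteal.x, state.endosteal.y)
        np.testing.assert_allclose(r_new, 400.0 + 1.398, atol=1e-9)

    def test_disuse_21_day_closed_form(self, circle_pair, schedule):
        peri, endo = circle_pair
        params = MechanostatParams(model_id="M4", k_sn=1.398)
        state = simulate(peri, endo, params, schedule, beam.LoadCase(F=0.0))
        r_endo = np.hypot(state.endosteal.x, state.endosteal.y)
        np.testing.assert_allclose(r_endo, 400.0 + 21 * 1.398, atol=1e-9)
        np.testing.assert_allclose(state.periosteal.xy, peri.xy, atol=1e-9)

    def test_all_zero_rates_endpoint_is_baseline(self, circle_pair, schedule):
        peri, endo = circle_pair
        params = MechanostatParams(model_id="M4", k_sn=0.0)
        state = simulate(peri, endo, params, schedule, beam.LoadCase(F=12.0, p_F=(0.0, -1250.0)))
        np.testing.assert_array_equal(state.periosteal.xy, peri.xy)
        np.testing.assert_array_equal(state.endosteal.xy, endo.xy)

    def test_subthreshold_load_leaves_periosteum(self, baseline_pair, schedule):
        """A small load keeps |ε| below the periosteal threshold every day,
        so the periosteal endpoint equals the baseline exactly."""
        peri, endo = baseline_pair
        params = MechanostatParams(model_id="M4", k_sn=1.398, **TBL_RATES)
        load = beam.LoadCase(F=2.0, p_F=(0.0, -1250.0))
        props = beam.section_properties(peri, endo)
        eps = beam.flexure_strain(props, load, peri, endo)
        assert np.abs(eps.periosteal).max() < 2785.0  # branch-coverage guard
        state = simulate(peri, endo, params, schedule, load)
        np.testing.assert_array_equal(state.periosteal.xy, peri.xy)

    def test_determinism(self, baseline_pair, schedule, calibration_load):
        params = MechanostatParams(model_id="M4", **TBL_RATES)
        a = simulate(*baseline_pair, params, schedule, calibration_load)
        b = simulate(*baseline_pair, params, schedule, calibration_load)
        np.testing.assert_array_equal(a.periosteal.xy, b.periosteal.xy)
        np.testing.assert_array_equal(a.endosteal.xy, b.endosteal.xy)

    def test_audit_trail_records_each_day(self, circle_pair, schedule):
        params = MechanostatParams(model_id="M4", k_sn=1.0)
        state = simulate(*circle_pair, params, schedule, beam.LoadCase(F=0.0), record_audit=True)
        assert len(state.audit) == schedule.total_days
        assert [d.loaded for d in state.audit] == [False] * 5 + [True] * 14 + [False] * 2
        frame = mechanostat.audit_to_frame(state)
        assert list(frame["day"]) == list(range(1, 22))
        np.testing.assert_allclose(frame["rate_e_mean_um_day"], -1.0)


class TestGeometryFeedback:
    def test_formation_grows_area_and_relaxes_strain(self, baseline_pair, schedule, calibration_load):
        """Self-limiting adaptation: after loaded formation days the cortical
        area is larger and the peak compressive strain under the same load
        is smaller than at baseline."""
        peri, endo = baseline_pair
        params = MechanostatParams(model_id="M4", k_sn=0.0, **TBL_RATES)
        state = simulate(peri, endo, params, schedule, calibration_load)
        p0 = beam.section_properties(peri, endo)
        p1 = beam.section_properties(state.periosteal, state.endosteal)
        assert p1.area > p0.area
        eps0 = beam.flexure_strain(p0, calibration_load, peri, endo)
        eps1 = beam.flexure_strain(p1, calibration_load, state.periosteal, state.endosteal)
        assert eps1.periosteal.min() > eps0.periosteal.min()  # less compressive


class TestModelNesting:
    def test_equal_rates_reproduce_m1_bitwise(self, circle_pair, schedule):
        """With all rates tied and a common threshold, M2–M4 runs equal M1's."""
        peri, endo = circle_pair
        load = beam.LoadCase(F=10.0, p_F=(0.0, -900.0))
        k = 0.8
        ref = simulate(
            peri, endo,
            MechanostatParams.from_free_rates("M1", (k,)),
            schedule, load,
        )
        for model, rates in [("M2", (k, k)), ("M3", (k, k)), ("M4", (k, k, k, k))]:
            params = MechanostatParams.from_free_rates(
                model, rates, eps_hom_p=1100.0, eps_hom_e=1100.0
            )
            got = simulate(peri, endo, params, schedule, load)
            np.testing.assert_array_equal(got.periosteal.xy, ref.periosteal.xy)
            np.testing.assert_array_equal(got.endosteal.xy, ref.endosteal.xy)


def test_schedule_defaults_replicate_protocol(schedule):
    assert schedule.total_days == 21
    flags = schedule.daily_loaded()
    assert flags.sum() == 14 and not flags[:5].any() and not flags[-2:].any()
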