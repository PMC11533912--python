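"""TIAC integration, human projection, and RBE-weighted dose arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from tapdose import dosimetry as dm
from tapdose.errors import InsufficientDataError, InvalidParameterError, MappingError
from tapdose.nuclide_chain import LN2, EmissionSummary

T_HALF = 10.6
LAM = LN2 / T_HALF


def exp_curve(times, organ="kidneys", scale=1.0):
    t = np.asarray(times, dtype=float)
    return dm.TimeActivityCurve(organ=organ, times_h=t, activity_fraction=scale * np.exp(-LAM * t))


class TestBuildCurves:
    @staticmethod
    def _summary(organ, times, idg):
        return pd.DataFrame({"organ": organ, "timepoint_h": times, "mean_idg": idg})

    def test_constant_biological_retention_is_pure_physical_decay(self):
        times = [1.0, 4.0, 24.0]
        summary = self._summary("wb", times, [100.0] * 3)
        tacs = dm.build_time_activity_curves(
            summary, {"wb": 1.0}, T_HALF, include_t0=True, t0_fractions={"wb": 1.0}
        )
        np.testing.assert_allclose(
            tacs["wb"].activity_fraction, np.exp(-LAM * np.array([0.0] + times)), rtol=1e-12
        )

    def test_single_point_value(self):
        summary = self._summary("tumor", [1.0], [5.0])
        tacs = dm.build_time_activity_curves(summary, {"tumor": 1.0}, T_HALF)
        assert tacs["tumor"].activity_fraction[1] == pytest.approx(
            0.05 * 2 ** (-1 / 10.6), rel=1e-9
        )
        assert tacs["tumor"].activity_fraction[1] == pytest.approx(0.0468, abs=0.0001)

    def test_zero_uptake_is_identically_zero(self):
        summary = self._summary("spleen", [1.0, 4.0], [0.0, 0.0])
        tacs = dm.build_time_activity_curves(summary, {"spleen": 0.1}, T_HALF)
        assert np.all(tacs["spleen"].activity_fraction == 0.0)

    def test_missing_mass_rejected(self):
        summary = self._summary("liver", [1.0, 4.0], [1.0, 1.0])
        with pytest.raises(MappingError):
            dm.build_time_activity_curves(summary, {"kidneys": 1.0}, T_HALF)


class TestComputeTiac:
    def test_dense_exponential_matches_closed_form(self):
        tac = exp_curve(np.linspace(0, 72, 1000))
        assert dm.compute_tiac(tac, T_HALF) == pytest.approx(1 / LAM, rel=1e-4)
        assert 1 / LAM == pytest.approx(15.29, abs=0.01)

    def test_sparse_sampling_overestimates_convex_decay(self):
        tac = exp_curve([0.0, 1.0, 4.0, 24.0])
        tiac = dm.compute_tiac(tac, T_HALF)
        # hand trapezoid + analytic tail A(24)/lambda
        a = np.exp(-LAM * np.array([0.0, 1.0, 4.0, 24.0]))
        hand = (
            (a[0] + a[1]) / 2 + (a[1] + a[2]) / 2 * 3 + (a[2] + a[3]) / 2 * 20 + a[3] / LAM
        )
        assert tiac == pytest.approx(hand, rel=1e-12)
        assert tiac == pytest.approx(16.5, abs=0.1)
        assert tiac >= 1 / LAM  # trapezoid over a convex decaying curve

    def test_zero_curve(self):
        tac = dm.TimeActivityCurve("x", np.array([0.0, 24.0]), np.zeros(2))
        assert dm.compute_tiac(tac, T_HALF) == 0.0

    def test_single_timepoint_rejected(self):
        with pytest.raises(InsufficientDataError):
            dm.TimeActivityCurve("x", np.array([1.0]), np.array([0.5]))

    def test_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            times = np.sort(rng.uniform(0, 48, 6))
            times[0] = 0.0
            frac = rng.uniform(0, 0.2, 6)
            tac = dm.TimeActivityCurve("x", times, frac)
            tiac = dm.compute_tiac(tac, T_HALF)
            assert frac[-1] / LAM <= tiac <= frac.max() * (times[-1] + 1 / LAM)


class TestHumanExtrapolation:
    @staticmethod
    def _phantoms():
        mouse = dm.Phantom("mouse", "male", {"kidneys": 0.0004, "liver": 0.0013}, 0.025)
        human = dm.Phantom("human", "female", {"kidneys": 0.275, "liver": 1.4}, 60.0)
        return mouse, human

    def test_wholebody_concentration_organ(self):
        mouse, human = self._phantoms()
        times = np.array([0.0, 1.0, 4.0, 24.0])
        wb = exp_curve(times, organ="whole_body")
        # organ whose concentration equals whole-body concentration: R = 1
        frac = wb.activity_fraction * (0.0004 / 0.025)
        organ = dm.TimeActivityCurve("kidneys", times, frac)
        out = dm.extrapolate_to_human({"kidneys": organ}, mouse, human, whole_body=wb)
        expected = (0.275 / 60.0) * wb.activity_fraction
        np.testing.assert_allclose(out["kidneys"].activity_fraction, expected, rtol=1e-12)

    def test_relative_concentration_round_trip(self):
        mouse, human = self._phantoms()
        times = np.array([0.5, 1.0, 4.0, 24.0, 48.0])
        rng = np.random.default_rng(5)
        wb = dm.TimeActivityCurve("whole_body", times, np.exp(-LAM * times))
        tacs = {
            o: dm.TimeActivityCurve(o, times, rng.uniform(0.01, 0.2, len(times)))
            for o in ("kidneys", "liver")
        }
        out = dm.extrapolate_to_human(tacs, mouse, human, whole_body=wb)
        for o, tac in tacs.items():
            r_mouse = (tac.activity_fraction / mouse.organ_masses_kg[o]) / (
                wb.activity_fraction / mouse.body_mass_kg
            )
            r_human = (out[o].activity_fraction / human.organ_masses_kg[o]) / (
                out["whole_body"].activity_fraction / human.body_mass_kg
            )
            np.testing.assert_allclose(r_human, r_mouse, rtol=1e-9)

    def test_scale_invariance_of_relative_concentration(self):
        mouse, human = self._phantoms()
        times = np.array([1.0, 4.0, 24.0])
        wb = exp_curve(times, organ="whole_body", scale=0.5)
        organ = dm.TimeActivityCurve("kidneys", times, 0.05 * np.exp(-LAM * times))
        out1 = dm.extrapolate_to_human({"kidneys": organ}, mouse, human, whole_body=wb)
        doubled = dm.TimeActivityCurve("kidneys", times, 2 * organ.activity_fraction)
        wb2 = dm.TimeActivityCurve("whole_body", times, 2 * wb.activity_fraction)
        out2 = dm.extrapolate_to_human({"kidneys": doubled}, mouse, human, whole_body=wb2)
        np.testing.assert_allclose(
            out2["kidneys"].activity_fraction, 2 * out1["kidneys"].activity_fraction, rtol=1e-12
        )

    def test_missing_human_organ_rejected(self):
        mouse, human = self._phantoms()
        times = np.array([1.0, 4.0])
        tac = dm.TimeActivityCurve("pancreas", times, np.array([0.1, 0.05]))
        mouse.organ_masses_kg["pancreas"] = 0.00025
        with pytest.raises(MappingError):
            dm.extrapolate_to_human(
                {"pancreas": tac}, mouse, human,
                whole_body=exp_curve(times, organ="whole_body"),
            )


class TestDoseCoefficients:
    def test_reference_arithmetic(self):
        emissions = EmissionSummary(e_alpha=7.8, e_electron=0.81, e_photon=1.5)
        phantom = dm.Phantom("human", "male", {"kidneys": 0.31}, 73.0)
        coeffs = dm.absorbed_dose_coefficients({"kidneys": 1.0}, phantom, emissions, rbe=5.0)
        # 3600 decays/Bq x (5*7.8+0.81) MeV in J / 0.31 kg, per GBq
        expected = 3600 * (5 * 7.8 + 0.81) * 1.602176634e-13 / 0.31 * 1e9
        assert coeffs.coefficients_gy_per_gbq["kidneys"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(74.0, abs=0.5)

    def test_rbe_one_no_electrons_is_unweighted_alpha_dose(self):
        emissions = EmissionSummary(e_alpha=7.8, e_electron=0.0, e_photon=0.0)
        phantom = dm.Phantom("human", "male", {"kidneys": 0.31}, 73.0)
        c1 = dm.absorbed_dose_coefficients({"kidneys": 1.0}, phantom, emissions, rbe=1.0)
        expected = 3600 * 7.8 * 1.602176634e-13 / 0.31 * 1e9
        assert c1.coefficients_gy_per_gbq["kidneys"] == pytest.approx(expected, rel=1e-12)
        assert c1.alpha_fraction["kidneys"] == 1.0

    def test_doubling_mass_halves_coefficient(self, emissions):
        p1 = dm.Phantom("h", "f", {"kidneys": 0.275}, 60.0)
        p2 = dm.Phantom("h", "f", {"kidneys": 0.550}, 60.0)
        c1 = dm.absorbed_dose_coefficients({"kidneys": 2.0}, p1, emissions, 5.0)
        c2 = dm.absorbed_dose_coefficients({"kidneys": 2.0}, p2, emissions, 5.0)
        assert c1.coefficients_gy_per_gbq["kidneys"] == pytest.approx(
            2 * c2.coefficients_gy_per_gbq["kidneys"], rel=1e-12
        )

    def test_dose_linear_in_activity_and_tiac(self, emissions):
        rng = np.random.default_rng(9)
        phantom = dm.Phantom("h", "f", {"kidneys": 0.275}, 60.0)
        for _ in range(20):
            tiac = rng.uniform(0.01, 10.0)
            act = rng.uniform(0.01, 10.0)
            k = rng.uniform(0.1, 10.0)
            c1 = dm.absorbed_dose_coefficients({"kidneys": tiac}, phantom, emissions, 5.0)
            ck = dm.absorbed_dose_coefficients({"kidneys": k * tiac}, phantom, emissions, 5.0)
            d1 = dm.dose_table(c1, [act]).doses_gy.loc["kidneys", act]
            dk = dm.dose_table(c1, [k * act]).doses_gy.loc["kidneys", k * act]
            assert dk == pytest.approx(k * d1, rel=1e-12)
            assert ck.coefficients_gy_per_gbq["kidneys"] == pytest.approx(
                k * c1.coefficients_gy_per_gbq["kidneys"], rel=1e-12
            )


class TestDoseReports:
    def test_reference_dose_grid_scaling(self, emissions):
        coeffs, limits = dm.reference_dose_coefficients(emissions)
        report = dm.dose_table(coeffs, [0.111, 0.555, 1.110], limits)
        assert report.doses_gy.loc["kidneys", 1.110] == pytest.approx(3.080, abs=1e-9)
        assert report.doses_gy.loc["pancreas", 0.555] == pytest.approx(1.435, abs=1e-9)
        assert report.limiting_organ == "kidneys"
        assert not report.exceeded.loc["kidneys", 1.110]

    def test_zero_activity_forbidden_but_small_allowed(self, emissions):
        coeffs, limits = dm.reference_dose_coefficients(emissions)
        with pytest.raises(InvalidParameterError):
            dm.dose_table(coeffs, [0.0], limits)

    def test_activity_limit_two_organ_example(self):
        coeffs = dm.DoseCoefficients(
            rbe=5.0, coefficients_gy_per_gbq={"a": 1.0, "b": 2.0},
            alpha_fraction={"a": 1.0, "b": 1.0},
        )
        organ, limit = dm.activity_limit(coeffs, {"a": 10.0, "b": 10.0})
        assert (organ, limit) == ("b", pytest.approx(5.0))

    def test_activity_limit_round_trip(self, emissions):
        coeffs, limits = dm.reference_dose_coefficients(emissions)
        organ, a_limit = dm.activity_limit(coeffs, limits)
        dose_at_limit = coeffs.coefficients_gy_per_gbq[organ] * a_limit
        assert dose_at_limit == pytest.approx(limits[organ], rel=1e-12)

    def test_zero_coefficient_unbounded(self):
        coeffs = dm.DoseCoefficients(
            rbe=5.0, coefficients_gy_per_gbq={"a": 0.0}, alpha_fraction={"a": 1.0}
        )
        organ, limit = dm.activity_limit(coeffs, {"a": 10.0})
        assert organ is None and math.isinf(limit)

    def test_safety_margin_at_activity_limit_is_one(self, emissions):
        coeffs, limits = dm.reference_dose_coefficients(emissions)
        organ, a_limit = dm.activity_limit(coeffs, limits)
        assert dm.safety_margin(coeffs, organ, a_limit, limits[organ]) == pytest.approx(1.0)


class TestPhantoms:
    @pytest.mark.parametrize("name", ["mouse_male", "mouse_female", "human_male", "human_female"])
    def test_bundled_phantoms_valid(self, name):
        phantom = dm.Phantom.bundled(name)
        assert sum(phantom.organ_masses_kg.values()) < phantom.body_mass_kg
        assert phantom.dose_limits_gy["kidneys"] == 23.0

    def test_organ_masses_must_fit_in_body(self):
        with pytest.raises(InvalidParameterError):
            dm.Phantom("h", "f", {"a": 50.0, "b": 20.0}, 60.0)
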