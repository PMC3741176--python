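"""Arrhenius fitting, Eyring decomposition and differential analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychrotryp.constants import CODATA
from psychrotryp.thermokinetics import (
    ActivityTemperatureSeries,
    ArrheniusFit,
    DifferentialActivation,
    EyringState,
    activity_ratio_from_ddg,
    arrhenius_to_eyring,
    characterize_calcium_profile,
    differential_activation,
    eyring_from_rate,
    fit_arrhenius,
    fit_arrhenius_two_sided,
    rate_from_eyring,
    summarize_profile,
)

R = CODATA.R


def peaked_series(Ea=35_000.0, lnA=math.log(1e8), n_asc=6):
    """Exact Arrhenius ascending limb plus an appended descending limb."""
    t_asc = np.linspace(277.0, 313.0, n_asc)
    k_asc = np.exp(lnA - Ea / (R * t_asc))
    t_desc = np.array([318.0, 323.0, 328.0, 333.0])
    k_desc = k_asc[-1] * np.exp(-0.1 * (t_desc - t_asc[-1]))
    return ActivityTemperatureSeries(
        "enzyme", "substrate",
        tuple(t_asc) + tuple(t_desc), tuple(k_asc) + tuple(k_desc),
    )


class TestArrheniusFit:
    def test_exact_recovery_on_noiseless_data(self):
        asc, desc, t_opt = fit_arrhenius_two_sided(peaked_series())
        assert asc.Ea == pytest.approx(35_000.0, rel=1e-6)
        assert asc.lnA == pytest.approx(math.log(1e8), rel=1e-6)
        assert asc.r_squared == pytest.approx(1.0, abs=1e-9)
        assert t_opt == pytest.approx(313.0)
        assert desc.limb == "descending" and desc.Ea < 0

    @pytest.mark.parametrize("ratio", [0.70, 0.60])
    def test_planted_activation_energy_ratio_recovered(self, ratio):
        """Cold/mesophilic Ea ratios like the reported ~70% and ~40% lower."""
        ea_meso = 50_000.0
        asc_c, _, _ = fit_arrhenius_two_sided(peaked_series(Ea=ratio * ea_meso))
        asc_m, _, _ = fit_arrhenius_two_sided(peaked_series(Ea=ea_meso))
        assert asc_c.Ea / asc_m.Ea == pytest.approx(ratio, rel=1e-6)

    def test_insufficient_limb_data_rejected(self):
        t = (277.0, 287.0, 297.0, 307.0)
        k = (1.0, 2.0, 3.0, 1.5)  # only 2 points on the descending side
        with pytest.raises(ValueError, match="insufficient limb"):
            fit_arrhenius_two_sided(ActivityTemperatureSeries("e", "s", t, k))

    def test_interior_zero_rate_is_an_error(self):
        with pytest.raises(ValueError, match="nonpositive rate"):
            fit_arrhenius([277.0, 287.0, 297.0, 307.0], [1.0, 0.0, 2.0, 3.0])

    def test_edge_zero_rates_trimmed(self, caplog):
        with caplog.at_level("WARNING"):
            fit = fit_arrhenius([277.0, 287.0, 297.0, 307.0], [0.0, 1.0, 2.0, 3.0])
        assert fit.n_points == 3
        assert any("trimmed" in rec.message for rec in caplog.records)

    def test_unit_scaling_leaves_slope_invariant(self):
        """Specific-activity (U/mg) series fit identically up to lnA."""
        s1 = peaked_series()
        s2 = ActivityTemperatureSeries(
            "e", "s", s1.temperatures, tuple(40.0 * r for r in s1.rates), unit_tag="U/mg"
        )
        a1, _, _ = fit_arrhenius_two_sided(s1)
        a2, _, _ = fit_arrhenius_two_sided(s2)
        assert a2.Ea == pytest.approx(a1.Ea, rel=1e-9)
        assert a2.lnA - a1.lnA == pytest.approx(math.log(40.0), rel=1e-9)


class TestEyring:
    def test_rate_equal_to_frequency_factor_gives_zero_barrier(self):
        T = 300.0
        k = CODATA.kappa * CODATA.k_B * T / CODATA.h
        assert eyring_from_rate(k, T) == pytest.approx(0.0, abs=1e-6)

    def test_unit_rate_at_20C(self):
        """Closed form evaluated independently from the stated constants."""
        T = 293.15
        expected = R * T * math.log(CODATA.k_B * T / (CODATA.h * 1.0))
        dg = eyring_from_rate(1.0, T)
        assert dg == pytest.approx(expected, rel=1e-12)
        assert dg / 1000.0 == pytest.approx(71.76, abs=0.01)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        k=st.floats(min_value=1e-6, max_value=1e6),
        T=st.floats(min_value=250.0, max_value=400.0),
    )
    def test_round_trip(self, k, T):
        assert rate_from_eyring(eyring_from_rate(k, T), T) == pytest.approx(k, rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="invalid kinetic input"):
            eyring_from_rate(0.0, 300.0)
        with pytest.raises(ValueError, match="invalid kinetic input"):
            eyring_from_rate(1.0, -1.0)

    def test_arrhenius_to_eyring_conventions(self):
        fit = ArrheniusFit(Ea=50_000.0, lnA=20.0, r_squared=1.0,
                           window=(277.0, 313.0), limb="ascending")
        state = arrhenius_to_eyring(fit, k_at_Tref=1.0, T_ref=293.15)
        assert state.dH == pytest.approx(47_563.0, abs=1.0)  # Ea - R*T by hand
        assert state.dS == pytest.approx((47_563.0 - 71_756.0) / 293.15, abs=0.05)
        # identity holds by construction
        assert state.dG == pytest.approx(state.dH - state.T_ref * state.dS, rel=1e-9)

    def test_degenerate_cancellation(self):
        T = 293.15
        fit = ArrheniusFit(Ea=R * T, lnA=0.0, r_squared=1.0,
                           window=(277.0, 313.0), limb="ascending")
        assert arrhenius_to_eyring(fit, 1.0, T).dH == pytest.approx(0.0, abs=1e-9)

    def test_descending_limb_rejected(self):
        fit = ArrheniusFit(Ea=-30_000.0, lnA=0.0, r_squared=1.0,
                           window=(313.0, 333.0), limb="descending")
        with pytest.raises(ValueError, match="no TST interpretation"):
            arrhenius_to_eyring(fit, 1.0, 293.15)


class TestDifferentials:
    def _state(self, k, T=293.15, Ea=50_000.0):
        fit = ArrheniusFit(Ea=Ea, lnA=20.0, r_squared=1.0,
                           window=(277.0, 313.0), limb="ascending")
        return arrhenius_to_eyring(fit, k, T)

    def test_self_comparison_is_zero(self):
        s = self._state(1.0)
        d = differential_activation(s, s)
        assert d.ddG == d.ddH == d.TddS == 0.0

    def test_rate_ratio_path_agrees_with_subtraction_path(self):
        T = 293.15
        sp, sm = self._state(1.74, T), self._state(1.0, T)
        d = differential_activation(sp, sm)
        assert d.ddG == pytest.approx(-R * T * math.log(1.74), rel=1e-9)
        assert d.ddG / 1000.0 == pytest.approx(-1.350, abs=0.002)

    def test_reference_temperature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="reference temperature mismatch"):
            differential_activation(self._state(1.0, 293.15), self._state(1.0, 283.15))

    def test_enthalpy_entropy_compensation_pattern(self):
        """ddH and T*ddS both large and negative, nearly cancelling in ddG."""
        d = DifferentialActivation(ddG=-1_350.0, ddH=-57_400.0,
                                   TddS=-56_050.0, T_ref=293.15)
        assert d.ddH < 0 and d.TddS < 0
        assert d.ddG == pytest.approx(d.ddH - d.TddS)


class TestActivityRatio:
    def test_zero_ddg_means_no_advantage(self):
        assert activity_ratio_from_ddg(0.0, 293.15) == 1.0

    def test_printed_ddg_implies_74_percent_advantage(self):
        assert activity_ratio_from_ddg(-1_350.0, 293.15) == pytest.approx(1.740, abs=0.002)

    def test_cold_advantage_grows_toward_low_temperature(self):
        assert activity_ratio_from_ddg(-3_262.0, 283.15) == pytest.approx(4.0, abs=0.01)
        # fixed ddH < 0: ratio increases as T decreases
        ddH, ddS = -57_400.0, -191.2
        ratios = [
            activity_ratio_from_ddg(ddH - T * ddS, T) for T in (283.15, 293.15, 303.15)
        ]
        assert ratios[0] > ratios[1] > ratios[2]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        ddg=st.floats(min_value=-5e3, max_value=5e3),
        delta=st.floats(min_value=1.0, max_value=1e3),
    )
    def test_monotone_decreasing_in_ddg(self, ddg, delta):
        assert activity_ratio_from_ddg(ddg, 293.15) > activity_ratio_from_ddg(ddg + delta, 293.15)


class TestProfiles:
    def test_flat_top_plateau(self):
        xs = [4, 5, 6, 7, 8, 9, 10, 11, 12]
        ys = [0.3, 0.4, 0.6, 1.0, 1.0, 1.0, 1.0, 0.5, 0.3]
        s = summarize_profile(xs, ys)
        assert s.plateau == (7.0, 10.0)
        assert s.x_opt == 7.0  # tie broken toward the lowest position

    def test_single_peak_has_no_plateau(self):
        xs = [6, 7, 8, 9, 10, 11]
        ys = [0.3, 0.5, 0.85, 1.0, 0.8, 0.4]
        s = summarize_profile(xs, ys)
        assert s.x_opt == 9.0 and s.plateau is None

    def test_thermal_optimum_location(self):
        xs = [283.15, 293.15, 303.15, 313.15, 323.15, 333.15]
        ys = [0.2, 0.5, 0.8, 0.95, 1.0, 0.4]
        assert summarize_profile(xs, ys).x_opt == 323.15

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="empty profile"):
            summarize_profile([1, 2, 3], [0, 0, 0])


class TestCalciumProfile:
    def test_constant_activity(self):
        p = characterize_calcium_profile([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert p.activity_fraction_at_zero == 1.0

    def test_monotone_increasing(self):
        p = characterize_calcium_profile([0.0, 1.0, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p.ratio_at_max == 4.0

    def test_saturating_curve_and_missing_zero_point(self):
        ratios = np.linspace(0.5, 8.0, 16)
        acts = ratios / (2.0 + ratios)  # half-saturation at ratio 2
        p = characterize_calcium_profile(ratios, acts)
        assert p.ratio_at_max == ratios[int(np.argmax(acts))]
        assert p.activity_fraction_at_zero is None
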