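"""Clearance construction: pore-limited paracellular transport,
steady-state Kp_uu, and asymmetry calibration."""

import math

import pytest
from hypothesis import given, strategies as st

import cns_whatif as cw
from cns_whatif.physicochem import ParameterError
from cns_whatif.transport import (
    CalibrationError,
    aqueous_diffusivity,
    build_clearances,
    calibrate_asymmetry,
    renkin_hindrance,
    scale_paracellular,
    solute_radius,
    steady_state_kpuu,
)


class TestRenkinHindrance:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            (0.0, 1.0),  # unhindered limit
            (1.0, 0.0),  # solute fills the pore
            (1.7, 0.0),  # too large to enter
            (0.5, 0.04489),  # polynomial evaluated by hand
        ],
    )
    def test_values(self, lam, expected):
        assert renkin_hindrance(lam) == pytest.approx(expected, rel=1e-4)

    @given(lam=st.floats(min_value=0.0, max_value=2.0))
    def test_bounded(self, lam):
        assert 0.0 <= renkin_hindrance(lam) <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            renkin_hindrance(-0.1)


class TestSoluteSize:
    def test_diffusivity_correlation(self):
        # 9.9e-5 * 194.2**-0.453, evaluated independently
        assert aqueous_diffusivity(194.2) == pytest.approx(9.10e-6, rel=0.01)

    def test_radius_monotone_in_mwt(self):
        radii = [solute_radius(m) for m in (150.0, 250.0, 350.0, 500.0)]
        assert all(r > 0 for r in radii)
        assert radii == sorted(radii)

    def test_nonpositive_mwt_rejected(self):
        with pytest.raises(ParameterError):
            solute_radius(0.0)


class TestScaleParacellular:
    def test_identity(self, panel):
        caffeine = panel["caffeine"]
        assert scale_paracellular(48.9, caffeine, 0.0007, 0.0007) == pytest.approx(48.9)

    def test_widening_exceeds_area_factor(self, panel):
        """Widening also relieves hindrance, so the gain exceeds r^2."""
        caffeine = panel["caffeine"]
        assert scale_paracellular(48.9, caffeine, 5 * 0.0007, 0.0007) > 25 * 48.9

    def test_narrowing_against_independent_oracle(self, panel):
        """Spreadsheet-style recomputation: area factor times the ratio
        of Renkin polynomials at the drug's Stokes-Einstein radius."""
        caffeine = panel["caffeine"]
        r_drug = solute_radius(caffeine.mwt)
        expected = (
            48.9 * 0.25
            * renkin_hindrance(r_drug / 0.00035)
            / renkin_hindrance(r_drug / 0.0007)
        )
        value = scale_paracellular(48.9, caffeine, 0.00035, 0.0007)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value < 48.9 / 4  # hindrance ratio < 1 on top of area 0.25

    def test_strictly_increasing_in_pore_radius(self, panel):
        caffeine = panel["caffeine"]
        r_drug = solute_radius(caffeine.mwt)
        radii = [r_drug * (1.0 + 0.3 * i) for i in range(1, 8)]
        values = [scale_paracellular(48.9, caffeine, r, 0.0007) for r in radii]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_drug_larger_than_reference_pore_rejected(self, panel):
        big = panel["caffeine"]
        with pytest.raises(ParameterError, match="caffeine"):
            scale_paracellular(48.9, big, 0.0007, 1e-5)


class TestSteadyStateKpuu:
    @pytest.mark.parametrize(
        "cl_p, cl_in, cl_ef, expected",
        [
            (48.9, 2.38, 4.28, 0.9607),  # caffeine
            (51.9, 0.0, 347.0, 0.1300),  # gabapentin
            (44.2, 508.0, 569.0, 0.9002),  # thiopental
        ],
    )
    def test_printed_panel_values(self, cl_p, cl_in, cl_ef, expected):
        assert steady_state_kpuu(cl_p, cl_in, cl_ef, 0.2) == pytest.approx(
            expected, abs=1e-4
        )

    def test_symmetric_passive_is_unity(self):
        assert steady_state_kpuu(10.0, 3.0, 3.0, 0.0) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ParameterError):
            steady_state_kpuu(0.0, 1.0, 0.0, 0.0)

    @given(cl_p=st.floats(min_value=1.0, max_value=1e5))
    def test_approaches_unity_with_growing_paracellular_route(self, cl_p):
        """More passive pore transport always pulls Kp_uu toward 1."""
        base = steady_state_kpuu(cl_p, 0.34, 138.5, 0.2)
        wider = steady_state_kpuu(10 * cl_p, 0.34, 138.5, 0.2)
        assert abs(wider - 1.0) < abs(base - 1.0)


class TestCalibration:
    def test_passively_consistent_drug_needs_no_asymmetry(self, panel):
        cal = calibrate_asymmetry(panel["codeine"])
        assert (cal.af_in, cal.af_ef) == (1.0, 1.0)
        assert cal.feasible

    @pytest.mark.parametrize(
        "name, af_ef",
        [("morphine", 4.59), ("levetiracetam", 31.6)],
    )
    def test_net_efflux_factor_solved_algebraically(self, panel, name, af_ef):
        cal = calibrate_asymmetry(panel[name])
        assert cal.af_in == 1.0
        assert cal.af_ef == pytest.approx(af_ef, rel=0.01)

    def test_factor_reproduces_target_exactly(self, panel, physiology):
        for drug in panel.values():
            cal = calibrate_asymmetry(drug)
            if not cal.feasible:
                continue
            achieved = steady_state_kpuu(
                drug.cl_para,
                cal.af_in * drug.cl_trans_in,
                cal.af_ef * drug.cl_trans_ef,
                physiology.Q_ECF_bulk,
            )
            assert achieved == pytest.approx(drug.kpuu_ecf, rel=0.02)

    def test_unreachable_target_is_flagged(self, panel):
        """Cephalexin's target sits above the passive prediction but its
        influx clearance is below detection: no factor can reach it."""
        cal = calibrate_asymmetry(panel["cephalexin"])
        assert not cal.feasible
        assert "cephalexin" in cal.note
        with pytest.raises(CalibrationError, match="cephalexin"):
            build_clearances(panel["cephalexin"], strict=True)


class TestBuildClearances:
    def test_reference_conditions_pass_inputs_through(self, panel):
        """At reference pH and pore radius a passively consistent drug's
        BBB clearances equal the tabulated inputs exactly."""
        codeine = panel["codeine"]
        cs = build_clearances(codeine)
        assert cs.bbb_para == pytest.approx(codeine.cl_para, rel=1e-12)
        assert cs.bbb_trans_in == codeine.cl_trans_in
        assert cs.bbb_trans_ef == codeine.cl_trans_ef

    def test_assembled_caffeine_kpuu(self, panel):
        cs = build_clearances(panel["caffeine"])
        kpuu = steady_state_kpuu(cs.bbb_para, cs.bbb_trans_in, cs.bbb_trans_ef, 0.2)
        assert kpuu == pytest.approx(0.96, abs=0.005)

    def test_cell_membrane_scaling(self, panel, physiology):
        """ECF->ICF clearance at baseline is the mean BBB transcellular
        clearance scaled by the membrane area ratio."""
        caffeine = panel["caffeine"]
        cs = build_clearances(caffeine)
        expected = 0.5 * (4.28 + 2.38) * physiology.SA_BCM / physiology.SA_BBB
        assert cs.cell_in == pytest.approx(expected, rel=1e-12)

    def test_cell_partition_set_by_ph(self, panel):
        """The directed cell-membrane clearances encode the ion-trapping
        equilibrium: out/in equals f_u(pH_ICF)/f_u(pH_ECF)."""
        morphine = panel["morphine"]
        cs = build_clearances(morphine)
        f = cw.fraction_unionized
        expected = f(morphine.ionization, 7.0) / f(morphine.ionization, 7.3)
        assert cs.cell_out / cs.cell_in == pytest.approx(expected, rel=1e-12)

    def test_all_panel_drugs_yield_nonnegative_clearances(self, panel):
        for drug in panel.values():
            cs = build_clearances(drug, strict=False)
            assert cs.q_csf_chain == pytest.approx(0.62)
            assert cs.bbb_para >= 0 and cs.cell_in >= 0 and cs.lys_in >= 0
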