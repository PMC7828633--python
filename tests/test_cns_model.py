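"""ODE system assembly and integration."""

import numpy as np
import pytest

import cns_whatif as cw
from cns_whatif.cns_model import (
    COMPARTMENTS,
    DoseRegimen,
    build_system,
    plasma_concentration,
    simulate,
    simulate_drug,
)
from cns_whatif.physicochem import IonClass, IonizationSpec, ParameterError
from cns_whatif.transport import CalibrationResult, ClearanceSet, build_clearances


def flow_only_clearances(q_cbf=689.0, **overrides):
    fields = dict(
        q_cbf=q_cbf, bbb_para=0.0, bbb_trans_in=0.0, bbb_trans_ef=0.0,
        cell_in=0.0, cell_out=0.0, lys_in=0.0, lys_out=0.0,
        bcsfb_para_lv=0.0, bcsfb_para_tfv=0.0,
        bcsfb_trans_in_lv=0.0, bcsfb_trans_ef_lv=0.0,
        bcsfb_trans_in_tfv=0.0, bcsfb_trans_ef_tfv=0.0,
        q_ecf_bulk=0.0, q_csf_chain=0.0,
        calibration=CalibrationResult(),
    )
    fields.update(overrides)
    return ClearanceSet(**fields)


class TestPlasmaModel:
    def test_starts_at_zero(self):
        assert plasma_concentration(0.0, DoseRegimen()) == 0.0

    def test_end_of_infusion_concentration(self):
        # (R0/CL)(1 - e^{-k*15}) with R0 = 1000/15 mg/min, CL = 4950
        # mL/min, k = CL/V: 6.70 mg/L
        c = plasma_concentration(15.0, DoseRegimen()) * 1e3
        assert c == pytest.approx(6.70, abs=0.01)

    def test_auc_infinity_is_dose_over_clearance(self, caffeine_result):
        auc = cw.auc_infinity(caffeine_result.time, caffeine_result.trace("plasma"))
        assert auc == pytest.approx(202.0, rel=1e-3)  # 1000 mg / 4.95 L/min

    def test_regimen_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            DoseRegimen(dose=0.0)


class TestSystemStructure:
    def test_state_dimension_and_metzler_structure(self, panel, physiology):
        cs = build_clearances(panel["caffeine"])
        system = build_system(panel["caffeine"], physiology, cs)
        a = system.matrix
        assert a.shape == (len(COMPARTMENTS), len(COMPARTMENTS)) == (8, 8)
        off_diag = a - np.diag(np.diag(a))
        assert np.all(off_diag >= 0.0)  # Metzler: mass flows between states
        # column sums are -outflow_to_plasma/V <= 0: mass-conservative
        col_sums = a.sum(axis=0)
        assert np.all(col_sums <= 1e-12)
        assert np.allclose(-col_sums * system.volumes, system.output_coeffs)

    def test_flow_only_system_equilibrates_mv_to_plasma(self, panel, physiology):
        system = build_system(
            panel["caffeine"], physiology, flow_only_clearances()
        )
        result = simulate(system, t_end=120.0)
        i60 = np.searchsorted(result.time, 60.0)
        mv = result.trace("MV")
        plasma = result.trace("plasma")
        # MV volume turns over every ~4 s, so it tracks plasma closely
        assert mv[i60] == pytest.approx(plasma[i60], rel=1e-2)
        for name in ("ECF", "ICF", "LYS", "LV", "TFV", "CM", "SAS"):
            assert np.all(result.trace(name) == 0.0)


class TestSimulation:
    def test_single_interior_maximum(self, caffeine_result):
        ecf = caffeine_result.trace("ECF")
        peak = int(np.argmax(ecf))
        assert 0 < peak < len(ecf) - 1
        # single peak: rises before, falls after
        assert np.all(np.diff(ecf[: peak + 1]) >= 0)
        assert np.all(np.diff(ecf[peak:]) <= 0)

    def test_mass_balance_closed(self, panel):
        for name in ("caffeine", "morphine", "gabapentin"):
            result = simulate_drug(panel[name])
            assert result.mass_balance_error < 1e-6

    def test_dose_linearity(self, panel):
        base = simulate_drug(panel["thiopental"], t_end=200.0)
        double = simulate_drug(
            panel["thiopental"], regimen=DoseRegimen(dose=2.0), t_end=200.0
        )
        for name in ("MV", "ECF", "ICF"):
            # pointwise to solver accuracy (adaptive steps differ
            # slightly between the two runs)
            np.testing.assert_allclose(
                double.trace(name), 2.0 * base.trace(name), rtol=1e-4, atol=1e-12
            )

    def test_simulated_kpuu_matches_flux_balance_closed_form(self, panel):
        """AUC-integration and steady-state flux balance agree for the
        linear system."""
        for name, expected in [("caffeine", 0.9607), ("gabapentin", 0.1300)]:
            result = simulate_drug(panel[name])
            ratio = cw.kpuu(result.time, result.trace("ECF"), result.trace("MV"))
            assert ratio == pytest.approx(expected, rel=0.02)

    def test_terminal_cell_partitioning_is_ph_ratio(self, morphine_result):
        """Equilibrium ICF/ECF exposure ratio equals the closed-form
        unionized-fraction ratio (1.98 for a base with pkb 9.12)."""
        ratio = cw.kpuu(
            morphine_result.time,
            morphine_result.trace("ICF"),
            morphine_result.trace("ECF"),
        )
        assert ratio == pytest.approx(1.9804, rel=0.01)

    def test_lysosomal_trapping_ratio(self, morphine_result, panel):
        ion = panel["morphine"].ionization
        expected = cw.fraction_unionized(ion, 7.0) / cw.fraction_unionized(ion, 5.0)
        ratio = cw.kpuu(
            morphine_result.time,
            morphine_result.trace("LYS"),
            morphine_result.trace("ICF"),
        )
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_slow_cell_uptake_triggers_horizon_extension(self, physiology):
        """A drug whose ICF peak lies beyond the default window is
        automatically re-simulated over the long horizon."""
        sluggish = cw.DrugParameters(
            name="sluggish",
            mwt=300.0,
            logp=0.0,
            ionization=IonizationSpec(IonClass.NEUTRAL),
            kpuu_ecf=1.0,
            cl_para=40.0,
            cl_trans_ef=0.005,
            cl_trans_in=0.005,
        )
        result = simulate_drug(sluggish, t_end=100.0)
        assert result.extended
        assert result.horizon == pytest.approx(20_000.0)
        icf = result.trace("ICF")
        assert int(np.argmax(icf)) < len(icf) - 1

    def test_neutral_drug_traces_invariant_under_ph_scenarios(self, panel):
        """pH perturbations cannot touch a never-ionized drug: traces
        are bitwise identical."""
        reference = cw.default_physiology()
        for scenario in cw.pathophysiological_scenarios():
            if scenario.target not in ("pH_ECF", "pH_ICF"):
                continue
            perturbed = cw.apply_scenario(reference, scenario)
            base = simulate_drug(panel["caffeine"], t_end=200.0)
            shifted = simulate_drug(
                panel["caffeine"], perturbed, reference=reference, t_end=200.0
            )
            for name in COMPARTMENTS:
                assert np.array_equal(base.trace(name), shifted.trace(name))

    def test_tidy_export_round_trips(self, caffeine_result):
        frame = caffeine_result.to_frame()
        assert set(frame.columns) == {"time", "compartment", "concentration"}
        ecf = frame[frame.compartment == "ECF"]
        np.testing.assert_array_equal(
            ecf.concentration.to_numpy(), caffeine_result.trace("ECF")
        )
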