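"""Inter-compartment drug clearances.

This module turns one drug's tabulated BBB clearances into the full set
of directed clearances of the CNS model under a given (possibly
perturbed) physiology:

* the paracellular route through tight-junction pores, modelled as
  hindered diffusion through cylindrical water-filled pores (Renkin
  hindrance), with an explicit pore-radius scaling law used by the
  pore-widening scenarios;
* the transcellular route across the BBB, restricted to the neutral
  microspecies and therefore rescaled when a source compartment's pH is
  perturbed, with influx/efflux asymmetry factors calibrated so that the
  model reproduces a measured unbound partition coefficient Kp_uu,BBB;
* brain-cell and lysosomal membrane clearances derived from the BBB
  transcellular permeability by surface-area scaling;
* the blood-CSF barrier (paracellular + transcellular) at the lateral
  and third+fourth ventricles;
* the convective routes: ECF bulk flow into the CSF and the CSF chain
  back to plasma.

Tabulated clearances (``CL_P``, ``CL_T,ef``, ``CL_T,in``) are canonical
inputs at reference physiology; first-principles formulas here exist
only to rescale them under scenario perturbations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .physicochem import (
    IonizationSpec,
    ParameterError,
    fraction_unionized,
    ph_scaling_factor,
)
from .physiology import CNSPhysiology, default_physiology, derive_bcsfb_area

__all__ = [
    "DrugParameters",
    "ClearanceSet",
    "CalibrationResult",
    "CalibrationError",
    "renkin_hindrance",
    "aqueous_diffusivity",
    "solute_radius",
    "scale_paracellular",
    "steady_state_kpuu",
    "calibrate_asymmetry",
    "build_clearances",
]

TRANSPORTER_NAMES = ("BCRP", "p-gp", "OAT3", "MRP4")


class CalibrationError(ValueError):
    """Raised when a Kp_uu target cannot be met by any asymmetry factor."""


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemistry, partition targets and BBB clearances of one drug.

    ``cl_para``, ``cl_trans_ef`` and ``cl_trans_in`` (mL/min) are the
    paracellular, transcellular efflux (ECF->MV) and transcellular
    influx (MV->ECF) BBB clearances at reference physiology (pore radius
    0.0007 um, plasma pH 7.4, ECF pH 7.3).  Values reported below the
    detection limit are stored as 0.
    """

    name: str
    mwt: float  # g/mol
    logp: float
    ionization: IonizationSpec
    kpuu_ecf: float  # target AUC ratio ECF/MV
    kpuu_lv: Optional[float] = None
    kpuu_cm: Optional[float] = None
    transporters: frozenset = frozenset()
    cl_para: float = 0.0  # mL/min
    cl_trans_ef: float = 0.0  # mL/min
    cl_trans_in: float = 0.0  # mL/min

    def __post_init__(self) -> None:
        if not 100.0 <= self.mwt <= 1000.0:
            raise ParameterError(
                f"{self.name}: Mwt {self.mwt} outside the supported [100, 1000] g/mol"
            )
        if self.kpuu_ecf <= 0:
            raise ParameterError(f"{self.name}: Kpuu_ECF must be positive")
        for fld in ("kpuu_lv", "kpuu_cm"):
            val = getattr(self, fld)
            if val is not None and val <= 0:
                raise ParameterError(f"{self.name}: {fld} must be positive")
        for fld in ("cl_para", "cl_trans_ef", "cl_trans_in"):
            if getattr(self, fld) < 0:
                raise ParameterError(f"{self.name}: {fld} must be non-negative")
        unknown = set(self.transporters) - set(TRANSPORTER_NAMES)
        if unknown:
            raise ParameterError(f"{self.name}: unknown transporters {sorted(unknown)}")


@dataclass(frozen=True)
class CalibrationResult:
    """Asymmetry factors reproducing a Kp_uu,BBB target.

    Exactly one of ``af_in``/``af_ef`` exceeds 1 when net active
    transport is required; both are 1 when the passive prediction
    already matches the target.  ``feasible`` is False when the target
    lies on a side whose transcellular clearance is zero, in which case
    the factors fall back to (1, 1)."""

    af_in: float = 1.0
    af_ef: float = 1.0
    feasible: bool = True
    note: str = ""


@dataclass(frozen=True)
class ClearanceSet:
    """All directed inter-compartment clearances (mL/min) of one
    drug x physiology combination, plus the calibration applied."""

    q_cbf: float  # plasma <-> MV perfusion flow
    bbb_para: float  # MV <-> ECF, symmetric
    bbb_trans_in: float  # MV -> ECF (effective: AF and pH applied)
    bbb_trans_ef: float  # ECF -> MV (effective)
    cell_in: float  # ECF -> ICF
    cell_out: float  # ICF -> ECF
    lys_in: float  # ICF -> LYS
    lys_out: float  # LYS -> ICF
    bcsfb_para_lv: float  # plasma <-> LV, symmetric
    bcsfb_para_tfv: float  # plasma <-> TFV, symmetric
    bcsfb_trans_in_lv: float  # plasma -> LV
    bcsfb_trans_ef_lv: float  # LV -> plasma
    bcsfb_trans_in_tfv: float  # plasma -> TFV
    bcsfb_trans_ef_tfv: float  # TFV -> plasma
    q_ecf_bulk: float  # ECF -> LV convective
    q_csf_chain: float  # LV -> TFV -> CM -> SAS -> plasma convective
    calibration: CalibrationResult = field(default_factory=CalibrationResult)

    def __post_init__(self) -> None:
        for fld in self.__dataclass_fields__:
            if fld == "calibration":
                continue
            if getattr(self, fld) < 0:
                raise ParameterError(f"clearance {fld} must be non-negative")


def renkin_hindrance(lam: float) -> float:
    """Hindrance factor for diffusion of a spherical solute through a
    cylindrical pore, as a function of lambda = solute radius / pore
    radius: ``(1-lam)^2 * (1 - 2.104 lam + 2.09 lam^3 - 0.95 lam^5)``,
    clipped to [0, 1]; 0 for lam >= 1."""
    if lam < 0:
        raise ParameterError(f"lambda must be non-negative, got {lam}")
    if lam >= 1.0:
        return 0.0
    value = (1.0 - lam) ** 2 * (
        1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
    )
    return min(max(value, 0.0), 1.0)


#: Aqueous diffusivity correlation D_aq = A * Mwt**B (cm^2/s); a simple
#: small-molecule size correlation, configurable via these constants.
DIFFUSIVITY_COEFF = 9.9e-5
DIFFUSIVITY_EXPONENT = -0.453

_BOLTZMANN_ERG = 1.380649e-16  # erg/K
_TEMPERATURE_K = 310.0
_WATER_VISCOSITY_POISE = 6.913e-3  # water at 310 K, g/(cm s)


def aqueous_diffusivity(mwt: float) -> float:
    """Aqueous diffusivity (cm^2/s) from molecular weight (g/mol)."""
    if mwt <= 0:
        raise ParameterError(f"Mwt must be positive, got {mwt}")
    return DIFFUSIVITY_COEFF * mwt**DIFFUSIVITY_EXPONENT


def solute_radius(mwt: float) -> float:
    """Stokes-Einstein hydrodynamic radius (um) at body temperature,
    from the aqueous-diffusivity correlation."""
    d_aq = aqueous_diffusivity(mwt)
    radius_cm = _BOLTZMANN_ERG * _TEMPERATURE_K / (
        6.0 * math.pi * _WATER_VISCOSITY_POISE * d_aq
    )
    return radius_cm * 1.0e4  # cm -> um


def scale_paracellular(
    cl_p_ref: float, drug: DrugParameters, r_new: float, r_ref: float
) -> float:
    """Rescale a paracellular clearance from pore radius ``r_ref`` to
    ``r_new`` (um): pore count fixed, aperture area proportional to
    r^2, Renkin hindrance re-evaluated at the drug's solute radius.

    Returns 0 when the drug no longer fits the new pore."""
    if r_new <= 0 or r_ref <= 0:
        raise ParameterError("pore radii must be positive")
    if cl_p_ref < 0:
        raise ParameterError("CL_P must be non-negative")
    r_drug = solute_radius(drug.mwt)
    h_ref = renkin_hindrance(r_drug / r_ref)
    if h_ref <= 0.0:
        raise ParameterError(
            f"{drug.name}: solute radius {r_drug:.2e} um does not pass the "
            f"reference pore (radius {r_ref:.2e} um)"
        )
    h_new = renkin_hindrance(r_drug / r_new)
    return cl_p_ref * (r_new / r_ref) ** 2 * h_new / h_ref


def steady_state_kpuu(
    cl_p: float, cl_in_eff: float, cl_ef_eff: float, q_bulk: float
) -> float:
    """Closed-form unbound partition coefficient Kp_uu,BBB implied by a
    linear ECF mass balance:

        Kp_uu = (CL_P + CL_in) / (CL_P + CL_ef + Q_bulk)

    The dead-end cell/lysosome fluxes integrate to zero over 0..inf and
    drop out, so this equals the AUC(0-inf) ratio ECF/MV of the full
    simulation."""
    if min(cl_p, cl_in_eff, cl_ef_eff, q_bulk) < 0:
        raise ParameterError("clearances must be non-negative")
    denom = cl_p + cl_ef_eff + q_bulk
    if denom == 0.0:
        raise ParameterError("Kp_uu undefined: no route out of the ECF")
    return (cl_p + cl_in_eff) / denom


def calibrate_asymmetry(
    drug: DrugParameters,
    physiology: Optional[CNSPhysiology] = None,
    rel_tol: float = 0.02,
    *,
    _target: Optional[float] = None,
    _cl_p: Optional[float] = None,
    _q_bulk: Optional[float] = None,
    _cl_in: Optional[float] = None,
    _cl_ef: Optional[float] = None,
) -> CalibrationResult:
    """Solve for the influx/efflux asymmetry factor that makes the
    steady-state Kp_uu,BBB equal the drug's measured target.

    Exactly one factor is adjusted: the efflux factor when the passive
    prediction exceeds the target (net active efflux), the influx factor
    when it falls below (net active influx); the other stays 1.  Targets
    within ``rel_tol`` of the passive prediction need no active
    transport and yield (1, 1).  When the required side has zero
    transcellular clearance the target is unattainable and a flagged
    (infeasible) result is returned."""
    if physiology is None:
        physiology = default_physiology()
    target = drug.kpuu_ecf if _target is None else _target
    cl_p = drug.cl_para if _cl_p is None else _cl_p
    q_bulk = physiology.Q_ECF_bulk if _q_bulk is None else _q_bulk
    cl_in = drug.cl_trans_in if _cl_in is None else _cl_in
    cl_ef = drug.cl_trans_ef if _cl_ef is None else _cl_ef

    passive = steady_state_kpuu(cl_p, cl_in, cl_ef, q_bulk)
    if abs(passive - target) <= rel_tol * target:
        return CalibrationResult(note="passive prediction matches target")
    if passive > target:
        # need extra efflux: (cl_p + cl_in)/(cl_p + af*cl_ef + q) = target
        if cl_ef <= 0:
            return CalibrationResult(
                feasible=False,
                note=(
                    f"{drug.name}: Kp_uu target {target:g} below passive "
                    f"prediction {passive:.4g} but CL_T,ef is 0"
                ),
            )
        af_ef = ((cl_p + cl_in) / target - cl_p - q_bulk) / cl_ef
        if af_ef < 1.0:  # target above what pure passive efflux allows
            af_ef = max(af_ef, 0.0)
        return CalibrationResult(af_ef=af_ef)
    # need extra influx: (cl_p + af*cl_in)/(cl_p + cl_ef + q) = target
    if cl_in <= 0:
        return CalibrationResult(
            feasible=False,
            note=(
                f"{drug.name}: Kp_uu target {target:g} above passive "
                f"prediction {passive:.4g} but CL_T,in is 0"
            ),
        )
    af_in = (target * (cl_p + cl_ef + q_bulk) - cl_p) / cl_in
    return CalibrationResult(af_in=af_in)


def _neutral_species_permeability(
    drug: DrugParameters, mean_cl_trans: float, ref_ph: float
) -> float:
    """Neutral-species membrane permeability-clearance implied by a mean
    transcellular clearance tabulated at ``ref_ph``."""
    return mean_cl_trans / fraction_unionized(drug.ionization, ref_ph)


def build_clearances(
    drug: DrugParameters,
    physiology: Optional[CNSPhysiology] = None,
    reference: Optional[CNSPhysiology] = None,
    *,
    strict: bool = True,
) -> ClearanceSet:
    """Assemble every directed clearance of the CNS model for one drug
    under ``physiology`` (possibly scenario-perturbed), with tabulated
    clearances anchored at ``reference`` (the healthy default).

    Asymmetry factors are calibrated at reference conditions and carried
    unchanged into perturbed physiologies.  When calibration is
    infeasible, ``strict=True`` raises ``CalibrationError`` while
    ``strict=False`` proceeds with purely passive transport and a
    warning (the flagged result is kept on the returned set).
    """
    if physiology is None:
        physiology = default_physiology()
    if reference is None:
        reference = default_physiology()

    cal = calibrate_asymmetry(drug, reference)
    if not cal.feasible:
        if strict:
            raise CalibrationError(cal.note)
        warnings.warn(cal.note, stacklevel=2)

    ion = drug.ionization

    # --- BBB paracellular (symmetric), rescaled for the current pore radius
    bbb_para = scale_paracellular(
        drug.cl_para, drug, physiology.para_radius_BBB, reference.para_radius_BBB
    )

    # --- BBB transcellular with source-pH rescaling and asymmetry
    bbb_in = (
        cal.af_in
        * drug.cl_trans_in
        * ph_scaling_factor(ion, physiology.pH_plasma, reference.pH_plasma)
    )
    bbb_ef = (
        cal.af_ef
        * drug.cl_trans_ef
        * ph_scaling_factor(ion, physiology.pH_ECF, reference.pH_ECF)
    )

    # --- brain-cell and lysosomal membranes: only the neutral species
    # crosses, so each directed clearance is the neutral-species
    # permeability times the source compartment's unionized fraction.
    mean_cl_trans = 0.5 * (drug.cl_trans_in + drug.cl_trans_ef)
    ps_cell = _neutral_species_permeability(
        drug, mean_cl_trans * physiology.SA_BCM / physiology.SA_BBB, reference.pH_ECF
    )
    cell_in = ps_cell * fraction_unionized(ion, physiology.pH_ECF)
    cell_out = ps_cell * fraction_unionized(ion, physiology.pH_ICF)
    ps_lys = _neutral_species_permeability(
        drug, mean_cl_trans * physiology.SA_LYS / physiology.SA_BBB, reference.pH_ICF
    )
    lys_in = ps_lys * fraction_unionized(ion, physiology.pH_ICF)
    lys_out = ps_lys * fraction_unionized(ion, physiology.pH_LYS)

    # --- BCSFB paracellular: the BBB paracellular permeability per unit
    # effective aperture area, re-evaluated at the BCSFB pore radius and
    # applied to each interface's effective area (half of the BCSFB).
    r_drug = solute_radius(drug.mwt)
    h_bbb = renkin_hindrance(r_drug / reference.para_radius_BBB)
    h_bcsfb = renkin_hindrance(r_drug / physiology.para_radius_BCSFB)
    area_eff_bbb = reference.SA_BBB * reference.frac_SA_para_BBB / 100.0
    bcsfb_halves = derive_bcsfb_area(physiology.SA_BBB)
    area_eff_lv = bcsfb_halves.at_LV * physiology.frac_SA_para_BCSFB / 100.0
    area_eff_tfv = bcsfb_halves.at_TFV * physiology.frac_SA_para_BCSFB / 100.0
    if h_bbb <= 0.0:
        raise ParameterError(
            f"{drug.name}: solute does not pass the reference BBB pore"
        )
    per_area = drug.cl_para / area_eff_bbb * (h_bcsfb / h_bbb)
    bcsfb_para_lv = per_area * area_eff_lv
    bcsfb_para_tfv = per_area * area_eff_tfv

    # --- BCSFB transcellular: BBB transcellular scaled to each
    # interface's area, calibrated to Kp_uu,LV when given (else the BBB
    # factors are reused).  Sources are plasma (pH 7.4) and CSF (pH 7.3),
    # neither of which the scenarios perturb.
    area_ratio_side = bcsfb_halves.at_LV / physiology.SA_BBB
    base_in = drug.cl_trans_in * area_ratio_side
    base_ef = drug.cl_trans_ef * area_ratio_side
    q_chain = physiology.Q_CSF + physiology.Q_ECF_bulk
    if drug.kpuu_lv is not None:
        cal_bcsfb = calibrate_asymmetry(
            drug,
            reference,
            _target=drug.kpuu_lv,
            _cl_p=bcsfb_para_lv + bcsfb_para_tfv,
            _q_bulk=q_chain,
            _cl_in=2.0 * base_in,
            _cl_ef=2.0 * base_ef,
        )
        if not cal_bcsfb.feasible:
            cal_bcsfb = cal  # fall back to the BBB factors
    else:
        cal_bcsfb = cal
    ph_in_bcsfb = ph_scaling_factor(ion, physiology.pH_plasma, reference.pH_plasma)
    ph_ef_bcsfb = ph_scaling_factor(ion, physiology.pH_CSF, reference.pH_CSF)
    bcsfb_in = cal_bcsfb.af_in * base_in * ph_in_bcsfb
    bcsfb_ef = cal_bcsfb.af_ef * base_ef * ph_ef_bcsfb

    return ClearanceSet(
        q_cbf=physiology.Q_CBF,
        bbb_para=bbb_para,
        bbb_trans_in=bbb_in,
        bbb_trans_ef=bbb_ef,
        cell_in=cell_in,
        cell_out=cell_out,
        lys_in=lys_in,
        lys_out=lys_out,
        bcsfb_para_lv=bcsfb_para_lv,
        bcsfb_para_tfv=bcsfb_para_tfv,
        bcsfb_trans_in_lv=bcsfb_in,
        bcsfb_trans_ef_lv=bcsfb_ef,
        bcsfb_trans_in_tfv=bcsfb_in,
        bcsfb_trans_ef_tfv=bcsfb_ef,
        q_ecf_bulk=physiology.Q_ECF_bulk,
        q_csf_chain=q_chain,
        calibration=cal,
    )
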