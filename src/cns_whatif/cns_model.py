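"""Compartmental ODE model of CNS drug disposition.

A fixed one-compartment plasma model (IV infusion, first-order
elimination) drives nine CNS states: brain microvasculature (MV), brain
ECF, brain ICF, lysosomes (LYS), lateral ventricles (LV), third+fourth
ventricles (TFV), cisterna magna (CM) and subarachnoid space (SAS),
plus two audit integrals (cumulative drug mass entering and leaving the
CNS) used for mass-balance checks.  Plasma is a forcing function: the
CNS takes up a negligible fraction of the dose, so CNS uptake does not
deplete plasma and the plasma trace has an exact closed form.

All inter-compartment fluxes are linear (clearance times source
concentration), making the system a constant-matrix linear ODE with a
piecewise-exponential forcing; it is integrated with LSODA on a fixed
output grid so that downstream metrics are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .physicochem import ParameterError
from .physiology import CNSPhysiology, default_physiology
from .transport import ClearanceSet, DrugParameters

__all__ = [
    "DoseRegimen",
    "ODESystem",
    "SimulationResult",
    "SolverError",
    "COMPARTMENTS",
    "plasma_concentration",
    "build_system",
    "simulate",
    "simulate_drug",
]

#: CNS compartments, in state order.
COMPARTMENTS = ("MV", "ECF", "ICF", "LYS", "LV", "TFV", "CM", "SAS")

#: Default observation horizon (min) and the extended horizon used when
#: a monitored compartment has not peaked within the default window.
DEFAULT_HORIZON = 600.0
EXTENDED_HORIZON = 20_000.0

#: Compartments whose unfinished peak triggers the horizon extension.
MONITORED = ("ECF", "ICF")


class SolverError(RuntimeError):
    """Raised when the ODE integration fails or produces invalid output."""


@dataclass(frozen=True)
class DoseRegimen:
    """IV dosing and one-compartment plasma PK.

    Defaults are the virtual regimen used for every drug in the scenario
    analysis: 1 g infused over 15 min into a 108 L central compartment
    cleared at 297 L/h, so that CNS effects are never confounded by
    drug-specific plasma PK.
    """

    dose: float = 1.0  # g
    infusion_duration: float = 15.0  # min
    plasma_cl: float = 297.0  # L/h
    plasma_v: float = 108.0  # L

    def __post_init__(self) -> None:
        for fld in ("dose", "infusion_duration", "plasma_cl", "plasma_v"):
            if getattr(self, fld) <= 0:
                raise ParameterError(f"DoseRegimen.{fld} must be strictly positive")

    @property
    def dose_mg(self) -> float:
        return self.dose * 1000.0

    @property
    def cl_ml_min(self) -> float:
        return self.plasma_cl * 1000.0 / 60.0

    @property
    def v_ml(self) -> float:
        return self.plasma_v * 1000.0

    @property
    def k_el(self) -> float:
        """Plasma elimination rate constant (1/min)."""
        return self.cl_ml_min / self.v_ml

    @property
    def infusion_rate(self) -> float:
        """Infusion rate (mg/min)."""
        return self.dose_mg / self.infusion_duration


def plasma_concentration(t, regimen: DoseRegimen) -> np.ndarray:
    """Closed-form plasma concentration (mg/mL) at time ``t`` (min).

    During the infusion ``C = (R0/CL)(1 - e^{-kt})``; afterwards the
    concentration decays mono-exponentially from its end-of-infusion
    value.  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("time must be non-negative")
    k = regimen.k_el
    css = regimen.infusion_rate / regimen.cl_ml_min  # mg/mL plateau
    tin = regimen.infusion_duration
    c_end = css * (1.0 - np.exp(-k * tin))
    during = css * (1.0 - np.exp(-k * np.minimum(t, tin)))
    after = c_end * np.exp(-k * np.maximum(t - tin, 0.0))
    return np.where(t <= tin, during, after)


def _cumulative_plasma_exposure(t: np.ndarray, regimen: DoseRegimen) -> np.ndarray:
    """Analytic integral of plasma concentration 0..t (mg*min/mL)."""
    k = regimen.k_el
    css = regimen.infusion_rate / regimen.cl_ml_min
    tin = regimen.infusion_duration
    c_end = css * (1.0 - np.exp(-k * tin))
    t1 = np.minimum(t, tin)
    during = css * (t1 - (1.0 - np.exp(-k * t1)) / k)
    t2 = np.maximum(t - tin, 0.0)
    after = c_end * (1.0 - np.exp(-k * t2)) / k
    return during + after


@dataclass(frozen=True)
class ODESystem:
    """Assembled linear state equations of the CNS model.

    ``matrix`` acts on the vector of compartment amounts (mg);
    ``input_coeffs`` multiplies the plasma concentration (mg/mL) to give
    each compartment's inflow from plasma (mL/min); ``output_coeffs``
    gives, per compartment, the clearance (mL/min) of its flux back to
    plasma (used for the mass-balance audit).
    """

    matrix: np.ndarray  # (8, 8) mL/min divided by source volume
    input_coeffs: np.ndarray  # (8,) mL/min against C_plasma
    output_coeffs: np.ndarray  # (8,) mL/min against each C_i
    volumes: np.ndarray  # (8,) mL
    drug: DrugParameters
    physiology: CNSPhysiology
    clearances: ClearanceSet


def build_system(
    drug: DrugParameters,
    physiology: CNSPhysiology,
    clearances: ClearanceSet,
) -> ODESystem:
    """Assemble the linear ODE system for one drug under one physiology.

    Fluxes: MV exchanges with plasma by perfusion (Q_CBF) and with ECF
    across the BBB (symmetric paracellular + directed transcellular);
    ECF exchanges with ICF across the cell membrane and feeds the CSF by
    bulk flow; ICF exchanges with the lysosomes; LV and TFV exchange
    with plasma across the BCSFB; the CSF chain LV -> TFV -> CM -> SAS
    is one-way convective, and the SAS absorbs to plasma at the same
    flow.  Concentrations are amounts divided by (scenario-adjusted)
    volumes.
    """
    p, c = physiology, clearances
    vol = np.array(
        [p.V_MV, p.V_ECF, p.V_ICF, p.V_LYS, p.V_LV, p.V_TFV, p.V_CM, p.V_SAS]
    )
    idx = {name: i for i, name in enumerate(COMPARTMENTS)}
    n = len(COMPARTMENTS)
    # flow[i, j] = clearance (mL/min) carrying drug from compartment j to i
    flow = np.zeros((n, n))

    def connect(src: str, dst: str, cl: float) -> None:
        flow[idx[dst], idx[src]] += cl

    connect("MV", "ECF", c.bbb_para + c.bbb_trans_in)
    connect("ECF", "MV", c.bbb_para + c.bbb_trans_ef)
    connect("ECF", "ICF", c.cell_in)
    connect("ICF", "ECF", c.cell_out)
    connect("ICF", "LYS", c.lys_in)
    connect("LYS", "ICF", c.lys_out)
    connect("ECF", "LV", c.q_ecf_bulk)
    connect("LV", "TFV", c.q_csf_chain)
    connect("TFV", "CM", c.q_csf_chain)
    connect("CM", "SAS", c.q_csf_chain)

    # clearances of flux leaving the CNS back to plasma, per compartment
    output = np.zeros(n)
    output[idx["MV"]] = c.q_cbf
    output[idx["LV"]] = c.bcsfb_para_lv + c.bcsfb_trans_ef_lv
    output[idx["TFV"]] = c.bcsfb_para_tfv + c.bcsfb_trans_ef_tfv
    output[idx["SAS"]] = c.q_csf_chain

    # inflow from plasma, per compartment (mL/min against C_plasma)
    inputs = np.zeros(n)
    inputs[idx["MV"]] = c.q_cbf
    inputs[idx["LV"]] = c.bcsfb_para_lv + c.bcsfb_trans_in_lv
    inputs[idx["TFV"]] = c.bcsfb_para_tfv + c.bcsfb_trans_in_tfv

    matrix = flow / vol[np.newaxis, :]  # divide each column by source volume
    matrix -= np.diag((flow.sum(axis=0) + output) / vol)
    return ODESystem(
        matrix=matrix,
        input_coeffs=inputs,
        output_coeffs=output,
        volumes=vol,
        drug=drug,
        physiology=physiology,
        clearances=c,
    )


@dataclass
class SimulationResult:
    """Concentration-time traces of one drug x scenario run.

    ``concentrations`` holds unbound concentrations in mg/L per
    compartment (including the analytic ``plasma`` trace); the ICF trace
    is cytosolic (the lysosomes are a separate sub-compartment).
    """

    time: np.ndarray  # min
    concentrations: dict  # name -> mg/L
    amounts: np.ndarray  # (n_t, 8) mg
    drug_name: str
    rtol: float
    atol: float
    horizon: float
    extended: bool
    mass_balance_error: float
    regimen: DoseRegimen = field(default_factory=DoseRegimen)

    volumes: np.ndarray = field(default_factory=lambda: np.zeros(8))

    def trace(self, compartment: str) -> np.ndarray:
        return self.concentrations[compartment]

    def total_cell_trace(self) -> np.ndarray:
        """Volume-weighted total brain-cell concentration (cytosol +
        lysosomes), mg/L."""
        v_icf, v_lys = self.volumes[2], self.volumes[3]
        return (self.amounts[:, 2] + self.amounts[:, 3]) / (v_icf + v_lys) * 1e3

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, compartment, concentration) table, mg/L."""
        frames = [
            pd.DataFrame(
                {"time": self.time, "compartment": name, "concentration": conc}
            )
            for name, conc in self.concentrations.items()
        ]
        return pd.concat(frames, ignore_index=True)


def _integrate(
    system: ODESystem,
    regimen: DoseRegimen,
    t_grid: np.ndarray,
    rtol: float,
    atol_conc: float,
) -> np.ndarray:
    """Integrate the forced linear system over ``t_grid``, splitting at
    the end-of-infusion kink so LSODA never steps across it.

    The state is augmented with two audit integrals — cumulative mass
    entering the CNS from plasma and cumulative mass returned to plasma
    — so the mass balance can be closed to solver accuracy.  Returns an
    array of shape (len(t_grid), 10).
    """
    a = system.matrix
    b = system.input_coeffs
    out = system.output_coeffs / system.volumes  # per-amount outflow rates
    b_total = b.sum()
    n = len(COMPARTMENTS)

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        c_pl = plasma_concentration(t, regimen)
        dx = np.empty_like(x)
        dx[:n] = a @ x[:n] + b * c_pl
        dx[n] = b_total * c_pl  # cumulative inflow from plasma
        dx[n + 1] = out @ x[:n]  # cumulative return to plasma
        return dx

    atol = np.concatenate(
        [atol_conc * system.volumes, atol_conc * system.volumes.sum() * np.ones(2)]
    )
    tin = regimen.infusion_duration
    if t_grid[0] < tin < t_grid[-1]:
        breaks = [t_grid[0], tin, t_grid[-1]]
    else:
        breaks = [t_grid[0], t_grid[-1]]
    x0 = np.zeros(n + 2)
    rows = [x0]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        seg = t_grid[(t_grid > lo) & (t_grid <= hi)]
        if len(seg) == 0 or seg[-1] < hi:
            t_eval = np.concatenate([seg, [hi]])
        else:
            t_eval = seg
        sol = solve_ivp(
            rhs,
            (lo, hi),
            x0,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"{system.drug.name}: integration failed on [{lo}, {hi}]: "
                f"{sol.message}"
            )
        x0 = sol.y[:, -1]
        keep = np.isin(sol.t, seg)
        rows.extend(sol.y[:, keep].T)
    return np.vstack(rows)


def simulate(
    system: ODESystem,
    regimen: Optional[DoseRegimen] = None,
    t_end: float = DEFAULT_HORIZON,
    *,
    dt: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    auto_extend: bool = True,
) -> SimulationResult:
    """Integrate the CNS model on a fixed grid of spacing ``dt`` (min).

    If any monitored compartment (brain ECF or ICF) attains its maximum
    on the final grid point — i.e. its peak lies beyond the window — the
    run is repeated once over the extended horizon and flagged.
    Raises ``SolverError`` on integration failure or on negative
    concentrations beyond tolerance.
    """
    if regimen is None:
        regimen = DoseRegimen()
    if t_end <= 0:
        raise ParameterError("t_end must be positive")
    if not 0 < dt <= 1.0:
        raise ParameterError("grid spacing must be in (0, 1] min")

    t_grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    states = _integrate(system, regimen, t_grid, rtol, atol)
    amounts, cum_in, cum_out = states[:, :8], states[:, 8], states[:, 9]

    neg_floor = -atol * system.volumes[np.newaxis, :] * 100.0
    if np.any(amounts < neg_floor):
        raise SolverError(
            f"{system.drug.name}: negative concentrations beyond tolerance"
        )
    amounts = np.maximum(amounts, 0.0)

    conc = {
        name: amounts[:, i] / system.volumes[i] * 1e3  # mg/mL -> mg/L
        for i, name in enumerate(COMPARTMENTS)
    }
    conc["plasma"] = plasma_concentration(t_grid, regimen) * 1e3

    if auto_extend and t_end < EXTENDED_HORIZON:
        last = len(t_grid) - 1
        if any(int(np.argmax(conc[name])) == last for name in MONITORED):
            result = simulate(
                system,
                regimen,
                EXTENDED_HORIZON,
                dt=dt,
                rtol=rtol,
                atol=atol,
                auto_extend=False,
            )
            result.extended = True
            return result

    # mass-balance audit: the total CNS amount must equal cumulative
    # inflow minus cumulative outflow; the inflow integral itself is
    # audited against the analytic plasma exposure.
    exposure = _cumulative_plasma_exposure(t_grid, regimen)
    cum_in_analytic = system.input_coeffs.sum() * exposure
    residual = amounts.sum(axis=1) - (cum_in - cum_out)
    forcing_residual = cum_in - cum_in_analytic
    scale = max(float(cum_in_analytic[-1]), 1e-12)
    balance = float(
        max(np.max(np.abs(residual)), np.max(np.abs(forcing_residual))) / scale
    )

    return SimulationResult(
        time=t_grid,
        concentrations=conc,
        amounts=amounts,
        drug_name=system.drug.name,
        rtol=rtol,
        atol=atol,
        horizon=float(t_grid[-1]),
        extended=False,
        mass_balance_error=balance,
        regimen=regimen,
        volumes=system.volumes,
    )


def simulate_drug(
    drug: DrugParameters,
    physiology: Optional[CNSPhysiology] = None,
    regimen: Optional[DoseRegimen] = None,
    *,
    reference: Optional[CNSPhysiology] = None,
    strict: bool = True,
    **kwargs,
) -> SimulationResult:
    """Convenience wrapper: build clearances and system, then simulate."""
    from .transport import build_clearances

    if physiology is None:
        physiology = default_physiology()
    clearances = build_clearances(
        drug, physiology, reference=reference, strict=strict
    )
    system = build_system(drug, physiology, clearances)
    return simulate(system, regimen, **kwargs)
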