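"""Pathophysiological what-if scenarios and the drug x scenario grid.

Each scenario perturbs exactly one CNS physiology parameter — cerebral
blood flow, BBB tight-junction pore radius, brain ECF volume, or the pH
of brain ECF or ICF — to a value reported for CNS disease states
(ischemia, traumatic brain injury, tumors, epilepsy, anesthesia/sleep,
aging).  The same fixed plasma model and dosing regimen are used for
every drug and scenario, so any change in brain exposure is attributable
to the CNS perturbation alone.  Results are summarized per drug and
compartment as log2 fold changes against the reference scenario.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cns_model import EXTENDED_HORIZON, DoseRegimen, simulate_drug
from .metrics import ExtrapolationError, PKSummary, summarize, two_fold_change
from .physicochem import ParameterError
from .physiology import CNSPhysiology, default_physiology, validate
from .transport import DrugParameters

__all__ = [
    "Scenario",
    "ScenarioMode",
    "GridResult",
    "REFERENCE_SCENARIO",
    "pathophysiological_scenarios",
    "apply_scenario",
    "simulate_and_summarize",
    "run_grid",
]

logger = logging.getLogger(__name__)

#: Physiology fields a scenario may target.
SCENARIO_TARGETS = ("Q_CBF", "para_radius_BBB", "V_ECF", "pH_ECF", "pH_ICF")

#: Compartments reported in the heatmap (the drug target sites).
HEATMAP_COMPARTMENTS = ("ECF", "ICF")

#: Metrics reported per compartment in the heatmap.
HEATMAP_METRICS = ("cmax", "tmax", "auc_0_t", "kpuu_bbb", "kpuu_cell")


class ScenarioMode(str, enum.Enum):
    REFERENCE = "reference"
    MULTIPLIER = "multiplier"
    ABSOLUTE = "absolute"


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of one physiology parameter.

    Multiplier mode scales the reference value (used for flows, volumes
    and pore radii); absolute mode sets the value outright and is only
    meaningful for pH targets.
    """

    name: str
    target: Optional[str] = None
    mode: ScenarioMode = ScenarioMode.REFERENCE
    value: Optional[float] = None

    def __post_init__(self) -> None:
        mode = ScenarioMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is ScenarioMode.REFERENCE:
            return
        if self.target not in SCENARIO_TARGETS:
            raise ParameterError(
                f"scenario {self.name!r}: target must be one of {SCENARIO_TARGETS}"
            )
        if self.value is None:
            raise ParameterError(f"scenario {self.name!r}: value required")
        if mode is ScenarioMode.MULTIPLIER and self.value <= 0:
            raise ParameterError(f"scenario {self.name!r}: multiplier must be > 0")
        if mode is ScenarioMode.ABSOLUTE and not self.target.startswith("pH"):
            raise ParameterError(
                f"scenario {self.name!r}: absolute mode is reserved for pH targets"
            )

    @property
    def is_reference(self) -> bool:
        return self.mode is ScenarioMode.REFERENCE


REFERENCE_SCENARIO = Scenario(name="reference")


def pathophysiological_scenarios() -> list[Scenario]:
    """The standard what-if set: the reference plus ten one-at-a-time
    disease-level perturbations (CBF to 70%/150%, pore radius to
    50%/500%, ECF volume to 70%/150%, pH_ECF to 5/8, pH_ICF to
    6/7.6)."""
    mult = ScenarioMode.MULTIPLIER
    absolute = ScenarioMode.ABSOLUTE
    return [
        REFERENCE_SCENARIO,
        Scenario("CBF_low", "Q_CBF", mult, 0.7),
        Scenario("CBF_high", "Q_CBF", mult, 1.5),
        Scenario("para_radius_low", "para_radius_BBB", mult, 0.5),
        Scenario("para_radius_high", "para_radius_BBB", mult, 5.0),
        Scenario("V_ECF_low", "V_ECF", mult, 0.7),
        Scenario("V_ECF_high", "V_ECF", mult, 1.5),
        Scenario("pH_ECF_low", "pH_ECF", absolute, 5.0),
        Scenario("pH_ECF_high", "pH_ECF", absolute, 8.0),
        Scenario("pH_ICF_low", "pH_ICF", absolute, 6.0),
        Scenario("pH_ICF_high", "pH_ICF", absolute, 7.6),
    ]


def apply_scenario(
    physiology: CNSPhysiology, scenario: Scenario
) -> CNSPhysiology:
    """Return a copy of ``physiology`` with the scenario applied.

    Only the targeted field changes: an ECF volume perturbation does
    not rescale surface areas, flows or the other volumes, and pH
    perturbations act purely through ionization at clearance-build
    time.  The perturbed physiology must still pass validation."""
    if scenario.is_reference:
        return physiology
    current = getattr(physiology, scenario.target)
    if scenario.mode is ScenarioMode.MULTIPLIER:
        new_value = current * scenario.value
    else:
        new_value = scenario.value
    perturbed = physiology.replace(**{scenario.target: new_value})
    violations = validate(perturbed)
    if violations:
        raise ParameterError(
            f"scenario {scenario.name!r} produces an invalid physiology: "
            + "; ".join(violations)
        )
    logger.info(
        "scenario %s: %s %s -> %g", scenario.name, scenario.target, current, new_value
    )
    return perturbed


def simulate_and_summarize(
    drug: DrugParameters,
    physiology: Optional[CNSPhysiology] = None,
    regimen: Optional[DoseRegimen] = None,
    *,
    reference: Optional[CNSPhysiology] = None,
    compartments: Sequence[str] = HEATMAP_COMPARTMENTS,
    strict: bool = False,
    **simulate_kwargs,
):
    """Simulate one drug and summarize the requested compartments,
    extending the horizon when the default window is too short.

    Two conditions trigger a single re-run over the extended horizon:
    a monitored compartment that has not peaked (handled inside
    ``simulate``), and a terminal phase so incomplete that more than
    the accepted fraction of an AUC(0-inf) would be extrapolated.
    Returns ``(result, {compartment: PKSummary})``.
    """
    result = simulate_drug(
        drug, physiology, regimen, reference=reference, strict=strict,
        **simulate_kwargs,
    )
    try:
        summaries = {c: summarize(result, c) for c in compartments}
    except ExtrapolationError:
        if result.horizon >= EXTENDED_HORIZON:
            raise
        simulate_kwargs = dict(simulate_kwargs)
        simulate_kwargs["t_end"] = EXTENDED_HORIZON
        simulate_kwargs["auto_extend"] = False
        result = simulate_drug(
            drug, physiology, regimen, reference=reference, strict=strict,
            **simulate_kwargs,
        )
        result.extended = True
        summaries = {c: summarize(result, c) for c in compartments}
    return result, summaries


@dataclass
class GridResult:
    """Raw per-run PK summaries and the fold-change heatmap table.

    ``summaries`` has one row per (drug, scenario, compartment);
    ``heatmap`` has one row per (drug, compartment) and one column per
    (scenario, metric) holding log2 fold changes vs the reference.
    ``failures`` records (drug, scenario) cells that could not be
    simulated, with the reason."""

    summaries: pd.DataFrame
    heatmap: pd.DataFrame
    failures: list


def run_grid(
    drugs: Sequence[DrugParameters],
    scenarios: Iterable[Scenario],
    regimen: Optional[DoseRegimen] = None,
    physiology: Optional[CNSPhysiology] = None,
    **simulate_kwargs,
) -> GridResult:
    """Simulate every drug under every scenario and tabulate the PK
    metrics and their fold changes against the reference scenario.

    The plasma model is identical across all cells.  Per-cell failures
    (calibration or solver) are recorded and skipped rather than
    aborting the grid.  The computation is deterministic."""
    scenarios = list(scenarios)
    if not drugs:
        raise ParameterError("run_grid requires at least one drug")
    if not any(s.is_reference for s in scenarios):
        raise ParameterError("the scenario set must include the reference")
    if regimen is None:
        regimen = DoseRegimen()
    if physiology is None:
        physiology = default_physiology()

    rows = []
    failures = []
    for drug in drugs:
        for scenario in scenarios:
            try:
                perturbed = apply_scenario(physiology, scenario)
                result, summaries = simulate_and_summarize(
                    drug,
                    perturbed,
                    regimen,
                    reference=physiology,
                    **simulate_kwargs,
                )
                for compartment in HEATMAP_COMPARTMENTS:
                    summary: PKSummary = summaries[compartment]
                    rows.append(
                        {
                            "drug": drug.name,
                            "scenario": scenario.name,
                            "compartment": compartment,
                            "cmax": summary.cmax,
                            "tmax": summary.tmax,
                            "auc_0_t": summary.auc_0_t,
                            "auc_0_inf": summary.auc_0_inf,
                            "kpuu_bbb": summary.kpuu_bbb,
                            "kpuu_cell": summary.kpuu_cell,
                            "extended": result.extended,
                        }
                    )
            except Exception as exc:  # noqa: BLE001 - cell-level isolation
                logger.warning("cell (%s, %s) failed: %s", drug.name, scenario.name, exc)
                failures.append((drug.name, scenario.name, str(exc)))
    summaries = pd.DataFrame(rows)

    heat_rows = []
    for (drug_name, compartment), group in summaries.groupby(
        ["drug", "compartment"], sort=False
    ):
        by_scenario = group.set_index("scenario")
        if "reference" not in by_scenario.index:
            continue
        ref = by_scenario.loc["reference"]
        row = {"drug": drug_name, "compartment": compartment}
        for scenario in scenarios:
            if scenario.name not in by_scenario.index:
                continue
            pert = by_scenario.loc[scenario.name]
            for metric in HEATMAP_METRICS:
                row[f"{scenario.name}:{metric}"] = two_fold_change(
                    float(pert[metric]), float(ref[metric])
                )
        heat_rows.append(row)
    heatmap = pd.DataFrame(heat_rows)
    return GridResult(summaries=summaries, heatmap=heatmap, failures=failures)
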