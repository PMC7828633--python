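"""Reference human CNS physiology: compartment volumes, fluid flows,
barrier surface areas, pore radii, and compartment pH values.

The parameter set describes a healthy adult human CNS as used by
compartmental CNS PBPK models: brain microvasculature (MV), brain
extracellular fluid (ECF), brain intracellular fluid (ICF) with a
lysosomal sub-compartment (LYS), and the cerebrospinal fluid chain of
lateral ventricles (LV), third+fourth ventricles (TFV), cisterna magna
(CM), and subarachnoid space (SAS).  Several stored values are derived
from others by fixed anatomical rules (lysosomal volume is 1/80 of ICF
volume; the blood-CSF barrier area is 10% of the BBB area, split evenly
between the LV and TFV interfaces); ``validate`` checks those rules.

Units are fixed by the schema: volumes mL, flows mL/min, areas cm^2,
radii and widths um, pH dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import yaml

from .physicochem import ParameterError

#: Literature ranges for parameters that have them (metadata only;
#: simulations always use the central values stored on the dataclass).
PARAMETER_RANGES = {
    "V_ECF": (217.0, 300.0),
    "V_MV": (37.0, 50.0),
    "V_LV": (11.0, 16.0),
    "V_TFV": (2.3, 3.7),
    "V_SAS": (110.0, 116.0),
    "Q_CBF": (644.0, 722.0),
    "Q_CSF": (0.28, 0.68),
    "SA_BBB": (140_000.0, 360_000.0),
    "para_radius_BBB": (0.0007, 0.0009),
}


@dataclass(frozen=True)
class CNSPhysiology:
    """One consistent human CNS physiology parameter set."""

    # volumes (mL)
    V_brain_total: float
    V_ECF: float
    V_ICF: float
    V_LYS: float
    V_MV: float
    V_LV: float
    V_TFV: float
    V_CM: float
    V_SAS: float
    # flows (mL/min)
    Q_CBF: float
    Q_ECF_bulk: float
    Q_CSF: float
    # surface areas (cm^2)
    SA_BBB: float
    SA_BCSFB: float
    SA_BCM: float
    SA_LYS: float
    # barrier geometry
    width_barrier: float  # um
    para_radius_BBB: float  # um
    para_radius_BCSFB: float  # um
    frac_SA_trans: float  # % of barrier area available transcellularly
    frac_SA_para_BBB: float  # % of BBB area that is paracellular aperture
    frac_SA_para_BCSFB: float  # % of BCSFB area that is paracellular aperture
    # pH
    pH_plasma: float
    pH_ECF: float
    pH_CSF: float
    pH_ICF: float
    pH_LYS: float
    # counts
    N_cells: float

    def replace(self, **changes) -> "CNSPhysiology":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CNSPhysiology":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ParameterError(f"unknown physiology keys: {sorted(unknown)}")
        missing = fields - set(data)
        if missing:
            raise ParameterError(f"missing physiology keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def default_physiology() -> CNSPhysiology:
    """The reference healthy human CNS parameter set (central values)."""
    return CNSPhysiology(
        V_brain_total=1250.0,
        V_ECF=253.0,
        V_ICF=1000.0,
        V_LYS=12.5,
        V_MV=45.0,
        V_LV=20.0,
        V_TFV=3.0,
        V_CM=1.0,
        V_SAS=116.0,
        Q_CBF=689.0,
        Q_ECF_bulk=0.2,
        Q_CSF=0.42,
        SA_BBB=150_000.0,
        SA_BCSFB=15_000.0,
        SA_BCM=2_666_520.0,
        SA_LYS=1_980_260.0,
        width_barrier=0.5,
        para_radius_BBB=0.0007,
        para_radius_BCSFB=0.0027,
        frac_SA_trans=99.8,
        frac_SA_para_BBB=0.004,
        frac_SA_para_BCSFB=0.016,
        pH_plasma=7.4,
        pH_ECF=7.3,
        pH_CSF=7.3,
        pH_ICF=7.0,
        pH_LYS=5.0,
        N_cells=1.71e11,
    )


def derive_lysosome_volume(v_icf: float) -> float:
    """Lysosomal volume as 1.25% (1/80) of brain ICF volume (mL)."""
    if v_icf <= 0:
        raise ParameterError(f"V_ICF must be positive, got {v_icf}")
    return v_icf / 80.0


class BCSFBArea(NamedTuple):
    total: float
    at_LV: float
    at_TFV: float


def derive_bcsfb_area(sa_bbb: float) -> BCSFBArea:
    """Blood-CSF barrier area as 10% of the BBB area (cm^2), split
    50/50 between the lateral-ventricle and third+fourth-ventricle
    interfaces."""
    if sa_bbb <= 0:
        raise ParameterError(f"SA_BBB must be positive, got {sa_bbb}")
    total = 0.1 * sa_bbb
    return BCSFBArea(total=total, at_LV=total / 2.0, at_TFV=total / 2.0)


_POSITIVE_FIELDS = (
    "V_brain_total", "V_ECF", "V_ICF", "V_LYS", "V_MV", "V_LV", "V_TFV",
    "V_CM", "V_SAS", "Q_CBF", "Q_ECF_bulk", "Q_CSF", "SA_BBB", "SA_BCSFB",
    "SA_BCM", "SA_LYS", "width_barrier", "para_radius_BBB",
    "para_radius_BCSFB", "N_cells",
)
_PH_FIELDS = ("pH_plasma", "pH_ECF", "pH_CSF", "pH_ICF", "pH_LYS")


def validate(physiology: CNSPhysiology, rel_tol: float = 0.05) -> list[str]:
    """Check internal consistency; returns a list of violation messages
    (empty when the parameter set is valid).  Violations are data, not
    exceptions, so callers can report all of them at once."""
    violations: list[str] = []
    for name in _POSITIVE_FIELDS:
        if getattr(physiology, name) <= 0:
            violations.append(f"{name}: must be strictly positive")
    for name in _PH_FIELDS:
        if not 0.0 <= getattr(physiology, name) <= 14.0:
            violations.append(f"{name}: pH must lie in [0, 14]")
    if violations:
        return violations  # ratio rules are meaningless on bad magnitudes

    expected_lys = derive_lysosome_volume(physiology.V_ICF)
    if abs(physiology.V_LYS - expected_lys) > rel_tol * expected_lys:
        violations.append(
            f"V_LYS: expected V_ICF/80 = {expected_lys:g}, got {physiology.V_LYS:g}"
        )
    expected_bcsfb = derive_bcsfb_area(physiology.SA_BBB).total
    if abs(physiology.SA_BCSFB - expected_bcsfb) > rel_tol * expected_bcsfb:
        violations.append(
            f"SA_BCSFB: expected 0.1*SA_BBB = {expected_bcsfb:g}, "
            f"got {physiology.SA_BCSFB:g}"
        )
    # ECF bulk flow is formed from (roughly half of) the CSF flow
    if physiology.Q_ECF_bulk > physiology.Q_CSF:
        violations.append("Q_ECF_bulk: must not exceed Q_CSF")
    return violations


_YAML_HEADER = (
    "# Human CNS physiology parameter set.\n"
    "# Units: volumes mL; flows mL/min; surface areas cm^2;\n"
    "# width/para_radius um; frac_SA_* percent; pH dimensionless.\n"
)


def write_physiology(physiology: CNSPhysiology, path) -> None:
    """Write a physiology as a flat key-value YAML file with a unit header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_YAML_HEADER)
        yaml.safe_dump(physiology.to_dict(), fh, sort_keys=False)


def read_physiology(path) -> CNSPhysiology:
    """Read a physiology from a flat key-value YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a flat key-value mapping")
    return CNSPhysiology.from_dict(data)
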