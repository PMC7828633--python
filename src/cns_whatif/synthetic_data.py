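"""Drug panels: the published eight-drug reference set and virtual
panels spanning the same physicochemical space.

The reference panel carries the fully published parameters of eight
well-characterized CNS-relevant drugs (caffeine, cephalexin, codeine,
gabapentin, genistein, levetiracetam, morphine, thiopental): molecular
weight, lipophilicity, ionization class and constants, measured
Kp_uu targets, transporter-substrate annotations and BBB clearances.

Virtual panels emulate the wider 46-drug study space (Mwt 150-500
g/mol, logP -3.7 to 4.3, pk_a 3-16, pk_b -9 to 10) so every pipeline
stage can be exercised at any panel size without external data.  The
synthetic clearance formulas are deliberately simple monotone
relations — paracellular clearance falls with molecular size (hindered
pore diffusion), transcellular clearance rises with lipophilicity —
and are not property predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .physicochem import IonClass, IonizationSpec, ParameterError
from .physiology import default_physiology
from .transport import (
    DrugParameters,
    renkin_hindrance,
    aqueous_diffusivity,
    solute_radius,
)

__all__ = ["VirtualDrugSpec", "reference_drug_panel", "generate_virtual_drugs"]

#: Physicochemical spans of the study's drug space; virtual panels must
#: stay within them.
STUDY_RANGES = {
    "mwt": (150.0, 500.0),
    "logp": (-3.7, 4.3),
    "pka": (3.0, 16.0),
    "pkb": (-9.0, 10.0),
    "kpuu_ecf": (0.01, 3.0),
}


def reference_drug_panel() -> list[DrugParameters]:
    """The eight fully published drugs, parameters verbatim (clearances
    in mL/min at reference physiology; below-detection values are 0)."""

    def drug(name, mwt, logp, cls, pka, pkb, kpuu, flags, cl_p, cl_ef, cl_in):
        return DrugParameters(
            name=name,
            mwt=mwt,
            logp=logp,
            ionization=IonizationSpec(ion_class=cls, pka=pka, pkb=pkb),
            kpuu_ecf=kpuu,
            kpuu_lv=kpuu,
            kpuu_cm=kpuu,
            transporters=frozenset(flags),
            cl_para=cl_p,
            cl_trans_ef=cl_ef,
            cl_trans_in=cl_in,
        )

    n, a, b, z = IonClass.NEUTRAL, IonClass.ACID, IonClass.BASE, IonClass.ZWITTERION
    return [
        drug("caffeine", 194.2, -0.07, n, None, -0.92, 0.96, {"BCRP"}, 48.9, 4.28, 2.38),
        drug("cephalexin", 347.4, 0.65, z, 3.26, 7.23, 0.015, {"OAT3"}, 37.4, 2736.0, 0.0),
        drug("codeine", 299.4, 1.39, b, 13.8, 9.19, 1.0, set(), 40.1, 0.71, 0.89),
        drug("gabapentin", 171.2, 1.25, z, 4.63, 9.91, 0.13, set(), 51.9, 347.0, 0.0),
        drug("genistein", 270.2, 3.04, a, 6.55, -5.3, 0.04, {"BCRP", "p-gp"}, 42.3, 1557.0, 245.0),
        drug("levetiracetam", 170.2, -0.64, n, 16.1, -1.6, 0.31, {"p-gp", "MRP4"}, 52.0, 3.73, 0.69),
        drug("morphine", 285.3, 0.87, b, 10.3, 9.12, 0.23, {"p-gp"}, 41.0, 30.2, 0.34),
        drug("thiopental", 242.3, 2.85, a, 7.2, -3.0, 0.9, set(), 44.2, 569.0, 508.0),
    ]


@dataclass(frozen=True)
class VirtualDrugSpec:
    """Sampling specification for a virtual drug panel.

    Ranges default to (and must stay within) the study's spans; the
    ion-class mix gives the sampling proportions of the four classes.
    """

    n: int = 46
    seed: int = 0
    mwt_range: tuple = STUDY_RANGES["mwt"]
    logp_range: tuple = STUDY_RANGES["logp"]
    pka_range: tuple = STUDY_RANGES["pka"]
    pkb_range: tuple = STUDY_RANGES["pkb"]
    kpuu_range: tuple = STUDY_RANGES["kpuu_ecf"]
    class_mix: dict = field(
        default_factory=lambda: {
            IonClass.NEUTRAL: 0.25,
            IonClass.ACID: 0.25,
            IonClass.BASE: 0.30,
            IonClass.ZWITTERION: 0.20,
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("panel size must be at least 1")
        for attr, key in [
            ("mwt_range", "mwt"),
            ("logp_range", "logp"),
            ("pka_range", "pka"),
            ("pkb_range", "pkb"),
            ("kpuu_range", "kpuu_ecf"),
        ]:
            lo, hi = getattr(self, attr)
            full_lo, full_hi = STUDY_RANGES[key]
            if not (full_lo <= lo < hi <= full_hi):
                raise ParameterError(
                    f"{attr} ({lo}, {hi}) must lie within the study span "
                    f"({full_lo}, {full_hi})"
                )
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class proportions must sum to 1, got {total}")


def _synthetic_paracellular(mwt: float, pore_radius: float) -> float:
    """Synthetic paracellular clearance (mL/min): proportional to
    aqueous diffusivity times the Renkin hindrance at the reference
    pore, anchored so a 194 g/mol solute clears ~49 mL/min."""
    coeff = 1.414e8  # mL/min per (cm^2/s), anchor at Mwt ~194
    lam = solute_radius(mwt) / pore_radius
    return coeff * aqueous_diffusivity(mwt) * renkin_hindrance(lam)


def _synthetic_transcellular(logp: float) -> float:
    """Synthetic passive transcellular clearance (mL/min): log-linear
    in lipophilicity, spanning ~0.01-5000 over the study logP span."""
    return 10.0 ** (0.7 * logp + 0.7)


def generate_virtual_drugs(spec: Optional[VirtualDrugSpec] = None) -> list[DrugParameters]:
    """Sample a reproducible virtual drug panel.

    Physicochemical properties are uniform within the spec's ranges,
    the ion class follows the mix, and Kp_uu,ECF is log-uniform so that
    net-influx and strong net-efflux drugs are both represented.
    Clearances follow the documented monotone synthetic formulas with
    the influx/efflux split left symmetric — the asymmetry needed to
    meet the sampled Kp_uu is reconstructed downstream by calibration,
    which is feasible for every generated drug (both transcellular
    directions are strictly positive).
    """
    if spec is None:
        spec = VirtualDrugSpec()
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_mix.keys())
    probs = np.array([spec.class_mix[c] for c in classes], dtype=float)
    pore_radius = default_physiology().para_radius_BBB

    drugs = []
    for i in range(spec.n):
        mwt = rng.uniform(*spec.mwt_range)
        logp = rng.uniform(*spec.logp_range)
        ion_class = classes[rng.choice(len(classes), p=probs)]
        pka = rng.uniform(*spec.pka_range) if ion_class in (
            IonClass.ACID, IonClass.ZWITTERION
        ) else None
        pkb = rng.uniform(*spec.pkb_range) if ion_class in (
            IonClass.BASE, IonClass.ZWITTERION
        ) else None
        lo, hi = spec.kpuu_range
        kpuu = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        cl_p = _synthetic_paracellular(mwt, pore_radius)
        cl_t = _synthetic_transcellular(logp)
        passive = (cl_p + cl_t) / (cl_p + cl_t + 0.2)
        # annotate net active efflux with an efflux-transporter flag
        flags = frozenset({"p-gp"}) if kpuu < 0.9 * passive else frozenset()
        drugs.append(
            DrugParameters(
                name=f"virtual_{i:03d}",
                mwt=mwt,
                logp=logp,
                ionization=IonizationSpec(ion_class=ion_class, pka=pka, pkb=pkb),
                kpuu_ecf=kpuu,
                kpuu_lv=kpuu,
                kpuu_cm=kpuu,
                transporters=flags,
                cl_para=cl_p,
                cl_trans_ef=cl_t,
                cl_trans_in=cl_t,
            )
        )
    return drugs
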