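"""Ionization arithmetic for pH-dependent membrane transport.

Only the neutral (unionized) microspecies of a drug crosses lipid
membranes in this model; charged species are confined to aqueous routes
(paracellular pores and bulk fluid flows).  The fraction of drug present
as the neutral species in a compartment therefore controls every
transcellular clearance, and differences in pH across a membrane produce
unequal partitioning of total unbound drug (ion trapping, e.g. of bases
in acidic lysosomes).

Fractions are computed with the Henderson-Hasselbalch relation on the
strongest acidic and/or basic group.  Basic groups are parameterized by
the pKa of the conjugate acid (the "strongest basic pKa" convention of
common predictors), so a negative ``pkb`` simply means the compound is
essentially never protonated at physiological pH.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class IonClass(str, enum.Enum):
    """Ionization class of a drug at physiological pH."""

    ACID = "acid"
    BASE = "base"
    NEUTRAL = "neutral"
    ZWITTERION = "zwitterion"


class ParameterError(ValueError):
    """Raised when a drug or physiology parameter is missing or invalid."""


@dataclass(frozen=True)
class IonizationSpec:
    """Ionization constants of one drug.

    Parameters
    ----------
    ion_class:
        One of acid / base / neutral / zwitterion.
    pka:
        Acid dissociation constant of the strongest acidic group.
        Required for acids and zwitterions.
    pkb:
        Conjugate-acid pKa of the strongest basic group.  Required for
        bases and zwitterions.

    Notes
    -----
    At most one acidic and one basic group are modelled; multiprotic
    behaviour beyond that is out of scope.  Neutral drugs may carry pk
    values for bookkeeping but they are ignored (fraction unionized is
    exactly 1 at every pH).
    """

    ion_class: IonClass
    pka: Optional[float] = None
    pkb: Optional[float] = None

    def __post_init__(self) -> None:
        cls = IonClass(self.ion_class)
        object.__setattr__(self, "ion_class", cls)
        if cls in (IonClass.ACID, IonClass.ZWITTERION) and self.pka is None:
            raise ParameterError(f"ion class {cls.value!r} requires pka")
        if cls in (IonClass.BASE, IonClass.ZWITTERION) and self.pkb is None:
            raise ParameterError(f"ion class {cls.value!r} requires pkb")


def _check_ph(ph: float) -> None:
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH {ph} outside [0, 14]")


def fraction_unionized(spec: IonizationSpec, ph: float) -> float:
    """Fraction of total drug present as the neutral microspecies.

    Henderson-Hasselbalch on each ionizable group:

    * acid:       ``1 / (1 + 10**(pH - pka))``
    * base:       ``1 / (1 + 10**(pkb - pH))`` (pkb = conjugate-acid pKa)
    * zwitterion: product of the acid and base factors
    * neutral:    1 exactly

    Returns a value in (0, 1].
    """
    _check_ph(ph)
    cls = spec.ion_class
    if cls is IonClass.NEUTRAL:
        return 1.0
    if cls is IonClass.ACID:
        return 1.0 / (1.0 + 10.0 ** (ph - spec.pka))
    if cls is IonClass.BASE:
        return 1.0 / (1.0 + 10.0 ** (spec.pkb - ph))
    # zwitterion: both groups must be neutral simultaneously
    acid = 1.0 / (1.0 + 10.0 ** (ph - spec.pka))
    base = 1.0 / (1.0 + 10.0 ** (spec.pkb - ph))
    return acid * base


def ph_scaling_factor(spec: IonizationSpec, ph_new: float, ph_ref: float) -> float:
    """Multiplier applied to a transcellular clearance when the source
    compartment's pH moves from ``ph_ref`` to ``ph_new``.

    Defined as ``fraction_unionized(ph_new) / fraction_unionized(ph_ref)``:
    clearances tabulated at reference pH already embed the reference
    ionization, so only the ratio is applied.  Identity when the pH is
    unchanged or the drug is neutral; composes multiplicatively across
    successive pH changes.
    """
    return fraction_unionized(spec, ph_new) / fraction_unionized(spec, ph_ref)
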