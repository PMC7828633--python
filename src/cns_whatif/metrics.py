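"""Non-compartmental PK summary statistics of simulated traces.

Rate of target-site exposure is summarized by C_max and T_max, extent
by AUC over the observation window and extrapolated to infinity.  The
unbound partition coefficients are AUC(0-inf) ratios:

* ``Kp_uu,BBB  = AUC(0-inf, brain ECF) / AUC(0-inf, microvascular)``
* ``Kp_uu,cell = AUC(0-inf, brain ICF) / AUC(0-inf, brain ECF)``

Scenario effects are expressed as the two-fold-change statistic,
``log2(metric_perturbed / metric_reference)``: a value of +-1 is a
doubling or halving.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .physicochem import ParameterError

__all__ = [
    "PKSummary",
    "ExtrapolationError",
    "cmax_tmax",
    "auc",
    "auc_infinity",
    "kpuu",
    "two_fold_change",
    "summarize",
]

#: Number of terminal grid points used for the log-linear elimination fit.
TERMINAL_POINTS = 5
#: Largest acceptable extrapolated fraction of AUC(0-inf).
MAX_EXTRAPOLATED_FRACTION = 0.20


class ExtrapolationError(ValueError):
    """Raised when a trace has no usable terminal elimination phase."""


def cmax_tmax(time: np.ndarray, conc: np.ndarray) -> tuple[float, float]:
    """Peak concentration and its time; ties broken to the earliest
    time.  An all-zero trace returns (0, 0) with a warning."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if len(time) == 0 or len(time) != len(conc):
        raise ParameterError("trace must be non-empty with matching grids")
    if np.all(conc == 0.0):
        warnings.warn("all-zero trace: Cmax/Tmax undefined", stacklevel=2)
        return 0.0, 0.0
    i = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[i]), float(time[i])


def _window_indices(time: np.ndarray, t_start: float, t_end: float) -> slice:
    if t_start >= t_end:
        raise ParameterError("t_start must precede t_end")
    i0 = np.searchsorted(time, t_start)
    i1 = np.searchsorted(time, t_end)
    if i0 >= len(time) or time[i0] != t_start or i1 >= len(time) or time[i1] != t_end:
        raise ParameterError(
            f"window [{t_start}, {t_end}] must lie on the stored grid"
        )
    return slice(i0, i1 + 1)


def auc(
    time: np.ndarray,
    conc: np.ndarray,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> float:
    """Linear trapezoidal AUC on the stored grid (mass*min/volume).

    The window endpoints must coincide with grid points, which makes
    the integral exactly additive across adjacent windows."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if t_start is None:
        t_start = float(time[0])
    if t_end is None:
        t_end = float(time[-1])
    win = _window_indices(time, t_start, t_end)
    return float(np.trapezoid(conc[win], time[win]))


def terminal_rate_constant(
    time: np.ndarray, conc: np.ndarray, n_terminal: int = TERMINAL_POINTS
) -> float:
    """Elimination rate constant (1/min) from a log-linear fit over the
    last ``n_terminal`` grid points after T_max."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    cmax, tmax = cmax_tmax(time, conc)
    # Ignore the deep tail where the trace has decayed into solver
    # noise: a point 6 orders of magnitude below the peak contributes
    # nothing to the AUC but can flip the fitted slope's sign.
    floor = cmax * 1e-6
    post = (time > tmax) & (conc > floor)
    if post.sum() < 3:
        post = (time > tmax) & (conc > 0.0)
    if post.sum() < 3:
        raise ExtrapolationError(
            "need at least 3 positive post-peak points for the terminal fit"
        )
    t_fit = time[post][-n_terminal:]
    c_fit = conc[post][-n_terminal:]
    slope = np.polyfit(t_fit, np.log(c_fit), 1)[0]
    if slope >= 0.0:
        raise ExtrapolationError(
            f"terminal phase not decaying (slope {slope:.3g} >= 0)"
        )
    return -float(slope)


def auc_infinity(
    time: np.ndarray,
    conc: np.ndarray,
    n_terminal: int = TERMINAL_POINTS,
    max_extrapolated_fraction: float = MAX_EXTRAPOLATED_FRACTION,
) -> float:
    """AUC extrapolated to infinity: the trapezoidal AUC over the window
    plus ``C_last / k_el`` with the terminal rate constant from a
    log-linear fit.  Refuses (raises ``ExtrapolationError``) when the
    terminal phase is not decaying or the extrapolated tail exceeds the
    accepted fraction of the total."""
    time = np.asarray(time, dtype=float)
    conc = np.asarray(conc, dtype=float)
    k_el = terminal_rate_constant(time, conc, n_terminal)
    auc_window = auc(time, conc)
    tail = float(conc[-1]) / k_el
    total = auc_window + tail
    if total > 0 and tail / total > max_extrapolated_fraction:
        raise ExtrapolationError(
            f"extrapolated fraction {tail / total:.1%} exceeds "
            f"{max_extrapolated_fraction:.0%}; extend the observation window"
        )
    return total


def kpuu(
    time: np.ndarray, conc_numerator: np.ndarray, conc_denominator: np.ndarray
) -> float:
    """Unbound partition coefficient: ratio of the two AUC(0-inf)."""
    return auc_infinity(time, conc_numerator) / auc_infinity(time, conc_denominator)


def two_fold_change(metric_perturbed: float, metric_reference: float) -> float:
    """log2 ratio of a PK metric under perturbed vs reference
    conditions; +-1 corresponds to a doubling/halving."""
    if metric_perturbed <= 0 or metric_reference <= 0:
        raise ParameterError("two-fold change requires strictly positive metrics")
    return math.log2(metric_perturbed / metric_reference)


@dataclass(frozen=True)
class PKSummary:
    """Per-compartment PK summary of one simulated trace."""

    compartment: str
    cmax: float  # mg/L
    tmax: float  # min
    auc_0_t: float  # mg*min/L over the observation window
    auc_0_inf: float  # mg*min/L
    kpuu_bbb: float  # AUC-inf ratio ECF/MV (same for every compartment row)
    kpuu_cell: float  # AUC-inf ratio ICF/ECF


def summarize(result, compartment: str) -> PKSummary:
    """Compute the full PK summary for one compartment of a simulation.

    ``kpuu_bbb`` and ``kpuu_cell`` are properties of the run, computed
    from the microvascular, ECF and ICF traces, and repeated on every
    compartment's summary row for convenience."""
    t = result.time
    c = result.trace(compartment)
    cmax, tmax = cmax_tmax(t, c)
    return PKSummary(
        compartment=compartment,
        cmax=cmax,
        tmax=tmax,
        auc_0_t=auc(t, c),
        auc_0_inf=auc_infinity(t, c),
        kpuu_bbb=kpuu(t, result.trace("ECF"), result.trace("MV")),
        kpuu_cell=kpuu(t, result.trace("ICF"), result.trace("ECF")),
    )
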