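# Methods

## Model structure

The CNS is represented by eight drug-containing states — brain
microvasculature (MV, 45 mL), brain ECF (253 mL), brain ICF (1000 mL),
lysosomes (12.5 mL), lateral ventricles (20 mL), third+fourth
ventricles (3 mL), cisterna magna (1 mL) and subarachnoid space
(116 mL) — plus two audit integrals (cumulative mass into and out of
the CNS). Plasma is a forcing function with an exact closed form: a
one-compartment model (V 108 L, CL 297 L/h) receiving a 1 g IV infusion
over 15 min. CNS uptake does not deplete plasma; the amount ever taken
up by the CNS is of order 0.1 mg·min-equivalents against a 1000 mg
dose, so the approximation is far below solver tolerance in effect.

Every flux is linear (clearance × source concentration), so the system
is a constant-matrix linear ODE with piecewise-exponential forcing.
Connectivity: plasma ⇄ MV by perfusion (Q_CBF, 689 mL/min); MV ⇄ ECF
across the BBB (symmetric paracellular + directed transcellular);
ECF ⇄ ICF and ICF ⇄ lysosome across cell membranes; plasma ⇄ LV and
plasma ⇄ TFV across the blood–CSF barrier (BCSFB); ECF → LV by bulk
flow (0.2 mL/min); LV → TFV → CM → SAS → plasma by convection at
Q_CSF + Q_ECF_bulk = 0.62 mL/min. The ECF bulk flow is routed into the
lateral ventricles; routing it to the cisterna magna instead would be a
one-line change and does not affect the BBB-level statistics, which is
why the simpler upstream junction was chosen. There is no diffusive
ECF ⇄ CSF exchange besides the bulk flow; this keeps the closed form
`Kp_uu,BBB = (CL_P + CL_in)/(CL_P + CL_ef + Q_bulk)` exact for the
simulated AUC ratio, which the tests exploit as an independent oracle.

The reported ICF concentration is cytosolic; the lysosomes are a
separate state (1/80 of ICF volume, pH 5) and a volume-weighted
total-cell concentration is available separately
(`SimulationResult.total_cell_trace`).

## Ionization and membrane transport

Only the neutral microspecies crosses lipid membranes. Unionized
fractions come from Henderson–Hasselbalch on at most one acidic and one
basic group; basic groups are parameterized by the conjugate-acid pKa,
so a negative value means "essentially never protonated". Zwitterions
use the product of the acid and base factors — a simplification that
ignores microspecies coupling, adopted because the drug tables list at
most one constant of each kind.

Tabulated BBB transcellular clearances are taken to be values *at
reference pH* (plasma 7.4, ECF 7.3). A pH perturbation therefore
multiplies a membrane clearance by the *ratio* of unionized fractions
at the new vs reference pH of its source compartment only.

Cell and lysosome membrane clearances are derived from the mean BBB
transcellular clearance scaled by membrane surface area
(SA_BCM/SA_BBB ≈ 17.8, SA_LYS/SA_BBB ≈ 13.2). Internally they are
stored as a neutral-species permeability multiplied by the source
compartment's unionized fraction, so that the equilibrium
concentration ratio across each membrane is exactly
f_u(pH_source)/f_u(pH_destination) — the ion-trapping relation.  For a
base with conjugate-acid pKa 9.12 this gives an ICF/ECF exposure ratio
of 0.01491/0.00753 = 1.98 and a lysosome/ICF ratio of ≈ 99, both of
which the test suite checks against the simulated AUC ratios. This
surface-area-derived permeability controls only the *rate* of cellular
equilibration; the steady-state partitioning is pH-determined and
insensitive to it.

## Paracellular transport and pore scaling

Tabulated paracellular clearances are canonical inputs; first-principles
formulas exist only to rescale them. The pore model is a population of
identical cylindrical water-filled pores of radius 0.0007 µm (BBB) /
0.0027 µm (BCSFB). The solute radius comes from the Stokes–Einstein
relation at 310 K (water viscosity 0.6913 mPa·s) applied to the
aqueous-diffusivity correlation D_aq = 9.9×10⁻⁵·Mwt⁻⁰·⁴⁵³ cm²/s; both
constants are module-level and configurable. Hindrance is the Renkin
cylinder polynomial, clipped to [0, 1]. A pore-radius scenario keeps
the pore count fixed: aperture area scales with r², hindrance is
re-evaluated. A consequence worth knowing: halving the pore radius
excludes any solute whose Stokes–Einstein radius exceeds the new pore
(≈ Mwt 180 and up), so drugs with no measurable transcellular influx
can lose their only entry route into the ECF entirely; the grid records
such cells as flagged failures rather than inventing numbers for them.

The BCSFB paracellular clearance is constructed from the BBB value as
permeability per effective aperture area (0.004% of SA_BBB),
re-evaluated at the BCSFB pore radius and applied to each interface's
effective area (0.016% of half the BCSFB area at the LV and TFV each).
Because the BCSFB pores are ~4× wider, the per-interface clearance can
exceed the BBB value; this follows directly from the stored effective
areas and is accepted as the model's reading of them.

## Active-transport calibration

Net active transport at the BBB is a single asymmetry factor applied to
transcellular influx (if the passive prediction falls below the
measured Kp_uu,BBB) or efflux (if above), solved in closed form from
the steady-state relation. Targets within 2% of the passive prediction
get no factor. If the required side has zero transcellular clearance
the target is unattainable; the calibration result is flagged, strict
callers raise, and the scenario grid proceeds with purely passive
transport for that drug (its simulated Kp_uu then reflects the passive
prediction). Of the eight reference drugs, four are passively
consistent, three calibrate to efflux factors between 4.6 and 32, and
one (an influx target with influx below detection) is flagged.

BCSFB transcellular clearances are the BBB values scaled by interface
area, calibrated analogously to the ventricular Kp_uu target when one
is provided, falling back to the BBB factors otherwise.

## Numerics

LSODA (stiff-capable) with rtol 10⁻⁸ and atol 10⁻¹⁰ in concentration
units (converted to per-state amount tolerances), integrated piecewise
across the end-of-infusion kink, on a fixed output grid of 0.5 min
spacing for metric reproducibility. The mass balance — total CNS amount
vs cumulative in minus cumulative out, with the inflow integral checked
against the analytic plasma exposure — closes to better than 10⁻⁶
relative on the reference panel and is asserted in the tests. Negative
solver excursions beyond 100× atol abort; smaller ones are clipped
to 0.

The default horizon is 600 min. Two conditions trigger a single re-run
to 20,000 min, flagged on the result: a monitored compartment (ECF or
ICF) whose maximum falls on the final grid point, or a terminal phase
so incomplete that the AUC extrapolation would exceed 20% of the total.
AUC uses the linear trapezoid on the stored grid; AUC₀₋∞ adds
C_last/k_el with k_el from a log-linear fit over the last five
post-peak grid points (window size configurable; the point-selection
rule is a package choice, since no standard exists at this grid
resolution). Points more than six decades below the peak are excluded
from the fit — they lie below the integrator's absolute-error floor and
carry no information. T_max ties break to the earliest time; its
resolution equals the 0.5 min grid spacing, i.e. ~3% of a typical
~17 min brain-ECF T_max.

## Scenarios

Eleven scenarios: reference plus one-at-a-time perturbations — CBF
×0.7/×1.5, BBB pore radius ×0.5/×5, ECF volume ×0.7/×1.5, pH_ECF to
5/8, pH_ICF to 6/7.6. A volume perturbation changes only the volume
(surface areas, flows and the other volumes are untouched, isolating
the dilution/turnover effect); a pore perturbation propagates only
through the paracellular scaling law; a pH perturbation only through
ionization rescaling of membrane clearances. Perturbed physiologies
must still pass validation. Combined disease presets are deliberately
out of scope — the point of the grid is attribution of effects to
single parameters.

The grid output is per (drug, compartment ∈ {ECF, ICF}) and per
(scenario, metric ∈ {C_max, T_max, AUC₀₋T, Kp_uu,BBB, Kp_uu,cell}),
expressed as log₂ fold change against the reference. The reference
column is identically zero by construction.

## Virtual drug panels

The generator samples physicochemical space uniformly within the study
spans (Mwt 150–500 g/mol, logP −3.7–4.3, pk_a 3–16, pk_b −9–10), an
ion-class mix (default 25% neutral / 25% acid / 30% base / 20%
zwitterion, roughly balancing the four classes with a slight tilt
toward bases as is typical of CNS drugs), and a log-uniform
Kp_uu,ECF ∈ [0.01, 3] so both strong net efflux and net influx are
represented. Clearances follow documented monotone formulas:
paracellular ∝ D_aq(Mwt)·H(λ), anchored at ≈ 49 mL/min for a 194 g/mol
solute; transcellular 10^(0.7·logP + 0.7) mL/min, split symmetrically
between influx and efflux with the asymmetry left for calibration to
reconstruct (feasible for every generated drug since both directions
are strictly positive). These formulas are pipeline-exercisers, not
property predictions: they preserve the qualitative structure (small
hydrophilic drugs are pore-dependent, lipophilic drugs
membrane-dominant) but no quantitative QSPR claim. Panels are
reproducible under (seed, size) and serialize to the same CSV schema
as measured tables, so the pipeline is agnostic to their origin.

What passing tests on synthetic panels do *not* show: correctness of
any individual real drug's parameters, transporter saturation
(clearances are linear), plasma protein-binding kinetics, brain
non-specific binding (all concentrations are unbound), or regional
heterogeneity.

## Known limitations

- One acidic + one basic group per drug; no multiprotic or ion-pair
  transport.
- Pore geometry (cylinder, fixed count) is the simplest defensible
  model of "pore radius"; a slit-pore variant would change the
  magnitude but not the direction of pore-scenario effects.
- The BCSFB construction (area-scaled clearances, ventricular Kp_uu
  calibration against a steady-state form that neglects the ECF bulk
  inflow) is a pragmatic closure; CSF-compartment metrics should be
  read as order-of-magnitude.
- Problem sizes used in the shipped analyses: 8 drugs × 11 scenarios,
  600 min horizon at 0.5 min resolution (extended to 20,000 min where
  flagged) — the full grid runs in well under a minute on one core, so
  larger virtual panels scale linearly.
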