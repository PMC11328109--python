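# Methods

## Two-state DSC model

The package models reversible two-state denaturation N ⇌ D. With Td the
midpoint temperature, ΔHd the denaturation enthalpy at Td, and ΔCp the
(temperature-independent) heat-capacity increment, the Gibbs–Helmholtz
free energy is

    ΔG(T) = ΔHd (1 − T/Td) + ΔCp [(T − Td) − T ln(T/Td)],

the denatured fraction is f = 1/(1 + e^{ΔG/RT}) (computed with a logistic
to avoid overflow), and the excess molar heat capacity is the exact
derivative of f·ΔH(T):

    Cp,ex(T) = ΔH(T)² f(1−f)/(RT²) + f ΔCp,   ΔH(T) = ΔHd + ΔCp (T − Td).

Units are Kelvin, kJ mol⁻¹ and kJ K⁻¹ mol⁻¹ internally; every file and CLI
surface is Celsius. R = 8.314462618×10⁻³ kJ K⁻¹ mol⁻¹.

### Trace workup conventions

* **Baseline.** Straight lines are fit to the outer 15% windows of the scan
  (`window_frac`, default 0.15) and joined by a sigmoidal progress baseline
  weighted by the reaction extent. The extent is the normalised running
  area of the subtracted peak — the standard calorimetric convention —
  found by fixed-point iteration (8 rounds; convergence is geometric). An
  enthalpy-weighted extent (dα ∝ Cp,ex dT/ΔH(T)) was evaluated and
  rejected: it improves the area slightly but degrades the peak-height
  van't Hoff estimate for broad transitions.
* **Td.** Grid maximum refined by a quadratic fit to the contiguous points
  within 97% of the peak — a noise-averaging window that stays inside the
  locally parabolic cap. A maximum on the first/last grid point raises an
  error (truncated transition), as does a scan whose both edge windows are
  steep relative to the peak prominence (no baseline region).
* **ΔHcal.** Trapezoid on the native grid; no resampling. Negative areas
  raise (baseline failure).
* **ΔHvH.** Peak-height form ΔHvH = 4 R Td² Cp,ex(Td)/ΔHcal. On an ideal
  two-state trace this equals ΔHcal up to discretisation, so
  ΔHcal/ΔHvH ≈ 1 diagnoses a single cooperative unit.
* **Forward fit.** `fit_two_state` fits Cp,ex(T; Td, ΔHd, ΔCp) by bounded
  least squares with deterministic initialisation (Td from the peak, ΔHd
  from the raw area, ΔCp from the edge offset). No random restarts.

### Analysis grids and the validity domain

Simulated recovery studies use grids spanning Td ± 15·RTd²/ΔHd (about
±7–29 K over the parameter ranges exercised). When ΔCp > 0 would bring
cold denaturation into that span, the cold edge is pulled up so the
pre-transition window straddles the stability-curve maximum
T_S = Td·exp(−ΔHd/(ΔCp·Td)), where f′(T_S) = 0 makes the flattest
available baseline region.

The model-free workup is quantitative only where the folded baseline is
actually reached. Two intrinsic effects bound its accuracy when
ΔCp·RTd²/ΔHd² is large (broad transition, strong Kirchhoff slope):

1. the subtracted area equals ΔHd + ΔCp·E_f[T − Td] even with a perfect
   baseline (the enthalpy released is averaged over the transition, not
   evaluated at Td), and
2. for, e.g., ΔHd = 200 kJ/mol with ΔCp = 6 kJ/K/mol the stability-curve
   maximum is only ≈ 9 kJ/mol, so the protein is never more than ~95–98%
   folded and part of the transition enthalpy is unobservable.

For such parameters the area misses ΔHd by 1–5% and the cooperativity
ratio drops to 0.91–0.98 no matter the algorithm; the package reports what
the trace contains. At the D2-like conditions this package targets
(ΔHd ≳ 350 kJ/mol) both effects are well below 0.5%.

## ITC independent-sites isotherm

For n equal and independent sites the bound-ligand concentration [B]
solves Kb = [B]/((n[P₀] − [B])([L₀] − [B])); the fractional saturation is
the smaller quadratic root, evaluated in the cancellation-free form
2·Kb·[L₀]/(b + √(b² − 4ac)) (the textbook (b − √)/(2a[P₀]) form loses up
to eight digits in the weak-binding limit). Cumulative heat per mole of
protein is ΔHb,total times the fractional saturation; ΔHb is stored as the
total (saturation) enthalpy, with the per-site value ΔHb/n derived.

* **Concentration ledger.** The instrument cell is overfilled: each v-μl
  injection into the V-μl cell displaces cell liquid, scaling resident
  concentrations by (1 − v/V). A "none" strategy (pure accumulation) is
  available. Default protocol: 25 × 10 μl into 961 μl, 300 mM syringe,
  42 μM protein.
* **Heats.** Simulated per-injection heats are first differences of the
  cumulative model value, converted to μJ with the initial cell protein
  content; Gaussian noise is added per injection. Dilution heats are
  subtracted elementwise before fitting.
* **Fit.** The RSS is profiled over log n (bounded scalar minimisation),
  with an inner bounded least-squares fit in (log Kb, ΔHb) at each n, then
  polished by a full three-parameter refinement; if the polish stalls on
  the flat valley the profiled solution is kept. Fits are unweighted
  (no uncertainty model for the heats). Standard errors come from the
  Jacobian at the solution.
* **Identifiability.** The default conditions sit deep in the low-c regime
  (c = n[P₀]Kb ≈ 8×10⁻³): the curve shape determines Kb and the product
  ΔHb·(saturation) well, but n only through a ≲1% depletion correction.
  Noiseless data are recovered to optimizer precision; with realistic
  noise the stoichiometry estimate is bounds-dominated and biased, which
  is a property of the experiment design, not of the optimizer. Treat
  fitted n from a single low-c titration as order-of-magnitude.

## Cross-condition ΔCp regression

`fit_dcp` is an ordinary least-squares regression of ΔHd(Td) on Td across
conditions (scipy.stats.linregress behind the module surface). Only buffer
and pure-denaturant rows enter (KSCN, GdmSCN, GdmCl series); mixtures with
stabilizing osmolytes shift Td without the matching ΔHd change and are
excluded. The packaged table gives slope 5.22 ± 0.21 kJ K⁻¹ mol⁻¹ over 11
conditions. Downstream extrapolation uses the slope rounded to the one
decimal its standard error supports (5.2), keeping derived numbers stable
against sub-significant digits. ΔH(T) = ΔHd + ΔCp(T − Td) is affine, so
the Celsius/Kelvin choice cannot affect results.

## Trajectory ion-shell statistics

* **Surface convention.** "Protein surface" means any protein heavy atom;
  no SASA filter. Hydrogens are excluded on both protein and ion sides.
* **Shell membership.** An ion is in the shell if any of its heavy atoms is
  within the cutoff (default 4.0 Å) of any protein heavy atom — per-ion,
  not per-atom, counting.
* **Contacts.** A side-chain contact is an (ion, residue) pair with any ion
  heavy atom within the cutoff of any heavy side-chain atom, deduplicated
  per frame; a per-atom convention is exposed behind a flag. Residue
  classes: Lys/Arg positive, Asp/Glu negative, Phe/Tyr aromatic,
  Val/Ile/Leu/Ala aliphatic; Gly/Pro (and anything else) unclassified and
  skipped. The contact cutoff defaults to the same 4.0 Å as the shell.
* **Distances.** Minimum-distance distributions are collected per frame and
  per SCN ion for the chosen element (N or S) against protein heavy atoms,
  binned at 0.05 Å by default.
* Neighbour search uses a k-d tree; the test suite pins it to exhaustive
  all-pairs computation on hundreds of random frames. Frames are weighted
  equally (no time-correlation correction).

## Synthetic generators

The generators emulate the study's three data sources at the published
conditions: thermograms default to the buffer transition (Td = 102.6 °C,
ΔHd = 470 kJ/mol, ΔCp = 5.2 kJ/K/mol), titrations to n = 30, Kb = 6.3 M⁻¹,
ΔHb = −14.9 kJ/mol on the 25 × 10 μl schedule, and frame sets to ~20 ions
in the 4 Å shell. They reproduce the *data layout and ground truth*, not
the physics they stand in for: thermogram noise is white Gaussian (real
scans drift), dilution heats follow a smooth geometric decay, the toy
protein is a 12-residue ring with schematic geometry (correct PDB atom
names, one residue per class), and ions are placed along outward surface
normals with rejection sampling so each realised minimum distance equals
its assignment to 1×10⁻⁶ Å. Passing tests therefore demonstrate correct
bookkeeping, estimators and geometry kernels — not force-field realism or
instrument artefact handling. All randomness flows through
`numpy.random.default_rng(seed)`; fixed seeds give identical outputs.

## Problem sizes

Default test and reproduction runs use 0.1 K grids of ~750–1700 points per
thermogram, 25-injection titrations, Monte-Carlo studies of 100–200
replicates, and frame sets of 40–120 frames with up to ~25 ions — sizes at
which every stage completes in seconds while keeping Monte-Carlo standard
errors small enough to resolve the documented tolerances.

## Known limitations

* No multi-transition deconvolution, kinetic (scan-rate) models, or
  absolute partial specific heat capacities.
* Single-site-class ITC only; no Hill/cooperative models; raw power traces
  are not modelled, only integrated per-injection heats.
* The ΔCp regression assumes a temperature- and cosolute-independent ΔCp.
* PDB is the only trajectory format read natively; convert GRO/XTC
  upstream (e.g. with MDAnalysis) if needed.
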