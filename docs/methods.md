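# Methods

## Two-state model

The analysis assumes a reversible two-state equilibrium N ⇌ D with a
van't Hoff equilibrium constant `K(T) = exp[(ΔH^VH/R)(1/Tm − 1/T)]` and
excess heat capacity `Cp_ex = ΔH·ΔH^VH·K/(R·T²·(1+K)²)`. The
calorimetric enthalpy ΔH (peak area) and van't Hoff enthalpy ΔH^VH (peak
sharpness) are estimated independently; their ratio is the standard
two-state diagnostic. The model contains no ΔCp term for the transition
itself: the unfolding heat-capacity increment is handled entirely by the
chemical-baseline step, and the peak shape is fitted with
temperature-independent enthalpies. This is the simplest form consistent
with the ΔH/ΔH^VH diagnostic; adding a ΔCp term to the transition would
change the fitted enthalpies by less than their standard errors for
transitions as narrow as those treated here, but it is a known
limitation for very broad transitions.

Thermal denaturation of aggregation-prone proteins is in reality
irreversible. The equilibrium treatment is justified, as in the
experimental practice the package mirrors, when the midpoint is
scan-rate independent and the transition symmetric; accordingly the scan
rate is carried as metadata only and never enters a fit (asserted by
test).

All internal arithmetic uses kelvin and cal/mol with
R = 1.9872 cal mol⁻¹ K⁻¹; public interfaces accept °C and reports are in
°C / kcal/mol, matching how calorimetric results are conventionally
printed.

## Baseline processing

A raw scan is reduced to excess molar heat capacity in three forward-only
stages: buffer-reference subtraction (linear interpolation of the
reference onto the sample grid, no extrapolation), molar normalisation
(division by moles in the cell = concentration × cell volume; default
cell volume 0.527 mL, the instrument class this emulates), and chemical
baseline removal.

The chemical baseline uses the standard progress-baseline construction:
linear trends are fitted in pre- and post-transition windows (default:
the lowest and highest 15 % of the grid — the acquisitions emulated here
span 15–95 °C with transitions near 52–71 °C, leaving both windows
transition-free; configurable), joined initially by a cubic Hermite
segment matching value and slope at the inner window edges, then refined
by weighting the two trends with the extent of conversion computed from
the running integral of the current excess signal. Iteration stops when
the baseline moves by < 1e-6 of the peak scale (≤ 20 passes; a warning
and the last iterate on non-convergence). The routine is idempotent to
< 0.1 % of peak height and recovers injected baselines to < 1 % of peak
height on noiseless data.

## Fitting

All fits are bounded trust-region least squares
(`scipy.optimize.least_squares`, positivity bounds, relative tolerance
1e-10, iteration budget 500 per free parameter, parameter-scaled).
Starting values are moment-based: midpoint from the interior peak
position (ties broken toward the lowest temperature), ΔH from the
trapezoidal area, ΔH^VH by inverting the peak-height identity
`Cp_max = ΔH·ΔH^VH/(4R·Tm²)`. Standard errors are Gauss–Newton:
`cov = (JᵀJ)⁻¹·rss/(n−p)` at the optimum; numerically unconstrained
directions (singular Jacobian columns) report infinite errors, which is
how an unidentifiable Kd in a flat titration is flagged. No bootstrap is
performed by default.

The CD melt fit has six parameters (apparent midpoint and enthalpy, two
linear baselines). The apparent van't Hoff enthalpy is deliberately
independent of the calorimetric one: optical and calorimetric probes can
report different midpoints for the same protein (here ~5 °C apart), and
the package reports both without reconciling them.

The titration fit estimates (Tm0, Kd) with ΔH0 fixed by the caller to
the calorimetric apo value; a handful of (concentration, Tm) points
cannot constrain three parameters. The linkage model is single-site
saturable binding to the native state with temperature-independent Kd
referenced at Tm0, and no ΔCp term in the linkage relation — the
simplest model reproducing a monotone semi-log titration. Note the
resulting Tm(ln L) is convex, not sigmoidal: with no unfolded-state
binding there is no true saturation plateau, and "saturation shift"
means the shift at the highest concentration used.

## Surface areas and energetics

ASA is computed with an own Shrake–Rupley implementation: each atom's
solvent-expanded sphere (van der Waals radius + 1.4 Å probe) is sampled
on a deterministic golden-spiral lattice (default 960 points, making
results bit-reproducible), and points inside any neighbour's expanded
sphere are rejected. Radii: C 1.70, N 1.55, O 1.52, S 1.80 Å; heavy
atoms only. Polarity split by element: C/S apolar, N/O polar. PDB input
goes through gemmi (first model; HETATM and waters excluded by default,
so bound nucleotides add no buried surface; highest-occupancy altloc
kept, ties to 'A'). The test suite checks the lattice against exact
isolated-sphere areas and an independent Monte-Carlo rejection-sampling
estimator.

The unfolded reference is an additive per-residue table of extended
Gly-X-Gly accessibilities bundled in `constants.py`. Different ASA
programs, radius sets and unfolded references legitimately differ at the
percent level, so recomputing ΔASA from real crystal structures is a
supported workflow (`thermostab energetics --pdb ...`) but the canonical
entry point takes ΔASA values directly.

The correlations `ΔCp = (0.45·ΔASA_ap − 0.26·ΔASA_pol)/1000` and
`ΔH(60 °C) = (31.4·ΔASA_pol − 8.44·ΔASA_ap)/1000` (areas in Å², results
in kcal) are pinned in `constants.py`; they reproduce the reference
energetics rows used in the acceptance tests to within printed rounding.
Kirchhoff extrapolation with constant ΔCp carries ΔH to the transition
temperature. The residual-structure index ΔH_exp/ΔH_calc(Tm) is the
package's single-number diagnostic: ≈ 0.5 for the systems this package
was built around, i.e. roughly half the expected unfolding enthalpy is
never released.

## Synthetic data

The generators produce what the fits assume: model curves plus iid
Gaussian noise on the dependent variable only (the temperature grid is
treated as exact), with every generator a pure function of (spec, seed).
Defaults mirror the emulated acquisitions: 15–95 °C at 0.1 °C spacing,
1.5 K/min scan-rate metadata, 4 µM protein, 0.527 mL cell, DSC noise
σ = 0.1 kcal mol⁻¹ K⁻¹ (small against the ~12 kcal mol⁻¹ K⁻¹ peak).
Injected chemical baselines blend pre/post linear trends with the true
unfolded fraction — the fixed point of the removal routine, which is
what makes injection/recovery a sharp test. Reference parameter sets:
apo (62.5 °C, 111.6, 96.3 kcal/mol), ligand-saturated (71.0 °C, 120.4,
139.9), destabilised site-B mutant (52.1 °C, apo-like enthalpies). The
titration default Kd = 6.5 µM at Tm0 gives a ~10 °C shift at 800 µM
ligand, the saturating condition emulated. CD defaults use a
mean-residue-ellipticity scale (−12 native → −5 denatured, mild slopes)
with midpoints 68 / 73.5 °C for apo / ligand-bound.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: irreversible aggregation kinetics and
scan-rate-dependent distortion, correlated (1/f) instrument drift beyond
the polynomial baseline, exothermic aggregation dips, concentration-
dependent transitions, or the optical signatures of the α→β conversion
that follows denaturation in the motivating system.

## Problem sizes and numerical choices

Monte-Carlo recovery experiments use 20 seeds per condition on the
801-point standard grid; conservation properties use 50 random parameter
draws on 6001-point grids; the ASA-vs-Monte-Carlo comparison uses
5-atom clusters at 10⁵–10⁶ samples. These sizes give sampling error an
order of magnitude below every tolerance asserted. Quadrature is
trapezoidal on the native grid; the excess-heat-capacity identity
∫Cp_ex dT = ΔH holds to 0.1 % on a ±60 K window. Degenerate inputs fail
loudly: flat or edge-peaked excess curves raise a no-transition error,
empty baseline windows an invalid-window error, missing normalisation
metadata a missing-metadata error.

## Known limitations

Single-transition, single-scan analysis only (no global multi-curve
fits, no three-state or kinetic models); linkage assumes
temperature-independent Kd; the unfolded-reference table, like all such
tables, is one convention among several; predicted ΔASA from real
structures inherits every upstream modelling choice (missing loops,
alternate conformers, bound ions) and should be compared across
programs before quantitative use.
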