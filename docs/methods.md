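# Methods

## The measurement being modeled

Isothermal titration calorimetry keeps a sample cell at constant
temperature and records the differential power needed to do so while a
syringe makes a programmed series of injections. Two experiment families
are covered:

1. **Binding titrations** — inhibitor (sesquiterpene lactone or extract,
   1 mmol/L as lactucin equivalents) injected into acetylcholinesterase
   (1 µmol/L) in a 200 µL cell at 36.6 °C. Each injection's integrated
   heat reflects the increment of bound ligand; the heats versus molar
   ratio define the single-site isotherm.
2. **Kinetic (hydrolysis) runs** — acetylcholine injected into the enzyme;
   the steady heat flow is proportional to the catalytic rate,
   P = ΔH_app·V₀·v, so the thermogram is a direct rate meter. Inhibited
   runs add a competitive inhibitor to the cell.

## Displacement (perfusion-cell) ledger

The cell is always full: injecting dV expels dV of mixed contents. The
per-injection mole balance, taking the expelled liquid at the average of
the pre- and post-injection concentrations (trapezoidal/mid-displacement
rule), gives the dilution factor for pre-existing species

    f = (1 − dV/2V₀) / (1 + dV/2V₀)

and credits injected ligand at c_syr·(dV/V₀)/(1 + dV/2V₀). This is the
standard overfilled-cell correction; the tests verify it against a
brute-force mole bookkeeping oracle that solves the implicit balance
numerically. Concentrations, molar ratios and moles injected are derived
exclusively from this ledger everywhere in the package.

## Single-site isotherm and fitting

With total ligand X, total macromolecule M (both from the ledger), n
identical sites and dissociation constant K_D, bound ligand is the root of
the binding quadratic; the heat of injection i is ΔH·V₀ times the newly
bound material, after the previously bound complex is diluted by f_i. The
fitter runs bounded nonlinear least squares (scipy `least_squares`) over
(n, log K_D, ΔH) plus an optional constant per-injection offset absorbing
un-subtracted dilution heat (on by default; a separately measured dilution
control can be subtracted instead). Standard errors are asymptotic, from
the Jacobian at the optimum; K_D's SE is mapped from the log scale by the
delta method.

Initialisation: ΔH from the first injection's molar heat, K_D from the
in-cell ligand concentration at half cumulative heat, n = 1. Bounds:
n ∈ [0.1, 10], K_D ∈ [1e−3, 1e6] µmol/L. The Wiseman parameter
c = n[M]/K_D is reported and flagged when outside [1, 1000].

**Low-c regime.** The published design (1 µM enzyme against K_D of
30–300 µM) gives c ≈ 0.003–0.03, far below the classical window. In this
regime n is not identifiable and the standard practice is to fix n = 1 and
rely on excess titrant to reach saturation; the analysis scripts and
recovery studies do exactly that (the fitter still floats n by default for
generic use). Weak binders with small |ΔH| are genuinely hard here: the
campaign's weakest-signal row (K_D ≈ 300 µM, ΔH ≈ −59 kJ/mol) carries a
K_D standard error of the same order as the estimate, which the fit
reports honestly.

## Thermodynamic bookkeeping

Outputs satisfy, exactly as stored: K_A = 1/K_D (unit-consistent),
ΔG = −RT ln(K_A·c°) with c° = 1 mol/L and R = 8.314 J/(mol·K) at
T = 309.75 K, and ΔS = (ΔH − ΔG)/T so that ΔG = ΔH − TΔS holds by
construction. The published per-inhibitor table is internally consistent
only in K_A = 1/K_D (to one unit in the last printed decimal); its printed
ΔG, ΔH and TΔS columns do not satisfy the Gibbs relation for any row, and
−RT ln K_D differs from the printed ΔG (lactucin: −26.8 vs −23.41 kJ/mol).
This package therefore reproduces the reciprocity identity and derives
ΔG/ΔS from its own stated convention rather than guessing the vendor
software's internal path.

## Simulator

* Ideal power: each injection's heat released uniformly over the injection
  duration (4 s). Samples represent a piecewise-linear signal that is zero
  at the injection-start sample, so trapezoidal quadrature over the
  injection window recovers the pulse heat exactly — the discrete analogue
  of a band-limited DAQ.
* Instrument response: single-exponential (first-order) convolution with
  unit DC gain, default τ = 10 s; τ = 0 is ideal. The discrete filter
  preserves pulse areas to ≪0.1% once the response has decayed.
* Noise: white Gaussian on power plus optional linear baseline drift,
  seeded explicitly per call; identical seeds give bit-identical traces.
  The campaign default σ = 2×10⁻⁴ µcal/s (≈0.8 nW RMS) matches modern
  small-cell calorimeters; tests also exercise 10× harsher noise.
* Hydrolysis: between injections [S] follows d[S]/dt = −Vmax·S/(K_app + S)
  with K_app = Km·(1 + I/K_i), integrated by LSODA at rtol 1e−9; each
  injection applies the displacement ledger to S and I. Power is
  ΔH_app·V₀·v with ΔH_app = +20 kJ/mol by default (the hydrolysis signal
  is endothermic in this assay); exothermic events are negative throughout.
* Schedules: binding runs use the instrument's canonical 19 × 2 µL at
  180 s; kinetics runs use 12 × 5 µL at 60 s with Vmax = 0.3 µmol/L/s so
  that substrate accumulates from ~24 to ~250 µmol/L across injections,
  spanning Km = 48.5 µmol/L from both sides. Spacings below 5τ trigger a
  peak-overlap warning.

## Thermogram processing

* Baseline for titration traces: piecewise linear through (midpoint,
  median) anchors of the 30 s quiet window before each injection, plus a
  trailing anchor; windows shorter than 5 samples widen toward the
  previous injection and fail if still short. Kinetic traces do **not**
  return to baseline between injections, so rate conversion uses the
  pre-titration instrument baseline instead.
* Integration windows run injection-to-injection (robust under noise;
  return-to-baseline detection is deliberately avoided); trapezoidal
  quadrature; windows cut by the end of trace are flagged partial.
* Rate extraction: Tian-corrected power, v = P/(ΔH_app·V₀); [S](t) is
  reconstructed from the ledger minus cumulative observed hydrolysis. The
  saturation curve takes the median v and S over a window 8–28 s after
  each injection — past the instrument rise, before appreciable depletion.
  First-order Tian correction is exact away from the injection
  discontinuities; round-trip accuracy is ~0.2% there and is not claimed
  at the transients themselves.

## Inhibition statistic

IA% compares corrected hydrolysis heats with and without inhibitor (see
README for the formula). The trailing division in the printed form of the
statistic is read as division by the parenthesized corrected uninhibited
heat (ΔH_hyd − ΔH_dilS): the numerator is built from exactly that
quantity, and any other precedence leaves the ratio dimensionally
incoherent. IA is scale-free, exactly 0 when hydrolysis is unchanged,
exactly 100 when the corrected inhibited heat vanishes, and is reported
unclipped with an out-of-range flag (negative IA = apparent activation).

IC50 comes from a log-logistic dose curve (floor 0, ceiling ≤ 100 floated,
Hill slope free); the reported IC50 is where the fitted curve crosses
IA = 50, which requires the data to bracket 50%. Because a whole-run IA
integrates over rising substrate — and competitive inhibition is relieved
as S grows — the dose-curve IC50 (≈6 µM in the simulated campaign) sits
above the fixed-S Cheng–Prusoff value K_i·(1 + S̄/Km) (≈3.3 µM at the mean
working S); the package reports both, with Cheng–Prusoff labeled as a
cross-check only.

## What the synthetic data does and does not establish

The generator reproduces the experimental design (volumes, concentrations,
temperature, schedules), a first-order instrument response, white power
noise and linear drift. It does not model stirring hydrodynamics, feedback
controller dynamics, 1/f noise, titrant heat-capacity mismatch, enzyme
inactivation or product inhibition. Green recovery tests therefore
establish that the estimators invert the stated forward model at realistic
noise — not that the published values are correct, which would require the
unavailable raw thermograms. The published composition table is checked
only by arithmetic: three of six columns reproduce their printed totals
exactly at 3 decimals; the audit flags the other three (50/50, CPC 70/30 I,
CPC 50/50 I) whose printed totals do not equal their component sums, and
takes no position on which figures are typos.

## Numerical choices

* 1 cal = 4.184 J; heats stored in µcal on disk, reported in kJ/mol.
* Lactucin molar mass 276.28 g/mol (package constant, used for
  lactucin-equivalent doses; 2 g at 3% SLs → 217.2 µmol).
* Nonlinear fits use xtol = ftol = gtol = 1e−14 so exact data are
  recovered to ≤1e−8 relative; the IC50 curve uses bounded `curve_fit`.
* Degenerate inputs fail loudly with named error kinds: all-equal
  substrate concentrations, all-zero heats, zero ΔH_app, zero IA
  denominator, non-bracketing dose series, falling dose curves.
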