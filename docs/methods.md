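# Methods

## The measurement problem

A potted plant sits with its leaves enclosed in a 17.2 L glass chamber
and its root/soil compartment in a 2 L vessel, each flushed with VOC-free
air (defaults 3.0 and 0.5 L min^-1; the study-condition scenario uses
2.65 L min^-1 for the leaf chamber so that the residence time V/Q matches
the stated ca. 6.5 min). The outflow is sampled at 1 Hz by an SRI-ToF-MS
that alternates reagent ions every 6 minutes (H3O+ / NO+) and, when the
root chamber is in use, alternates chambers in a 24-min-root / 36-min-leaf
cycle. Quantification uses the H3O+ (proton-transfer) channels; NO+
blocks provide structural discrimination (aldehydes appear at [M-H]+,
ketones at M.NO+, terpenes at M+).

Processing follows the standard chain

    I_norm = counts * 1e6 / primary          (normalized counts, ncps)
    VMR    = (I_norm - background) / eps_norm  (ppbv)
    c      = VMR * 1e-9 * P/(R T)            (mol m^-3, ideal gas)
    E      = Q * (c_out - c_in) / A          (nmol m^-2 s^-1)

with eps_norm the slope of a through-origin least-squares fit of ncps
against ppbv over six calibration levels. The fit is forced through the
origin because the background-corrected signal must vanish at zero VMR;
the quantification equation has no intercept term. Calibration is
unweighted (the convention adopted here; the source procedure does not
state weighting). Compounds absent from the calibration standard receive
the sensitivity of the nearest calibrated m/z within the same compound
class (ties broken toward lower m/z), a proxy for matching dipole moment
and oxidation state.

The first 30 s of every reagent-ion/chamber block are discarded as a
switching transient (configurable; the source procedure is silent on
transients). Backgrounds are applied as constant per-channel offsets;
negatives created by the subtraction are floored at zero with a logged
count (a keep-negatives switch exists for unbiased averaging of signals
near the detection limit).

## Ion-channel masses

Channel m/z values derive from monoisotopic masses (pyteomics element
table) with centralized shifts: protonation +1.00728 Da (proton), hydride
abstraction −1.00783 Da (H atom), NO+ cluster +29.99799 Da, charge
transfer +0 (electron mass neglected). These constants reproduce the
printed instrument labels of the well-identified peaks within 0.004 Da
(e.g. sesquiterpenes: computed 205.195 vs printed 205.198). Printed m/z
are display labels of measured peaks, not identities: three tentatively
assigned peaks (dimethyl disulfide 94.991 vs computed 94.998,
methanedithiol 80.962 vs 80.983, an unknown C9H10O alcohol 135.071 vs
135.080) cannot be reconciled with their proposed formulas under any
mechanism convention and are stored with an `anomalous` flag, excluded
from the tolerance contract.

## Chamber model

Each chamber is one well-mixed CSTR (the pierced-ring inlet justifies
neglecting spatial gradients): per compound,

    dC/dt = E(t) A/V + (Q/V)(C_in - C) - L_chem C + P_chem

At constant forcing this converges to
C_ss = (E A/V + (Q/V) C_in)/(Q/V + k_chem) with time constant
1/(Q/V + k_chem); the chemical loss fraction at steady state is
f = k_chem τ_res/(1 + k_chem τ_res). Simulations start from the
self-consistent steady state of the initial forcing (so constant-forcing
runs are transient-free); `init="zero"` starts from an empty chamber.
Integration is LSODA with rtol 1e-9, segmented at forcing discontinuities
(ozone step, scavenger onset).

Chemistry comprises:

- **Gas-phase ozonolysis**: first-order loss k_O3·[O3] with [O3] from the
  piecewise-constant ozone schedule (reference state 296 K, air number
  density 2.46e19 cm^-3, so 135 ppbv = 3.32e12 cm^-3). Molar-yield
  product maps feed ozonolysis products (default: an alpha-farnesene-like
  split of 0.25 each into acetone, methyl vinyl ketone, oxopentanal and
  6-methyl-5-hepten-2-one; identities observed, yields a modeling choice
  constrained by carbon conservation).
- **Surface ozonolysis**: a configurable fraction of a compound's
  emission is consumed at the leaf surface while O3 > 0 (semi-volatile
  terpenoids oxidized before escaping the surface).
- **OH chemistry**: OH is produced with yield `oh_yield` per ozonolysis
  event — gas-phase and surface — and partitioned in quasi-steady state
  among reactants in proportion to k_OH·C. Gas-phase production alone
  cannot supply the observed monoterpene suppression at physical yields
  (≤1); including the surface pathway, which dominates sesquiterpene
  loss, yields a calibrated oh_yield of ~0.63, inside the 0.2–1 range
  reported for terpene ozonolysis.

Reported lifetimes are e-folding times τ = 1/(k[O3]); this convention
(not ln2/(k[O3])) reproduces all seven printed terpene lifetimes at
one-decimal rounding.

## The study-condition scenario

The generator's defaults encode the experimental conditions: basal leaf
emissions dominated by methanol (4.05e-1 nmol m^-2 s^-1) and monoterpenes
(5.73e-2), sesquiterpenes at 4.0e-2, root emissions by reduced-sulfur
compounds (methanethiol 2.4 nmol m^-2 soil min^-1, dimethyl disulfide
0.64, dimethyl sulfide 0.58); an ozone step to 135 ppbv after 2.5 h;
induced oxygenate bursts rising first-order (time constant 30 min, a
shape choice, not fitted) to new plateaus sized so the total carbon
increase is ~2.3 nmol C m^-2 s^-1 with the four alpha-farnesene products
contributing ~23% of it.

Chemistry attribution follows the study's conclusions rather than raw
rate constants:

- The scenario zeroes the monoterpene *in-chamber* gas-phase ozonolysis
  (at τ_res = 6.5 min direct ozonolysis is discountable) and drives its
  suppression through OH. `oh_yield` is calibrated once, by bisection, so
  the simulated 2-h post-fumigation window mean sits 17% below the pre
  window — the windowed quantity the pre/post analysis reports (the
  instantaneous steady-state drop is ~14%; the transient after the step
  is deeper because OH sinks build up over the burst rise time).
- The sesquiterpene channel keeps gas-phase ozonolysis
  (alpha-farnesene-like k_O3 = 5.9e-16 cm^3 s^-1; the beta-elemene
  surrogate 3.15e-15 would make gas loss ~80% alone, contradicting the
  surface-dominated attribution) and adds a surface sink of 0.68 of the
  emission, so the total suppression is ~82%. Its k_OH is set to zero in
  the scenario, mirroring the observed insensitivity of sesquiterpene
  levels to the OH scavenger.
- A cyclohexane scavenger option injects a sustained inflow (10 ppmv in
  the scavenger scenario); at that level cyclohexane captures >99% of the
  OH flux and the steady-state monoterpene concentration returns to
  within 2% of its pre-fumigation value, while the ozone-driven
  sesquiterpene suppression is untouched.

Between-plant variability is lognormal with mean 1 and CV 0.4 per
(plant, compound) — the study reports standard errors over 10 plants but
not the variance model, so both the distribution family (as specified
for this generator) and the CV are modeling choices. The instrument
model uses sensitivities of 5–25 ncps ppbv^-1 and small channel
backgrounds, typical of proton-transfer instruments; raw counts are
Poisson per 1-s sample around sensitivity × VMR + background, scaled by
the primary-ion rate (6e5 cps). All randomness flows from one seeded
generator; identical seeds give byte-identical fixtures.

What the generator does *not* emulate: raw ToF spectra and mass-scale
drift, humidity-dependent sensitivities (relevant mainly to
formaldehyde, which is excluded), NO+ branching-ratio physics,
fragmentation, cyclohexanone formation from the scavenger (OH-product
channels are not modeled), and day-to-day instrument drift. Passing
recovery tests therefore demonstrate the correctness of the processing
algebra and statistics under idealized acquisition, not robustness to
those instrumental artifacts.

## Flux and ozone budget

Emission rates are signed (negative = uptake); inflow VOC concentration
defaults to zero (catalytic VOC scrubber upstream) and is configurable.
Root-chamber rates are reported per m^2 soil surface per minute, the
convention for below-ground fluxes here (1 nmol m^-2 s^-1 =
60 nmol m^-2 min^-1). The ozone budget subtracts the blank-chamber wall
loss (a constant offset from empty-chamber runs) from the in/out
difference before attributing the remainder to the plant; the deposition
velocity divides the uptake flux by a reference O3 concentration.
Whether that reference is the outlet, inlet or mean concentration is
selectable (default: outlet) because the printed v_d of 0.11 cm s^-1
with an uptake of 3.4 nmol m^-2 s^-1 implies a reference of ~76 ppbv,
which matches none of the printed chamber concentrations unambiguously.

## Statistics

The ozone effect per compound is a classical paired t-test on per-plant
mean emissions over the 2 h before vs the 2 h after the ozone step;
two-sided (sidedness unstated in the source; two-sided is conservative),
uncorrected for multiple testing by default (Bonferroni and
Benjamini-Hochberg switches exist). Stars: * p<0.05, ** p<0.01, strict
inequalities. Zero-variance differences are handled explicitly (identical
pairs: t=0, p=1; constant nonzero shift: p=0 flagged degenerate). The
type-I error of the test under the generator's null is checked against
its nominal level by simulation at the plant-summary level (lognormal
plant factors plus counting-level noise on window means), and p-values
are verified against an independent numerical integration of the
Student-t density.

## Numerical choices and problem sizes

Default fixtures run 5 h of chamber time at 1 Hz; recovery studies use a
2.5-h clean-air run (the pre-fumigation window) with 10 plants, and the
stochastic recovery analysis uses 100 seeded replicates — sizes chosen so
the whole suite runs comfortably on a laptop while leaving the Poisson
and between-plant statistics well resolved. Mass matching uses a 0.005 Da
tolerance. Calibration requires ≥2 distinct levels; degenerate fits
(zero or negative slope) raise. Block segmentation rejects label changes
faster than 60 s as corrupt input, exempting the final (truncated) block.

## Known limitations

- The OH quasi-steady-state closure ignores OH reaction with O3, NO2 and
  the chamber walls; absolute [OH] is therefore scenario-calibrated, not
  predictive.
- The surface sink is a lumped fraction, not a deposition-velocity model;
  its split against gas-phase ozonolysis is constrained only by the total
  suppression target.
- Paired windows inherit whatever transient falls inside them; the
  2-h window mean is the designed estimand, and quantities defined on
  steady states (scavenger restoration) are computed from steady states
  instead.
- GC-MS support covers quantification conventions only; chromatogram
  parsing, peak integration and spectral matching are out of scope.
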