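# Methods

## The measurement chain being modelled

In the in vitro gas production technique (IVGPT), a feed substrate (~0.5 g
dry matter, DM) ferments in 90 mL of buffered rumen fluid inside a sealed
100 mL bottle at 39.5 °C for 24 h. A pressure module on each bottle records
the headspace gauge pressure (relative to concurrently measured ambient)
every 10 min and vents the headspace into a gas-tight bag whenever it
exceeds 0.75 psi; the logger maintains a cumulative pressure register.
Blank bottles (fluid, no substrate) quantify the inoculum's baseline
microbial activity. After incubation, the bag gas is assayed for CH4 by
GC-TCD against a standard series, and the undegraded residue is filtered,
dried and weighed.

`ivgp` turns these raw records into the standard report quantities and
their repeatability across fermentation trials and rumen-fluid donor types
(`RF_T`, fasted heifers; `RF_A`, non-fasted lactating cows).

## Analysis procedure

1. **Blank correction** (`ivgp.blank`). The mean blank cumulative curve is
   formed pointwise on the sample grid; its earliest global maximum marks
   the onset of headspace-gas absorption. Up to that peak, the time-matched
   mean blank pressure is subtracted from each sample bottle; after it, the
   blank's maximum is subtracted. The two formulas agree at the boundary,
   so the rule introduces no discontinuity. Negative corrected values are
   retained (clamping would bias total gas production upward) and counted
   as a QC flag. An optional centred moving mean (default off — the
   reference protocol applies none) guards peak *detection* against sensor
   noise; it never alters the subtracted values. The mean over all blanks
   is used; a config switch selects a single named blank instead.

2. **Gas conversion** (`ivgp.gas`). Cumulative gauge pressure is converted
   with the ideal gas law: `V_STP = p·V_h·T_STP / (T_inc·P_STP)`, linear in
   `p`, then divided by incubated DM, giving TGP in mL STP/g DM. STP is
   273.15 K / 101.325 kPa (the dominant IVGP convention) and is
   configurable, as is the headspace volume `V_h` (default 10 mL, the
   nominal 100 mL bottle minus 90 mL fluid; real bottles exceed nominal
   volume, so the value used is echoed in every report). No non-ideal-gas
   or humidity corrections are applied.

3. **Kinetics** (`ivgp.kinetics`). All parameters are nonparametric — no
   curve family is fitted in the analysis path. TGP at the report hours
   {3, 6, 9, 12, 24} is linear interpolation on the grid. `tgp_end` is the
   value at end of fermentation (default 24 h, configurable); `H` is
   exactly half of it; `H1` is the earliest interpolated time the curve
   reaches `H` (sub-grid resolution, matching the 0.1 h precision such
   values are reported at). The rate over each recording interval is its
   slope in mL/g/h; `Vmax` is the maximum and `Tmax` the left endpoint of
   the earliest maximal-rate interval — grid resolution only, since the
   rate is defined per interval. Trial-level parameters are computed per
   bottle and averaged over the QC-included technical replicates.

4. **Replicate QC** (`ivgp.qc`). Bottles deviating more than 10% from the
   group-mean TGP at 12 h are excluded from the trial average. The
   reference mean is computed once over all candidates (single pass);
   iterating after exclusions could cascade and is available only as a
   sensitivity option. With exactly two replicates disagreeing, the rule
   cannot identify the outlier: both are flagged and the trial is marked
   unusable (conservative). GC analytical replicates must agree within 10%
   of their mean or an error prompts re-injection.

5. **Methane** (`ivgp.methane`). %CH4 is regressed on peak area over the
   standard levels (1–25% CH4 in N2) by OLS — the *prediction* direction,
   so bag areas read off directly. Fits with R² ≤ 0.985 are rejected.
   Predictions are clipped to [0, 100]% with a flag. CH4 yield is
   TGP × %CH4/100 per trial, then averaged across trials; because averaging
   and multiplication do not commute, the mean yield need not equal mean
   TGP × mean concentration. The yield basis is blank-corrected TGP at
   24 h (consistent with every other reported gas value); an uncorrected
   variant is a config switch. CH4 remaining in the bottle headspace
   (vs the collected bag) is not modelled.

6. **Degradation** (`ivgp.degradation`).
   `dDM = 1 − (residue − blank biomass)/DM`, with blank biomass the mean
   blank-bottle residue of the trial. Values outside [0, 1] (weighing
   noise) are retained with a flag so repeatability statistics stay
   unbiased.

7. **Statistics** (`ivgp.stats`). Repeatability per parameter is
   `CV_RF = 100·σ/mean` across trials, with σ the unbiased (n−1) SD;
   computed within donor type and overall. Two overall estimators are
   reported because pooling trial means across donor types that differ
   systematically inflates the SD: the plain CV over all trial means, and
   the pooled within-type SD over the grand mean. Donor comparisons use the
   fixed-effects model `Y = μ + trial + donor + trial:donor + ε` with
   backward reduction of non-significant terms (α = 0.05) plus a Welch
   t-test for the unbalanced 5-vs-12 comparison. When every trial uses a
   single donor — the actual study layout — the trial factor is confounded
   with donor type, the full model is rank deficient, and the fit
   auto-reduces to the donor effect with a warning; the crossed branch
   (interaction test, split-by-donor re-test) applies only to genuinely
   crossed tables. No multiple-testing correction is applied across
   parameters, matching common practice for this design; all parameters
   are reported with their raw p-values.

## The synthetic-data generator

`ivgp.synthetic` generates complete studies — pressure logs with venting,
blanks, GC standards and bag areas, residue weights — with closed-form
ground truth for every downstream quantity.

**Curve families.** `RF_T` substrate gas follows an offset logistic
(monophasic sigmoid, zero at t = 0, inflection at `t_half`):
`V(t) = A·(σ(k(t−t_half)) − σ(−k·t_half))` with defaults A = 196.7 mL/g,
k = 0.2226 /h, `t_half` = 11.81 h. `RF_A` follows a lagged exponential
`V(t) = A·(1 − e^(−k·max(0, t−lag)))` with A = 201.9 mL/g, k = 0.0819 /h,
lag = 0.23 h. These defaults were calibrated once against the reference
study's printed per-type TGP time course and reproduce it within 5% at
every report hour, with the sigmoid's maximum rate near 12 h and the
exponential's immediately after its lag. Two published kinetic quantities
cannot be hit simultaneously with any single curve of these families: a
late `Tmax` (≈11.4 h) together with an earlier `H1` (≈9.7 h) for the
sigmoid, and an `RF_A` `Tmax` of 2.3 h together with the steep early TGP
profile. Those printed values are averages of per-trial estimates, not
properties of one curve; the generator prioritises the TGP profile.

**Baseline gas.** The blank model separates gas *produced* by the baseline
community (rises smoothly to 8 mL at 6 h, then constant) from gas
*observed* in a blank bottle's headspace (declines after the peak at
0.15 mL/h as CO2 is absorbed into the fluid). Sample bottles carry the
produced component — their ongoing fermentation keeps the headspace
flushed — while blanks show the observed one. This is precisely the
situation the two-phase correction addresses, and it makes noise-free
pipeline recovery exact at the grid points.

**Venting and recording.** The simulation runs on a 1-min internal step
(the sensor's live interval): headspace pressure accumulates, and any step
reaching 0.75 psi vents the full gauge overpressure into the bag. Venting
conserves gas exactly: cumulative register = vented + instantaneous at
every step. Records are kept every 10 min; recorded pressures get additive
Gaussian sensor noise (SD 0.005 psi, ~0.1% of typical readings) and the
cumulative record is forced non-decreasing, as the logger's register is.

**Noise and variation.** Independent Gaussian noise throughout: weighing
SD 2 mg, GC area CV 1%, between-bottle curve scale CV 1%, pH SD 0.02. No
autocorrelated sensor drift, temperature excursions, or microbial-community
dynamics are simulated — passing tests show the *computational* chain is
correct and unbiased under these error models, not that real rumen-fluid
variation is captured. Between-trial biological variation multiplies the
curve amplitude (CV 3% for RF_T, 1% for RF_A) and shifts true CH4% (SD
0.30/0.15) and dDM (SD 0.003); magnitudes were chosen so simulated CV_RF
values fall in the low-percent range typical of this assay without
targeting any particular published CV. True CH4 is 9.2% (RF_T) / 9.9%
(RF_A); true dDM 0.609 / 0.587; pH 7.00/6.85 and 5.90/6.71 (pre/post).
Each bottle's RNG stream derives from a stable hash of
(seed, trial, bottle), so adding bottles never perturbs existing ones;
`NoiseModel.none()` freezes both measurement noise and between-trial
variation for fully deterministic datasets.

## Numerical choices and degenerate inputs

* Missing samples within a series are allowed; queries interpolate
  linearly. Grids must be covered by the recorded range; extrapolation is
  an error.
* Earliest-tie conventions everywhere an argmax/crossing occurs: blank
  peak, `H1` (0 for an all-zero curve), `Tmax`.
* Zero-variance Welch comparisons: equal means give t = 0, p = 1; unequal
  means with zero variance give p = 0.
* Reported CSV/JSON numbers are written with `%.17g` and read back with a
  round-trip float parser, so results reload bit-identically.
* Readers reject decreasing cumulative registers (corrupt exports) and
  name the bottle and time; in-memory blank series may decline — that is
  what the peak logic is for.
* Extremum statistics under noise: the maximum of noisy per-interval
  slopes carries a small positive bias (a property of any max estimator)
  and `Tmax` is grid-quantised, so simulation checks hold the smooth
  functionals (TGP, H, H1, CH4%, dDM) to 0.5% mean bias and the extremum
  statistics (`Vmax`, `Tmax`) to their discretization bounds (2% / one
  recording interval) against the analytic curve.

## Problem sizes

The test suite simulates trials of 3 sample + 2 blank bottles at 10-min
recording over 24 h; recovery checks average 200 seeded trials per donor
type, and the calibration of the donor test uses 2000 null and 500
shifted simulated study tables — sizes at which the binomial uncertainty
of a 5% rejection rate is about ±0.5%. The acceptance script runs the
default 17-trial study (5 RF_T + 12 RF_A).

## Known limitations

* The sensor's quantisation is not modelled (the published resolution
  figure is implausible beside its stated accuracy; the reader makes no
  assumption about quantisation).
* Filter-bag porosity losses, headspace humidity, non-ideal gas behaviour
  and VFA/microbiome dynamics are out of scope.
* The blank "produced vs observed" split is an idealisation; in real
  sample bottles absorption and production overlap, so the two-phase rule
  remains an approximation there.
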