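# Methods

## Calibration model

Cq is modelled as a three-parameter logistic in z = log10(concentration,
amol/L):

    Cq(z) = c / (1 + exp(g (z − b))),  g > 0.

`c` is the Cq plateau reached as template vanishes, `b` the midpoint of
the sigmoid on the z axis, and `g` the rate; the constraint g > 0 makes
the curve monotone non-increasing in concentration, and the lower
asymptote is pinned at zero since no calibration series approaches it.
This single family accommodates both the nearly log-linear curves seen in
well-behaved assays and the strongly flattened low ends seen when a
series runs past the detection floor; at the midpoint the local slope is
−c·g/4 Cq per decade, so a textbook −3.32 Cq/decade assay around c ≈ 38
corresponds to g ≈ 0.35–0.65 depending on where in the curve the series
sits.

Fitting is ordinary nonlinear least squares (scipy `curve_fit`,
trust-region reflective) on replicate-level wells, censored replicates
excluded. Initialisation is deterministic: c₀ = 1.05 × max Cq, b₀ =
median z, g₀ from the straight-line slope of the middle 50% of points via
the midpoint-slope identity; if that start fails to converge, a fixed
3×3 grid of (c₀, g₀) perturbations is tried before the fit is declared
non-converged (downstream LLOQs then become indeterminate rather than
wrong). The lower bound c ≥ max(Cq) − 0.5 keeps the plateau at or above
the data ceiling it models. The parameter covariance is σ̂²(JᵀJ)⁻¹ with
σ̂² = SSE/(n − 3). With fewer than four usable calibrator points the fit
refuses to run (three parameters plus one residual degree of freedom).

## Inverse prediction and its standard error

The fitted curve is inverted in closed form, z(y) = b + ln(c/y − 1)/g,
for observed Cq y strictly inside (εc, c − εc) with ε = 0.01; outside
that interior — including censored observations — the prediction is
reported `out_of_range` rather than as a wild number, because the
inversion diverges at the asymptotes. The variance of ẑ is propagated to
first order:

    Var(ẑ) ≈ ∇zᵀ V ∇z + (∂z/∂y)² σ̂² / m,

where ∇z = (∂z/∂c, ∂z/∂g, ∂z/∂b) at the estimates, V the parameter
covariance, and m the replicate count behind y. The second
(new-observation) term is included by default because the interval is
meant to describe a *new sample's* uncertainty, not just the curve's;
`include_new_observation=False` switches to calibration-only mode. 95%
intervals use the normal quantile 1.96 on the log10 scale (no df
correction is applied; at typical n ≈ 30 wells the difference is
negligible against replicate noise). The delta-method SE was checked
against a 2000-resample parametric bootstrap (agreement within a few
percent at mid-range) and CI coverage against simulation (93–95% at
nominal 95% over 200 seeded runs).

## LLOQ from the logistic fit

Each calibrator's across-replicate mean Cq is inverse-predicted and
scored by one metric: percent relative error against the known
concentration (default threshold 20%) or the SE of the inverse prediction
(default 0.25, log10-concentration units — the scale the model and its
CIs live on; 0.25 log10 units ≈ 1.78-fold; a natural-log variant is
available since the convention is not universal). "Below the threshold"
is strict: a tie at exactly 20.0% or 0.2500 fails — the conservative
reading, and configurable. Scanning ascending concentrations, the LLOQ is
the smallest concentration contained in any consecutive pair of passing
calibrators, or missing when no pair passes; calibrators with wholly
censored replicates automatically fail. A single isolated passing point
is deliberately not enough: requiring two adjacent passes protects
against one dilution passing by luck inside the noise floor.

## LLOQ from baseline noise

The tree has three mutually exclusive nodes, and the node taken is always
recorded:

1. **NTC determined** (≥ 1 NTC replicate with a Cq; the mean is over
   detected replicates): the quantifiability line is NTC+10 = mean NTC Cq
   − log2(10) = mean − 3.32, a 10-fold signal margin under perfect
   doubling. The offset is computed as log2(fold), not hard-coded, so a
   different signal-to-noise multiple or efficiency-adjusted base can be
   configured. The LLOQ is the lowest calibrator whose mean Cq is below
   NTC+10 *and* above the next-higher calibrator's mean Cq — a local
   monotonicity guard (equality fails it) that rejects points still
   rattling in the floor; the top calibrator has no higher neighbor and
   is never a candidate.
2. **NTC and ≥ 1 calibrator undetermined**: the noise floor is the
   highest wholly-censored dilution; LLOQ = measured calibrator nearest
   to 10× that floor.
3. **NTC undetermined, all calibrators determined**: the hypothetical
   next dilution (lowest concentration / dilution factor) is the floor;
   LLOQ = measured calibrator nearest to 10× it.

"Nearest" is measured in |Δlog10 concentration| — serial dilutions are
geometric, so log distance is the natural metric — with ties broken
toward the higher concentration (conservative; configurable). A
calibrator point counts as "undetermined" when *all* its replicates are
censored; a majority-censored policy is available as a switch for
stricter instruments. Both LLOQ workflows only ever return a measured
calibrator concentration of the run, or missing.

## Sample quantitation

Unknowns are grouped by sample id, replicate wells averaged, and the mean
inverse-predicted with the replicate count m in the variance. Copies/µL
of biofluid = amol/L × N_A × 10⁻¹⁸ / 10⁶ × volume factor, where the
volume factor encodes the dataset's extraction/dilution chain and is
most conveniently pinned from one documented equivalence
(`volume_factor_from_equivalence`). Sub-LLOQ estimates are reported with
a flag instead of being censored to missing: the error bars are exactly
the information a reader needs to judge such values, and a censored
table cannot be un-censored later. When the LLOQ itself is indeterminate
(non-converged fit, no qualifying pair), estimates are still reported and
flagged `lloq_indeterminate`.

## Synthetic data

The generator draws replicate Cqs as truth + N(0, sd) around a true 3PL
curve, censors anything past the instrument ceiling (default cycle 40) as
undetermined, draws NTC background independently of the curve (background
signal in blanks comes from primer artifacts, not template), and pushes
unknowns through the same curve. Defaults describe one realistic run: 11
dilutions, 3-fold steps from 1 pmol/L (floor 16.9 amol/L), 3 PCR
replicates, sd 0.2 Cq, true parameters (c, g, b) = (38, 0.63, 5.8) —
a curve running from Cq ≈ 18 at 1 pmol/L to a plateau just below 38.
Noise is homoscedastic by default, the simplest model consistent with
replicate scatter; a heteroscedastic option doubles the SD linearly
toward the lowest dilution, since real low-input scatter grows. Two
cohort-level generators reproduce study *designs*: a 65-run multi-site
cohort (six sites × four protocol arms × three rounds, one failed plate;
10–12 dilutions; per-run noise SD uniform on 0.1–0.4 Cq; NTC background
present with probability 0.7) and a 14-run biofluid study carrying 104
unknowns drawn log-uniformly from 10 amol/L to 0.1 pmol/L.

What passing tests on these simulations do **not** show: the generator
has no plate or site batch effects, no amplification-efficiency drift, no
correlation between NTC level and curve quality, and its unknown-level
distribution is a broad log-uniform rather than the bimodal
control/elevated structure of a real injury study. Cohort-level summary
fractions (e.g. how often a workflow's LLOQ equals the lowest calibrator)
therefore characterise the *methods'* relative conservatism under
controlled conditions, not the exact percentages any particular real
dataset would give.

## Numerical and interface choices

* The logistic exponent is clipped at ±500 before `exp` to avoid
  overflow; forward prediction is exact elsewhere.
* The inversion interior guard ε = 0.01·c trades a little usable range
  near the plateau for bounded standard errors; predictions at the guard
  boundary are `out_of_range`, never clamped.
* Input parsing is total: every row of a long-format well table is either
  consumed into a run or reported (cell-level errors carry the 1-based
  file line; runs with < 2 calibrator points are dropped with a named
  warning). Censored-token matching is case-insensitive over a
  configurable list ("Undetermined", "Undet.", "NA") because instrument
  exports differ. Concentrations are stored internally in amol/L, with
  declared-unit conversion at the reader.
* LLOQ tables round-trip at six significant digits; output files carry
  the package version and a hash of the effective configuration.
* Fits, LLOQs and simulations are deterministic given their inputs and
  seeds; problem sizes in the test suite and acceptance script (200-seed
  coverage/bias loops, 2000-resample bootstrap, 65-run cohort) were
  chosen to give stable statistics at interactive runtimes.

## Known limitations

4PL/5PL models, weighted least squares, efficiency-based (slope)
quantitation, upper limits of quantitation, and NTC-SD-based detection
limits are out of scope. The SE-threshold convention (0.25 on log10) is a
package default, not a universal standard; users comparing against other
software should confirm which scale that software uses. LLOQs are
per-run by construction and are not commutable across runs or platforms.
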