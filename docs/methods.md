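# Methods

## Measurement model

### From fragment sizes to repeat counts

Capillary electrophoresis reports apparent fragment sizes in base pairs.
For CAG-repeat PCR products the apparent mobility per repeat unit deviates
from the nominal 3 bp because of sequence-dependent migration; the package
uses a linear map

    size_bp = intercept_bp + repeat × bp_per_repeat

with `bp_per_repeat = 2.724117` by default. The constant is treated as the
*slope* of this map — the only reading under which a single constant
suffices to convert sizes to repeat counts — and the intercept is
calibrated per run by anchoring the tallest peak of a sample of known
modal genotype (here the 125-CAG line) to its known repeat count. Because
the intercept is calibrated, the choice of sizing interpolation upstream
(piecewise-linear here, versus Local Southern in commercial software) is
absorbed and does not bias repeat calls. Repeats are assigned by
nearest-integer rounding (half-up; half-even is available), peaks rounding
to the same repeat are merged by summing heights, and a computed negative
repeat raises a calibration error rather than being clipped.

### Threshold filter and instability index

Within each sample, peaks below 20% of the modal peak height are discarded
(inclusive comparison: a peak exactly at the threshold is kept; the modal
peak always survives). Proportional heights are renormalised over the
retained peaks — "proportional peak height" is read as the post-filter
proportion. The modified instability index is the height-weighted mean
deviation of retained repeat lengths from a reference repeat; the
reference is each replicate culture's *baseline* modal repeat, so the
index measures drift relative to where that culture started. The index is
invariant to uniform height scaling and shifts by exactly k when the
reference moves by −k.

A consequence worth knowing: with a mode-relative threshold the measured
index is a *sublinear* function of the underlying expansion rate at low
rates (slow arms lose more of their distribution tail to the filter), so
percent slowing measured on the index is systematically larger than the
generative rate reduction. This is a property of the estimator, not a bug;
the same ordering (index slowing > modal slowing) appears in real
knockdown data. The closed-loop tests therefore compare interval coverage
against the model's *expected measured* slowing, not against the raw rate
ratio.

### Peak calling and sizing

Peak detection reports local maxima (plateaus report their leftmost scan)
with signal at or above a height floor and a minimum mutual spacing;
conflicts are resolved tallest-first. Detection wraps
`scipy.signal.find_peaks` with an explicit height-ranked spacing pass and
is verified against a brute-force all-windows scan on randomized traces.
Sizing interpolates bp piecewise-linearly between ladder points
(`numpy.interp`); peaks outside the ladder span cannot be sized and are
excluded with a warning. The bundled 50–1000 bp ladder is a synthetic
stand-in with round fragment sizes, not the published composition of any
commercial standard.

## Time-course estimation

Metrics are first expressed as deltas from each replicate's designated
baseline sample (baseline rows become exactly 0), with time measured from
the baseline timepoint in the sample sheet's unit (days for dividing
cultures, weeks for neuronal cultures). Each replicate contributes one OLS
slope through the origin — the intercept is fixed at zero because the
response is defined relative to baseline. Replicates with fewer than three
distinct timepoints are excluded with a warning; a condition losing all
replicates is an error.

The condition rate is the mean of replicate slopes, with SE = SD/√n and a
t-interval on n−1 df. For balanced designs this equals the condition-slope
estimates of a linear mixed-effects model with a random slope per culture;
that model (statsmodels `MixedLM`, REML) is provided as `method="mixed"`
and agrees with the two-stage estimates within 2% on balanced simulated
data. The two-stage form is the primary estimator because it is fully
specified without reference to a fitting library and is transparent about
where its degrees of freedom come from.

Percent slowing is 100·(1 − rate/control_rate), pooling all control
replicate slopes; it is NaN when the control rate is not positive. Its 95%
interval uses the delta method on the ratio of replicate-slope means with
Welch–Satterthwaite degrees of freedom. Pairwise condition contrasts use
Tukey's HSD on replicate slopes (`scipy.stats.tukey_hsd`); at two groups
this reduces exactly to the pooled-variance t-test. Significance is
declared at 0.05.

Independent CRISPRi pools are carried as part of the replicate label
(pool–culture); no pool-level random effect is fitted, as replicate
cultures are treated as the exchangeable unit.

## Generative model (simulator)

The simulator exists to give the pipeline a ground truth. Each allele
performs a length-dependent birth–death walk on integer repeat counts:
over an interval Δt it gains Poisson(gain_rate·m·Δt·f(L)) and loses
Poisson(loss_rate·Δt·f(L)) repeats, with f(L) = max(0, 1 +
length_dependence·(L − initial_repeat)) and m the condition's gain-rate
multiplier. Lengths are floored at 1. For the length-independent case the
net gain has mean and variance (gain−loss)·t and (gain+loss)·t in closed
form, which the Monte-Carlo tests check. This process was chosen for
analytic tractability and because it reproduces the unimodal, upward-
drifting distributions seen in culture; it does not model MMR biochemistry,
cell division, or contraction-biased dynamics, and the variance structure
beyond the Poisson choice is a modelling assumption not constrained by
available data.

Measurement artefacts: PCR stutter is downward-only with geometric decay —
each allele of length L contributes mass `stutter_ratio^k` at L−k for
k = 0..stutter_orders (defaults 0.3 and 5; upward stutter is negligible at
these repeat lengths). Traces are sums of Gaussian kernels (σ = 0.8 bp) on
a 20 scans/bp axis with optional Gaussian baseline noise, plus the ladder
channel returned as its peak calls.

### Calibration and presets

Two presets pin the generator to observed control behaviour:

* `ipsc-control` — gain_rate = 0.07/day, chosen so the expected *measured*
  modal gain at day 80 is 5 CAG (Poisson mean 5.6; the stutter-smoothed
  mode sits at +5).
* `msn-control` — gain_rate = 0.03220567/day, chosen so the expected
  fitted instability-index slope on the 0/3/6/9-week design is 0.20
  units/week.

Both were fixed by computing the expected readout of the full measurement
chain (stutter + threshold + index, infinite-allele limit). The
`KNOCKDOWN_MULTIPLIERS` for the MutL arms (MLH1 0.3162, PMS1 0.5804, PMS2
0.6304, MLH3 0.6652) were calibrated by Monte-Carlo inversion of the full
pipeline on the 9-week design, because the infinite-allele readout is
piecewise-discontinuous in the gain rate (threshold-set membership changes
in jumps) while the finite-allele pipeline smooths across those jumps; the
multipliers are the values whose expected measured index slowing matches
the knockdown effects the generator emulates (~75/46/41/38%).

Per-culture biological variability is emulated by a lognormal multiplier
on each replicate's gain rate (mean 1, CV 0.10 by default), matching the
visible scatter of parallel cultures in real rate data; without it,
finite-allele sampling alone would understate between-replicate variance
and interval coverage would be misleadingly narrow.

### Default problem sizes

Preset populations use 10⁴ alleles (roughly the template count of a
genomic PCR). Closed-loop coverage and null-behaviour simulations in the
test suite run at 10³ and 3×10² alleles respectively with the full
8-culture (4 replicates × 2 pools), 5-timepoint design, sizes chosen to
keep Monte-Carlo repetition cheap while leaving replicate-level noise
realistic. The acceptance script averages each reported quantity over 20
independently seeded studies so that reported values estimate the expected
readout (single-study SE on percent slowing is ~2–3 points at 8 cultures).

## What the simulations do and do not show

Passing closed-loop tests demonstrate that the pipeline recovers modal
drift, index slopes, percent slowing, and type-I-controlled contrasts from
data with the *assumed* statistical structure: Poisson gains, geometric
downward stutter, Gaussian peaks, lognormal replicate variability. Real
electropherograms additionally contain baseline drift, dye pull-up,
off-scale peaks, heteroduplex artefacts and interrupted-repeat structure,
none of which are modelled; results on real data depend on upstream peak
calling quality in ways these tests cannot certify. The simulator is
calibrated to control-culture summary statistics (modal gain, index
slope), not to any distribution-level measurements, so distributional
details beyond the mode and mean are modelling choices.

## Numerical conventions and degenerate inputs

* Modal ties: the smaller repeat wins (conservative against spurious
  expansion calls); a calibration-sample height tie spanning more than one
  repeat unit is an error.
* Threshold comparison inclusive; rounding half-up; plateau peaks report
  their leftmost scan.
* Distribution masses must sum to 1 within 1e-9; peak tables reject
  non-positive sizes/heights and duplicate peaks within 0.1 bp; traces
  shorter than 3 samples, ladders with fewer than 2 points, unsorted or
  negative time grids, and empty sample sheets are errors rather than
  warnings.
* All randomness flows through one `numpy.random.Generator` per run,
  seeded explicitly; identical configuration and seed give byte-identical
  output files.
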