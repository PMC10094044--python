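# Methods

## The stochastic-dynamic quantification model

The toolkit treats the per-scan intensity of a monitored m/z window as a
discrete random variable and quantifies its fluctuation over short spans of
scan time.  For a span *i* holding the intensities `I_i`, the second-order
diffusion parameter is

    D″_SD,i = K2 × ( ⟨I_i²⟩ − ⟨I_i⟩² ),       K2 = 2.6388×10⁻¹⁷,

and the total over a series is the sum over its spans (additivity is exact
by construction).  The first-order form is

    D_SD,i = K1 × A_i × ( ⟨I_i²⟩ − ⟨I_i⟩² ) / ⟨(I_i − ⟨I_i⟩)²⟩,
    K1 = 1.3194×10⁻¹⁷,

with `A_i` the amplitude of the sine-squared model
`y = y0 + A·sin²(π(x − xc)/w)` fitted to the squared-deviation trace
`(I − ⟨I⟩)² = f(t)` within the span.  The constants satisfy `K2 = 2·K1`
exactly (asserted in code); when the squared-deviation trace is a pure
sine-squared oscillation, `A_i = 2·var` and the fitted-curve mean equals the
variance, so `D_SD = D″_SD` — the two forms are one model seen through a raw
statistic and a fitted one.

**Numerator/denominator convention.**  Taken as the same sample statistic,
the numerator variance and the denominator mean squared deviation are
algebraically identical and the ratio collapses to 1, reducing `D_SD` to
`K1·A_i`.  The default instead uses the raw population variance in the
numerator and the *time-average of the fitted curve* in the denominator.
Under noise the two differ, and the discrepancy between `D′` and `D″` then
reflects exactly the fitting error of the sine-squared model — the intended
diagnostic.  The collapsed convention (`sample_msd`) remains selectable.

The constants are applied verbatim to intensities in counts and the result
is labelled cm²·s⁻¹.  Their physical provenance and unit consistency are
not derivable from first principles here; no unit conversion is attempted,
and no absolute diffusion-coefficient interpretation should be attached to
the values.  All comparative uses (calibration slopes, correlations) are
invariant to the constant.

**Variance convention and numerics.**  Population (denominator *n*), since
the model is written in raw-moment form.  The implementation evaluates the
mathematically identical two-pass form `mean((I − ⟨I⟩)²)`: for realistic
traces (mean ~10⁵ counts, sd ~10² counts) the raw-moment difference
`⟨I²⟩ − ⟨I⟩²` cancels catastrophically and loses ~6 significant digits.

**Spans.**  Default: consecutive spans of 5 scans (`fixed_count`); a
trailing single scan is absorbed into the last span so every span covers at
least 2 scans.  Explicit span boundaries are supported for emulating
acquisition-method segments.  Whether spans should coincide with instrument
segments or sliding windows is an open question of the method; both
interpretations are expressible.

## SineSqr fitting

Model: `y0 + A·sin²(π(x − xc)/w)`, the common plotting-software
parameterization.  The fit is multi-start nonlinear least squares
(`scipy.optimize.least_squares`, trf, w bounded positive):

1. a spectral start — since `sin²` is a shifted cosine of frequency `1/w`,
   the dominant FFT mode of `y − ⟨y⟩` on a uniform grid gives `w`, and a
   linear cos/sin fit at that frequency gives amplitude, phase, and offset
   in closed form (this start alone converges to machine precision on
   noiseless data);
2. a coarse heuristic start `(min, ptp, argmax, 2×range)`;
3. ten seeded random restarts drawn around those scales.

The lowest-RSS solution wins; results are deterministic for a fixed seed.
A negative fitted amplitude is folded into a half-period shift of the
center so the reported `A` is always ≥ 0.  A constant ordinate returns
`A = 0, y0 = mean(y)` with a `degenerate` flag rather than an error.

## Collision-energy intensity relation

For a fragment ion *q* measured at several collision energies, the profiles
`D″_SD = f(CE)` and `⟨I⟩ = f(CE)` are each fitted with the SineSqr model;
their amplitudes `A_D^q` and `A_I^q` convert each measured `D″_SD,tot` into
a theoretical mean intensity `⟨I⟩_theor = ½ (A_I^q/A_D^q) D″_SD,tot`.  The
Pearson correlation between theoretical and experimental intensities is the
validity check.  `A_D = 0` (flat diffusion profile) makes the relation
undefined and raises a degeneracy error.

## Chemometric grouping of m/z measurands

Pooled per-scan m/z values of one monitored peak are partitioned into
statistically distinct subsets (tautomers/co-isolated species):

1. **Gap pre-split** at consecutive sorted spacings > `gap`
   (default 0.2 Th, matching the typical spacing of resolved fragment
   groups).
2. **Mixture refinement** within each gap-block: a 1-D Gaussian mixture
   with the component count chosen by BIC (1..4), hard assignment by
   maximum responsibility.  This step is essential for *overlapping*
   clouds: two Gaussians 0.4 Th apart with sds 0.10/0.15 leave no empty
   0.2 Th gap anywhere (valley spacings are ~0.02 Th), so a gap split alone
   can never separate them, while BIC selects two components reliably at
   n ≈ 80.
3. **Welch-merge fixpoint**: candidate groups whose Welch t-test p-value is
   ≥ α are merged (single linkage, iterated until stable).  Welch rather
   than Student, because empirical group sds differ materially.  Groups
   smaller than 3 are absorbed into the nearest-mean candidate before
   testing.
4. **Report**: pairwise Welch matrix, one-way ANOVA across final groups,
   per-group Shapiro–Wilk normality.  α defaults to 0.05; no
   multiple-testing correction is applied across the pairwise verdicts (raw
   pairwise significance is the quantity of interest; a Bonferroni-style
   workflow can be had by passing a smaller α).

Caveat: the merge step compares *value-disjoint* subsets, so it can undo
spurious mixture components only when their means genuinely overlap; the
BIC selection, not the merge, is what guards against over-splitting.

## Calibration and the TIA comparator

`calibrate` fits ordinary least squares of `ln D″` (default) or raw `D″`
against concentration (ng/mL), reporting slope/intercept with standard
errors and Pearson r.  The log transform is the natural one: under a
log-linear variance law the calibration is exactly linear, and the
intercept absorbs any multiplicative prefactor (so the slope is invariant
to the diffusion constant).

`tia_quantify` implements the classical comparator: optional
Savitzky–Golay smoothing (odd window > polyorder), optional linear baseline
through the endpoints, trapezoidal integration of the non-negative
residual.  It is labelled a TIA comparator; the proprietary vendor
peak-detection algorithm it stands beside in practice is not reimplemented.

## Quantum-chemical diffusion parameter

    D_QC = ( Π νᵢ⁰ / Π νᵢˢ ) × exp( −ΔH‡ / (R·T) )

computed entirely in log space (`Σ ln ν⁰ − Σ ln νˢ − ΔH‡/RT`, then one
`exp`), since frequency products over dozens of modes overflow double
precision — the log-space and direct evaluations agree to 1e-12 relative on
small inputs (tested).  Inputs are vibrational wavenumber lists for the
ground and transition states (the TS list exactly one mode shorter — the
reactive mode), an activation enthalpy, and a temperature:

- ΔH‡ unit default **hartree** with R = 3.1668116×10⁻⁶ hartree/K (matching
  quantum-chemistry program output); kJ/mol mode with
  R = 8.31446262×10⁻³ kJ/(mol·K) selectable.  1 hartree = 2625.49964 kJ/mol.
- T default 298.15 K.
- Wavenumbers are used as given in cm⁻¹; the unit cancels in the ratio up
  to one leftover factor, and no unit is attached to D_QC.
- Non-positive (imaginary) modes are rejected, never silently dropped: the
  caller must exclude the imaginary TS mode explicitly.

Electronic-structure computation itself is out of scope: frequencies and
enthalpies are inputs, never computed.

**Structure assignment.**  Given measured `D″_SD` values for ≥ 3 ions and
candidate structures per ion, `assign_structures` enumerates the candidate
product space (capped at 10⁶ combinations) and returns the combination
maximizing |r| of the `D″_SD = f(D_QC)` line, with ties broken toward
earlier-listed candidates.  Two caveats discovered in validation and worth
knowing: (a) a candidate set that rescales *every* ion's D_QC by a common
factor is invisible to correlation (scale invariance), and (b) a single
candidate orders of magnitude away from the rest dominates the fit through
leverage and can produce trivially high |r|.  Candidate sets should
therefore span comparable magnitudes and differ per-ion, which is exactly
what distinct tautomer geometries provide.

## Mass annotation

Nominal masses are integer sums over most-abundant-isotope integer masses
(C=12, H=1, N=14, O=16, Na=23, K=39, S=32, Cl=35, …); monoisotopic masses
use pinned exact isotope masses with an electron-mass correction applied in
monoisotopic mode only (nominal assignments are integer-level).  `D` is a
pseudo-element for deuterium so d₃-labelled standards parse directly.
Isotope patterns are built by per-element self-convolution (exponentiation
by squaring) followed by cross-element convolution, binned at 0.01 Da with
abundance-weighted mean masses, pruned at 1e-12 during accumulation and at
the user threshold on output.

One annotation subtlety: the paracetamol fragment at nominal m/z 110 is the
42 Da ketene loss from the protonated molecular ion at m/z 152, i.e.
protonated 4-aminophenol, C₆H₈NO⁺.  A label sometimes attached to this
fragment implies a 56 Da loss inconsistent with m/z 110; the package ships
the 110-consistent composition.

## Synthetic data generator

`simulate_srm` emits one centroid per species per scan: m/z ~
Normal(mean, sd), intensity from a Gaussian (clipped at 0) or Poisson
model; times on a uniform grid (default dt = 0.01 min, 100 scans).
`simulate_calibration` drives one species per concentration level with the
log-linear variance law `ln var = a + b·conc`.

Defaults, chosen once as the study conditions:

- grid 2, 6, 10, 20, 40, 80 ng/mL — the low-level biomonitoring range;
- `a = 16.0`, `b = 0.08` per ng/mL: the law spans ~6 ln-units across the
  grid (a D″ dynamic range of ~500×), the regime in which near-exact
  calibration linearity is attainable;
- base intensity 10⁶ counts, so the largest sd on the grid (~7 % of base)
  makes clipping at zero negligible and the planted variance is preserved;
- 100 scans per level.

A note on attainable precision: the sampling error of a variance estimate
from *n* scans is ≈ sqrt(2/n) in relative terms, so |r| of the log-linear
calibration is bounded by the scan budget — at 100 scans/level the pipeline
delivers |r| ≈ 0.996, at 800 scans/level ≈ sqrt(2/800) ≈ 5 % scatter and
|r| ≥ 0.999.  Tests of near-exact recovery therefore use 800 scans/level.

What the generator does *not* emulate — chromatographic peak shapes, ion
suppression, matrix effects, detector saturation, correlated drift — bounds
what passing tests show: they validate the statistical machinery under the
model's own assumptions, not instrument behaviour.  The generator's noise
laws are declared assumptions, not claims about any particular instrument.

Oscillatory intensity families (amplitude-modulated sine plus noise) are
used when a test needs the squared-deviation trace to carry genuine
sine-squared structure; for white noise the fitted `A_i` is erratic and the
`D′`/`D″` correlation degrades to |r| ≈ 0.3, which is a property of the
model, not a bug.

## Scan I/O

CSV dialect fixed as `scan,time_min,mz,intensity` (comma, dot decimal),
0-based scan indices, times in minutes; rows with the same scan index merge
into one scan and peaks are kept m/z-sorted.  The mzML reader covers the
minimal subset needed here — centroided spectra, 32/64-bit float arrays,
plain or zlib-compressed, scan start time in minutes or seconds — via the
standard-library XML parser, namespace-agnostic.  Window extraction takes
the most intense in-window peak per scan (closed interval), ties broken
toward the window center then toward lower m/z; unmatched scans contribute
zero intensity by default (`zero`) or are omitted (`skip`) — which
treatment is "right" depends on whether absence of a centroid means zero
signal or a dropped scan, so both are exposed.

## Known limitations

- The diffusion constants' absolute scale is taken on faith; only relative
  quantities are scientifically interpretable.
- Grouping assumes roughly Gaussian m/z clouds; heavy-tailed or drifting
  clouds will over-split (the BIC step) before the merge can repair it.
- The SineSqr fit is multimodal in `w`; the spectral start makes recovery
  reliable on uniformly sampled data, but sparse or strongly non-uniform
  abscissas fall back to random restarts and may need more of them.
- Profile-mode centroiding, vendor raw formats, and chromatographic peak
  detection are out of scope.
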