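# Methods

This note records the models, estimators and numerical choices behind
`cnadiff`, in the order the pipeline applies them, together with what the
synthetic generator does and does not emulate.

## Signal model

A two-channel aCGH probe measures test and reference intensities whose log2
ratio estimates the relative copy number at the probe's locus; zero is the
balanced state.  The pipeline treats a sample as a genome-ordered vector of
log2(Test/Ref) values and models it as piecewise-constant copy-number levels
plus probe-level noise, distorted by two array artifacts: a dye-composition
bias that varies with spot intensity, and a local-GC bias.

## Normalization

**Dye correction.**  The Cy3/Cy5 relation is fitted with a robust loess of
M = log2(T/R) against abundance A = (log2 T + log2 R)/2, and the reference
channel is rescaled by the fitted curve (span 0.3, degree 1, 3 robustness
iterations; fitted on a ≤ 20,000-probe uniform subsample of the sorted
predictor and linearly interpolated).  Two properties drove the choice of the
(A, M) frame over regressing one raw channel on the other: both channels are
equally noisy, so a channel-on-channel regression is an errors-in-variables
fit whose attenuated slope distorts the ratios of copy-altered probes in
proportion to their amplitude; and bias that depends on the probe's own
abundance can only be removed by conditioning on that abundance — a correction
conditioned on the test intensity alone leaves a residual at probes where the
channels genuinely disagree.  On generator defaults the residual inflation of
a 4.7-amplitude aberration was +0.13 under the channel-on-channel fit and
within noise under the (A, M) fit.

**GC correction.**  A loess of the ratio against probe GC fraction (same
settings), subtracted after mean-centering so only the GC-dependent component
is removed and the profile's overall level is preserved.  GC is taken from
the probe table; computing it from a reference genome is out of scope.  A
constant GC vector makes the fit undefined and the step becomes a warned
no-op.  The correction is idempotent to within the loess fit noise
(≲ 1e-3 RMS at array scale).

## Segmentation (CBS)

Per chromosome, the arc (i, j] maximizing

    t(i, j) = |mean_in − mean_out| / (sd · sqrt(1/k + 1/(n − k))),   k = j − i

is found (the circular scan: an arc and its complement give the same split),
where `sd` is the segment's trimmed SD (2.5% per tail).  The split is
accepted iff its Monte-Carlo permutation p-value

    p = (1 + #{permuted max-statistic ≥ observed}) / (1 + nperm)

is ≤ α; permutations are label permutations of the probe values within the
segment under test, with early rejection once the exceedance count makes
p > α certain.  Accepted splits cut at both arc ends; recursion proceeds on
the pieces.  Defaults: α = 0.01, nperm = 1,000 (the classical reference
default of 10,000 is supported but 10× slower), min_width = 2, trim = 0.025.
This is a pure permutation CBS: no hybrid tail approximation, no split
undoing.  Because the trimmed SD is a common factor within a segment test,
breakpoints and accept/reject decisions are invariant to the SD convention.

Numerics worth knowing:

* In centered-cumsum form the statistic is |z[j] − z[i]| · sqrt(n/(k(n−k)))/sd
  with z the cumulative sum of mean-centered values, so for fixed width k the
  scan reduces to tracking sliding-sum extremes (three operations per probe
  pair), and the window's z-range gives an O(1) upper bound per width.
  Permutation scans skip widths whose bound cannot reach the observed
  statistic; the returned value is exact whenever it reaches the comparison
  threshold, which is all the test uses.  These kernels are numba-compiled.
* Segments longer than 5,000 probes use a windowed scan (window 2,500, 50%
  overlap); below that the scan is exhaustive over all O(n²) arcs.  A
  deliberately naive exhaustive implementation (`cbs_segment_bruteforce`,
  direct per-arc formula, same RNG protocol) serves as an independent
  cross-check; the two agree on 100/100 random 60-probe arrays.
* A permuted maximum within 1e-9 (relative) of the observed one counts as an
  exceedance: permutations of small segments regularly reproduce the observed
  arc multiset exactly, and those ties must count identically regardless of
  floating-point evaluation order.
* Ties in the arc search break to the smallest i, then smallest j.
* Isolated outlier probes — more than 4 trimmed SDs from every neighbor
  within ±5 probes — are pulled to the local median before segmentation
  (`smooth_outliers`).  Without this, each such probe seeds a spurious
  2-probe segment whose selected mean far exceeds any calling threshold.
  Probes at true copy-number steps have same-level neighbors and are
  untouched.

## Centering and calling

The probe-value density is estimated on a 2,048-point grid (linear binning
convolved with a Gaussian of Silverman bandwidth — the standard binned KDE,
O(n) at array scale).  Local maxima are ranked by height; peaks below 5% of
the top peak's height are discarded (smoothing isolated tail points otherwise
creates massless local maxima).  Among the top three remaining peaks, the one
closest to zero is subtracted ("most centered"; a flag switches to
closest-to-mean).  Centering is idempotent to within half a bandwidth.

The calling threshold is median(|Δ consecutive log2 ratios|)/4 over
within-chromosome neighbor pairs (the ~23 junction pairs are excluded by
default; a flag restores the literal along-the-genome reading — at 180K
probes the difference is negligible).  For i.i.d. N(0, σ²) values the
threshold converges to σ·√2·Φ⁻¹(0.75)/4 ≈ 0.2385σ.  Calls are strict:
a segment mean exactly at ±threshold is neutral.

## Differential profiling

Dynamics = interquartile range of probe values.  The lower-IQR profile is
mapped onto the other by a robust errors-in-variables line fit: starting from
a plain dynamic-range match, probes whose residual exceeds 3 robust SDs
(1.4826·MAD) are masked, the Deming (λ = 1, equal error variances) solution
is recomputed on the rest, and the mask is re-derived from all probes until
stable.  The robustness matters twice over: ordinary least squares between
two equally noisy profiles attenuates the slope by their correlation (leaving
shared aberrations half-uncancelled), and probes carrying acquired
aberrations follow a different structural relation and must not steer the
fit.  Pairs with no resolvable shared structure (|r| below max(0.05, 4/√n))
fall back to matching interquartile ranges.

The difference `test − scaled(ref)` (always oriented resistant − parental) is
then treated as a profile: outliers smoothed, its own calling threshold
computed (`--threshold-source` can inherit an input's instead), CBS-segmented
with the same parameters, and called.  Maximal runs of contiguous same-call
segments at the same level (smaller |mean| ≥ half the larger) are merged into
regions — CBS occasionally splits one aberration into adjacent same-level
segments — while a low-level shoulder adjacent to a strong region stays
separate so it cannot dilute the region's reported mean.  Regions are
annotated with overlapping genes and cytobands (half-open overlap, ≥ 1 bp)
and sorted by |Diff.l2r| descending.

Swapping the pair flips every sign exactly (same breakpoints, gains ↔
losses).  On null pairs — independent noise plus an affine transform — the
measured false-call rate is ≈ 0.1–0.3 regions per 24-chromosome genome,
driven by the per-split α of the segmentation; it is not zero by design.

## Clustering and enrichment

Profiles sharing a probe universe are clustered on per-probe values (or
segment-mean-expanded values) with dissimilarity 1 − Pearson r and Ward
aggregation via the Lance–Williams recursion; output is deterministic and
exportable as Newick.  Enrichment of a differential gene list against a
background is a per-cytoband hypergeometric upper tail with BH correction —
a transparent, self-contained substitute for web-service enrichment tools,
not a reproduction of any of them.  A gene overlapping several bands counts
in each.

## Dose response

The 4PL model is fitted by bounded least squares in log10-dose space with
multi-start initialization (hill ∈ {0.5, 1, 2} × a 5-point geometric IC50
grid over the dose range; best RSS wins; 500 evaluations per start).  Vehicle
wells (dose 0) are excluded from the fit.  Data with no dose-dependent
inhibition (non-negative slope of mean response vs log dose), or fits whose
IC50 lands outside [min dose/10, max dose·10], are reported as censored
bounds.  RI censoring arithmetic: bound/point keeps the bound's direction,
point/bound flips it, bound/bound is indeterminate.  The fit is exactly
equivariant under a common rescaling of all doses.  A scikit-learn estimator
facade (`FourPLRegressor`) exposes the same fit for pipeline composition.

## Synthetic data generator

The generator is the package's study condition, not a tuning knob.  Defaults:

* **Design**: 180,000 probes spread proportionally to hg19-like chromosome
  lengths (24 chromosomes, hard-coded Mb table) with jittered even spacing;
  a smooth per-chromosome GC field in [0.3, 0.7] (Gaussian-filtered white
  noise scaled by the filter's theoretical output SD, plus ±0.02 probe
  jitter — normalizing by the realized SD would degenerate on chromosomes
  shorter than the filter).
* **Aberrations**: shared regions appear in both pair members, acquired
  (`resistant_only`) regions only in the resistant one; default amplitude
  magnitudes {0.58, 1.0, 3.2, 4.7} in log2 units, spanning the differential
  magnitudes reported for acquired aberrations in resistant osteosarcoma
  lines; 80–300 probes per region; same-scope overlaps are rejected
  (ambiguous truth).
* **Channels**: reference baseline log2-normal (mean 10, SD 1.8 — intensities
  spanning ~3 decades as on real scanners), test = reference · 2^(true log2);
  quadratic GC bias (peak 0.3 log2 units), intensity-dependent dye multiplier
  (amplitude 0.1) on the reference, Gaussian probe noise (ratio SD 0.25,
  split evenly between channels in log space), and 0.1% heavy-tailed outlier
  probes (t₃-scaled).
* Everything is deterministic under a fixed seed.

What it does *not* emulate: spatial (sub-grid) artifacts, replicate probes,
saturation, background subtraction, probe-sequence effects beyond GC, mosaic
or subclonal copy states, and any RNA-level readout.  Passing the recovery
suites therefore demonstrates correctness of the estimators under this noise
model, not performance on arbitrary real arrays.

## Problem sizes used in the checks

The acceptance checks run the differential recovery at full array scale
(180K probes, 8–10 seeded replicates, nperm = 1,000), the CBS/oracle
comparison on 100 arrays of 60 probes, the threshold closed form at 100K
probes, scaling at 10K probes × 50 seeds, clustering on 4K-probe designs ×
20 seeds, 4PL recovery over 100 seeds, and the null false-call rate on
20K-probe genomes × 20 seeds.  These sizes exercise every code path
(including the windowed scan, which engages above 5,000 probes per segment)
while keeping a full run to a few CPU-minutes.

## Known limitations

* The permutation test's per-split α is not genome-wide corrected (matching
  the reference tool's semantics); expect ~α × (number of segment tests)
  spurious splits per genome, a subset of which exceed the calling threshold.
* The dynamics scaling assumes the pair shares most of its copy-number
  structure; for pairs differing nearly everywhere the fit falls back to
  IQR matching.
* Censored IC50 bounds are propagated, not modelled; no confidence intervals
  are attached to IC50 or RI.
* Cytoband enrichment ignores gene length and probe density biases; it is a
  first-pass ranking, not a calibrated genome-wide test.
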