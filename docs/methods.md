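# Methods

## Scope

`cfhotspot` implements window-based calling of cfDNA fragmentation
hotspots from paired-end WGS fragments, plus the downstream feature
extraction, classification and tissue-of-origin procedures that consume
them. Everything upstream of fragments (trimming, alignment, duplicate
marking) and everything interpretive downstream (chromatin-state
enrichment, motif analysis, tumor-fraction estimation) is out of scope.

## Fragment model and filters

A fragment is the outer template span of a properly-paired read pair
(0-based half-open); soft-clips are ignored. Filters: not
duplicate/secondary/supplementary, max-of-mates MAPQ ≥ 30, autosomes
only (chr1–chr22, either naming dialect), length in [50, 1000] bp
inclusive. Fragment BED input (chrom, start, end[, mapq]) is treated as
pre-paired; a missing mapq column is assumed pre-filtered. BAM/SAM
reading pairs mates by query name in memory, which is adequate for the
scales this package targets; a streaming pairer would be the next step
for full-depth BAMs. Midpoints are `(start + end) // 2` — the floor
breaks even-length ties deterministically toward the left.

## Windows and covariates

Windows of width 200 bp advance in 20-bp steps from position 0 of each
autosome (the phase is a convention; hotspot coordinates can shift by
< step relative to other anchorings). A trailing partial window is not
emitted. Windows are removed when they overlap ≥ 1 bp of the exclusion
list or when mean per-base mappability < 0.9 (missing values count as
0 — conservative removal; a uniform track exactly at threshold is kept,
guarded by a 1e-9 tolerance against cumulative-sum rounding). GC is
computed over non-N bases; the 199 overlapping dinucleotides are
tallied excluding any dimer touching an N; windows with > 10% N are
flagged invalid and excluded from correction and testing.

## The integrated fragmentation score

`IFS_i = n_i (1 + l_i / L)` with `C_i = floor(IFS_i)`; `L` is the mean
fragment length over the window's chromosome, so the size weighting is
relative to the chromosome's own size distribution. Empty windows score
0. Because a midpoint falls in width/step = 10 overlapping windows,
window counts are 10× the fragment count in aggregate; all inference is
within-window, so this sharing only smooths the track.

### GC correction

A loess curve (span 0.75, tricube weights, locally linear, **no
robustness iterations**) of raw IFS on window GC is fitted genome-wide.
`it=0` matters: robustness passes downweight the right-skewed upper
tail of count data and bias the conditional mean low (measured residual
|r| 0.012 with 3 iterations vs 0.0005 without); it is also the default
behaviour of the R `loess` family the procedure is modelled on. Above
200k windows the fit uses a seeded uniform subsample with interpolation
over the fitted curve. Residuals are recentred per chromosome and the
per-chromosome mean raw IFS is added back, so per-chromosome means are
preserved exactly (to rounding). Consequence: between-chromosome IFS
offsets — including any correlated with chromosome-level GC — are
intentionally retained; decorrelation claims are within-chromosome
statements. Fewer than 100 windows: pass-through with a warning;
constant GC: residual against the global mean.

### Dinucleotide correction

Per dimer type d, the genome-wide mean IFS `m_d` is the
dimer-frequency-weighted average of window IFS; a window's expected IFS
is `Σ_d f_d m_d`, and the adjusted score is observed/expected, rescaled
per chromosome by mean(expected)/mean(adjusted) so the corrected track
keeps IFS units (a dimensionless track would floor to zero in the
integer test). The operationalisation of "composition at a location" is
the window's own dimer frequencies.

## Background model and testing

`C_i` is modelled NB with moment estimates `p = μ/ν`,
`n = μ²/(ν − μ)`, requiring ν > μ; ν = μ falls back to the Poisson
limit (logged), ν = 0 is an error. Outliers by the MAD rule
(|x − median|/MAD > 5, MAD without the 1.4826 consistency constant; a
zero MAD falls back to the MAD of nonzero deviations) are excluded from
**both** background estimation and testing. The low-side exclusion is
not incidental: isolated sampling gaps otherwise collect extreme
lower-tail p-values the fitted NB cannot price — the integer score is
approximately a *scaled* NB (C ≈ 2n under typical size ratios), whose
far lower tail is fatter than the moment-matched NB — and measured
null genomes then emit spurious hotspots. With the exclusion the null
is clean (zero false hotspots per 2.2-Mb null genome at desk density
across seeds). The flip side is a detection-depth cap: windows deeper
than ~5 MAD below the median are not testable. At physiological
coverage the cut sits at or below zero counts, so it binds only on
extreme synthetic depletions (see Limitations).

Each tested window gets a lower-tail p-value against (i) the NB fitted
to all non-outlier windows of its chromosome and (ii) the NB fitted to
non-outlier windows whose centres lie within ±25 kb (the window itself
included; config-exposed). Local moments come from running sums over
sorted centres (O(W log W)); spans with fewer than 30 windows defer to
the global test. The larger of the two p-values is kept (a hotspot must
be depleted relative to *both* backgrounds, which guards against focal
copy-number loss), BH-adjusted in one genome-wide family (per-
chromosome BH is config-exposed), and windows at FDR ≤ 0.2 are merged
into hotspots when interval gaps are strictly under 200 bp. A hotspot
reports its union span, centre `floor((start+end)/2)`, member count and
best member FDR.

## Features and models

Per-sample features re-evaluate the IFS over fixed 200-bp regions at
hotspot centres (±100 bp, regardless of merged length), with L from the
sample's own fragments per chromosome; empty regions score 0. Features
are z-scored within each chromosome of each sample using the sample
(n−1) standard deviation (population sd is config-exposed; the
convention is a free choice and documented as such). Classification:
linear SVM, C = 1, no internal re-standardisation, stratified 10-fold
CV repeated 10×, controls downsampled (seeded) to the case count within
training folds, one AUC per fold, CI = mean ± 1.96·sd/√iterations.
`cross_validate_svm` operates on a supplied feature matrix;
`cross_validate_pipeline` is the leakage-proof variant that re-calls
hotspots from pooled training fragments inside every fold and is the
procedure of record (the matrix path exists because per-fold calling is
orders of magnitude slower). Differential hotspots: per-hotspot
two-sample t-test, BH, classes split by sign of (case − control) mean
z-scored IFS at FDR < 0.01 — class I (positive Δz) is *hypo*-fragmented
in cases because hotspots are IFS-depleted regions. Open-chromatin
benchmark: 100-tree random forest on [IFS, 16 dimer frequencies] under
10-fold CV.

Tissue of origin: types below 2×10⁸ pooled training fragments are
excluded as unsaturated; over-represented types are downsampled
(seeded) to the median per-type sample count; centroids are mean
z-scored IFS vectors; candidates are ranked by Spearman correlation
(rank-based, hence invariant to monotone transforms of the sample
vector); the top-2 pair's decision tree (impurity splitting, no depth
cap, seeded) makes the final call, and its output is always taken.

## Synthetic data

The generator reproduces the structure the caller assumes, so its
guarantees are testable: fragment midpoints are drawn from a
gamma-modulated intensity (gamma-distributed rate per 1-kb block, shape
150 by default → window variance/mean ≈ 1.2–1.4 at the coverages used
here, the modest overdispersion of mappability-filtered WGS coverage),
giving NB window counts under the null. Fragment lengths are lognormal,
mean 166 bp, sd 40, truncated to [50, 1000] — the mononucleosomal mode.
Planted regions multiply intensity by a depletion factor and shift
fragment sizes; cohort class effects convert per-hotspot z-shifts to
intensity multipliers via `1 + dz/√μ_r` (μ_r the expected per-sample
region count — the dominant noise scale at low depth). Optional smooth
GC bias acts on block GC; mappability dropout and blacklist intervals
emulate the filtered genome. Sequences are random with a
smoothly-varying GC landscape (reflected random walk in [0.30, 0.60]).

What the simulator does **not** emulate: sequence-specific cleavage
preferences, batch effects, real chromatin structure, copy-number
aberrations, and mapping artefacts correlated with signal. Passing
tests therefore demonstrate statistical correctness of the machinery
under its stated model, not clinical performance on patient data.

The open-chromatin benchmark pairs the −2 sd IFS shift in open regions
with a GC-rich, non-CpG-depleted dinucleotide composition against an
AT-rich CpG-depleted background — the compositional contrast real
promoter-like regions carry. On an IFS-only contrast the Bayes-optimal
AUC would be Φ(2/√2) ≈ 0.92.

Fixture profiles: `tiny` (2 × 1 Mb, 1e5 fragments, 20 regions) is a
smoke fixture; at ~10 midpoints/window a 50% depletion is z ≈ −1.5 and
undetectable, so its planted effect is deep (depletion 0.15 over
600 bp). `desk` (1 × 10 Mb, 2e6 fragments, 200 × 400 bp regions at
depletion 0.5, −15 bp size shift) is the recovery benchmark. Problem
sizes throughout the tests (2.2-Mb null genomes at 0.2 midpoints/bp,
10-Mb desk genome, feature-level cohorts of 60–120 samples) were chosen
as the smallest scales at which the asymptotic statistical claims are
cleanly measurable.

## Known limitations

* **Hotspot-level precision under strong planted signal.** BH controls
  the *window*-level FDR; measured window FDP on the desk benchmark is
  ~0.15–0.16, inside the 0.2 budget. But ~1,500 true significant
  windows merge into ~170 hotspots while false windows stay near-
  singletons, so hotspot-level precision sits near 0.55–0.65 — and
  *increasing* power makes it worse, since false discoveries scale with
  total discoveries. The method's guarantee is per-window; hotspot-level
  precision is not controlled and should not be read as such.
* **Detection-depth cap.** The MAD exclusion makes depletions deeper
  than ~5 MAD below the median untestable; on the desk benchmark this
  caps recall near 0.85 at 50% depletion. Real hotspots (10–30%
  depletion at pooled depth) sit well inside the testable band.
* **Shallow-coverage calibration.** Below roughly the 2×10⁸-fragment
  saturation floor, the scaled-NB tail mismatch inflates false calls
  (the tiny fixture shows this deliberately); pooling to saturation is
  part of the method, not an optimisation.
* The in-memory BAM pairer and bedGraph-to-array mappability reader are
  sized for the package's simulation-scale inputs, not full-depth human
  genomes; pyBigWig/streaming equivalents would slot behind the same
  interfaces.
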