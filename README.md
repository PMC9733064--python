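# cfhotspot

De novo identification of **cell-free DNA fragmentation hotspots** from
paired-end WGS fragment data, with the downstream analyses that make them
useful for liquid biopsy: cancer-vs-control classification, differential
hotspot analysis, open-chromatin prediction and tissue-of-origin
assignment.

Plasma cfDNA is released mainly by dying cells and is preferentially cut in
nucleosome-depleted, accessible chromatin. Fragmentation hotspots are the
fine-scale (~200 bp) regions where both fragment coverage drops and
fragments run short — a joint signal that single-dimension peak callers
miss. This package is aimed at cfDNA fragmentomics researchers who want a
transparent, testable implementation of window-based hotspot calling and
its statistical guarantees, runnable end to end on synthetic data.

## The model

Each autosome is scanned with 200-bp windows advanced in 20-bp steps.
For window *i*, with `n_i` fragments assigned by midpoint, `l_i` their mean
length, and `L` the chromosome-wide mean fragment length:

    IFS_i = n_i · (1 + l_i / L)        C_i = ⌊IFS_i⌋

The integrated fragmentation score weights coverage by relative fragment
size, so hotspots (more, shorter fragments) are *depleted* in IFS. The
integer background `C_i` is modelled as negative binomial — a gamma-mixed
Poisson that absorbs slow coverage-rate variation — with method-of-moments
parameters from the sample mean μ and variance ν:

    p = μ/ν        n = μ²/ν · 1/(1−p)

Every non-outlier window (MAD rule, |x−median|/MAD ≤ 5) is tested
lower-tail (`P(X ≤ C_i)`) against both a local 50-kb background and the
whole-chromosome background; the **larger** p-value is kept, BH-corrected
genome-wide, and windows at FDR ≤ 0.2 are merged into hotspots when closer
than 200 bp. Optional corrections regress out GC (loess, span 0.75, with
the per-chromosome mean added back) and dinucleotide composition.

Downstream, per-sample IFS at hotspot centres (±100 bp) is z-scored per
chromosome and fed to a linear SVM under 10×10-fold stratified CV (controls
downsampled to case count per training fold), with AUC CIs via
SE = sd/√iterations. Tissue of origin uses per-type centroids, Spearman
ranking, and pairwise decision trees on the top-2 candidates.

## Worked example

`examples/` holds one short script per capability. `01_call_hotspots.py`
builds a 2 × 1 Mb synthetic genome with 20 planted low-fragmentation
regions and 100k fragments, and runs the full caller:

```
fragments retained : 100000
windows tested     : 97509
hotspots called    : 117
planted regions    : 20  recall 1.00  precision 0.17
```

All 20 planted regions are recovered; the many extra calls are what shallow
coverage (~1000× below the ~2×10⁸-fragment saturation floor the method
expects) does to a count model — the deep-coverage experiments in
`scripts/acceptance.py` show the calibrated behaviour (zero false hotspots
per null genome at desk density). `02_bias_correction.py` plants a strong
GC bias and removes it:

```
corr(IFS, GC) before    : +0.837
corr(IFS, GC) after     : -0.002
mean IFS before / after : 80.00 / 80.00
```

`03_classify_cohort.py` (30 vs 30 cohort, 100/500 hotspots shifted 1.5 sd)
reports `mean AUC 1.000, sensitivity 1.00 at 100% specificity` and
recovers all 100 planted class-I hotspots; `04_tissue_of_origin.py` gets
mean top-1 accuracy 0.90 and top-2 accuracy 1.00 on three synthetic cancer
types.

A thin CLI mirrors the library (`cfhotspot simulate | fragments | ifs |
callhotspots | run`); `cfhotspot run --config run.yaml` executes the whole
chain with manifests and stage skipping.

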