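# Methods

This note documents the models and procedures implemented in `gutreads`,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not emulate.

## Read-mapping detection pipeline

The pipeline turns raw local-alignment hits of unassembled shotgun reads
against annotated reference mitogenomes into per-sample prey detections.

**Mismatch reanalysis.** BLAST counts identity as exact character matches,
so a read base aligned to a degenerate IUPAC reference code (R, Y, S, W, K,
M, B, D, H, V, N) is reported as a mismatch even when the code's expansion
contains that base. Each alignment column is reclassified: a mismatch is
*false* iff the two symbols' expansions intersect (this covers
degenerate-vs-degenerate columns too), and the corrected identity is
`100·(L − gap_columns − true_mismatches)/L`. Corrected identity can never
fall below the reported one, and equals 100 exactly when there are no true
mismatches and no gaps — consequently any gapped alignment fails the default
threshold. Requiring the aligned-string columns is why the parser rejects
12-column `outfmt 6`: the reanalysis is impossible from summary columns.

**Thresholds and their defaults.**

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 100 % | corrected identity floor |
| `min_overlap` | 130 bp | alignment-length floor |
| `min_reads_per_species` | 2 | singleton elimination |
| `coding_overlap_fraction` | 0.5 | fraction of alignment columns inside coding features |
| `coding_kinds` | CDS, rRNA, tRNA | features counted as coding |
| `predator_species` | none | reported separately, excluded from prey |

The 100 %/130 bp operating point trades sensitivity for specificity in
mixtures where a related species' DNA vastly outnumbers the target's.
Singleton elimination is implemented per species within a sample: a species
detection requires at least two supporting reads. The coding filter is
strand-agnostic (a minus-strand hit over a plus-strand CDS counts): read
orientation is random with respect to gene orientation. When a reference has
no annotation the hit fails the filter by default (`missing_annotation=
"pass"` reverses this with the caveat that unannotated references then skip
the filter entirely).

**Best-hit resolution.** Hits passing the threshold are ranked by corrected
identity, then overlap, then bitscore. If the best rank is shared by hits to
more than one species the read is discarded as ambiguous (conservative: a
tie carries no species information). Several passing hits to the same
species count as one read. Thresholding before or after ranking yields the
same assignment because the rank keys are exactly the thresholded
quantities; a property test asserts this on randomized hit sets.

**Audit.** Every read's fate is logged (`counted`, `unassigned`,
`ambiguous`, `non_coding`, `singleton`), so a detection table can always be
traced back to reads.

## Melt-curve analysis

The derivative −dF/dT is estimated at each grid point as the negative slope
of a least-squares quadratic over the nearest 5 points (one-sided at the
ends). The 5-point window suits the standard 60–95 °C scan at 6 readings/°C
(211 points); it attenuates a sharp peak by a few percent, which is
irrelevant to calling since the thresholds sit far below real peak heights.
Background is the **median** of −dF/dT over the scan — robust while a melt
transition occupies a minority of the grid. Peaks are local maxima above
background with prominence ≥ 0.02 (floor suppresses point noise); each
peak's Tm is refined as the vertex of a parabola fitted over ±4 grid points
around the maximum, which keeps Tm error well under 0.2 °C at fluorescence
noise up to 0.01.

**Calls.** With a positive control of known Tm, a sample is positive iff
≥ 2 technical replicates have a peak more than 0.1 above background, or one
replicate more than 0.2 above background, within ± 0.5 °C of the control Tm.
Evidence is the height of an *extracted local peak* inside the window — not
the raw maximum of −dF/dT there, which would see the flank of a neighbouring
product melting at the wrong temperature and misclassify it. The 0.5 °C
tolerance is chosen because a product ~1.4 °C away must count as a different
amplicon; it is configurable. The 0.1/0.2 thresholds are values on the
instrument's fluorescence scale; inputs are expected as raw cycler exports.
Without a control, ≥ 3 replicates must share a single dominant peak (within
the tolerance of their common median, each above the 0.1 margin) with every
secondary peak under half the dominant height — multiple comparable peaks
indicate heterogeneous amplicons, dimers, or chimeras. Fewer than three
replicates give an *indeterminate* call. An NTC-derived baseline mode was
considered and not implemented; the median baseline serves the same purpose
without requiring extra wells.

## qPCR quantification

**Model.** Observed fluorescence saturates as reagents deplete; to first
order F = x/(1 + x/P) for exponential signal x = N0·E^c and plateau P. The
fitter inverts this (x = F·P/(P − F), with P estimated as the mean of the
terminal three cycles — the raw maximum is biased upward by noise extremes
and the transform is very sensitive to P near the top). Desaturation can be
disabled to fit raw fluorescence.

**Efficiency.** The exponential phase is operationalized as fluorescence
between baseline + 5·noise_sd (both from the first five cycles) and 0.85·P
on the desaturated curve (0.5·P raw). Among contiguous 4–6-cycle windows the
fitter takes the one with the largest Fisher information for the log-slope
(point weights (F(P−F))², the correct weighting for additive fluorescence
noise) and estimates the slope by weighted least squares; E = 10^slope,
report-clipped to (1, 2]. Selecting the window on r² instead is fragile:
short noise-dominated windows win by chance alignment. The unweighted window
r² is still reported, and r² < 0.99 sets a `low_quality` flag.

**Cq and N0.** Cq interpolates the threshold crossing linearly in log signal
between the bracketing cycles (on the desaturated curve, with the threshold
transformed consistently); N0 = Fq/E^Cq. A curve that never reaches the
threshold yields an "undetected" fit rather than an error. The threshold is
a required user input — results are relative quantities, comparable within
an assay at a fixed threshold.

**Precision.** The relative N0 error propagates as ≈ Cq·δE/E plus the
relative fluorescence noise at the threshold. With a ~6-point exponential
window this is a hard information limit: at noise 0.5 % of plateau, Monte
Carlo over seeds puts |δE| ≤ 0.02 in ~85 % of curves (≤ 0.05 in ~100 %), and
N0 cannot be pinned to 10 %. At 0.1 % of plateau — routine for a modern
cycler in the exponential region — E is recovered within 0.02 and N0 within
10 % on every tested seed. The recovery tests state both operating points
explicitly.

**Limit of detection.** Each replicate dilution series (Cq vs log₁₀ mass) is
fitted by least squares; the slope must be negative (more template, earlier
Cq). The mass at Cq = 40 is extrapolated per replicate; the estimate is the
geometric mean with its upper 95 % confidence bound computed on the log
scale with the t distribution — replicate counts are small, so a normal
quantile would understate the bound (with two replicates, t₀.₉₇₅,₁ = 12.71
dominates: extrapolations of 0.01 and 0.04 pg give a geometric mean of
0.02 pg but an upper bound near 134 pg).

## In-silico PCR

Primer scanning is an ungapped sliding comparison on both strands: a site
requires ≤ `max_mismatches` mismatching positions (default 2) and exact
matches over the last `anchored_3prime` bases (default 2) — polymerase
extension is launched from the 3′ end, so terminal mismatches are
disqualifying regardless of the total. Degenerate codes on either side match
iff their expansions intersect; this rule is applied to the anchor as well.
Amplicons pair a forward site with an opposite-strand reverse site in proper
orientation, emit the spanned template sequence (primers included), and
filter by length bounds. Indel-tolerant binding and thermodynamic (Tm/ΔG)
models are out of scope.

## Evaluation

Detections are classified against independent melt-curve verification: TP =
detected and verified; FP = detected, not verified; TN = neither; FN = not
detected but verified — except that a verified species absent from the
method's reference database is *excluded* rather than counted as FN (the
method never had a chance), as are species never tested by melt-curve
analysis. The five metrics follow the standard formulas; any metric with a
zero denominator is reported as missing (never 0) and excluded from
cross-sample means.

The statistical layer implements the comparisons used around such data:
Welch's t with Welch–Satterthwaite df, the paired t, logistic regression of
verification outcome on ln read count (statsmodels GLM/IRLS behind the
module surface; the Wald χ² of the single slope equals the type-II
statistic), and Pearson correlation with a Fisher-transform z-test. All
p-values are two-sided. Tests validate each statistic against an independent
route (direct formula evaluation, scipy, or a grid-search likelihood
maximizer for the logistic slope).

## Synthetic data: what it emulates, what it does not

The generators produce every input format with known truth, deterministic
per seed. Reference "mitogenomes" are i.i.d. random sequences (pairwise
identity ~25 %) tiled with coding blocks covering ~90 % of their length —
they have realistic size and annotation density but no gene grammar, codon
structure, or between-species homology. Consequently cross-species alignment
is effectively impossible at the default thresholds, so passing the
end-to-end equivalence test demonstrates the pipeline's bookkeeping and
filter logic, not its discrimination among closely related real taxa.

Gut communities are multinomial mixtures (predator ≥ 0.9 by default) with
fragment lengths from a lognormal (median ≈ 90 bp, log-sd 0.45) truncated to
30–150 bp — digestion modeled purely as length attenuation, reads single-end,
no base-quality profile, substitution errors optional (default 0), no
cytosine-deamination damage patterns. Melt curves are sums of logistic
dissociation transitions (peak height A/(4s)) over a linear drift with
Gaussian noise; amplification curves are the saturating exponential above.

`oracle_align` performs full local alignment (match +1, mismatch −1, gap −2,
via Biopython's pairwise aligner) of every read against both strands of
every reference — the correctness oracle for the pipeline at desk scale.
For error-free reads the exact source-locus hit is also constructible
directly from the truth table (`hits_from_truth`); a test asserts the two
routes produce identical rows, which licenses using the fast route for
large runs.

**Problem sizes.** The end-to-end oracle-equivalence check runs at 6 species
× 4-kb genomes × 400 reads (the full aligner is quadratic per pair); the
quantitative-signal check uses 60 000 reads with seven prey spanning 1.5
orders of magnitude in abundance (0.045 → 0.0014) via the exact-truth hit
route. Both finish in seconds to tens of seconds on one CPU.

## Known limitations

- The pipeline consumes alignment hits; it does not run BLASTn, and results
  inherit whatever sensitivity the upstream aligner had.
- Reference-database completeness is decisive and outside the package's
  control; the evaluation layer's database-coverage exemption handles it
  only at the bookkeeping level.
- Relative N0 is comparable within an assay (fixed threshold, primer pair,
  plate); no absolute copy-number calibration, inter-plate normalization, or
  PCR-inhibition modeling is attempted.
- Melt-call thresholds (0.1/0.2) are instrument-scale constants; data from a
  differently scaled instrument must be normalized by the caller.
- The no-control melt rule cannot distinguish a reproducible wrong product
  from a true one — it verifies amplicon homogeneity and consistency, not
  identity.
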