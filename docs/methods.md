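# Methods

## Depth model and bin-size selection

Read starts are counted in non-overlapping bins of a fixed size `b`
(0-based half-open; a read belongs to `floor(start/b)`).  With `n` uniquely
mapping reads on a mappable genome of `g` bases, a diploid bin receives
`λ = n·b/g` reads in expectation.  Observed bin counts are overdispersed,
so copy-number class `c ∈ {1,2,3}` is modelled as negative binomial with
mean `μ_c = c·λ/2` and size `r_c = μ_c/(d−1)` (variance `d·μ_c`), where `d`
is the variance-to-mean ratio (VMR).  `d = 1` is treated as the Poisson
limit.  The default `d = 3` reflects what Illumina whole-genome data
typically show; the parameter is exposed everywhere because library
protocols differ, and automatic estimation of `d` from data is deliberately
out of scope.

**Thresholds.** Bins are classified by two integer cuts: `count < t_loss`
is a loss, `count > t_gain` a gain, anything else neutral (boundary counts
go to the lower class).  The cuts minimise the total misclassified
probability mass

```
P₁(X ≥ t_loss) + P₂(X < t_loss) + P₂(X > t_gain) + P₃(X ≤ t_gain)
```

and that minimised mass is reported as the model FDR.  The two terms are
separable, so each cut is optimised independently with exact CDFs (no
truncation error; the support bound `1−10⁻⁹` quantile only limits the
search range).  Ties are broken toward the pair whose midpoint is closest
to `λ`, then the smaller pair.  Exact probability mass replaces the random
sampling historically used for this computation; a seeded sampling mode is
retained in the test suite to confirm the two agree within Monte-Carlo
error.  Note the FDR is a *sum over the three class distributions* — the
expected miscalled fraction contributed by each boundary — not the average;
this convention reproduces the published worked example (next paragraph).

**Bin-size search.** The achieved FDR is non-increasing in `b` (more reads
per bin separate the classes).  The search grid is every multiple of 100 bp
from 100 bp to min(10 Mbp, genome size); the smallest admissible size is
found by geometric expansion from below followed by bisection, which avoids
evaluating the model at very large `λ`.  For 47×10⁶ reads at 0.85×
coverage of 55 bp reads (`g ≈ 3.04` Gbp), VMR 3 and FDR 0.01 the selection
returns 26.0 kbp with λ ≈ 402 and thresholds (293, 496).

## Corrections

Order is fixed: mapability first, then GC (the GC curve is fitted on
mapability-corrected depth).

**Mapability.** Counts are divided by the bin's fraction of uniquely
mappable positions; bins below the floor `min_map = 0.25` are masked rather
than rescaled, preventing explosive overcorrection.  Masked bins carry no
weight anywhere downstream.

**GC bias.** Unmasked bins are grouped by GC fraction in increments of
0.001 (0.1%); the per-group mean depth, weighted by group occupancy, is
smoothed by a locally weighted quadratic regression (tricube kernel,
span 0.3, no robustness iterations — the smoother agrees with R's
`loess(..., degree = 2, family = "gaussian")` to ~5×10⁻⁵ on test data).
Each bin then receives the additive correction
`median(depth) − fitted(gc)`, corrected depths are floored at zero, and all
unmasked depths are rescaled multiplicatively so their sum is exactly the
pre-correction sum — the correction is neutral with respect to the total
read count (conserved to 1e-9 relative, asserted in tests).  With fewer
than 10 occupied GC groups or fewer than 200 unmasked bins the correction
is the identity, with a warning.  The 0.1% increment is configurable.

**Effective GC for bisulfite libraries.** Bisulfite treatment converts
unmethylated cytosines to uracil (read as thymine); methylated cytosines
are protected.  Each cytosine therefore contributes its methylation
fraction `m ∈ [0,1]` to the bin's G+C tally; guanines contribute fully
(read-strand tally); cytosines absent from the per-cytosine methylation
map contribute the genome-wide mean fraction.  Effective GC is the
adjusted G+C count over mappable (non-N) bases, and is monotone
non-decreasing in every per-cytosine fraction.  A fully methylated map
reduces exactly to standard GC, so a bisulfite run on fully protected DNA
reproduces the plain pipeline bin for bin (asserted end-to-end).  When a
reference FASTA is supplied, GC is computed over non-N bases; bins with no
mappable bases are masked.

## Segmentation and calling

Masked bins are removed, depths are transformed to
`log2(depth/median)` (zeros replaced by half the minimum positive depth),
and the compacted vector is segmented by recursive circular binary
segmentation: the arc `(i, j]` maximising the circular two-sample
t-statistic (arc mean vs rest, pooled segment SD, factor
`sqrt(m/(k(m−k)))`) is accepted as a split when its permutation p-value —
unbiased form `(exceedances+1)/(n_perm+1)` — falls below `alpha = 0.01`
with `n_perm = 1000`.  Both the arc and its complement must contain at
least `min_width` bins; `min_width` defaults to 2 when λ < 100 (sensitivity
at low coverage) and 4 otherwise (false-positive control at high coverage),
and is overridable.

The permutation test is *decision-exact* but pruned for speed: per
permutation, small and near-full arc lengths are scanned exactly, and the
range of the centred cumulative sums bounds the statistic of every
remaining arc; only permutations whose bound reaches the observed statistic
are rescanned exhaustively (with a numba kernel when available).  Early
stopping rejects a split as soon as the exceedance count makes `p < alpha`
impossible.  Both shortcuts provably reproduce the brute-force decision,
which is verified against a naive full-permutation oracle in the tests.

Breakpoint indices are re-expanded to original coordinates; a segment may
span a masked gap, and gap bases stay with the left segment, so segments
tile the unmasked extent.  Absolute copy number is
`2 · mean_depth / anchor` with the genome-wide median unmasked depth as the
diploid anchor (the modelled λ is the fallback when more than half the
genome is altered); gain/loss calls compare segment means against the
model's per-bin thresholds, which is conservative because segment means are
much tighter than single bins.

## Boundary refinement

Depth boundaries are quantised to the bin grid; junction coordinates from
discordant read pairs are not.  For every boundary touching a called
segment, if *exactly one* supplied breakpoint lies strictly within
`bin_size/2` of it, the boundary (both adjacent segments) moves to that
breakpoint; zero or several candidates leave it unchanged, as does a move
that would empty a segment.  Ties at exactly half a bin do not refine.
Refinement is idempotent and preserves the segment tiling.  Support counts
are carried but not thresholded.  Neutral–neutral junctions are not
refined.

## Simulation harness

`simulate_counts` draws per-bin counts from the model (CN 2 outside, the
seeded copy number inside the alteration) at the bin size the model selects
for the trial's coverage; mapability is 1 and GC flat unless biases are
injected.  Working at bin level is the minimal faithful form of the
validation protocol, which is defined on read counts per region; an
optional read-start emitter exercises the BED/binning path end to end.
Alteration edges snap to bin boundaries by default; in off-grid mode edge
bins are assigned by majority overlap, so the discretisation error is below
half a bin and recoverable by refinement.  A trial is *detected* when both
edges of some gain/loss call are within one bin size of the seeded truth;
any call failing that both-ends test is a false positive, and specificity
is one minus the fraction of trials with at least one false positive.
Per-trial seeds derive deterministically from the master seed.

The default trial chromosome is 247 Mbp (a large human chromosome).  The
acceptance-level end-to-end checks run on a 15 Mbp chromosome instead:
with 1000 permutations per split test, the full-size simulation is not a
desk-scale computation, and the sensitivity/specificity of a 2 Mbp event
at 5× coverage is unaffected by the surrounding chromosome length.  What a
green end-to-end test establishes is calibration and recovery *under the
generator's assumptions* (independent negative-binomial bins, flat biases,
single event); it does not establish robustness to correlated noise, wavy
GC residuals or replication-timing effects, which real genomes show.

## Parallelism and determinism

Binning, correction and segmentation are chromosome-level work units;
permutation seeds are derived per chromosome from the master seed
(CRC32 of the chromosome name), and results are merged in sorted
chromosome order, so output is byte-identical for any worker count.  Every
run writes `params.txt` and a `provenance.json` with all parameters, seeds
and SHA-256 digests of the inputs.

## Numerical choices and edge cases

- Exact `sf`/`cdf` tails everywhere in the model; no truncation error.
- At very large λ the misclassification mass underflows to an exactly flat
  minimum; the midpoint tie-break keeps threshold selection deterministic.
- Constant (zero-variance) segments never split; all-masked chromosomes
  yield no segments; a zero diploid anchor is an error.
- Track values outside [0,1], methylated counts exceeding totals,
  duplicate methylation positions, overlapping output segments and reads
  beyond the declared chromosome length are hard errors; reads on
  undeclared chromosomes are skipped with a warning.

## Known limitations

- VMR is an input, not estimated from the data.
- Threshold optimisation covers CN 1/2/3 only; higher amplifications are
  still reported via the continuous copy-number estimate but the FDR
  guarantee concerns the three-class decision.
- GC correction is per chromosome when run through the pipeline; very
  short chromosomes fall back to the identity correction.
- The caller assumes a largely diploid genome for the median anchor;
  heavily rearranged genomes should rely on the modelled-λ fallback.
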