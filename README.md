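# depthcnv

Detection of copy-number alterations (CNAs) from the depth of coverage of
uniquely mapping short sequencing reads — without a matched normal sample.

## Who this is for

Whole-genome (and whole-genome bisulfite) sequencing experiments at
anywhere from ~0.5× to deep coverage, where the number of reads landing in
a genomic window is proportional to the underlying copy number.  depthcnv
tiles the genome with fixed-size bins, counts read starts per bin, corrects
the counts for mapability and GC bias, segments the resulting depth profile
and reports absolute copy numbers with gain/loss calls.  Segment boundaries
can optionally be sharpened with breakpoint coordinates from paired-end
sequencing.

## The model

Given `n` uniquely mapping reads on a (mappable) genome of size `g` and a
bin size `b`, the expected reads per diploid bin is

```
λ = n·b / g
```

Illumina bin counts are overdispersed relative to Poisson, so the count in
a bin of copy number `c ∈ {1, 2, 3}` is modelled as negative binomial with
mean `μ_c = c·λ/2` and size parameter `μ_c/(d − 1)`, where `d` is the
variance-to-mean ratio (VMR; `d = 1` recovers Poisson, `d = 3` fits
Illumina data well).  Integer count thresholds `t_loss < t_gain` are chosen
to minimise the total probability mass misclassified among the three
copy-number classes; that misclassified mass is the model's false-discovery
rate (FDR).  Because the classes separate as bins grow, depthcnv selects
the **smallest bin size whose FDR meets the user's target** — resolution is
traded for reliability automatically.

Corrected depths are segmented with circular binary segmentation (CBS,
permutation-tested arc t-statistics on `log2(depth/median)`), segments are
converted to absolute copy number against the genome-wide median depth, and
gains/losses are flagged with the model thresholds.

## Worked example

The published low-coverage breast-cancer configuration: 47 million uniquely
mapping 55 bp reads representing 0.85-fold coverage (implying a ~3.04 Gbp
genome), VMR 3, FDR target 0.01:

```
$ depthcnv model --n-reads 47e6 --genome-size 3.041e9 --vmr 3 --fdr 0.01
n_reads=47000000
genome_size=3041000000.0
bin_size=26000
lam=401.84149950674123
vmr=3.0
fdr_target=0.01
t_loss=293
t_gain=496
fdr_achieved=0.009991038731706627
```

Reading: bins of 26 kbp give ≈402 expected reads per diploid bin; a bin
with fewer than 293 reads is a candidate loss, more than 496 a candidate
gain, and the expected fraction of miscalled bins is just under the 0.01
target.  A full run on aligned reads:

```
$ depthcnv run --reads reads.bed --genome genome.txt \
    --mapability map.bedGraph --fasta ref.fa --outdir out/
```

writes `out/segments.seg` (chrom, start, end, n_bins, mean_depth,
copy_number, call; 0-based half-open), `out/params.txt` and a provenance
record.  `depthcnv simulate` reproduces the sensitivity/specificity
validation harness on seeded alterations, and `depthcnv refine` applies
breakpoint-based boundary refinement to an existing SEG file.

## Acceptance script

`scripts/acceptance.py` recomputes the model's headline number from
scratch — the smallest admissible bin size for the configuration above —
by running the bin-size selection and writing the result as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the statistical model, correction procedures,
segmentation details, simulation design and known limitations.
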