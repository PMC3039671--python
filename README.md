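# broadcall

Broad-region peak calling for spreading histone marks, with the downstream
analytics used to compare two marks genome-wide.

Classical ChIP-seq peak callers were built for site-specific transcription
factors, which produce narrow, punctate peaks. Spreading histone
modifications — H3K9me3 over heterochromatic and zinc-finger-gene domains,
H3K36me3 over transcribed gene bodies — instead cover kilobases to
megabases with jagged "mountain range" profiles that a narrow-peak caller
shatters into fragments or misses outright. `broadcall` implements a
calling strategy designed for such marks, together with the region
analytics needed to characterize loci carrying two marks at once (e.g. the
3′ exons of KRAB zinc-finger genes, marked by both H3K9me3 and H3K36me3),
and a synthetic-experiment generator so every stage is testable without
external data.

It is a library first (importable from Python, with narrative scripts under
`examples/`), plus a thin `broadcall` command-line wrapper.

## The method

Calling proceeds in three stages, all driven by the input
(non-immunoprecipitated) channel:

1. **Single-copy normalization.** The smoothed input coverage is compared
   with its genome-wide baseline μ (trimmed mean of nonzero bins).
   Runs of bins with fold ≥ 1.5 (or ≤ 0.5) spanning ≥ 2 kb become
   duplication (deletion) segments with copy number
   `round(2·depth/μ)/2`; windows significant under a one-sample
   t-statistic against μ (Bonferroni-corrected) whose fold exceeds any
   plausible copy number (> 5×) are flagged as over-sequenced protocol
   artifacts. ChIP bins inside copy-number segments are divided by the
   copy number; over-sequenced bins are masked to the ChIP median. The
   result approximates a single-copy, bias-free genome.
2. **Smoothing (broad mode).** A centered sliding average (default 9 bins
   of 200 bp) flattens within-domain valleys so an entire jagged domain
   clears one height cutoff as a single region.
3. **FDR-calibrated height cutoff.** Input tags are resampled into
   megabase-scale bins and shuffled uniformly within each bin — preserving
   large-scale sequencing bias, destroying local structure. For rising
   candidate heights *h*, the number of ChIP regions ≥ *h* is compared
   with the counts from *B* shuffled backgrounds (default 10):

   FDR(h) = (1 + Σ background regions) / (B × ChIP regions)

   The cutoff is the smallest *h* (scanned above the background's
   fragmentation peak) with FDR(h) ≤ the user's target. Regions are
   maximal above-cutoff runs, merged across gaps ≤ 1 kb (broad) and
   filtered by a minimum length.

Downstream, the package computes two-set region overlap (Venn counts),
tags-per-kb densities, PWM motif densities on both strands,
promoter/intragenic/intergenic classification, nearest-gene assignment,
per-peak repeat fractions with decile histograms, coverage percent per
zinc-finger-domain class, mean summit heights, and the coverage fold
statistic; and it classifies allele-specific expression with the strict
rule that an allele is *fixed* only when it exceeds 90% of all reads at a
position.

## Worked example

```bash
python examples/01_call_broad_domains.py
```

```
simulated 200,000 ChIP and 200,000 input tags
height cutoff 12.25 (empirical FDR 0.0100)
called 20 regions covering 641,000 bp
recovered 100% of planted domains (mean Jaccard 0.958)
```

Twenty jagged 10–50 kb domains at 8-fold enrichment were planted on a
2 × 5 Mb genome. Broad-mode calling at FDR 0.01 calibrated a height cutoff
of 12.25 (the first height where shuffled input backgrounds yield ≤ 1% as
many regions as the ChIP track) and returned exactly one region per planted
domain; a mean Jaccard of 0.958 means boundaries are accurate to about a
kilobase. The other examples demonstrate copy-number normalization
(`02`), dual-mark overlap analytics (`03`), promoter-motif densities
(`04`), allele fixation (`05`) and the finger-domain association trend
(`06`).

The same pipeline is available from the shell:

```bash
broadcall simulate --preset broad-domains --seed 1 --outdir sim/
broadcall call --chip sim/chip.bed --input sim/input.bed \
    --mode broad --fdr 0.01 --seed 1 --out peaks.bed --json-report report.json
```

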