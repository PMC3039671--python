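# Methods

## Model and assumptions

`broadcall` treats a ChIP-seq experiment as two tag sets over a shared
genome: a ChIP channel whose local tag density reflects occupancy of the
immunoprecipitated mark, and an input channel that sees everything the
ChIP channel sees *except* enrichment — copy-number structure, mappability
and protocol biases, and Poisson-like sampling noise. Three assumptions
follow:

- **Multiplicative bias.** A region at copy number *c* contributes *c*
  times the tags in both channels, so dividing ChIP depth by the
  input-estimated copy number restores a single-copy genome. (Whether the
  underlying tool subtracted input or divided by it is not documented; we
  divide and state it.)
- **Scale separation.** Sequencing bias varies on the megabase scale;
  enrichment structure on the 0.1–100 kb scale. The shuffle background
  (below) preserves the former and destroys the latter, which is what
  makes the empirical FDR meaningful.
- **Broad marks are contiguous but jagged.** Enrichment domains of
  spreading marks fluctuate internally ("mountain ranges"); a sliding
  average converts them into single above-cutoff runs without inventing
  enrichment where none exists (the smoother is a contraction: output
  extremes never exceed input extremes).

All coordinates are 0-based half-open; tag 5′ positions are BED start for
+ reads and end−1 for − reads; fragments are extended 350 bp (midpoint of
a typical 300–500 bp sonication size range) in the strand direction; bin
values are mean per-bp fragment depth, so changing the bin size rescales
nothing.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `extension` | 350 | bp | sonication fragment midpoint |
| `bin_size` | 50 narrow / 200 broad | bp | resolution vs noise per bin |
| `smoothing_window` | 1 narrow / 9 broad | bins | ~1.8 kb: spans within-domain valleys, ≪ domain size |
| `merge_gap` | 100 narrow / 1000 broad | bp | bridges sub-cutoff gaps inside domains |
| `min_region_len` | 100 narrow / 400 broad | bp | discards single-bin noise runs |
| `trim` (baseline) | 0.01 | fraction/tail | robust to isolated spikes; raise it when CNV segments occupy a large genome fraction |
| `dup_fold` / `del_fold` | 1.5 / 0.5 | fold vs baseline | CN=2 detectable, CN=1 robust at depth ≥ 10 |
| `cn_min_len` | 2000 | bp | CNV events are long; kills bin-level noise |
| `max_copy_fold` | 5 | fold | beyond any plausible copy number ⇒ protocol artifact |
| `n_background_draws` | 10 | draws | sets the empirical-FDR floor (below) |
| `background_bin_width` | 1e6 | bp | shuffle bins: preserve megabase bias only |
| allele `threshold` | 0.9 | fraction | strict: exactly 90% is heterogeneous |

Copy numbers of duplications are quantized to halves (1.5, 2, 2.5, …)
because fractional estimates at sequencing depth are noisy; deletions keep
their continuous fold, clamped to (0, `del_fold`]. Same-class CNV runs
separated by less than `cn_min_len` are bridged before length filtering so
sampling dips cannot leave the interior of one event unnormalized.
Over-sequenced windows are *masked* to the ChIP median rather than
divided: a protocol artifact has no meaningful copy number.

## The empirical FDR and its floor

At candidate height *h* (stepped by the track's depth quantum: 1 for raw
tracks, the smallest positive value difference floored at 0.25 for
smoothed ones), the calibration compares the ChIP region count with counts
from `n_background_draws` within-bin shuffles of the input, depth-scaled
to the ChIP track:

    FDR(h) = (1 + total background regions) / (draws × ChIP regions)

Two deliberate choices:

- **Add-one correction.** With finitely many draws, a background count of
  zero bounds the noise rate, it does not measure it. The plain ratio
  lets a single ChIP region that happens to top all background maxima
  pass any FDR (probability ≈ 1/(draws+1) under the null — we measured
  32% of null runs calling a region with 3 draws). The corrected
  estimator with 10 draws brought this to 0/50 null runs while leaving
  strong-signal recovery untouched. The corollary is an FDR floor of
  `1/(draws × ChIP regions)`: an experiment with 2 true regions cannot be
  certified at FDR 0.01 by 10 shuffles, and the calibration says so
  rather than inventing a cutoff.
- **Scan regime.** Below the background's own count maximum, raising the
  cutoff merely fragments one genome-wide "region" into pieces; counts
  there carry no false-discovery meaning (and made the naive scan accept
  absurdly low cutoffs). Candidates are scanned from the background count
  peak upward, and the scan aborts once backgrounds are exhausted with
  the target still unreachable — past that point the ratio could only
  fall through ChIP summit fragmentation, which is not evidence.

## What the simulator emulates — and what it does not

`simdata` places tags by a single multinomial draw over base pairs with
weight background × copy number × hotspot inflation × enrichment
(enrichment in the ChIP channel only), so totals are exact and
conservation checks are trivial. Jagged domains alternate 1.5× / 0.5×
sub-blocks of the stated fold on a 1 kb period. Planted allele-count sites
realize their drawn allele fraction exactly (rounded) so planted classes
are unambiguous at depth ≥ 20. The default desk-scale genome is
2 × 5 Mb with 0.02 tags/bp (≈ 7× fragment depth) — large enough for
megabase shuffle bins, small enough that a full call runs in seconds.

Not modeled: read sequences and mapping error, PCR duplicates,
mappability holes, paired ends, chromatin accessibility bias correlated
between channels, and inter-replicate variability. Passing tests on this
generator therefore demonstrate the *algorithmic* properties (recovery,
FDR control, normalization, mode contrast) under the stated noise model,
not performance on any particular real library.

## Numerical and degenerate-input choices

- Sliding-average edges use a shrinking window (mean over available
  bins): constant tracks stay constant; area is not exactly conserved at
  chromosome ends.
- Region statistics (max, area, mean) are computed over the merged span,
  gap bins included; region ends are clipped to the chromosome extent.
- Venn "both" counts merged overlap events; per-set "participating
  region" counts are reported alongside, since either accounting is
  defensible.
- Nearest-gene ties break by gap to the TSS, then lexicographic gene id —
  deterministic across runs.
- Motif scanning windows containing N are skipped; thresholds default to
  80% of each PWM's maximal log-odds score. This is a per-window score
  rule, not an E-value model: results are reproducible from the matrix
  alone, at the cost of not matching any particular E-value cutoff.
- Repeat fractions merge (union) repeat intervals before intersecting, so
  fragmented or overlapping repeat annotations cannot push a peak past
  100%.
- Empty classes in the finger-domain association are absent from the
  result, never reported as 0%.
- The allele-fixation denominator is *all* reads at the position,
  including reads matching neither allele; the comparison is strict.

## Known limitations

- The FDR floor makes very sparse experiments (a handful of true regions)
  uncertifiable at stringent FDRs; raise the target or the draw count.
- Copy-number detection is threshold-run based, not an HMM; events closer
  together than the bridge gap merge, and folds between `del_fold` and
  `dup_fold` are invisible.
- Broad and narrow modes calibrate cutoffs independently; their region
  sets are only nested at a matched cutoff on one track, not across
  modes.
- The baseline trimmed mean assumes CNV segments occupy a small fraction
  of the genome; on small test genomes with large planted segments the
  trim fraction must be raised accordingly.
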