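"""Downstream analytics on called regions: overlap Venn counts, per-kb tag
and motif densities, promoter/intragenic/intergenic classification,
nearest-gene mapping, repeat-fraction histograms, zinc-finger-domain
association, and summary height/coverage statistics.

These mirror the comparisons made between two spreading histone marks
(e.g. H3K9me3 vs H3K36me3): which regions carry both marks, how transcribed
each class is, whether coverage of a zinc-finger gene tracks the number of
tandem finger domains in its 3' exon, and how repetitive each peak is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, PeakRegion, TagSet

__all__ = [
    "Pwm",
    "VennResult",
    "intersect_sets",
    "tag_density_per_kb",
    "classify_location",
    "nearest_gene",
    "motif_density",
    "repeat_fraction_histogram",
    "RepeatFractionResult",
    "top_decile_ratio",
    "finger_domain_association",
    "mean_max_height",
    "fold_coverage_difference",
]


# ---------------------------------------------------------------------------
# interval bookkeeping


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for lst in out.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(_by_chrom(intervals).items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass
class VennResult:
    """Two-set region overlap accounting.

    ``both`` counts merged overlap events (a region of one set overlapping
    two regions of the other yields one event after merging the pairwise
    intersections); ``a_both``/``b_both`` count the regions of each set
    that participate in at least one qualifying overlap, so
    ``a_only + a_both == |A|``.
    """

    a_only: int
    b_only: int
    both: int
    a_both: int
    b_both: int
    a_only_intervals: list[GenomicInterval] = field(default_factory=list)
    b_only_intervals: list[GenomicInterval] = field(default_factory=list)
    both_intervals: list[GenomicInterval] = field(default_factory=list)


def intersect_sets(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> VennResult:
    """Venn-style overlap of two region sets at a minimum overlap in bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    b_map = _by_chrom(b)
    a_hit = np.zeros(len(a), dtype=bool)
    b_hit: dict[int, bool] = {id(iv): False for iv in b}
    overlaps: list[GenomicInterval] = []
    for i, iv in enumerate(a):
        candidates = b_map.get(iv.chrom, [])
        # sorted by start: stop once candidate starts at/after iv.end
        for cand in candidates:
            if cand.start >= iv.end:
                break
            ov = iv.overlap_bp(cand)
            if ov >= min_overlap:
                a_hit[i] = True
                b_hit[id(cand)] = True
                overlaps.append(
                    GenomicInterval(
                        iv.chrom, max(iv.start, cand.start), min(iv.end, cand.end)
                    )
                )
    merged = merge_intervals(overlaps) if overlaps else []
    a_both = int(a_hit.sum())
    b_both = sum(b_hit.values())
    return VennResult(
        a_only=len(a) - a_both,
        b_only=len(b) - b_both,
        both=len(merged),
        a_both=a_both,
        b_both=b_both,
        a_only_intervals=[iv for i, iv in enumerate(a) if not a_hit[i]],
        b_only_intervals=[iv for iv in b if not b_hit[id(iv)]],
        both_intervals=merged,
    )


# ---------------------------------------------------------------------------
# densities


def tag_density_per_kb(
    tags: TagSet, regions: Sequence[GenomicInterval]
) -> tuple[list[float], float]:
    """Tags per 1,000 bp, per region and aggregate.

    A tag belongs to a region when its 5' position falls inside the span.
    The aggregate is total count x 1000 / total length, so splitting a
    region into adjacent halves leaves it unchanged.
    """
    if not regions:
        raise ValueError("no regions given")
    per_region: list[float] = []
    total_count = 0
    total_len = 0
    for region in regions:
        pos = tags.positions(region.chrom)
        count = int(
            np.searchsorted(pos, region.end, side="left")
            - np.searchsorted(pos, region.start, side="left")
        )
        per_region.append(count * 1000.0 / region.length())
        total_count += count
        total_len += region.length()
    return per_region, total_count * 1000.0 / total_len


# ---------------------------------------------------------------------------
# gene context


def _promoter_window(gene: GeneModel, halfwidth: int) -> GenomicInterval:
    start = max(0, gene.tss - halfwidth)
    return GenomicInterval(gene.span.chrom, start, gene.tss + halfwidth)


def classify_location(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 500,
) -> str:
    """Classify a region as promoter, intragenic or intergenic.

    Promoter wins: any overlap with a TSS +/- halfwidth window, regardless
    of gene-body overlap. Otherwise overlap with any gene span makes it
    intragenic; otherwise intergenic.
    """
    if promoter_halfwidth <= 0:
        raise ValueError("promoter_halfwidth must be positive")
    intragenic = False
    for gene in genes:
        if gene.span.chrom != region.chrom:
            continue
        if region.overlap_bp(_promoter_window(gene, promoter_halfwidth)) > 0:
            return "promoter"
        if region.overlap_bp(gene.span) > 0:
            intragenic = True
    return "intragenic" if intragenic else "intergenic"


def nearest_gene(region: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Gene id minimizing the bp gap to the region (0 when overlapping).

    Ties break by the smaller gap to the TSS, then lexicographic gene id.
    Returns "none" when the region's chromosome has no gene.
    """
    best: tuple[int, int, str] | None = None
    for gene in genes:
        gap = region.gap_to(gene.span)
        if gap is None:
            continue
        tss_gap = max(0, region.start - gene.tss, gene.tss - (region.end - 1))
        key = (gap, tss_gap, gene.gene_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else "none"


# ---------------------------------------------------------------------------
# motif scanning

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix of per-base log-odds against uniform background."""

    name: str
    matrix: np.ndarray  # (length, 4) for A, C, G, T
    score_threshold: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("matrix must be (length >= 1, 4)")
        object.__setattr__(self, "matrix", m)
        if self.score_threshold > self.max_score() + 1e-9:
            raise ValueError("threshold exceeds the maximal achievable score")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def max_score(self) -> float:
        return float(np.asarray(self.matrix).max(axis=1).sum())

    @classmethod
    def from_probabilities(
        cls, name: str, probs: np.ndarray, threshold_fraction: float = 0.8
    ) -> "Pwm":
        """Build from per-position base probabilities; log-odds vs uniform
        0.25 background, thresholded at a fraction of the maximal score."""
        probs = np.asarray(probs, dtype=float)
        probs = np.clip(probs, 1e-4, None)
        probs /= probs.sum(axis=1, keepdims=True)
        matrix = np.log2(probs / 0.25)
        max_score = float(matrix.max(axis=1).sum())
        return cls(name, matrix, threshold_fraction * max_score)

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        match_prob: float = 0.85,
        threshold_fraction: float = 0.8,
    ) -> "Pwm":
        probs = np.full((len(consensus), 4), (1 - match_prob) / 3)
        for i, base in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[base]] = match_prob
        return cls.from_probabilities(name, probs, threshold_fraction)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode(
            "latin1"
        ),
        dtype=np.uint8,
    ).astype(np.int64)


def scan_pwm(sequence: str, pwm: Pwm) -> list[tuple[int, str]]:
    """All (offset, strand) hits of a PWM on a sequence and its reverse
    complement; offsets are forward-strand window starts, N windows skipped."""
    hits: list[tuple[int, str]] = []
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return hits
    for strand, seq in (("+", sequence), ("-", sequence.translate(_COMPLEMENT)[::-1])):
        codes = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = ~(windows == 4).any(axis=1)
        safe = np.where(windows == 4, 0, windows)
        scores = pwm.matrix[np.arange(L)[None, :], safe].sum(axis=1)
        for i in np.flatnonzero(valid & (scores >= pwm.score_threshold - 1e-12)):
            offset = int(i) if strand == "+" else n - L - int(i)
            hits.append((offset, strand))
    return sorted(hits)


def motif_density(
    sequences: Sequence[tuple[GenomicInterval, str]],
    pwms: Sequence[Pwm],
) -> dict[str, float]:
    """Per-motif hit density (hits per 1,000 bp) over a set of region
    sequences, both orientations counted."""
    total_len = 0
    for region, seq in sequences:
        if len(seq) != region.length():
            raise ValueError(
                f"sequence length {len(seq)} != region length {region.length()} "
                f"for {region.chrom}:{region.start}-{region.end}"
            )
        total_len += len(seq)
    if total_len == 0:
        raise ValueError("no sequence given")
    return {
        pwm.name: sum(len(scan_pwm(seq, pwm)) for _, seq in sequences)
        * 1000.0
        / total_len
        for pwm in pwms
    }


# ---------------------------------------------------------------------------
# repeats


@dataclass
class RepeatFractionResult:
    """Per-peak repetitive percentages and their decile histogram.

    Histogram bins are [0, 10], (10, 20], ..., (90, 100]; a peak 95%
    covered by (merged) repeats lands in the top decile.
    """

    percents: list[float]
    decile_counts: np.ndarray  # length 10

    def top_decile_count(self) -> int:
        return int(self.decile_counts[-1])


def repeat_fraction_histogram(
    peaks: Sequence[GenomicInterval], repeats: Sequence[GenomicInterval]
) -> RepeatFractionResult:
    """Percent of each peak covered by repeats, with a decile histogram.

    Repeats are merged (union) before intersecting, so fragmentation or
    overlap among repeat annotations cannot inflate the percentage.
    """
    merged = _by_chrom(merge_intervals(repeats)) if repeats else {}
    percents: list[float] = []
    for peak in peaks:
        overlap = sum(peak.overlap_bp(r) for r in merged.get(peak.chrom, []))
        percents.append(100.0 * overlap / peak.length())
    counts = np.zeros(10, dtype=np.int64)
    for p in percents:
        idx = 0 if p <= 10 else min(int(np.ceil(p / 10.0)) - 1, 9)
        counts[idx] += 1
    return RepeatFractionResult(percents=percents, decile_counts=counts)


def top_decile_ratio(a: RepeatFractionResult, b: RepeatFractionResult) -> float:
    """How many times more top-decile (91-100% repetitive) peaks set A has."""
    if b.top_decile_count() == 0:
        raise ZeroDivisionError("comparison set has no top-decile peaks")
    return a.top_decile_count() / b.top_decile_count()


# ---------------------------------------------------------------------------
# gene-class association and summary statistics


def finger_domain_association(
    genes: Sequence[GeneModel],
    peaks: Sequence[GenomicInterval],
    min_overlap: int = 1,
    classes: Sequence[int] = tuple(range(1, 26)),
) -> dict[int, float]:
    """Percent of genes of each finger-domain count overlapped by a peak.

    Classes with no annotated gene are absent from the result (not 0%).
    """
    annotated = [g for g in genes if g.n_finger_domains is not None]
    if not annotated:
        raise ValueError("no gene carries a finger-domain annotation")
    peak_map = _by_chrom(peaks)
    out: dict[int, float] = {}
    for k in classes:
        members = [g for g in annotated if g.n_finger_domains == k]
        if not members:
            continue
        covered = sum(
            any(
                g.span.overlap_bp(p) >= min_overlap
                for p in peak_map.get(g.span.chrom, [])
            )
            for g in members
        )
        out[k] = 100.0 * covered / len(members)
    return out


def mean_max_height(peaks: Sequence[PeakRegion]) -> float:
    """Arithmetic mean of the per-region summit heights."""
    if not peaks:
        raise ValueError("no peaks given")
    return float(np.mean([p.max_height for p in peaks]))


def fold_coverage_difference(coverage_a: float, coverage_b: float) -> float:
    """Genome-coverage fold gain b/a, rounded half-up to one decimal."""
    if coverage_a <= 0 or coverage_b <= 0:
        raise ValueError("coverages must be positive")
    return float(
        Decimal(coverage_b / coverage_a).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
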