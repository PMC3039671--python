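"""Synthetic ChIP-seq experiments with planted, recoverable structure.

The generator emulates what the normalization and calling stages assume
real data looks like: a Poisson-like tag background shared by ChIP and
input channels, copy-number segments (duplications/deletions) that inflate
or deflate both channels, over-sequenced protocol hotspots, and enrichment
domains present only in the ChIP channel — either flat "block" profiles or
"jagged" mountain-range profiles whose enrichment alternates between high
and low sub-blocks on a ~1 kb period.

Tags are placed by a single multinomial draw over base pairs with the
composite weight (background x copy number x hotspot inflation x
enrichment), so total tag counts are exact and per-region conservation
checks are easy. Every output round-trips through the package's writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import AlleleCount, GeneModel, GenomicInterval, PeakRegion, TagSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_gene_catalog",
    "simulate_allele_counts",
    "domain_recovery",
    "broad_domain_preset",
]

JAGGED_PERIOD = 1000  # bp; sub-block width of the jagged profile
JAGGED_HIGH = 1.5  # multiplies the domain fold in high sub-blocks
JAGGED_LOW = 0.5  # ... and in low sub-blocks; mean stays at the stated fold


@dataclass
class SimConfig:
    """Study conditions of one synthetic experiment.

    ``planted_regions`` holds (span, enrichment_fold, profile) with profile
    "block" or "jagged"; ``cn_segments`` holds (span, copy_number);
    ``oversequenced`` holds (span, inflation_fold). ``background_rate`` is
    expected input tags per bp on a normal-copy background and only sets
    tag totals when ``n_input_tags``/``n_chip_tags`` are not given.
    """

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    planted_regions: Sequence[tuple[GenomicInterval, float, str]] = ()
    cn_segments: Sequence[tuple[GenomicInterval, float]] = ()
    oversequenced: Sequence[tuple[GenomicInterval, float]] = ()
    background_rate: float = 0.02
    n_chip_tags: int | None = None
    n_input_tags: int | None = None
    read_length: int = 36
    fragment_length: int = 350
    seed: int = 0

    def __post_init__(self) -> None:
        genome = sum(self.chrom_sizes.values())
        if self.n_chip_tags is None:
            self.n_chip_tags = int(self.background_rate * genome)
        if self.n_input_tags is None:
            self.n_input_tags = int(self.background_rate * genome)
        if self.n_chip_tags <= 0 or self.n_input_tags <= 0:
            raise ValueError("tag counts must be positive")
        for span, fold, profile in self.planted_regions:
            if fold <= 0:
                raise ValueError("enrichment folds must be positive")
            if profile not in ("block", "jagged"):
                raise ValueError(f"unknown profile {profile!r}")
            if span.end > self.chrom_sizes.get(span.chrom, 0):
                raise ValueError(f"planted region {span} outside chromosome")
        for span, cn in self.cn_segments:
            if cn <= 0:
                raise ValueError("copy numbers must be positive")


@dataclass
class SimTruth:
    """Ground truth needed to score recovery; nothing else is required."""

    planted: list[tuple[GenomicInterval, float, str]]
    cn_segments: list[tuple[GenomicInterval, float]]
    oversequenced: list[tuple[GenomicInterval, float]]


def _base_weights(config: SimConfig, chrom: str) -> np.ndarray:
    """Per-bp weight shared by both channels: copy number x inflation."""
    w = np.ones(config.chrom_sizes[chrom])
    for span, cn in config.cn_segments:
        if span.chrom == chrom:
            w[span.start : span.end] *= cn
    for span, fold in config.oversequenced:
        if span.chrom == chrom:
            w[span.start : span.end] *= fold
    return w


def _enrichment_weights(config: SimConfig, chrom: str) -> np.ndarray:
    w = np.ones(config.chrom_sizes[chrom])
    for span, fold, profile in config.planted_regions:
        if span.chrom != chrom:
            continue
        if profile == "block":
            w[span.start : span.end] *= fold
        else:
            offsets = np.arange(span.length())
            sub = (offsets // JAGGED_PERIOD) % 2
            w[span.start : span.end] *= fold * np.where(
                sub == 0, JAGGED_HIGH, JAGGED_LOW
            )
    return w


def _place_tags(
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    n_tags: int,
    config: SimConfig,
) -> TagSet:
    chroms = sorted(weights)
    totals = np.array([weights[c].sum() for c in chroms])
    per_chrom = rng.multinomial(n_tags, totals / totals.sum())
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, n in zip(chroms, per_chrom):
        w = weights[chrom]
        # inverse-CDF sampling keeps memory flat on multi-Mb chromosomes
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        pos = np.searchsorted(cdf, rng.random(n), side="right").astype(np.int64)
        strand = rng.choice(np.array([1, -1], dtype=np.int8), size=n)
        tags[chrom] = (pos, strand)
    return TagSet(
        tags, read_length=config.read_length, chrom_sizes=dict(config.chrom_sizes)
    )


def simulate_experiment(config: SimConfig) -> tuple[TagSet, TagSet, SimTruth]:
    """Draw (chip, input, truth) under the configured study conditions.

    Input tag weights: background x copy number x hotspot inflation.
    ChIP tag weights: the same, additionally multiplied by the enrichment
    fold inside planted regions. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = {c: _base_weights(config, c) for c in config.chrom_sizes}
    enrich = {c: base[c] * _enrichment_weights(config, c) for c in config.chrom_sizes}
    chip = _place_tags(rng, enrich, config.n_chip_tags, config)
    input_tags = _place_tags(rng, base, config.n_input_tags, config)
    truth = SimTruth(
        planted=list(config.planted_regions),
        cn_segments=list(config.cn_segments),
        oversequenced=list(config.oversequenced),
    )
    return chip, input_tags, truth


def broad_domain_preset(
    seed: int = 0,
    n_domains: int = 20,
    fold: float = 8.0,
    profile: str = "jagged",
    chrom_sizes: Mapping[str, int] | None = None,
) -> SimConfig:
    """Study conditions for broad-domain recovery: ``n_domains`` planted
    domains of 10-50 kb at the given fold on a 2 x 5 Mb genome, placed
    non-overlapping with >= 60 kb spacing so merging cannot fuse two truths.
    """
    sizes = dict(chrom_sizes or {"chr1": 5_000_000, "chr2": 5_000_000})
    rng = np.random.default_rng(seed)
    chroms = sorted(sizes)
    planted: list[tuple[GenomicInterval, float, str]] = []
    per_chrom = np.array_split(np.arange(n_domains), len(chroms))
    for chrom, idx in zip(chroms, per_chrom):
        k = len(idx)
        if k == 0:
            continue
        slot = sizes[chrom] // k
        for i in range(k):
            length = int(rng.integers(10_000, 50_001))
            lo = i * slot + 5_000
            hi = (i + 1) * slot - length - 5_000
            start = int(rng.integers(lo, max(lo + 1, hi)))
            planted.append(
                (GenomicInterval(chrom, start, start + length), fold, profile)
            )
    return SimConfig(
        chrom_sizes=sizes, planted_regions=planted, background_rate=0.02, seed=seed
    )


def domain_recovery(
    truth: SimTruth, called: Sequence[PeakRegion], jaccard_min: float = 0.8
) -> tuple[float, list[float]]:
    """Fraction of planted domains recovered at a per-domain Jaccard floor.

    A domain's Jaccard is the best overlap/union against any single called
    region; merging in broad mode should leave one region per domain.
    """
    jaccards: list[float] = []
    for span, _, _ in truth.planted:
        best = 0.0
        for region in called:
            ov = span.overlap_bp(region.span)
            if ov == 0:
                continue
            union = span.length() + region.span.length() - ov
            best = max(best, ov / union)
        jaccards.append(best)
    if not jaccards:
        return 0.0, []
    recovered = sum(j >= jaccard_min for j in jaccards)
    return recovered / len(jaccards), jaccards


def simulate_gene_catalog(
    n_genes: int,
    finger_count_range: tuple[int, int] = (1, 25),
    coverage_trend: Callable[[int], float] | None = None,
    seed: int = 0,
) -> tuple[list[GeneModel], list[GenomicInterval]]:
    """Genes with uniform finger-domain counts, each covered by a peak with
    probability ``coverage_trend(k)`` (default: logistic in k, midpoint 10).

    Genes are laid out non-overlapping along one synthetic chromosome;
    covering peaks sit inside the gene span.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if coverage_trend is None:
        coverage_trend = lambda k: 1.0 / (1.0 + np.exp(-(k - 10) / 2.0))
    rng = np.random.default_rng(seed)
    lo, hi = finger_count_range
    genes: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    cursor = 1000
    for i in range(n_genes):
        k = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(5_000, 20_000))
        span = GenomicInterval("chrSim", cursor, cursor + length, "+")
        genes.append(GeneModel(gene_id=f"g{i:05d}", span=span, n_finger_domains=k))
        if rng.random() < coverage_trend(k):
            peaks.append(GenomicInterval("chrSim", cursor + 100, cursor + length - 100))
        cursor += length + int(rng.integers(2_000, 10_000))
    return genes, peaks


def simulate_allele_counts(
    n_sites: int,
    fraction_heterogeneous: float = 0.4,
    depth_range: tuple[int, int] = (20, 100),
    seed: int = 0,
) -> list[AlleleCount]:
    """Positions with planted fixation status.

    Heterogeneous sites draw their wt read fraction from Uniform(0.35,
    0.65); fixed sites give the majority allele (wt or variant, equally
    likely) a fraction from Uniform(0.95, 1.0). Depths are uniform over
    ``depth_range`` and counts realize the drawn fraction exactly (rounded),
    so planted classes are unambiguous at depth >= 20.
    """
    if not 0 <= fraction_heterogeneous <= 1:
        raise ValueError("fraction_heterogeneous must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts: list[AlleleCount] = []
    for i in range(n_sites):
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        if rng.random() < fraction_heterogeneous:
            wt_frac = rng.uniform(0.35, 0.65)
        else:
            major = rng.uniform(0.95, 1.0)
            wt_frac = major if rng.random() < 0.5 else 1.0 - major
        wt = int(round(depth * wt_frac))
        counts.append(
            AlleleCount(chrom="chrSim", position=1000 + i, wt_count=wt, var_count=depth - wt)
        )
    return counts
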