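"""FDR-calibrated height cutoffs and narrow/broad region calling.

The caller has no per-peak statistical model. Instead it asks: at which
height cutoff does a shuffled background stop producing regions, relative
to the real ChIP data? Input tags are resampled into megabase-scale bins
and shuffled uniformly within each bin — preserving large-scale sequencing
bias while destroying local structure — and the cutoff is raised until the
number of background regions is a sufficiently small fraction (the
user-defined FDR) of the number of ChIP regions at that same height.

Narrow mode (transcription-factor style) uses small bins, no smoothing and
a small merge gap; broad mode (spreading histone marks) smooths the track
and merges across kilobase gaps so jagged "mountain range" domains come out
as single regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CopyNumberSegment, GenomicInterval, PeakRegion, TagSet
from .coverage import (
    DEFAULT_EXTENSION,
    CoverageTrack,
    build_coverage,
    sliding_average,
)
from .normalization import (
    combine_segments,
    detect_copy_number,
    detect_oversequenced,
    estimate_global_mean,
    normalize_chip,
)

__all__ = [
    "PeakCallConfig",
    "FdrCalibration",
    "CalibrationError",
    "make_background",
    "regions_above",
    "calibrate_height_cutoff",
    "call_peaks",
]

MODE_DEFAULTS = {
    # bin_size, smoothing_window (bins), merge_gap (bp), min_region_len (bp)
    "narrow": dict(bin_size=50, smoothing_window=1, merge_gap=100, min_region_len=100),
    "broad": dict(bin_size=200, smoothing_window=9, merge_gap=1000, min_region_len=400),
}


@dataclass
class PeakCallConfig:
    """Tunable knobs of one peak-calling run.

    Unset geometry fields (bin_size, smoothing_window, merge_gap,
    min_region_len) take the mode's defaults. ``background_bin_width`` sets
    the scale of the shuffle bins (one per megabase by default);
    ``n_background_draws`` shuffled backgrounds are averaged.
    """

    fdr: float = 0.01
    mode: str = "broad"
    bin_size: int | None = None
    extension: int = DEFAULT_EXTENSION
    smoothing_window: int | None = None
    input_smoothing_window: int = 9
    merge_gap: int | None = None
    min_region_len: int | None = None
    seed: int = 0
    n_background_draws: int = 10
    background_bin_width: int = 1_000_000
    dup_fold: float = 1.5
    del_fold: float = 0.5
    cn_min_len: int = 2000
    oversequenced_window: int = 10
    oversequenced_alpha: float = 0.05
    max_copy_fold: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"mode must be narrow or broad, got {self.mode!r}")
        if self.n_background_draws < 1:
            raise ValueError("n_background_draws must be >= 1")
        defaults = MODE_DEFAULTS[self.mode]
        for name in ("bin_size", "smoothing_window", "merge_gap", "min_region_len"):
            if getattr(self, name) is None:
                setattr(self, name, defaults[name])
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class FdrCalibration:
    """The calibrated cutoff and the height-by-height count table.

    ``table`` rows are (height, chip_region_count, mean_background_count,
    empirical_fdr), one per candidate height scanned.
    """

    height_cutoff: float
    table: list[tuple[float, int, float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "height_cutoff": self.height_cutoff,
            "table": [
                {"height": h, "chip_regions": c, "mean_background_regions": b, "fdr": f}
                for h, c, b, f in self.table
            ],
        }


class CalibrationError(RuntimeError):
    """No height satisfied the target FDR before ChIP regions vanished."""


def make_background(input_tags: TagSet, n_bins: int, seed: int) -> TagSet:
    """Shuffle input tags within equal-width sampling bins per chromosome.

    Each chromosome is partitioned into ``n_bins`` equal-width bins; every
    tag keeps its bin and strand but gets a fresh uniform position inside
    the bin, so per-bin counts (hence megabase-scale bias) are conserved
    exactly while local structure is destroyed. Deterministic given seed.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    shuffled: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pos, strand in input_tags:
        extent = input_tags.chrom_sizes[chrom]
        if n_bins > extent:
            raise ValueError(f"{chrom}: n_bins {n_bins} exceeds extent {extent}")
        edges = np.linspace(0, extent, n_bins + 1)
        bin_idx = np.minimum(
            np.searchsorted(edges, pos, side="right") - 1, n_bins - 1
        )
        lo = edges[bin_idx]
        width = edges[bin_idx + 1] - lo
        new_pos = np.floor(lo + rng.random(pos.size) * width).astype(np.int64)
        shuffled[chrom] = (new_pos, strand.copy())
    return TagSet(
        shuffled, read_length=input_tags.read_length, chrom_sizes=input_tags.chrom_sizes
    )


def _runs_above(values: np.ndarray, height: float) -> np.ndarray:
    """(k, 2) array of maximal bin runs [i, j) with values >= height."""
    mask = values >= height
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges.reshape(-1, 2)


def _merged_runs(
    values: np.ndarray, height: float, gap_bins: int
) -> np.ndarray:
    runs = _runs_above(values, height)
    if runs.shape[0] <= 1 or gap_bins <= 0:
        return runs
    gaps = runs[1:, 0] - runs[:-1, 1]
    keep = gaps > gap_bins  # True where a new merged run starts
    starts = runs[np.concatenate([[True], keep]), 0]
    ends = runs[np.concatenate([keep, [True]]), 1]
    return np.column_stack([starts, ends])


def regions_above(
    track: CoverageTrack,
    height: float,
    merge_gap: int = 0,
    min_region_len: int = 0,
    mode: str = "narrow",
) -> list[PeakRegion]:
    """Maximal runs of bins at or above ``height``, merged and length-filtered.

    Runs separated by at most ``merge_gap`` bp of sub-threshold bins are
    merged; merged spans shorter than ``min_region_len`` bp are dropped.
    Height statistics (max, area, mean) are computed over the merged span,
    gap bins included.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    gap_bins = merge_gap // track.bin_size
    regions: list[PeakRegion] = []
    for chrom in track.chroms:
        values = track.bins[chrom]
        for i, j in _merged_runs(values, height, gap_bins):
            start, end = track.bin_span(chrom, int(i), int(j))
            if end - start < min_region_len:
                continue
            window = values[i:j]
            area = float(window.sum()) * track.bin_size
            regions.append(
                PeakRegion(
                    span=GenomicInterval(chrom, start, end),
                    max_height=float(window.max()),
                    area=area,
                    mean_height=area / (end - start),
                    mode=mode,
                )
            )
    return regions


def _count_regions(
    track: CoverageTrack, height: float, merge_gap: int, min_region_len: int
) -> int:
    gap_bins = merge_gap // track.bin_size
    n = 0
    for chrom in track.chroms:
        runs = _merged_runs(track.bins[chrom], height, gap_bins)
        if runs.size:
            starts = runs[:, 0] * track.bin_size
            ends = np.minimum(runs[:, 1] * track.bin_size, track.chrom_sizes[chrom])
            n += int(np.sum(ends - starts >= min_region_len))
    return n


def _height_step(track: CoverageTrack, smoothed: bool) -> float:
    """Candidate-height step: one tag depth for raw tracks; for smoothed
    tracks the smallest positive difference between distinct observed
    values, floored at 0.25."""
    if not smoothed:
        return 1.0
    values = np.unique(track.all_values())
    diffs = np.diff(values)
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        return 1.0
    return float(max(0.25, diffs.min()))


def _background_tracks(
    input_tags: TagSet, config: PeakCallConfig, target_area: float
) -> list[CoverageTrack]:
    mean_extent = np.mean([max(1, s) for s in input_tags.chrom_sizes.values()])
    n_bins = max(1, int(round(mean_extent / config.background_bin_width)))
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_background_draws
    ) % (2**31)
    tracks = []
    for s in seeds:
        bg_tags = make_background(input_tags, n_bins=n_bins, seed=int(s))
        bg = build_coverage(
            bg_tags,
            bin_size=config.bin_size,
            extension=config.extension,
            chrom_sizes=input_tags.chrom_sizes,
        )
        if config.smoothing_window > 1:
            bg = sliding_average(bg, config.smoothing_window)
        # Scale to ChIP depth so region counts compare like with like.
        bg_area = bg.total_area()
        if bg_area > 0 and target_area > 0:
            scale = target_area / bg_area
            for chrom in bg.bins:
                bg.bins[chrom] *= scale
        tracks.append(bg)
    return tracks


def calibrate_height_cutoff(
    chip_track: CoverageTrack, input_tags: TagSet, config: PeakCallConfig
) -> FdrCalibration:
    """Find the smallest height whose empirical FDR meets the target.

    Candidate heights rise in steps of the track's depth quantum. At each
    height the ChIP region count and the region counts over
    ``n_background_draws`` shuffled backgrounds (depth-scaled to the ChIP
    track) are compared: empirical FDR = (1 + total background regions) /
    (draws x ChIP regions), the add-one correction keeping a lucky all-zero
    background from certifying a single ChIP region. The scan stops at the
    first height meeting ``config.fdr``; if ChIP regions run out first,
    calibration fails.
    """
    backgrounds = _background_tracks(input_tags, config, chip_track.total_area())
    step = _height_step(chip_track, smoothed=config.smoothing_window > 1)
    max_height = float(chip_track.all_values().max(initial=0.0))
    heights = np.arange(step, max_height + step, step)
    chip_counts = np.array(
        [
            _count_regions(chip_track, h, config.merge_gap, config.min_region_len)
            for h in heights
        ]
    )
    bg_counts = np.mean(
        [
            [
                _count_regions(bg, h, config.merge_gap, config.min_region_len)
                for h in heights
            ]
            for bg in backgrounds
        ],
        axis=0,
    )
    # Below the background's own count maximum, raising the cutoff is still
    # fragmenting one genome-wide "region" into pieces and counts carry no
    # false-discovery meaning; the cutoff scan starts at that peak.
    start = int(np.argmax(bg_counts)) if bg_counts.size else 0
    n_draws = config.n_background_draws
    table: list[tuple[float, int, float, float]] = []
    for i in range(start, heights.size):
        chip_count = int(chip_counts[i])
        if chip_count == 0:
            break
        # permutation-style add-one correction: a background count of zero
        # over finitely many draws bounds, not measures, the noise rate
        fdr = (1.0 + n_draws * float(bg_counts[i])) / (n_draws * chip_count)
        table.append((float(heights[i]), chip_count, float(bg_counts[i]), fdr))
        if fdr <= config.fdr:
            return FdrCalibration(height_cutoff=float(heights[i]), table=table)
        if bg_counts[i] == 0 and bg_counts[i:].max() == 0:
            # backgrounds are exhausted; the only way fdr could still fall is
            # summit noise fragmenting real regions into more pieces, which
            # is not evidence. The target is unreachable for this data.
            raise CalibrationError(
                f"FDR floor 1/(draws x {chip_count} ChIP regions) = "
                f"{1.0 / (n_draws * chip_count):.3g} exceeds target {config.fdr}; "
                "consider a higher target FDR or more background draws"
            )
    raise CalibrationError(
        f"no height cutoff reaches FDR {config.fdr} before ChIP regions vanish; "
        "consider a higher target FDR"
    )


def call_peaks(
    chip_tags: TagSet, input_tags: TagSet, config: PeakCallConfig | None = None
) -> tuple[list[PeakRegion], FdrCalibration, list[CopyNumberSegment]]:
    """End-to-end calling: normalize, (optionally) smooth, calibrate, call.

    Stages: input coverage -> input smoothing -> baseline -> copy-number +
    over-sequenced detection -> ChIP coverage -> single-copy normalization
    -> broad-mode smoothing -> FDR calibration against shuffled input ->
    region extraction with the mode's merge gap and length floor.
    Deterministic given ``config.seed``.
    """
    if config is None:
        config = PeakCallConfig()
    if chip_tags.n_tags == 0 or input_tags.n_tags == 0:
        raise ValueError("both ChIP and input tag sets must be non-empty")
    sizes = dict(input_tags.chrom_sizes)
    for c, s in chip_tags.chrom_sizes.items():
        sizes[c] = max(s, sizes.get(c, 0))

    input_track = build_coverage(
        input_tags, config.bin_size, config.extension, chrom_sizes=sizes
    )
    smooth_input = sliding_average(input_track, config.input_smoothing_window)
    baseline = estimate_global_mean(smooth_input)
    cn = detect_copy_number(
        smooth_input, baseline, config.dup_fold, config.del_fold, config.cn_min_len
    )
    overseq = detect_oversequenced(
        smooth_input,
        window=config.oversequenced_window,
        alpha=config.oversequenced_alpha,
        dup_fold=config.dup_fold,
        max_copy_fold=config.max_copy_fold,
    )
    segments = combine_segments(cn, overseq)

    chip_track = build_coverage(
        chip_tags, config.bin_size, config.extension, chrom_sizes=sizes
    )
    chip_track = normalize_chip(chip_track, segments)
    if config.smoothing_window > 1:
        chip_track = sliding_average(chip_track, config.smoothing_window)

    calibration = calibrate_height_cutoff(chip_track, input_tags, config)
    regions = regions_above(
        chip_track,
        calibration.height_cutoff,
        merge_gap=config.merge_gap,
        min_region_len=config.min_region_len,
        mode=config.mode,
    )
    return regions, calibration, segments
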