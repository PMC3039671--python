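"""Input-driven copy-number and sequencing-bias correction.

The input (non-immunoprecipitated) channel sees the genome's copy-number
structure and protocol hotspots but no immunoprecipitation signal, so fold
coverage of the smoothed input against its genome-wide average exposes
duplications and deletions, while a windowed t-statistic flags regions
over-sequenced beyond any plausible copy fold. The ChIP track is then
rescaled to a single-copy, bias-free genome: bins inside copy-number
segments are divided by the copy number, and over-sequenced bins are masked
to the ChIP-wide median (a protocol artifact has no meaningful copy number
to divide by).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .core import CopyNumberSegment, GenomicInterval
from .coverage import CoverageTrack

__all__ = [
    "estimate_global_mean",
    "detect_copy_number",
    "detect_oversequenced",
    "combine_segments",
    "normalize_chip",
    "write_segments_bed",
]


def estimate_global_mean(input_track: CoverageTrack, trim: float = 0.01) -> float:
    """Average input coverage: trimmed mean of nonzero bins.

    Zero bins (unmappable or unsequenced) are excluded; ``trim`` is the
    fraction cut from each tail so CNV spikes and deserts do not drag the
    baseline.
    """
    values = input_track.all_values()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero input track: no coverage baseline")
    return float(stats.trim_mean(nonzero, trim))


def _runs(mask: np.ndarray, gap_bins: int = 0) -> list[tuple[int, int]]:
    """Maximal [i, j) runs of True, closing gaps of <= gap_bins False bins."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = list(zip(edges[::2], edges[1::2]))
    if gap_bins <= 0 or len(runs) < 2:
        return runs
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= gap_bins:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def detect_copy_number(
    input_track: CoverageTrack,
    baseline: float,
    dup_fold: float = 1.5,
    del_fold: float = 0.5,
    min_len: int = 2000,
    merge_gap: int | None = None,
) -> list[CopyNumberSegment]:
    """Call duplication/deletion segments from fold coverage vs the baseline.

    Maximal runs of bins at depth >= dup_fold * baseline (duplication) or
    <= del_fold * baseline (deletion) that span at least ``min_len`` bp are
    reported; same-class runs separated by at most ``merge_gap`` bp
    (default ``min_len``) are bridged first, so sampling-noise dips cannot
    shatter one event into fragments that leave its interior unnormalized.
    Duplication copy numbers are quantized to halves
    (round(depth / baseline * 2) / 2, floored at 1.5) because fractional
    estimates at sequencing depth are noisy; deletions keep the raw fold
    floored at 0.25. Everything not reported is implicitly copy 1.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not (dup_fold > 1 > del_fold > 0):
        raise ValueError("need dup_fold > 1 > del_fold > 0")
    if merge_gap is None:
        merge_gap = min_len
    gap_bins = merge_gap // input_track.bin_size
    segments: list[CopyNumberSegment] = []
    for chrom in input_track.chroms:
        values = input_track.bins[chrom]
        for klass, mask in (
            ("duplication", values >= dup_fold * baseline),
            ("deletion", (values <= del_fold * baseline) & (values >= 0)),
        ):
            for i, j in _runs(mask, gap_bins):
                start, end = input_track.bin_span(chrom, i, j)
                if end - start < min_len:
                    continue
                depth = float(values[i:j].mean())
                if klass == "duplication":
                    cn = max(1.5, round(depth / baseline * 2) / 2)
                else:
                    # bridged gap bins can inflate the run mean; a deletion's
                    # fold stays within (0, del_fold] by construction
                    cn = float(np.clip(depth / baseline, 0.25, del_fold))
                segments.append(
                    CopyNumberSegment(GenomicInterval(chrom, start, end), cn, klass)
                )
    segments.sort(key=lambda s: (s.span.chrom, s.span.start))
    # gap bridging can (rarely) make a dup and a del span collide; keep the first
    kept: list[CopyNumberSegment] = []
    for seg in segments:
        if kept and seg.span.overlap_bp(kept[-1].span) > 0:
            continue
        kept.append(seg)
    return kept


def detect_oversequenced(
    input_track: CoverageTrack,
    window: int = 10,
    alpha: float = 0.05,
    dup_fold: float = 1.5,
    max_copy_fold: float = 5.0,
) -> list[CopyNumberSegment]:
    """Flag windows over-sequenced beyond chance with a one-sample t-statistic.

    Every sliding window of ``window`` bins is tested against the global
    mean using the global bin-level standard deviation
    (t = (window mean - mu) / (sd / sqrt(window)), upper tail, df = window-1),
    Bonferroni-corrected over the number of windows tested. Overlapping
    significant windows merge. A flagged region whose fold over the mean
    would pass as an ordinary duplication (fold in [dup_fold, max_copy_fold])
    is left to the copy-number caller; only folds beyond ``max_copy_fold`` —
    too high for a plausible copy number — or below ``dup_fold`` are kept as
    protocol artifacts.
    """
    if window < 2:
        raise ValueError("window must span >= 2 bins")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    values = input_track.all_values()
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        return []
    n_windows = sum(
        max(0, v.size - window + 1) for v in input_track.bins.values()
    )
    segments: list[CopyNumberSegment] = []
    for chrom in input_track.chroms:
        v = input_track.bins[chrom]
        if v.size < window:
            warnings.warn(
                f"{chrom}: fewer bins than the test window; skipped", stacklevel=2
            )
            continue
        cs = np.concatenate([[0.0], np.cumsum(v)])
        win_mean = (cs[window:] - cs[:-window]) / window
        t = (win_mean - mu) / (sd / np.sqrt(window))
        pvals = stats.t.sf(t, df=window - 1)
        sig = pvals * n_windows < alpha
        for i, j in _runs(sig):
            # window starting at bin k covers bins [k, k + window)
            b0, b1 = i, j - 1 + window
            start, end = input_track.bin_span(chrom, b0, b1)
            fold = float(v[b0:b1].mean()) / mu if mu > 0 else np.inf
            if dup_fold <= fold <= max_copy_fold:
                continue  # plausible duplication; handled by detect_copy_number
            segments.append(
                CopyNumberSegment(
                    GenomicInterval(chrom, start, end), max(fold, 1e-9), "oversequenced"
                )
            )
    segments.sort(key=lambda s: (s.span.chrom, s.span.start))
    return segments


def combine_segments(
    cn_segments: Sequence[CopyNumberSegment],
    oversequenced: Sequence[CopyNumberSegment],
) -> list[CopyNumberSegment]:
    """Merge the two detector outputs into one non-overlapping list.

    Over-sequenced segments win: any copy-number segment overlapping one is
    dropped (its depth excess is already explained by the artifact).
    """
    kept = list(oversequenced)
    for seg in cn_segments:
        if any(seg.span.overlap_bp(o.span) > 0 for o in oversequenced):
            continue
        kept.append(seg)
    kept.sort(key=lambda s: (s.span.chrom, s.span.start))
    return kept


def write_segments_bed(segments: Sequence[CopyNumberSegment], path) -> None:
    """Export segments as BED6: class in the name field, copy number x 100
    as the score."""
    with open(path, "w") as fh:
        for seg in segments:
            s = seg.span
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{seg.klass}\t"
                f"{round(seg.copy_number * 100)}\t.\n"
            )


def normalize_chip(
    chip_track: CoverageTrack, segments: Sequence[CopyNumberSegment]
) -> CoverageTrack:
    """Rescale the ChIP track to a single-copy, bias-free genome.

    Bins inside duplication/deletion segments are divided by the segment's
    copy number; bins inside over-sequenced segments are masked to the
    global ChIP median; all other bins are untouched. The result carries
    ``normalized=True`` so the pipeline cannot normalize twice.
    """
    ordered = sorted(segments, key=lambda s: (s.span.chrom, s.span.start))
    for a, b in zip(ordered, ordered[1:]):
        if a.span.chrom == b.span.chrom and a.span.end > b.span.start:
            raise ValueError(f"overlapping segments {a.span} and {b.span}")
    out = chip_track.copy(normalized=True)
    all_values = chip_track.all_values()
    chip_median = float(np.median(all_values)) if all_values.size else 0.0
    bs = out.bin_size
    for seg in ordered:
        if seg.span.chrom not in out.bins:
            continue
        v = out.bins[seg.span.chrom]
        i = seg.span.start // bs
        j = min(-(-seg.span.end // bs), v.size)
        if seg.klass == "oversequenced":
            v[i:j] = chip_median
        else:
            v[i:j] /= seg.copy_number
    return out
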