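"""Allele-fixation classification of per-position RNA-seq read counts.

At an expressed polymorphic position, an allele is called fixed when it
strictly exceeds a majority threshold (default 90%) of all reads at that
position — reference ("wt") and variant alike — otherwise both alleles are
being transcribed and the position is heterogeneous. The denominator is
every sequenced nucleotide at the position, including reads matching
neither allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import AlleleCount

__all__ = ["classify_fixation", "summarize_fixation", "FixationSummary"]

WT_FIXED = "wt_fixed"
VARIANT_FIXED = "variant_fixed"
HETEROGENEOUS = "heterogeneous"
LOW_DEPTH = "low_depth"


def classify_fixation(
    count: AlleleCount, threshold: float = 0.9, min_depth: int = 1
) -> str:
    """Classify one position as wt_fixed / variant_fixed / heterogeneous /
    low_depth.

    The comparison is strict: exactly ``threshold`` of the reads is not
    enough to call fixation. Scale-invariant in the counts.
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = count.total
    if total < min_depth:
        return LOW_DEPTH
    if count.wt_count > threshold * total:
        return WT_FIXED
    if count.var_count > threshold * total:
        return VARIANT_FIXED
    return HETEROGENEOUS


@dataclass(frozen=True)
class FixationSummary:
    n_wt_fixed: int
    n_variant_fixed: int
    n_heterogeneous: int
    n_low_depth: int
    n_total: int

    def as_dict(self) -> dict[str, int]:
        return {
            "wt_fixed": self.n_wt_fixed,
            "variant_fixed": self.n_variant_fixed,
            "heterogeneous": self.n_heterogeneous,
            "low_depth": self.n_low_depth,
            "total": self.n_total,
        }


def summarize_fixation(
    counts: Sequence[AlleleCount], threshold: float = 0.9, min_depth: int = 1
) -> FixationSummary:
    """Tally fixation classes over a set of positions."""
    if not counts:
        raise ValueError("no allele counts given")
    tally = {WT_FIXED: 0, VARIANT_FIXED: 0, HETEROGENEOUS: 0, LOW_DEPTH: 0}
    for c in counts:
        tally[classify_fixation(c, threshold, min_depth)] += 1
    return FixationSummary(
        n_wt_fixed=tally[WT_FIXED],
        n_variant_fixed=tally[VARIANT_FIXED],
        n_heterogeneous=tally[HETEROGENEOUS],
        n_low_depth=tally[LOW_DEPTH],
        n_total=len(counts),
    )
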