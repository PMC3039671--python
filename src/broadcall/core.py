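"""Core domain types shared across the package.

All coordinates are 0-based, half-open ``[start, end)`` on opaque chromosome
name tokens (no ``chr`` normalization is attempted). Tag positions are the
5' base of the mapped read: the BED ``start`` for + strand reads and
``end - 1`` for - strand reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "TagSet",
    "GeneModel",
    "CopyNumberSegment",
    "PeakRegion",
    "AlleleCount",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """bp separating two intervals; 0 if they overlap or abut, None if trans."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class TagSet:
    """Mapped sequence tags (5' position + strand) grouped per chromosome.

    Positions are stored sorted; strands as int8 (+1 for '+', -1 for '-').
    ``chrom_sizes`` records the chromosome extents the tags live on; when not
    given it is inferred from the rightmost tag.
    """

    def __init__(
        self,
        tags: Mapping[str, tuple[np.ndarray, np.ndarray]],
        read_length: int = 36,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.read_length = int(read_length)
        self._tags: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, strand) in tags.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            if pos.shape != strand.shape:
                raise ValueError("position/strand arrays must align")
            if pos.size and pos.min() < 0:
                raise ValueError(f"negative tag position on {chrom}")
            order = np.lexsort((strand, pos))
            self._tags[chrom] = (pos[order], strand[order])
        if chrom_sizes is not None:
            self.chrom_sizes = {c: int(s) for c, s in chrom_sizes.items()}
            for chrom, (pos, _) in self._tags.items():
                if pos.size and chrom not in self.chrom_sizes:
                    raise ValueError(f"no size for chromosome {chrom}")
        else:
            self.chrom_sizes = {
                c: int(p.max()) + 1 if p.size else 0
                for c, (p, _) in self._tags.items()
            }

    @property
    def n_tags(self) -> int:
        return sum(p.size for p, _ in self._tags.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._tags)

    def positions(self, chrom: str) -> np.ndarray:
        return self._tags.get(chrom, (np.empty(0, np.int64), None))[0]

    def strands(self, chrom: str) -> np.ndarray:
        if chrom not in self._tags:
            return np.empty(0, np.int8)
        return self._tags[chrom][1]

    def __iter__(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        for chrom in self.chroms:
            pos, strand = self._tags[chrom]
            yield chrom, pos, strand

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagSet):
            return NotImplemented
        if self.read_length != other.read_length or set(self._tags) != set(other._tags):
            return False
        return all(
            np.array_equal(self._tags[c][0], other._tags[c][0])
            and np.array_equal(self._tags[c][1], other._tags[c][1])
            for c in self._tags
        )

    def __repr__(self) -> str:
        return f"TagSet(n_tags={self.n_tags}, chroms={self.chroms})"


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its strand-aware TSS and optional finger-domain count.

    ``n_finger_domains`` counts tandemly repeated C2H2 zinc-finger domains in
    the 3' exon; ``None`` when the annotation does not provide it.
    """

    gene_id: str
    span: GenomicInterval
    tss: int = field(init=False)
    n_finger_domains: int | None = None

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        tss = self.span.start if self.span.strand == "+" else self.span.end - 1
        object.__setattr__(self, "tss", tss)
        if self.n_finger_domains is not None and self.n_finger_domains < 0:
            raise ValueError(f"gene {self.gene_id}: negative finger count")


@dataclass(frozen=True)
class CopyNumberSegment:
    """A span whose input coverage departs from the single-copy baseline.

    ``copy_number`` is relative to diploid-normal (1.0); deletions sit below
    1, duplications above. ``oversequenced`` marks protocol artifacts whose
    depth excess has no copy-number interpretation.
    """

    span: GenomicInterval
    copy_number: float
    klass: str  # deletion | duplication | oversequenced

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("copy_number must be positive")
        if self.klass not in ("deletion", "duplication", "oversequenced"):
            raise ValueError(f"unknown segment class {self.klass!r}")
        if self.klass == "deletion" and not self.copy_number < 1:
            raise ValueError("deletion requires copy_number < 1")
        if self.klass == "duplication" and not self.copy_number > 1:
            raise ValueError("duplication requires copy_number > 1")


@dataclass(frozen=True)
class PeakRegion:
    """A called enriched region with its summit height and area."""

    span: GenomicInterval
    max_height: float
    area: float
    mean_height: float
    mode: str = "narrow"

    def __post_init__(self) -> None:
        if self.mode not in ("narrow", "broad"):
            raise ValueError(f"unknown calling mode {self.mode!r}")


@dataclass(frozen=True)
class AlleleCount:
    """Reference/variant read counts at one expressed position."""

    chrom: str
    position: int
    wt_count: int
    var_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.wt_count, self.var_count, self.other_count) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.wt_count + self.var_count + self.other_count
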