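"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED6 for tags, repeats and called regions; tab-separated
tables (header line, ``#`` comments) for gene models and allele counts;
FASTA (via pyfaidx) for sequence handed to the motif scanner. Everything
is 0-based half-open, including the gene table.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AlleleCount, GeneModel, GenomicInterval, PeakRegion, TagSet

__all__ = [
    "read_tag_bed",
    "write_tag_bed",
    "read_region_bed",
    "write_region_bed",
    "write_interval_bed",
    "read_gene_table",
    "write_gene_table",
    "read_allele_counts",
    "write_allele_counts",
    "region_sequences",
]


class ParseError(ValueError):
    """Raised on a malformed input line; the message names the line number."""


def _bed_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_coords(fields: list[str], lineno: int, path: str | Path) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
    if start < 0 or start >= end:
        raise ParseError(f"{path}:{lineno}: invalid span [{start}, {end})")
    return chrom, start, end


def read_tag_bed(
    path: str | Path,
    read_length: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> TagSet:
    """Read mapped tags from a BED3/BED6 file into a :class:`TagSet`.

    The tag 5' position is the BED start for + strand entries and end-1 for
    - strand entries. A missing strand column defaults to '+' (warned once:
    fragment extension is directional, so strand matters). ``read_length``
    defaults to the modal span length in the file, or 36 for an empty file.
    """
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    lengths: list[int] = []
    warned = False
    for lineno, fields in _bed_rows(path):
        chrom, start, end = _parse_coords(fields, lineno, path)
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            strand = fields[5]
        else:
            strand = "+"
            if not warned:
                warnings.warn(
                    f"{path}:{lineno}: no strand column; defaulting tags to '+'",
                    stacklevel=2,
                )
                warned = True
        pos = start if strand == "+" else end - 1
        bucket = per_chrom.setdefault(chrom, ([], []))
        bucket[0].append(pos)
        bucket[1].append(1 if strand == "+" else -1)
        lengths.append(end - start)
    if read_length is None:
        read_length = int(np.bincount(lengths).argmax()) if lengths else 36
    tags = {
        c: (np.array(p, dtype=np.int64), np.array(s, dtype=np.int8))
        for c, (p, s) in per_chrom.items()
    }
    return TagSet(tags, read_length=read_length, chrom_sizes=chrom_sizes)


def write_tag_bed(tags: TagSet, path: str | Path) -> None:
    """Write tags as BED6 reads of ``read_length`` bp anchored at the 5' end
    (clipped at the chromosome start for - strand tags near 0)."""
    rl = tags.read_length
    with open(path, "w") as fh:
        for chrom, pos, strand in tags:
            for p, s in zip(pos, strand):
                if s > 0:
                    fh.write(f"{chrom}\t{p}\t{p + rl}\t.\t0\t+\n")
                else:
                    fh.write(f"{chrom}\t{max(0, p - rl + 1)}\t{p + 1}\t.\t0\t-\n")


def read_region_bed(path: str | Path) -> list[GenomicInterval]:
    """Read generic intervals (repeats, called regions, ...) from BED."""
    out = []
    for lineno, fields in _bed_rows(path):
        chrom, start, end = _parse_coords(fields, lineno, path)
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_region_bed(regions: Sequence[PeakRegion], path: str | Path) -> None:
    """Write called regions as BED6: name ``peak_<i>``, score = rounded max height."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions, start=1):
            s = region.span
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tpeak_{i}\t"
                f"{round(region.max_height)}\t.\n"
            )


def write_interval_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


GENE_COLUMNS = ["gene_id", "chrom", "strand", "txStart", "txEnd", "n_fingers"]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV (header: gene_id, chrom, strand, txStart, txEnd,
    n_fingers; the last column optional/blank). Coordinates are 0-based
    half-open; the TSS is txStart for + genes and txEnd-1 for - genes.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing gene table columns {missing}")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise ParseError(f"{path}: duplicate gene_id {dupes.iloc[0]!r}")
    genes = []
    for row in df.itertuples(index=False):
        if row.txStart >= row.txEnd:
            raise ParseError(f"{path}: gene {row.gene_id}: txStart >= txEnd")
        fingers = None
        if "n_fingers" in df.columns and pd.notna(getattr(row, "n_fingers", None)):
            fingers = int(row.n_fingers)
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                span=GenomicInterval(row.chrom, int(row.txStart), int(row.txEnd), row.strand),
                n_finger_domains=fingers,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            fingers = "" if g.n_finger_domains is None else str(g.n_finger_domains)
            fh.write(
                f"{g.gene_id}\t{g.span.chrom}\t{g.span.strand}\t"
                f"{g.span.start}\t{g.span.end}\t{fingers}\n"
            )


ALLELE_COLUMNS = ["chrom", "pos", "wt_base", "var_base", "wt_count", "var_count", "other_count"]


def read_allele_counts(path: str | Path) -> list[AlleleCount]:
    """Read per-position allele counts (TSV with the standard header)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns and c not in ("wt_base", "var_base")]
    if missing:
        raise ParseError(f"{path}: missing allele count columns {missing}")
    return [
        AlleleCount(
            chrom=row.chrom,
            position=int(row.pos),
            wt_count=int(row.wt_count),
            var_count=int(row.var_count),
            other_count=int(getattr(row, "other_count", 0) or 0),
        )
        for row in df.itertuples(index=False)
    ]


def write_allele_counts(counts: Sequence[AlleleCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALLELE_COLUMNS) + "\n")
        for c in counts:
            fh.write(
                f"{c.chrom}\t{c.position}\tN\tN\t{c.wt_count}\t{c.var_count}\t{c.other_count}\n"
            )


def region_sequences(
    fasta_path: str | Path, regions: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, str]]:
    """Fetch the (region, sequence) pairs the motif scanner consumes."""
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    return [(r, str(fasta[r.chrom][r.start : r.end])) for r in regions]
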