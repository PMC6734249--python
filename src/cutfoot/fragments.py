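"""Paired-end fragment records: loading, size fractionation, duplicate handling.

A fragment is the genomic interval released by two nuclease cuts.  Its two
boundary coordinates are the 5' alignment boundaries of the two mates:
``s1`` (mate R1) and ``e2`` (mate R2).  All coordinates are 0-based
half-open (BED convention); cut sites are inter-base boundary indices, so
the forward cut of a plus-orientation fragment is ``start`` and the reverse
cut is ``end`` with no further shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import pysam

__all__ = [
    "Fragment",
    "load_fragments",
    "load_fragments_bed",
    "load_fragments_bam",
    "write_fragments_bed",
    "fractionate",
    "duplication_rate",
    "mark_duplicates",
]


@dataclass(frozen=True)
class Fragment:
    """One sequenced DNA fragment.

    Attributes
    ----------
    chrom : str
        Reference sequence name.
    start, end : int
        Outer fragment interval, 0-based half-open.
    s1 : int
        Inter-base boundary of mate R1's 5' end (a cut site).
    e2 : int
        Inter-base boundary of mate R2's 5' end (the other cut site).
    r1_strand : str
        Strand of mate R1, ``+`` or ``-``.
    """

    chrom: str
    start: int
    end: int
    s1: int
    e2: int
    r1_strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment must have start < end, got [{self.start}, {self.end})"
            )
        if self.r1_strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.r1_strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Duplicate grouping key: identical R1 start and R2 end, same strand."""
        return (self.chrom, self.s1, self.e2, self.r1_strand)


def _fragment_from_bed_fields(fields: list[str], lineno: int) -> Fragment:
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        strand = fields[5] if len(fields) >= 6 else "+"
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed BED line {lineno}: {fields!r}") from exc
    if strand == "+":
        s1, e2 = start, end
    else:
        s1, e2 = end, start
    return Fragment(chrom, start, end, s1, e2, strand)


def load_fragments_bed(path: Union[str, Path]) -> list[Fragment]:
    """Read fragments from a BED file (>= 3 columns; column 6 = R1 strand)."""
    frags: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            frags.append(_fragment_from_bed_fields(fields, lineno))
    return frags


def load_fragments_bam(
    path: Union[str, Path],
    min_mapq: int = 0,
) -> list[Fragment]:
    """Extract one Fragment per properly paired read pair from BAM/SAM.

    Only primary, non-supplementary, QC-pass alignments contribute.  Pairs
    are joined by query name; R1's 5' boundary becomes ``s1`` and R2's 5'
    boundary becomes ``e2``.  The fragment interval is the outer min/max of
    both mates' alignment boundaries (the bamtobed convention).  Unmatched
    reads are skipped.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    frags: list[Fragment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_paired
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
            ):
                continue
            if read.mapping_quality < min_mapq:
                continue
            name = read.query_name
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = read
                continue
            r1, r2 = (read, mate) if read.is_read1 else (mate, read)
            frags.append(_pair_to_fragment(r1, r2))
    n_skipped = len(pending)
    if n_skipped:
        # unmatched mates are counted but tolerated
        pass
    return frags


def _pair_to_fragment(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> Fragment:
    s1 = r1.reference_end if r1.is_reverse else r1.reference_start
    e2 = r2.reference_end if r2.is_reverse else r2.reference_start
    start = min(r1.reference_start, r2.reference_start)
    end = max(r1.reference_end, r2.reference_end)
    strand = "-" if r1.is_reverse else "+"
    return Fragment(r1.reference_name, start, end, s1, e2, strand)


def load_fragments(path: Union[str, Path], min_mapq: int = 0) -> list[Fragment]:
    """Load fragments from a BED, SAM, or BAM file, dispatching on suffix."""
    suffix = Path(path).suffix.lower()
    if suffix in (".bam", ".sam", ".cram"):
        return load_fragments_bam(path, min_mapq=min_mapq)
    return load_fragments_bed(path)


def write_fragments_bed(frags: Iterable[Fragment], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(frags):
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\tfrag{i}\t{f.length}\t{f.r1_strand}\n"
            )


def fractionate(
    frags: list[Fragment], threshold: float = 120
) -> tuple[list[Fragment], list[Fragment]]:
    """Partition fragments into (length <= threshold, length > threshold).

    ``threshold=math.inf`` disables fractionation (everything small).
    """
    small = [f for f in frags if f.length <= threshold]
    large = [f for f in frags if f.length > threshold]
    return small, large


def duplication_rate(frags: list[Fragment]) -> float:
    """Fraction of fragments sharing an identical (chrom, s1, e2, strand) key."""
    if not frags:
        return 0.0
    n_groups = len({f.key for f in frags})
    return (len(frags) - n_groups) / len(frags)


def mark_duplicates(
    frags: list[Fragment], remove: bool = False
) -> tuple[list[Fragment], list[bool]]:
    """Flag duplicate fragments; optionally keep one representative per group.

    Returns ``(fragments, is_duplicate)`` where the first occurrence of each
    key is not a duplicate.  With ``remove=True`` only the representatives
    are returned (flags then all False).
    """
    seen: set = set()
    flags: list[bool] = []
    kept: list[Fragment] = []
    for f in frags:
        dup = f.key in seen
        seen.add(f.key)
        flags.append(dup)
        if not dup:
            kept.append(f)
    if remove:
        return kept, [False] * len(kept)
    return list(frags), flags
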