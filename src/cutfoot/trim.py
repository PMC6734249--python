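"""Second-pass 3' adapter overhang trimming for short paired-end fragments.

Template-based trimmers miss read-through overhangs of 6 bp or less; this
stage removes the longest read suffix (1..max_overhang bp) that exactly
matches a prefix of the adapter, then drops pairs with a mate shorter than
the minimum alignable length.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_MAX_OVERHANG = 6
DEFAULT_MIN_LENGTH = 25


def _open_text_write(path: Union[str, Path]):
    """Text writer; gzip paths get mtime=0 so outputs are byte-reproducible."""
    import io

    if str(path).endswith(".gz"):
        # empty filename + fixed mtime keep the gzip header reproducible
        raw = gzip.GzipFile(
            filename="", mode="wb", fileobj=open(path, "wb"), mtime=0
        )
        return io.TextIOWrapper(raw)
    return open(path, "w")

__all__ = [
    "ReadPair",
    "TrimStats",
    "trim_overhang",
    "trim_pair",
    "filter_min_length",
    "trim_fastq_pair",
]


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.name}")


@dataclass
class TrimStats:
    """Counters consumed by the QC report."""

    pairs_in: int = 0
    pairs_out: int = 0
    pairs_dropped: int = 0
    reads_trimmed: int = 0
    bases_trimmed: int = 0

    @property
    def drop_pct(self) -> float:
        return 100.0 * self.pairs_dropped / self.pairs_in if self.pairs_in else 0.0

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__ | {"drop_pct": self.drop_pct}, fh, indent=2)


def trim_overhang(
    seq: str,
    qual: str,
    adapter: str = DEFAULT_ADAPTER,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> tuple[str, str, int]:
    """Remove the longest read suffix that exactly equals an adapter prefix.

    Tries k = max_overhang down to 1 and trims at the first exact match
    (longest wins; at most one trim).  Returns the trimmed sequence and
    quality plus the number of bases removed.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if max_overhang > len(adapter):
        raise ValueError("max_overhang exceeds adapter length")
    upper = min(max_overhang, len(seq))
    for k in range(upper, 0, -1):
        if seq[-k:] == adapter[:k]:
            return seq[:-k], qual[:-k], k
    return seq, qual, 0


def trim_pair(
    pair: ReadPair,
    adapter: str = DEFAULT_ADAPTER,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
) -> tuple[ReadPair, int, int]:
    s1, q1, k1 = trim_overhang(pair.seq1, pair.qual1, adapter, max_overhang)
    s2, q2, k2 = trim_overhang(pair.seq2, pair.qual2, adapter, max_overhang)
    return ReadPair(pair.name, s1, q1, s2, q2), k1, k2


def filter_min_length(pair: ReadPair, min_len: int = DEFAULT_MIN_LENGTH) -> bool:
    """Keep a pair only if both mates are at least ``min_len`` bp (inclusive)."""
    return len(pair.seq1) >= min_len and len(pair.seq2) >= min_len


def _read_fastq(path: Union[str, Path]) -> Iterator[tuple[str, str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:], seq, qual


def trim_fastq_pair(
    in1: Union[str, Path],
    in2: Union[str, Path],
    out1: Union[str, Path],
    out2: Union[str, Path],
    adapter: str = DEFAULT_ADAPTER,
    max_overhang: int = DEFAULT_MAX_OVERHANG,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> TrimStats:
    """Trim both mates of a paired FASTQ and drop under-length pairs.

    The whole pair is dropped when either mate falls below ``min_len``
    after trimming.
    """
    stats = TrimStats()
    with _open_text_write(out1) as fh1, _open_text_write(out2) as fh2:
        for (n1, s1, q1), (n2, s2, q2) in zip(
            _read_fastq(in1), _read_fastq(in2), strict=True
        ):
            stats.pairs_in += 1
            pair = ReadPair(n1, s1, q1, s2, q2)
            trimmed, k1, k2 = trim_pair(pair, adapter, max_overhang)
            stats.reads_trimmed += int(k1 > 0) + int(k2 > 0)
            stats.bases_trimmed += k1 + k2
            if not filter_min_length(trimmed, min_len):
                stats.pairs_dropped += 1
                continue
            stats.pairs_out += 1
            fh1.write(f"@{n1}\n{trimmed.seq1}\n+\n{trimmed.qual1}\n")
            fh2.write(f"@{n2}\n{trimmed.seq2}\n+\n{trimmed.qual2}\n")
    return stats
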