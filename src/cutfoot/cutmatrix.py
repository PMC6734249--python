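"""Strand-specific, motif-oriented cut matrices at single-nucleotide resolution.

Rows are motif sites, columns are inter-base positions in an oriented window
of ``motif_length + 2*flank`` around each site.  A count in column *i* means
a cut situated just before oriented nucleotide *i*.  For minus-strand sites
the column axis is mirrored and the forward/reverse labels swap, so that all
rows share one orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .fragments import Fragment

__all__ = [
    "MotifSite",
    "CutMatrix",
    "CutSiteOffsets",
    "assign_cut_positions",
    "build_cut_matrix",
    "aggregate_profile",
    "write_cut_tracks",
    "load_motif_sites_bed",
    "write_motif_sites_bed",
]


@dataclass(frozen=True)
class MotifSite:
    """One motif occurrence (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str = "motif"
    score: Optional[float] = None
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"motif site must have start < end: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.site_id is None:
            object.__setattr__(
                self,
                "site_id",
                f"{self.chrom}:{self.start}-{self.end}({self.strand})",
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CutSiteOffsets:
    """Genomic shifts applied to cut boundaries before window mapping.

    CUT&RUN leaves blunt ends, so the default is (0, 0).  ATAC-seq-style
    data needs the transposase overhang correction, e.g. ``(4, -4)``.
    """

    forward: int = 0
    reverse: int = 0


@dataclass
class CutMatrix:
    sites: list[MotifSite]
    flank: int
    forward_counts: np.ndarray  # (n_sites, W) int
    reverse_counts: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def width(self) -> int:
        return self.forward_counts.shape[1]

    def combined(self) -> np.ndarray:
        return self.forward_counts + self.reverse_counts

    def row_totals(self) -> np.ndarray:
        """Per-site total fragment-end count R."""
        return self.forward_counts.sum(axis=1) + self.reverse_counts.sum(axis=1)

    def to_tsv(self, path_forward: Union[str, Path], path_reverse: Union[str, Path]) -> None:
        for path, mat in ((path_forward, self.forward_counts), (path_reverse, self.reverse_counts)):
            with open(path, "w") as fh:
                for site, row in zip(self.sites, mat):
                    fh.write(site.site_id + "\t" + "\t".join(map(str, row.tolist())) + "\n")


def assign_cut_positions(
    fragment: Fragment,
    site: MotifSite,
    flank: int = 100,
    offsets: CutSiteOffsets = CutSiteOffsets(),
) -> list[tuple[str, int]]:
    """Map a fragment's two cut boundaries into a site's oriented window.

    Returns a list of ``(strand_label, column)`` pairs, where strand_label is
    ``"forward"`` or ``"reverse"`` and column indexes the oriented window
    ``[site.start - flank, site.end + flank)`` of width W.  For plus-strand
    sites, ``s1`` is the forward cut and ``e2`` the reverse cut; for
    minus-strand sites the labels swap and columns flip to ``W - 1 - col``.
    Boundaries falling outside the window are dropped.
    """
    if fragment.chrom != site.chrom:
        return []
    win_start = site.start - flank
    width = site.length + 2 * flank
    out: list[tuple[str, int]] = []
    for boundary, label in (
        (fragment.s1 + offsets.forward, "forward"),
        (fragment.e2 + offsets.reverse, "reverse"),
    ):
        col = boundary - win_start
        if not 0 <= col < width:
            continue
        if site.strand == "-":
            col = width - 1 - col
            label = "reverse" if label == "forward" else "forward"
        out.append((label, col))
    return out


def build_cut_matrix(
    fragments: Sequence[Fragment],
    sites: Sequence[MotifSite],
    flank: int = 100,
    offsets: CutSiteOffsets = CutSiteOffsets(),
) -> CutMatrix:
    """Tabulate fragment-end cuts over all sites into a CutMatrix.

    All sites must share one motif length.  Row order equals input site
    order.  Uses a sorted-boundary sweep per chromosome so the cost is
    O((F + S) log S) rather than F x S.
    """
    sites = list(sites)
    if sites:
        lengths = {s.length for s in sites}
        if len(lengths) > 1:
            raise ValueError(f"mixed motif lengths in site list: {sorted(lengths)}")
        width = sites[0].length + 2 * flank
    else:
        width = 2 * flank
    fwd = np.zeros((len(sites), width), dtype=np.int64)
    rev = np.zeros((len(sites), width), dtype=np.int64)

    # index sites per chromosome by window start for fast boundary lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for idx, site in enumerate(sites):
        by_chrom.setdefault(site.chrom, ([], []))  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int]]] = {c: [] for c in by_chrom}
    for idx, site in enumerate(sites):
        tmp[site.chrom].append((site.start - flank, idx))
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in tmp.items():
        pairs.sort()
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        idxs = np.array([p[1] for p in pairs], dtype=np.int64)
        index[chrom] = (starts, idxs)

    for frag in fragments:
        entry = index.get(frag.chrom)
        if entry is None:
            continue
        starts, idxs = entry
        for boundary, base_label in (
            (frag.s1 + offsets.forward, "forward"),
            (frag.e2 + offsets.reverse, "reverse"),
        ):
            # windows with win_start in (boundary - width, boundary] can contain it
            lo = np.searchsorted(starts, boundary - width + 1, side="left")
            hi = np.searchsorted(starts, boundary, side="right")
            for j in range(lo, hi):
                site_idx = int(idxs[j])
                site = sites[site_idx]
                col = boundary - int(starts[j])
                if not 0 <= col < width:
                    continue
                label = base_label
                if site.strand == "-":
                    col = width - 1 - col
                    label = "reverse" if label == "forward" else "forward"
                if label == "forward":
                    fwd[site_idx, col] += 1
                else:
                    rev[site_idx, col] += 1
    return CutMatrix(sites=sites, flank=flank, forward_counts=fwd, reverse_counts=rev)


def aggregate_profile(m: CutMatrix) -> dict[str, np.ndarray]:
    """Column totals of the cut matrix: forward, reverse, and combined."""
    forward = m.forward_counts.sum(axis=0)
    reverse = m.reverse_counts.sum(axis=0)
    return {"forward": forward, "reverse": reverse, "combined": forward + reverse}


def write_aggregate_tsv(m: CutMatrix, path: Union[str, Path]) -> None:
    prof = aggregate_profile(m)
    with open(path, "w") as fh:
        fh.write("position\tforward\treverse\tcombined\n")
        for i in range(m.width):
            fh.write(
                f"{i}\t{prof['forward'][i]}\t{prof['reverse'][i]}\t{prof['combined'][i]}\n"
            )


def write_cut_tracks(
    fragments: Sequence[Fragment],
    region: tuple[str, int, int],
    path_forward: Union[str, Path],
    path_reverse: Union[str, Path],
    offsets: CutSiteOffsets = CutSiteOffsets(),
) -> None:
    """Export per-base strand-specific cut counts in a region as bedGraph.

    Forward counts come from ``s1`` boundaries, reverse from ``e2``.
    Intervals are 0-based half-open; zero-count bases are omitted.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"invalid region {region}")
    n = end - start
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for frag in fragments:
        if frag.chrom != chrom:
            continue
        b1 = frag.s1 + offsets.forward
        b2 = frag.e2 + offsets.reverse
        if start <= b1 < end:
            fwd[b1 - start] += 1
        if start <= b2 < end:
            rev[b2 - start] += 1
    for path, track in ((path_forward, fwd), (path_reverse, rev)):
        with open(path, "w") as fh:
            for i in np.nonzero(track)[0]:
                pos = start + int(i)
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{int(track[i])}\n")


def load_motif_sites_bed(path: Union[str, Path], motif_id: Optional[str] = None) -> list[MotifSite]:
    """Read motif occurrences from BED6 (name column = motif id)."""
    sites: list[MotifSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"motif BED needs 6 columns, line {lineno}: {line!r}")
            try:
                score = float(fields[4]) if fields[4] not in (".", "") else None
                sites.append(
                    MotifSite(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        strand=fields[5],
                        motif_id=motif_id or fields[3],
                        score=score,
                        site_id=f"site{lineno - 1}_{fields[0]}:{fields[1]}-{fields[2]}",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed motif BED line {lineno}: {line!r}") from exc
    return sites


def write_motif_sites_bed(sites: Iterable[MotifSite], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            score = "." if s.score is None else f"{s.score:g}"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.motif_id}\t{score}\t{s.strand}\n")
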