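"""Synthetic fixture generator: fragments, motif sites, peaks, and FASTQ.

Everything downstream (trimming, cut matrices, the mixture model, symmetry
scoring, binding calls, QC) is testable offline against the ground truth
emitted here.  Bound sites draw fragment-end positions from a configurable
per-position cut-probability vector; unbound sites cut uniformly.  Per-site
end totals follow a negative binomial.  No genome sequence is needed:
coordinates live on synthetic contigs, one per site, so fragments from
different sites never cross-contaminate windows.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cutmatrix import MotifSite
from .fragments import Fragment

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "SimulatedReadPair",
    "default_lambda_template",
    "simulate_fragments",
    "simulate_fastq",
    "write_truth_tsv",
    "write_fastq_pair",
]

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # Illumina TruSeq read-through


def default_lambda_template(motif_length: int, flank: int, depth: float = 0.05,
                            rate: float = 0.04) -> np.ndarray:
    """Symmetric center-depleted cut-probability template.

    Flanks rise exponentially toward the motif edges; the motif core sits on
    a low plateau.  Normalized to sum to 1 over ``motif_length + 2*flank``
    positions.
    """
    w = motif_length + 2 * flank
    prof = np.empty(w, dtype=float)
    left = np.exp(rate * np.arange(flank))       # ascending toward the core
    prof[:flank] = left
    prof[flank:flank + motif_length] = left[-1] * depth
    prof[flank + motif_length:] = left[::-1]
    return prof / prof.sum()


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for the fragment/FASTQ simulator."""

    n_bound_sites: int = 300
    n_unbound_sites: int = 200
    motif_length: int = 6
    flank: int = 100
    lambda_truth: Optional[np.ndarray] = None
    nb_mean_bound: float = 40.0
    nb_mean_unbound: float = 8.0
    nb_size_bound: float = 10.0
    nb_size_unbound: float = 10.0
    frag_len_range: tuple[int, int] = (250, 400)
    duplicate_fraction: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER
    read_length: int = 42
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bound_sites < 0 or self.n_unbound_sites < 0:
            raise ValueError("site counts must be >= 0")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if self.flank < 0 or self.motif_length <= 0:
            raise ValueError("flank >= 0 and motif_length > 0 required")
        lam = self.lambda_truth
        if lam is not None:
            lam = np.asarray(lam, dtype=float)
            if lam.shape != (self.window_width,):
                raise ValueError(
                    f"lambda_truth must have length motif_length + 2*flank "
                    f"= {self.window_width}, got {lam.shape}"
                )
            if np.any(lam < 0) or abs(lam.sum() - 1.0) > 1e-9:
                raise ValueError("lambda_truth must be non-negative and sum to 1")
            object.__setattr__(self, "lambda_truth", lam)

    @property
    def window_width(self) -> int:
        return self.motif_length + 2 * self.flank

    def resolved_lambda(self) -> np.ndarray:
        if self.lambda_truth is not None:
            return np.asarray(self.lambda_truth, dtype=float)
        return default_lambda_template(self.motif_length, self.flank)


@dataclass
class SimulatedDataset:
    fragments: list[Fragment]
    sites: list[MotifSite]
    truth: list[bool]              # per-site bound flag, aligned with sites
    site_totals: list[int]         # drawn R per site (pre-duplication)
    peaks: list[tuple[str, int, int]]
    params: SimulationParams


def _emit_fragment(chrom: str, boundary: int, label: str, site_strand: str,
                   width: int, length: int) -> Fragment:
    """Build a fragment whose s1 or e2 lands exactly on ``boundary``.

    ``label`` is the oriented strand label the cut should get in the cut
    matrix.  The partner end is pushed ``length`` bp away; callers choose
    ``length > width`` so it falls outside every site window.
    """
    if site_strand == "-":
        # labels swap during orientation flipping, so pre-swap here
        label = "reverse" if label == "forward" else "forward"
    if label == "forward":
        # boundary must be s1: R1 forward, fragment extends right
        return Fragment(chrom, boundary, boundary + length,
                        s1=boundary, e2=boundary + length, r1_strand="+")
    # boundary must be e2: R2 reverse end, fragment extends left
    return Fragment(chrom, boundary - length, boundary,
                    s1=boundary - length, e2=boundary, r1_strand="+")


def simulate_fragments(params: SimulationParams) -> SimulatedDataset:
    """Draw stranded fragments around simulated motif sites.

    Bound sites place their drawn number of fragment ends according to
    ``lambda_truth`` over the oriented window; unbound sites place them
    uniformly.  Minus-strand sites are emitted mirror-imaged so that the
    cut-matrix orientation flip recovers the same oriented profile.  A
    ``duplicate_fraction`` of the final fragment list are exact copies.
    """
    rng = np.random.default_rng(params.seed)
    lam = params.resolved_lambda()
    width = params.window_width
    lo, hi = params.frag_len_range
    if lo <= width:
        lo = width + 1          # partner end must clear the window
        hi = max(hi, lo + 1)

    n_sites = params.n_bound_sites + params.n_unbound_sites
    bound_flags = np.zeros(n_sites, dtype=bool)
    bound_flags[: params.n_bound_sites] = True
    rng.shuffle(bound_flags)

    site_spacing = 10 * hi
    fragments: list[Fragment] = []
    sites: list[MotifSite] = []
    totals: list[int] = []
    peaks: list[tuple[str, int, int]] = []
    uniform = np.full(width, 1.0 / width)

    for i, bound in enumerate(bound_flags):
        chrom = f"ctg{i}"
        motif_start = site_spacing
        strand = "+" if rng.random() < 0.5 else "-"
        site = MotifSite(chrom, motif_start, motif_start + params.motif_length,
                         strand, motif_id="SIM", site_id=f"sim_site{i}")
        sites.append(site)
        peaks.append((chrom, motif_start - params.flank - 50,
                      motif_start + params.motif_length + params.flank + 50))
        if bound:
            r = _draw_nb(rng, params.nb_mean_bound, params.nb_size_bound)
            probs = lam
        else:
            r = _draw_nb(rng, params.nb_mean_unbound, params.nb_size_unbound)
            probs = uniform
        totals.append(int(r))
        if r == 0:
            continue
        cols = rng.choice(width, size=r, p=probs)
        labels = rng.random(r) < 0.5
        win_start = motif_start - params.flank
        for col, is_fwd in zip(cols, labels):
            # invert the cut-matrix orientation mapping
            genomic_col = int(col) if strand == "+" else width - 1 - int(col)
            boundary = win_start + genomic_col
            length = int(rng.integers(lo, hi + 1))
            fragments.append(
                _emit_fragment(chrom, boundary, "forward" if is_fwd else "reverse",
                               strand, width, length)
            )

    if params.duplicate_fraction > 0 and fragments:
        n = len(fragments)
        n_extra = int(round(params.duplicate_fraction / (1 - params.duplicate_fraction) * n))
        picks = rng.integers(0, n, size=n_extra)
        fragments.extend(fragments[int(j)] for j in picks)

    return SimulatedDataset(
        fragments=fragments,
        sites=sites,
        truth=[bool(b) for b in bound_flags],
        site_totals=totals,
        peaks=peaks,
        params=params,
    )


def _draw_nb(rng: np.random.Generator, mean: float, size: float) -> int:
    """One negative-binomial draw parameterized by (mean, size)."""
    if mean <= 0:
        return 0
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


@dataclass(frozen=True)
class SimulatedReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    insert_length: int
    overhang: int  # adapter bases on each 3' end; read_length - insert, clipped


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    arr = np.frombuffer(alphabet.encode(), dtype="S1")
    return b"".join(rng.choice(arr, size=n)).decode()


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_fastq(
    params: SimulationParams,
    n_pairs: int,
    insert_lengths: Optional[Sequence[int]] = None,
    adapter_free_inserts: bool = False,
) -> list[SimulatedReadPair]:
    """Generate paired reads with adapter read-through on short inserts.

    Each pair sequences a random insert from both ends with reads of
    ``params.read_length``.  Inserts shorter than the read length leave
    ``read_length - insert`` adapter bases on the 3' end of both mates.
    ``adapter_free_inserts`` draws insert sequence from an alphabet missing
    the adapter's first base, so the true overhang is exactly recoverable by
    an exact-match trimmer.
    """
    if params.read_length <= 0:
        raise ValueError("read_length must be > 0")
    if not params.adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    rng = np.random.default_rng(params.seed + 1)
    rl = params.read_length
    adapter = params.adapter_seq
    alphabet = "ACGT"
    if adapter_free_inserts:
        # both mates must be safe: R2 is the reverse complement, so the
        # alphabet also has to exclude the complement of the adapter start
        banned = {adapter[0], adapter[0].translate(_COMP)}
        alphabet = "".join(b for b in "ACGT" if b not in banned)
    if insert_lengths is None:
        lo, hi = params.frag_len_range
        insert_lengths = rng.integers(lo, hi + 1, size=n_pairs)
    else:
        insert_lengths = list(insert_lengths)
        if len(insert_lengths) != n_pairs:
            raise ValueError("insert_lengths must have n_pairs entries")

    pairs: list[SimulatedReadPair] = []
    for i in range(n_pairs):
        ins_len = int(insert_lengths[i])
        insert = _random_seq(rng, ins_len, alphabet)
        read1 = _with_adapter(insert, adapter, rl)
        read2 = _with_adapter(revcomp(insert), adapter, rl)
        overhang = min(max(rl - ins_len, 0), rl - 1) if ins_len < rl else 0
        pairs.append(
            SimulatedReadPair(
                name=f"simread{i}",
                seq1=read1, qual1="I" * len(read1),
                seq2=read2, qual2="I" * len(read2),
                insert_length=ins_len,
                overhang=overhang,
            )
        )
    return pairs


def _with_adapter(template: str, adapter: str, read_length: int) -> str:
    if len(template) >= read_length:
        return template[:read_length]
    n_adapter = read_length - len(template)
    tail = (adapter * (n_adapter // len(adapter) + 1))[:n_adapter]
    return template + tail


def write_fastq_pair(
    pairs: Sequence[SimulatedReadPair],
    path1: Union[str, Path],
    path2: Union[str, Path],
) -> None:
    """Write mates to two FASTQ files (gzipped when the path ends in .gz)."""
    from .trim import _open_text_write

    for path, which in ((path1, 1), (path2, 2)):
        with _open_text_write(path) as fh:
            for p in pairs:
                seq = p.seq1 if which == 1 else p.seq2
                qual = p.qual1 if which == 1 else p.qual2
                fh.write(f"@{p.name}/{which}\n{seq}\n+\n{qual}\n")


def write_truth_tsv(ds: SimulatedDataset, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tbound\tn_ends\n")
        for site, bound, r in zip(ds.sites, ds.truth, ds.site_totals):
            fh.write(f"{site.site_id}\t{int(bound)}\t{r}\n")


def write_peaks_bed(peaks: Sequence[tuple[str, int, int]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(peaks):
            fh.write(f"{chrom}\t{max(start, 0)}\t{end}\tpeak{i}\t0\t.\n")
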