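"""Quality-control metrics: fragment sizes, adapter loss, duplication,
alignment rate, peak count and motif enrichment, with pass/warn flags.

Thresholds follow common practice for nuclease-release assays: adapter loss
above 15% of pairs, library size below 10 million pairs, duplication above
15%, or concordant alignment below 90% each raise a warning flag.  There is
deliberately no single overall verdict — only per-metric flags.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .binding import Interval, _IntervalIndex
from .cutmatrix import MotifSite
from .fragments import Fragment, duplication_rate

__all__ = ["QCThresholds", "QCReport", "fragment_size_histogram", "compute_qc"]


@dataclass(frozen=True)
class QCThresholds:
    adapter_loss_warn_pct: float = 15.0
    library_size_warn: int = 10_000_000
    duplication_warn_pct: float = 15.0
    alignment_warn_pct: float = 90.0
    small_fraction_bp: int = 120


@dataclass
class QCReport:
    fragment_size_histogram: dict[int, int]
    small_fraction: Optional[float]  # share of fragments <= 120 bp
    adapter_loss_pct: Optional[float]
    library_size: Optional[int]
    duplication_rate_pct: Optional[float]
    alignment_pct: Optional[float]
    n_peaks: Optional[int]
    expected_motif_enrichment: Optional[float]  # fraction of peaks with >= 1 site
    flags: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = dict(self.__dict__)
        payload["fragment_size_histogram"] = {
            str(k): v for k, v in self.fragment_size_histogram.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "QCReport":
        with open(path) as fh:
            d = json.load(fh)
        d["fragment_size_histogram"] = {
            int(k): v for k, v in d["fragment_size_histogram"].items()
        }
        return cls(**d)

    def summary(self) -> str:
        def fmt(v, suffix=""):
            return "n/a" if v is None else f"{v:,}{suffix}" if isinstance(v, int) else f"{v:.2f}{suffix}"

        lines = [
            "QC summary",
            f"  library size:        {fmt(self.library_size)} pairs [{self.flags.get('library_size', 'n/a')}]",
            f"  adapter loss:        {fmt(self.adapter_loss_pct, '%')} [{self.flags.get('adapter_loss', 'n/a')}]",
            f"  duplication rate:    {fmt(self.duplication_rate_pct, '%')} [{self.flags.get('duplication', 'n/a')}]",
            f"  alignment:           {fmt(self.alignment_pct, '%')} [{self.flags.get('alignment', 'n/a')}]",
            f"  fragments <= 120 bp: {fmt(None if self.small_fraction is None else 100 * self.small_fraction, '%')}",
            f"  peaks:               {fmt(self.n_peaks)}",
            f"  motif enrichment:    {fmt(self.expected_motif_enrichment)} (fraction of peaks with a motif site)",
        ]
        return "\n".join(lines)


def fragment_size_histogram(frags: Sequence[Fragment]) -> dict[int, int]:
    """Exact integer histogram of fragment lengths (end - start)."""
    return dict(sorted(Counter(f.length for f in frags).items()))


def compute_qc(
    fragments: Sequence[Fragment] = (),
    trim_counters: Optional[dict] = None,
    alignment_summary: Optional[dict] = None,
    peaks: Optional[Sequence[Interval]] = None,
    motif_sites: Optional[Sequence[MotifSite]] = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Assemble the QC report from whatever upstream artifacts exist.

    Missing inputs yield metric = None (never a crash).  ``trim_counters``
    is the trim stage's JSON (``pairs_in``/``pairs_dropped``);
    ``alignment_summary`` is user-supplied (``concordant_pct``,
    optionally ``library_size``) since alignment happens outside this
    package.  Boundary convention: warn flags fire strictly beyond each
    threshold, so a value exactly at the limit passes.
    """
    hist = fragment_size_histogram(fragments)
    total = sum(hist.values())
    small_fraction = (
        sum(v for k, v in hist.items() if k <= thresholds.small_fraction_bp) / total
        if total
        else None
    )

    adapter_loss_pct: Optional[float] = None
    library_size: Optional[int] = None
    if trim_counters:
        pairs_in = trim_counters.get("pairs_in")
        dropped = trim_counters.get("pairs_dropped")
        if pairs_in:
            library_size = int(pairs_in)
            if dropped is not None:
                adapter_loss_pct = 100.0 * dropped / pairs_in
    if alignment_summary and alignment_summary.get("library_size") is not None:
        library_size = int(alignment_summary["library_size"])

    duplication_pct = 100.0 * duplication_rate(list(fragments)) if fragments else None

    alignment_pct: Optional[float] = None
    if alignment_summary and alignment_summary.get("concordant_pct") is not None:
        alignment_pct = float(alignment_summary["concordant_pct"])

    n_peaks = len(peaks) if peaks is not None else None
    enrichment: Optional[float] = None
    if peaks is not None and motif_sites is not None and len(peaks) > 0:
        site_index = _IntervalIndex((s.chrom, s.start, s.end) for s in motif_sites)
        with_motif = sum(1 for p in peaks if site_index.overlaps(*p))
        enrichment = with_motif / len(peaks)

    flags: dict[str, str] = {}

    def flag(name: str, value: Optional[float], warn_if: bool) -> None:
        if value is None:
            flags[name] = "n/a"
        else:
            flags[name] = "warn" if warn_if else "pass"

    flag(
        "adapter_loss",
        adapter_loss_pct,
        adapter_loss_pct is not None and adapter_loss_pct > thresholds.adapter_loss_warn_pct,
    )
    flag(
        "library_size",
        library_size,
        library_size is not None and library_size < thresholds.library_size_warn,
    )
    flag(
        "duplication",
        duplication_pct,
        duplication_pct is not None and duplication_pct > thresholds.duplication_warn_pct,
    )
    flag(
        "alignment",
        alignment_pct,
        alignment_pct is not None and alignment_pct < thresholds.alignment_warn_pct,
    )

    return QCReport(
        fragment_size_histogram=hist,
        small_fraction=small_fraction,
        adapter_loss_pct=adapter_loss_pct,
        library_size=library_size,
        duplication_rate_pct=duplication_pct,
        alignment_pct=alignment_pct,
        n_peaks=n_peaks,
        expected_motif_enrichment=enrichment,
        flags=flags,
    )
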