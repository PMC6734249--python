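from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from cutfoot.cutmatrix import CutMatrix, MotifSite
from cutfoot.fragments import Fragment
from cutfoot.sim import SimulationParams, default_lambda_template, simulate_fragments


def brute_force_cut_matrix(fragments, sites, flank=100):
    """Independent per-base-scan oracle for the cut matrix.

    For every site and every window column, scan all fragments and count
    boundary coincidences directly, applying the minus-strand base flip and
    strand-label swap by explicit case analysis.
    """
    if sites:
        width = sites[0].length + 2 * flank
    else:
        width = 2 * flank
    fwd = np.zeros((len(sites), width), dtype=np.int64)
    rev = np.zeros((len(sites), width), dtype=np.int64)
    for i, site in enumerate(sites):
        win_start = site.start - flank
        for col in range(width):
            boundary = win_start + col
            n_s1 = sum(
                1 for f in fragments if f.chrom == site.chrom and f.s1 == boundary
            )
            n_e2 = sum(
                1 for f in fragments if f.chrom == site.chrom and f.e2 == boundary
            )
            if site.strand == "+":
                fwd[i, col] += n_s1
                rev[i, col] += n_e2
            else:
                fwd[i, width - 1 - col] += n_e2
                rev[i, width - 1 - col] += n_s1
    return fwd, rev


def random_toy_set(rng, max_fragments=50, max_sites=5, flank=8, motif_length=5):
    """Random fragments and sites on a couple of small contigs."""
    n_sites = int(rng.integers(1, max_sites + 1))
    n_frags = int(rng.integers(0, max_fragments + 1))
    chroms = ["ctgA", "ctgB"]
    sites = []
    for j in range(n_sites):
        start = int(rng.integers(flank, 120))
        sites.append(
            MotifSite(
                chrom=chroms[int(rng.integers(0, 2))],
                start=start,
                end=start + motif_length,
                strand="+" if rng.random() < 0.5 else "-",
                motif_id="TOY",
                site_id=f"toy{j}",
            )
        )
    frags = []
    for _ in range(n_frags):
        start = int(rng.integers(0, 150))
        length = int(rng.integers(1, 60))
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + length
        s1, e2 = (start, end) if strand == "+" else (end, start)
        frags.append(
            Fragment(
                chrom=chroms[int(rng.integers(0, 2))],
                start=start,
                end=end,
                s1=s1,
                e2=e2,
                r1_strand=strand,
            )
        )
    return frags, sites


@pytest.fixture(scope="session")
def recovery_dataset():
    """The 500-site parameter-recovery simulation used by the model tests."""
    params = SimulationParams(
        n_bound_sites=300,
        n_unbound_sites=200,
        motif_length=6,
        flank=100,
        nb_mean_bound=40.0,
        nb_mean_unbound=8.0,
        seed=42,
    )
    return simulate_fragments(params), params


def write_sam(path: Path, pairs, contig="chr1", contig_len=100000) -> None:
    """Write a SAM file from (name, r1_start, r1_len, r1_rev, r2_start, r2_len, r2_rev)."""
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{contig}\tLN:{contig_len}",
    ]
    records = []
    for name, r1s, r1l, r1rev, r2s, r2l, r2rev in pairs:
        f1 = 0x1 | 0x2 | 0x40 | (0x10 if r1rev else 0) | (0x20 if r2rev else 0)
        f2 = 0x1 | 0x2 | 0x80 | (0x10 if r2rev else 0) | (0x20 if r1rev else 0)
        records.append((r1s, f"{name}\t{f1}\t{contig}\t{r1s + 1}\t60\t{r1l}M\t=\t{r2s + 1}\t0\t{'A' * r1l}\t{'I' * r1l}"))
        records.append((r2s, f"{name}\t{f2}\t{contig}\t{r2s + 1}\t60\t{r2l}M\t=\t{r1s + 1}\t0\t{'A' * r2l}\t{'I' * r2l}"))
    records.sort(key=lambda r: r[0])
    lines.extend(r[1] for r in records)
    path.write_text("\n".join(lines) + "\n")
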