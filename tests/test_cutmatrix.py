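import numpy as np
import pytest

from cutfoot.cutmatrix import (
    CutSiteOffsets,
    MotifSite,
    aggregate_profile,
    assign_cut_positions,
    build_cut_matrix,
    write_cut_tracks,
)
from cutfoot.fragments import Fragment
from cutfoot.sim import SimulationParams, simulate_fragments

from conftest import brute_force_cut_matrix, random_toy_set


def frag(start, end, chrom="chr1", strand="+"):
    s1, e2 = (start, end) if strand == "+" else (end, start)
    return Fragment(chrom, start, end, s1, e2, strand)


class TestAssignCutPositions:
    def test_plus_site_manual_enumeration(self):
        f = frag(115, 130)
        site = MotifSite("chr1", 120, 126, "+")
        got = sorted(assign_cut_positions(f, site, flank=10))
        assert got == [("forward", 5), ("reverse", 20)]

    def test_minus_site_flip_and_swap(self):
        f = frag(115, 130)
        site = MotifSite("chr1", 120, 126, "-")
        got = sorted(assign_cut_positions(f, site, flank=10))
        # flip formula: 26-1-5 = 20 and 26-1-20 = 5, labels swapped
        assert got == [("forward", 5), ("reverse", 20)]

    def test_fragment_outside_window(self):
        f = frag(500, 600)
        site = MotifSite("chr1", 120, 126, "+")
        assert assign_cut_positions(f, site, flank=10) == []

    def test_one_end_in_window(self):
        f = frag(115, 400)
        site = MotifSite("chr1", 120, 126, "+")
        assert assign_cut_positions(f, site, flank=10) == [("forward", 5)]

    def test_window_edge_exclusive(self):
        # e2 exactly at win_start + W is outside the half-open window
        site = MotifSite("chr1", 120, 126, "+")
        f = frag(110, 136)
        got = assign_cut_positions(f, site, flank=10)
        assert ("reverse", 26) not in got
        assert got == [("forward", 0)]

    def test_wrong_chrom(self):
        f = frag(115, 130, chrom="chr2")
        site = MotifSite("chr1", 120, 126, "+")
        assert assign_cut_positions(f, site, flank=10) == []


class TestBuildCutMatrix:
    def test_zero_fragments_all_zero(self):
        sites = [MotifSite("chr1", 100, 106, "+"), MotifSite("chr1", 300, 306, "-")]
        m = build_cut_matrix([], sites, flank=10)
        assert m.forward_counts.shape == (2, 26)
        assert m.forward_counts.sum() == 0 and m.reverse_counts.sum() == 0

    def test_mixed_motif_lengths_rejected(self):
        sites = [MotifSite("chr1", 100, 106, "+"), MotifSite("chr1", 300, 310, "+")]
        with pytest.raises(ValueError, match="mixed motif lengths"):
            build_cut_matrix([], sites, flank=10)

    def test_fragment_overlapping_two_sites(self):
        sites = [
            MotifSite("chr1", 100, 105, "+", site_id="a"),
            MotifSite("chr1", 110, 115, "+", site_id="b"),
        ]
        f = frag(100, 112)
        m = build_cut_matrix([f], sites, flank=20)
        # both ends fall in both windows -> 4 total entries
        assert m.forward_counts.sum() + m.reverse_counts.sum() == 4
        assert m.row_totals().tolist() == [2, 2]

    def test_matches_brute_force_oracle_small(self):
        rng = np.random.default_rng(0)
        frags, sites = random_toy_set(rng, max_fragments=10, max_sites=3)
        m = build_cut_matrix(frags, sites, flank=8)
        fwd, rev = brute_force_cut_matrix(frags, sites, flank=8)
        np.testing.assert_array_equal(m.forward_counts, fwd)
        np.testing.assert_array_equal(m.reverse_counts, rev)

    def test_conservation_of_end_incidences(self):
        rng = np.random.default_rng(1)
        frags, sites = random_toy_set(rng)
        m = build_cut_matrix(frags, sites, flank=8)
        flank = 8
        n_incidences = 0
        for site in sites:
            lo, hi = site.start - flank, site.end + flank
            for f in frags:
                if f.chrom != site.chrom:
                    continue
                n_incidences += int(lo <= f.s1 < hi) + int(lo <= f.e2 < hi)
        assert int(m.forward_counts.sum() + m.reverse_counts.sum()) == n_incidences

    def test_simulator_round_trip_recovers_lambda(self):
        params = SimulationParams(
            n_bound_sites=400, n_unbound_sites=0, motif_length=6, flank=100,
            nb_mean_bound=250.0, duplicate_fraction=0.0, seed=9,
        )
        ds = simulate_fragments(params)
        m = build_cut_matrix(ds.fragments, ds.sites, flank=100)
        prof = aggregate_profile(m)["combined"].astype(float)
        assert prof.sum() >= 1e5 * 0.8  # sanity: enough ends drawn
        emp = prof / prof.sum()
        tv = 0.5 * np.abs(emp - params.resolved_lambda()).sum()
        assert tv < 0.02

    def test_mirror_invariance_exact(self):
        """Reflecting the genome leaves the oriented matrix unchanged.

        Physical mirror: fragment boundaries reflect as b -> L - b with mate
        identities relabeled (R1 <-> R2); site intervals reflect with a one
        base offset, (start, end) -> (L+1-end, L+1-start), which compensates
        the base-anchored (rather than boundary-anchored) minus-strand
        column flip. Strands invert on both.
        """
        rng = np.random.default_rng(3)
        frags, sites = random_toy_set(rng, max_fragments=40, max_sites=4)
        L = 1000
        m = build_cut_matrix(frags, sites, flank=8)

        mfrags = [
            Fragment(f.chrom, L - f.end, L - f.start,
                     s1=L - f.e2, e2=L - f.s1,
                     r1_strand="-" if f.r1_strand == "+" else "+")
            for f in frags
        ]
        msites = [
            MotifSite(s.chrom, L + 1 - s.end, L + 1 - s.start,
                      "-" if s.strand == "+" else "+",
                      s.motif_id, s.score, s.site_id)
            for s in sites
        ]
        mm = build_cut_matrix(mfrags, msites, flank=8)
        np.testing.assert_array_equal(m.forward_counts, mm.forward_counts)
        np.testing.assert_array_equal(m.reverse_counts, mm.reverse_counts)

    def test_offset_shifts_columns(self):
        rng = np.random.default_rng(4)
        frags, _ = random_toy_set(rng, max_fragments=30, max_sites=1)
        site = MotifSite("ctgA", 60, 66, "+", site_id="s")
        base = build_cut_matrix(frags, [site], flank=20)
        shifted = build_cut_matrix(
            frags, [site], flank=20, offsets=CutSiteOffsets(4, -5)
        )
        w = base.width
        # interior columns shift exactly by the configured offsets
        np.testing.assert_array_equal(
            shifted.forward_counts[0, 4:], base.forward_counts[0, : w - 4]
        )
        np.testing.assert_array_equal(
            shifted.reverse_counts[0, : w - 5], base.reverse_counts[0, 5:]
        )


class TestAggregateProfile:
    def test_single_row_equals_row(self):
        site = MotifSite("chr1", 100, 106, "+")
        frags = [frag(95, 300), frag(103, 260)]
        m = build_cut_matrix(frags, [site], flank=10)
        prof = aggregate_profile(m)
        np.testing.assert_array_equal(prof["forward"], m.forward_counts[0])
        np.testing.assert_array_equal(
            prof["combined"], m.forward_counts[0] + m.reverse_counts[0]
        )

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(6)
        frags, sites = random_toy_set(rng, max_fragments=40, max_sites=5)
        m = build_cut_matrix(frags, sites, flank=8)
        perm = rng.permutation(len(sites))
        m2 = build_cut_matrix(frags, [sites[i] for i in perm], flank=8)
        for key in ("forward", "reverse", "combined"):
            np.testing.assert_array_equal(
                aggregate_profile(m)[key], aggregate_profile(m2)[key]
            )

    def test_unbound_profile_flat(self):
        params = SimulationParams(
            n_bound_sites=0, n_unbound_sites=300, motif_length=6, flank=50,
            nb_mean_unbound=100.0, seed=2,
        )
        ds = simulate_fragments(params)
        m = build_cut_matrix(ds.fragments, ds.sites, flank=50)
        prof = aggregate_profile(m)["combined"].astype(float)
        n, w = prof.sum(), prof.size
        expected = n / w
        # each column is ~Binomial(n, 1/w); allow 5 sigma
        sigma = np.sqrt(n * (1 / w) * (1 - 1 / w))
        assert np.all(np.abs(prof - expected) < 5 * sigma)


class TestCutTracks:
    def test_empty_region(self, tmp_path):
        write_cut_tracks([], ("chr1", 0, 100),
                         tmp_path / "f.bedGraph", tmp_path / "r.bedGraph")
        assert (tmp_path / "f.bedGraph").read_text() == ""

    def test_toy_hand_enumeration(self, tmp_path):
        frags = [frag(10, 50), frag(10, 60), frag(55, 90, strand="-")]
        write_cut_tracks(frags, ("chr1", 0, 100),
                         tmp_path / "f.bedGraph", tmp_path / "r.bedGraph")
        fwd = (tmp_path / "f.bedGraph").read_text().splitlines()
        rev = (tmp_path / "r.bedGraph").read_text().splitlines()
        # s1 boundaries: 10, 10, 90 ; e2 boundaries: 50, 60, 55
        assert fwd == ["chr1\t10\t11\t2", "chr1\t90\t91\t1"]
        assert rev == ["chr1\t50\t51\t1", "chr1\t55\t56\t1", "chr1\t60\t61\t1"]

    def test_total_conserved(self, tmp_path):
        rng = np.random.default_rng(8)
        frags, _ = random_toy_set(rng, max_fragments=40, max_sites=1)
        write_cut_tracks(frags, ("ctgA", 0, 300),
                         tmp_path / "f.bedGraph", tmp_path / "r.bedGraph")
        total = 0
        for name in ("f.bedGraph", "r.bedGraph"):
            for line in (tmp_path / name).read_text().splitlines():
                total += int(line.split("\t")[3])
        n_in = sum(
            (0 <= f.s1 < 300) + (0 <= f.e2 < 300)
            for f in frags if f.chrom == "ctgA"
        )
        assert total == n_in
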