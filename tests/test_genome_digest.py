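"""In-silico digestion: scanning, fragments, gaps, and bias tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import naive_scan
from relacs.genome_digest import (
    CVIKI_1,
    DegenerateMotif,
    GenomeSequence,
    IntervalSet,
    SiteIndex,
    build_fragments,
    cut_usage,
    gap_report,
    reverse_complement,
    scan_sites,
    site_density_by_class,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


def _genome(seq: str) -> GenomeSequence:
    return GenomeSequence({"chr1": seq})


class TestScanSites:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AGCT", [2]),  # A in R, T in Y
            ("TTTT", []),
            ("GGCCGGCC", [2, 6]),
            ("AGNT", []),  # N in the genome never matches
            ("agct", [2]),  # case-normalized on load
        ],
    )
    def test_small_examples(self, seq, expected):
        idx = scan_sites(_genome(seq), CVIKI_1)
        assert idx.sites["chr1"].tolist() == expected
        assert idx.total_sites == len(expected)

    def test_chromosome_shorter_than_pattern(self):
        idx = scan_sites(_genome("AG"), CVIKI_1)
        assert idx.total_sites == 0

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            DegenerateMotif("RGXQ")

    def test_cut_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DegenerateMotif("RGCY", cut_offset=5)

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, size=2000)])
            idx = scan_sites(_genome(seq), CVIKI_1)
            assert idx.sites["chr1"].tolist() == naive_scan(seq)

    @given(seq=dna)
    @settings(max_examples=100, deadline=None)
    def test_palindromy_mirrors_site_set(self, seq):
        """RGCY is its own degenerate reverse complement, so scanning the
        reverse complement yields the mirrored cut positions p -> L - p."""
        fwd = scan_sites(_genome(seq) if seq else _genome("A"), CVIKI_1)
        rc = scan_sites(_genome(reverse_complement(seq) if seq else "T"), CVIKI_1)
        L = max(len(seq), 1)
        mirrored = sorted(L - p for p in fwd.sites["chr1"])
        assert rc.sites["chr1"].tolist() == mirrored

    def test_nonpalindromic_motif_reverse_scan(self):
        # GAATC is not its own reverse complement (GATTC); a reverse-strand
        # match must be picked up by the merged scan.
        motif = DegenerateMotif("GAATC", cut_offset=1, blunt=False)
        assert not motif.is_palindromic
        # forward strand has revcomp(GAATC)=GATTC at position 0
        idx = scan_sites(_genome("GATTCAA"), motif)
        # reverse-strand match starting at 0 cuts at 0 + (5 - 1) = 4
        assert idx.sites["chr1"].tolist() == [4]

    def test_agrees_with_biopython_restriction_enzyme(self, rng):
        """Cross-check against Bio.Restriction's CviKI-1 digestion, an
        independent implementation of the same RG|CY site search."""
        from Bio.Restriction import CviKI_1
        from Bio.Seq import Seq

        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=5000)])
            ours = scan_sites(_genome(seq), CVIKI_1).sites["chr1"].tolist()
            # Bio.Restriction reports 1-based position of the first base
            # after the cut
            theirs = [p - 1 for p in CviKI_1.search(Seq(seq))]
            assert ours == theirs

    def test_match_density_on_uniform_sequence(self, rng):
        """Uniform GC=0.5 sequence: RGCY matches ~1/64 of eligible windows."""
        n = 400_000
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        idx = scan_sites(_genome(seq), CVIKI_1)
        windows = n - 3
        expect = windows / 64
        sd = np.sqrt(windows * (1 / 64) * (63 / 64))
        assert abs(idx.total_sites - expect) < 5 * sd


class TestFragmentsAndGaps:
    def _sites(self, positions, genome):
        return SiteIndex(motif=CVIKI_1, sites={"chr1": np.asarray(positions)})

    def test_fragments_between_consecutive_cuts(self):
        g = GenomeSequence({"chr1": "A" * 5000})
        fmap = build_fragments(self._sites([100, 300, 2000], g), g)
        assert fmap.fragments["chr1"].tolist() == [[100, 300], [300, 2000]]

    def test_terminal_segments_appended(self):
        g = GenomeSequence({"chr1": "A" * 5000})
        fmap = build_fragments(self._sites([100, 300, 2000], g), g, include_terminal=True)
        assert fmap.fragments["chr1"].tolist() == [
            [0, 100], [100, 300], [300, 2000], [2000, 5000]
        ]

    def test_unknown_chromosome_rejected(self):
        g = GenomeSequence({"chr1": "A" * 100})
        sites = SiteIndex(motif=CVIKI_1, sites={"chr2": np.asarray([10])})
        with pytest.raises(ValueError, match="chr2"):
            build_fragments(sites, g)

    def test_fragment_lengths_conserve_genome_length(self, random_genome):
        sites = scan_sites(random_genome, CVIKI_1)
        fmap = build_fragments(sites, random_genome, include_terminal=True)
        assert int(fmap.lengths().sum()) == random_genome.total_length

    def test_gap_report_example(self):
        g = GenomeSequence({"chr1": "A" * 5000})
        rep = gap_report(self._sites([100, 300, 2000], g), g, threshold=1000)
        assert rep.n_gaps == 1
        assert rep.gaps == [("chr1", 300, 2000)]
        assert rep.gap_bases == 1700
        assert rep.blind_fraction == pytest.approx(0.34)

    def test_no_sites_no_internal_gaps(self):
        g = GenomeSequence({"chr1": "A" * 5000})
        rep = gap_report(SiteIndex(CVIKI_1, {"chr1": np.asarray([])}), g, threshold=1000)
        assert rep.n_gaps == 0
        # whereas counting terminal segments makes the whole chromosome a gap
        rep_t = gap_report(
            SiteIndex(CVIKI_1, {"chr1": np.asarray([])}), g, threshold=1000,
            include_terminal=True,
        )
        assert rep_t.n_gaps == 1 and rep_t.gap_bases == 5000

    def test_threshold_strictly_greater(self):
        g = GenomeSequence({"chr1": "A" * 5000})
        rep = gap_report(self._sites([1000, 2000], g), g, threshold=1000)
        assert rep.n_gaps == 0  # exactly 1000 bp is not > 1000

    def test_raising_threshold_never_increases_gap_count(self, random_genome):
        sites = scan_sites(random_genome, CVIKI_1)
        counts = [
            gap_report(sites, random_genome, threshold=t).n_gaps
            for t in (50, 100, 200, 400, 800)
        ]
        assert counts == sorted(counts, reverse=True)
        assert all(
            gap_report(sites, random_genome, threshold=t).gap_bases
            <= random_genome.total_length
            for t in (50, 200)
        )


class TestSiteDensity:
    def test_simple_density(self):
        sites = SiteIndex(CVIKI_1, {"chr1": np.arange(10) * 100})  # 0..900
        states = IntervalSet([("chr1", 0, 2000, "open")])
        table = site_density_by_class(sites, states)
        assert table.frame.loc["open", "site_count"] == 10
        assert table.frame.loc["open", "sites_per_kbp"] == pytest.approx(5.0)

    def test_class_with_no_sites(self):
        sites = SiteIndex(CVIKI_1, {"chr1": np.asarray([5000])})
        states = IntervalSet([("chr1", 0, 1000, "empty")])
        table = site_density_by_class(sites, states)
        assert table.frame.loc["empty", "sites_per_kbp"] == 0.0

    def test_matches_bruteforce_membership(self, rng):
        pos = np.unique(rng.integers(0, 10_000, size=300))
        sites = SiteIndex(CVIKI_1, {"chr1": pos})
        ivs = []
        for _ in range(40):
            s = int(rng.integers(0, 9_900))
            e = s + int(rng.integers(1, 100))
            ivs.append(("chr1", s, e, rng.choice(["a", "b"])))
        states = IntervalSet(ivs)
        table = site_density_by_class(sites, states)
        for label in states.classes:
            merged = states.by_class(label)["chr1"]
            brute = sum(
                1 for p in pos if any(s <= p < e for s, e in merged)
            )
            assert table.frame.loc[label, "site_count"] == brute

    def test_invariant_to_splitting_intervals(self):
        sites = SiteIndex(CVIKI_1, {"chr1": np.arange(50) * 37})
        whole = IntervalSet([("chr1", 100, 1300, "x")])
        split = IntervalSet(
            [("chr1", 100, 500, "x"), ("chr1", 500, 900, "x"), ("chr1", 900, 1300, "x")]
        )
        t1 = site_density_by_class(sites, whole).frame
        t2 = site_density_by_class(sites, split).frame
        assert t1.loc["x", "sites_per_kbp"] == pytest.approx(t2.loc["x", "sites_per_kbp"])

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            IntervalSet([("chr1", 5, 5, "null")])


class TestCutUsage:
    def test_every_site_used_once(self):
        pos = np.arange(1, 11) * 100
        sites = SiteIndex(CVIKI_1, {"chr1": pos})
        frags = [("chr1", int(a), int(b)) for a, b in zip(pos[:-1], pos[1:])]
        # every internal site appears as both an end and a start -> 2 ends,
        # boundary sites once; use a single full-coverage class
        states = IntervalSet([("chr1", 0, 1200, "all")])
        table = cut_usage(sites, frags, states)
        assert table.n_violations == 0
        assert table.frame.loc["all", "observed_fragment_ends"] == 2 * len(frags)
        assert table.frame.loc["all", "relative_usage"] == pytest.approx(1.0)

    def test_off_site_ends_counted_as_violations(self):
        sites = SiteIndex(CVIKI_1, {"chr1": np.asarray([100, 200])})
        states = IntervalSet([("chr1", 0, 300, "all")])
        table = cut_usage(sites, [("chr1", 100, 200), ("chr1", 103, 200)], states)
        assert table.n_violations == 1
        assert table.frame.loc["all", "observed_fragment_ends"] == 3

    def test_empty_observations_rejected(self):
        sites = SiteIndex(CVIKI_1, {"chr1": np.asarray([100])})
        states = IntervalSet([("chr1", 0, 300, "all")])
        with pytest.raises(ValueError, match="empty"):
            cut_usage(sites, [], states)
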