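"""Read processing: trimming, seed-and-extend alignment, site correction,
unique-site tables and library summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tnseqkit as tk
from tnseqkit.models import AlignmentHit, revcomp
from tnseqkit.readproc import (
    AttritionCounts,
    GenomeAligner,
    filter_and_trim,
    gap_stats,
    insertion_density,
    library_stats,
    reads_to_sites,
    to_insertion_site,
    unique_sites,
)

MARKER = "CTGTCTCTTATACACATCT"


def random_genome(n, rng, gc=0.5):
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(np.array(list("GCAT"))[rng.choice(4, size=n, p=p)])


class TestFilterAndTrim:
    def test_marker_is_stripped(self):
        out = list(filter_and_trim([("r1", MARKER + "ACGTACGTACGTACGTT")], MARKER))
        assert out == [("r1", "ACGTACGTACGTACGTT")]

    def test_read_without_marker_is_dropped_and_counted(self):
        counts = AttritionCounts()
        out = list(filter_and_trim([("r1", "A" * 40)], MARKER, counts=counts))
        assert out == []
        assert counts.n_no_marker == 1

    def test_trailing_primer_removed(self):
        primer = "GACCACGAGACGCCACACTG"
        frag = "ACGTACGTACGTACGTACGT"
        reads = [("r1", MARKER + frag + primer + "TTTT")]
        out = list(filter_and_trim(reads, MARKER, [primer]))
        assert out == [("r1", frag)]

    def test_spiked_decoys_are_dropped_exactly(self, rng):
        genome = random_genome(2_000, rng)
        good = [(f"g{i}", MARKER + genome[i * 30: i * 30 + 30]) for i in range(50)]
        decoys = [(f"d{i}", random_genome(49, rng)) for i in range(10)]
        counts = AttritionCounts()
        out = list(filter_and_trim(good + decoys, MARKER, counts=counts))
        assert len(out) == 50
        assert counts.n_no_marker == 10

    def test_empty_marker_rejected(self):
        with pytest.raises(ValueError):
            list(filter_and_trim([("r", "ACGT")], ""))


class TestAlignFragment:
    def test_unique_substring_maps_with_identity_one(self, rng):
        genome = random_genome(5_000, rng)
        frag = genome[1_000:1_040]
        hit = tk.align_fragment(frag, genome)
        assert (hit.contig_position, hit.strand) == (1_001, "+")
        assert hit.identity == 1.0 and hit.coverage == 1.0 and not hit.ambiguous

    def test_minus_strand_fragment_maps_to_first_read_base(self, rng):
        genome = random_genome(5_000, rng)
        # read starting at genome position 2000 (1-based), running leftwards
        frag = revcomp(genome[1_960:2_000])
        hit = tk.align_fragment(frag, genome)
        assert (hit.contig_position, hit.strand) == (2_000, "-")
        assert hit.identity == 1.0

    def test_duplicated_locus_with_equal_identity_is_ambiguous(self, rng):
        core = random_genome(60, rng)
        genome = random_genome(500, rng) + core + random_genome(500, rng) + core
        hit = tk.align_fragment(core[:40], genome)
        assert hit.ambiguous

    def test_fragment_shorter_than_seed_returns_none(self, rng):
        genome = random_genome(1_000, rng)
        assert tk.align_fragment(genome[10:20], genome) is None

    def test_mismatch_outside_seed_lowers_identity_not_position(self, rng):
        genome = random_genome(5_000, rng)
        frag = list(genome[3_000:3_040])
        frag[30] = {"A": "C"}.get(frag[30], "A")
        hit = tk.align_fragment("".join(frag), genome)
        assert hit.contig_position == 3_001
        assert hit.identity == pytest.approx(39 / 40)

    def test_matches_brute_force_scan(self, rng):
        """Error-free fragments agree with an exhaustive all-positions scan."""
        genome = random_genome(20_000, rng, gc=0.68)
        aligner = GenomeAligner(genome)
        rcg = revcomp(genome)
        L = len(genome)
        for _ in range(120):
            start = int(rng.integers(0, L - 40))
            frag = genome[start:start + 40] if rng.random() < 0.5 \
                else rcg[start:start + 40]
            # independent oracle: scan every position on both strands
            best = []
            seed = frag[:15]
            i = genome.find(seed)
            while i >= 0:
                seg = genome[i:i + 40]
                best.append((len(seg) / 40, sum(a == b for a, b in zip(frag, seg)) / len(seg), i + 1, "+"))
                i = genome.find(seed, i + 1)
            i = rcg.find(seed)
            while i >= 0:
                seg = rcg[i:i + 40]
                best.append((len(seg) / 40,
                             sum(a == b for a, b in zip(frag, seg)) / len(seg),
                             L - i, "-"))
                i = rcg.find(seed, i + 1)
            hit = aligner.align(frag)
            best.sort(key=lambda t: (-t[0], -t[1]))
            assert hit is not None
            assert (hit.contig_position, hit.strand) == (best[0][2], best[0][3])
            assert hit.ambiguous == (len(best) > 1 and best[1][:2] == best[0][:2])


class TestToInsertionSite:
    @pytest.mark.parametrize("strand,contig_pos,dup,expected", [
        ("+", 100, 9, (108, "-")),
        ("-", 100, 9, (92, "+")),
        ("+", 100, 0, (99, "-")),
        ("-", 100, 0, (101, "+")),
    ])
    def test_duplication_arithmetic(self, strand, contig_pos, dup, expected):
        hit = AlignmentHit(contig_pos, strand, 1.0, 1.0)
        assert to_insertion_site(hit, dup) == expected

    def test_circular_wrap(self):
        hit = AlignmentHit(998, "+", 1.0, 1.0)
        assert to_insertion_site(hit, 9, genome_length=1_000) == (6, "-")
        with pytest.raises(ValueError):
            to_insertion_site(hit, 9, genome_length=1_000, circular=False)

    def test_ambiguous_hit_rejected(self):
        with pytest.raises(ValueError):
            to_insertion_site(AlignmentHit(5, "+", 1.0, 1.0, ambiguous=True))

    def test_simulator_round_trip_recovers_all_sites(self, small_config,
                                                     small_genome, small_pool):
        """Error-free reads map back to the exact truth (position, orientation)."""
        genome, _ = small_genome
        pool, _ = small_pool
        reads, sidecar = tk.simulate_reads(pool, genome, small_config,
                                           library_size=20_000)
        sites, counts = reads_to_sites(iter(reads), GenomeAligner(genome),
                                       small_config.oend_marker,
                                       small_config.primer_set)
        truth = set(zip(sidecar["position"], sidecar["orientation"]))
        recovered = set(zip(sites["position"], sites["orientation"]))
        assert recovered == truth
        assert counts.n_mapped == len(reads)


class TestUniqueSites:
    def test_grouping_and_counts(self):
        obs = [(10, "+"), (10, "+"), (10, "+"), (10, "-"), (5, "+")]
        table = unique_sites(obs)
        assert table.to_dict("records") == [
            {"position": 5, "orientation": "+", "read_count": 1},
            {"position": 10, "orientation": "+", "read_count": 3},
            {"position": 10, "orientation": "-", "read_count": 1},
        ]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(1, 50),
                              st.sampled_from("+-")), max_size=200))
    def test_matches_dictionary_grouping(self, obs):
        table = unique_sites(obs)
        expected = {}
        for key in obs:
            expected[key] = expected.get(key, 0) + 1
        got = {(r.position, r.orientation): r.read_count
               for r in table.itertuples()}
        assert got == expected
        assert table["position"].is_monotonic_increasing


class TestLibrarySummaries:
    @pytest.mark.parametrize("n_sites,expected", [
        (183_437, 24), (105_421, 42), (61_594, 71), (55_198, 79), (65_198, 67),
    ])
    def test_density_matches_published_library_table(self, n_sites, expected):
        assert insertion_density(4_376_040, n_sites) == expected

    def test_single_site_density_is_genome_length(self):
        assert insertion_density(12_345, 1) == 12_345

    def test_empty_table_has_undefined_density(self):
        empty = pd.DataFrame(columns=["position", "orientation", "read_count"])
        stats = library_stats(empty, 1_000)
        assert stats.density_bp_per_insertion is None

    def test_intragenic_fraction(self):
        genes = [tk.GeneModel("a", 100, 199, "+"), tk.GeneModel("b", 300, 399, "-")]
        table = unique_sites([(150, "+"), (150, "-"), (350, "+"), (500, "+")])
        stats = library_stats(table, 1_000, genes)
        assert stats.intragenic_fraction == 75  # 3 of 4 sites


class TestGapStats:
    def test_two_sites_on_circular_genome(self):
        table = unique_sites([(10, "+"), (20, "+")])
        g = gap_stats(table, 30, circular=True)
        assert sorted(g.gap_sizes.tolist()) == [9, 19]

    def test_single_site_circular_gap(self):
        table = unique_sites([(7, "+")])
        g = gap_stats(table, 500, circular=True)
        assert g.gap_sizes.tolist() == [499]
        assert g.largest_gap == 499

    def test_orientations_collapse_by_position(self):
        table = unique_sites([(10, "+"), (10, "-"), (20, "+")])
        g = gap_stats(table, 30)
        assert len(g.gap_sizes) == 2

    def test_zero_sites_raise(self):
        empty = pd.DataFrame(columns=["position", "orientation", "read_count"])
        with pytest.raises(ValueError):
            gap_stats(empty, 100)

    def test_uniform_sites_give_geometric_like_gaps(self, rng):
        """Uniform random sites: gap sizes match the geometric expectation."""
        L = 100_000
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=1_000, replace=False))
        table = pd.DataFrame({"position": pos, "orientation": "+",
                              "read_count": 1})
        g = gap_stats(table, L)
        from scipy import stats as sps
        ks = sps.kstest(g.gap_sizes, sps.geom(1_000 / L, loc=-1).cdf)
        assert ks.pvalue > 0.001
        assert g.gap_sizes.sum() == L - 1_000


def test_strand_symmetry_mirrors_site_table(small_config, small_genome, small_pool):
    """Reverse-complementing genome and reads mirrors every site."""
    genome, _ = small_genome
    pool, _ = small_pool
    reads, _ = tk.simulate_reads(pool.head(40), genome, small_config,
                                 library_size=400)
    sites, _ = reads_to_sites(iter(reads), GenomeAligner(genome),
                              small_config.oend_marker, small_config.primer_set)
    mirrored_genome = revcomp(genome)
    sites_m, _ = reads_to_sites(iter(reads), GenomeAligner(mirrored_genome),
                                small_config.oend_marker, small_config.primer_set)
    L = len(genome)
    expected = {(L - p + 1, "-" if o == "+" else "+")
                for p, o in zip(sites["position"], sites["orientation"])}
    got = set(zip(sites_m["position"], sites_m["orientation"]))
    assert got == expected
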