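"""Cluster detection, splitting, spliced-read resolution, read extension,
normalization and profiling."""

import numpy as np
import pandas as pd
import pytest

from seedscope import (
    GenomeSource,
    build_profile,
    detect_clusters,
    extend_reads,
    normalize_experiments,
    resolve_spliced_reads,
    split_cluster,
)
from seedscope.clustering import connected_components, main_site_count_matrix

from conftest import make_read

GENOME = GenomeSource.from_dict(
    {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 4}
)


def reads_at(start, n_species, counts, chrom="chr1", length=12, conv_at=5):
    """n_species distinct reads sharing a locus, with a conversion inside."""
    out = []
    for i in range(n_species):
        seq = list("A" * length)
        seq[0] = "ACGT"[i % 4]  # make sequences distinct
        out.append(
            make_read(chrom, "+", start, "".join(seq), count=counts[i],
                      conversions={conv_at})
        )
    return out


class TestDetectClusters:
    def test_read_count_threshold(self):
        # 4 reads, 3 species: fails the >= 5 read-count filter
        reads = reads_at(100, 3, [2, 1, 1])
        assert detect_clusters({"e": reads}, min_reads=5, min_species=3) == []

    def test_species_threshold(self):
        # 6 identical reads = 1 species: fails the >= 3 species filter
        reads = [make_read("chr1", "+", 100, "A" * 12, count=6, conversions={5})]
        assert detect_clusters({"e": reads}, min_reads=5, min_species=3) == []

    def test_gap_separates_clusters(self):
        a = reads_at(100, 3, [3, 1, 1])
        b = reads_at(200, 3, [3, 1, 1])
        clusters = detect_clusters({"e": a + b})
        assert len(clusters) == 2

    def test_components_match_union_find_oracle(self, rng):
        # random reads over three planted sites; compare against brute-force
        # pairwise-overlap union-find
        reads = []
        for site in (100, 160, 400):
            for _ in range(60):
                start = site + int(rng.integers(-15, 16))
                reads.append(make_read("chr1", "+", start, "A" * 20))
        groups = connected_components(reads)

        def overlaps(r1, r2):
            return any(
                s1 < e2 and s2 < e1 for s1, e1 in r1.blocks for s2, e2 in r2.blocks
            )

        n = len(reads)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if overlaps(reads[i], reads[j]):
                    pi, pj = find(i), find(j)
                    if pi != pj:
                        parent[pj] = pi
        oracle = {}
        for i, r in enumerate(reads):
            oracle.setdefault(find(i), set()).add(id(r))
        ours = {frozenset(map(id, g)) for g in groups}
        assert ours == {frozenset(v) for v in oracle.values()}

    def test_order_invariance(self):
        reads = reads_at(100, 4, [2, 2, 1, 1])
        fwd = detect_clusters({"e": list(reads)})
        rev = detect_clusters({"e": list(reversed(reads))})
        assert len(fwd) == len(rev) == 1
        assert {r.sequence for r in fwd[0].reads} == {r.sequence for r in rev[0].reads}

    def test_strands_do_not_merge(self):
        plus = reads_at(100, 3, [3, 1, 1])
        minus = [
            make_read("chr1", "-", 100 + i, "ACGT"[i % 4] + "A" * 11,
                      conversions={5})
            for i in range(5)
        ]
        clusters = detect_clusters({"e": plus + minus}, min_reads=3, min_species=3)
        strands = {c.strand for c in clusters}
        assert strands == {"+", "-"}


class TestSplitCluster:
    def test_single_site_keeps_all_reads(self):
        reads = reads_at(100, 3, [3, 1, 1], conv_at=5)
        out = split_cluster(reads, 5, 3)
        assert len(out) == 1
        assert sum(r.count for r in out[0]) == 5

    def test_two_maxima_bridged_by_two_reads(self):
        # two conversion maxima connected only via 2 bridging reads: the
        # splitting procedure yields exactly 2 sub-clusters partitioning reads
        left = reads_at(100, 3, [3, 2, 1], length=12, conv_at=5)
        right = reads_at(120, 3, [3, 2, 1], length=12, conv_at=6)
        bridge = [
            make_read("chr1", "+", 108, "G" * 16, count=1),
            make_read("chr1", "+", 109, "C" * 16, count=1),
        ]
        out = split_cluster(left + right + bridge, 5, 3)
        assert len(out) == 2
        ids = [set(map(id, g)) for g in out]
        assert not (ids[0] & ids[1])
        # bridging reads cover neither conversion maximum's site exclusively;
        # each emitted sub-cluster contains one full site's reads
        left_sets = set(map(id, left))
        right_sets = set(map(id, right))
        assert left_sets <= ids[0] | ids[1]
        assert right_sets <= ids[0] | ids[1]

    def test_partition_property(self, rng):
        # greedy peel oracle: repeatedly take argmax-conversion covers
        reads = reads_at(100, 4, [3, 2, 1, 1], conv_at=4) + reads_at(
            110, 4, [3, 2, 1, 1], conv_at=7
        )
        out = split_cluster(reads, 3, 2)
        seen = [id(r) for g in out for r in g]
        assert len(seen) == len(set(seen))  # no read in two sub-clusters

    def test_no_conversions_yields_nothing(self):
        reads = [make_read("chr1", "+", 100, "ACGT" * 3, count=2) for _ in range(4)]
        assert split_cluster(reads, 2, 1) == []


class TestResolveSplicedReads:
    def test_unspliced_unchanged(self):
        reads = reads_at(100, 3, [1, 1, 1])
        assert resolve_spliced_reads(reads) == reads

    def test_exon_intron_reads_removed(self):
        spliced = [
            make_read("chr1", "+", 100, "A" * 20,
                      blocks=((100, 110), (150, 160)), count=5)
            for _ in range(2)
        ]
        exon_intron = [
            make_read("chr1", "+", 105, "A" * 10, count=1),  # runs over donor at 110
        ]
        out = resolve_spliced_reads(spliced + exon_intron)
        assert exon_intron[0] not in out
        assert all(r in out for r in spliced)

    def test_weaker_junction_removed(self):
        strong = [
            make_read("chr1", "+", 100, "A" * 20,
                      blocks=((100, 110), (150, 160)), count=8)
        ]
        weak = [
            make_read("chr1", "+", 100, "A" * 20,
                      blocks=((100, 110), (140, 150)), count=3)
        ]
        out = resolve_spliced_reads(strong + weak)
        assert out == strong


class TestExtendReads:
    genome = GenomeSource.from_dict({"c": "A" * 20 + "CCATGAAAA" + "A" * 20})

    def test_untrimmed_extended_past_next_g(self):
        # read ends at position 22 (...CC), genome continues ATG -> +3 bases
        r = make_read("c", "+", 15, "AAAAACC", untrimmed=True)
        out = extend_reads([r], self.genome)[0]
        assert out.blocks == ((15, 25),)
        assert out.sequence.endswith("ATG")

    def test_trimmed_unchanged(self):
        r = make_read("c", "+", 15, "AAAAACC", untrimmed=False)
        assert extend_reads([r], self.genome) == [r]

    def test_terminal_g_still_extended_to_next_g(self):
        genome = GenomeSource.from_dict({"c": "A" * 10 + "GTTG" + "A" * 10})
        r = make_read("c", "+", 5, "AAAAAG", untrimmed=True)  # ends on the G at 10
        out = extend_reads([r], genome)[0]
        assert out.blocks == ((5, 14),)  # next G at 13, ends right after it

    def test_minus_strand_extends_genomic_upstream(self):
        # sense 3' end of a minus read is its genomic start; sense G = genomic C
        genome = GenomeSource.from_dict({"c": "AACAAAAAAAAAAAAAAA"})
        r = make_read("c", "-", 5, "TTTTT", untrimmed=True)
        out = extend_reads([r], genome)[0]
        assert out.blocks == ((2, 10),)  # genomic C at 2 -> sense G
        assert out.sequence == "TTTTT" + "TTG"

    def test_missing_chrom_raises(self):
        r = make_read("x", "+", 0, "AAAA", untrimmed=True)
        with pytest.raises(KeyError):
            extend_reads([r], self.genome)

    def test_max_extension_cap(self):
        genome = GenomeSource.from_dict({"c": "A" * 100})
        r = make_read("c", "+", 0, "AAAA", untrimmed=True)
        out = extend_reads([r], genome, max_extension=6)[0]
        assert out.blocks == ((0, 10),)


class TestNormalization:
    def test_single_experiment_filters_small_clusters(self):
        counts = pd.DataFrame({"e1": [30.0, 5.0, 12.0]}, index=list("abc"))
        factors, kept = normalize_experiments(counts, min_norm_count=10)
        assert factors.factors == {"e1": 1.0}
        assert list(kept.index) == ["a", "c"]

    def test_constant_double_ratio(self):
        a = pd.Series([10.0, 20.0, 40.0])
        counts = pd.DataFrame({"A": a * 2, "B": a * 4})  # B = 2x A; B is reference
        factors, _ = normalize_experiments(counts, min_norm_count=0)
        assert factors.reference == "B"
        assert factors.factors["A"] == pytest.approx(2.0)

    def test_factors_match_median_of_ratios_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(50, 3)).astype(float), columns=list("XYZ")
        )
        factors, _ = normalize_experiments(counts, min_norm_count=0)
        ref = counts.sum().idxmax()
        for e in "XYZ":
            if e == ref:
                assert factors.factors[e] == 1.0
            else:
                oracle = 1.0 / np.median(counts[e] / counts[ref])
                assert factors.factors[e] == pytest.approx(oracle)

    def test_median_fold_change_is_one_post_hoc(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(51, 3)).astype(float), columns=list("XYZ")
        )
        factors, _ = normalize_experiments(counts, min_norm_count=0)
        normalized = counts * pd.Series(factors.factors)
        ref = factors.reference
        for e in "XYZ":
            med = np.median(normalized[e] / normalized[ref])
            assert med == pytest.approx(1.0)

    def test_all_zero_experiment_rejected(self):
        counts = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        with pytest.raises(ValueError):
            normalize_experiments(counts)


class TestBuildProfile:
    def test_single_read_profile(self):
        genome = GenomeSource.from_dict({"c": "AAAAATAAAAAA"})
        r = make_read("c", "+", 0, "AAAAACAAAA", count=3, conversions={5})
        clusters = detect_clusters({"e": [r]}, min_reads=1, min_species=1)
        c = build_profile(clusters[0], genome)
        assert c.conv[5] == 3
        assert c.starts[0] == 3
        assert c.ends[len(c.sequence) - 1] == 3
        assert c.main_site == 5

    def test_dominant_site_is_main_site(self):
        # one position carries the bulk of conversions -> main cross-link site
        genome = GenomeSource.from_dict({"c": "ATATATATATATATAT"})
        reads = [
            make_read("c", "+", 0, "ACATATATATAT", count=7, conversions={1}),
            make_read("c", "+", 0, "ATATACATATAT", count=2, conversions={5}),
            make_read("c", "+", 0, "ATATATATACAT", count=1, conversions={9}),
        ]
        clusters = detect_clusters({"e": reads}, min_reads=1, min_species=1)
        c = build_profile(clusters[0], genome)
        assert c.conv[1] == 7
        assert c.conv[1] / c.conv.sum() >= 0.6
        assert c.main_site == 1

    def test_vectors_match_tally_oracle(self, sim_small):
        data, genome, clusters = sim_small
        c = clusters[0]
        index = c.position_index()
        conv = np.zeros(len(c.sequence))
        starts = np.zeros(len(c.sequence))
        ends = np.zeros(len(c.sequence))
        for r in c.reads:
            pos = r.sense_positions()
            starts[index[pos[0]]] += r.count
            ends[index[pos[-1]]] += r.count
            for p in r.conversion_positions():
                conv[index[p]] += r.count
        assert np.array_equal(conv, c.conv)
        assert np.array_equal(starts, c.starts)
        assert np.array_equal(ends, c.ends)
        # conversions only at reference T
        t_mask = np.array([b == "T" for b in c.sequence])
        assert c.conv[~t_mask].sum() == 0

    def test_quantification_counts_main_site_covering_reads(self):
        genome = GenomeSource.from_dict({"c": "AAAAATAAAAAAAAAAAAAA"})
        covering = make_read("c", "+", 0, "AAAAACAAAA", count=4, conversions={5})
        not_covering = make_read("c", "+", 8, "AAAAAAAA", count=2)
        clusters = detect_clusters(
            {"e": [covering, not_covering]}, min_reads=1, min_species=1
        )
        c = build_profile(clusters[0], genome)
        assert c.per_experiment_counts == {"e": 4.0}
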