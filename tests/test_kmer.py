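import random
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from srnadapt.fastq_io import SequenceRead
from srnadapt.kmer import (
    AdapterCandidate,
    EmptyTableError,
    KmerTable,
    assemble,
    count_kmers,
    filter_by_ratio,
    filter_low_complexity,
    score_normalize,
)

from oracles import (
    chain_merges_bruteforce,
    homopolymer_filter_bruteforce,
    is_path_shaped,
    ratio_filter_bruteforce,
)


def _reads(*seqs):
    return [SequenceRead(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestCountKmers:
    def test_sliding_window_counts(self):
        t = count_kmers(_reads("ACGTACGT"), k=4)
        assert t.counts == {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
        assert t.total_windows == 5

    def test_windows_with_n_are_skipped_everywhere(self):
        t = count_kmers(_reads("ACNGT"), k=2)
        assert t.counts == {"AC": 1, "GT": 1}
        assert t.total_windows == 2

    def test_duplicate_reads_double_everything(self):
        t1 = count_kmers(_reads("ACGTACGT"), k=4)
        t2 = count_kmers(_reads("ACGTACGT", "ACGTACGT"), k=4)
        assert t2.counts == {s: 2 * c for s, c in t1.counts.items()}
        assert t2.total_windows == 2 * t1.total_windows

    def test_counts_sum_to_total_windows(self):
        t = count_kmers(_reads("ACGTACGT", "TTACG", "ACNGTT"), k=3)
        assert sum(t.counts.values()) == t.total_windows

    def test_k_exceeding_every_read_raises(self):
        with pytest.raises(EmptyTableError):
            count_kmers(_reads("ACGT"), k=10)


class TestLowComplexityFilter:
    @pytest.mark.parametrize(
        "kmer, kept",
        [
            ("AAAAAAAAA", False),  # poly(A)
            ("TGGAATTCT", True),  # longest run 2 < 4
            ("TGAAAACTC", False),  # run of 4 >= floor(9/2)
            ("TGAAACTCG", True),  # run of 3 < 4
        ],
    )
    def test_homopolymer_rule_at_k9(self, kmer, kept):
        table = KmerTable(k=9, counts={kmer: 5}, total_windows=100)
        out = filter_low_complexity(table)
        assert (kmer in out.counts) is kept
        assert out.total_windows == 100  # normalization total is untouched


class TestRatioFilter:
    def test_keeps_kmers_within_ratio_of_top(self):
        table = KmerTable(
            k=5, counts={"TGGAA": 100, "GGAAT": 80, "GAATT": 60}, total_windows=500
        )
        out = filter_by_ratio(table, 1.4)
        assert set(out.counts) == {"TGGAA", "GGAAT"}  # 100/60 ~ 1.67 dropped

    def test_single_kmer_always_survives(self):
        table = KmerTable(k=5, counts={"TGGAA": 7}, total_windows=7)
        assert set(filter_by_ratio(table, 1.1).counts) == {"TGGAA"}

    def test_boundary_ratio_is_kept(self):
        table = KmerTable(k=5, counts={"TGGAA": 100, "ACGTC": 50}, total_windows=300)
        assert set(filter_by_ratio(table, 2.0).counts) == {"TGGAA", "ACGTC"}

    def test_empty_table_passes_through(self):
        table = KmerTable(k=5, counts={}, total_windows=300)
        assert filter_by_ratio(table, 1.4).counts == {}

    def test_invalid_ratio_raises(self):
        table = KmerTable(k=5, counts={"TGGAA": 1}, total_windows=1)
        with pytest.raises(ValueError):
            filter_by_ratio(table, 1.0)


class TestScoreNormalize:
    def test_arithmetic(self):
        assert score_normalize([("TGGA", 50), ("GGAA", 40), ("GAAT", 30)], 200) == 0.6

    def test_bounds(self):
        assert score_normalize([("ACGT", 10)], 10) == 1.0
        assert score_normalize([], 10) == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            score_normalize([("ACGT", 1)], 0)


class TestAssemble:
    def test_three_link_chain(self):
        table = KmerTable(
            k=4, counts={"TGGA": 50, "GGAA": 40, "GAAT": 30}, total_windows=200
        )
        (cand,) = assemble(table)
        assert cand.sequence == "TGGAAT"
        assert cand.score == 120 / 200
        assert [m for m, _ in cand.members] == ["TGGA", "GGAA", "GAAT"]

    def test_disjoint_chains_ordered_by_score(self):
        table = KmerTable(
            k=4,
            counts={"ACGT": 5, "CGTA": 5, "TTAG": 30},
            total_windows=100,
        )
        cands = assemble(table)
        assert [c.sequence for c in cands] == ["TTAG", "ACGTA"]
        assert cands[0].score == 0.30 and cands[1].score == 0.10

    def test_empty_table_gives_no_candidates(self):
        assert assemble(KmerTable(k=4, counts={}, total_windows=10)) == []

    def test_overlap_cycle_terminates_with_each_kmer_used_once(self):
        # AC -> CA -> AC ... : a 2-cycle in the overlap graph
        table = KmerTable(k=2, counts={"AC": 3, "CA": 2}, total_windows=10)
        cands = assemble(table)
        used = [m for c in cands for m, _ in c.members]
        assert sorted(used) == ["AC", "CA"]


def _random_path_table(rng: random.Random, k: int = 5):
    """A k-mer set whose overlap graph is a disjoint union of simple paths."""
    while True:
        kmers: set[str] = set()
        for _ in range(rng.randint(1, 3)):
            seq = "".join(rng.choice("ACGT") for _ in range(k + rng.randint(0, 3)))
            kmers.update(seq[i : i + k] for i in range(len(seq) - k + 1))
        kmers_l = sorted(kmers)
        if 1 <= len(kmers_l) <= 8 and is_path_shaped(kmers_l):
            counts = {s: rng.randint(1, 100) for s in kmers_l}
            return KmerTable(k=k, counts=counts, total_windows=sum(counts.values()))


class TestAssemblyOracle:
    def test_greedy_equals_bruteforce_on_path_shaped_sets(self):
        rng = random.Random(2024)
        for _ in range(200):
            table = _random_path_table(rng)
            got = sorted(c.sequence for c in assemble(table))
            expected = sorted(chain_merges_bruteforce(sorted(table.counts)))
            assert got == expected


def _random_table(rng: random.Random) -> KmerTable:
    k = rng.randint(4, 9)
    n = rng.randint(1, 30)
    counts = {
        "".join(rng.choice("ACGT") for _ in range(k)): rng.randint(1, 100)
        for _ in range(n)
    }
    return KmerTable(k=k, counts=counts, total_windows=sum(counts.values()) + rng.randint(0, 50))


class TestFilterOracles:
    def test_filters_match_set_comprehension_reimplementations(self):
        rng = random.Random(99)
        for _ in range(1000):
            table = _random_table(rng)
            ratio = rng.choice([1.1, 1.2, 1.4, 1.7, 2.0, 3.0])
            assert filter_low_complexity(table).counts == homopolymer_filter_bruteforce(
                table.counts, table.k
            )
            assert filter_by_ratio(table, ratio).counts == ratio_filter_bruteforce(
                table.counts, ratio
            )


@st.composite
def tables(draw):
    k = draw(st.integers(min_value=4, max_value=9))
    kmer = st.text(alphabet="ACGT", min_size=k, max_size=k)
    counts = draw(
        st.dictionaries(kmer, st.integers(min_value=1, max_value=1000), min_size=1, max_size=20)
    )
    extra = draw(st.integers(min_value=0, max_value=100))
    return KmerTable(k=k, counts=counts, total_windows=sum(counts.values()) + extra)


class TestInvariants:
    @given(tables())
    def test_filters_are_contractions_preserving_counts(self, table):
        for out in (
            filter_low_complexity(table),
            filter_by_ratio(table, 1.4),
            filter_by_ratio(filter_low_complexity(table), 1.3),
        ):
            assert set(out.counts) <= set(table.counts)
            assert all(out.counts[s] == table.counts[s] for s in out.counts)
            assert out.total_windows == table.total_windows

    @given(tables(), st.sampled_from([1.1, 1.3, 1.5, 2.0]))
    def test_ratio_filter_keeps_top_kmer_and_its_frequency(self, table, ratio):
        out = filter_by_ratio(table, ratio)
        assert max(out.counts.values()) == max(table.counts.values())

    @given(tables())
    def test_assembly_soundness_and_score_conservation(self, table):
        cands = assemble(table)
        used = Counter()
        for c in cands:
            members = [m for m, _ in c.members]
            used.update(members)
            assert len(c.sequence) == table.k + len(members) - 1
            for a, b in zip(members, members[1:]):
                assert a[1:] == b[:-1]
            for m in members:
                assert m in c.sequence
            assert c.score == pytest.approx(
                sum(n for _, n in c.members) / table.total_windows
            )
        assert all(v == 1 for v in used.values())  # each k-mer in exactly one chain
        assert sum(c.member_count_sum for c in cands) <= table.total_windows
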