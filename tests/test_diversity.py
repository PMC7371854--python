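import itertools

import numpy as np
import pytest

from riboclass.diversity import (
    diversity_score,
    family_diversity_table,
    greedy_cluster,
    pairwise_identity,
)
from riboclass.sequence_io import RiboswitchDataset, SequenceRecord


def _needleman_identity(a: str, b: str) -> float:
    """Independent oracle: dynamic-programming global alignment
    (match 1, mismatch 0, gap -1) maximising score, identity =
    matches / alignment length maximised over optimal alignments."""
    n, m = len(a), len(b)
    # state: best (score, matches, -alen) lexicographically per cell
    NEG = float("-inf")
    best = [[(NEG, 0, 0)] * (m + 1) for _ in range(n + 1)]
    best[0][0] = (0.0, 0, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            score, match, alen = best[i][j]
            if score == NEG:
                continue
            if i < n and j < m:
                s = score + (1.0 if a[i] == b[j] else 0.0)
                cand = (s, match + (a[i] == b[j]), alen + 1)
                if cand[:1] >= best[i + 1][j + 1][:1]:
                    cur = best[i + 1][j + 1]
                    if (cand[0], cand[1] / cand[2]) > (
                        cur[0],
                        (cur[1] / cur[2]) if cur[2] else 0.0,
                    ):
                        best[i + 1][j + 1] = cand
            for di, dj in ((1, 0), (0, 1)):
                if i + di <= n and j + dj <= m:
                    cand = (score - 1.0, match, alen + 1)
                    cur = best[i + di][j + dj]
                    if (cand[0], cand[1] / cand[2]) > (
                        cur[0],
                        (cur[1] / cur[2]) if cur[2] else 0.0,
                    ):
                        best[i + di][j + dj] = cand
    score, match, alen = best[n][m]
    return match / alen


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 1.0),
            ("AAAAAAAAAA", "AAAAAAAAAT", 0.9),
            ("AAAA", "TTTT", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 30)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 30)))
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_equal_length_pairs(self, rng):
        # equal-length random pairs rarely need gaps under the gap penalty,
        # so the identity reduces to a checkable alignment computation
        for _ in range(15):
            n = int(rng.integers(4, 18))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = "".join(rng.choice(list("ACGT"), size=n))
            assert pairwise_identity(a, b) == pytest.approx(
                _needleman_identity(a, b), abs=1e-9
            )


def _records(seqs):
    return [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        clusters = greedy_cluster(_records(["ACGTACGT"] * 5))
        assert len(clusters) == 1
        assert len(clusters[0]) == 5

    def test_threshold_splits_distant_sequences(self):
        clusters = greedy_cluster(
            _records(["AAAAAAAAAA", "AAAAAAAAAT", "CCCCCCCCCC"]), threshold=0.9
        )
        assert len(clusters) == 2

    def test_random_sequences_become_singletons(self, rng):
        seqs = [
            "".join(rng.choice(list("ACGT"), size=60)) for _ in range(50)
        ]
        # verify the premise with the pairwise oracle before asserting
        for a, b in itertools.combinations(seqs[:20], 2):
            assert pairwise_identity(a, b) < 0.9
        clusters = greedy_cluster(_records(seqs), threshold=0.9)
        assert len(clusters) == 50

    def test_partition_and_threshold_properties(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=40))
        seqs = []
        for _ in range(30):
            s = list(base)
            for pos in rng.choice(40, size=int(rng.integers(0, 12)), replace=False):
                s[pos] = str(rng.choice(list("ACGT")))
            seqs.append("".join(s))
        records = _records(seqs)
        clusters = greedy_cluster(records, threshold=0.9)
        members = [m.id for c in clusters for m in c.members]
        assert sorted(members) == sorted(r.id for r in records)  # partition
        for c in clusters:
            for m in c.members:
                assert (
                    pairwise_identity(m.sequence, c.representative.sequence)
                    >= 0.9
                )

    def test_cluster_count_monotone_in_threshold(self, rng):
        seqs = []
        base = "".join(rng.choice(list("ACGT"), size=30))
        for _ in range(20):
            s = list(base)
            for pos in rng.choice(30, size=int(rng.integers(0, 10)), replace=False):
                s[pos] = str(rng.choice(list("ACGT")))
            seqs.append("".join(s))
        counts = [
            len(greedy_cluster(_records(seqs), threshold=t))
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts)

    def test_representative_is_longest(self):
        clusters = greedy_cluster(_records(["ACGT", "ACGTAC", "ACGTA"]), 0.5)
        assert clusters[0].representative.sequence == "ACGTAC"


class TestDiversityScore:
    @pytest.mark.parametrize(
        "clusters,size,expected",
        [
            (2484, 4080, 0.61),
            (47686, 68520, 0.70),
            (5, 5, 1.0),
        ],
    )
    def test_ratio(self, clusters, size, expected):
        assert round(diversity_score(clusters, size), 2) == pytest.approx(
            expected
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diversity_score(0, 10)
        with pytest.raises(ValueError):
            diversity_score(11, 10)
        with pytest.raises(ValueError):
            diversity_score(1, 0)


class TestFamilyTable:
    def test_one_row_per_family_plus_total(self):
        records = [
            SequenceRecord(f"a{i}", "ACGTACGTAC", label="famA") for i in range(3)
        ] + [
            SequenceRecord("t1", "GGGGGGGGGG", label="famB"),
            SequenceRecord("t2", "GGGGGGGGGG", label="famB"),
        ]
        ds = RiboswitchDataset(records)
        table = family_diversity_table(ds)
        assert list(table["family"]) == ["famA", "famB", "ALL"]

    def test_duplicate_family_statistics(self):
        records = [
            SequenceRecord(f"d{i}", "ACGTACGTACGT", label="dup") for i in range(6)
        ]
        table = family_diversity_table(RiboswitchDataset(records))
        row = table[table.family == "dup"].iloc[0]
        assert row.n_clusters == 1
        assert row.diversity == pytest.approx(1 / 6)
        assert row.n_redundant == 5

    def test_planted_three_cluster_family(self, rng):
        # three motif variants, 10 near-copies each; within-variant identity
        # is >= 0.95 and between-variant identity well below 0.9
        variants = []
        while len(variants) < 3:
            v = "".join(rng.choice(list("ACGT"), size=60))
            if all(pairwise_identity(v, w) < 0.75 for w in variants):
                variants.append(v)
        seqs = []
        for v in variants:
            for _ in range(10):
                s = list(v)
                for pos in rng.choice(60, size=2, replace=False):
                    s[pos] = str(rng.choice(list("ACGT")))
                seqs.append("".join(s))
        # confirm the construction with the pairwise oracle
        for i, a in enumerate(seqs):
            vi = i // 10
            assert pairwise_identity(a, variants[vi]) >= 0.9
            for vj, v in enumerate(variants):
                if vj != vi:
                    assert pairwise_identity(a, v) < 0.9
        records = [
            SequenceRecord(f"p{i}", s, label="fam") for i, s in enumerate(seqs)
        ]
        table = family_diversity_table(RiboswitchDataset(records))
        assert int(table[table.family == "fam"].iloc[0].n_clusters) == 3

    def test_unlabeled_records_warn(self, tiny_records):
        ds = RiboswitchDataset(
            tiny_records + [SequenceRecord("u1", "ACGTACGT")]
        )
        with pytest.warns(UserWarning, match="unlabeled"):
            family_diversity_table(ds)
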