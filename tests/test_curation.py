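"""Curation pipeline: labeling, filtering, identity, clustering, hard
negatives, splits, Tm bins, identity bins, SQLite round trip.

The pairwise-identity implementation is cross-checked against an
independent affine-gap (Gotoh) dynamic-programming oracle written here.
"""

import numpy as np
import pytest

from thermadapt.curation import (
    Cluster,
    HardNegativePair,
    ThermalLabelRule,
    TmBinPlan,
    _MATRIX_X2,
    align_global,
    assign_splits,
    bin_by_max_identity,
    export_sqlite,
    filter_records,
    greedy_cluster,
    identity_upper_bound,
    import_sqlite,
    label_from_growth_temp,
    mine_hard_negatives,
    pairwise_identity,
    plan_tm_splits,
)
from thermadapt.seqio import SequenceRecord
from thermadapt.synthgen import mutate_to_identity, sample_sequences

AA = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_score(a: str, b: str, open_: int = 20, ext: int = 1) -> int:
    """Independent affine-gap global alignment score (gap of length n costs
    open + (n-1)*ext, terminal gaps penalized), same doubled-matrix scale."""
    S = _MATRIX_X2.score_matrix()
    alph = _MATRIX_X2.get_alphabet1()
    sym = {str(s): i for i, s in enumerate(alph)}
    n, m = len(a), len(b)
    NEG = -(10**9)
    M = np.full((n + 1, m + 1), NEG, float)
    Ix = M.copy()
    Iy = M.copy()
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[sym[a[i - 1]], sym[b[j - 1]]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - ext, Iy[i - 1, j] - open_)
            Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - ext, Ix[i, j - 1] - open_)
    return int(max(M[n, m], Ix[n, m], Iy[n, m]))


def rec(i: str, seq: str, **kw) -> SequenceRecord:
    return SequenceRecord(id=i, sequence=seq, **kw)


class TestLabeling:
    @pytest.mark.parametrize(
        "temp,expected",
        [(65, "thermophilic"), (25, "non_thermophilic"), (45, "unlabeled"),
         (60, "unlabeled"), (30, "unlabeled")],
    )
    def test_thresholds_are_strict(self, temp, expected):
        assert label_from_growth_temp(temp) == expected

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            ThermalLabelRule(t_hot=20, t_cold=30)


class TestFiltering:
    def test_length_and_ambiguity_rules(self):
        records = [
            rec("short", "A" * 29),
            rec("exact", "A" * 30),
            rec("ambig", "A" * 49 + "X"),
        ]
        kept, dropped = filter_records(records)
        assert [r.id for r in kept] == ["exact"]
        assert dropped == {"short": "short", "ambig": "ambiguous"}


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKLV", "MKLV") == 1.0

    def test_hand_alignment_three_of_four(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_symmetry_and_identity_iff_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = "".join(rng.choice(list(AA), 40))
            b = "".join(rng.choice(list(AA), 40))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)
            assert pairwise_identity(a, a) == 1.0
            if a != b:
                assert pairwise_identity(a, b) < 1.0

    def test_alignment_score_matches_dp_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(8):
            la, lb = rng.integers(30, 100, 2)
            a = "".join(rng.choice(list(AA), la))
            b = "".join(rng.choice(list(AA), lb))
            assert align_global(a, b).score == gotoh_score(a, b)

    def test_upper_bound_is_valid(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), int(rng.integers(30, 70))))
            b = mutate_to_identity(rec("p", a), float(rng.uniform(0.4, 1.0))).sequence
            assert identity_upper_bound(a, b) >= pairwise_identity(a, b) - 1e-12


class TestGreedyCluster:
    def test_singleton(self):
        clusters = greedy_cluster([rec("a", "MKLVAEAGHIKWWFYP")], 0.5)
        assert len(clusters) == 1 and clusters[0].centroid_id == "a"

    def test_hand_built_two_clusters(self):
        records = [rec("a", "AAAAAAAAAA"), rec("b", "AAAAAAAAAT"), rec("w", "WWWWWWWWWW")]
        clusters = greedy_cluster(records, 0.8)
        assert len(clusters) == 2
        by_centroid = {c.centroid_id: set(c.member_ids) for c in clusters}
        assert by_centroid["a"] == {"a", "b"}
        assert by_centroid["w"] == {"w"}

    def test_member_to_centroid_identity_meets_threshold(self, curation_benchmark):
        thermo = curation_benchmark.by_class("thermophilic")[:200]
        clusters = greedy_cluster(thermo, 0.5)
        seq = {r.id: r.sequence for r in thermo}
        for c in clusters:
            for m in c.member_ids:
                assert pairwise_identity(seq[m], seq[c.centroid_id]) >= c.threshold

    def test_threshold_one_groups_exact_duplicates_only(self):
        records = [rec("a", "MKLVAEAGHIKWWFYP"), rec("b", "MKLVAEAGHIKWWFYP"),
                   rec("c", "MKLVAEAGHIKWWFYA")]
        clusters = greedy_cluster(records, 1.0)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]

    def test_vanishing_threshold_gives_single_cluster(self):
        records = sample_sequences(10, "thermophilic", (30, 40), seed=0)
        assert len(greedy_cluster(records, 1e-6)) == 1

    def test_cluster_type_invariant(self):
        with pytest.raises(ValueError, match="centroid"):
            Cluster(centroid_id="x", member_ids=("a",), threshold=0.5)


class TestHardNegatives:
    def test_strict_bounds(self):
        with pytest.raises(ValueError):
            HardNegativePair("t", "n", 0.95)
        with pytest.raises(ValueError):
            HardNegativePair("t", "n", 0.80)

    def test_generator_pairs_recovered(self, curation_benchmark):
        bench = curation_benchmark
        thermo = bench.by_class("thermophilic")
        non = bench.by_class("non_thermophilic")
        pairs = mine_hard_negatives(non, thermo)
        found = {(p.thermo_id, p.non_thermo_id) for p in pairs}
        expected = {(a, b) for a, b, _ in bench.homolog_pairs}
        assert expected <= found
        for p in pairs:
            assert 0.80 < p.identity < 0.95


class TestAssignSplits:
    def _equal_clusters(self, n=10, size=5):
        return [
            Cluster(
                centroid_id=f"c{k}_0",
                member_ids=tuple(f"c{k}_{i}" for i in range(size)),
                threshold=0.5,
            )
            for k in range(n)
        ]

    def test_quota_arithmetic_eight_one_one(self):
        clusters = self._equal_clusters()
        sa = assign_splits(clusters, seed=3)
        counts = {s: len(sa.ids_in(s)) for s in ("train", "val", "test")}
        assert counts == {"train": 40, "val": 5, "test": 5}

    def test_forced_ids_pull_whole_cluster_to_train(self):
        clusters = self._equal_clusters()
        for seed in range(5):
            sa = assign_splits(clusters, seed=seed, force_train_ids={"c4_2"})
            assert all(sa.assignment[f"c4_{i}"] == "train" for i in range(5))

    def test_single_cluster_goes_to_train(self):
        only = Cluster(centroid_id="a", member_ids=("a", "b"), threshold=0.5)
        sa = assign_splits([only], seed=0)
        assert set(sa.assignment.values()) == {"train"}

    def test_no_cluster_spans_two_splits(self, curation_benchmark):
        bench = curation_benchmark
        records = bench.records
        from thermadapt.curation import cluster_classes

        clusters = cluster_classes(records)
        pairs = mine_hard_negatives(
            bench.by_class("non_thermophilic"), bench.by_class("thermophilic")
        )
        forced = {p.thermo_id for p in pairs} | {p.non_thermo_id for p in pairs}
        sa = assign_splits(clusters, seed=11, force_train_ids=forced)
        for c in clusters:
            assert len({sa.assignment[m] for m in c.member_ids}) == 1
        # hard-negative closure
        for i in forced:
            assert sa.assignment[i] == "train"

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            assign_splits(self._equal_clusters(), ratios=(0.7, 0.2, 0.2))


class TestTmSplits:
    def _tm_records(self, counts: dict[int, int], seed=0):
        rng = np.random.default_rng(seed)
        records = []
        for k, n in counts.items():
            for i in range(n):
                seq = "".join(rng.choice(list(AA), 40))
                records.append(
                    rec(f"b{k}_{i}", seq, melting_temp=float(k * 10 + rng.uniform(0, 10)))
                )
        return records

    def test_eval_sampling_and_rebalancing(self):
        records = self._tm_records({4: 100, 5: 40, 6: 8})
        train, val, test = plan_tm_splits(records, TmBinPlan(train_target=50), seed=0)
        val_ids, test_ids = {r.id for r in val}, {r.id for r in test}
        assert len(val_ids & test_ids) == 0
        assert not (val_ids | test_ids) & {r.id for r in train}
        # bins with >= 20 records give 10 + 10 evaluation points
        assert sum(i.startswith("b4") for i in val_ids) == 10
        assert sum(i.startswith("b4") for i in test_ids) == 10
        # rebalanced train bins hit the target, oversampling the scarce bin
        from collections import Counter

        by_bin = Counter(r.id.split("_")[0] for r in train)
        assert by_bin["b4"] == 50 and by_bin["b5"] == 50
        # the 8-record bin lost all members to evaluation; bins with
        # leftover members are equalized
        scarce = self._tm_records({6: 28})
        tr2, _, _ = plan_tm_splits(scarce, TmBinPlan(train_target=50), seed=0)
        assert len(tr2) == 50
        assert len({r.id for r in tr2}) == 8  # drawn with replacement from 8

    def test_median_target_default_and_errors(self):
        records = self._tm_records({3: 60, 7: 30})
        train, val, test = plan_tm_splits(records, seed=1)
        from collections import Counter

        by_bin = Counter(r.id.split("_")[0] for r in train)
        assert len(set(by_bin.values())) == 1  # equalized
        with pytest.raises(ValueError):
            plan_tm_splits([], seed=0)


class TestIdentityBins:
    def test_duplicate_lands_in_top_bin_and_family_structure_respected(self):
        rng = np.random.default_rng(4)
        train = sample_sequences(30, "thermophilic", (40, 60), seed=1)
        # relatives of train members at generator-known identity
        close = mutate_to_identity(train[0], 0.95, seed=0, new_id="close")
        dup = train[1].with_(id="dup")
        far = sample_sequences(1, "thermophilic", (40, 60), seed=99, id_prefix="far")[0]
        bins = bin_by_max_identity([dup, close, far], train)
        def bin_of(i):
            return next(k for k, v in bins.items() if i in v)
        assert bin_of("dup") == (0.8, 1.0)
        assert bin_of("close") == (0.8, 1.0)
        assert bin_of(far.id)[1] <= 0.4  # unrelated random sequence

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            bin_by_max_identity([], [rec("a", "A" * 30)])


class TestSqlite:
    def test_empty_corpus_round_trips(self, tmp_path):
        path = export_sqlite([], tmp_path / "empty.db")
        records, splits, clusters, pairs = import_sqlite(path)
        assert records == [] and splits is None and clusters == [] and pairs == []

    def test_full_round_trip(self, tmp_path):
        records = sample_sequences(20, "thermophilic", (30, 40), seed=0)
        records = [r.with_(melting_temp=50.0 + i) for i, r in enumerate(records)]
        clusters = greedy_cluster(records, 0.5)
        sa = assign_splits(clusters, seed=0)
        pairs = [HardNegativePair(records[0].id, records[1].id, 0.9)]
        path = export_sqlite(records, tmp_path / "c.db", sa, clusters, pairs)
        r2, s2, c2, p2 = import_sqlite(path)
        assert sorted(r2, key=lambda r: r.id) == sorted(records, key=lambda r: r.id)
        assert dict(s2.assignment) == dict(sa.assignment)
        assert {c.centroid_id: set(c.member_ids) for c in c2} == {
            c.centroid_id: set(c.member_ids) for c in clusters
        }
        assert [(p.thermo_id, p.non_thermo_id, p.identity) for p in p2] == [
            (p.thermo_id, p.non_thermo_id, p.identity) for p in pairs
        ]
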