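"""De novo OTU stages: dereplication, preclustering, complete linkage,
representatives, consensus taxonomy, and table assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliquery import SequenceRecord, TaxonomyLineage
from ampliquery.otu_pipeline import (
    OTUCluster,
    build_otu_table,
    cluster_furthest_neighbour,
    consensus_taxonomy,
    filter_by_taxonomy,
    hamming_distance,
    pick_representative,
    precluster,
    precluster_map,
    remove_singletons,
    run_denovo,
    trim_and_dereplicate,
)
from conftest import mutate, random_seq


def brute_force_complete_linkage(seqs: list[str], cutoff: float) -> set[frozenset]:
    """Independent oracle: naive agglomeration recomputing the maximum
    pairwise distance from scratch at every step, with ties resolved by
    the lexicographically smallest pair of sorted member-index sets."""
    length = len(seqs[0])
    clusters = [(i,) for i in range(len(seqs))]

    def linkage(a, b):
        return max(
            hamming_distance(seqs[i], seqs[j]) / length for i in a for j in b
        )

    while len(clusters) > 1:
        candidates = []
        for a, b in itertools.combinations(clusters, 2):
            d = linkage(a, b)
            if d <= cutoff + 1e-12:
                candidates.append((d, tuple(sorted((a, b)))))
        if not candidates:
            break
        _, (a, b) = min(candidates)
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
    return {frozenset(c) for c in clusters}


def records(seq_counts):
    return [
        SequenceRecord(f"u{i}", seq, count)
        for i, (seq, count) in enumerate(seq_counts)
    ]


class TestTrimAndDereplicate:
    def test_short_reads_discarded(self, rng):
        reads = [
            SequenceRecord("a", random_seq(rng, 120)),
            SequenceRecord("b", random_seq(rng, 100)),
            SequenceRecord("c", random_seq(rng, 90)),
        ]
        out = trim_and_dereplicate(reads, length=100)
        assert len(out) == 2
        assert all(len(r.seq) == 100 for r in out)

    def test_identical_reads_merge(self):
        reads = [SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")]
        out = trim_and_dereplicate(reads, length=4)
        assert len(out) == 1 and out[0].count == 2

    def test_multiplicities(self, rng):
        s1, s2, s3 = (random_seq(rng, 50) for _ in range(3))
        reads = [
            SequenceRecord(f"r{i}", s) for i, s in enumerate([s1, s1, s2, s3])
        ]
        out = trim_and_dereplicate(reads, length=50)
        assert sorted(r.count for r in out) == [1, 1, 2]
        assert out[0].count == 2  # descending count order

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=3, max_size=12), max_size=20))
    def test_count_conservation(self, seqs):
        reads = [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        out = trim_and_dereplicate(reads, length=5)
        retained = sum(1 for s in seqs if len(s) >= 5)
        assert sum(r.count for r in out) == retained


class TestRemoveSingletons:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 1, 2, 1], [5, 2]), ([2, 3], [2, 3]), ([1, 1, 1], [])],
    )
    def test_examples(self, counts, expected, rng):
        recs = records((random_seq(rng, 10), c) for c in counts)
        assert [r.count for r in remove_singletons(recs)] == expected


class TestPrecluster:
    def test_greedy_absorption(self, rng):
        a = random_seq(rng, 60)
        b = mutate(a, [5])        # 1 mismatch from a
        c = mutate(a, [10, 20])   # 2 mismatches from a
        out = precluster(records([(a, 10), (b, 3), (c, 2)]), max_diffs=1)
        assert {(r.seq, r.count) for r in out} == {(a, 13), (c, 2)}

    def test_zero_diffs_is_identity_on_dereplicated(self, rng):
        recs = records((random_seq(rng, 30), c) for c in [5, 4, 3])
        assert precluster(recs, max_diffs=0) == recs

    def test_absorbed_cannot_reabsorb(self, rng):
        a = random_seq(rng, 60)
        b = mutate(a, [7])          # 1 from a
        c = mutate(a, [7, 30], 1)   # 1 from b at pos 30... construct below
        # c must be 1 diff from b and 2 from a: start from b, mutate pos 30
        c = mutate(b, [30])
        assert hamming_distance(a, c) == 2 and hamming_distance(b, c) == 1
        out = precluster(records([(a, 10), (b, 5), (c, 4)]), max_diffs=1)
        assert {(r.seq, r.count) for r in out} == {(a, 15), (c, 4)}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            precluster(records([("ACGT", 2), ("ACG", 2)]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_survivor_separation_and_conservation(self, data):
        """Survivors pairwise differ at > max_diffs positions; counts conserved."""
        n = data.draw(st.integers(1, 10))
        seqs = data.draw(
            st.lists(
                st.text(alphabet="ACGT", min_size=8, max_size=8),
                min_size=n, max_size=n, unique=True,
            )
        )
        counts = data.draw(
            st.lists(st.integers(1, 20), min_size=len(seqs), max_size=len(seqs))
        )
        recs = records(zip(seqs, counts))
        out = precluster(recs, max_diffs=1)
        assert sum(r.count for r in out) == sum(counts)
        for r1, r2 in itertools.combinations(out, 2):
            assert hamming_distance(r1.seq, r2.seq) > 1


class TestFilterByTaxonomy:
    def test_chloroplast_removed(self, rng):
        recs = records([(random_seq(rng, 20), 5)])
        cls = {
            recs[0].id: TaxonomyLineage.from_string(
                "Bacteria;Cyanobacteria;Chloroplast"
            )
        }
        assert filter_by_taxonomy(recs, cls) == []

    def test_empty_blacklist_is_identity(self, rng):
        recs = records([(random_seq(rng, 20), 5)])
        cls = {recs[0].id: TaxonomyLineage.from_string("Eukaryota;Metazoa")}
        assert filter_by_taxonomy(recs, cls, blacklist=()) == recs

    def test_unknown_domain_removed(self, rng):
        recs = records((random_seq(rng, 20), 2) for _ in range(5))
        cls = {}
        for i, r in enumerate(recs):
            lineage = "unknown" if i < 2 else "Bacteria;Proteobacteria"
            cls[r.id] = TaxonomyLineage.from_string(lineage)
        assert len(filter_by_taxonomy(recs, cls)) == 3

    def test_missing_classification_treated_unknown(self, rng):
        recs = records([(random_seq(rng, 20), 2)])
        assert filter_by_taxonomy(recs, {}) == []


class TestClusterFurthestNeighbour:
    def test_single_record_one_cluster(self, rng):
        out = cluster_furthest_neighbour(records([(random_seq(rng, 100), 3)]))
        assert len(out) == 1 and out[0].max_intra_distance == 0.0

    def test_pair_joins_outlier_stays(self, rng):
        # d(1,2)=0.02, d(1,3)=0.05, d(2,3)=0.07 at cutoff 0.03 -> {1,2},{3}
        s1 = random_seq(rng, 100)
        s2 = mutate(s1, [0, 1])
        s3 = mutate(s1, [10, 11, 12, 13, 14])
        assert hamming_distance(s1, s3) == 5 and hamming_distance(s2, s3) == 7
        out = cluster_furthest_neighbour(records([(s1, 5), (s2, 4), (s3, 3)]), 0.03)
        parts = {frozenset(m.seq for m in c.members) for c in out}
        assert parts == {frozenset({s1, s2}), frozenset({s3})}

    def test_complete_linkage_blocks_chain(self, rng):
        # d(1,2)=0.02, d(2,3)=0.02, d(1,3)=0.04: single linkage would chain
        s1 = random_seq(rng, 100)
        s2 = mutate(s1, [0, 1])
        s3 = mutate(s2, [2, 3])
        assert hamming_distance(s1, s3) == 4
        out = cluster_furthest_neighbour(records([(s1, 5), (s2, 4), (s3, 3)]), 0.03)
        parts = {frozenset(m.seq for m in c.members) for c in out}
        assert parts == {frozenset({s1, s2}), frozenset({s3})}

    def test_otu_ids_by_descending_abundance(self, rng):
        s1 = random_seq(rng, 100)
        s2 = mutate(s1, list(range(10)))
        out = cluster_furthest_neighbour(records([(s1, 2), (s2, 9)]), 0.03)
        assert out[0].otu_id == "OTU0001" and out[0].total_count == 9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_matches_brute_force_and_diameter(self, data):
        n = data.draw(st.integers(2, 12))
        length = 20
        seqs = data.draw(
            st.lists(
                st.text(alphabet="ACGT", min_size=length, max_size=length),
                min_size=n, max_size=n, unique=True,
            )
        )
        cutoff = data.draw(st.sampled_from([0.05, 0.1, 0.2, 0.3]))
        recs = records((s, i + 1) for i, s in enumerate(seqs))
        out = cluster_furthest_neighbour(recs, cutoff)
        got = {
            frozenset(int(m.id[1:]) for m in c.members) for c in out
        }  # member ids u0..un encode input index
        assert got == brute_force_complete_linkage(seqs, cutoff)
        for c in out:
            assert c.max_intra_distance <= cutoff + 1e-12
        # clusters partition the input
        assert sorted(i for g in got for i in g) == list(range(n))


class TestPickRepresentative:
    def test_singleton(self, rng):
        c = OTUCluster("OTU0001", records([(random_seq(rng, 10), 1)]))
        assert pick_representative(c) == c.members[0].id

    def test_min_mean_distance(self, rng):
        # middle sequence is 1 mismatch from both ends; ends are 2 apart
        a = random_seq(rng, 100)
        mid = mutate(a, [0])
        b = mutate(mid, [1])
        c = OTUCluster("x", records([(a, 1), (mid, 1), (b, 1)]))
        assert pick_representative(c) == "u1"  # the middle record

    def test_tie_broken_by_count(self, rng):
        a = random_seq(rng, 50)
        b = mutate(a, [3])
        c = OTUCluster("x", records([(a, 3), (b, 7)]))
        assert pick_representative(c) == "u1"  # count 7 wins the symmetric tie

    def test_permutation_invariant(self, rng):
        seqs = [random_seq(rng, 40)]
        seqs += [mutate(seqs[0], [i]) for i in range(1, 4)]
        recs = records((s, i + 1) for i, s in enumerate(seqs))
        ref = pick_representative(OTUCluster("x", recs))
        for perm in itertools.permutations(recs):
            assert pick_representative(OTUCluster("x", list(perm))) == ref


class TestConsensusTaxonomy:
    def lin(self, s):
        return TaxonomyLineage.from_string(s, source_db="silva")

    def test_unanimous(self, rng):
        recs = records((random_seq(rng, 10), 1) for _ in range(3))
        cls = {r.id: self.lin("Bacteria;Proteobacteria;Gamma") for r in recs}
        out = consensus_taxonomy(OTUCluster("x", recs), cls)
        assert out.taxa == ("Bacteria", "Proteobacteria", "Gamma")

    def test_truncates_at_split_rank(self, rng):
        recs = records((random_seq(rng, 10), 1) for _ in range(4))
        cls = {
            recs[0].id: self.lin("Bacteria;PhylA;ClassX"),
            recs[1].id: self.lin("Bacteria;PhylA;ClassX"),
            recs[2].id: self.lin("Bacteria;PhylA;ClassY"),
            recs[3].id: self.lin("Bacteria;PhylB;ClassY"),
        }
        out = consensus_taxonomy(OTUCluster("x", recs), cls, threshold=0.51)
        # 4/4 at domain, 3/4 at phylum, 2/4 at class -> truncate after phylum
        assert out.taxa == ("Bacteria", "PhylA")

    def test_count_weighted(self, rng):
        recs = records([(random_seq(rng, 10), 10), (random_seq(rng, 10), 1)])
        cls = {
            recs[0].id: self.lin("Bacteria;X;Y"),
            recs[1].id: self.lin("Archaea;Z;W"),
        }
        out = consensus_taxonomy(OTUCluster("x", recs), cls)
        assert out.taxa == ("Bacteria", "X", "Y")  # 10/11 >= 0.51 at every rank

    def test_threshold_must_exceed_half(self, rng):
        recs = records([(random_seq(rng, 10), 1)])
        with pytest.raises(ValueError):
            consensus_taxonomy(
                OTUCluster("x", recs), {recs[0].id: self.lin("Bacteria")}, 0.5
            )


class TestBuildOtuTable:
    def test_member_counts_summed(self, rng):
        a, b = random_seq(rng, 10), random_seq(rng, 10)
        cluster = OTUCluster("OTU0001", records([(a, 3), (b, 2)]))
        t = build_otu_table([cluster], {("S1", "u0"): 3, ("S1", "u1"): 2})
        assert t.counts.tolist() == [[5]]

    def test_singleton_clusters_relabel_matrix(self, rng):
        recs = records((random_seq(rng, 10), 2) for _ in range(2))
        clusters = [OTUCluster(f"OTU000{i+1}", [r]) for i, r in enumerate(recs)]
        per_sample = {("S1", "u0"): 2, ("S2", "u1"): 4}
        t = build_otu_table(clusters, per_sample)
        assert t.counts.tolist() == [[2, 0], [0, 4]]

    def test_empty_clusters(self):
        t = build_otu_table([], {})
        assert t.n_features == 0

    def test_member_without_counts_raises(self, rng):
        cluster = OTUCluster("OTU0001", records([(random_seq(rng, 10), 2)]))
        with pytest.raises(ValueError, match="u0"):
            build_otu_table([cluster], {("S1", "other"): 2})


class TestRunDenovo:
    def test_end_to_end_count_conservation(self, rng):
        base = random_seq(rng, 100)
        near = mutate(base, [0])
        far = mutate(base, list(range(10, 20)))
        reads = (
            [SequenceRecord(f"r{i}", base) for i in range(10)]
            + [SequenceRecord(f"n{i}", near) for i in range(3)]
            + [SequenceRecord(f"f{i}", far) for i in range(5)]
            + [SequenceRecord("lone", mutate(base, list(range(40, 60))))]
        )
        per_sample = {}
        for i, r in enumerate(reads):
            per_sample[("S1" if i % 2 else "S2", r.id)] = 1
        res = run_denovo(reads, per_sample_counts=per_sample)
        # the singleton is removed, near absorbed into base -> 2 OTUs
        assert len(res.clusters) == 2
        assert res.table is not None
        # all reads except the singleton land in the table
        assert int(res.table.counts.sum()) == len(reads) - 1
        assert res.clusters[0].total_count == 13

    def test_blacklisted_database_hit_removes_sequence(self, rng):
        base = random_seq(rng, 100)
        other = mutate(base, list(range(20)))
        reads = [SequenceRecord(f"r{i}", base) for i in range(4)] + [
            SequenceRecord(f"q{i}", other) for i in range(4)
        ]
        cls = {
            "silva": {
                base: TaxonomyLineage.from_string("Bacteria;Cyanobacteria;Chloroplast"),
                other: TaxonomyLineage.from_string("Bacteria;Proteobacteria"),
            },
            "greengenes": {
                base: TaxonomyLineage.from_string("Bacteria;Cyanobacteria"),
                other: TaxonomyLineage.from_string("Bacteria;Proteobacteria"),
            },
        }
        res = run_denovo(reads, classifications=cls)
        assert len(res.clusters) == 1
        assert res.clusters[0].members[0].seq == other
        assert res.clusters[0].consensus["silva"].taxa == ("Bacteria", "Proteobacteria")
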