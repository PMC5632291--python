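"""De novo OTU construction from trimmed amplicon reads.

The stages mirror the classic Mothur-style de novo workflow: fixed-length
5' trimming with dereplication, singleton removal, single-nucleotide
preclustering, removal of non-target lineages (eukaryotes, organelles,
unknowns), furthest-neighbour (complete-linkage) clustering at a distance
cutoff, representative selection by minimal mean intra-cluster distance,
and per-database consensus taxonomy.

Distances here are Hamming mismatch fractions on equal-length trimmed
sequences; ``N`` matches only ``N``. Reference-based alignment, chimera
detection, and classifier execution are upstream concerns: classifications
arrive as inputs, and an externally produced id blacklist can be applied
with :func:`drop_blacklisted_ids`.

Every operation in this module is deterministic: ties are broken by
abundance and then lexicographic sequence/member order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ampliquery.core_tables import FeatureTable, SequenceRecord, TaxonomyLineage

__all__ = [
    "OTUCluster",
    "DenovoResult",
    "DEFAULT_TAXON_BLACKLIST",
    "hamming_distance",
    "trim_and_dereplicate",
    "remove_singletons",
    "precluster",
    "precluster_map",
    "filter_by_taxonomy",
    "drop_blacklisted_ids",
    "cluster_furthest_neighbour",
    "pick_representative",
    "consensus_taxonomy",
    "build_otu_table",
    "run_denovo",
]

logger = logging.getLogger(__name__)

#: Lineage names whose sequences are dropped before clustering.
DEFAULT_TAXON_BLACKLIST = frozenset(
    {"eukaryota", "eukaryote", "chloroplast", "mitochondria", "unknown"}
)


@dataclass
class OTUCluster:
    """One operational taxonomic unit.

    Attributes
    ----------
    otu_id : str
        Identifier assigned by descending total member count
        (``OTU0001`` is the most abundant).
    members : list of SequenceRecord
        Dereplicated member sequences with their counts.
    representative_id : str
        Member id minimising mean distance to the other members.
    max_intra_distance : float
        Cluster diameter (largest pairwise member distance), always
        <= the clustering cutoff.
    consensus : dict source_db -> TaxonomyLineage
        Per-database consensus lineage over the members.
    """

    otu_id: str
    members: list[SequenceRecord]
    representative_id: str = ""
    max_intra_distance: float = 0.0
    consensus: dict[str, TaxonomyLineage] = dc_field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(m.count for m in self.members)

    @property
    def representative(self) -> SequenceRecord:
        for m in self.members:
            if m.id == self.representative_id:
                return m
        raise ValueError(f"{self.otu_id}: representative not among members")


def _encode(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Stack equal-length sequences into a (n, L) byte matrix."""
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
    return np.frombuffer(
        "".join(rec.seq for rec in records).encode("ascii"), dtype=np.uint8
    ).reshape(len(records), lengths.pop())


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


def _mismatch_matrix(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Pairwise Hamming mismatch counts, shape (n, n), dtype int."""
    mat = _encode(records)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)


# ---------------------------------------------------------------------------
# Read preparation
# ---------------------------------------------------------------------------


def trim_and_dereplicate(
    reads: Iterable[SequenceRecord], length: int = 100
) -> list[SequenceRecord]:
    """Trim reads to a fixed 5' length and merge identical sequences.

    Reads shorter than ``length`` are discarded (downstream distances
    need equal lengths). Identical trimmed sequences are merged with
    their counts summed; the total output count equals the number of
    reads retained. Output is sorted by descending count, ties broken
    by lexicographic sequence order, and re-identified ``U1``, ``U2``...

    Parameters
    ----------
    reads : iterable of SequenceRecord
        Raw or pre-dereplicated reads (counts are honoured).
    length : int
        Trim length in bp (default 100).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    pooled: dict[str, int] = {}
    for read in reads:
        if len(read.seq) < length:
            continue
        trimmed = read.seq[:length]
        pooled[trimmed] = pooled.get(trimmed, 0) + read.count
    ordered = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        SequenceRecord(id=f"U{i + 1}", seq=seq, count=count)
        for i, (seq, count) in enumerate(ordered)
    ]


def remove_singletons(uniques: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Drop dereplicated sequences observed exactly once, keeping order."""
    return [u for u in uniques if u.count >= 2]


def precluster_map(
    uniques: Sequence[SequenceRecord], max_diffs: int = 1
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Like :func:`precluster`, also returning the absorption map.

    The second element maps every input record id to the id of the
    survivor that absorbed it (survivors map to themselves).
    """
    if max_diffs < 0:
        raise ValueError("max_diffs must be >= 0")
    if not uniques:
        return [], {}
    order = sorted(range(len(uniques)), key=lambda i: (-uniques[i].count, uniques[i].seq))
    recs = [uniques[i] for i in order]
    mm = _mismatch_matrix(recs)
    n = len(recs)
    absorbed = np.zeros(n, dtype=bool)
    survivors: list[SequenceRecord] = []
    absorbed_by: dict[str, str] = {}
    for i in range(n):
        if absorbed[i]:
            continue
        count = recs[i].count
        absorbed_by[recs[i].id] = recs[i].id
        close = np.flatnonzero((mm[i] <= max_diffs) & ~absorbed)
        for j in close:
            if j > i:
                count += recs[j].count
                absorbed[j] = True
                absorbed_by[recs[j].id] = recs[i].id
        survivors.append(SequenceRecord(id=recs[i].id, seq=recs[i].seq, count=count))
    return survivors, absorbed_by


def precluster(
    uniques: Sequence[SequenceRecord], max_diffs: int = 1
) -> list[SequenceRecord]:
    """Absorb near-identical low-abundance sequences into abundant ones.

    Greedy pre.cluster-style absorption: records are visited in
    descending count order (ties by sequence); each record that has not
    itself been absorbed becomes a survivor and absorbs every
    not-yet-absorbed later record within ``max_diffs`` mismatches,
    adding its count. Absorbed records cannot absorb others, so two
    survivors always differ at more than ``max_diffs`` positions.
    Total count is conserved.
    """
    survivors, _ = precluster_map(uniques, max_diffs)
    return survivors


def filter_by_taxonomy(
    uniques: Sequence[SequenceRecord],
    classifications: Mapping[str, TaxonomyLineage],
    blacklist: Iterable[str] = DEFAULT_TAXON_BLACKLIST,
) -> list[SequenceRecord]:
    """Remove sequences classified into blacklisted lineages.

    A record is removed when its lineage contains any blacklisted name
    at any rank (case-insensitive). Records without a classification
    are treated as "unknown" — removed and logged — so unclassifiable
    reads never reach clustering.
    """
    names = {b.lower() for b in blacklist}
    kept: list[SequenceRecord] = []
    for rec in uniques:
        lineage = classifications.get(rec.id)
        if lineage is None or not len(lineage):
            # unclassified == "unknown" lineage
            if "unknown" in names:
                if lineage is None:
                    logger.warning(
                        "sequence %s has no classification; removed", rec.id
                    )
                continue
            kept.append(rec)
            continue
        if any(lineage.contains(b) for b in names):
            continue
        kept.append(rec)
    return kept


def drop_blacklisted_ids(
    uniques: Sequence[SequenceRecord], ids: Iterable[str]
) -> list[SequenceRecord]:
    """Remove records by id (hook for externally detected chimeras)."""
    drop = set(ids)
    return [u for u in uniques if u.id not in drop]


# ---------------------------------------------------------------------------
# Furthest-neighbour clustering
# ---------------------------------------------------------------------------


def cluster_furthest_neighbour(
    uniques: Sequence[SequenceRecord], cutoff: float = 0.03
) -> list[OTUCluster]:
    """Agglomerative complete-linkage clustering at a distance cutoff.

    Pairwise distance is Hamming mismatches / length on the
    equal-length sequences. Merges are performed in ascending order of
    complete-linkage (maximum pairwise) distance while that distance is
    <= ``cutoff``; equal-distance merges are resolved by the
    lexicographically smallest pair of sorted member-index sets. Every
    resulting cluster therefore has diameter <= ``cutoff``, and the
    clusters partition the input. OTU ids are assigned by descending
    total member count (``OTU0001``...), ties by member set.

    The default cutoff 0.03 corresponds to the conventional 97%
    similarity threshold.
    """
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must be in [0, 1]")
    if not uniques:
        return []
    mm = _mismatch_matrix(uniques)
    length = len(uniques[0].seq)
    max_mm = int(np.floor(cutoff * length + 1e-9))

    clusters: list[tuple[int, ...]] = [(i,) for i in range(len(uniques))]
    while len(clusters) > 1:
        best_key = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = int(mm[np.ix_(clusters[a], clusters[b])].max())
                if d > max_mm:
                    continue
                pair = tuple(sorted((clusters[a], clusters[b])))
                key = (d, pair)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]

    def total(members: tuple[int, ...]) -> int:
        return sum(uniques[i].count for i in members)

    ordered = sorted(clusters, key=lambda c: (-total(c), c))
    width = max(4, len(str(len(ordered))))
    out = []
    for rank, members in enumerate(ordered, start=1):
        recs = [uniques[i] for i in members]
        diam = max((mm[i, j] for i in members for j in members), default=0) / length
        cluster = OTUCluster(
            otu_id=f"OTU{rank:0{width}d}",
            members=recs,
            max_intra_distance=float(diam),
        )
        cluster.representative_id = pick_representative(cluster)
        out.append(cluster)
    return out


def pick_representative(cluster: OTUCluster) -> str:
    """Id of the member with minimal mean distance to the other members.

    Ties are broken by larger count, then lexicographic sequence order;
    invariant under permutation of the member list.
    """
    members = cluster.members
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0].id
    mm = _mismatch_matrix(members)
    n = len(members)
    mean_d = mm.sum(axis=1) / (n - 1)
    best = min(range(n), key=lambda i: (mean_d[i], -members[i].count, members[i].seq))
    return members[best].id


def consensus_taxonomy(
    cluster: OTUCluster,
    classifications: Mapping[str, TaxonomyLineage],
    threshold: float = 0.51,
) -> TaxonomyLineage:
    """Count-weighted per-rank majority lineage over a cluster's members.

    Going rank by rank from the domain downward, a taxon is kept when
    the members carrying it represent at least ``threshold`` of the
    cluster's total count; the lineage is truncated at the first rank
    where no taxon reaches the threshold.

    ``threshold`` must exceed 0.5 so that at most one taxon can win a
    rank; the default 0.51 is a simple count-weighted majority.
    """
    if not (0.5 < threshold <= 1):
        raise ValueError("threshold must be in (0.5, 1]")
    lineages = []
    total = 0
    source = ""
    for m in cluster.members:
        lin = classifications[m.id]
        lineages.append((lin, m.count))
        total += m.count
        source = lin.source_db or source
    ranks: list[tuple[str, str]] = []
    depth = 0
    while True:
        tally: dict[tuple[str, str], int] = {}
        for lin, weight in lineages:
            if depth < len(lin.ranks):
                tally[lin.ranks[depth]] = tally.get(lin.ranks[depth], 0) + weight
        winner = None
        for rank_taxon, weight in sorted(tally.items()):
            if weight / total >= threshold:
                winner = rank_taxon
                break
        if winner is None:
            break
        ranks.append(winner)
        depth += 1
    return TaxonomyLineage(ranks=tuple(ranks), source_db=source)


def build_otu_table(
    clusters: Sequence[OTUCluster],
    per_sample_counts: Mapping[tuple[str, str], int],
) -> FeatureTable:
    """Collapse per-sequence sample counts into an OTU abundance table.

    ``per_sample_counts`` maps ``(sample_id, sequence_id)`` to a read
    count. Each table entry is the sum of the cluster's member counts in
    that sample, so the grand total is conserved. Samples appear in
    sorted id order. A cluster member absent from every sample raises.
    """
    sample_ids = sorted({s for s, _ in per_sample_counts})
    by_seq: dict[str, dict[str, int]] = {}
    for (sid, qid), c in per_sample_counts.items():
        col = by_seq.setdefault(qid, {})
        col[sid] = col.get(sid, 0) + c
    counts = np.zeros((len(sample_ids), len(clusters)), dtype=np.int64)
    sindex = {s: i for i, s in enumerate(sample_ids)}
    taxonomy: dict[str, TaxonomyLineage] = {}
    for j, cluster in enumerate(clusters):
        for m in cluster.members:
            if m.id not in by_seq:
                raise ValueError(
                    f"{cluster.otu_id}: member {m.id!r} has no per-sample counts"
                )
            for sid, c in by_seq[m.id].items():
                counts[sindex[sid], j] += c
        if cluster.consensus:
            # prefer silva, then any source, for the table's single lineage slot
            db = "silva" if "silva" in cluster.consensus else sorted(cluster.consensus)[0]
            taxonomy[cluster.otu_id] = cluster.consensus[db]
    return FeatureTable(
        sample_ids,
        [c.otu_id for c in clusters],
        counts,
        taxonomy or None,
    )


@dataclass
class DenovoResult:
    """Everything :func:`run_denovo` produces.

    ``seq_to_otu`` maps each retained trimmed sequence (string) to its
    OTU id, letting callers assign original reads to OTUs.
    """

    clusters: list[OTUCluster]
    seq_to_otu: dict[str, str]
    table: FeatureTable | None = None


def run_denovo(
    reads: Sequence[SequenceRecord],
    per_sample_counts: Mapping[tuple[str, str], int] | None = None,
    classifications: Mapping[str, Mapping[str, TaxonomyLineage]] | None = None,
    trim_length: int = 100,
    min_count: int = 2,
    max_diffs: int = 1,
    cutoff: float = 0.03,
    blacklist: Iterable[str] = DEFAULT_TAXON_BLACKLIST,
    chimera_ids: Iterable[str] = (),
    consensus_threshold: float = 0.51,
) -> DenovoResult:
    """Run the whole de novo workflow on raw reads.

    Stages: trim to ``trim_length`` and dereplicate; drop records with
    count < ``min_count`` (default removes singletons); precluster at
    ``max_diffs`` mismatches; drop blacklisted lineages (a sequence is
    removed when *any* database classifies it into a blacklisted taxon,
    or when no database classifies it at all); drop externally supplied
    chimera ids; complete-linkage cluster at ``cutoff``; pick
    representatives and per-database consensus taxonomies.

    Parameters
    ----------
    reads : sequence of SequenceRecord
        Raw reads, or dereplicated records with counts.
    per_sample_counts : mapping (sample_id, read_id) -> count, optional
        Per-sample abundances of the *input* reads; when given, an OTU
        table is assembled by following each read through trimming,
        dereplication, and preclustering into its OTU. Reads lost along
        the way (too short, singleton, blacklisted) are dropped.
    classifications : mapping source_db -> (mapping key -> lineage)
        Per-database classifications keyed by trimmed sequence string
        (read ids are also accepted as keys).
    """
    # read id -> trimmed sequence, for table assembly later
    read_seq: dict[str, str] = {}
    for r in reads:
        if len(r.seq) >= trim_length:
            read_seq[r.id] = r.seq[:trim_length]

    uniques = trim_and_dereplicate(reads, length=trim_length)
    uniques = [u for u in uniques if u.count >= min_count]
    survivors, absorbed_by = precluster_map(uniques, max_diffs=max_diffs)

    seq_of_uid = {u.id: u.seq for u in uniques}

    def _resolve(db_map: Mapping[str, TaxonomyLineage], rec: SequenceRecord):
        return db_map.get(rec.seq) or db_map.get(rec.id)

    classifications = classifications or {}
    if classifications:
        kept = []
        for rec in survivors:
            lineages = [
                lin
                for db_map in classifications.values()
                if (lin := _resolve(db_map, rec)) is not None
            ]
            if not lineages:
                logger.warning("sequence %s unclassified in every database; removed", rec.id)
                continue
            names = {b.lower() for b in blacklist}
            if any(any(lin.contains(b) for b in names) or not len(lin) for lin in lineages):
                continue
            kept.append(rec)
        survivors = kept
    survivors = drop_blacklisted_ids(survivors, chimera_ids)

    clusters = cluster_furthest_neighbour(survivors, cutoff=cutoff)
    for cluster in clusters:
        for db, db_map in classifications.items():
            member_lineages = {m.id: _resolve(db_map, m) for m in cluster.members}
            if all(v is not None for v in member_lineages.values()):
                cluster.consensus[db] = consensus_taxonomy(
                    cluster, member_lineages, threshold=consensus_threshold
                )

    # map every retained trimmed sequence to its OTU via its precluster survivor
    uid_to_otu = {
        m.id: c.otu_id for c in clusters for m in c.members
    }
    seq_to_otu: dict[str, str] = {}
    for u in uniques:
        survivor_id = absorbed_by.get(u.id)
        if survivor_id in uid_to_otu:
            seq_to_otu[u.seq] = uid_to_otu[survivor_id]
    # survivors' own sequences too (identical, but keeps the map total)
    for uid, otu in uid_to_otu.items():
        seq_to_otu[seq_of_uid[uid]] = otu

    table = None
    if per_sample_counts is not None:
        member_counts: dict[tuple[str, str], int] = {}
        otu_members = {
            c.otu_id: {m.id for m in c.members} for c in clusters
        }
        uid_of_seq = {u.seq: u.id for u in uniques}
        for (sample_id, read_id), count in per_sample_counts.items():
            seq = read_seq.get(read_id)
            if seq is None or seq not in seq_to_otu:
                continue
            survivor_id = absorbed_by[uid_of_seq[seq]]
            key = (sample_id, survivor_id)
            member_counts[key] = member_counts.get(key, 0) + count
        table = build_otu_table(clusters, member_counts)
    return DenovoResult(clusters=clusters, seq_to_otu=seq_to_otu, table=table)
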