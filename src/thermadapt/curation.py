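"""Dataset-curation pipeline: thermal labeling, filtering, identity
clustering, hard-negative mining, leakage-free splitting, Tm-bin
rebalancing, identity-binned test stratification, and SQLite export.

Clustering is a deterministic greedy incremental scheme (CD-HIT-style):
records are sorted by descending length (ties by id) and each joins the
first existing centroid it matches at or above the identity threshold,
otherwise founds a new cluster.  Sequence identity is defined once for the
whole package: global alignment, BLOSUM62 scoring with affine gaps
(open 10, extend 0.5), identity = identical aligned columns / alignment
length, gap columns counted in the denominator.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import (
    SubstitutionMatrix,
    align_optimal,
    get_sequence_identity,
)

from .seqio import (
    NON_THERMOPHILIC,
    RARE_AA,
    THERMOPHILIC,
    UNLABELED,
    SequenceRecord,
)

TRAIN, VAL, TEST = "train", "val", "test"


@dataclass(frozen=True)
class ThermalLabelRule:
    """Growth-temperature thresholds defining the two thermal classes."""

    t_hot: float = 60.0
    t_cold: float = 30.0

    def __post_init__(self) -> None:
        if self.t_cold >= self.t_hot:
            raise ValueError("t_cold must be below t_hot")


@dataclass(frozen=True)
class Cluster:
    """An identity cluster: centroid plus members (centroid included)."""

    centroid_id: str
    member_ids: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be a member of its cluster")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class HardNegativePair:
    """A cross-class pair at 80 % < identity < 95 %."""

    thermo_id: str
    non_thermo_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.80 < self.identity < 0.95:
            raise ValueError("hard-negative identity must be in (0.80, 0.95)")


@dataclass(frozen=True)
class SplitAssignment:
    """Cluster-granular train/val/test assignment."""

    assignment: Mapping[str, str]    # id -> split
    seed: int
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def ids_in(self, split: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == split]


@dataclass(frozen=True)
class TmBinPlan:
    """Per-10-°C-bin evaluation sampling and train rebalancing plan."""

    bin_width: float = 10.0
    eval_per_bin: int = 10
    train_target: int | None = None  # None = median occupied-bin size


def label_from_growth_temp(
    growth_temp: float, rule: ThermalLabelRule | None = None
) -> str:
    """Thermal class from growth temperature: >60 °C thermophilic,
    <30 °C non-thermophilic, otherwise unlabeled (excluded)."""
    rule = rule or ThermalLabelRule()
    if not np.isfinite(growth_temp):
        raise ValueError("growth temperature must be finite")
    if growth_temp > rule.t_hot:
        return THERMOPHILIC
    if growth_temp < rule.t_cold:
        return NON_THERMOPHILIC
    return UNLABELED


def label_records(
    records: Sequence[SequenceRecord], rule: ThermalLabelRule | None = None
) -> list[SequenceRecord]:
    """Apply the labeling rule to every record carrying a growth temperature."""
    out = []
    for r in records:
        if r.growth_temp is None:
            out.append(r)
        else:
            out.append(r.with_(thermal_class=label_from_growth_temp(r.growth_temp, rule)))
    return out


_AMBIGUOUS = frozenset(RARE_AA)


def filter_records(
    records: Sequence[SequenceRecord], min_len: int = 30
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Drop short (< ``min_len``) and ambiguous (B/J/O/U/X/Z-containing)
    sequences; return kept records and a reason per dropped id."""
    kept: list[SequenceRecord] = []
    dropped: dict[str, str] = {}
    for r in records:
        if len(r.sequence) < min_len:
            dropped[r.id] = "short"
        elif set(r.sequence) & _AMBIGUOUS:
            dropped[r.id] = "ambiguous"
        else:
            kept.append(r)
    return kept, dropped


# -- pairwise identity -------------------------------------------------------

# biotite requires integer gap penalties, so the (BLOSUM62, open 10,
# extend 0.5) scoring is applied in score-equivalent integer form:
# matrix doubled, open 20, extend 1.  Optimal alignments are unchanged.
_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()
_MATRIX_X2 = SubstitutionMatrix(
    _BLOSUM62.get_alphabet1(), _BLOSUM62.get_alphabet2(),
    _BLOSUM62.score_matrix() * 2,
)
GAP_PENALTY = (-20, -1)  # doubled (open 10, extend 0.5)


def align_global(a: str, b: str):
    """Optimal global alignment of two sequences (first optimum returned)."""
    return align_optimal(
        ProteinSequence(a), ProteinSequence(b), _MATRIX_X2,
        gap_penalty=GAP_PENALTY, terminal_penalty=True, max_number=1,
    )[0]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned columns over the global alignment
    length (gap columns count in the denominator)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return float(get_sequence_identity(align_global(a, b), mode="all"))


def identity_upper_bound(a: str, b: str) -> float:
    """Cheap exact upper bound on :func:`pairwise_identity`.

    Identical columns cannot exceed the residue-multiset intersection, and
    the alignment length is at least the longer sequence, so
    ``intersection / max(len)`` bounds the identity from above.  Used to
    skip alignments that cannot reach a threshold.
    """
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    inter = sum(min(ca[x], cb[x]) for x in ca)
    return inter / max(len(a), len(b))


# -- clustering --------------------------------------------------------------


def greedy_cluster(
    records: Sequence[SequenceRecord], threshold: float
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Records are visited by descending length (ties by id); each joins the
    first centroid with identity >= threshold, else founds a new cluster.
    Deterministic given the input set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    centroids: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        for ci, cen in enumerate(centroids):
            if identity_upper_bound(rec.sequence, cen.sequence) < threshold:
                continue
            if pairwise_identity(rec.sequence, cen.sequence) >= threshold:
                members[ci].append(rec.id)
                break
        else:
            centroids.append(rec)
            members.append([rec.id])
    return [
        Cluster(centroid_id=c.id, member_ids=tuple(m), threshold=threshold)
        for c, m in zip(centroids, members)
    ]


def cluster_classes(
    records: Sequence[SequenceRecord],
    thermo_threshold: float = 0.50,
    non_thermo_threshold: float = 0.80,
) -> list[Cluster]:
    """Cluster each thermal class separately at its own threshold
    (50 % thermophilic, 80 % non-thermophilic)."""
    thermo = [r for r in records if r.thermal_class == THERMOPHILIC]
    non = [r for r in records if r.thermal_class == NON_THERMOPHILIC]
    return greedy_cluster(thermo, thermo_threshold) + greedy_cluster(
        non, non_thermo_threshold
    )


# -- hard negatives ----------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def mine_hard_negatives(
    non_thermo: Sequence[SequenceRecord],
    thermo: Sequence[SequenceRecord],
    low: float = 0.80,
    high: float = 0.95,
    prefilter_k: int = 5,
) -> list[HardNegativePair]:
    """All cross-class pairs with ``low < identity < high`` (strict bounds).

    Pairs that share no exact ``prefilter_k``-mer are skipped without
    alignment (MMseqs-style prefilter); at the identities of interest
    (> 80 %) homologous pairs always share short exact words.
    """
    thermo_kmers = [(t, _kmer_set(t.sequence, prefilter_k)) for t in thermo]
    pairs: list[HardNegativePair] = []
    for n in non_thermo:
        nk = _kmer_set(n.sequence, prefilter_k)
        for t, tk in thermo_kmers:
            if prefilter_k > 0 and not (nk & tk):
                continue
            ident = pairwise_identity(n.sequence, t.sequence)
            if low < ident < high:
                pairs.append(
                    HardNegativePair(thermo_id=t.id, non_thermo_id=n.id, identity=ident)
                )
    return pairs


# -- splitting ---------------------------------------------------------------


def assign_splits(
    clusters: Sequence[Cluster],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    force_train_ids: Iterable[str] = (),
) -> SplitAssignment:
    """Assign whole clusters to train/val/test.

    Clusters containing any forced-train id (e.g. hard-negative members) go
    to train.  The remaining clusters are shuffled by the seed and greedily
    fill the validation quota, then the test quota (quotas measured in
    sequences = ratio × total), with the remainder in train.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    forced = set(force_train_ids)
    all_ids = [i for c in clusters for i in c.member_ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("clusters are not disjoint")
    unknown = forced - set(all_ids)
    if unknown:
        raise ValueError(f"forced ids not present in any cluster: {sorted(unknown)}")
    total = len(all_ids)
    quota_val = ratios[1] * total
    quota_test = ratios[2] * total
    rng = np.random.default_rng(seed)
    free: list[Cluster] = []
    assignment: dict[str, str] = {}
    for c in clusters:
        if forced & set(c.member_ids):
            for i in c.member_ids:
                assignment[i] = TRAIN
        else:
            free.append(c)
    order = rng.permutation(len(free))
    n_val = n_test = 0
    for ci in order:
        c = free[ci]
        # a cluster joins an evaluation split only if at least half of it
        # fits the remaining quota, so a lone oversized cluster stays in
        # train rather than emptying the training set
        if n_val < quota_val and quota_val - n_val >= len(c) / 2:
            split = VAL
            n_val += len(c)
        elif n_test < quota_test and quota_test - n_test >= len(c) / 2:
            split = TEST
            n_test += len(c)
        else:
            split = TRAIN
        for i in c.member_ids:
            assignment[i] = split
    return SplitAssignment(assignment=assignment, seed=seed, ratios=ratios)


# -- Tm-bin splitting --------------------------------------------------------


def _tm_bin(tm: float, width: float) -> int:
    return int(np.floor(tm / width))


def plan_tm_splits(
    records: Sequence[SequenceRecord],
    plan: TmBinPlan | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[SequenceRecord]]:
    """Bin records by melting temperature and build train/val/test.

    Bins are half-open ``[10k, 10(k+1))`` °C.  Per non-empty bin, up to 10
    records go to validation and up to 10 to test (without replacement).
    The remaining train records are rebalanced per bin to a common target
    count (default: median occupied-bin train count) — undersampled without
    replacement or oversampled with replacement.
    """
    plan = plan or TmBinPlan()
    if not records:
        raise ValueError("no records to split")
    for r in records:
        if r.melting_temp is None:
            raise ValueError(f"record {r.id!r} has no melting temperature")
    rng = np.random.default_rng(seed)
    bins: dict[int, list[SequenceRecord]] = {}
    for r in records:
        bins.setdefault(_tm_bin(r.melting_temp, plan.bin_width), []).append(r)
    val: list[SequenceRecord] = []
    test: list[SequenceRecord] = []
    train_bins: dict[int, list[SequenceRecord]] = {}
    for k in sorted(bins):
        pool = sorted(bins[k], key=lambda r: r.id)
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        n_eval = plan.eval_per_bin
        val.extend(pool[:n_eval])
        test.extend(pool[n_eval : 2 * n_eval])
        train_bins[k] = pool[2 * n_eval :]
    occupied = [len(v) for v in train_bins.values() if len(v) > 0]
    if not occupied:
        return [], val, test
    target = plan.train_target or int(np.median(occupied))
    target = max(target, 1)
    train: list[SequenceRecord] = []
    for k in sorted(train_bins):
        pool = train_bins[k]
        if not pool:
            continue
        if len(pool) >= target:
            idx = rng.choice(len(pool), size=target, replace=False)
        else:
            idx = rng.choice(len(pool), size=target, replace=True)
        train.extend(pool[i] for i in idx)
    return train, val, test


# -- identity-binned test stratification -------------------------------------

DEFAULT_IDENTITY_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8)


def max_identity_to_train(
    record: SequenceRecord, train_records: Sequence[SequenceRecord]
) -> float:
    """Maximum identity of one record to any training record (exact;
    alignments whose upper bound cannot beat the current best are skipped)."""
    best = 0.0
    for t in train_records:
        if identity_upper_bound(record.sequence, t.sequence) <= best:
            continue
        best = max(best, pairwise_identity(record.sequence, t.sequence))
    return best


def bin_by_max_identity(
    test_records: Sequence[SequenceRecord],
    train_records: Sequence[SequenceRecord],
    bin_edges: Sequence[float] = DEFAULT_IDENTITY_EDGES,
) -> dict[tuple[float, float], list[str]]:
    """Group test records by their maximum identity to any training record.

    Bins are half-open ``[lo, hi)``; the top bin is closed at 1.0 so exact
    duplicates land in it.
    """
    if not test_records or not train_records:
        raise ValueError("both test and train sets must be non-empty")
    edges = list(bin_edges) + [1.0 + 1e-12]
    out: dict[tuple[float, float], list[str]] = {
        (edges[i], min(edges[i + 1], 1.0)): [] for i in range(len(edges) - 1)
    }
    keys = list(out)
    for rec in test_records:
        m = max_identity_to_train(rec, train_records)
        for (lo, hi), key in zip(zip(edges, edges[1:]), keys):
            if lo <= m < hi:
                out[key].append(rec.id)
                break
    return out


# -- SQLite export -----------------------------------------------------------

_SCHEMA = """
CREATE TABLE sequences (
    id TEXT PRIMARY KEY, sequence TEXT NOT NULL, organism TEXT,
    growth_temp REAL, melting_temp REAL, thermal_class TEXT NOT NULL
);
CREATE TABLE clusters (
    centroid_id TEXT NOT NULL, member_id TEXT NOT NULL, threshold REAL NOT NULL
);
CREATE TABLE splits (id TEXT PRIMARY KEY, split TEXT NOT NULL, seed INTEGER);
CREATE TABLE pairs (
    thermo_id TEXT NOT NULL, non_thermo_id TEXT NOT NULL, identity REAL NOT NULL
);
"""


def export_sqlite(
    records: Sequence[SequenceRecord],
    path: str | Path,
    splits: SplitAssignment | None = None,
    clusters: Sequence[Cluster] = (),
    pairs: Sequence[HardNegativePair] = (),
) -> Path:
    """Write a one-file relational store (sequences/clusters/splits/pairs)."""
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO sequences VALUES (?,?,?,?,?,?)",
            [
                (r.id, r.sequence, r.organism, r.growth_temp, r.melting_temp,
                 r.thermal_class)
                for r in records
            ],
        )
        con.executemany(
            "INSERT INTO clusters VALUES (?,?,?)",
            [(c.centroid_id, m, c.threshold) for c in clusters for m in c.member_ids],
        )
        if splits is not None:
            con.executemany(
                "INSERT INTO splits VALUES (?,?,?)",
                [(i, s, splits.seed) for i, s in splits.assignment.items()],
            )
        con.executemany(
            "INSERT INTO pairs VALUES (?,?,?)",
            [(p.thermo_id, p.non_thermo_id, p.identity) for p in pairs],
        )
        con.commit()
    finally:
        con.close()
    return path


def import_sqlite(
    path: str | Path,
) -> tuple[list[SequenceRecord], SplitAssignment | None, list[Cluster], list[HardNegativePair]]:
    """Read back an :func:`export_sqlite` store losslessly."""
    con = sqlite3.connect(Path(path))
    try:
        records = [
            SequenceRecord(
                id=i, sequence=s, organism=o or "",
                growth_temp=g, melting_temp=m, thermal_class=c,
            )
            for i, s, o, g, m, c in con.execute(
                "SELECT id, sequence, organism, growth_temp, melting_temp,"
                " thermal_class FROM sequences"
            )
        ]
        cluster_rows = list(con.execute("SELECT centroid_id, member_id, threshold FROM clusters"))
        grouped: dict[tuple[str, float], list[str]] = {}
        for cen, mem, thr in cluster_rows:
            grouped.setdefault((cen, thr), []).append(mem)
        clusters = [
            Cluster(centroid_id=cen, member_ids=tuple(mem), threshold=thr)
            for (cen, thr), mem in grouped.items()
        ]
        split_rows = list(con.execute("SELECT id, split, seed FROM splits"))
        splits = None
        if split_rows:
            splits = SplitAssignment(
                assignment={i: s for i, s, _ in split_rows}, seed=split_rows[0][2]
            )
        pairs = [
            HardNegativePair(thermo_id=t, non_thermo_id=n, identity=d)
            for t, n, d in con.execute(
                "SELECT thermo_id, non_thermo_id, identity FROM pairs"
            )
        ]
    finally:
        con.close()
    return records, splits, clusters, pairs
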