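"""Housekeeping-cluster detection on a binary encoding of gene order.

Genes on an arm are encoded 1 (housekeeping: low tissue specificity,
tau <= cutoff, or detected in every tissue) and 0 otherwise.  Clustering of
1s is measured by the number of state transitions along the arm — maximal
clustering of five 1s among ten genes, 1111100000, has a single transition;
the dispersed 0110010101 has seven — and tested against shuffled gene
orders.  Clusters are maximal stretches that begin and end with a 1 and in
which at least every fourth gene is a 1 (internal 0-runs of at most
``max_gap`` = 3), then filtered empirically: a cluster is retained only
when clusters at least as large in both gene count and span have a <5%
chance of arising in shuffled genomes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import add_one_p, rng_from_seed

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryEncoding",
    "Cluster",
    "encode_arm",
    "drop_duplicate_genes",
    "count_transitions",
    "transition_test",
    "call_hk_clusters",
    "filter_hk_clusters",
    "cluster_recombination_test",
    "clusters_to_frame",
]


@dataclass
class BinaryEncoding:
    """0/1 states aligned to the gene order of one arm."""

    arm: str
    states: np.ndarray  # 0/1 ints in map order
    gene_ids: list[str]
    rule: str = "tau_le_cutoff"  # or "breadth_all_tissues"
    cutoff: float = 0.25

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(self.states) != len(self.gene_ids):
            raise ValueError("states and gene_ids length mismatch")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0/1")


@dataclass
class Cluster:
    """A called cluster of any type, with members in map order.

    ``span`` counts genes from first to last member inclusive (interior
    non-marked genes included); ``n_marked`` counts the marked
    (housekeeping or co-expressed) members only.
    """

    type: str  # hk_tau | hk_breadth | sr | type1
    arm: str
    member_ids: list[str]
    span: int
    n_marked: int
    passed_filter: bool | None = None
    p_filter: float | None = None
    start_index: int | None = None  # map index of first member on arm
    end_index: int | None = None  # map index of last member on arm

    def __post_init__(self):
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if self.n_marked > self.span:
            raise ValueError("n_marked cannot exceed span")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def encode_arm(
    arm: str,
    gene_ids: list[str],
    marker: pd.Series,
    rule: str = "tau_le_cutoff",
    cutoff: float = 0.25,
    n_tissues: int | None = None,
) -> BinaryEncoding:
    """Build the 0/1 encoding for one arm from a per-gene metric.

    ``marker`` is tau (rule ``tau_le_cutoff``) or breadth (rule
    ``breadth_all_tissues``, requiring ``n_tissues``).  Genes missing from
    ``marker`` or with undefined tau are encoded 0.
    """
    vals = marker.reindex(gene_ids)
    if rule == "tau_le_cutoff":
        states = (vals <= cutoff).fillna(False).to_numpy().astype(np.int8)
    elif rule == "breadth_all_tissues":
        if n_tissues is None:
            raise ValueError("breadth rule requires n_tissues")
        states = (vals >= n_tissues).fillna(False).to_numpy().astype(np.int8)
    else:
        raise ValueError(f"unknown encoding rule {rule!r}")
    return BinaryEncoding(arm=arm, states=states, gene_ids=list(gene_ids), rule=rule, cutoff=cutoff)


def drop_duplicate_genes(
    gene_ids: list[str],
    duplicates: list[tuple[str, str]],
    seed: int | None = None,
    blacklist: set[str] | None = None,
) -> set[str]:
    """Gene ids retained after removing one random member of each duplicate pair.

    Pairs with a blacklisted member are left untouched (neither removed).
    Used to re-run the transition test and cluster calling free of the
    confounding effect of tandem duplicates.
    """
    rng = rng_from_seed(seed)
    blacklist = blacklist or set()
    keep = set(gene_ids)
    for a, b in duplicates:
        if a in blacklist or b in blacklist:
            continue
        if a in keep and b in keep:
            keep.discard(a if rng.random() < 0.5 else b)
    return keep


def count_transitions(states) -> int:
    """Number of adjacent positions where the 0/1 state switches."""
    s = np.asarray(states)
    if s.size < 1:
        raise ValueError("empty state vector")
    return int(np.count_nonzero(np.diff(s.astype(np.int8))))


def transition_test(
    b: BinaryEncoding | np.ndarray,
    n_shuffles: int = 10_000,
    seed: int | None = None,
) -> tuple[int, float, float]:
    """One-tailed shuffle test for clustering of 1s (fewer transitions).

    Shuffles the state vector uniformly ``n_shuffles`` times; the p-value
    is ``(r + 1)/(n_shuffles + 1)`` where r counts shuffles with as few or
    fewer transitions than observed.  Returns
    ``(observed, p, null_median)``.
    """
    states = b.states if isinstance(b, BinaryEncoding) else np.asarray(b, dtype=np.int8)
    observed = count_transitions(states)
    k = int(states.sum())
    if k == 0 or k == states.size:
        warnings.warn("state vector is constant; clustering test is vacuous (p = 1)")
        return observed, 1.0, float(observed)
    rng = rng_from_seed(seed)
    null = np.empty(n_shuffles, dtype=np.int64)
    s = states.copy()
    for i in range(n_shuffles):
        rng.shuffle(s)
        null[i] = np.count_nonzero(np.diff(s))
    r = int((null <= observed).sum())
    return observed, add_one_p(r, n_shuffles), float(np.median(null))


def _cluster_bounds(states: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """(first, last) index of each maximal stretch of 1s with internal
    0-runs of at most ``max_gap``.  Singletons included."""
    ones = np.flatnonzero(states == 1)
    if ones.size == 0:
        return []
    # split where the gap (intervening 0s) between consecutive 1s exceeds max_gap
    breaks = np.flatnonzero(np.diff(ones) - 1 > max_gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ones.size - 1]))
    return [(int(ones[a]), int(ones[b])) for a, b in zip(starts, ends)]


def call_hk_clusters(b: BinaryEncoding, max_gap: int = 3) -> list[Cluster]:
    """Maximal housekeeping stretches on one arm.

    Each cluster begins and ends with a marked gene and no internal run of
    unmarked genes exceeds ``max_gap`` (the default 3 realizes "at least
    every fourth gene" marked).  Members are the marked genes.  Singleton
    stretches are reported (span 1) but can never pass the empirical
    filter and are excluded from downstream statistics.
    """
    clusters = []
    rule_type = "hk_tau" if b.rule == "tau_le_cutoff" else "hk_breadth"
    for first, last in _cluster_bounds(b.states, max_gap):
        members = [b.gene_ids[i] for i in range(first, last + 1) if b.states[i] == 1]
        clusters.append(
            Cluster(
                type=rule_type,
                arm=b.arm,
                member_ids=members,
                span=last - first + 1,
                n_marked=len(members),
                start_index=first,
                end_index=last,
            )
        )
    return clusters


def _random_cluster_stats(
    states: np.ndarray, max_gap: int, n_random: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (n_marked, span) of every cluster called on shuffled encodings."""
    marks: list[np.ndarray] = []
    spans: list[np.ndarray] = []
    s = states.copy()
    for _ in range(n_random):
        rng.shuffle(s)
        ones = np.flatnonzero(s == 1)
        if ones.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(ones) - 1 > max_gap)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [ones.size - 1]))
        marks.append(ends - starts + 1)
        spans.append(ones[ends] - ones[starts] + 1)
    if not marks:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(marks), np.concatenate(spans)


def filter_hk_clusters(
    clusters: list[Cluster],
    b: BinaryEncoding,
    n_random: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    max_gap: int = 3,
    joint: bool = True,
) -> list[Cluster]:
    """Empirical span/count filter against shuffled genomes.

    Clusters from ``n_random`` shuffles of the encoding are pooled; a real
    cluster passes when the (add-one) fraction of random clusters at least
    as extreme — jointly in marked-gene count AND span by default, or in
    each marginally — is below ``alpha``.  Sets ``passed_filter`` and
    ``p_filter`` on each input cluster and returns them.
    """
    rng = rng_from_seed(seed)
    marks, spans = _random_cluster_stats(b.states, max_gap, n_random, rng)
    n_pool = marks.size
    if n_pool == 0:
        warnings.warn("no random clusters generated; all real clusters pass")
        for c in clusters:
            c.passed_filter, c.p_filter = True, add_one_p(0, 1)
        return clusters
    order = np.argsort(marks)
    marks_sorted = marks[order]
    spans_by_mark = spans[order]
    for c in clusters:
        if joint:
            i0 = np.searchsorted(marks_sorted, c.n_marked, side="left")
            r = int((spans_by_mark[i0:] >= c.span).sum())
        else:
            r = max(int((marks >= c.n_marked).sum()), int((spans >= c.span).sum()))
        c.p_filter = add_one_p(r, n_pool)
        c.passed_filter = c.p_filter < alpha and c.n_marked >= 2
    return clusters


def cluster_recombination_test(
    clusters: list[Cluster],
    rates: pd.DataFrame,
    estimator: str = "RP",
) -> tuple[float, float, float]:
    """Compare recombination rates of cluster genes against the genome.

    Two-sided Wilcoxon rank-sum of per-gene rates (column ``estimator``,
    RP or ACE) for genes inside passed clusters versus all genes in the
    rate table.  Returns ``(cluster_median, genome_median, p)``.
    """
    if estimator not in rates.columns:
        raise ValueError(f"estimator column {estimator!r} not in rate table")
    in_cluster: set[str] = set()
    for c in clusters:
        if c.passed_filter is not False:
            in_cluster.update(c.member_ids)
    cluster_rates = rates.loc[rates.index.intersection(list(in_cluster)), estimator].dropna()
    genome_rates = rates[estimator].dropna()
    if cluster_rates.empty:
        raise ValueError("no recombination rates available for cluster genes")
    stat, p = stats.ranksums(cluster_rates, genome_rates)
    return float(cluster_rates.median()), float(genome_rates.median()), float(p)


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    rows = [
        {
            "type": c.type,
            "arm": c.arm,
            "first_gene": c.member_ids[0] if c.member_ids else None,
            "last_gene": c.member_ids[-1] if c.member_ids else None,
            "members": ",".join(c.member_ids),
            "span": c.span,
            "n_marked": c.n_marked,
            "p_filter": c.p_filter,
            "passed_filter": c.passed_filter,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "type", "arm", "first_gene", "last_gene", "members",
            "span", "n_marked", "p_filter", "passed_filter",
        ],
    )
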