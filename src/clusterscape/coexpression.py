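"""Co-expression cluster callers.

Two complementary definitions operate on gene order plus an expression
matrix:

* the fixed ten-gene sliding-window ("SR") caller: where the mean of all 45
  pairwise Pearson correlations in a window meets the per-arm 97.5th
  percentile randomized cutoff, the whole window enters a cluster, and
  overlapping or abutting above-threshold windows are merged;

* the dynamic growth ("type 1") caller: a cluster is seeded by the first
  pair of genes at or above the per-arm top-5% pair cutoff separated by at
  most ``gap`` intervening genes, then extended rightward — a candidate
  within ``gap`` of the current rightmost member joins if its mean
  correlation with all current members, or its correlation with the last
  member added, meets the cutoff.  Genes physically inside a cluster's
  limits that never qualify are not members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import rng_from_seed
from .expression import CoexpressionThresholds, ExpressionMatrix
from .genome import GenomeMap
from .housekeeping import Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterCallConfig",
    "sr_clusters",
    "grow_clusters",
    "nearest_coexpressed_gaps",
    "dedup_clusters",
    "distance_decay",
    "median_within_cluster_r",
]


@dataclass
class ClusterCallConfig:
    """Knobs for both callers: window size, gap tolerance, thresholds."""

    thresholds: CoexpressionThresholds
    window: int = 10
    gap: int = 3
    merge_adjacent: bool = True
    bidirectional: bool = False

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


class _ArmCorr:
    """Lazy pairwise Pearson r between genes on one arm (by map index).

    Rows with undefined profiles (zero variance or missing) yield NaN.
    """

    def __init__(self, e: ExpressionMatrix, gene_ids: list[str]):
        present = [gid in e for gid in gene_ids]
        m = e.values.shape[1]
        z = np.full((len(gene_ids), m), np.nan)
        idx = [gid for gid, p in zip(gene_ids, present) if p]
        if idx:
            zs = e.zscores().loc[idx].to_numpy()
            z[np.flatnonzero(present)] = zs
        self._z = z
        self._m = m

    def r(self, i: int, j: int) -> float:
        return float(np.dot(self._z[i], self._z[j]) / self._m)

    def r_vec(self, i: int, js: np.ndarray) -> np.ndarray:
        return self._z[js] @ self._z[i] / self._m

    def defined(self, i: int) -> bool:
        return not np.isnan(self._z[i]).any()


def sr_clusters(e: ExpressionMatrix, g: GenomeMap, cfg: ClusterCallConfig) -> list[Cluster]:
    """Ten-gene sliding-window clusters, merged where windows overlap or abut."""
    out: list[Cluster] = []
    w = cfg.window
    for arm in g.arms:
        thr = cfg.thresholds.window_threshold.get(arm)
        if thr is None:
            logger.info("arm %s: no window threshold, SR calling skipped", arm)
            continue
        ids = [gene.id for gene in g.genes_on(arm)]
        n = len(ids)
        if n < w:
            logger.info("arm %s: %d genes < window %d, no SR calls", arm, n, w)
            continue
        corr = _ArmCorr(e, ids)
        # window mean over defined pairs only
        above = np.zeros(n - w + 1, dtype=bool)
        for s in range(n - w + 1):
            block = corr._z[s : s + w]
            rmat = block @ block.T / corr._m
            iu = np.triu_indices(w, k=1)
            vals = rmat[iu]
            vals = vals[~np.isnan(vals)]
            if vals.size and vals.mean() >= thr:
                above[s] = True
        # merge overlapping (and, by default, abutting) above-threshold windows
        reach = w if cfg.merge_adjacent else w - 1
        s = 0
        while s < above.size:
            if not above[s]:
                s += 1
                continue
            first = s
            last_window = s
            t = s + 1
            while t < above.size and t <= last_window + reach:
                if above[t]:
                    last_window = t
                t += 1
            members = ids[first : last_window + w]
            out.append(
                Cluster(
                    type="sr",
                    arm=arm,
                    member_ids=members,
                    span=len(members),
                    n_marked=len(members),
                    start_index=first,
                    end_index=last_window + w - 1,
                )
            )
            s = last_window + w
    return out


def grow_clusters(e: ExpressionMatrix, g: GenomeMap, cfg: ClusterCallConfig) -> list[Cluster]:
    """Dynamic gap-tolerant type-1 clusters grown from seed pairs.

    Scans each arm left to right; assigned genes never seed or join a
    later cluster (clusters are disjoint).
    """
    out: list[Cluster] = []
    gap = cfg.gap
    for arm in g.arms:
        thr = cfg.thresholds.pair_threshold.get(arm)
        if thr is None:
            logger.info("arm %s: no pair threshold, growth calling skipped", arm)
            continue
        ids = [gene.id for gene in g.genes_on(arm)]
        n = len(ids)
        corr = _ArmCorr(e, ids)
        assigned = np.zeros(n, dtype=bool)
        i = 0
        while i < n - 1:
            if assigned[i] or not corr.defined(i):
                i += 1
                continue
            # seed: first partner within gap intervening genes at/above threshold
            seed_j = None
            for j in range(i + 1, min(i + gap + 2, n)):
                if assigned[j] or not corr.defined(j):
                    continue
                if corr.r(i, j) >= thr:
                    seed_j = j
                    break
            if seed_j is None:
                i += 1
                continue
            members = [i, seed_j]
            last_added = seed_j
            rightmost = seed_j
            while True:
                joined = False
                for k in range(rightmost + 1, min(rightmost + gap + 2, n)):
                    if assigned[k] or not corr.defined(k):
                        continue
                    r_last = corr.r(k, last_added)
                    mean_r = float(np.nanmean(corr.r_vec(k, np.array(members))))
                    if mean_r >= thr or r_last >= thr:
                        members.append(k)
                        last_added = k
                        rightmost = k
                        joined = True
                        break
                if not joined:
                    break
            for k in members:
                assigned[k] = True
            out.append(
                Cluster(
                    type="type1",
                    arm=arm,
                    member_ids=[ids[k] for k in members],
                    span=members[-1] - members[0] + 1,
                    n_marked=len(members),
                    start_index=members[0],
                    end_index=members[-1],
                )
            )
            i = rightmost + 1
    return out


def nearest_coexpressed_gaps(clusters: list[Cluster], g: GenomeMap) -> pd.Series:
    """Distribution of intervening-gene counts to each member's nearest co-member.

    For every member of every (type-1) cluster, the number of intervening
    genes between it and its nearest co-member on the map; returned as a
    frequency table indexed by gap size.
    """
    gaps: list[int] = []
    for c in clusters:
        pos = sorted(g.position(m)[1] for m in c.member_ids)
        if len(pos) < 2:
            continue
        for a, p in enumerate(pos):
            nearest = min(
                abs(p - q) - 1 for b, q in enumerate(pos) if b != a
            )
            gaps.append(nearest)
    counts = pd.Series(gaps, dtype=int).value_counts().sort_index()
    counts.name = "n_members"
    counts.index.name = "intervening_genes"
    return counts


def dedup_clusters(
    clusters: list[Cluster], duplicates: list[tuple[str, str]], seed: int | None = None
) -> list[Cluster]:
    """Remove one random gene of each duplicate pair found within a cluster.

    Clusters left with fewer than two members are deleted.  Deterministic
    under ``seed``.
    """
    rng = rng_from_seed(seed)
    out: list[Cluster] = []
    for c in clusters:
        members = list(c.member_ids)
        member_set = set(members)
        for a, b in duplicates:
            if a in member_set and b in member_set:
                drop = a if rng.random() < 0.5 else b
                member_set.discard(drop)
        members = [m for m in members if m in member_set]
        if len(members) < 2:
            continue
        out.append(
            Cluster(
                type=c.type,
                arm=c.arm,
                member_ids=members,
                span=c.span,
                n_marked=len(members),
                passed_filter=c.passed_filter,
                p_filter=c.p_filter,
                start_index=c.start_index,
                end_index=c.end_index,
            )
        )
    return out


def distance_decay(
    clusters: list[Cluster],
    g: GenomeMap,
    e: ExpressionMatrix,
    metric: str = "igd",
) -> tuple[float, float, int] | None:
    """Spearman correlation between within-cluster pair distance and co-expression.

    Uses all non-overlapping same-cluster gene pairs; distance is the bp
    gap between the two gene intervals (``igd``) or the distance between
    interval midpoints (``midpoint``).  Returns ``(rho, p, n)`` or None
    when fewer than 10 pairs are available.
    """
    if metric not in ("igd", "midpoint"):
        raise ValueError("metric must be 'igd' or 'midpoint'")
    dists: list[float] = []
    rs: list[float] = []
    zs = e.zscores()
    m = e.values.shape[1]
    for c in clusters:
        genes = [g.gene(gid) for gid in c.member_ids if gid in e]
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                ga, gb = genes[a], genes[b]
                if ga.start > gb.start:
                    ga, gb = gb, ga
                if gb.start <= ga.end:  # overlapping pair: excluded
                    continue
                za, zb = zs.loc[ga.id].to_numpy(), zs.loc[gb.id].to_numpy()
                r = float(np.dot(za, zb) / m)
                if np.isnan(r):
                    continue
                if metric == "igd":
                    dists.append(gb.start - ga.end - 1)
                else:
                    dists.append(abs(gb.midpoint - ga.midpoint))
                rs.append(r)
    if len(rs) < 10:
        warnings.warn(f"only {len(rs)} usable within-cluster pairs; distance decay undefined")
        return None
    rho, p = stats.spearmanr(dists, rs)
    return float(rho), float(p), len(rs)


def median_within_cluster_r(clusters: list[Cluster], e: ExpressionMatrix) -> float:
    """Median of all within-cluster pairwise Pearson correlations."""
    zs = e.zscores()
    m = e.values.shape[1]
    vals: list[float] = []
    for c in clusters:
        ids = [gid for gid in c.member_ids if gid in e]
        if len(ids) < 2:
            continue
        z = zs.loc[ids].to_numpy()
        rmat = z @ z.T / m
        iu = np.triu_indices(len(ids), k=1)
        v = rmat[iu]
        vals.extend(v[~np.isnan(v)].tolist())
    return float(np.median(vals)) if vals else float("nan")
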