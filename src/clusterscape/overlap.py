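"""Overlap tests between cluster sets.

The containment randomization asks whether small (type-1) clusters fall
wholly inside large (SR or housekeeping) clusters more often than chance:
small-cluster locations are held fixed while each large cluster is
re-placed uniformly at random on its arm, preserving its gene-span length.
All containment is evaluated on gene-index spans, not bp coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import add_one_p, rng_from_seed
from .genome import GenomeMap
from .housekeeping import Cluster

logger = logging.getLogger(__name__)

__all__ = ["OverlapResult", "containment_test", "per_large_overlap", "shared_gene_fraction"]


@dataclass
class OverlapResult:
    observed_proportion: float
    null_max: float
    p: float
    n_random: int


def _spans(clusters: list[Cluster], g: GenomeMap) -> list[tuple[str, int, int, int]]:
    """(arm, first index, last index, n member genes) per cluster."""
    out = []
    for c in clusters:
        pos = sorted(g.position(m)[1] for m in c.member_ids)
        if not pos:
            continue
        out.append((c.arm, pos[0], pos[-1], len(pos)))
    return out


def _contained_gene_fraction(
    small: list[tuple[str, int, int, int]], large: list[tuple[str, int, int, int]]
) -> float:
    """Fraction of small-cluster member genes whose cluster lies wholly
    within some large-cluster span.  Genes counted once each."""
    total = sum(s[3] for s in small)
    if total == 0:
        return 0.0
    inside = 0
    for arm, lo, hi, ngenes in small:
        for larm, llo, lhi, _ in large:
            if larm == arm and llo <= lo and hi <= lhi:
                inside += ngenes
                break
    return inside / total


def containment_test(
    small: list[Cluster],
    large: list[Cluster],
    g: GenomeMap,
    n_random: int = 10_000,
    seed: int | None = None,
    same_arm: bool = True,
) -> OverlapResult:
    """Randomization test for small clusters falling inside large clusters.

    Large-cluster placements are uniform over valid start genes on the
    cluster's own arm (gene-span length preserved; random placements may
    overlap each other); with ``same_arm=False`` placements are uniform
    over valid starts genome-wide.  p is the add-one fraction of
    replicates whose contained-gene proportion reaches the observed one.
    """
    rng = rng_from_seed(seed)
    arm_len = {arm: len(g.genes_on(arm)) for arm in g.arms}
    small_spans = _spans(small, g)
    large_spans = _spans(large, g)
    for arm, lo, hi, _ in large_spans:
        if hi - lo + 1 > arm_len[arm]:
            raise ValueError(f"large cluster span exceeds arm {arm} length")
    observed = _contained_gene_fraction(small_spans, large_spans)

    def _draw_placement(arm: str, span: int) -> tuple[str, int]:
        if same_arm:
            return arm, int(rng.integers(0, arm_len[arm] - span + 1))
        starts = [(a, n - span + 1) for a, n in arm_len.items() if n >= span]
        total = sum(n for _, n in starts)
        pick = int(rng.integers(0, total))
        for a, n in sorted(starts):
            if pick < n:
                return a, pick
            pick -= n
        raise AssertionError("unreachable")

    exceed = 0
    null_max = 0.0
    for _ in range(n_random):
        placed = []
        for arm, lo, hi, n in large_spans:
            span = hi - lo + 1
            parm, start = _draw_placement(arm, span)
            placed.append((parm, start, start + span - 1, n))
        prop = _contained_gene_fraction(small_spans, placed)
        null_max = max(null_max, prop)
        if prop >= observed:
            exceed += 1
    return OverlapResult(
        observed_proportion=observed,
        null_max=null_max,
        p=add_one_p(exceed, n_random),
        n_random=n_random,
    )


def per_large_overlap(
    small: list[Cluster], large: list[Cluster], g: GenomeMap
) -> tuple[float, float, float | None]:
    """Containment counts per large cluster.

    Returns the fraction of large clusters containing at least one small
    cluster, the median number of contained small clusters (over large
    clusters that contain any), and the Spearman correlation between
    large-cluster size (member genes) and contained-small count (None
    when sizes or counts are constant).
    """
    if not small or not large:
        raise ValueError("both cluster sets must be non-empty")
    small_spans = _spans(small, g)
    large_spans = _spans(large, g)
    counts = []
    for arm, llo, lhi, _ in large_spans:
        k = sum(1 for sarm, lo, hi, _ in small_spans if sarm == arm and llo <= lo and hi <= lhi)
        counts.append(k)
    counts = np.array(counts)
    sizes = np.array([n for _, _, _, n in large_spans])
    frac = float((counts > 0).mean())
    med = float(np.median(counts[counts > 0])) if (counts > 0).any() else 0.0
    if np.unique(sizes).size < 2 or np.unique(counts).size < 2:
        rho = None
    else:
        rho = float(stats.spearmanr(sizes, counts)[0])
    return frac, med, rho


def shared_gene_fraction(a: list[Cluster], b: list[Cluster]) -> tuple[float, float, float]:
    """Set-overlap fractions between two cluster collections.

    Returns (fraction of a-clusters sharing >= 1 gene with any b-cluster,
    fraction of a-cluster genes found in b-clusters, fraction of b-cluster
    genes found in a-clusters).
    """
    genes_a = {gid for c in a for gid in c.member_ids}
    genes_b = {gid for c in b for gid in c.member_ids}
    if a:
        frac_clusters = sum(1 for c in a if set(c.member_ids) & genes_b) / len(a)
    else:
        frac_clusters = 0.0
    frac_a = len(genes_a & genes_b) / len(genes_a) if genes_a else 0.0
    frac_b = len(genes_b & genes_a) / len(genes_b) if genes_b else 0.0
    return frac_clusters, frac_a, frac_b
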