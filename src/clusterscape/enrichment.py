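"""Functional (GO-Slim) enrichment of clusters.

Per cluster and term, the cumulative hypergeometric tail gives the
probability of observing ``k`` or more annotated members in a cluster of
``n`` members, when ``A`` of the ``G`` genes on the cluster's chromosomal
arm carry the term.  A cluster is *enriched* when any term's tail
probability falls below alpha; the genome-level control for multiplicity
is a randomization test on the number of enriched clusters, refilling
every cluster with random same-arm genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import add_one_p, rng_from_seed
from .genome import GenomeMap
from .housekeeping import Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "hypergeom_tail",
    "cluster_enrichment",
    "enriched_count_test",
]


class AnnotationTable:
    """Gene -> GO-Slim term sets, with a per-arm background gene list.

    A gene lacking annotation counts in the background (``G``) but toward
    no term (``A``).
    """

    def __init__(self, term_of: dict[str, set[str]], background: dict[str, list[str]]):
        self.term_of = {g: set(t) for g, t in term_of.items()}
        self.background = {arm: list(genes) for arm, genes in background.items()}
        for g in self.term_of:
            if not all(t for t in self.term_of[g]):
                raise ValueError(f"gene {g}: empty term id")
        bg_all = {g for genes in self.background.values() for g in genes}
        unknown = set(self.term_of) - bg_all
        if unknown:
            raise ValueError(f"{len(unknown)} annotated gene(s) missing from background")
        # per-arm term counts (A) cached for the randomization test
        self._arm_term_counts: dict[str, pd.Series] = {}
        for arm, genes in self.background.items():
            counts: dict[str, int] = {}
            for g in genes:
                for t in self.term_of.get(g, ()):
                    counts[t] = counts.get(t, 0) + 1
            self._arm_term_counts[arm] = pd.Series(counts, dtype=int)

    @classmethod
    def from_tsv(cls, path: str | Path, genome: GenomeMap) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "term"}.issubset(df.columns):
            df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"], dtype=str)
        term_of: dict[str, set[str]] = {}
        for r in df.itertuples():
            term_of.setdefault(r.gene_id, set()).add(r.term)
        background = {arm: [g.id for g in genome.genes_on(arm)] for arm in genome.arms}
        return cls(term_of, background)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene_id": g, "term": t}
            for g in sorted(self.term_of)
            for t in sorted(self.term_of[g])
        ]
        pd.DataFrame(rows, columns=["gene_id", "term"]).to_csv(path, sep="\t", index=False)

    def arm_size(self, arm: str) -> int:
        return len(self.background[arm])

    def term_count(self, arm: str, term: str) -> int:
        return int(self._arm_term_counts[arm].get(term, 0))


@dataclass
class EnrichmentResult:
    cluster_id: str
    term: str
    k: int  # cluster members carrying the term
    n: int  # cluster members (interior non-members excluded)
    A: int  # same-arm genes carrying the term
    G: int  # genes on the arm
    p: float


def hypergeom_tail(k: int, n: int, A: int, G: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(G, A, n).

    The probability that a uniform draw of ``n`` of ``G`` genes contains
    ``k`` or more of the ``A`` term-annotated ones.  Computed via scipy's
    log-space survival function (numerically stable).
    """
    if not (0 <= k <= n <= G and 0 <= A <= G):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} A={A} G={G}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, G, A, n))


def cluster_enrichment(
    c: Cluster, ann: AnnotationTable, alpha: float = 0.05
) -> tuple[list[EnrichmentResult], bool]:
    """Hypergeometric tests for every term carried by at least one member.

    Returns the per-term results and whether the cluster is enriched
    (any term with p < alpha).  No within-cluster multiple-testing
    correction: multiplicity is controlled genome-wide by
    :func:`enriched_count_test`.
    """
    if c.arm not in ann.background or not ann.background[c.arm]:
        raise ValueError(f"no background genes for arm {c.arm!r}")
    G = ann.arm_size(c.arm)
    n = len(c.member_ids)
    term_k: dict[str, int] = {}
    for gid in c.member_ids:
        for t in ann.term_of.get(gid, ()):
            term_k[t] = term_k.get(t, 0) + 1
    results = []
    cid = f"{c.type}:{c.arm}:{c.member_ids[0]}" if c.member_ids else f"{c.type}:{c.arm}:-"
    for t in sorted(term_k):
        A = ann.term_count(c.arm, t)
        results.append(
            EnrichmentResult(
                cluster_id=cid, term=t, k=term_k[t], n=n, A=A, G=G,
                p=hypergeom_tail(term_k[t], n, A, G),
            )
        )
    enriched = any(r.p < alpha for r in results)
    return results, enriched


class _FastEnricher:
    """Vectorized per-arm machinery for the enriched-count randomization.

    Precomputes, per arm, a gene x term membership matrix and, per
    (term, cluster size), the minimal k whose hypergeometric tail is
    below alpha — a replicate then only needs term counts.
    """

    def __init__(self, ann: AnnotationTable, alpha: float):
        self.ann = ann
        self.alpha = alpha
        self.arm_members: dict[str, np.ndarray] = {}
        self.arm_terms: dict[str, list[str]] = {}
        self._kmin_cache: dict[tuple[str, int], np.ndarray] = {}
        for arm, genes in ann.background.items():
            terms = sorted(ann._arm_term_counts[arm].index)
            self.arm_terms[arm] = terms
            tindex = {t: j for j, t in enumerate(terms)}
            mat = np.zeros((len(genes), len(terms)), dtype=np.int16)
            for i, g in enumerate(genes):
                for t in ann.term_of.get(g, ()):
                    mat[i, tindex[t]] = 1
            self.arm_members[arm] = mat

    def kmin(self, arm: str, n: int) -> np.ndarray:
        """Per-term minimal count k such that P(X >= k) < alpha for cluster size n."""
        key = (arm, n)
        if key not in self._kmin_cache:
            G = self.ann.arm_size(arm)
            A = np.array([self.ann.term_count(arm, t) for t in self.arm_terms[arm]])
            kmin = np.full(A.size, n + 1, dtype=int)  # n+1 = never enriched
            for j, a in enumerate(A):
                for k in range(1, min(n, a) + 1):
                    if stats.hypergeom.sf(k - 1, G, a, n) < self.alpha:
                        kmin[j] = k
                        break
            self._kmin_cache[key] = kmin
        return self._kmin_cache[key]

    def enriched(self, arm: str, member_rows: np.ndarray) -> bool:
        """Whether a cluster given by row indices into the arm background is enriched."""
        counts = self.arm_members[arm][member_rows].sum(axis=0)
        return bool((counts >= self.kmin(arm, member_rows.size)).any())


def enriched_count_test(
    clusters: list[Cluster],
    ann: AnnotationTable,
    n_random: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[int, float]:
    """Randomization test on the number of enriched clusters.

    Each replicate refills every cluster with the same number of random
    genes from its arm (without replacement within a cluster) and recounts
    enriched clusters; p is the add-one fraction of replicates with as
    many or more enriched clusters than observed.
    """
    if not clusters:
        raise ValueError("enriched_count_test requires at least one cluster")
    rng = rng_from_seed(seed)
    fast = _FastEnricher(ann, alpha)
    arm_index = {
        arm: {g: i for i, g in enumerate(genes)} for arm, genes in ann.background.items()
    }
    observed = 0
    sizes: list[tuple[str, int]] = []
    for c in clusters:
        rows = np.array([arm_index[c.arm][g] for g in c.member_ids if g in arm_index[c.arm]])
        if rows.size == 0:
            continue
        sizes.append((c.arm, rows.size))
        if fast.enriched(c.arm, rows):
            observed += 1
    # all replicates of one cluster are drawn in a batch: random keys,
    # partial argsort = sampling without replacement within each replicate
    null_counts = np.zeros(n_random, dtype=int)
    for arm, n in sizes:
        N = len(ann.background[arm])
        keys = rng.random((n_random, N))
        rows = np.argpartition(keys, n, axis=1)[:, :n]
        counts = fast.arm_members[arm][rows].sum(axis=1)  # n_random x terms
        enriched = (counts >= fast.kmin(arm, n)[None, :]).any(axis=1)
        null_counts += enriched
    r = int((null_counts >= observed).sum())
    return observed, add_one_p(r, n_random)
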