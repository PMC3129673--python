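"""Gene-order-evolution statistics on adjacent pairs and synteny blocks.

Covers: per-block size / recombination / breakpoint-index summaries;
equal-count IGD binning of pair conservation; orientation-by-conservation
contingency tests; logistic models of conserved linkage on IGD and high
co-expression; the cluster-conservation randomization (clusters versus
random equal-size gene stretches, orthologous landmarks as a rearrangement
proxy); and polarity labeling of pairs against ancestral and outgroup
nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import add_one_p, rng_from_seed
from .genome import AdjacentPair, GenomeMap, SyntenyAnnotation, pair_conservation
from .housekeeping import Cluster

logger = logging.getLogger(__name__)

__all__ = [
    "ConservedBlock",
    "BinnedConservation",
    "LogisticFit",
    "block_stats",
    "size_recombination_corr",
    "bin_conservation",
    "orientation_tables",
    "orientation_composition_test",
    "logistic_conservation",
    "coexpr_recombination_corr",
    "cluster_conservation_test",
    "polarity_subset",
]


@dataclass
class ConservedBlock:
    id: object
    arm: str
    member_ids: list[str]
    size: int
    mean_recomb: dict[str, float] = field(default_factory=dict)
    breakpoint_index: float = 0.0


@dataclass
class BinnedConservation:
    n_bins: int
    bin_median_igd: np.ndarray
    bin_n: np.ndarray
    bin_prop_conserved: np.ndarray


@dataclass
class LogisticFit:
    """Logistic regression of conserved linkage on IGD and high co-expression."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    null_deviance: float
    residual_deviance: float
    lrt_p: dict[str, float]  # p for dropping each predictor
    n: int
    converged: bool


# ---------------------------------------------------------------------------
# Blocks


def block_stats(
    s: SyntenyAnnotation,
    g: GenomeMap,
    rates: pd.DataFrame | None,
    node: str,
) -> list[ConservedBlock]:
    """Per-block size, mean recombination and breakpoint index at ``node``.

    Blocks must be contiguous runs in map order (validated).  The
    breakpoint index is the number of breaks at either edge of the block,
    divided by two, where a break at an edge is a lineage (any annotation
    node other than ``node``) whose block label changes across that edge;
    arm ends contribute no breaks.
    """
    other_nodes = [n for n in s.node_labels if n != node]
    blocks: list[ConservedBlock] = []
    seen_ids: set = set()
    for arm in g.arms:
        genes = g.genes_on(arm)
        labels = [s.block(x.id, node) for x in genes]
        i = 0
        while i < len(genes):
            if labels[i] is None:
                i += 1
                continue
            j = i
            while j + 1 < len(genes) and labels[j + 1] == labels[i]:
                j += 1
            bid = labels[i]
            if bid in seen_ids:
                raise ValueError(f"block {bid!r} is not contiguous (re-appears on {arm})")
            seen_ids.add(bid)
            members = [genes[k].id for k in range(i, j + 1)]
            breaks = 0
            for edge in ((i - 1, i), (j, j + 1)):
                a, b = edge
                if a < 0 or b >= len(genes):
                    continue  # arm end: no break
                for other in other_nodes:
                    la, lb = s.block(genes[a].id, other), s.block(genes[b].id, other)
                    if la is None or lb is None or la != lb:
                        breaks += 1
            mean_recomb: dict[str, float] = {}
            if rates is not None:
                present = rates.index.intersection(members)
                for col in rates.columns:
                    vals = rates.loc[present, col].dropna()
                    mean_recomb[col] = float(vals.mean()) if len(vals) else float("nan")
            blocks.append(
                ConservedBlock(
                    id=bid,
                    arm=arm,
                    member_ids=members,
                    size=j - i + 1,
                    mean_recomb=mean_recomb,
                    breakpoint_index=breaks / 2.0,
                )
            )
            i = j + 1
    return blocks


def size_recombination_corr(
    blocks: list[ConservedBlock],
    estimator: str = "RP",
    exclude_nonrecombining: bool = False,
    zero_rate_estimator: str = "RP",
) -> tuple[float, float, int] | None:
    """Spearman correlation between block size and mean recombination rate.

    With ``exclude_nonrecombining``, blocks whose mean rate under
    ``zero_rate_estimator`` is 0 are dropped first.  None with fewer than
    3 usable blocks.
    """
    use = [
        b
        for b in blocks
        if estimator in b.mean_recomb and not np.isnan(b.mean_recomb[estimator])
    ]
    if exclude_nonrecombining:
        use = [b for b in use if b.mean_recomb.get(zero_rate_estimator, np.nan) != 0.0]
    if len(use) < 3:
        warnings.warn(f"only {len(use)} blocks; size-recombination correlation undefined")
        return None
    sizes = [b.size for b in use]
    rs = [b.mean_recomb[estimator] for b in use]
    rho, p = stats.spearmanr(sizes, rs)
    return float(rho), float(p), len(use)


def breakpoint_recombination_corr(
    blocks: list[ConservedBlock], estimator: str = "RP"
) -> tuple[float, float, int] | None:
    """Spearman correlation between mean recombination and breakpoint index."""
    use = [
        b for b in blocks
        if estimator in b.mean_recomb and not np.isnan(b.mean_recomb[estimator])
    ]
    if len(use) < 3:
        return None
    rho, p = stats.spearmanr(
        [b.mean_recomb[estimator] for b in use], [b.breakpoint_index for b in use]
    )
    return float(rho), float(p), len(use)


# ---------------------------------------------------------------------------
# Pair conservation vs IGD and orientation


def _conserved_pairs(
    pairs: list[AdjacentPair], s: SyntenyAnnotation, node: str
) -> list[tuple[AdjacentPair, bool]]:
    out = []
    for p in pairs:
        c = pair_conservation(p, s, node)
        if c is not None:
            out.append((p, c))
    return out


def equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` approximately equal-count bins.

    Nearest-rank splits on the sorted order; tied values straddling an
    edge go to the lower bin.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_bins:
        raise ValueError(f"{n} values cannot fill {n_bins} bins")
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    bins = np.minimum((ranks * n_bins) // n, n_bins - 1)
    # push ties across an edge down into the lower bin
    sorted_vals = values[order]
    sorted_bins = bins[order]
    for i in range(1, n):
        if sorted_vals[i] == sorted_vals[i - 1] and sorted_bins[i] != sorted_bins[i - 1]:
            sorted_bins[i] = sorted_bins[i - 1]
    bins[order] = sorted_bins
    if np.unique(bins).size < n_bins:
        logger.info("ties collapsed some IGD bins; %d of %d non-empty", np.unique(bins).size, n_bins)
    return bins


def bin_conservation(
    pairs: list[AdjacentPair],
    s: SyntenyAnnotation,
    node: str,
    n_bins: int = 30,
    subset: str | None = None,
) -> tuple[BinnedConservation, float, float]:
    """Equal-count IGD bins and the across-bin conservation trend.

    Uses eligible pairs only (optionally restricted to one orientation
    class); returns the binned summary plus Spearman rho and p between
    per-bin median IGD and per-bin proportion conserved (n = bins).
    """
    labeled = [
        (p, c)
        for p, c in _conserved_pairs(pairs, s, node)
        if p.eligible and (subset is None or p.orientation == subset)
    ]
    if len(labeled) < n_bins:
        raise ValueError(f"{len(labeled)} eligible pairs < {n_bins} bins")
    igd = np.array([p.igd for p, _ in labeled], dtype=float)
    cons = np.array([c for _, c in labeled], dtype=float)
    bins = equal_count_bins(igd, n_bins)
    uniq = np.unique(bins)
    med = np.array([np.median(igd[bins == b]) for b in uniq])
    nb = np.array([(bins == b).sum() for b in uniq])
    prop = np.array([cons[bins == b].mean() for b in uniq])
    rho, p = stats.spearmanr(med, prop)
    return (
        BinnedConservation(n_bins=len(uniq), bin_median_igd=med, bin_n=nb, bin_prop_conserved=prop),
        float(rho),
        float(p),
    )


def orientation_tables(
    pairs: list[AdjacentPair], s: SyntenyAnnotation, node: str
) -> tuple[pd.DataFrame, float, int, float, pd.Series]:
    """Orientation x conservation contingency table and Pearson chi-square.

    Returns (table, chi_sq, df, p, per-orientation % conserved).  Empty
    orientation classes are dropped with the df adjusted.
    """
    labeled = [(p, c) for p, c in _conserved_pairs(pairs, s, node) if p.eligible]
    if not labeled:
        raise ValueError("no eligible annotated pairs")
    df_rows = pd.DataFrame(
        {"orientation": [p.orientation for p, _ in labeled], "conserved": [c for _, c in labeled]}
    )
    table = pd.crosstab(df_rows["orientation"], df_rows["conserved"])
    table = table.reindex(columns=[True, False], fill_value=0)
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("need at least two orientation classes")
    if (table.sum(axis=0) == 0).any():
        # one conservation outcome absent: no association measurable
        chi, p, dof = 0.0, 1.0, table.shape[0] - 1
    else:
        chi, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    pct = table[True] / table.sum(axis=1) * 100.0
    pct.name = "pct_conserved"
    return table, float(chi), int(dof), float(p), pct


def orientation_composition_test(
    cluster_pairs: list[AdjacentPair], all_pairs: list[AdjacentPair]
) -> tuple[pd.DataFrame, float, int, float]:
    """Are orientation classes differently represented inside clusters?

    Compares the four-way orientation composition (divergent, convergent,
    parallel split by strand sign) of within-cluster adjacent pairs
    against all adjacent pairs (df = 3).  Returns (table, chi_sq, df, p).
    """
    from .genome import classify_orientation

    def comp(pairs):
        return pd.Series(
            [classify_orientation(p.left.strand, p.right.strand, split_parallel=True) for p in pairs]
        ).value_counts()

    cats = ["divergent", "convergent", "parallel_plus", "parallel_minus"]
    table = pd.DataFrame(
        {"cluster": comp(cluster_pairs).reindex(cats, fill_value=0),
         "genome": comp(all_pairs).reindex(cats, fill_value=0)}
    )
    table = table[table.sum(axis=1) > 0]
    chi, p, dof, _ = stats.chi2_contingency(table.to_numpy().T, correction=False)
    return table, float(chi), int(dof), float(p)


def logistic_conservation(
    pairs: list[AdjacentPair],
    s: SyntenyAnnotation,
    node: str,
    coexpr_quantile: float = 0.95,
    subset: str | None = None,
) -> LogisticFit:
    """Logistic fit: conserved linkage ~ IGD + high co-expression indicator.

    High co-expression = being in the top ``1 - coexpr_quantile`` of pair
    co-expression within the analyzed subset.  Each predictor's
    dispensability is assessed by a deviance likelihood-ratio test.
    ``subset`` restricts to one orientation class; ``"non-convergent"``
    keeps divergent plus parallel pairs.
    """
    labeled = []
    for p, c in _conserved_pairs(pairs, s, node):
        if not p.eligible or p.coexpression is None:
            continue
        if subset == "non-convergent":
            if p.orientation == "convergent":
                continue
        elif subset is not None and p.orientation != subset:
            continue
        labeled.append((p, c))
    if not labeled:
        raise ValueError("no usable pairs for the logistic model")
    y = np.array([c for _, c in labeled], dtype=float)
    if y.min() == y.max():
        raise ValueError("single-class outcome: logistic model undefined")
    igd = np.array([p.igd for p, _ in labeled], dtype=float)
    coex = np.array([p.coexpression for p, _ in labeled], dtype=float)
    cutoff = np.quantile(coex, coexpr_quantile)
    top = (coex >= cutoff).astype(float)
    X = pd.DataFrame({"igd": igd, "top_coexpr": top})
    X = sm.add_constant(X)

    def _fit(exog):
        return sm.GLM(y, exog, family=sm.families.Binomial()).fit()

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = _fit(X)
            converged = bool(getattr(full, "converged", True)) and np.isfinite(full.params).all()
        except Exception:
            raise
    null_dev = float(full.null_deviance)
    res_dev = float(full.deviance)
    lrt_p = {}
    for term in ("igd", "top_coexpr"):
        reduced = _fit(X.drop(columns=[term]))
        lr = float(reduced.deviance - full.deviance)
        lrt_p[term] = float(stats.chi2.sf(max(lr, 0.0), 1))
    if not converged:
        logger.warning("logistic fit did not converge (possible complete separation)")
    return LogisticFit(
        params=pd.Series(full.params, index=X.columns),
        bse=pd.Series(full.bse, index=X.columns),
        pvalues=pd.Series(full.pvalues, index=X.columns),
        null_deviance=null_dev,
        residual_deviance=res_dev,
        lrt_p=lrt_p,
        n=len(labeled),
        converged=converged,
    )


def coexpr_recombination_corr(
    pairs: list[AdjacentPair], rates: pd.DataFrame, estimator: str = "RP"
) -> tuple[float, float, int] | None:
    """Spearman correlation between pair co-expression and pair-mean recombination."""
    xs, ys = [], []
    dropped = 0
    for p in pairs:
        if p.coexpression is None:
            continue
        vals = [
            rates.at[gid, estimator]
            for gid in (p.left.id, p.right.id)
            if gid in rates.index and not pd.isna(rates.at[gid, estimator])
        ]
        if len(vals) < 2:
            dropped += 1
            continue
        xs.append(p.coexpression)
        ys.append(float(np.mean(vals)))
    if dropped:
        logger.info("%d pair(s) dropped for missing recombination rates", dropped)
    if len(xs) < 4:
        warnings.warn("fewer than 4 usable pairs; correlation undefined")
        return None
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), len(xs)


# ---------------------------------------------------------------------------
# Cluster conservation


def _span_landmarks(
    labels: list, start: int, end: int, statistic: str
) -> int:
    """Landmark statistic for a gene-index window on one arm.

    ``landmarks``: distinct non-missing block ids overlapped (1 = wholly
    inside one block; more = more breaks; unannotated genes ignored).
    ``breaks``: label changes between consecutive genes (a missing label
    breaks a run).
    """
    window = labels[start : end + 1]
    if statistic == "landmarks":
        return len({b for b in window if b is not None})
    if statistic == "breaks":
        return sum(1 for k in range(1, len(window)) if window[k] != window[k - 1])
    raise ValueError(f"unknown statistic {statistic!r}")


def cluster_conservation_test(
    clusters: list[Cluster],
    s: SyntenyAnnotation,
    g: GenomeMap,
    node: str,
    n_random: int = 1_000,
    seed: int | None = None,
    statistic: str = "landmarks",
) -> tuple[int, float]:
    """Are clusters more conserved in gene order than random gene stretches?

    The observed statistic totals, over clusters, the number of
    orthologous landmarks (distinct synteny blocks at ``node``)
    intersected by each cluster's gene span — fewer landmarks = fewer
    rearrangements = more conserved.  Each null replicate draws, per
    cluster, a random same-arm stretch of equal gene count that does not
    overlap any input cluster.  p = add-one fraction of replicates with a
    total at or below the observed.  ``statistic="breaks"`` counts
    block-label changes inside the span instead (breaks at ``node``).
    """
    rng = rng_from_seed(seed)
    arm_labels = {
        arm: [s.block(x.id, node) for x in g.genes_on(arm)] for arm in g.arms
    }
    arm_len = {arm: len(g.genes_on(arm)) for arm in g.arms}
    # gene-index spans occupied by any cluster, per arm
    occupied: dict[str, np.ndarray] = {arm: np.zeros(n, dtype=bool) for arm, n in arm_len.items()}
    spans = []
    for c in clusters:
        pos = sorted(g.position(m)[1] for m in c.member_ids)
        if not pos:
            continue
        spans.append((c.arm, pos[0], pos[-1]))
        occupied[c.arm][pos[0] : pos[-1] + 1] = True
    observed = 0
    valid_starts: list[tuple[str, int, np.ndarray]] = []
    skipped = 0
    for arm, lo, hi in spans:
        observed += _span_landmarks(arm_labels[arm], lo, hi, statistic)
        span = hi - lo + 1
        occ = occupied[arm]
        cand = np.array(
            [
                st
                for st in range(arm_len[arm] - span + 1)
                if not occ[st : st + span].any()
            ],
            dtype=int,
        )
        if cand.size == 0:
            warnings.warn(f"no non-overlapping stretch of {span} genes on arm {arm}; cluster skipped")
            skipped += 1
            observed -= _span_landmarks(arm_labels[arm], lo, hi, statistic)
            continue
        valid_starts.append((arm, span, cand))
    if not valid_starts:
        raise ValueError("no clusters with valid null stretches")
    exceed = 0
    for _ in range(n_random):
        total = 0
        for arm, span, cand in valid_starts:
            st = int(cand[rng.integers(0, cand.size)])
            total += _span_landmarks(arm_labels[arm], st, st + span - 1, statistic)
        if total <= observed:
            exceed += 1
    return observed, add_one_p(exceed, n_random)


def polarity_subset(
    pairs: list[AdjacentPair],
    s: SyntenyAnnotation,
    ancestral: str,
    outgroup: str,
) -> dict[str, list[AdjacentPair]]:
    """Label pairs by the branch on which their linkage changed.

    ``newly_linked``: not same-block at the ancestral node (the adjacency
    arose on the focal lineage).  ``conserved``: same-block at both the
    ancestral and the outgroup-branch node.  ``broken_in_outgroup``:
    ancient linkage broken on the outgroup branch.  Pairs unannotated at a
    required node are excluded.
    """
    out: dict[str, list[AdjacentPair]] = {
        "newly_linked": [],
        "conserved": [],
        "broken_in_outgroup": [],
    }
    excluded = 0
    for p in pairs:
        anc = pair_conservation(p, s, ancestral)
        if anc is None:
            excluded += 1
            continue
        if not anc:
            out["newly_linked"].append(p)
            continue
        og = pair_conservation(p, s, outgroup)
        if og is None:
            excluded += 1
            continue
        out["conserved" if og else "broken_in_outgroup"].append(p)
    if excluded:
        logger.info("%d pair(s) unannotated at a required node; excluded from polarity", excluded)
    return out
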