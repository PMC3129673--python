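"""Synthetic genomes with planted, known structure.

Every analysis stage in this package has a ground-truth counterpart here:
gene coordinate maps with log-normal gene lengths and intergene distances;
condition-expression matrices with planted co-expression blocks built from
a shared latent factor (realized within-block Pearson r equals the target
in expectation); tissue-expression matrices with planted low-tau
(housekeeping) runs; inversion/translocation histories over a three-node
tree (focal species, ancestor, aggregated outgroup branch) yielding
synteny-block labels with polarizable breakpoints; smooth recombination
maps with two correlated estimator columns (RP, ACE); GO-style annotations
with tunable within-cluster functional coherence; and duplicate-pair
lists.

All operations are deterministic under their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_from_seed
from .expression import ExpressionMatrix, TissueExpressionMatrix
from .genome import Gene, GenomeMap, SyntenyAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_expression",
    "simulate_tissue_expression",
    "simulate_rearrangements",
    "simulate_recombination",
    "simulate_annotations",
    "simulate_duplicates",
    "simulate_all",
]

_FLY_ARMS = ["2L", "2R", "3L", "3R", "X", "4"]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe the reference synthetic genome used throughout the
    test suite: six arms of 2,000 genes (a fly-like karyotype), 80 planted
    type-1 co-expression clusters with a within-cluster Pearson target of
    0.85, 30 planted housekeeping runs of ~12 genes, 50 expression
    conditions and 14 tissues.
    """

    # genome
    n_arms: int = 6
    genes_per_arm: int = 2000
    gene_len_meanlog: float = 7.5  # ~1.8 kb median gene
    gene_len_sdlog: float = 0.6
    igd_meanlog: float = 6.5  # ~665 bp median intergene distance
    igd_sdlog: float = 1.0
    overlap_fraction: float = 0.0  # fraction of adjacencies made to overlap
    divergent_excess: float = 0.0  # per planted cluster: prob of a forced divergent lead pair
    # expression
    n_conditions: int = 50
    n_tissues: int = 14
    # planted type-1 co-expression clusters
    n_type1: int = 80
    type1_size_min: int = 2
    type1_size_max: int = 5
    type1_rho: float = 0.85
    # planted housekeeping runs
    n_hk_runs: int = 30
    hk_run_len: int = 12
    # annotations
    n_terms: int = 30
    term_freq_low: float = 0.01
    term_freq_high: float = 0.08
    coherence: float = 0.9
    # recombination map
    recomb_amplitude: float = 4.0
    recomb_noise_sd: float = 0.3
    zero_rate_arm: str | None = None
    # rearrangement history
    n_inversions_focal: int = 60
    n_inversions_outgroup: int = 60
    n_translocations_focal: int = 3
    n_translocations_outgroup: int = 3
    recomb_coupling: bool = False
    coexpr_coupling: bool = False
    coexpr_break_weight: float = 5.0  # relative breakage weight at high-coexpr adjacencies
    # duplicates
    n_duplicate_pairs: int = 100
    dup_in_cluster_frac: float = 0.0

    def __post_init__(self):
        if self.n_arms < 1 or self.genes_per_arm < 1:
            raise ValueError("counts must be positive")
        if not (-1.0 < self.type1_rho < 1.0):
            raise ValueError("type1_rho must be in (-1, 1)")

    @property
    def arm_names(self) -> list[str]:
        if self.n_arms <= len(_FLY_ARMS):
            return _FLY_ARMS[: self.n_arms]
        return [f"arm{i + 1}" for i in range(self.n_arms)]


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the data files."""

    type1_clusters: list[list[str]] = field(default_factory=list)
    hk_runs: list[list[str]] = field(default_factory=list)
    hk_genes: set[str] = field(default_factory=set)
    # per focal adjacency (pair id "left|right"): intact on each branch
    pair_intact: pd.DataFrame | None = None

    def type1_members(self) -> set[str]:
        return {g for cl in self.type1_clusters for g in cl}


# ---------------------------------------------------------------------------
# Genome


def _place_segments(
    rng: np.random.Generator,
    arm_names: list[str],
    genes_per_arm: int,
    lengths: list[int],
    margin: int = 6,
) -> list[tuple[str, int]]:
    """Non-overlapping (arm, start index) placements with a safety margin."""
    occupied = {arm: np.zeros(genes_per_arm, dtype=bool) for arm in arm_names}
    placements = []
    for L in lengths:
        for _ in range(10_000):
            arm = arm_names[int(rng.integers(0, len(arm_names)))]
            if genes_per_arm - L <= 0:
                continue
            start = int(rng.integers(0, genes_per_arm - L + 1))
            lo, hi = max(0, start - margin), min(genes_per_arm, start + L + margin)
            if not occupied[arm][lo:hi].any():
                occupied[arm][start : start + L] = True
                placements.append((arm, start))
                break
        else:
            raise RuntimeError("could not place planted segments (genome too crowded)")
    return placements


def simulate_genome(cfg: SimulationConfig, seed: int | None = None) -> tuple[GenomeMap, GroundTruth]:
    """Gene coordinate map plus the planted-structure bookkeeping.

    Coordinates are non-overlapping by construction unless
    ``overlap_fraction`` > 0, which makes that fraction of adjacencies
    overlap (to exercise the eligibility filters).
    """
    rng = rng_from_seed(seed)
    coords: dict[str, list[tuple[str, int, int]]] = {}
    strands: dict[str, list[str]] = {}
    ids_by_arm: dict[str, list[str]] = {}
    for arm in cfg.arm_names:
        prev_end = 0
        prev_start = 0
        arm_rows, arm_ids = [], []
        for i in range(cfg.genes_per_arm):
            length = max(int(rng.lognormal(cfg.gene_len_meanlog, cfg.gene_len_sdlog)), 50)
            igd = max(int(rng.lognormal(cfg.igd_meanlog, cfg.igd_sdlog)), 1)
            start = prev_end + igd + 1
            if i > 0 and cfg.overlap_fraction > 0 and rng.random() < cfg.overlap_fraction:
                overlap = int(rng.integers(1, 40))
                start = max(prev_end - overlap, prev_start + 1)
            end = start + length - 1
            gid = f"g{arm}_{i:04d}"
            arm_rows.append((gid, start, end))
            arm_ids.append(gid)
            prev_end = max(prev_end, end)
            prev_start = start
        coords[arm] = arm_rows
        strands[arm] = ["+" if rng.random() < 0.5 else "-" for _ in range(cfg.genes_per_arm)]
        ids_by_arm[arm] = arm_ids
    truth = GroundTruth()
    # plant type-1 clusters then housekeeping runs, all mutually separated
    sizes = [
        int(rng.integers(cfg.type1_size_min, cfg.type1_size_max + 1)) for _ in range(cfg.n_type1)
    ]
    lengths = sizes + [cfg.hk_run_len] * cfg.n_hk_runs
    placements = _place_segments(rng, cfg.arm_names, cfg.genes_per_arm, lengths)
    for (arm, start), L in zip(placements[: cfg.n_type1], sizes):
        truth.type1_clusters.append(ids_by_arm[arm][start : start + L])
        if cfg.divergent_excess > 0 and rng.random() < cfg.divergent_excess:
            # bidirectional-promoter analog: cluster leads with a divergent pair
            strands[arm][start] = "-"
            strands[arm][start + 1] = "+"
    for arm, start in placements[cfg.n_type1 :]:
        run = ids_by_arm[arm][start : start + cfg.hk_run_len]
        truth.hk_runs.append(run)
        truth.hk_genes.update(run)
    genes = [
        Gene(gid, arm, start, end, strands[arm][i])
        for arm in cfg.arm_names
        for i, (gid, start, end) in enumerate(coords[arm])
    ]
    return GenomeMap(genes), truth


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    cfg: SimulationConfig, g: GenomeMap, truth: GroundTruth, seed: int | None = None
) -> ExpressionMatrix:
    """Gene x condition matrix with latent-factor planted co-expression.

    Members of a planted cluster are ``sqrt(rho) * f + sqrt(1 - rho) * e``
    for a shared condition-profile factor f, so every within-cluster pair
    has Pearson correlation rho in expectation; background genes are
    i.i.d. standard normal.
    """
    if cfg.n_conditions < 2:
        raise ValueError("need at least 2 conditions for Pearson correlation")
    rng = rng_from_seed(seed)
    ids = g.gene_ids
    m = cfg.n_conditions
    values = rng.standard_normal((len(ids), m))
    index = {gid: i for i, gid in enumerate(ids)}
    rho = cfg.type1_rho
    lam = np.sqrt(abs(rho))
    for cl in truth.type1_clusters:
        f = rng.standard_normal(m)
        for gid in cl:
            values[index[gid]] = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(m)
    cols = [f"c{j:03d}" for j in range(m)]
    return ExpressionMatrix(pd.DataFrame(values, index=pd.Index(ids, name="gene_id"), columns=cols))


def simulate_tissue_expression(
    cfg: SimulationConfig, g: GenomeMap, truth: GroundTruth, seed: int | None = None
) -> TissueExpressionMatrix:
    """Gene x tissue signals with planted low-tau housekeeping runs.

    Housekeeping genes get near-uniform log signals (realized tau well
    below 0.25) and are detected in every tissue; background genes draw a
    per-gene specificity exponent giving a broad tau distribution, with
    per-tissue detection tied to signal strength.
    """
    rng = rng_from_seed(seed)
    ids = g.gene_ids
    n, t = len(ids), cfg.n_tissues
    scale = 6.0  # max log-signal
    logs = np.zeros((n, t))
    hk_mask = np.array([gid in truth.hk_genes for gid in ids])
    # housekeeping: logS = scale * (1 - eta), eta ~ U(0, 0.2) -> tau ~ 0.1
    eta = rng.uniform(0.0, 0.2, size=(int(hk_mask.sum()), t))
    logs[hk_mask] = scale * (1.0 - eta)
    # background: logS = scale * u^a with per-gene spikiness a
    n_bg = n - int(hk_mask.sum())
    a = rng.gamma(shape=2.0, scale=0.5, size=n_bg)
    u = rng.uniform(0.0, 1.0, size=(n_bg, t))
    logs[~hk_mask] = scale * u ** a[:, None]
    signal = np.exp(logs)
    # detection requires solid signal (log-signal > 1.5, i.e. S > ~4.5):
    # narrowly expressed genes are then detected in only a minority of
    # tissues, while planted housekeeping genes are detected everywhere
    detected = np.where(logs > 1.5, 4, 0)
    # a sprinkle of single-array detections that the tau rule must zero out
    single = (detected == 0) & (rng.random((n, t)) < 0.05)
    detected[single] = 1
    cols = [f"t{j:02d}" for j in range(t)]
    idx = pd.Index(ids, name="gene_id")
    return TissueExpressionMatrix(
        pd.DataFrame(signal, index=idx, columns=cols),
        pd.DataFrame(detected, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Recombination, annotations, duplicates


def simulate_recombination(
    cfg: SimulationConfig, g: GenomeMap, seed: int | None = None
) -> pd.DataFrame:
    """Smooth per-gene recombination map with RP and ACE estimator columns.

    The underlying rate is a mid-arm bump (suppressed toward telomere and
    centromere) plus estimator-specific noise; ``zero_rate_arm`` names an
    arm with no recombination at all (a dot-chromosome analog).
    """
    rng = rng_from_seed(seed)
    rows = []
    for arm in g.arms:
        genes = g.genes_on(arm)
        n = len(genes)
        frac = (np.arange(n) + 0.5) / n
        base = cfg.recomb_amplitude * 4.0 * frac * (1.0 - frac)
        if cfg.zero_rate_arm is not None and arm == cfg.zero_rate_arm:
            base = np.zeros(n)
            rp = np.zeros(n)
            ace = np.zeros(n)
        else:
            rp = np.clip(base + rng.normal(0, cfg.recomb_noise_sd, n), 0, None)
            ace = np.clip(0.4 * base + rng.normal(0, cfg.recomb_noise_sd * 0.4, n), 0, None)
        for gene, r1, r2 in zip(genes, rp, ace):
            rows.append({"gene_id": gene.id, "RP": float(r1), "ACE": float(r2)})
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_annotations(
    cfg: SimulationConfig, g: GenomeMap, truth: GroundTruth, seed: int | None = None
) -> "pd.DataFrame":
    """Gene/term association rows with planted within-cluster coherence.

    Each term has a genome-wide frequency drawn uniformly from
    ``[term_freq_low, term_freq_high]``; with probability ``coherence`` a
    planted cluster's members additionally all share one random term.
    Returned as a two-column frame (``gene_id``, ``term``) matching the
    annotation TSV format.
    """
    rng = rng_from_seed(seed)
    ids = g.gene_ids
    terms = [f"T{j:03d}" for j in range(cfg.n_terms)]
    freqs = rng.uniform(cfg.term_freq_low, cfg.term_freq_high, size=cfg.n_terms)
    hit = rng.random((len(ids), cfg.n_terms)) < freqs[None, :]
    assoc: set[tuple[str, str]] = {
        (ids[i], terms[j]) for i, j in zip(*np.nonzero(hit))
    }
    for cl in truth.type1_clusters:
        if rng.random() < cfg.coherence:
            t = terms[int(rng.integers(0, cfg.n_terms))]
            assoc.update((gid, t) for gid in cl)
    rows = sorted(assoc)
    return pd.DataFrame(rows, columns=["gene_id", "term"])


def simulate_duplicates(
    cfg: SimulationConfig, g: GenomeMap, truth: GroundTruth, seed: int | None = None
) -> list[tuple[str, str]]:
    """Random duplicate gene pairs, optionally enriched inside planted clusters."""
    rng = rng_from_seed(seed)
    ids = g.gene_ids
    pairs: list[tuple[str, str]] = []
    clusters = [cl for cl in truth.type1_clusters if len(cl) >= 2]
    for _ in range(cfg.n_duplicate_pairs):
        if clusters and rng.random() < cfg.dup_in_cluster_frac:
            cl = clusters[int(rng.integers(0, len(clusters)))]
            a, b = rng.choice(len(cl), size=2, replace=False)
            pairs.append((cl[int(a)], cl[int(b)]))
        else:
            a, b = rng.choice(len(ids), size=2, replace=False)
            pairs.append((ids[int(a)], ids[int(b)]))
    return pairs


# ---------------------------------------------------------------------------
# Rearrangement history


class _Karyotype:
    """Mutable gene order for one genome: per arm, a list of (gene id, strand)."""

    def __init__(self, order: dict[str, list[tuple[str, int]]]):
        self.order = {arm: list(lst) for arm, lst in order.items()}

    def copy(self) -> "_Karyotype":
        return _Karyotype(self.order)

    def positions(self) -> dict[str, tuple[str, int, int]]:
        """gene id -> (arm, index, strand)."""
        out = {}
        for arm, lst in self.order.items():
            for i, (gid, s) in enumerate(lst):
                out[gid] = (arm, i, s)
        return out

    def invert(self, arm: str, c1: int, c2: int) -> None:
        """Reverse segment between cut points c1 < c2, flipping strands."""
        seg = self.order[arm][c1:c2]
        self.order[arm][c1:c2] = [(gid, -s) for gid, s in reversed(seg)]

    def translocate(
        self, src_arm: str, c1: int, c2: int, dst_arm: str, at: int, flip: bool
    ) -> None:
        seg = self.order[src_arm][c1:c2]
        del self.order[src_arm][c1:c2]
        if flip:
            seg = [(gid, -s) for gid, s in reversed(seg)]
        self.order[dst_arm][at:at] = seg


def _cut_weights(
    kar: _Karyotype,
    arm: str,
    rate_of: dict[str, float] | None,
    coexpr_pairs: set[frozenset] | None,
    weight: float,
) -> np.ndarray:
    """Sampling weights over the n+1 cut points of one arm."""
    n = len(kar.order[arm])
    w = np.ones(n + 1)
    if rate_of is not None:
        gids = [kar.order[arm][min(c, n - 1)][0] for c in range(n + 1)]
        w += np.array([rate_of.get(gid, 0.0) for gid in gids])
    if coexpr_pairs:
        for c in range(1, n):
            key = frozenset((kar.order[arm][c - 1][0], kar.order[arm][c][0]))
            if key in coexpr_pairs:
                w[c] *= weight
    return w / w.sum()


def _apply_branch(
    kar: _Karyotype,
    rng: np.random.Generator,
    n_inversions: int,
    n_translocations: int,
    rate_of: dict[str, float] | None,
    coexpr_pairs: set[frozenset] | None,
    weight: float,
) -> None:
    arms = sorted(kar.order)
    arm_p = np.array([len(kar.order[a]) for a in arms], dtype=float)
    arm_p /= arm_p.sum()
    for _ in range(n_inversions):
        arm = arms[int(rng.choice(len(arms), p=arm_p))]
        n = len(kar.order[arm])
        if n < 2:
            continue
        w = _cut_weights(kar, arm, rate_of, coexpr_pairs, weight)
        c1, c2 = sorted(rng.choice(n + 1, size=2, replace=False, p=w).tolist())
        if c1 == c2:
            continue
        kar.invert(arm, int(c1), int(c2))
    for _ in range(n_translocations):
        src = arms[int(rng.choice(len(arms), p=arm_p))]
        n = len(kar.order[src])
        if n < 4:
            continue
        c1 = int(rng.integers(0, n - 1))
        c2 = int(min(n, c1 + rng.integers(1, max(2, n // 20))))
        dst = arms[int(rng.integers(0, len(arms)))]
        at = int(rng.integers(0, len(kar.order[dst]) + 1)) if dst != src else 0
        if dst == src:
            continue
        kar.translocate(src, c1, c2, dst, at, flip=bool(rng.random() < 0.5))


def _adjacency_intact(
    left: tuple[str, int], right: tuple[str, int], pos: dict[str, tuple[str, int, int]]
) -> bool:
    """Is a focal adjacency preserved in order and orientation in another genome?"""
    (ga, sa), (gb, sb) = left, right
    arm_a, ia, sa2 = pos[ga]
    arm_b, ib, sb2 = pos[gb]
    if arm_a != arm_b:
        return False
    if ib == ia + 1:
        return sa2 == sa and sb2 == sb
    if ib == ia - 1:
        return sa2 == -sa and sb2 == -sb
    return False


def simulate_rearrangements(
    cfg: SimulationConfig,
    g: GenomeMap,
    seed: int | None = None,
    rates: pd.DataFrame | None = None,
    coexpr_pairs: set[frozenset] | None = None,
    truth: GroundTruth | None = None,
) -> SyntenyAnnotation:
    """Inversion/translocation history and the derived synteny-block labels.

    The observed genome order is the focal species.  The ancestral order
    is produced by applying the focal branch's rearrangements (inversions
    are involutions, so the ancestor-to-focal history contains exactly
    those events); the outgroup order applies its own events to the
    ancestor.  Block labels are emitted for three lineage nodes —
    ``"tree"`` (order and orientation maintained across the whole species
    set), ``"ancestor"`` (maintained between the ancestor and the focal
    species) and ``"outgroup"`` (focal adjacency maintained in the
    outgroup lineage) — as maximal runs of intact adjacencies.

    With ``recomb_coupling``, breakpoint positions are sampled
    proportionally to the local RP recombination rate; with
    ``coexpr_coupling``, adjacencies listed in ``coexpr_pairs`` attract
    ``coexpr_break_weight``-fold breakage weight.  When ``truth`` is
    given, per-adjacency intactness is stored on it.
    """
    rng = rng_from_seed(seed)
    focal = _Karyotype(
        {
            arm: [(x.id, 1 if x.strand == "+" else -1) for x in g.genes_on(arm)]
            for arm in g.arms
        }
    )
    use_rates = (
        {gid: float(v) for gid, v in rates["RP"].items()}
        if (cfg.recomb_coupling and rates is not None)
        else None
    )
    use_coex = coexpr_pairs if cfg.coexpr_coupling else None
    ancestor = focal.copy()
    _apply_branch(
        ancestor, rng, cfg.n_inversions_focal, cfg.n_translocations_focal,
        use_rates, use_coex, cfg.coexpr_break_weight,
    )
    outgroup = ancestor.copy()
    _apply_branch(
        outgroup, rng, cfg.n_inversions_outgroup, cfg.n_translocations_outgroup,
        use_rates, use_coex, cfg.coexpr_break_weight,
    )
    pos_anc = ancestor.positions()
    pos_out = outgroup.positions()
    block_of: dict[tuple[str, str], object] = {}
    counters = {"tree": 0, "ancestor": 0, "outgroup": 0}
    intact_rows = []
    for arm in g.arms:
        lst = focal.order[arm]
        intact = {"ancestor": [], "outgroup": [], "tree": []}
        for i in range(len(lst) - 1):
            ia = _adjacency_intact(lst[i], lst[i + 1], pos_anc)
            io = _adjacency_intact(lst[i], lst[i + 1], pos_out)
            intact["ancestor"].append(ia)
            intact["outgroup"].append(io)
            intact["tree"].append(ia and io)
            intact_rows.append(
                {
                    "pair_id": f"{lst[i][0]}|{lst[i + 1][0]}",
                    "arm": arm,
                    "intact_ancestor": ia,
                    "intact_outgroup": io,
                }
            )
        for node in ("tree", "ancestor", "outgroup"):
            counters[node] += 1
            bid = f"{node[0].upper()}{counters[node]:05d}"
            block_of[(lst[0][0], node)] = bid
            for i in range(1, len(lst)):
                if not intact[node][i - 1]:
                    counters[node] += 1
                    bid = f"{node[0].upper()}{counters[node]:05d}"
                block_of[(lst[i][0], node)] = bid
    if truth is not None:
        truth.pair_intact = pd.DataFrame(intact_rows)
    return SyntenyAnnotation(block_of)


# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig, seed: int) -> dict:
    """Run every generator with one master seed; returns a bundle dict.

    Child seeds are spawned deterministically from the master seed, so
    identical (config, seed) gives identical data across runs.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [np.random.default_rng(s) for s in ss.spawn(7)]
    genome, truth = simulate_genome(cfg, seeds[0])
    expr = simulate_expression(cfg, genome, truth, seeds[1])
    tissue = simulate_tissue_expression(cfg, genome, truth, seeds[2])
    rates = simulate_recombination(cfg, genome, seeds[3])
    synteny = simulate_rearrangements(cfg, genome, seeds[4], rates=rates, truth=truth)
    annotations = simulate_annotations(cfg, genome, truth, seeds[5])
    duplicates = simulate_duplicates(cfg, genome, truth, seeds[6])
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "expression": expr,
        "tissue": tissue,
        "rates": rates,
        "synteny": synteny,
        "annotations": annotations,
        "duplicates": duplicates,
    }
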