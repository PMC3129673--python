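"""Genome representation: genes on chromosome arms, adjacency, intergene
distance, transcriptional orientation and synteny-block annotations.

Coordinates are 1-based inclusive internally (GFF convention).  BED input
(0-based half-open) is converted on read.  Intergene distance (IGD) between
two non-overlapping neighbors is the number of base pairs strictly between
them: ``right.start - left.end - 1``.  A pair is *eligible* for
rearrangement-opportunity analyses only when its intergenic interval is
non-empty and not overlapped by any third gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GenomeMap",
    "AdjacentPair",
    "SyntenyAnnotation",
    "load_genome",
    "write_genome",
    "adjacent_pairs",
    "classify_orientation",
    "pair_conservation",
    "load_synteny",
    "write_pair_table",
]


@dataclass(frozen=True)
class Gene:
    """A gene as a single oriented interval (transcript boundaries, UTRs included)."""

    id: str
    arm: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if not self.arm:
            raise ValueError(f"gene {self.id}: empty arm label")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class GenomeMap:
    """Ordered genes per chromosome arm, sorted by start coordinate.

    The spatial backbone for all windows, adjacencies and shuffles: gene
    *map order* (index within the arm) is what cluster spans, gap rules and
    random-stretch placements are defined on.
    """

    def __init__(self, genes: Iterable[Gene]):
        by_arm: dict[str, list[Gene]] = {}
        seen: set[str] = set()
        was_sorted = True
        for g in genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            by_arm.setdefault(g.arm, []).append(g)
        for arm, lst in by_arm.items():
            if any(lst[i].start > lst[i + 1].start for i in range(len(lst) - 1)):
                was_sorted = False
            lst.sort(key=lambda g: (g.start, g.end, g.id))
        if not was_sorted:
            logger.info("input genes were not sorted by start; sorted silently")
        self._by_arm = by_arm
        self._index: dict[str, tuple[str, int]] = {
            g.id: (arm, i) for arm, lst in by_arm.items() for i, g in enumerate(lst)
        }

    @property
    def arms(self) -> list[str]:
        return sorted(self._by_arm)

    def genes_on(self, arm: str) -> list[Gene]:
        return list(self._by_arm[arm])

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __iter__(self):
        for arm in self.arms:
            yield from self._by_arm[arm]

    def gene(self, gene_id: str) -> Gene:
        arm, i = self._index[gene_id]
        return self._by_arm[arm][i]

    def position(self, gene_id: str) -> tuple[str, int]:
        """(arm, map index) of a gene."""
        return self._index[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self]


@dataclass
class AdjacentPair:
    """A pair of neighboring genes on one arm, in map order."""

    left: Gene
    right: Gene
    igd: int
    orientation: str  # divergent | convergent | parallel
    eligible: bool
    coexpression: float | None = None
    conserved: bool | None = None

    @property
    def id(self) -> str:
        return f"{self.left.id}|{self.right.id}"


class SyntenyAnnotation:
    """Per-gene synteny-block (orthologous landmark) labels at lineage nodes.

    ``block_of[(gene_id, node)]`` gives the block id, or None for a gene
    without linkage information at that node.  Within a node, genes of one
    block must occupy a contiguous run on one arm (validated lazily by
    :func:`clusterscape.evolution.block_stats`).
    """

    def __init__(self, block_of: Mapping[tuple[str, str], object]):
        self._block_of = dict(block_of)
        self.node_labels = sorted({node for (_, node) in self._block_of})

    def block(self, gene_id: str, node: str):
        return self._block_of.get((gene_id, node))

    def annotated(self, gene_id: str, node: str) -> bool:
        return self._block_of.get((gene_id, node)) is not None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "node": n, "block": b}
            for (g, n), b in sorted(self._block_of.items())
            if b is not None
        ]
        return pd.DataFrame(rows, columns=["gene_id", "node", "block"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SyntenyAnnotation":
        return cls({(r.gene_id, r.node): r.block for r in df.itertuples()})


# ---------------------------------------------------------------------------
# I/O


def load_genome(path: str | Path, format: str | None = None) -> GenomeMap:
    """Read a gene table (BED6, GFF3 or plain TSV) into a :class:`GenomeMap`.

    BED's 0-based half-open coordinates are converted to the internal
    1-based inclusive convention.  The format is inferred from the file
    suffix when not given.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "tsv", ".bed": "bed6", ".gff": "gff3", ".gff3": "gff3", ".tsv": "tsv"}.get(
            suffix, "tsv"
        )
    genes: list[Gene] = []
    if format == "bed6":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["arm", "start", "end", "id", "score", "strand"],
            dtype={"arm": str, "id": str, "strand": str},
        )
        if df["strand"].isna().any():
            raise ValueError("BED6 input with missing strand column")
        for r in df.itertuples():
            genes.append(Gene(r.id, r.arm, int(r.start) + 1, int(r.end), r.strand))
    elif format == "gff3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
            dtype=str,
        )
        df = df[df["type"] == "gene"]
        for r in df.itertuples():
            gid = None
            for fld in str(r.attributes).split(";"):
                k, _, v = fld.partition("=")
                if k.strip() == "ID":
                    gid = v.strip()
            if gid is None:
                raise ValueError(f"GFF3 gene feature without ID attribute: {r.attributes!r}")
            if r.strand not in ("+", "-"):
                raise ValueError(f"gene {gid}: missing strand")
            genes.append(Gene(gid, r.seqid, int(r.start), int(r.end), r.strand))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "arm": str, "strand": str})
        required = {"id", "arm", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"gene TSV must have columns {sorted(required)}")
        if df["strand"].isna().any():
            raise ValueError("gene TSV with missing strand")
        for r in df.itertuples():
            genes.append(Gene(r.id, r.arm, int(r.start), int(r.end), r.strand))
    else:
        raise ValueError(f"unknown genome format {format!r}")
    return GenomeMap(genes)


def write_genome(g: GenomeMap, path: str | Path) -> None:
    """Write a genome as the plain TSV format ``load_genome`` reads back bit-exactly."""
    rows = [
        {"id": gene.id, "arm": gene.arm, "start": gene.start, "end": gene.end, "strand": gene.strand}
        for gene in g
    ]
    pd.DataFrame(rows, columns=["id", "arm", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def load_synteny(path: str | Path) -> SyntenyAnnotation:
    """Read a gene/node/block TSV (one row per gene per lineage node)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "node": str})
    return SyntenyAnnotation.from_frame(df)


# ---------------------------------------------------------------------------
# Adjacency


def classify_orientation(left_strand: str, right_strand: str, split_parallel: bool = False) -> str:
    """Orientation class of a neighboring pair.

    divergent: transcribed away from the shared intergenic region (-,+);
    convergent: toward it (+,-); parallel: same strand.  With
    ``split_parallel`` the parallel class is split by shared strand sign
    (``parallel_plus`` / ``parallel_minus``), giving four classes for
    df = 3 composition tests.
    """
    if left_strand == right_strand:
        if split_parallel:
            return "parallel_plus" if left_strand == "+" else "parallel_minus"
        return "parallel"
    if left_strand == "-":
        return "divergent"
    return "convergent"


def adjacent_pairs(g: GenomeMap) -> list[AdjacentPair]:
    """All neighboring gene pairs in map order, with IGD and eligibility.

    Overlapping pairs, abutting pairs (IGD 0 — rearrangement would disrupt
    coding region or UTRs) and pairs whose intergenic interval is
    overlapped by a third gene are flagged ineligible.
    """
    pairs: list[AdjacentPair] = []
    n_dropped_arms = 0
    for arm in g.arms:
        genes = g.genes_on(arm)
        if len(genes) < 2:
            n_dropped_arms += 1
            continue
        # genes are sorted by start, so the only third gene that can reach
        # into the intergenic interval (left.end, right.start) is an earlier
        # gene with a long 3' extent: track the running max end of the prefix
        prefix_max_end = 0
        for i in range(len(genes) - 1):
            left, right = genes[i], genes[i + 1]
            igd = right.start - left.end - 1
            eligible = igd > 0
            if eligible:
                lo = left.end + 1
                if prefix_max_end >= lo:
                    eligible = False
            prefix_max_end = max(prefix_max_end, left.end)
            pairs.append(
                AdjacentPair(
                    left=left,
                    right=right,
                    igd=igd,
                    orientation=classify_orientation(left.strand, right.strand),
                    eligible=eligible,
                )
            )
    if n_dropped_arms:
        logger.info("%d arm(s) with <2 genes produced no adjacent pairs", n_dropped_arms)
    return pairs


def pair_conservation(p: AdjacentPair, s: SyntenyAnnotation, node: str) -> bool | None:
    """Whether both genes of a pair reside in the same conserved block at ``node``.

    Returns None (pair excluded from conservation analyses) when either
    gene is unannotated at the node.
    """
    bl = s.block(p.left.id, node)
    br = s.block(p.right.id, node)
    if bl is None or br is None:
        return None
    return bl == br


def annotate_conservation(
    pairs: Sequence[AdjacentPair], s: SyntenyAnnotation, node: str
) -> list[AdjacentPair]:
    """Set ``conserved`` on each pair in place; returns the annotated pairs."""
    n_excluded = 0
    for p in pairs:
        p.conserved = pair_conservation(p, s, node)
        if p.conserved is None:
            n_excluded += 1
    if n_excluded:
        logger.info("%d pair(s) unannotated at node %s excluded from conservation", n_excluded, node)
    return list(pairs)


def write_pair_table(pairs: Sequence[AdjacentPair], path: str | Path) -> None:
    rows = [
        {
            "pair_id": p.id,
            "arm": p.left.arm,
            "igd": p.igd,
            "orientation": p.orientation,
            "eligible": p.eligible,
            "coexpression": p.coexpression,
            "conserved": p.conserved,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
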