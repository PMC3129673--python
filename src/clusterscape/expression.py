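"""Expression metrics: the tissue-specificity index tau, expression breadth,
pairwise Pearson co-expression, and the two randomized co-expression
thresholds (per-pair and per-window) used by the cluster callers.

tau is defined over per-tissue log signals ``logS(j)``::

    tau = sum_j (1 - x_j) / (n - 1),   x_j = logS(j) / max_j logS(j)

tau = 0 for a uniformly expressed (housekeeping-like) gene, 1 for a
strictly single-tissue gene.  A tissue's logS is set to 0 when the gene was
called present on at most one array for that tissue (a single supporting
array is treated as unreliable); genes with all tissues at 0 are undefined
and removed from analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import nearest_rank_percentile, rng_from_seed
from .genome import GenomeMap

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TissueExpressionMatrix",
    "CoexpressionThresholds",
    "compute_tau",
    "compute_breadth",
    "coexpression",
    "compute_thresholds",
]


class ExpressionMatrix:
    """Gene x condition expression values for Pearson co-expression."""

    def __init__(self, values: pd.DataFrame):
        if values.isna().all(axis=1).any():
            raise ValueError("expression matrix contains all-missing gene rows")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()

    def zscores(self) -> pd.DataFrame:
        """Row-standardized matrix; zero-variance rows come out as NaN.

        With z-scored rows, Pearson r between genes a and b is
        ``dot(z_a, z_b) / m`` (population standardization), which the
        threshold sampler and window callers exploit.
        """
        v = self.values.to_numpy()
        mu = np.nanmean(v, axis=1, keepdims=True)
        sd = np.nanstd(v, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (v - mu) / sd
        return pd.DataFrame(z, index=self.values.index, columns=self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


class TissueExpressionMatrix:
    """Gene x tissue signal plus per-tissue counts of arrays calling the gene present."""

    def __init__(self, values: pd.DataFrame, detected_arrays: pd.DataFrame):
        if (values.to_numpy() < 0).any():
            raise ValueError("tissue signal values must be >= 0")
        if (detected_arrays.to_numpy() < 0).any():
            raise ValueError("detected_arrays must be >= 0")
        if not values.index.equals(detected_arrays.index) or not values.columns.equals(
            detected_arrays.columns
        ):
            raise ValueError("values and detected_arrays must share index and columns")
        self.values = values.astype(float)
        self.detected_arrays = detected_arrays.astype(int)

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    @classmethod
    def from_tsv(cls, values_path: str | Path, detected_path: str | Path) -> "TissueExpressionMatrix":
        v = pd.read_csv(values_path, sep="\t", index_col=0, float_precision="round_trip")
        d = pd.read_csv(detected_path, sep="\t", index_col=0)
        v.index, d.index = v.index.astype(str), d.index.astype(str)
        return cls(v, d)

    def to_tsv(self, values_path: str | Path, detected_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id", float_format="%.17g")
        self.detected_arrays.to_csv(detected_path, sep="\t", index_label="gene_id")


@dataclass
class CoexpressionThresholds:
    """Per-arm randomized co-expression cutoffs.

    ``pair_threshold``: 95th percentile of random-pair Pearson r (type-1
    seed/extension cutoff, "top 5%").  ``window_threshold``: 97.5th
    percentile of random ten-gene mean pairwise r (the stricter
    sliding-window cutoff).
    """

    pair_threshold: dict[str, float] = field(default_factory=dict)
    window_threshold: dict[str, float] = field(default_factory=dict)
    seed: int | None = None


# ---------------------------------------------------------------------------


def _log_signal(t: TissueExpressionMatrix, min_arrays: int = 2) -> np.ndarray:
    """logS matrix with the unreliable-detection rule applied.

    Natural log of the signal, clamped at 0 (signals <= 1 carry no usable
    magnitude), and forced to 0 wherever fewer than ``min_arrays`` arrays
    called the gene present.
    """
    s = t.values.to_numpy()
    with np.errstate(divide="ignore"):
        logs = np.where(s > 1.0, np.log(s), 0.0)
    logs[t.detected_arrays.to_numpy() < min_arrays] = 0.0
    return logs


def compute_tau(t: TissueExpressionMatrix, gene: str | None = None) -> float | pd.Series | None:
    """tau for one gene, or for every gene (as a Series) when ``gene`` is None.

    Genes with zero logS in every tissue are undefined (NaN in the Series,
    None for a single gene) and should be removed from analyses.
    """
    if t.n_tissues < 2:
        raise ValueError("tau requires at least 2 tissues")
    logs = _log_signal(t)
    mx = logs.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = logs / mx[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (t.n_tissues - 1)
    tau[mx <= 0.0] = np.nan
    out = pd.Series(tau, index=t.values.index, name="tau")
    if gene is None:
        return out
    val = out.loc[gene]
    return None if np.isnan(val) else float(val)


def compute_breadth(
    t: TissueExpressionMatrix, gene: str | None = None, min_arrays: int = 2
) -> int | pd.Series:
    """Number of tissues in which a gene is detected (>= ``min_arrays`` arrays).

    A gene is housekeeping-by-breadth when breadth equals the tissue count.
    """
    counts = (t.detected_arrays.to_numpy() >= min_arrays).sum(axis=1)
    out = pd.Series(counts, index=t.values.index, name="breadth")
    return out if gene is None else int(out.loc[gene])


def coexpression(e: ExpressionMatrix, a: str, b: str) -> float | None:
    """Pearson r between two genes over pairwise-complete conditions.

    None when fewer than 3 shared conditions remain or either profile has
    zero variance over them.
    """
    xa, xb = e.row(a), e.row(b)
    mask = ~(np.isnan(xa) | np.isnan(xb))
    if mask.sum() < 3:
        return None
    xa, xb = xa[mask], xb[mask]
    sa, sb = xa.std(), xb.std()
    if sa == 0 or sb == 0:
        return None
    r = float(np.corrcoef(xa, xb)[0, 1])
    return r


def _sample_pair_r(z: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pearson r for many gene pairs at once from a z-scored matrix."""
    m = z.shape[1]
    return np.einsum("ij,ij->i", z[idx_a], z[idx_b]) / m


def compute_thresholds(
    e: ExpressionMatrix,
    g: GenomeMap,
    n_pairs: int = 100_000,
    n_windows: int = 10_000,
    window: int = 10,
    seed: int | None = None,
) -> CoexpressionThresholds:
    """Randomized co-expression cutoffs per chromosomal class (arm).

    For each arm: ``n_pairs`` random gene pairs give the per-pair null r
    distribution (95th percentile = pair threshold); ``n_windows`` random
    sets of ``window`` genes give the null distribution of mean pairwise r
    (97.5th percentile = window threshold).  Percentiles are nearest-rank.
    Deterministic under ``seed``.
    """
    rng = rng_from_seed(seed)
    z_df = e.zscores()
    out = CoexpressionThresholds(seed=seed if isinstance(seed, int) else None)
    iu = np.triu_indices(window, k=1)
    for arm in g.arms:
        ids = [gene.id for gene in g.genes_on(arm) if gene.id in e]
        z = z_df.loc[ids].to_numpy() if ids else np.empty((0, 0))
        # drop zero-variance / undefined rows from the sampling pool
        ok = ~np.isnan(z).any(axis=1) if z.size else np.array([], dtype=bool)
        z = z[ok]
        n = z.shape[0]
        if n < 2:
            logger.warning("arm %s: <2 usable genes, no thresholds", arm)
            continue
        ia = rng.integers(0, n, size=n_pairs)
        ib = rng.integers(0, n - 1, size=n_pairs)
        ib = np.where(ib >= ia, ib + 1, ib)  # distinct pair members
        rs = _sample_pair_r(z, ia, ib)
        out.pair_threshold[arm] = nearest_rank_percentile(rs, 95.0)
        if n < window:
            logger.warning("arm %s: %d genes < window %d, no window threshold", arm, n, window)
            continue
        means = np.empty(n_windows)
        for w in range(n_windows):
            pick = rng.choice(n, size=window, replace=False)
            zz = z[pick]
            rmat = zz @ zz.T / zz.shape[1]
            means[w] = rmat[iu].mean()
        out.window_threshold[arm] = nearest_rank_percentile(means, 97.5)
    if all(v >= 1.0 for v in out.pair_threshold.values()) and out.pair_threshold:
        warnings.warn("degenerate thresholds at 1.0 (identical expression profiles?)")
    return out
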