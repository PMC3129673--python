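"""Sliding-window and dynamic-growth co-expression cluster callers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clusterscape.coexpression import (
    ClusterCallConfig,
    dedup_clusters,
    distance_decay,
    grow_clusters,
    median_within_cluster_r,
    nearest_coexpressed_gaps,
    sr_clusters,
)
from clusterscape.expression import CoexpressionThresholds, ExpressionMatrix
from clusterscape.housekeeping import Cluster

from conftest import spaced_genome


def expr_from_rows(gene_ids, rows):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows, dtype=float), index=pd.Index(gene_ids, name="gene_id"))
    )


def fixed_thresholds(arms, pair=0.5, window=0.5):
    return CoexpressionThresholds(
        pair_threshold={a: pair for a in arms}, window_threshold={a: window for a in arms}
    )


def correlated_rows(rng, n, m, rho):
    f = rng.normal(size=m)
    lam = np.sqrt(rho)
    return [lam * f + np.sqrt(1 - rho) * rng.normal(size=m) for _ in range(n)]


class TestSR:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(0)
        g = spaced_genome(60, seed=0)
        rows = list(rng.normal(size=(60, 40)))
        rows[20:30] = correlated_rows(rng, 10, 40, 0.9)
        e = expr_from_rows(g.gene_ids, rows)
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], window=0.3))
        clusters = sr_clusters(e, g, cfg)
        assert len(clusters) == 1
        members = set(clusters[0].member_ids)
        assert {f"g{i:04d}" for i in range(20, 30)} <= members

    def test_identical_profiles_merge_whole_arm(self):
        g = spaced_genome(25, seed=1)
        base = np.arange(30.0)
        e = expr_from_rows(g.gene_ids, [base + i * 0 for i in range(25)])
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], window=0.99))
        clusters = sr_clusters(e, g, cfg)
        assert len(clusters) == 1 and len(clusters[0].member_ids) == 25

    def test_short_arm_skipped(self):
        g = spaced_genome(5, seed=2)
        e = expr_from_rows(g.gene_ids, np.random.default_rng(0).normal(size=(5, 20)))
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"]))
        assert sr_clusters(e, g, cfg) == []

    def test_merged_clusters_disjoint(self):
        rng = np.random.default_rng(3)
        g = spaced_genome(120, seed=3)
        rows = list(rng.normal(size=(120, 30)))
        rows[10:22] = correlated_rows(rng, 12, 30, 0.85)
        rows[40:52] = correlated_rows(rng, 12, 30, 0.85)
        e = expr_from_rows(g.gene_ids, rows)
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], window=0.3))
        clusters = sr_clusters(e, g, cfg)
        seen = set()
        for c in clusters:
            ids = set(c.member_ids)
            assert not ids & seen
            seen |= ids


def brute_force_grow(g, e, arm, thr, gap):
    """Independent implementation of the growth rules, using scipy pearsonr
    on raw profiles and explicit list scans."""
    ids = [x.id for x in g.genes_on(arm)]

    def r(i, j):
        return stats.pearsonr(e.row(ids[i]), e.row(ids[j])).statistic

    n = len(ids)
    assigned = set()
    clusters = []
    i = 0
    while i < n - 1:
        if i in assigned:
            i += 1
            continue
        seed = None
        for j in range(i + 1, min(i + gap + 2, n)):
            if j in assigned:
                continue
            if r(i, j) >= thr:
                seed = j
                break
        if seed is None:
            i += 1
            continue
        members = [i, seed]
        last = seed
        while True:
            added = False
            for k in range(members[-1] + 1, min(members[-1] + gap + 2, n)):
                if k in assigned:
                    continue
                mean_r = np.mean([r(k, mm) for mm in members])
                if mean_r >= thr or r(k, last) >= thr:
                    members.append(k)
                    last = k
                    added = True
                    break
            if not added:
                break
        assigned.update(members)
        clusters.append([ids[k] for k in members])
        i = members[-1] + 1
    return clusters


class TestGrow:
    def test_isolated_pair_yields_two_member_cluster(self):
        rng = np.random.default_rng(0)
        g = spaced_genome(12, seed=0)
        rows = list(rng.normal(size=(12, 30)))
        rows[6] = rows[5] + rng.normal(0, 0.05, 30)
        e = expr_from_rows(g.gene_ids, rows)
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], pair=0.8))
        clusters = grow_clusters(e, g, cfg)
        assert len(clusters) == 1
        assert clusters[0].member_ids == ["g0005", "g0006"]

    def test_pair_beyond_gap_not_seeded(self):
        rng = np.random.default_rng(1)
        g = spaced_genome(12, seed=1)
        rows = list(rng.normal(size=(12, 30)))
        rows[9] = rows[4] + rng.normal(0, 0.05, 30)  # 4 intervening genes
        e = expr_from_rows(g.gene_ids, rows)
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], pair=0.8), gap=3)
        assert grow_clusters(e, g, cfg) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = spaced_genome(100, seed=seed)
        rows = list(rng.normal(size=(100, 25)))
        # plant clusters of sizes 2, 3, 5, one with a gap-1 interruption
        for start, size in ((10, 2), (30, 3), (60, 5)):
            rows[start : start + size] = correlated_rows(rng, size, 25, 0.9)
        rows[61] = rng.normal(size=25)  # interior interruption in the 5-block
        e = expr_from_rows(g.gene_ids, rows)
        thr = 0.55
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], pair=thr), gap=3)
        got = [c.member_ids for c in grow_clusters(e, g, cfg)]
        expected = brute_force_grow(g, e, "2L", thr, 3)
        assert got == expected

    def test_members_within_gap_of_a_co_member(self, seed=5):
        rng = np.random.default_rng(seed)
        g = spaced_genome(150, seed=seed)
        rows = list(rng.normal(size=(150, 20)))
        e = expr_from_rows(g.gene_ids, rows)
        cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], pair=0.45), gap=3)
        for c in grow_clusters(e, g, cfg):
            pos = sorted(g.position(m)[1] for m in c.member_ids)
            for a, p in enumerate(pos):
                assert min(abs(p - q) for b, q in enumerate(pos) if b != a) - 1 <= 3

    def test_noise_seed_rate_near_nominal(self):
        """On pure noise, the per-pair seed rate tracks the 5% threshold."""
        rng = np.random.default_rng(9)
        m = 40
        t95 = stats.t.ppf(0.95, m - 2)
        thr = t95 / np.sqrt(m - 2 + t95**2)  # analytic null 95th percentile
        n_sims, hits, trials = 60, 0, 0
        for s in range(n_sims):
            rng_s = np.random.default_rng(100 + s)
            g = spaced_genome(80, seed=s)
            e = expr_from_rows(g.gene_ids, rng_s.normal(size=(80, m)))
            cfg = ClusterCallConfig(thresholds=fixed_thresholds(["2L"], pair=thr), gap=0)
            clusters = grow_clusters(e, g, cfg)
            hits += len(clusters)
            trials += 79  # adjacent pairs tested at gap 0
        rate = hits / trials
        se = np.sqrt(0.05 * 0.95 / trials)
        assert abs(rate - 0.05) < 3 * se


class TestGapsDedupDecay:
    def _cluster(self, members, g, type="type1"):
        pos = sorted(g.position(m)[1] for m in members)
        return Cluster(
            type=type, arm="2L", member_ids=members, span=pos[-1] - pos[0] + 1,
            n_marked=len(members), start_index=pos[0], end_index=pos[-1],
        )

    def test_adjacent_pair_gaps_zero(self):
        g = spaced_genome(10, seed=0)
        c = self._cluster(["g0002", "g0003"], g)
        hist = nearest_coexpressed_gaps([c], g)
        assert hist.to_dict() == {0: 2}

    def test_gap_counting(self):
        g = spaced_genome(10, seed=0)
        c = self._cluster(["g0000", "g0002", "g0006"], g)
        hist = nearest_coexpressed_gaps([c], g)
        # members at 0, 2, 6 -> nearest gaps 1, 1, 3
        assert hist.to_dict() == {1: 2, 3: 1}

    def test_dedup_deletes_pair_cluster(self):
        g = spaced_genome(10, seed=0)
        c = self._cluster(["g0001", "g0002"], g)
        assert dedup_clusters([c], [("g0001", "g0002")], seed=0) == []

    def test_dedup_removes_one_member(self):
        g = spaced_genome(10, seed=0)
        c = self._cluster([f"g{i:04d}" for i in range(5)], g)
        out = dedup_clusters([c], [("g0001", "g0003")], seed=0)
        assert len(out) == 1 and len(out[0].member_ids) == 4

    def test_dedup_matches_set_difference(self):
        rng = np.random.default_rng(4)
        g = spaced_genome(40, seed=4)
        members = [f"g{i:04d}" for i in range(20)]
        c = self._cluster(members, g)
        dups = [(f"g{a:04d}", f"g{b:04d}") for a, b in [(0, 5), (7, 12), (30, 31)]]
        out = dedup_clusters([c], dups, seed=1)
        kept = set(out[0].member_ids)
        for a, b in dups:
            if a in members and b in members:
                assert (a in kept) != (b in kept)  # exactly one survivor
            else:
                assert kept >= ({a, b} & set(members))

    def test_distance_decay_recovers_planted_decay(self):
        rng = np.random.default_rng(6)
        g = spaced_genome(200, seed=6, igd=2000)
        m = 60
        rows = np.empty((200, m))
        # correlation decays with map distance inside 20-gene neighborhoods
        for block in range(10):
            f = rng.normal(size=m)
            for off in range(20):
                i = block * 20 + off
                lam = np.sqrt(max(0.9 - 0.045 * off, 0.0))
                rows[i] = lam * f + np.sqrt(1 - lam**2) * rng.normal(size=m)
        e = expr_from_rows(g.gene_ids, rows)
        clusters = [
            self._cluster([f"g{i:04d}" for i in range(b * 20, b * 20 + 20)], g) for b in range(10)
        ]
        rho, p, n = distance_decay(clusters, g, e, metric="igd")
        assert rho < -0.1 and p < 1e-4 and n == 10 * 190

    def test_distance_decay_degenerate_returns_none(self):
        g = spaced_genome(6, seed=7)
        e = expr_from_rows(g.gene_ids, np.random.default_rng(0).normal(size=(6, 10)))
        c = self._cluster(["g0000", "g0001"], g)
        with pytest.warns(UserWarning):
            assert distance_decay([c], g, e) is None

    def test_median_within_cluster_r_at_least_threshold_shape(self):
        rng = np.random.default_rng(8)
        g = spaced_genome(30, seed=8)
        rows = list(rng.normal(size=(30, 30)))
        rows[5:8] = correlated_rows(rng, 3, 30, 0.9)
        e = expr_from_rows(g.gene_ids, rows)
        c = self._cluster(["g0005", "g0006", "g0007"], g)
        assert median_within_cluster_r([c], e) > 0.5


class TestSRMergeSwitch:
    def test_abutting_windows_split_when_merging_disabled(self):
        rng = np.random.default_rng(11)
        g = spaced_genome(40, seed=11)
        rows = list(rng.normal(size=(40, 30)))
        rows[0:10] = correlated_rows(rng, 10, 30, 0.95)
        rows[10:20] = correlated_rows(rng, 10, 30, 0.95)
        e = expr_from_rows(g.gene_ids, rows)
        merged = sr_clusters(e, g, ClusterCallConfig(thresholds=fixed_thresholds(["2L"], window=0.5)))
        split = sr_clusters(
            e, g,
            ClusterCallConfig(thresholds=fixed_thresholds(["2L"], window=0.5), merge_adjacent=False),
        )
        assert len(merged) <= len(split)
        assert sum(len(c.member_ids) for c in merged) == sum(len(c.member_ids) for c in split)
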