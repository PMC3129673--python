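"""Synteny-block statistics, IGD binning, orientation and logistic models,
cluster conservation and polarity labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clusterscape.evolution import (
    bin_conservation,
    block_stats,
    cluster_conservation_test,
    coexpr_recombination_corr,
    equal_count_bins,
    logistic_conservation,
    orientation_composition_test,
    orientation_tables,
    polarity_subset,
    size_recombination_corr,
)
from clusterscape.genome import SyntenyAnnotation, adjacent_pairs
from clusterscape.housekeeping import Cluster
from clusterscape.simulate import SimulationConfig, simulate_genome, simulate_rearrangements

from conftest import spaced_genome


def annotation_from_conserved(g, conserved_by_arm, node="n"):
    """Build a block annotation realizing a desired per-adjacency
    conservation vector: a new block starts wherever a pair is broken."""
    block_of = {}
    counter = 0
    for arm in g.arms:
        ids = [x.id for x in g.genes_on(arm)]
        counter += 1
        block_of[(ids[0], node)] = counter
        for i in range(1, len(ids)):
            if not conserved_by_arm[arm][i - 1]:
                counter += 1
            block_of[(ids[i], node)] = counter
    return SyntenyAnnotation(block_of)


class TestBlockStats:
    def test_breakpoint_index_formula(self):
        """A block whose two edges each break in two lineages has index
        (2 + 2) / 2 = 2."""
        g = spaced_genome(6, seed=0)
        ids = [x.id for x in g.genes_on("2L")]
        # focal node: genes 2..3 form the middle block
        focal = {}
        for i, gid in enumerate(ids):
            focal[(gid, "focal")] = 1 if i < 2 else (2 if i < 4 else 3)
        # two other lineages, both broken at each edge of block 2
        for node in ("l1", "l2"):
            for i, gid in enumerate(ids):
                focal[(gid, node)] = {0: 1, 1: 1, 2: 2, 3: 2, 4: 3, 5: 3}[i]
        s = SyntenyAnnotation(focal)
        blocks = block_stats(s, g, None, "focal")
        mid = next(b for b in blocks if b.size == 2 and b.member_ids[0] == ids[2])
        assert mid.breakpoint_index == 2.0

    def test_arm_end_block_no_breaks(self):
        g = spaced_genome(4, seed=0)
        ids = [x.id for x in g.genes_on("2L")]
        ann = {(gid, "focal"): 1 for gid in ids}
        for gid in ids:
            ann[(gid, "other")] = 9
        s = SyntenyAnnotation(ann)
        (b,) = block_stats(s, g, None, "focal")
        assert b.breakpoint_index == 0.0 and b.size == 4

    def test_non_contiguous_block_rejected(self):
        g = spaced_genome(4, seed=0)
        ids = [x.id for x in g.genes_on("2L")]
        s = SyntenyAnnotation({(ids[0], "n"): 1, (ids[1], "n"): 2, (ids[2], "n"): 1, (ids[3], "n"): 2})
        with pytest.raises(ValueError, match="contiguous"):
            block_stats(s, g, None, "n")

    def test_zero_rearrangements_one_block_per_arm(self):
        cfg = SimulationConfig(
            n_arms=2, genes_per_arm=50, n_type1=0, n_hk_runs=0,
            n_inversions_focal=0, n_inversions_outgroup=0,
            n_translocations_focal=0, n_translocations_outgroup=0,
        )
        g, truth = simulate_genome(cfg, seed=0)
        s = simulate_rearrangements(cfg, g, seed=0)
        for node in ("tree", "ancestor", "outgroup"):
            blocks = block_stats(s, g, None, node)
            assert len(blocks) == 2

    def test_inversion_block_count_bound(self):
        """k inversions on one branch produce at most 2k + 1 blocks per arm."""
        k = 5
        cfg = SimulationConfig(
            n_arms=1, genes_per_arm=80, n_type1=0, n_hk_runs=0,
            n_inversions_focal=k, n_inversions_outgroup=0,
            n_translocations_focal=0, n_translocations_outgroup=0,
        )
        for seed in range(5):
            g, _ = simulate_genome(cfg, seed=seed)
            s = simulate_rearrangements(cfg, g, seed=seed)
            blocks = block_stats(s, g, None, "ancestor")
            assert len(blocks) <= 2 * k + 1


class TestSizeRecombination:
    def test_too_few_blocks_undefined(self):
        from clusterscape.evolution import ConservedBlock

        blocks = [
            ConservedBlock(id=1, arm="2L", member_ids=["a"], size=1, mean_recomb={"RP": 1.0}),
            ConservedBlock(id=2, arm="2L", member_ids=["b"], size=2, mean_recomb={"RP": 2.0}),
        ]
        with pytest.warns(UserWarning):
            assert size_recombination_corr(blocks, "RP") is None

    def test_null_near_zero(self):
        from clusterscape.evolution import ConservedBlock

        rng = np.random.default_rng(0)
        blocks = [
            ConservedBlock(
                id=i, arm="2L", member_ids=["x"], size=int(rng.integers(1, 30)),
                mean_recomb={"RP": float(rng.gamma(3, 1))},
            )
            for i in range(400)
        ]
        rho, p, n = size_recombination_corr(blocks, "RP")
        assert abs(rho) < 0.12 and n == 400

    def test_exclude_nonrecombining(self):
        from clusterscape.evolution import ConservedBlock

        blocks = [
            ConservedBlock(id=i, arm="2L", member_ids=["x"], size=i + 1, mean_recomb={"RP": r})
            for i, r in enumerate([0.0, 0.0, 1.0, 2.0, 3.0, 1.5, 2.5, 0.5, 1.2, 0.8])
        ]
        out = size_recombination_corr(blocks, "RP", exclude_nonrecombining=True)
        assert out is not None and out[2] == 8

    def test_recomb_coupled_breakage_recovered_end_to_end(self):
        """With breakpoints sampled proportionally to the recombination map,
        large conserved blocks concentrate in low-recombination regions."""
        from clusterscape.simulate import simulate_recombination

        cfg = SimulationConfig(
            n_arms=2, genes_per_arm=600, n_type1=0, n_hk_runs=0,
            n_inversions_focal=60, n_inversions_outgroup=60,
            n_translocations_focal=0, n_translocations_outgroup=0,
            recomb_coupling=True,
        )
        rhos = []
        for seed in range(3):
            g, _ = simulate_genome(cfg, seed=seed)
            rates = simulate_recombination(cfg, g, seed=seed)
            s = simulate_rearrangements(cfg, g, seed=seed, rates=rates)
            blocks = block_stats(s, g, rates, "tree")
            out = size_recombination_corr(blocks, "RP")
            rhos.append(out[0])
        assert np.mean(rhos) < -0.1


class TestBinning:
    def test_degenerate_one_pair_bins(self):
        g = spaced_genome(31, seed=0, igd=50)
        # vary IGD by regenerating with distinct gaps
        from clusterscape.genome import Gene, GenomeMap

        genes, pos = [], 1
        rng = np.random.default_rng(0)
        for i in range(31):
            genes.append(Gene(f"g{i:04d}", "2L", pos, pos + 99, "+"))
            pos += 100 + 10 * (i + 1)
        g = GenomeMap(genes)
        pairs = adjacent_pairs(g)
        conserved = [bool(rng.random() < 0.5) for _ in pairs]
        s = annotation_from_conserved(g, {"2L": conserved})
        binned, rho, p = bin_conservation(pairs, s, "n", n_bins=30)
        assert binned.n_bins == 30
        assert set(np.round(binned.bin_prop_conserved, 6)) <= {0.0, 1.0}
        assert binned.bin_n.sum() == 30

    def test_bin_counts_sum_to_total(self):
        vals = np.random.default_rng(1).uniform(size=200)
        bins = equal_count_bins(vals, 30)
        assert bins.size == 200 and np.bincount(bins).sum() == 200

    def test_ties_go_to_lower_bin(self):
        vals = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        bins = equal_count_bins(vals, 3)
        assert len({bins[0], bins[1], bins[2]}) == 1

    def test_planted_igd_effect_recovered(self):
        """Breakage probability increasing with IGD gives a negative
        IGD-conservation trend across bins."""
        from clusterscape.genome import Gene, GenomeMap

        rng = np.random.default_rng(3)
        genes, pos = [], 1
        for i in range(900):
            genes.append(Gene(f"g{i:04d}", "2L", pos, pos + 99, "+"))
            pos += 100 + int(rng.integers(10, 3000))
        g = GenomeMap(genes)
        pairs = adjacent_pairs(g)
        conserved = [bool(rng.random() > min(p.igd / 3500, 0.9)) for p in pairs]
        s = annotation_from_conserved(g, {"2L": conserved})
        _, rho, p = bin_conservation(pairs, s, "n", n_bins=30)
        assert rho < -0.5 and p < 0.01

    def test_null_trend_near_zero(self):
        from clusterscape.genome import Gene, GenomeMap

        rng = np.random.default_rng(4)
        rhos = []
        for rep in range(10):
            genes, pos = [], 1
            for i in range(300):
                genes.append(Gene(f"g{i:04d}", "2L", pos, pos + 99, "+"))
                pos += 100 + int(rng.integers(10, 2000))
            g = GenomeMap(genes)
            pairs = adjacent_pairs(g)
            conserved = [bool(rng.random() < 0.6) for _ in pairs]
            s = annotation_from_conserved(g, {"2L": conserved})
            _, rho, _ = bin_conservation(pairs, s, "n", n_bins=30)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.25


class TestOrientation:
    def _genome_with_strands(self, strands):
        from clusterscape.genome import Gene, GenomeMap

        genes, pos = [], 1
        for i, st in enumerate(strands):
            genes.append(Gene(f"g{i:04d}", "2L", pos, pos + 99, st))
            pos += 200
        return GenomeMap(genes)

    def test_chi_square_matches_hand_formula(self):
        """A fabricated 3x2 table is compared against the Pearson statistic
        computed directly from observed and expected counts."""
        table = np.array([[10, 90], [50, 50], [90, 10]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        chi_hand = ((table - expected) ** 2 / expected).sum()
        chi_scipy = stats.chi2_contingency(table, correction=False)[0]
        assert chi_scipy == pytest.approx(chi_hand)

    def test_all_conserved_gives_zero_chi(self):
        g = self._genome_with_strands(["+", "-", "+", "-", "+", "-", "+"])
        pairs = adjacent_pairs(g)
        s = annotation_from_conserved(g, {"2L": [True] * len(pairs)})
        table, chi, dof, p, pct = orientation_tables(pairs, s, "n")
        assert chi == 0.0 and p == 1.0
        assert (pct == 100.0).all()

    def test_df_two_with_three_classes(self):
        rng = np.random.default_rng(5)
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(200)]
        g = self._genome_with_strands(strands)
        pairs = adjacent_pairs(g)
        conserved = [bool(rng.random() < 0.6) for _ in pairs]
        s = annotation_from_conserved(g, {"2L": conserved})
        table, chi, dof, p, pct = orientation_tables(pairs, s, "n")
        assert dof == 2 and table.to_numpy().sum() == len(pairs)

    def test_composition_test_df3(self):
        rng = np.random.default_rng(6)
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(300)]
        g = self._genome_with_strands(strands)
        pairs = adjacent_pairs(g)
        cluster_pairs = pairs[:50]
        table, chi, dof, p = orientation_composition_test(cluster_pairs, pairs)
        assert dof == 3


class TestLogistic:
    def _make_pairs(self, n, beta_igd=0.0, beta_coexpr=0.0, seed=0, base_logit=0.8):
        from clusterscape.genome import Gene, GenomeMap

        rng = np.random.default_rng(seed)
        genes, pos = [], 1
        for i in range(n + 1):
            genes.append(Gene(f"g{i:05d}", "2L", pos, pos + 99, "+"))
            pos += 100 + int(rng.integers(50, 4000))
        g = GenomeMap(genes)
        pairs = adjacent_pairs(g)
        coex = rng.normal(0.1, 0.3, size=len(pairs))
        for p, r in zip(pairs, coex):
            p.coexpression = float(r)
        cutoff = np.quantile(coex, 0.95)
        top = coex >= cutoff
        igd = np.array([p.igd for p in pairs], dtype=float)
        logits = base_logit + beta_igd * igd + beta_coexpr * top
        conserved = rng.random(len(pairs)) < 1 / (1 + np.exp(-logits))
        s = annotation_from_conserved(g, {"2L": conserved.tolist()})
        return pairs, s, g

    def test_single_class_outcome_errors(self):
        pairs, _, g = self._make_pairs(50, seed=1)
        s = annotation_from_conserved(g, {"2L": [True] * len(pairs)})
        with pytest.raises(ValueError, match="single-class"):
            logistic_conservation(pairs, s, "n")

    def test_null_coefficients_centered(self):
        """With conservation independent of both predictors, the dropped-term
        LRT p-values are not systematically small."""
        ps = []
        for seed in range(15):
            pairs, s, _ = self._make_pairs(800, seed=seed)
            fit = logistic_conservation(pairs, s, "n")
            ps.extend(fit.lrt_p.values())
        assert np.mean(np.asarray(ps) < 0.05) < 0.25

    def test_deviance_ordering(self):
        pairs, s, _ = self._make_pairs(500, beta_coexpr=-0.5, seed=3)
        fit = logistic_conservation(pairs, s, "n")
        assert fit.residual_deviance <= fit.null_deviance

    def test_planted_negative_coexpression_effect(self):
        hits = 0
        for seed in range(10):
            pairs, s, _ = self._make_pairs(5000, beta_coexpr=np.log(0.7), seed=100 + seed)
            fit = logistic_conservation(pairs, s, "n")
            hits += fit.params["top_coexpr"] < 0
        assert hits >= 9


class TestCoexprRecomb:
    def test_too_few_pairs_undefined(self):
        g = spaced_genome(3, seed=0)
        pairs = adjacent_pairs(g)
        for p in pairs:
            p.coexpression = 0.5
        rates = pd.DataFrame({"RP": [1.0, 2.0, 3.0]}, index=[x.id for x in g])
        with pytest.warns(UserWarning):
            assert coexpr_recombination_corr(pairs, rates, "RP") is None

    def test_planted_coupling_sign(self):
        g = spaced_genome(500, seed=1)
        pairs = adjacent_pairs(g)
        rng = np.random.default_rng(2)
        rates = {}
        for p in pairs:
            r = float(rng.uniform(0, 1))
            p.coexpression = r + float(rng.normal(0, 0.2))
            rates[p.left.id] = 5 * r + float(rng.normal(0, 0.3))
        for x in g:
            rates.setdefault(x.id, float(rng.uniform(0, 5)))
        df = pd.DataFrame({"RP": pd.Series(rates)})
        rho, p, n = coexpr_recombination_corr(pairs, df, "RP")
        assert rho > 0.3 and p < 1e-6


class TestClusterConservation:
    def _clusters(self, g, spans):
        ids = {arm: [x.id for x in g.genes_on(arm)] for arm in g.arms}
        out = []
        for arm, a, b in spans:
            out.append(
                Cluster(
                    type="hk_tau", arm=arm, member_ids=ids[arm][a : b + 1],
                    span=b - a + 1, n_marked=b - a + 1, start_index=a, end_index=b,
                    passed_filter=True,
                )
            )
        return out

    def test_span_counts_blocks_crossed(self):
        g = spaced_genome(30, seed=0)
        ids = [x.id for x in g.genes_on("2L")]
        block_of = {}
        for i, gid in enumerate(ids):
            block_of[(gid, "tree")] = i // 10  # three 10-gene blocks
        s = SyntenyAnnotation(block_of)
        clusters = self._clusters(g, [("2L", 8, 12)])  # crosses blocks 0 and 1
        obs, p = cluster_conservation_test(clusters, s, g, "tree", n_random=50, seed=0)
        assert obs == 2

    def test_planted_conservation_hits_floor(self):
        """Clusters placed wholly inside single landmark blocks are more
        conserved than random stretches of the same size."""
        g = spaced_genome(400, seed=1)
        ids = [x.id for x in g.genes_on("2L")]
        rng = np.random.default_rng(1)
        # blocks of ~8 genes, except three large 30-gene blocks for planting
        block_of, b, i = {}, 0, 0
        planted_spans = []
        while i < 400:
            if b % 12 == 5 and len(planted_spans) < 3:
                size = 30
                planted_spans.append(("2L", i + 2, i + 2 + 10))
            else:
                size = int(rng.integers(3, 9))
            for j in range(i, min(i + size, 400)):
                block_of[(ids[j], "tree")] = b
            i += size
            b += 1
        s = SyntenyAnnotation(block_of)
        clusters = self._clusters(g, planted_spans)
        n_random = 300
        obs, p = cluster_conservation_test(clusters, s, g, "tree", n_random=n_random, seed=2)
        assert obs == 3  # each cluster inside one block
        assert p < 0.05

    def test_null_calibration_uniformish(self):
        g = spaced_genome(300, seed=2)
        ids = [x.id for x in g.genes_on("2L")]
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(60):
            block_of, b, i = {}, 0, 0
            while i < 300:
                size = int(rng.integers(2, 10))
                for j in range(i, min(i + size, 300)):
                    block_of[(ids[j], "tree")] = b
                i += size
                b += 1
            s = SyntenyAnnotation(block_of)
            starts = rng.choice(280, size=5, replace=False)
            clusters = self._clusters(g, [("2L", int(a), int(a) + int(rng.integers(3, 10))) for a in sorted(starts)])
            _, p = cluster_conservation_test(clusters, s, g, "tree", n_random=100, seed=rep)
            ps.append(p)
        assert 0.15 < np.mean(ps) < 0.85


class TestPolarity:
    def test_trivial_labels(self, toy_genome):
        pairs = adjacent_pairs(toy_genome)
        p12 = next(p for p in pairs if p.id == "a1|a2")
        ann = SyntenyAnnotation(
            {
                ("a1", "ancestor"): 1, ("a2", "ancestor"): 1,
                ("a1", "outgroup"): 5, ("a2", "outgroup"): 6,
            }
        )
        out = polarity_subset([p12], ann, "ancestor", "outgroup")
        assert out["broken_in_outgroup"] == [p12]
        ann2 = SyntenyAnnotation(
            {("a1", "ancestor"): 1, ("a2", "ancestor"): 2, ("a1", "outgroup"): 5, ("a2", "outgroup"): 5}
        )
        out2 = polarity_subset([p12], ann2, "ancestor", "outgroup")
        assert out2["newly_linked"] == [p12]

    def test_simulator_ground_truth_labels(self, small_bundle):
        g, s = small_bundle["genome"], small_bundle["synteny"]
        truth = small_bundle["truth"].pair_intact.set_index("pair_id")
        pairs = adjacent_pairs(g)
        out = polarity_subset(pairs, s, "ancestor", "outgroup")
        for label, plist in out.items():
            for p in plist:
                row = truth.loc[p.id]
                if label == "newly_linked":
                    assert not row.intact_ancestor
                elif label == "conserved":
                    assert row.intact_ancestor and row.intact_outgroup
                else:
                    assert row.intact_ancestor and not row.intact_outgroup
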