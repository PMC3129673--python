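"""Functional enrichment of clusters and overlap between cluster sets.

Tests whether more clusters than chance expects share a GO-Slim-style
term (cumulative hypergeometric per term, cluster-refilling randomization
for the count), then asks whether small grown clusters nest inside the
larger sliding-window clusters more often than random placement allows.
"""

from clusterscape import (
    AnnotationTable,
    ClusterCallConfig,
    SimulationConfig,
    compute_thresholds,
    containment_test,
    enriched_count_test,
    simulate_annotations,
    simulate_expression,
    simulate_genome,
)
from clusterscape.coexpression import grow_clusters, sr_clusters
from clusterscape.overlap import per_large_overlap

cfg = SimulationConfig(
    n_arms=2, genes_per_arm=600, n_type1=12, n_hk_runs=0, type1_rho=0.85, coherence=0.9
)
genome, truth = simulate_genome(cfg, seed=0)
expr = simulate_expression(cfg, genome, truth, seed=1)
ann_df = simulate_annotations(cfg, genome, truth, seed=2)

term_of = {}
for r in ann_df.itertuples():
    term_of.setdefault(r.gene_id, set()).add(r.term)
ann = AnnotationTable(term_of, {arm: [g.id for g in genome.genes_on(arm)] for arm in genome.arms})

thr = compute_thresholds(expr, genome, n_pairs=20_000, n_windows=2000, seed=3)
call_cfg = ClusterCallConfig(thresholds=thr)
t1 = [c for c in grow_clusters(expr, genome, call_cfg) if len(c.member_ids) >= 2]
sr = sr_clusters(expr, genome, call_cfg)

observed, p = enriched_count_test(t1, ann, n_random=1000, seed=4)
print(f"{observed} of {len(t1)} type-1 clusters enriched for at least one term "
      f"(refilling randomization p = {p:.4g})")

res = containment_test(t1, sr, genome, n_random=2000, seed=5)
print(f"proportion of type-1 cluster genes wholly inside an SR cluster: "
      f"{res.observed_proportion:.4f} (null max {res.null_max:.4f}, p = {res.p:.4g})")
frac, med, rho = per_large_overlap(t1, sr, genome)
print(f"{100 * frac:.1f}% of SR clusters contain >= 1 type-1 cluster "
      f"(median contained: {med:.0f}, size/count Spearman rho: {rho})")

# A small randomization p for the enriched count means clusters share
# functions beyond what random same-arm gene sets show; the containment
# test's small p means SR clusters and small clusters are not independent.
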