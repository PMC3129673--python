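"""Detect clusters of broadly expressed (housekeeping) genes.

Simulates a small genome with planted low-tau runs, encodes each arm as a
0/1 housekeeping vector, tests for clustering with the transition
statistic, then calls and filters housekeeping clusters.
"""

from clusterscape import (
    SimulationConfig,
    call_hk_clusters,
    compute_tau,
    encode_arm,
    filter_hk_clusters,
    simulate_genome,
    simulate_tissue_expression,
    transition_test,
)

cfg = SimulationConfig(n_arms=2, genes_per_arm=800, n_type1=0, n_hk_runs=8)
genome, truth = simulate_genome(cfg, seed=0)
tissue = simulate_tissue_expression(cfg, genome, truth, seed=1)
tau = compute_tau(tissue)  # 0 = uniformly expressed, 1 = single-tissue

for arm in genome.arms:
    ids = [g.id for g in genome.genes_on(arm)]
    enc = encode_arm(arm, ids, tau, rule="tau_le_cutoff", cutoff=0.25)
    observed, p, null_median = transition_test(enc, n_shuffles=2000, seed=2)
    print(f"arm {arm}: {observed} transitions between housekeeping/other "
          f"(shuffled median {null_median:.0f}, p = {p:.4g})")
    clusters = call_hk_clusters(enc, max_gap=3)
    clusters = filter_hk_clusters(clusters, enc, n_random=2000, seed=3)
    passed = [c for c in clusters if c.passed_filter]
    print(f"  {len([c for c in clusters if c.n_marked >= 2])} candidate stretches, "
          f"{len(passed)} survive the 5% span/count filter")
    for c in passed:
        print(f"    {c.n_marked} low-tau genes spanning {c.span} "
              f"({c.member_ids[0]} .. {c.member_ids[-1]}, p = {c.p_filter:.4g})")

# Fewer transitions than the shuffled median means housekeeping genes sit
# next to each other more than chance expects; surviving stretches are the
# clusters too large (in genes and span) to arise in shuffled genomes.
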