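# Methods

## Genome model and coordinate conventions

A genome is a set of chromosome arms, each an ordered list of genes; a
gene is a single oriented interval (transcript boundaries, UTRs included).
Coordinates are 1-based inclusive internally; BED input is converted on
read. Nested genes are ordered by start coordinate, so a gene contained in
another is that gene's map neighbor — ties and nesting may therefore order
differently than a curated annotation would.

Intergene distance (IGD) of a neighboring pair is
`right.start - left.end - 1`. A pair is *eligible* for
rearrangement-opportunity analyses only when this interval is non-empty
and no third gene reaches into it: overlapping pairs, abutting pairs
(IGD = 0) and pairs with an overlapped intergenic region are excluded
because a rearrangement between them would disrupt coding sequence or
UTRs. Orientation classes: divergent (`-`,`+`), convergent (`+`,`-`),
parallel (same strand). Parallel is one class by default; a switch splits
it by strand sign to give the four-category (df = 3) composition test
used when asking whether divergent pairs are overrepresented in clusters.

## Tissue specificity and breadth

tau is computed from per-tissue log signals with two conventions that the
underlying arrays force: a tissue's logS is set to 0 when at most one
array called the gene present (a single supporting array is unreliable),
and signals <= 1 are clamped to logS = 0 (a sub-unit signal carries no
usable magnitude; the ratio in tau is otherwise unstable near zero).
Genes with all tissues at zero are undefined and dropped. The log base
cancels in the ratio; natural log is fixed for reproducibility. Breadth
counts tissues with at least two supporting arrays (configurable),
mirroring the tau rule; housekeeping-by-breadth means detected in every
tissue.

## Randomized co-expression thresholds

Both cluster callers calibrate their cutoffs per chromosomal class (arm):
the pair cutoff is the 95th percentile of Pearson r over 100,000 random
same-arm gene pairs, the window cutoff the 97.5th percentile of mean
pairwise r over 10,000 random ten-gene sets. Percentiles are nearest-rank
(ceil) on the sorted sample — no interpolation, so results are identical
across platforms. Pearson correlations use pairwise-complete conditions;
zero-variance profiles are undefined and excluded from window means
rather than entered as zero.

## Cluster definitions

*Housekeeping:* maximal stretches that begin and end with a state-1 gene
and contain no internal state-0 run longer than `max_gap` = 3 ("at least
every fourth gene"). The empirical filter pools every cluster called on
10,000 shuffled encodings and retains a real cluster when the add-one
fraction of random clusters at least as large **jointly** in marked-gene
count and span is below 5%. The joint tail is the default because
retained clusters should be simultaneously extreme in both dimensions; a
marginal variant is available. Singleton stretches are reported but can
never pass and are excluded downstream. Shuffling permutes the observed
state vector, so state counts are preserved exactly.

*SR (sliding window):* any ten-gene window whose mean pairwise r meets
the window cutoff contributes all ten genes; overlapping or abutting
above-threshold windows merge into one cluster.

*Type 1 (dynamic growth):* scanning left to right, a cluster is seeded by
the first unassigned pair at or above the pair cutoff with at most
`gap` = 3 intervening genes; it extends rightward, a candidate within the
gap of the rightmost member joining when its mean r with all current
members, or its r with the last member added, meets the cutoff. Interior
genes failing both rules are never members, and the membership mean is
taken over accepted members only. Growth is single-pass rightward
(bidirectional extension is behind a flag); assigned genes cannot seed or
join later clusters, so clusters are disjoint. The gap default follows
the stricter of the two plausible readings (3, not 4) and is a parameter.
Duplicate handling removes one random member of each duplicate pair found
within a cluster and deletes clusters reduced below two members.

## Randomization tests

All permutation p-values use the add-one estimator `(r + 1)/(n + 1)`,
whose floor at 10,000 randomizations is 9.999e-5. Specifics:

- *Transition test:* one-tailed (clustering means fewer transitions);
  a constant encoding returns p = 1 with a warning.
- *Enriched-cluster count:* every cluster is refilled with the same number
  of random genes from its own arm (without replacement within a cluster),
  enrichment recomputed per replicate. Per-term alpha is 0.05 with no
  within-cluster correction — the genome-level refilling randomization is
  the multiplicity control. Only terms carried by at least one member are
  tested (absent terms have p = 1 by construction). The replicate loop is
  vectorized by precomputing, per term and cluster size, the minimal count
  whose hypergeometric tail is significant.
- *Containment:* small-cluster locations fixed; each large cluster is
  re-placed uniformly over valid start genes on its own arm with its
  gene-span length preserved; placements may overlap each other.
  Containment is evaluated on gene-index spans; a small-cluster gene
  counts once even if covered twice.
- *Cluster conservation:* the statistic is the total number of distinct
  synteny-block ids (orthologous landmarks) intersected by cluster spans
  (1 = wholly inside one block; more = more breaks); each replicate draws,
  per cluster, a random same-arm stretch of equal gene count that overlaps
  no input cluster. Fewer landmarks than the null means more conserved. A
  `breaks` variant counts block-label changes inside the span at one
  designated node, which is how rearrangements on a single branch are
  scored.

## Synteny blocks, breakpoint index and polarity

Block labels are consumed per lineage node (gene, node -> block id);
within a node a block must be a contiguous run on one arm (validated).
The breakpoint index of a block is the number of breaks at either edge
divided by two, where a break at an edge is any *other* node whose block
label changes across that edge; arm ends contribute none. This
edge-break definition is an interpretation — the index's original
construction is not fully specified by its source — and is recorded as
such. Polarity labels an adjacent pair by same-block status at the
ancestral node versus the outgroup-branch node: not linked ancestrally =
newly linked on the focal lineage; ancestrally linked and intact in the
outgroup = conserved; otherwise broken on the outgroup branch.

The logistic model regresses conserved linkage on IGD (bp) and a top-5%
co-expression indicator (quantile computed within the analyzed subset);
each predictor's dispensability is a deviance LRT on 1 df. Complete
separation is flagged rather than silently reported. Equal-count IGD
binning uses nearest-rank splits with ties assigned to the lower bin; the
across-bin trend is Spearman's rho between per-bin median IGD and per-bin
proportion conserved (bin medians are one of several defensible x
choices; the choice only relabels a monotone axis).

## Synthetic data generator

The generator's defaults define the reference study conditions used by
the test suite: 6 arms x 2,000 genes (a fly-like karyotype), log-normal
gene lengths (median ~1.8 kb) and IGDs (median ~0.7 kb), 50 expression
conditions, 14 tissues, 80 planted type-1 clusters of 2-5 genes at
within-cluster Pearson 0.85, and 30 planted 12-gene housekeeping runs.

- *Correlated expression* uses a shared latent factor per planted cluster:
  member = sqrt(rho) x factor + sqrt(1-rho) x noise, giving pairwise r =
  rho in expectation without a covariance factorization. Background is
  i.i.d. standard normal.
- *Tissue profiles:* housekeeping genes get near-uniform log signals
  (realized tau ~ 0.1) detected in every tissue; background genes draw a
  per-gene spikiness exponent (gamma-distributed) giving a broad tau
  distribution with ~15% of background genes at tau <= 0.25 and ~24%
  detected in all tissues — chosen as plausible adult-tissue-atlas
  magnitudes. Detection requires log-signal > 1.5; a 5% sprinkle of
  single-array detections exercises the unreliable-detection rule.
- *Rearrangements* act on gene-index order: the observed genome is the
  focal species, the ancestor is obtained by applying the focal branch's
  inversions/translocations (inversions are involutions), and the
  outgroup applies its own events to the ancestor — the outgroup
  aggregates a multi-species clade as one branch, which is all polarity
  semantics need. Block labels at three nodes (whole tree, ancestor
  vs focal, outgroup lineage) are maximal runs of adjacencies intact in
  order and orientation. Optional couplings weight breakpoint positions
  by local recombination rate or boost breakage between designated
  high-co-expression adjacencies. Base-pair coordinates are the focal
  genome's throughout, so IGD distributions are unaffected by history.
- *Recombination maps* are a mid-arm bump (suppressed toward telomere and
  centromere) with estimator-specific noise for RP and ACE and an
  optional all-zero arm (dot-chromosome analog).

What the generator does **not** emulate: real expression covariance
structure outside planted clusters (background genes are independent, so
genome-wide correlation is flatter than in real compendia), transcript
isoforms, unequal arm sizes, clustered duplicate architecture unless
requested, and breakpoint reuse. Passing tests therefore demonstrate the
statistics are correct and calibrated under the stated generative model,
not that any particular biological genome will show the planted effects.

## Validation design

- Exact oracles: the hypergeometric tail is checked against exhaustive
  integer-arithmetic enumeration for all parameters with G <= 25; both
  cluster callers are checked against independent brute-force
  implementations of their stated rules on 200 random 100-gene arms; the
  transition test's Monte-Carlo p converges to the exactly enumerated
  2/252 for the ten-gene worked example.
- Calibration: on structure-free genomes the transition, enriched-count,
  containment and cluster-conservation tests give approximately uniform p
  over 200 replicates (KS at 1%). Because all four statistics are
  discrete, the experiments are sized so the statistic's support is fine
  enough for the add-one estimator's granularity not to dominate: 400-gene
  encodings, 120 clusters per enrichment replicate, variable small-cluster
  sizes for containment, and synteny from an i.i.d. per-adjacency breakage
  process (geometric block lengths) with ~12 well-separated clusters for
  conservation. The conservation null constrains random stretches away
  from cluster positions, so its calibration premise requires sparse,
  mutually non-overlapping clusters; at high cluster density the null
  stretches crowd into the gaps and correlate, which is a property of the
  test's design, not an implementation artifact.
- Recovery: at the reference conditions the growth caller recovers >= 90%
  of planted type-1 members, and the housekeeping filter retains >= 80%
  of planted runs (a run is retained when a passed cluster contains at
  least half its genes). Recovery FDR is measured as the contamination of
  recovering clusters — the fraction of non-planted members among clusters
  that overlap planted ones (<= 15%). Clusters built entirely from
  background genes are not counted against recovery: with a top-5% pair
  cutoff they arise at the nominal rate by construction, and that rate is
  asserted separately as a calibration property.
- Determinism: every simulate/analysis function is reproducible under its
  seed; the pipeline writes floats at 17 significant digits and reads
  them back with round-trip parsing, so restarted and repeated runs are
  bit-identical.

## Problem sizes

The test suite and `scripts/acceptance.py` run the recovery experiments at
the full reference scale (12,000 genes) and the pipeline demonstrations on
scaled-down genomes (2-4 arms of 250-1,000 genes) with randomization
counts of 150-10,000 chosen per test so each check measures what it
claims with adequate Monte-Carlo resolution. The add-one floor check
always uses the full 10,000 shuffles.

## Known limitations

- The growth caller's left-to-right single pass makes cluster membership
  order-dependent near ties; a bidirectional variant exists but is not
  the default.
- The empirical housekeeping filter pools random clusters across shuffles,
  treating the pool as one exchangeable population per arm; arms with very
  few marked genes produce small pools and correspondingly coarse p.
- Breakpoint-index breaks are counted per node label, not per inferred
  event; reuse of a breakpoint by two lineages counts twice.
- With `overlap_fraction` > 0 the generator can produce nested genes;
  downstream eligibility filters handle them, but bp coordinates of
  overlapping neighbors are not meant to mimic real UTR overlap statistics.
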