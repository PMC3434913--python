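# Methods

This note documents the models, conventions and numerical choices behind
`otudelim`, and what the synthetic-data tests do and do not demonstrate.

## Distances and sequence statistics

All distances are uncorrected p-distances: the proportion of differing
nucleotides among comparable sites.  Gaps and `N` are treated as missing in
both distances and site statistics; under the default *pairwise deletion*
each pair's comparable-site count is tracked separately
(`DistanceMatrix.comparable_sites`), while *complete deletion* first removes
every column containing a gap or `N`.  The two modes coincide exactly on
gap-free alignments (property-tested).  No multiple-hit correction is
applied: the delimitation thresholds in this literature (2–10%) are quoted
as raw p-distances.

The net between-group distance follows the MEGA convention:
`d_net(A,B) = d̄_AB − (d̄_A + d̄_B)/2`, with the within-group mean of a
singleton defined as 0.  Consequently `d_net ≤ d̄_AB`, with equality iff both
within-means vanish.

A site is *variable* when ≥ 2 distinct non-missing states occur, and
*parsimony-informative* when ≥ 2 states each occur in ≥ 2 sequences.
Haplotype identity is exact string identity over the aligned length;
deduplication keeps the first-occurring specimen as the representative.

## Threshold clustering

Two linkage semantics are provided because the verbal rule ("maximum
pairwise distance within a cluster may not exceed the threshold") and the
behaviour of the classic clustering tools (transitive closure) differ:

* **single** (default): connected components of the graph with an edge
  wherever `d ≤ t`.  Cluster counts are provably non-increasing in `t`.
* **complete**: agglomerative merging while the merged cluster's maximum
  internal distance stays ≤ `t`, closest admissible pair first, ties broken
  by the lexicographically smallest member id.  The result satisfies the
  max-within rule and admits no further merge.

Distances exactly equal to `t` are inside the threshold.  Both modes are
checked against brute-force oracles (union-find components; exhaustive
max-within / no-admissible-merge verification) on hundreds of random
matrices with ≤ 8 taxa.

## Tree-guided partitions and the gap search

Rings: starting below the root (the root itself never defines a block), each
root-to-tip path is cut at the first node with support ≥ `pp_min` (default
0.95, compared with ≥); that node's tip set is one block, and tips that
never pass a supported node become singletons.  Level k+1 repeats the
traversal inside each level-k block; a block with no further supported node
persists unchanged, so the levels form a refinement chain (fuzz-tested).
Missing supports are stored as absent and never treated as 0.

Each ring is scored by `gap = min_net_between − max_within`, where
`max_within` is the maximum block-mean within distance (matching the "< x%
within" style of reporting, which is a bound over blocks) and
`min_net_between` the minimum pairwise net distance between blocks.  Rings
with a positive gap are admissible; the largest gap wins, earlier level on
ties.  A single-block ring has no between term and is never admissible.

When no externally estimated chronogram is available, a UPGMA tree (average
linkage, node height = half the merge distance) serves as an ultrametric
stand-in.  It carries no support values, so the ring method then degrades to
a single block with a warning — deliberate, since fabricating support would
be worse.

## GMYC

The tree is reduced to inter-event intervals: with n tips there are n−1
branching events and n−1 intervals from the root (2 lineages) to the
present; every interval, including the final one ending at the tips, is
modelled as an exponential waiting time, giving the closed-form null MLE
`λ̂ = m / Σ nᵢ^p xᵢ` for m intervals at fixed exponent p.  The exponents p
(bounded [0, 10]) allow departures from strict Yule (p = 1) and neutral
coalescent scalings.

Under a threshold T, a branch belongs to the speciation class while its
parent node is older than T; interval i then contributes rate
`b_i = λ₁·n_spec,i^p₁ + λ₂·n_coal,i^p₂` (the coalescent lineages are pooled
across putative species before the exponent is applied).  Candidate
thresholds are the midpoints of every interval plus an older-than-root
sentinel; the two extremes (everything coalescent / everything speciation)
reduce exactly to the null, which yields the nesting guarantee
`gmyc_loglik ≥ null_loglik` by construction and a non-negative LRT.  Ties in
the profile are broken toward the older T (fewer entities — conservative).
The LRT against the null uses 3 df (λ₂, p₂, T), the convention of the
original single-threshold implementation; implementations differ on whether
T is counted, which is why the df is stated explicitly in every report.

Numerics: mixed-class likelihoods are maximised by L-BFGS-B on
(log λ₁, log λ₂, p₁, p₂) with analytic gradients, warm-started from the
previous candidate's optimum and from the null solution; λ is bounded below
at 1e-12 and the convergence tolerance is ~1e-12 on the objective.
Ultrametricity is required within 1e-9 (root-to-tip spread); polytomies are
resolved to zero-length binary branches and tied node ages separated by a
deterministic jitter ≤ 1e-10 (fixed seed), preserving n−1 events.

### Multiple thresholds

The single global T generalises to a *cut*: an antichain of species-stem
branches covering all tips.  The greedy search starts from the
single-threshold ML cut and adds one local threshold per step — either
splitting one stem into its two children or merging two sibling stems into
their parent — accepting the best move while the χ² improvement at 1 df is
significant (α = 0.05), never revisiting a state.  The multiple-threshold
likelihood therefore never falls below the single-threshold one, and the
single-vs-multiple comparison is a χ² test with df = (thresholds − 1).

A structural property worth knowing: because the class rates follow a
power law in the lineage count, and lineage counts correlate strongly with
depth, the exponents already absorb most between-clade depth heterogeneity.
Single moves therefore rarely clear the 1-df significance gate even on data
built with 5–25× depth contrasts between clades (observed maximum
single-move log-likelihood gains ≈ 0.04 against a 1.92 cutoff).  Finding the
single- and multiple-threshold fits statistically indistinguishable is the
expected outcome on most data, not a failure of the search; the test suite
verifies that the greedy walk does reach local thresholds once the gate is
relaxed.

## Consensus OTUs

A candidate block is supported by a method iff it appears *verbatim* in that
method's partition (strictest reading; partial overlaps do not count).
Blocks with support ≥ 2 (of 3) are accepted greedily by (support desc, size
desc, lexicographic id asc), skipping blocks that overlap an accepted one;
leftover specimens are reported as flagged orphan singletons rather than
force-merged, keeping the consensus conservative.  The procedure is
symmetric in the method order and raising the support requirement can only
reduce the OTU count (both tested).  The adjusted Rand index for
method-agreement summaries comes from scikit-learn.

## Haplotype networks

The nuclear marker is assumed pre-phased (one sequence per haplotype); a
convenience expander resolves diploid records with ≤ 1 IUPAC ambiguity
deterministically and rejects anything more ambiguous.

The 95% connection limit is the largest step count j for which the
probability that j observed differences over L sites reflect exactly j
substitutions exceeds the confidence level.  That probability is evaluated
under a Jukes–Cantor finite-sites model: per-site substitution counts are
Poisson with mean d (the JC-corrected divergence for p̂ = j/L), a single hit
is always visible, multiple hits are visible with the JC chain probability,
and the parsimony event (total hits = visible differences) is conditioned on
the observed difference count.  The formula is validated against an
independent Monte-Carlo simulation of the same model; the resulting limits
(e.g. 6 steps at L = 400) are somewhat more conservative than historical TCS
program output.

The network is a minimum spanning network (all co-minimal edges per weight
class) over pairwise Hamming distances, never drawing edges beyond the
connection limit, so the result may fall into several sub-networks
(sub-network count is non-increasing in the limit).  Reticulation loops are
broken algorithmically in the priority order frequency > topology >
geography: remove the edge with the smallest endpoint-frequency sum, then
the edge with more inferred intermediates, then edges joining haplotypes
that share no group label; a fixed lexicographic tie-break keeps the result
deterministic.  Multi-step edges can be expanded into chains of inferred
median nodes (frequency 0, no group label) for output.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

* **Species tree** — Yule; two lineages at the root, waiting time Exp(kλ)
  while k lineages, final stretch Exp(Kλ) after reaching K (mean depth
  `Σ_{k=2..K} 1/(kλ)`, Monte-Carlo checked).  With `min_depth_frac > 0` the
  tree is rejection-sampled until every speciation is at least that fraction
  of the root age deep, emulating surveys whose species are all well
  separated.
* **Gene tree** — multispecies coalescent via msprime
  (`Demography.from_species_tree` + `sim_ancestry`, haploid samples); every
  population shares the scale θ = mean pairwise coalescence time (default
  0.02 in species-tree time units).  Incomplete lineage sorting is therefore
  modelled, though negligible under the default depth ratios.
* **Sequences** — finite-sites JC69 (or HKY85) simulation along the gene
  tree, validated against the JC closed form `p = ¾(1 − e^{−4d/3})`.  The
  substitution rate is calibrated per dataset so a chosen between-species
  p-distance statistic hits a target — median 8% by default, because the
  analyses are specified in terms of observed divergences rather than rates.
* **Regime conditioning** — the `set3_regime` configuration (used in all
  recovery studies) targets the study condition "within < 3%, between
  ≥ 6%": `min_depth_frac = 0.2`, rate calibrated so the *minimum* expected
  between-species p-distance is 7%, and the gene-tree/sequence draw retried
  (fresh subseed, ≤ 30 attempts) until the realized alignment satisfies the
  regime.  A raw Yule tree's youngest split is routinely too shallow for the
  regime at any rate scaling, which is why the conditioning exists; it is
  part of the stated study conditions, not a tuning knob.
* **Duplicates and supports** — exact-duplicate specimens are appended at a
  configurable fraction of the sample (emulating the usual surplus of
  specimens over unique haplotypes), and the true chronogram carries
  synthetic posterior supports: deep (between-species) nodes and species
  MRCAs draw from U(0.97, 1), within-species nodes from U(0.3, 0.9),
  mirroring the strong-deep/weak-shallow pattern of real consensus trees.
* **Nuclear marker** — the same machinery at a lower calibrated rate with
  two phased haplotypes per diploid specimen and optional forced haplotype
  sharing between designated species pairs.

What passing recovery tests shows: under clean, well-separated regimes each
method and the consensus recover the simulated species with high
probability (problem sizes: K = 10 species × 5 samples, 586 bp, 50
replicates; smaller K for unit tests).  What it does not show: behaviour
under introgression, recombination, rate variation among lineages or sites,
alignment error, or regimes where within- and between-species divergences
overlap — on real data the three methods can and do disagree, which is why
the consensus layer and the orphan flags exist.

## Pipeline

`run_pipeline` is a pure function of (inputs, config, seed): reruns are
byte-identical.  Analyses operate on unique haplotypes; a supplied tree is
pruned to the haplotype representatives (duplicate sequences carry no
information for any of the three methods), and a missing tree falls back to
UPGMA with a logged warning.  Every output TSV carries a 12-hex config hash
header so results can be matched to settings.  The method-1 partition fed to
the consensus is the preferred gap-search ring, method 2 the sweep entry at
the configured report threshold (default 5%, single linkage), method 3 the
single-threshold GMYC entities — all overridable.

## Known limitations

* The GMYC likelihood treats the final (censored) interval as
  event-terminated; with tens of tips the effect on T̂ is negligible, but
  likelihood values are not comparable across implementations using the
  n−2-interval convention.
* The ring traversal automates a procedure that was historically done by
  hand; on trees whose support pattern differs from the
  strong-deep/weak-shallow template, ring levels may not correspond to
  biologically meaningful groupings (the gap criterion, not the ring index,
  carries the inference).
* The parsimony connection limit is model-based (JC, uniform rates) and
  conservative relative to historical TCS output.
* Complete-linkage clustering is O(n³) and intended for the ≤ few hundred
  unique haplotypes typical of these surveys.
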