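# Methods

This note documents the models, rules and numerical choices behind
`fibronet`, the parameters that matter, and what the synthetic-data tests
do and do not establish about real data.

## Study shape and containers

The package targets time-course designs: an ordered group list (default
`control, d7, d14, d21, d28`) with a handful of replicates per group
(default 5) and the first group as the reference for every contrast.
Matrices are features × samples (`OmicsMatrix`), with missing values legal
only for metabolite and phenotype tables; count matrices must be
non-negative integers. Phenotype variables (lung-function parameters such
as forced vital capacity or the stiffness index) are rows of a phenotype
matrix and become explicitly typed network nodes, never counted as genes.

## Differential analysis

**Genes.** Library sizes are estimated by median-of-ratios over genes
positive in every sample; testing operates on y = log2(count/factor + 1)
with a Welch t-test per gene and BH adjustment across all tested genes per
contrast. This stage is deliberately simple and pluggable: downstream
stages consume only the effect sign and adjusted p, so any external
differential tool producing those columns can be substituted through the
`DifferentialTable` TSV schema (feature, log2fc, pvalue, padj, contrast).
Two limitations are inherent and documented rather than patched: the t-test
is underpowered at very low counts compared with negative-binomial GLMs,
and median-of-ratios develops a composition bias when a large fraction of
genes truly changes (visible in the knockout simulations when flipped
modules exceed roughly a quarter of the genome; the generator keeps them a
minority at defaults).

**Consistent sets.** DEG-0/DEG-1 require adjusted p < α (default 0.05) with
the same sign at *every* post-treatment time point. DM-0/DM-1 require
significance with one sign at ≥ 2 time points *and no significant call in
the opposite direction anywhere*; the conflict rule (a metabolite up twice
and down once is excluded from both) is a design decision — the recurrence
rule alone does not say what to do with mixed-direction metabolites, and
excluding them keeps DM-0 ∩ DM-1 = ∅ by construction.

**Metabolomics preprocessing.** Metabolites are kept only if every group
retains ≥ 2 observed values (`min_present`, matching the smallest group
size that still allows a variance estimate). Imputation is k-nearest
neighbours *within each time-point group independently* — abundances at
day 7 should not inform a missing day-28 value — with Euclidean distance on
co-observed metabolites, uniform donor weights, default k = 3 capped by
available donors. k, the metric and the scaling are free choices; k = 3 is
the smallest value that is not a single-donor copy while staying below the
default group size. Imputed values are means of observed donors, so they
always lie inside the observed per-group range, and observed entries are
never modified. The metabolite test is an equal-variance two-sample t on
relative peak areas, with the effect reported as the log2 ratio of group
means (an explicit convention; peak-area tables carry no canonical effect
measure).

**Mass-spec arithmetic.** Relative peak area = metabolite area /
(internal-standard area × sample amount). Mass error in ppm =
(measured − theoretical)/measured × 10⁶, checked against ±10 ppm for CE
acquisition and ±25 ppm for LC; migration/retention-time matching uses
±0.5 min (MT) and ±0.3 min (RT).

## Correlation networks

Correlations are Spearman's ρ (average ranks under ties; two-sided p from
the t approximation) over *all* samples pooled across groups — the
correlation signal of interest is the shared temporal trajectory, and
pooling control with all time points is what makes trajectory-coupled
features correlate. Values entering the correlation are log2-scale
(log2(normalized count + 1) for genes, log2 relative peak area after
imputation for metabolites); since Spearman is invariant to monotone
per-feature transforms this standardizes reporting without changing ρ.

Edge rules, after BH over all tested pairs:

- **Gene network (GCN):** keep pairs with adjusted p ≤ 0.05 **and** ρ > 0,
  then keep the top 25% by ρ. "Top 25%" is implemented as
  keep-first-⌈0.25·m⌉ after sorting by (ρ descending, pair lexicographic),
  which makes the retained edge count an exact counting function of the
  significant-positive count and the result independent of input order.
- **Metabolite network (MCN):** keep every pair with adjusted p ≤ 0.05,
  both signs (a positive-only switch exists).
- **Phenotype edges:** FDR filter only, both signs, bypassing the top-25%
  quantile (configurable). Rationale: declining lung-function parameters
  must be allowed to connect to up-regulated modules through negative
  correlations, and a quantile computed over ~10⁶ gene pairs would be
  meaningless for a handful of phenotype edges.

**Subnetworks.** Communities come from the Leiden algorithm under the
modularity objective on unweighted edges (ρ-weighting available), fixed
seed, labels reassigned in descending size order so label 0 is always the
largest (the G-0 / M-0 convention; ties broken by the lexicographically
smallest member, making labels a deterministic function of the graph and
seed). `detect_subnetworks` additionally excludes phenotype nodes from the
modularity optimization and then assigns each phenotype to the subnetwork
holding the majority of its *positively* correlated feature neighbours.
This is a deliberate deviation from simply clustering the augmented graph:
phenotype nodes correlate with large fractions of all features, and at
desk-scale network sizes (thousands of nodes rather than tens of
thousands) they act as hubs that can glue two anti-correlated feature
modules into one community. Assignment-by-adjacency preserves the
interpretation "this parameter clusters with that subnetwork" without
letting five hub nodes reshape the partition.

**Centrality and composition.** Local clustering coefficient is
2·triangles/(deg·(deg−1)) with degree < 2 mapped to 0; subnetwork averages
are computed on the full network's edges, not the induced subgraph (an
ambiguity resolved by config). Phenotype centrality counts adjacent
non-phenotype nodes. Composition statistics report subnetwork sizes as
percentages of the node count to 2 decimals, with an optional union share
(e.g. the two central subnetworks) and a phenotype-excluding denominator.

## Over-representation and integration

All enrichment is the upper-tail hypergeometric P(X ≥ k) with population =
universe size, successes = annotation∩universe, draws = query∩universe.
The universe for subnetwork profiles is *all partitioned features of that
omics type* (network features, not all measured features): subnetworks are
subsets of the network, and testing them against the measured universe
would confound network membership with subnetwork membership. BH is applied
within each library per query for profiles, and across the full
track × subnetwork matrix for track association; the chosen family is
recorded in output metadata.

**Bridging rule.** A gene subnetwork g and metabolite subnetwork m are
connected through subsystem s iff s is significant (BH ≤ 0.05) in g's gene
profile *and* in m's metabolite profile. The rule is symmetric in the two
omics sides and is this package's documented interpretation of
subsystem-based integration.

## Cross-species validation

Ortholog maps are reduced to one-to-one pairs (any row touching a
many-to-many relation is dropped). The same-trend fraction is computed over
genes significant in *both* tables (a `mouse`-denominator alternative is
exposed); overlap percentages keep unmapped genes in the denominator by
default so set sizes stay interpretable. The validated set requires
significance with one shared sign in the mouse table and both cohorts; all
summary percentages are raw ratios to 2 decimals, recomputable from the
per-gene output table.

## Perturbation reversal

With a disease table (disease vs control) and a perturbation table
(perturbed-disease vs disease), a gene is *reversed* iff significant in
both with opposite signs (a point-estimate mode exists but significance is
the default — opposite noise around zero is not reversal). Per subnetwork
the report carries the reversed fraction among disease-dysregulated
members, the hypergeometric enrichment of perturbation-affected genes
(universe = partitioned genes present in both tables), BH across
subnetworks, and a call: reversed-up/-down iff adjusted p ≤ 0.05 and the
median perturbation sign among dysregulated members opposes the median
disease sign. Both knockout contrast conventions (perturbed-disease vs
disease, or vs control) are supported; the first is the default.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
any particular organism's biology:

- **Counts:** NB(μ, variance μ + αμ²) with
  μ = L_s·exp(b_g + w_g·τ_m(t)); library factors L_s ~ U(0.8, 1.2),
  baselines b_g ~ N(4.5, 1) (mean counts ≈ 90), dispersion α = 0.05, and
  loadings w_g ~ N(loading_sd, 0.1·loading_sd) truncated at 0 so
  `loading_sd = 0` is an exact null and the default 1.0 gives coherent
  modules. A configurable fraction (default 0.8) of features is
  partitioned evenly into modules; the rest are background.
- **Trajectories τ_m:** five archetypes (sustained down with a mid-course
  nadir; early up with recovery; progressive up with plateau; late up;
  transient up then down), chosen to be near-orthogonal in group-rank
  space (max pairwise Spearman 0.4) so that modules are identifiable in
  principle — "distinct trajectories" is the planted property under test.
  Every trajectory is pinned to 0 in the reference group.
- **Metabolites:** lognormal with the *same* latent trajectories (module m
  of metabolites shares τ_m with gene module m), which is what makes the
  gene-metabolite bridge a planted, testable fact. Missingness is
  left-censoring-like: entries below the q-th abundance quantile (default
  0.10) are masked with probability 0.7, mimicking detection-limit
  dropout in MS data.
- **Phenotypes:** value = sign·τ_m(group) + N(0, σ). Defaults couple
  stiffness-like parameters (σ = 0, 0.2, 0.3) to the progressive module
  and volume parameters to the sustained-down module.
- **Cohort tables:** each mapped mouse-significant gene drops to
  non-significance with probability 0.1, otherwise stays significant with
  the mouse sign with probability `concordant_fraction` (default 0.75) —
  so the expected same-trend fraction among jointly significant genes
  equals the planted concordance exactly.
- **Knockout:** a two-arm experiment at one time point in which genes of
  the flipped modules return to baseline in the knockout arm while all
  other genes keep the disease effect.

Everything is driven by one integer seed through independent named
substreams, so each generator is individually deterministic.

**What the synthetic tests do not show.** Real data have batch effects,
outlier samples, correlated library-size and composition artifacts,
non-NB overdispersion, structured (not independent) missingness, and
annotation noise in subsystem/ortholog maps; none of these are simulated.
Passing the planted-recovery tests demonstrates that the pipeline's rules
are implemented correctly and recover structure under their own model
assumptions — not that the pipeline is robust to real-data pathology.

## Problem sizes and numerical conventions

The default synthetic study is 2000 genes × 300 metabolites × 25 samples —
large enough that the gene network has ~2·10⁶ tested pairs and community
detection is non-trivial, small enough that the full pipeline runs in well
under a minute. The committed fixture (30 genes, 12 metabolites, 2
phenotypes, 5 × 3 samples, seed 1) backs unit tests and the end-to-end
regression against committed golden outputs.

Conventions: two-sample tests on zero-variance data with equal means return
p = 1 (avoids NaN propagation); zero-variance features are excluded from
correlation (undefined ρ) and get all-zero z-scores in trajectory
summaries with a warning; empty networks are legal outputs with warnings,
not errors; all sort-based tie-breaks are lexicographic so outputs are
independent of input order; percentages are reported to 2 decimals as raw
ratios (never forced to a reference figure).

## Known limitations

- The Welch-on-log-counts differential stage is a documented default, not
  a replacement for shrinkage-based NB models at low counts.
- Median-of-ratios normalization biases fold changes when a large share of
  the genome truly changes between conditions.
- The top-25% edge rule couples a module's retained edge density to its
  correlation strength relative to other modules; weak-amplitude modules
  can be under-represented in the network.
- Multi-factor designs, batch correction and ranked gene-set statistics
  (GSEA-style) are out of scope.
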