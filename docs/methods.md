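# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model, and the numerical edge cases. It is
the package's own account of its design; no empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` compute.

## 1. Compositional handling

OTU counts are compositional: only relative information is meaningful.
Three representations are used.

- **Relative abundance** (rows sum to 1): input to Bray–Curtis, the core
  filter, Random-Forest features, and Spearman correlations. For rank
  correlations the choice between counts and proportions is nearly
  immaterial (ranks within a sample-constant rescaling are unchanged up to
  depth differences); relative abundance is the default for comparability
  across sequencing depths, with a raw-count flag.
- **CLR coordinates** `clr_i = ln(x_i + c) − mean_j ln(x_j + c)` (rows sum
  to 0): the space in which Euclidean distance is the Aitchison distance.
  The pseudocount default is **c = 1 on raw counts** — the simplest
  standard choice for count tables; both c and the counts-vs-proportions
  question are exposed as configuration because neither is canonical.
- **Raw counts**: alpha diversity only. Chao1 and the singleton/doubleton
  counts it needs are meaningless after normalization. Alpha diversity is
  computed on unrarefied counts; rarefaction is out of scope and the
  choice is flagged here because it affects richness comparability across
  depths.

Core-OTU filtering keeps OTUs with prevalence **strictly greater** than
50% of the stage's samples and mean relative abundance **strictly
greater** than 0.01%. Values exactly at a threshold are excluded; the
filter is idempotent.

## 2. Diversity and group testing

- Shannon uses the natural log; Simpson is reported as Gini–Simpson
  (1 − Σp²). Both conventions are stated in output column names
  (`shannon_ln`, `gini_simpson`) because the literature is split.
- Chao1 defaults to the bias-corrected estimator
  `S_obs + F1(F1−1) / (2(F2+1))`, which stays finite when doubletons are
  absent; the classic form is a flag.
- Kruskal–Wallis uses the tie-corrected H. Dunn's post-hoc z-tests are
  implemented from the pooled-rank formula with the Σ(t³−t) tie
  correction (no installed package provides them), and adjusted by
  Benjamini–Hochberg. The compact letter display is built greedily
  (insert-and-absorb) from the q < 0.05 separation matrix; letters are a
  presentation device, not an inferential one.
- PERMANOVA partitions Σd² by group membership; the permutation null is
  fully vectorized (one-hot einsum against the squared-distance matrix) so
  that calibration studies with hundreds of simulations stay cheap.
  ANOSIM ranks the distance vector once and re-scores group membership per
  permutation. Both use the (1 + exceedances)/(1 + n_perm) convention, so
  p = 0 is impossible and 0.001 is the floor at 999 permutations.
- PCoA is classical scaling of the double-centered Gower matrix. Negative
  eigenvalues (Bray–Curtis is not Euclidean-embeddable) are reported but
  contribute neither coordinates nor explained proportion; no
  Lingoes/Cailliez correction is applied.

## 3. Consensus staging

Two deliberately different clustering routes are run: Ward-linkage
agglomeration **directly on the Bray–Curtis matrix** and K-means (10
seeded restarts, best inertia) on **all positive-eigenvalue PCoA axes**.
Ward formally assumes Euclidean input; applying it to Bray–Curtis is the
field's common practice and is kept as the default, with a square-root
transform flag for metric safety. k is chosen by the silhouette score
scanned over k = 2…6 on each route separately.

K-means labels are aligned to the hierarchical labels by
maximum-agreement assignment (Hungarian matching on the contingency
table), which makes the consensus invariant to any relabeling of either
clusterer. Samples on which the aligned routes agree form Core stages;
the rest are Ambiguous and are excluded from Random-Forest validation,
network construction, and everything downstream of them.

Stage identity (which cluster is "Recovery") has two rules:

- **Convergence rule (default)**: the cluster with the smaller mean
  Aitchison distance to the non-degraded reference centroid is Recovery.
  Cheap and always computable.
- **Topology rule** (pipeline default, `stage_rule: topology`): build each
  cluster's co-occurrence network and call the cluster with the higher
  modularity Z-score Recovery. This is the structurally grounded
  definition; the pipeline falls back to the convergence rule when a
  cluster's network is too sparse to score. An exact tie in either
  criterion raises rather than guessing.

## 4. Random-Forest validation

100 trees, stratified 5-fold cross-validation, features = relative
abundances (CLR flag available). AUC is computed per fold from
out-of-fold probabilities; the confusion matrix thresholds at 0.5 and
accumulates across folds, so its total equals the number of Core samples.
Fold disjointness is asserted at run time. The classification threshold
and feature transform are recorded in the report because neither is
forced by the method.

## 5. Co-occurrence networks

Spearman ρ with average-rank ties over all pairs of core OTUs; two-sided
p from the t approximation for n > 9 samples and from **exact
enumeration of rank permutations** for n ≤ 9 (where the t approximation
is poorest and enumeration is affordable). BH-FDR is applied across all
pairs of one stage-kingdom network jointly — that is the natural test
family. An edge requires |ρ| > 0.7 **and** q < 0.01, both strict. Nodes
are edge-incident OTUs by default (matching how published node counts are
tallied); a flag includes isolated core OTUs. Constant OTU vectors have
undefined rank correlation and their pairs are skipped with a log entry.

## 6. Topology, roles, and the null model

Louvain runs on the unweighted, unsigned skeleton (sign and weight are
interaction semantics, not connectivity; the Zi–Pi role taxonomy and its
2.5/0.62 thresholds come from the unweighted tradition). Ten seeded
restarts, best Newman Q kept. Degenerate cases: edgeless graphs become
singleton modules with Q = 0; a module whose within-degree has zero
spread gives Zi = 0 for its members; isolated nodes get Pi = 0 and are
Peripheral. Role boundaries use ≤/> exactly as conventionally printed, so
the four boxes tile the (Zi, Pi) plane.

The modularity Z-score uses a **G(N, M)** ensemble (fixed edge count, not
fixed edge probability) of 100 graphs, each re-partitioned with identical
Louvain settings under fresh seeds derived from the master seed.
Re-optimizing per null graph is the conservative choice: it compares
best-found structure against best-found structure, rather than scoring
null graphs on a partition fitted to the data. σ_rand = 0 yields an
infinite sentinel with a warning. Self-calibration (a G(N, M) graph fed
to its own null) gives |Z| ≤ 3 in ≥ 95% of seeds in the acceptance suite.

## 7. Robustness

Removal orders are **static** (computed on the intact graph): random
(fresh permutation per repetition, 50 repetitions averaged, per-repetition
curves retained), degree (descending initial degree, id tie-break), and
keystone (role priority NetworkHub > ModuleHub > Connector > Peripheral,
degree then id within role). An adaptive-recomputation mode is not the
default because a fixed order is what "removed in descending order of
degree" describes. The relative LCC divides by the original node count,
so complete removal reaches 0. Curves are recorded after every removal
and computed by a reverse union-find sweep (exact, near-linear), which is
what keeps 50-repetition averages and multi-seed calibrations cheap.

**Collapse threshold**: the smallest recorded removal fraction at which
the relative LCC is ≤ the level (default 0.5). Removals are atomic, so
the threshold is a grid point rather than an interpolated crossing: a
10-node star under degree attack collapses at the first removal (0.1),
and a clique's LCC reaches exactly 0.5 when half its nodes are gone
(0.5). Interpolating between recorded points would instead place the
star's collapse at a fraction where no whole node has been removed. A
curve that never reaches the level reports 1.0 with a flag.

## 8. The synthetic chronosequence

The generator emulates the study design it is meant to exercise: 11
groups (severely degraded control SD; restoration ages 1, 4, 6, 8, 9, 12,
14, 16, 18 years; non-degraded reference ND) × 5 replicates = 55 samples,
one kingdom per table. Groups map to two latent regimes; the default puts
SD–6y in "chaos" (20 samples) and 8y–ND in "recovery" (35 samples). The
real system shows reversion events (late-year samples falling back to
chaos); the default map is monotone and does not reproduce them —
reversion scenarios can be configured via `chaos_groups`.

Mechanism (Gaussian copula → multinomial):

1. Per regime, a latent correlation matrix with block structure: modules
   of `module_size_mean` variables at `intra_module_corr` (chaos default
   10 × 4 at 0.90; recovery 6 × 10 at 0.94). A computed fraction f of each
   block's members is sign-flipped (diag(s)·Σ·diag(s), exactly
   positive-definite), where 2f(1−f) equals the target
   `negative_edge_fraction` (chaos 0.05, recovery 0.30).
2. Hub/connector truth marks: mild cross-block loadings (0.5). These are
   deliberately weak — a variable cannot be strongly correlated with
   several mutually independent blocks (Σρ² ≤ 1), and overreaching here
   only degrades the whole matrix through the positive-definite repair
   (eigenvalue clipping, logged). Dense keystone wiring is therefore
   planted at the **graph** layer instead: `planted_hub_network()` builds
   modular graphs with explicit connector/hub nodes for topology and
   robustness tests, where no correlation-geometry cap applies.
3. Group means sit on a per-OTU regime axis (`regime_centroid_shift`,
   default 2.0 on the log scale) separating the two regimes; per-sample
   latent = mean + correlated component + `noise_sd` × iid noise (chaos
   0.35, recovery 0.20).
4. Latents map through exp (monotone, hence Spearman-preserving) to
   expected relative abundances; counts are multinomial at `depth`
   (default 20,000 — small enough for desk-scale tests, deep enough for
   stable ranks).

Defaults were chosen once to realize the qualitative two-regime contrast
— sparse/weakly-modular/nearly-all-positive chaos networks versus
dense/modular/keystone-bearing recovery networks with a ~30% negative
fraction — at 55 samples and desk-scale runtime. The chaos regime's
correlations sit deliberately near the |ρ| > 0.7 detection edge at n = 20
samples, so chaos networks are small and seed-variable (1–10 edges),
which is the intended fragmentation.

What a green test does **not** establish: the generator draws i.i.d.
samples within groups (no spatial autocorrelation), uses a single global
depth (no library-size variation), plants hard regime membership (no
gradual transitions or reversions by default), and its taxonomy is a
three-phylum rotation. Results on it validate the machinery, not any
field system. Negative-pair correlations attenuate more than positive
ones through the count layer (low counts where the signal lives), so the
realized negative-edge proportion tracks the planted fraction only within
about ±0.1.

## 9. Reproducibility

Every stochastic step takes an explicit integer seed; derived seeds flow
from a master seed through a single `numpy` Generator, never global
state. The pipeline manifest records the configuration hash and all
seeds; two runs from the same seed produce byte-identical manifests, and
that is asserted in the acceptance suite.

## 10. Known limitations

- Spearman co-occurrence on relative abundances carries compositional
  bias; SparCC/SPIEC-EASI-style compositionally aware inference is
  explicitly out of scope.
- The ER null model preserves N and M but not the degree sequence;
  configuration-model nulls are out of scope, so Z-scores conflate
  modularity with degree heterogeneity to the usual extent.
- Module detection ignores edge signs; signed modularity is out of scope.
- Dunn's test uses the normal approximation; exact small-sample behavior
  is not implemented.
- At 5 replicates per group, per-group inferences (letters, compositions)
  are low-powered; the pipeline reports them but the staging analysis is
  the intended inference level.
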