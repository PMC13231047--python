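# Methods

This note records the models, defaults and design choices behind
`comorbhub`, in the order the pipeline runs them, together with what the
synthetic generator does and does not emulate.

## Differential expression

Each gene is modeled as a two-group Gaussian contrast on the log2 scale;
log2FC = mean(case) − mean(control). Residual variances s²ᵍ (d = n₁+n₂−2
df) are shrunk toward a prior: s̃²ᵍ = (d₀s₀² + d·s²ᵍ)/(d₀+d). The prior
(d₀, s₀²) is estimated in closed form by moment-matching log s²: under the
scaled-inverse-chi-square prior, Var(log s²) = ψ′(d/2) + ψ′(d₀/2) and
E(log s²) = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2); ψ′ is
inverted by Newton iteration. When the observed spread of log s² shows no
excess over ψ′(d/2), d₀ = ∞ and every gene uses the pooled prior variance;
in the exact-degenerate case of zero observed scatter the common variance
is taken at face value (the chi-square sampling model cannot hold there,
and correcting a bias that is absent would inflate s₀²). With d₀ = 0 the
statistic reduces to the ordinary two-sample t — exposed as
`moderated=False`, the second configuration whose direction-consistent
calls are intersected with the moderated ones. This mirrors the common
practice of cross-validating DEG lists with two tools that implement the
same family of tests; we treat them as two configurations of one routine
because a hosted re-implementation is not a distinct algorithm.

P-values use d₀+d df (normal when d₀ = ∞); adjustment is
Benjamini–Hochberg step-up with enforced monotonicity (the de facto
default of this toolchain). Thresholds are strict as printed:
direction "up" iff log2FC > 1 AND adj. p < 0.05; "down" symmetric.

No multi-factor designs, covariates, or count-model weighting.

## Co-expression modules

* **Outliers.** Mean pairwise Pearson correlation per sample; excluded iff
  strictly below μ − 3σ. Constant samples are an error (their correlation
  is undefined), reported by name.
* **Gene selection.** Top 5000 genes by median absolute deviation; equal
  MADs break lexicographically so selection is reproducible.
* **Soft threshold.** For each power β, connectivity kᵢ = Σⱼ |Sᵢⱼ|^β. The
  scale-free fit regresses log10 p(k) on log10 k over ten equal-occupancy
  (quantile) bins. Because equal-occupancy bins have constant raw counts
  by construction, p(k) is estimated as the per-bin density
  count/(n·width); zero-width bins from massive degree ties are dropped.
  The signed R² negates the coefficient when the slope is positive. The
  chosen β is the smallest with R² > 0.85; if none qualifies, the first
  plateau of the R² curve (|ΔR²| < 0.01 between consecutive powers) is
  used and a warning recorded.
* **TOM and modules.** Unsigned adjacency, unit diagonal;
  TOMᵢⱼ = (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ) with ℓᵢⱼ = Σ_{u≠i,j} aᵢᵤaᵤⱼ.
  Modules come from average-linkage clustering of 1−TOM with a *static*
  tree cut (height 0.99, minimum size 30): deterministic and sufficient
  for planted-block recovery, a deliberate simplification relative to the
  dynamic hybrid cut of the standard toolchain. Clusters below the
  minimum size become module 0 (grey); surviving modules are renumbered
  by size.
* **Eigengenes and trait.** Eigengene = first principal component of the
  module's standardized submatrix, sign-aligned to the module mean
  profile. Module–trait association is the Pearson correlation of the
  eigengene with the 0/1 case indicator; the strongest module maximizes
  |cor| (reported studies show only positive correlations, so the
  absolute value is the safe generalization).

## Disease gene sets

Disease A: step 1 intersects direction-consistent DEGs of the two
cohorts (moderated configuration); step 2 intersects with the
direction-consistent calls of the ordinary-t configuration (direction
consistency is applied uniformly in both steps); step 3 intersects the
strongest-module gene lists of both cohorts; the result is
step2 ∩ step3, sorted and deduplicated, with a provenance record of what
each step removed. Disease B: genes with relevance ≥ 10 (inclusive) in
the relevance source AND PubMed-ID count > 0 in the curation source.
Gene identifiers are exact strings; no symbol-alias harmonization.
Common hub genes = A ∩ B; key hub genes additionally intersect the two
single-disease network triangulations.

## PPI network analysis

Edges come from STRING-dialect TSV (combined_score 0–1000, divided by
1000) or SIF; the score filter is inclusive (≥ 0.4 by default, i.e. a
raw 400 passes), duplicates keep the maximum score, self-loops and
isolated nodes are dropped. Centralities are unweighted (scores only
gate edges): degree, betweenness normalized by (n−1)(n−2)/2, closeness
with Wasserman–Faust component scaling; the pre-filter keeps nodes
strictly above the mean on all three.

MCODE follows the original staged algorithm, with only its parameters
given by the reference workflow (degree cutoff 2, k-core 2, node score
cutoff 0.2, haircut on, fluff off): vertex weight = density of the
highest k-core of the closed neighborhood × its k; complexes grow
breadth-first from the highest-weight unvisited seed, admitting
neighbors with weight ≥ seed weight × (1 − 0.2); complexes without a
2-core are discarded and haircut iteratively strips degree-1 members.
Cluster score = density × node count to three decimals; ties in the
ranking break on the seed node id so results are independent of node
ordering. Fluff is not implemented (the parameter is accepted but must
remain False).

MCC enumerates maximal cliques (Bron–Kerbosch with pivoting, budgeted at
10⁶ cliques) and sums (|C|−1)! over cliques of size ≥ 2 containing each
node; a node whose neighborhood has no internal edges therefore scores
its degree (each incident edge is a maximal 2-clique). Ties at the top-20
boundary are all retained, with a logged warning, so the downstream
triangulation cannot depend on enumeration order.

## Enrichment and immune scoring

ORA is the hypergeometric upper tail P(X ≥ k) with BH adjustment within a
collection; the universe defaults to all measured genes of the
originating matrix (configurable), and query genes outside it are
dropped with a warning. Shared terms intersect the two diseases' top-20
term lists.

GSEA uses the weighted KS running sum (weight 1; weight 0 recovers the
classic statistic). The null is gene-set permutation — n_perm random
same-size sets over the ranked genes — because the per-hub rankings come
from median splits of small cohorts where phenotype permutation is not
meaningful; NES divides the ES by the mean |null ES| of matching sign and
p is the same-sign exceedance fraction. Significance: adj. p < 0.05 and
|NES| > 1, as printed. The pipeline ranks genes per hub by the
high-vs-low median-split mean difference within case samples.

ssGSEA ranks each sample's genes (average ranks on ties), weights in-set
genes by rank^0.25, and accumulates P_in − P_out down the list; the
score matrix is min–max normalized to [0, 1]. Scores depend only on
within-sample ranks, hence are invariant to any strictly monotone
per-sample transform — the property the tests assert. Group contrasts
use the two-sided Wilcoxon rank-sum with tie and continuity corrections;
hub–cell associations use Spearman's ρ (ranked Pearson, t approximation,
n−2 df) flagged at signed ρ > 0.3 and p < 0.05 (an absolute-value mode
exists; the signed rule follows the positive-association convention of
the reference workflow).

## Survival

Records with follow-up < 30 days are removed. Median splits assign
values strictly above the median to "high", strictly below to "low", and
exact ties to "low" (configurable; the convention is documented because
the reference workflow does not state one). Kaplan–Meier estimation and
the two-group log-rank test are delegated to `lifelines`; the tests pin
them to hand-computed product-limit values and closed-form null cases.
Overall survival is the only endpoint; no Cox models or confidence bands.

## miRNA network

miRNA identifiers are normalized by lowercasing and trimming only (no
miRBase version mapping — a documented limitation). Shared miRNAs are
the normalized intersection of the two disease lists; edges keep only
targets that are common hub genes; shared miRNAs with no hub target are
reported separately. The exported network is typed
(disease/mirna/gene) and round-trips through SIF and GraphML.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any real
platform: two case/control cohorts per study from a latent-factor
Gaussian block model (module gene = √ρ·factor + √(1−ρ)·noise, ρ = 0.8 by
default, expression on a log2-like scale around a baseline of 7 ± 0.5 so
the log2(x+1) step is toggled off), planted direction-consistent DEGs
(±2 log2 units at unit SD), a disease module whose factor is shifted by
1 SD in cases (giving module–trait correlations near 0.45 at the default
n = 40+40 per cohort), dual-source association tables in which the six
planted hubs pass both filters and decoys straddle the thresholds (each
decoy fails exactly one filter), a scored PPI edge table (within-module
edge probability 0.3, background 0.01, hubs wired to a configurable
fraction — at least half — of their module, scores uniform in 400–1000),
exponential survival with hazard h₀·exp(β·z) for standardized mean hub
expression z (h₀ = 1/730 per day, β = 1, censoring at rate 0.3
implemented as cutting the true time at a uniform fraction), miRNA lists
with 12 planted shared miRNAs each targeting at least one hub, and 28
immune signatures of which the first is drawn from planted up-genes and
is therefore up-shifted in cases.

One global seed fans out to per-generator child seeds (a stable hash of
the generator name mixed into a SeedSequence), so outputs are
byte-identical given the config and adding generators never perturbs
existing ones.

What the generator does **not** emulate: probe-level artifacts, batch
effects, heavy-tailed count noise, correlated censoring, miRNA identifier
dialects, or realistic pathway overlap structure. Passing tests therefore
demonstrate algorithmic correctness and recovery under the stated
generative model — not robustness to the messiness of real repository
data. One structural consequence worth knowing: the case-wise module
shift moves *all* disease-module genes upward, so planted down-regulated
genes sit against that shift and per-sample ranks of non-module genes
shift compositionally; both effects are real features of the model, and
the null-calibration tests use separate, genuinely null simulations.

## Numerical choices and degeneracies

* Strict inequalities follow the printed thresholds everywhere
  (log2FC > 1, score ≥ 0.4 inclusive, relevance ≥ 10 inclusive,
  PMIDs > 0 strict, outlier < μ−3σ strict).
* Ties: MAD ranking and MCC ranking break lexicographically on ids;
  MCODE ranking breaks on the seed id; median-split ties go low;
  ssGSEA ranks ties by average and orders equal values by gene id.
* Zero-variance genes are an error for correlation networks, but survive
  DE via moderation (s̃² > 0 whenever s₀² > 0).
* BH uses a stable mergesort so adjusted values are invariant to input
  order.
* The clique-enumeration budget (10⁶) turns pathological dense graphs
  into an explicit error rather than an unbounded run.

## Scale of the shipped simulations

The default study conditions — 300 genes (two modules of 100 plus 100
background), 40+40 samples per cohort, six planted hubs — keep a full
pipeline run around one second, so the recovery suite (10 seeded studies)
and the calibration suite (1000-replicate nulls) run comfortably inside a
normal CI budget. These sizes are the package's chosen desk-scale study
conditions; every threshold involved is configurable for larger runs.
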