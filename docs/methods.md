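# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Data model

Expression enters as a summarized gene × sample matrix on log2 scale (RMA-
style microarray summaries are the motivating input; any complete log2
matrix works). Missing values are a hard error, never imputed — microarray
summaries are complete, and silently imputing would corrupt the rank
weighting downstream. Linear-scale input is transformed as log2(x + offset)
with a caller-declared offset (default 0; use 1 for data containing zeros).
Gene sets enter as flat GMT member lists; ontology DAG structure is
deliberately not modeled — terms are treated as pre-flattened sets.

## Preprocessing

Three gene filters run before differential analysis:

* **Detection (presence) filter** — keep genes whose detection p-value is
  strictly below `alpha` (default 0.01) in *every* sample of at least one
  group. The all-samples-of-one-group rule keeps genes expressed in only
  one biological state, which is exactly the interesting case. When no
  detection matrix exists the filter must be disabled explicitly
  (`skip_detection`); it is never silently skipped.
* **Annotation filters** — drop multi-mapped probes and genes on the sex
  chromosomes (labels matched case-insensitively against X/Y/chrX/chrY) to
  avoid sex-driven confounding in cohorts of mixed sex.
* **Duplicate-symbol collapse** — among remaining rows sharing a symbol,
  keep the row with the highest mean expression. Collapse-by-max-mean is a
  common microarray convention (the best-responding probeset usually has
  the strongest signal); it is a documented choice, not the only defensible
  one, and each collapsed symbol is logged.

Filters touch genes only (samples and group labels are never altered) and
are idempotent. The detection filter commutes with the flag-based filters;
it does **not** commute with the collapse, because detection can remove a
symbol's winning row — the pipeline therefore always collapses last.

## Differential expression

The per-gene statistic is the moderated difference

    d(g) = (x̄₂(g) − x̄₁(g)) / (s(g) + s₀),
    s(g) = sqrt{ [SS₁ + SS₂] / (n₁ + n₂ − 2) · (1/n₁ + 1/n₂) }

i.e. the pooled-variance two-sample t statistic with an exchangeability
constant s₀ added to the denominator so that low-variance genes cannot
reach huge statistics by chance. With s₀ = 0, d is exactly the classical
pooled t (asserted to 1e-9 in the tests). `s0="auto"` picks the candidate
(percentiles of s) minimizing the coefficient of variation of the median
absolute deviation of d across s-quantile bins — the classic stabilization
heuristic; the chosen value is logged.

**Permutation FDR.** Group labels are permuted (all C(n, n₁) assignments
enumerated exhaustively when ≤ 10,000, otherwise seeded Monte-Carlo) and

    q(g) = median over permutations of #{|d_perm| ≥ |d_obs(g)|}
           ÷ #{|d_obs| ≥ |d_obs(g)|},

capped at 1 and made monotone non-increasing in |d| by cumulative-minimum
smoothing (so q-thresholds select contiguous |d| tails). This median-based
estimator was chosen over a delta-table sweep because it is simpler,
monotone by construction, and exactly testable by exhaustive enumeration.
Note one statistical subtlety found while testing: the Monte-Carlo median
of a *discrete* count distribution settles on either central order
statistic rather than the exhaustive midpoint, so MC and exhaustive
q-values for the few most extreme genes agree only to 0.5/count, not to
1/√B.

**Calls.** A gene is deregulated when both gates pass strictly: linear
fold-change magnitude 2^|Δmean| > 1.3 and q < 0.01 (`cells` preset); the
`mouse` preset relaxes the FDR gate to 10% for small in-vivo designs.
Direction is the sign of condition-minus-control; the caller always names
the condition group explicitly.

## Enrichment

One-sided over-representation only (depleted sets are out of scope): for
each set, p = P[X ≥ k], X ~ Hypergeometric(N, K, n), with N the declared
universe (default: all genes surviving preprocessing), K the set size
within the universe, n the query list, k the hits. Benjamini–Hochberg runs
over the sets actually tested — sets with fewer than `min_overlap_genes`
(default 3) universe members are excluded from the family, and the family
size is logged so the correction is auditable. Candidate ("mediated") sets
are those with adjusted p < 0.05 among the down-regulated genes.

## Single-sample set scores

Each sample is scored independently (column locality is asserted as a test
invariant). Genes are ranked descending within the sample, midranks for
ties, and weighted

    w(g) = x(g) · exp(−(r(g) − 1) / N)

so the top-ranked gene keeps its full log2 value and weights decay with
rank at scale N (the number of measured genes). The score of set m is
mean(w over members) − mean(w over non-members); a higher score means the
set's genes sit unusually high in that sample's expression ranking. The
weight function is pluggable (`weight_scheme`: `exp-rank` default, `rank`
for pure rank decay) because published rank-weighting variants differ and
downstream stages are agnostic to the choice. Sets are scored only when
their intersection with the measured genes lies in [5, 500] members
(degenerate tiny sets and near-universe sets produce unstable or
meaningless contrasts); a set equal to the whole universe has no complement
and is an error.

## Set-level statistics

* **Group test**: Welch (unequal-variance) two-sided t per set, with the
  "up-regulated in condition" list defined by direction > 0 and p < 0.05.
  Two-sided-plus-direction was chosen over one-sided because it matches the
  common reporting convention; a `greater` alternative is available.
* **Overlap**: cumulative hypergeometric tail on the number of shared set
  names. The universe is the sets scored in *both* analyses after size
  filtering — the smallest defensible universe — and is recorded in the
  result for auditability (a larger universe would only shrink p).
* **Heatmap order**: rows are z-scored (heatmaps show row-relative
  regulation), then average-linkage/Euclidean agglomerative clustering
  gives a deterministic leaf order (ties break by input index).
* **Concordance**: Pearson r on the shared-gene log2FC vectors with the
  two-sided t-transform p-value (n − 2 df); the commonly deregulated list
  collects genes called up in both or down in both analyses.

## Classification and the resampling null

PCA runs across samples on the candidate sets' scores, z-scoring each set
first (sets have heterogeneous scales; raw-covariance mode by flag). A
principal component's sign is arbitrary, so every component is oriented
deterministically: condition-group mean coordinate ≥ control-group mean,
ties resolved by making the largest loading positive. The designated
component (a config value, default 2; never a best-AUC search, which would
bias upward) is tested by Welch t and scored by AUC = P(condition sample >
control sample), ties ½.

The random-set null redraws `candidate_size` set names uniformly without
replacement from all scored sets, B times (default 1000), recomputes the
designated-component AUC per cohort under the same orientation rule, and
records the mean across cohorts; p_right = (1 + #{null ≥ observed})/(B+1)
— the add-one estimator, so p is never 0. Because orientation is applied
to null draws too, observed and null AUCs are exchangeable under the null
and p_right is uniform (verified by simulation). One known limitation: the
draw pool contains the candidate sets themselves. At realistic collection
sizes (thousands of terms, a dozen candidates) the contamination is
negligible, but in small synthetic universes (e.g. 10 strong candidates in
200 sets) draws containing two or more candidates reproduce the observed
separation and place a floor of roughly P[≥ 2 candidates in a draw] under
p_right whenever the observed AUC saturates at 1.0.

## Synthetic data

The generator emulates two-group microarray cohorts: per-gene log2
baselines uniform on [4, 12] and per-gene SDs uniform on [0.2, 0.8]
(typical RMA intensity and within-group spread), Gaussian noise, and an
additive shift `delta` applied in the condition group to a configurable
fraction (default all) of each planted set's members. Defaults mirror the
study conditions the pipeline is validated under: 2,000 genes, 10+10
samples, 200 sets, 10 planted sets, delta = 1.0. Detection p-values follow
a two-component model — Beta(0.05, 200) for expressed genes (≈99.7% of
values below 0.01, so reliably expressed genes pass the presence rule, as
on real arrays) and Uniform(0, 1) for a 10% silent fraction; this
exercises the filter and claims nothing about vendor detection internals.
Annotations plant duplicate symbols (2%, with independent expression rows
so the collapse is observable), multi-mapped flags (5%) and X/Y labels
(5%).

The paired-condition generator produces two log2FC vectors
fc = s + u + e with shared, private and noise components; the expected
Pearson correlation is shared²/(shared² + private² + noise²), so SDs can
be solved in closed form for any target r (the non-shared variance is
split equally between private effect and noise).

Not emulated: probe-level effects, batch/array effects, intensity-
dependent variance, correlated gene-gene noise, RNA-seq counts. Passing
tests therefore demonstrate correctness and calibration of the statistics
under a clean Gaussian model, not robustness to real-array artifacts.

## Numerical and reproducibility choices

Every stochastic step takes an explicit seed (numpy `default_rng`);
file-based workflows embed the package version, a config hash (excluding
the output location) and the seed in each output's header, and reruns are
byte-identical. Floats are written with ≥ 6 significant digits. Zero-
variance rows are z-scored to zeros with a warning in clustering, excluded
with a warning in the set group test, and guarded against division in the
moderated statistic. Exhaustive permutation is refused beyond 10,000
assignments.

## Problem sizes used in validation

Calibration and recovery tests run at the study design: 2,000 genes, 200
sets, 10+10 samples, 20 null replicates for p-value uniformity, 200 outer
replicates for resampling-p uniformity (B = 200 inner draws), 1,000
replicates for the null median-AUC estimate, 50 replicates for planted-
signal recovery, and 20 seeds at 10,000 genes for the paired-log2FC
correlation target of r = 0.274.
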