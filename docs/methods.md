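# Methods

## Model

`fhclust` treats a hierarchical clustering not as a sequence of merges but
as a *fuzzy equivalence relation*: a reflexive, symmetric matrix
R ∈ [0,1]ⁿˣⁿ that is transitive with respect to a t-norm. Two classical
facts drive the whole pipeline:

1. **Similarity from the Łukasiewicz bi-residuum.** With memberships
   y ∈ [0,1]ⁿˣᵐ, the similarity S(x,y) = (1/m) Σⱼ (1 − |y_xj − y_yj|)
   equals 1 minus the mean-L1 distance between membership rows. The L1
   triangle inequality makes S transitive under the Łukasiewicz t-norm
   T_L(a,b) = max(0, a+b−1), so S is a T_L-equivalence. (Aggregating the
   per-feature bi-residua by minimum instead — 1 minus the Chebyshev
   distance — is available via `aggregation="min"` and is also
   T_L-transitive.)
2. **Min-transitivity ⇔ ultrametricity ⇔ dendrogram.** R is min-transitive
   when R(x,z) ≥ min(R(x,y), R(y,z)) for all triples; this holds exactly
   when D = 1 − R satisfies the strong triangle inequality
   D(x,z) ≤ max(D(x,y), D(y,z)), and ultrametric dissimilarities are in
   bijection with dendrograms (the α-cuts of R are the nested partitions of
   the hierarchy). The smallest min-transitive relation dominating S — its
   *min-transitive closure* — is computed by iterated max–min composition
   and converts each view's similarity into a hierarchy.

Per view i: fuzzify Xᵢ → Yᵢ, compute Sᵢ, close to Cᵢ. The consensus
relation is A = closure(mean(C₁, …, C_v)); because the closure runs after
aggregation, A is min-transitive for any elementwise aggregator (`min` and
`max` are offered alongside the default `mean` for sensitivity analysis),
so a consensus dendrogram always exists. Single-linkage agglomeration of
D = 1 − A reproduces D exactly as its cophenetic distance (asserted to
1e−12 in tests); the merge heights are the distinct α-levels of A.

### Closure implementation

The production path is an all-pairs sweep in the (max, min) semiring
(Floyd–Warshall style, O(n³), exact in one pass); the test suite checks it
against an independent oracle — iterated squaring R ← max(R, R∘R) until a
fixed point — on hundreds of random relations. The closure is idempotent,
monotone, dominates its input and introduces no values absent from the
input matrix, all asserted as properties.

## Choosing the number of clusters

For k in the search range (default [2, 15], clamped to the cohort size) the
consensus dendrogram is cut and the quality curve is

v[k] = mean of (1 − A) over co-clustered patient pairs (pooled across
clusters; 0 when all clusters are singletons).

The chosen k maximises the magnitude of the discrete second derivative
v[k+1] + v[k−1] − 2 v[k]. The curve is evaluated on [k_min−1, k_max+1] so
that every searched k, including the boundary k = 2, is an interior point
of the scan. Among the candidate definitions of v (per-cluster mean sums,
total within-pair dissimilarity, pooled mean) only the pooled mean reliably
places the strongest curvature at the planted group count on synthetic
block designs — the total-sum variant provably prefers k = 2 for three
balanced groups because consecutive merge heights are ordered — so the
pooled mean is the default and only curve. Ties resolve to the smallest k;
a flat curve (e.g. all patients identical) falls back to the smallest k
with a warning.

## Preprocessing

Defaults mirror common TCGA practice, in this order:

| step | default | notes |
|------|---------|-------|
| missing-value filter | 20% | patients first, then features, strictly "more than" |
| KNN imputation | k = 10, unweighted | neighbours by Euclidean distance over co-observed features (scikit-learn `KNNImputer`) |
| log transform | log(1+x) | sequence-count views only; log1p keeps zeros finite |
| variance selection | n_keep per view (2000 is typical for expression/methylation, 5000 for large methylation panels) | zero-variance features always dropped; ties keep the earlier column |
| z-normalisation | sample sd (n−1) | per feature, mean 0 / sd 1 |
| Mean-Decrease-Gini cut-off | 500 trees | optional; unsupervised contrast: real rows vs independently column-permuted copies; features never used in a split (importance exactly 0) are removed |

The Gini step needs a target to be computable, so the standard unsupervised
random-forest device is used: the forest discriminates the real sample from
a marginal-preserving permuted copy, and importance-zero features carry no
joint structure. Constant features are provably importance-zero. The step
is deterministic per seed; if every feature were cut the step degrades to a
warning and a no-op.

Fuzzification is per-feature min–max rescaling to [0,1] (invariant to
positive affine rescaling; constant features map to the neutral 0.5). A
`membership_fn` hook accepts arbitrary user-supplied membership functions
(e.g. triangular/trapezoidal linguistic sets, possibly expanding each
feature into several membership columns).

## Evaluation statistics

- **Logrank** (k groups): observed vs expected events per group at each
  distinct event time under the hypergeometric model, ties handled by the
  hypergeometric variance; statistic ~ χ² with k−1 df (lifelines).
- **χ² independence** for discrete clinical labels, Pearson statistic
  without continuity correction, df = (r−1)(c−1).
- **Kruskal–Wallis** for numeric labels, tie-corrected H, df = k−1; a
  constant label returns H = 0 with a warning instead of an error.

`enrichment_summary` runs the appropriate test per label, drops missing
values per test, records untestable labels without counting them, counts
enrichments at raw (uncorrected) p ≤ 0.05 — matching how enrichment counts
are conventionally reported in multi-omics benchmarks — and reports
−log10 of the logrank p.

## Synthetic cohorts

- **Dispersion design** (`generate_dispersion_cohort`): 3 views,
  10 patients × 100 features; the first 5 patients' rows are N(0, 1) and
  the last 5 are N(0, 0.5), independently per view and feature. Group
  structure is carried by spread alone, with overlapping supports.
- **Block design** (`generate_block_cohort`): group g has mean
  g·shift on every feature plus N(0, noise_sd²) noise; a strongly
  identified fixture for k-recovery and monotonicity checks.
- **Hierarchy-combination triple** (`generate_concordant_relation_triple`):
  three hand-constructed min-transitive 4-patient relations where
  (s1,s2,s3) is a complete subtree in exactly two inputs; the consensus
  keeps it, nested in the full set.
- **Clinical tables** (`generate_clinical`): exponential survival per group
  scaled by hazard ratios (baseline scale 730 days), exponential censoring
  with the rate chosen so P(censored) equals the requested fraction
  exactly, one discrete and one numeric label with tunable group
  association.

Generators are pure functions of parameters and seed; the root seed is
split into independent per-view streams. None of them emulate real omics
marginals (counts, beta-values, feature correlation), so passing tests
demonstrate the algebra and the recovery behaviour of the method, not
performance on real TCGA-like data.

### What the dispersion design can and cannot show

For mean-zero groups with variances 1 and 0.5, the expected distance
between two high-variance patients (2/√π ≈ 1.13 per feature, L1) exceeds
the expected cross-group distance (√(3/π) ≈ 0.98). With 100 i.i.d.
features these concentrate, so high-variance patients are systematically
closer to the low-variance group than to each other, and *no*
distance-monotone similarity on independently transformed features can
place the high-variance group together at a two-cluster cut — the
high-variance patients chain in one at a time. What the fuzzy consensus
does achieve on this design, in every tested seed, is isolating the
low-variance group as a pure subtree of the consensus dendrogram before
any high-variance patient attaches. The two-cluster-cut comparison against
Euclidean single linkage is retained in the acceptance suite (both methods
tie at ARI 0 on average; the perfect-recovery assertion documents the
limitation by failing).

## Numerical choices

- Relations are stored in double precision; symmetry is enforced as
  (R + Rᵀ)/2 and the diagonal pinned to 1 at construction.
- Transitivity and ultrametricity tolerances default to 1e−12.
- Equal-height merges follow SciPy's deterministic single-linkage order;
  the hierarchy is unique up to reordering at equal heights, and all
  height-level quantities (cophenetic matrix, cuts) are order-independent.
- `Dendrogram.cut(k)` returns the nearest achievable partition below k
  with a warning when tied heights make exactly k unreachable.
- Relation TSV export uses `%.17g` and round-trip float parsing, so
  write/read is bit-exact.
- The consensus path contains no randomness; only `gini_select` and the
  synthetic generators take seeds.

## Problem sizes used in checks

Simulation-based checks run at deliberately small scale: dispersion
cohorts 3 × 10 × 100 over 20 seeds; block cohorts of 30 patients over 20
seeds per condition; closure oracles on n ≤ 8 relations (500 draws) and
dendrogram bijections on n ≤ 30 (100 draws); survival calibration with 500
null replicates (n = 60 for logrank/Kruskal–Wallis; n = 240 with a 3 × 3
table for χ², where the p-value distribution is fine enough for a
Kolmogorov–Smirnov uniformity check) and 50 power replicates at hazard
ratio 3 with n = 100.

## Known limitations

- Min-transitive closure is equivalent to single-linkage agglomeration and
  inherits chaining; dispersion-only group differences are not recoverable
  at coarse cuts (see above).
- The consensus aggregator (mean) weights all views equally; no per-view
  weighting is implemented.
- Methylation probe filtering against chromosome/SNP manifests and TCGA
  download tooling are out of scope; inputs are plain delimited matrices.
- No multiple-testing correction is applied across clinical labels, by
  design, to match conventional enrichment counting.
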