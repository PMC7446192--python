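# fhclust

Fuzzy similarity-based hierarchical consensus clustering for multi-omics
patient subtyping.

High-throughput studies routinely measure several omics on the same
patients — gene expression, miRNA expression, DNA methylation — and
subtypes that are invisible in any single omic can emerge when the views
are combined. `fhclust` implements a *late-integration* strategy: each
omic view is clustered hierarchically on its own, and the per-view
hierarchies are merged into a single consensus dendrogram, from which
patient subgroups are cut.

## The method

For each view, a patients × features matrix **X** is fuzzified feature-wise
into **Y** ∈ [0,1]ⁿˣᵐ (min–max rescaling by default; custom membership
functions can be plugged in). The patient × patient similarity is the mean
Łukasiewicz bi-residuum across features,

    S(x, y) = (1/m) Σⱼ (1 − |y_xj − y_yj|),

which is a fuzzy equivalence relation with respect to the Łukasiewicz
t-norm T_L(a, b) = max(0, a + b − 1): reflexive, symmetric and
T_L-transitive. Taking the **min-transitive closure** C of S (the smallest
relation with C(x,z) ≥ min(C(x,y), C(y,z)) dominating S, computed by
iterated max–min composition) makes D = 1 − C an **ultrametric**
dissimilarity, and ultrametrics are in one-to-one correspondence with
dendrograms: each view's closed relation *is* a hierarchy.

The per-view closures C₁, …, C_v are combined elementwise (arithmetic mean
by default) and re-closed, yielding a min-transitive consensus relation
**A** and hence a single consensus dendrogram. The number of clusters is
chosen in [2, 15] by the elbow of the within-cluster mean dissimilarity
curve v, locating the k that maximises |v[k+1] + v[k−1] − 2 v[k]|.

Clusterings are evaluated against clinical annotations with the k-group
logrank test (differential survival), the χ² test of independence
(discrete labels) and the Kruskal–Wallis test (numeric labels), counting
labels enriched at p ≤ 0.05.

## Worked example

Three synthetic views of 15 patients in three planted groups of 5, group
means separated by 6 noise standard deviations:

```python
from fhclust import run_fhclust
from fhclust.simulate import generate_block_cohort

cohort = generate_block_cohort(groups=(5, 5, 5), between_shift=6.0,
                               n_features=40, seed=7)
result = run_fhclust(cohort.views)
print("chosen number of clusters:", result.chosen_k)
print("cluster labels:", result.labels)
```

prints

```
chosen number of clusters: 3
cluster labels: {'s1': 3, 's2': 3, 's3': 3, 's4': 3, 's5': 3, 's6': 2,
 's7': 2, 's8': 2, 's9': 2, 's10': 2, 's11': 1, 's12': 1, 's13': 1,
 's14': 1, 's15': 1}
```

The elbow curve drops from 0.3005 (k=1) through 0.2147 (k=2) to 0.0721
(k=3) and then flattens (0.0713 at k=4), so the second-difference rule
selects k = 3; the cut reproduces the planted partition exactly. The two
between-group merges sit at consensus heights 0.386 and 0.395, far above
the within-group merges (≤ 0.077) — the dendrogram separates the groups
cleanly at every level.

The same pipeline is scriptable from the shell:

```bash
fhclust simulate block --seed 7 --groups 5,5,5 --between-shift 6 --out sim/
fhclust run --config cfg.yaml --out results/        # views listed in YAML
fhclust evaluate --labels results/labels.tsv --clinical clinical.tsv
```

`fhclust run` writes the consensus matrix (TSV), the dendrogram (Newick and
a merge table), the cluster labels and the elbow curve.

## Layout

| module               | contents                                              |
|----------------------|-------------------------------------------------------|
| `fhclust.datatypes`  | `OmicsView`, `FuzzyView`, `FuzzyRelation`, `UltrametricDissimilarity`, `Dendrogram`, `ClinicalTable` |
| `fhclust.preprocess` | matrix IO, missing-value filter, KNN imputation, log transform, variance selection, z-normalisation, Mean-Decrease-Gini cut-off, view alignment |
| `fhclust.fuzzy`      | Łukasiewicz t-norm / bi-residuum, fuzzification, similarity matrix |
| `fhclust.relations`  | max–min composition, min-transitive closure, ultrametric conversion, dendrogram construction and cutting |
| `fhclust.consensus`  | consensus matrix, dendrogram combination, elbow rule, `run_fhclust` |
| `fhclust.evaluate`   | logrank, χ², Kruskal–Wallis, enrichment summary       |
| `fhclust.simulate`   | synthetic multi-omic cohorts with planted structure   |

See `docs/methods.md` for the model, parameter defaults and known
limitations.
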