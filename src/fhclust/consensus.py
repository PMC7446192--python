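"""Consensus of per-view hierarchies and the end-to-end FH-Clust run.

Each view contributes a min-transitive (transitively closed) fuzzy
similarity C_i.  The consensus relation A aggregates the C_i elementwise
(arithmetic mean by default) and re-closes the aggregate under max-min
composition, so A is itself min-transitive and therefore corresponds to a
single consensus dendrogram.  The number of clusters is chosen on a
quality curve v over k by the largest-magnitude discrete second derivative
v[i+1] + v[i-1] - 2 v[i] (the "elbow").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import Dendrogram, FuzzyRelation, OmicsView
from .fuzzy import fuzzify, similarity_matrix
from .relations import build_dendrogram, min_transitive_closure, to_dissimilarity

__all__ = [
    "ElbowVector",
    "ConsensusResult",
    "consensus_matrix",
    "combine_dendrograms",
    "elbow_index",
    "run_fhclust",
]

_AGGREGATORS = {
    "mean": lambda stack: stack.mean(axis=0),
    "min": lambda stack: stack.min(axis=0),
    "max": lambda stack: stack.max(axis=0),
}


@dataclass
class ElbowVector:
    """Clustering-quality curve indexed by candidate cluster counts."""

    ks: list[int]
    v: list[float]

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.v):
            raise ValueError("ks and v must have equal length")


@dataclass
class ConsensusResult:
    """Output of a full FH-Clust run."""

    consensus_relation: FuzzyRelation
    dendrogram: Dendrogram
    chosen_k: int
    labels: dict[str, int]
    per_view_relations: list[FuzzyRelation] = field(default_factory=list)
    elbow_vector: ElbowVector | None = None


def consensus_matrix(
    relations: list[FuzzyRelation], aggregation: str = "mean"
) -> FuzzyRelation:
    """Aggregate closed per-view relations and re-close the aggregate.

    The elementwise aggregator is ``"mean"`` (default), ``"min"`` or
    ``"max"``; the subsequent min-transitive closure guarantees the output
    corresponds to a dendrogram regardless of the aggregator.
    """
    if not relations:
        raise ValueError("need at least one relation")
    ids = relations[0].patient_ids
    for r in relations[1:]:
        if r.patient_ids != ids:
            raise ValueError("relations must share patient ids and order")
    if aggregation not in _AGGREGATORS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    stack = np.stack([r.values for r in relations])
    agg = FuzzyRelation(list(ids), _AGGREGATORS[aggregation](stack))
    return min_transitive_closure(agg)


def combine_dendrograms(
    relations: list[FuzzyRelation], aggregation: str = "mean"
) -> Dendrogram:
    """Merge per-view hierarchies (given as closed relations) into one dendrogram."""
    return build_dendrogram(to_dissimilarity(consensus_matrix(relations, aggregation)))


def elbow_index(elbow: ElbowVector) -> int:
    """Candidate k at the strongest elbow of the quality curve.

    Returns ``ks[i]`` where ``i`` maximises the magnitude of the discrete
    second derivative ``v[i+1] + v[i-1] - 2 v[i]`` over interior points
    (the maximum of the expression when v decreases, the minimum when it
    increases).  Ties, including a perfectly linear curve, resolve to the
    smallest k.
    """
    if len(elbow.v) < 3:
        raise ValueError("elbow rule needs at least 3 points")
    v = np.asarray(elbow.v, dtype=float)
    second = np.abs(v[2:] + v[:-2] - 2.0 * v[1:-1])
    i = int(np.argmax(second)) + 1  # argmax takes the first (smallest-k) tie
    return int(elbow.ks[i])


def _within_cluster_dissimilarity(d: np.ndarray, flat: np.ndarray) -> float:
    """Mean dissimilarity over co-clustered patient pairs.

    Pooled over clusters: sum of D over within-cluster pairs divided by the
    number of within-cluster pairs.  Drops sharply once the cut stops
    merging distinct planted groups, which is what the second-difference
    elbow detects.  Zero when the partition has only singletons.
    """
    same = flat[:, None] == flat[None, :]
    iu = np.triu_indices(len(flat), k=1)
    within = same[iu]
    if not within.any():
        return 0.0
    return float(d[iu][within].sum() / within.sum())


def run_fhclust(
    views: list[OmicsView],
    *,
    aggregation: str = "mean",
    similarity_aggregation: str = "mean",
    k_min: int = 2,
    k_max: int = 15,
) -> ConsensusResult:
    """End-to-end FH-Clust on preprocessed views over a common patient set.

    Per view: fuzzify -> fuzzy similarity -> min-transitive closure.  The
    closed relations are merged by :func:`consensus_matrix`, the consensus
    dendrogram is built, and the number of clusters is chosen on
    ``k in [k_min, k_max]`` (clamped to the patient count) by the elbow
    rule applied to the within-cluster mean dissimilarity of 1 - A at each
    k-cut.  The core path is deterministic: no randomness enters after the
    input views.
    """
    if not views:
        raise ValueError("need at least one view")
    ids = views[0].patient_ids
    for v in views[1:]:
        if v.patient_ids != ids:
            raise ValueError("views must share patient ids and order; align first")

    per_view = [
        min_transitive_closure(
            similarity_matrix(fuzzify(v), aggregation=similarity_aggregation)
        )
        for v in views
    ]
    consensus = consensus_matrix(per_view, aggregation=aggregation)
    dend = build_dendrogram(to_dissimilarity(consensus))

    n = len(ids)
    d = 1.0 - consensus.values
    # pad the curve by one point on each side so that every searched k in
    # [k_min, k_max] is an interior point of the second-difference scan
    ks = list(range(max(1, k_min - 1), min(k_max + 1, n) + 1))
    if len(ks) < 3:
        # too few candidates for a second derivative: take the smallest k
        chosen_k = min(max(2, k_min), n)
        elbow = ElbowVector(ks, [0.0] * len(ks))
        warnings.warn(
            "fewer than 3 candidate cluster counts; elbow rule degenerate, "
            f"using k = {chosen_k}",
            stacklevel=2,
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tied heights during curve scan
            curve = [
                _within_cluster_dissimilarity(
                    d, np.asarray([dendcut for dendcut in dend.cut(k).values()])
                )
                for k in ks
            ]
        elbow = ElbowVector(ks, curve)
        if np.ptp(curve) == 0:
            warnings.warn(
                "elbow curve is flat; falling back to the smallest k",
                stacklevel=2,
            )
        chosen_k = elbow_index(elbow)

    labels = dend.cut(chosen_k)
    return ConsensusResult(
        consensus_relation=consensus,
        dendrogram=dend,
        chosen_k=chosen_k,
        labels=labels,
        per_view_relations=per_view,
        elbow_vector=elbow,
    )
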