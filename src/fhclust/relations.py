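"""Min-transitive closure, ultrametric conversion and dendrogram construction.

A fuzzy relation R is *min-transitive* when R(x,z) >= min(R(x,y), R(y,z))
for every triple.  The min-transitive closure — the smallest min-transitive
relation dominating R — is computed by iterated max-min composition.  For a
min-transitive similarity R the dissimilarity D = 1 - R is ultrametric, and
vice versa, so every closed relation corresponds to exactly one dendrogram:
the merge heights are the distinct alpha-levels of the relation, and the
cophenetic distance of the dendrogram reproduces D exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .datatypes import DEFAULT_TOL, Dendrogram, FuzzyRelation, UltrametricDissimilarity

__all__ = [
    "maxmin_compose",
    "min_transitive_closure",
    "is_min_transitive",
    "to_dissimilarity",
    "build_dendrogram",
    "cut_dendrogram",
]


def maxmin_compose(r1: FuzzyRelation, r2: FuzzyRelation) -> FuzzyRelation:
    """Max-min composition: out(x,z) = max_y min(r1(x,y), r2(y,z)).

    Both relations must be over the same patients in the same order.
    Reflexivity is preserved whenever both inputs are reflexive.
    """
    if r1.patient_ids != r2.patient_ids:
        raise ValueError("relations must share patient ids and order")
    a, b = r1.values, r2.values
    out = np.minimum(a[:, :, None], b[None, :, :]).max(axis=1)
    return FuzzyRelation(list(r1.patient_ids), out)


def _closure_values(v: np.ndarray) -> np.ndarray:
    """All-pairs max-min closure of a reflexive symmetric matrix, in place style.

    Floyd-Warshall-type sweep: allowing intermediate y = 0..n-1 one at a
    time, R(x,z) <- max(R(x,z), min(R(x,y), R(y,z))).  O(n^3) and exact for
    any finite matrix (no value not already present is ever created).
    """
    r = v.copy()
    n = r.shape[0]
    for y in range(n):
        np.maximum(r, np.minimum(r[:, y, None], r[None, y, :]), out=r)
    return r


def min_transitive_closure(r: FuzzyRelation, max_iter: int = 64) -> FuzzyRelation:
    """Smallest min-transitive relation dominating ``r``.

    Computed as the fixed point of ``R <- max(R, R o R)`` under max-min
    composition, implemented as a single all-pairs sweep.  The result is
    reflexive, symmetric and min-transitive, dominates ``r`` elementwise and
    introduces no values absent from ``r``.  ``max_iter`` guards the
    verification loop; convergence is guaranteed for finite matrices.
    """
    closed = _closure_values(r.values)
    # the single sweep is exact, but verify the fixed point defensively
    for _ in range(max_iter):
        again = _closure_values(closed)
        if np.array_equal(again, closed):
            return FuzzyRelation(list(r.patient_ids), closed)
        closed = again
    raise RuntimeError(f"closure did not converge within {max_iter} iterations")


def _transitivity_defect(v: np.ndarray) -> tuple[float, tuple[int, int, int]]:
    """Worst violation of min-transitivity and the triple (x, y, z) attaining it."""
    # defect(x,z) over y: min(R(x,y), R(y,z)) - R(x,z)
    via = np.minimum(v[:, :, None], v[None, :, :])  # (x, y, z)
    defect = via - v[:, None, :]
    flat = int(np.argmax(defect))
    x, y, z = np.unravel_index(flat, defect.shape)
    return float(defect[x, y, z]), (int(x), int(y), int(z))


def is_min_transitive(r: FuzzyRelation, tol: float = DEFAULT_TOL) -> bool:
    """True iff r(x,z) >= min(r(x,y), r(y,z)) - tol for all triples."""
    defect, _ = _transitivity_defect(r.values)
    return defect <= tol


def to_dissimilarity(r: FuzzyRelation, tol: float = DEFAULT_TOL) -> UltrametricDissimilarity:
    """Convert a min-transitive similarity into the ultrametric D = 1 - R."""
    defect, (x, y, z) = _transitivity_defect(r.values)
    if defect > tol:
        ids = r.patient_ids
        raise ValueError(
            "relation is not min-transitive: "
            f"R({ids[x]},{ids[z]}) = {r.values[x, z]:.6g} < "
            f"min(R({ids[x]},{ids[y]}), R({ids[y]},{ids[z]})) = "
            f"{min(r.values[x, y], r.values[y, z]):.6g}"
        )
    d = 1.0 - r.values
    np.fill_diagonal(d, 0.0)
    return UltrametricDissimilarity(list(r.patient_ids), d, tol=max(tol, DEFAULT_TOL))


def build_dendrogram(d: UltrametricDissimilarity) -> Dendrogram:
    """Single-linkage hierarchy over an ultrametric dissimilarity.

    For ultrametric input the cophenetic distance of the output equals the
    input exactly (up to floating-point representation); the merge heights
    are the distinct positive levels of ``d``.  Equal-height merges are
    ordered by SciPy's single-linkage traversal, which is deterministic; the
    hierarchy is unique up to reordering at equal heights.
    """
    n = d.n_patients
    if n == 1:
        return Dendrogram(list(d.patient_ids), np.empty((0, 4)))
    z = sch.linkage(squareform(d.values, checks=False), method="single")
    return Dendrogram(list(d.patient_ids), z)


def cut_dendrogram(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition of the leaves into ``k`` clusters (see ``Dendrogram.cut``)."""
    return dend.cut(k)
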