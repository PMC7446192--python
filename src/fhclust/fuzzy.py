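"""Fuzzification and Łukasiewicz-valued fuzzy similarity.

Each omic view is rescaled feature-wise into [0, 1] (a fuzzification step)
and the patient x patient similarity is the mean Łukasiewicz bi-residuum
across features:

    S(x, y) = (1/m) * sum_j (1 - |y_xj - y_yj|) = 1 - mean-L1(y_x, y_y)

Because 1 - mean-L1 satisfies the triangle inequality of the L1 metric,
S is transitive with respect to the Łukasiewicz t-norm
T_L(a, b) = max(0, a + b - 1); together with reflexivity and symmetry this
makes S a T_L-valued fuzzy equivalence relation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import FuzzyRelation, FuzzyView, OmicsView

__all__ = [
    "lukasiewicz_tnorm",
    "biresiduum",
    "fuzzify",
    "similarity_matrix",
]


def _check_unit_interval(*vals: float) -> None:
    for v in vals:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"value {v!r} outside [0, 1]")


def lukasiewicz_tnorm(a, b):
    """Łukasiewicz t-norm ``max(0, a + b - 1)``.

    Accepts scalars or arrays with entries in [0, 1]; 1 is the identity
    element and the operation is commutative, associative and monotone.
    """
    _check_unit_interval(a, b)
    return np.maximum(0.0, np.asarray(a, dtype=float) + np.asarray(b, dtype=float) - 1.0)


def biresiduum(a, b):
    """Łukasiewicz bi-residuum ``1 - |a - b|``: graded equality on [0, 1]."""
    _check_unit_interval(a, b)
    return 1.0 - np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def fuzzify(
    view: OmicsView,
    membership_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FuzzyView:
    """Map an omic matrix into membership degrees in [0, 1].

    The default membership function is per-feature min-max rescaling,
    ``y = (x - min) / (max - min)``, which is invariant to positive affine
    rescaling of each feature.  Constant features map to the neutral degree
    0.5 (in the default pipeline they are removed earlier by variance
    filtering).  A user-supplied ``membership_fn`` receives the full value
    matrix and must return an equally-shaped matrix in [0, 1], e.g. for
    triangular or trapezoidal per-feature membership functions.
    """
    if np.isnan(view.values).any():
        raise ValueError("fuzzify requires a fully observed matrix; impute first")
    if membership_fn is not None:
        y = np.asarray(membership_fn(view.values), dtype=float)
        if y.shape != view.values.shape:
            raise ValueError("membership_fn must preserve the matrix shape")
    else:
        x = view.values
        lo = x.min(axis=0, keepdims=True)
        hi = x.max(axis=0, keepdims=True)
        span = hi - lo
        constant = span[0] == 0
        span = np.where(constant, 1.0, span)
        y = (x - lo) / span
        y[:, constant] = 0.5
    return FuzzyView(list(view.patient_ids), list(view.feature_ids), y)


def similarity_matrix(fview: FuzzyView, aggregation: str = "mean") -> FuzzyRelation:
    """Patient x patient fuzzy similarity from a fuzzified view.

    Parameters
    ----------
    fview
        Fuzzified matrix with memberships in [0, 1].
    aggregation
        How per-feature bi-residua are combined: ``"mean"`` (default;
        equals 1 minus the mean-L1 distance and is provably
        T_L-transitive) or ``"min"`` (the most conservative graded
        equality across features).

    Returns
    -------
    FuzzyRelation
        Reflexive, symmetric and T_L-transitive similarity matrix.
    """
    if fview.n_features == 0:
        raise ValueError("cannot compute similarity from an empty feature set")
    y = fview.memberships
    if aggregation == "mean":
        # 1 - S is the cityblock distance divided by the feature count
        d = squareform(pdist(y, metric="cityblock")) / fview.n_features
        s = 1.0 - d
    elif aggregation == "min":
        s = 1.0 - squareform(pdist(y, metric="chebyshev"))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    # suppress floating-point asymmetry before constructing the relation
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return FuzzyRelation(list(fview.patient_ids), s)
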