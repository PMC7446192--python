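"""Core data containers for multi-view fuzzy hierarchical clustering.

The pipeline moves data through a fixed sequence of container types:
an :class:`OmicsView` (one omic matrix, patients x features, possibly with
missing entries) is fuzzified into a :class:`FuzzyView` (all entries in
[0, 1]), from which a patient x patient :class:`FuzzyRelation` is computed.
Min-transitive relations are in one-to-one correspondence with ultrametric
dissimilarities (:class:`UltrametricDissimilarity`) and hence with
dendrograms (:class:`Dendrogram`).  Clinical annotations used for cluster
evaluation live in a :class:`ClinicalTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "OmicsView",
    "FuzzyView",
    "FuzzyRelation",
    "UltrametricDissimilarity",
    "Dendrogram",
    "ClinicalTable",
]

#: numerical tolerance for symmetry / transitivity / ultrametricity checks
DEFAULT_TOL = 1e-12


def _as_str_list(ids: Sequence) -> list[str]:
    return [str(i) for i in ids]


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class OmicsView:
    """One omic data matrix with patients in rows and features in columns.

    Missing entries are represented as NaN in ``values``.
    """

    name: str
    patient_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_list(self.patient_ids)
        self.feature_ids = _as_str_list(self.feature_ids)
        _check_unique(self.patient_ids, "patient ids")
        _check_unique(self.feature_ids, "feature ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "") -> "OmicsView":
        return cls(
            name=name,
            patient_ids=list(df.index.astype(str)),
            feature_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.feature_ids
        )

    def replace_values(self, values: np.ndarray) -> "OmicsView":
        """Return a copy of the view with a new value matrix, same ids."""
        return OmicsView(self.name, list(self.patient_ids), list(self.feature_ids), values)

    def subset(self, patient_idx=None, feature_idx=None) -> "OmicsView":
        """Return a view restricted to the given positional indices."""
        pidx = np.arange(self.n_patients) if patient_idx is None else np.asarray(patient_idx)
        fidx = np.arange(self.n_features) if feature_idx is None else np.asarray(feature_idx)
        return OmicsView(
            self.name,
            [self.patient_ids[i] for i in pidx],
            [self.feature_ids[j] for j in fidx],
            self.values[np.ix_(pidx, fidx)],
        )


@dataclass
class FuzzyView:
    """Fuzzified omic matrix: same shape as its source view, entries in [0, 1]."""

    patient_ids: list[str]
    feature_ids: list[str]
    memberships: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_list(self.patient_ids)
        self.feature_ids = _as_str_list(self.feature_ids)
        self.memberships = np.asarray(self.memberships, dtype=float)
        if self.memberships.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValueError("memberships shape does not match ids")
        if np.isnan(self.memberships).any():
            raise ValueError("memberships contain NaN")
        if self.memberships.min(initial=0.0) < 0 or self.memberships.max(initial=1.0) > 1:
            raise ValueError("memberships must lie in [0, 1]")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class FuzzyRelation:
    """Reflexive, symmetric patient x patient relation with values in [0, 1]."""

    patient_ids: list[str]
    values: np.ndarray
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_list(self.patient_ids)
        _check_unique(self.patient_ids, "patient ids")
        v = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        if v.shape != (n, n):
            raise ValueError(f"relation must be {n}x{n}, got {v.shape}")
        if np.isnan(v).any():
            raise ValueError("relation contains NaN")
        if v.min() < -self.tol or v.max() > 1 + self.tol:
            raise ValueError("relation entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=self.tol):
            raise ValueError("relation must be reflexive (unit diagonal)")
        if not np.allclose(v, v.T, atol=self.tol):
            raise ValueError("relation must be symmetric")
        # canonicalise: clip rounding noise, enforce exact symmetry and diagonal
        v = np.clip(v, 0.0, 1.0)
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 1.0)
        self.values = v

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids)

    def write_tsv(self, path) -> None:
        # %.17g preserves doubles exactly through a text round trip
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path) -> "FuzzyRelation":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _ultrametric_defect(d: np.ndarray) -> float:
    """Largest violation of D(x,z) <= max(D(x,y), D(y,z)) over all triples."""
    relaxed = np.maximum(d[:, :, None], d[None, :, :]).min(axis=1)
    return float((d - relaxed).max())


@dataclass
class UltrametricDissimilarity:
    """Square dissimilarity in [0, 1] satisfying the strong triangle inequality."""

    patient_ids: list[str]
    values: np.ndarray
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_list(self.patient_ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        if v.shape != (n, n):
            raise ValueError(f"dissimilarity must be {n}x{n}, got {v.shape}")
        if not np.allclose(np.diag(v), 0.0, atol=self.tol):
            raise ValueError("dissimilarity must have zero diagonal")
        if not np.allclose(v, v.T, atol=self.tol):
            raise ValueError("dissimilarity must be symmetric")
        defect = _ultrametric_defect(v)
        if defect > self.tol:
            raise ValueError(
                f"dissimilarity is not ultrametric (max violation {defect:.3e})"
            )
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


class Dendrogram:
    """An agglomerative merge hierarchy over a fixed set of leaves.

    Internally backed by a SciPy linkage matrix; ``merges`` exposes the
    ordered list of (cluster-a, cluster-b, height) rows where clusters are
    numbered as in SciPy (0..n-1 leaves, then n, n+1, ... for merge nodes).
    """

    def __init__(self, leaves: Sequence[str], linkage: np.ndarray):
        self.leaves = _as_str_list(leaves)
        Z = np.asarray(linkage, dtype=float)
        n = len(self.leaves)
        if Z.shape != (n - 1, 4):
            raise ValueError(f"linkage must have shape ({n - 1}, 4), got {Z.shape}")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -DEFAULT_TOL):
            raise ValueError("merge heights must be non-decreasing")
        self.linkage = Z

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into (up to) ``k`` clusters.

        Cuts just below the (n-k)-th merge height.  When duplicated heights
        make exactly ``k`` clusters unreachable, the nearest achievable
        number of clusters below ``k`` is returned with a warning.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        achieved = len(np.unique(flat))
        if achieved != k:
            warnings.warn(
                f"requested {k} clusters but tied merge heights allow only "
                f"{achieved}; returning the {achieved}-cluster partition",
                stacklevel=2,
            )
        return {leaf: int(c) for leaf, c in zip(self.leaves, flat)}

    def cophenetic_matrix(self) -> np.ndarray:
        """Square matrix of cophenetic distances (height of lowest common merge)."""
        return squareform(sch.cophenet(self.linkage))

    def subtrees(self) -> set[frozenset[str]]:
        """Leaf sets of every internal node (all clusters at every level)."""
        n = self.n_leaves
        members: dict[int, frozenset[str]] = {
            i: frozenset([leaf]) for i, leaf in enumerate(self.leaves)
        }
        out: set[frozenset[str]] = set()
        for i, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            out.add(merged)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: self.leaves[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - node_height[a]
            lb = h - node_height[b]
            node_str[n + i] = f"({node_str[a]}:{la:g},{node_str[b]}:{lb:g})"
            node_height[n + i] = h
        return node_str[n + len(self.linkage) - 1] + ";"

    def merge_table(self) -> pd.DataFrame:
        """Four-column merge table: child-a, child-b, height, size."""
        return pd.DataFrame(
            self.linkage,
            columns=["child_a", "child_b", "height", "size"],
        ).astype({"child_a": int, "child_b": int, "size": int})


@dataclass
class ClinicalTable:
    """Per-patient survival outcome plus clinical labels for cluster evaluation.

    ``survival_time`` is in days; ``event`` is 1 when death was observed and
    0 when the follow-up was censored.  Discrete labels (e.g. gender,
    pathologic T/M/N/stage) and numeric labels (e.g. age at diagnosis) may
    contain missing values.
    """

    patient_ids: list[str]
    survival_time: np.ndarray
    event: np.ndarray
    discrete_labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    numeric_labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.patient_ids = _as_str_list(self.patient_ids)
        _check_unique(self.patient_ids, "patient ids")
        n = len(self.patient_ids)
        self.survival_time = np.asarray(self.survival_time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.survival_time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("survival_time and event must have one entry per patient")
        if (self.survival_time < 0).any():
            raise ValueError("survival_time must be non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event must be binary (0 = censored, 1 = death)")
        for df_name in ("discrete_labels", "numeric_labels"):
            df = getattr(self, df_name)
            if len(df) == 0:
                setattr(self, df_name, pd.DataFrame(index=self.patient_ids))
            elif list(df.index.astype(str)) != self.patient_ids:
                raise ValueError(f"{df_name} index must match patient_ids")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset(self, patients: Sequence[str]) -> "ClinicalTable":
        idx = {p: i for i, p in enumerate(self.patient_ids)}
        pos = [idx[str(p)] for p in patients]
        return ClinicalTable(
            [self.patient_ids[i] for i in pos],
            self.survival_time[pos],
            self.event[pos],
            self.discrete_labels.iloc[pos],
            self.numeric_labels.iloc[pos],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"survival_time": self.survival_time, "event": self.event},
            index=self.patient_ids,
        )
        return pd.concat([df, self.discrete_labels, self.numeric_labels], axis=1)
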