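"""Reading omic matrices and the standard multi-omics preprocessing chain.

The chain mirrors common TCGA-style preparation: remove patients and then
features with more than 20% missing values, impute the remainder with
k-nearest-neighbour imputation, log-transform sequence-derived counts,
keep the highest-variance features, z-normalise each feature, and finally
drop features with zero Mean-Decrease-Gini importance in an unsupervised
random-forest contrast (real samples vs column-permuted copies).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer

from .datatypes import ClinicalTable, OmicsView

__all__ = [
    "read_omics_matrix",
    "read_clinical_table",
    "filter_missing",
    "knn_impute",
    "log_transform",
    "select_top_variance",
    "zscore_normalize",
    "gini_select",
    "align_views",
    "preprocess_view",
]

#: cell contents accepted as missing, besides an empty cell
MISSING_TOKENS = ("", "NA", "NaN", "nan", "na")


def read_omics_matrix(
    path,
    orientation: str = "patients-in-rows",
    name: str | None = None,
    sep: str | None = None,
) -> OmicsView:
    """Read a delimited omic matrix (one header row, one label column).

    ``orientation`` declares where patients live in the file; the returned
    view always has patients in rows.  ``sep=None`` sniffs the delimiter
    (tab or comma).  Cells that are empty or one of the accepted missing
    tokens become NaN; any other non-numeric cell raises with its location.
    """
    if orientation not in ("patients-in-rows", "patients-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    if orientation == "patients-in-columns":
        df = df.T
    ids = list(df.index.astype(str))
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids in {path}: {dupes}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at patient {ids[i]!r}, "
                    f"feature {df.columns[j]!r} in {path}"
                ) from None
    return OmicsView(
        name=name if name is not None else str(path),
        patient_ids=ids,
        feature_ids=list(df.columns.astype(str)),
        values=values,
    )


def read_clinical_table(
    path,
    time_col: str = "survival_time",
    event_col: str = "event",
    discrete_cols: list[str] | None = None,
    numeric_cols: list[str] | None = None,
    sep: str | None = None,
) -> ClinicalTable:
    """Read a clinical table with survival columns and optional label columns.

    Label columns not listed explicitly are classified by dtype: numeric
    columns become numeric labels, everything else discrete labels.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        index_col=0,
        na_values=list(MISSING_TOKENS),
    )
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"clinical table misses required column {col!r}")
    label_cols = [c for c in df.columns if c not in (time_col, event_col)]
    if discrete_cols is None and numeric_cols is None:
        numeric_cols = [c for c in label_cols if pd.api.types.is_numeric_dtype(df[c])]
        discrete_cols = [c for c in label_cols if c not in numeric_cols]
    return ClinicalTable(
        patient_ids=list(df.index.astype(str)),
        survival_time=df[time_col].to_numpy(dtype=float),
        event=df[event_col].to_numpy(dtype=int),
        discrete_labels=df[discrete_cols or []].astype("object"),
        numeric_labels=df[numeric_cols or []].astype(float),
    )


def filter_missing(view: OmicsView, max_missing_fraction: float = 0.20) -> OmicsView:
    """Drop patients, then features, with missing fraction strictly above threshold."""
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    miss = view.missing_mask
    keep_p = np.flatnonzero(miss.mean(axis=1) <= max_missing_fraction)
    if keep_p.size == 0:
        raise ValueError("all patients exceed the missing-value threshold")
    miss = miss[keep_p]
    keep_f = np.flatnonzero(miss.mean(axis=0) <= max_missing_fraction)
    if keep_f.size == 0:
        raise ValueError("all features exceed the missing-value threshold")
    return view.subset(keep_p, keep_f)


def knn_impute(view: OmicsView, k: int = 10) -> OmicsView:
    """Fill missing entries with the unweighted mean of the k nearest patients.

    Neighbours are ranked by Euclidean distance over co-observed features.
    Patients or features with no observed value at all cannot be imputed.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k >= view.n_patients:
        raise ValueError("k must be smaller than the number of patients")
    if not view.missing_mask.any():
        return view
    if view.missing_mask.all(axis=1).any():
        raise ValueError("some patient has no observed value")
    if view.missing_mask.all(axis=0).any():
        raise ValueError("some feature has no observed value")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    return view.replace_values(imputer.fit_transform(view.values))


def log_transform(view: OmicsView) -> OmicsView:
    """Apply log(1 + x) entrywise; intended for sequence-derived count features."""
    if np.nanmin(view.values) < 0:
        raise ValueError("log transform requires non-negative values")
    return view.replace_values(np.log1p(view.values))


def select_top_variance(view: OmicsView, n_keep: int) -> OmicsView:
    """Keep the ``n_keep`` features with highest sample variance.

    Zero-variance features are always dropped, regardless of ``n_keep``.
    Ties are broken in favour of the earlier column; surviving features keep
    their original order.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    var = np.nanvar(view.values, axis=0, ddof=1)
    nonzero = np.flatnonzero(var > 0)
    if nonzero.size == 0:
        raise ValueError("all features have zero variance")
    # stable sort on descending variance keeps earlier columns on ties
    order = nonzero[np.argsort(-var[nonzero], kind="stable")]
    kept = np.sort(order[: min(n_keep, order.size)])
    return view.subset(feature_idx=kept)


def zscore_normalize(view: OmicsView) -> OmicsView:
    """Standardise each feature to mean 0 and (sample) standard deviation 1."""
    mean = np.nanmean(view.values, axis=0)
    sd = np.nanstd(view.values, axis=0, ddof=1)
    if np.any(sd == 0) or np.any(np.isnan(sd)):
        bad = [view.feature_ids[j] for j in np.flatnonzero(~(sd > 0))]
        raise ValueError(f"zero-variance features cannot be standardised: {bad}")
    return view.replace_values((view.values - mean) / sd)


def gini_select(view: OmicsView, n_trees: int = 500, seed: int = 0) -> OmicsView:
    """Unsupervised Mean-Decrease-Gini feature cut-off.

    A random forest is trained to discriminate the real samples from an
    equal-sized contrast set obtained by independently permuting each
    feature column (which preserves marginals but destroys joint
    structure).  Features whose Mean-Decrease-Gini importance is exactly
    zero — never chosen for a split — are removed.  Deterministic for a
    fixed seed.
    """
    if n_trees <= 0:
        raise ValueError("n_trees must be positive")
    if view.missing_mask.any():
        raise ValueError("gini_select requires a fully observed matrix")
    rng = np.random.default_rng(seed)
    x = view.values
    contrast = np.column_stack(
        [rng.permutation(x[:, j]) for j in range(view.n_features)]
    )
    data = np.vstack([x, contrast])
    target = np.r_[np.ones(len(x), dtype=int), np.zeros(len(contrast), dtype=int)]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(data, target)
    keep = np.flatnonzero(forest.feature_importances_ > 0)
    if keep.size == 0:
        warnings.warn(
            "every feature had zero Gini importance; keeping all features",
            stacklevel=2,
        )
        return view
    return view.subset(feature_idx=keep)


def align_views(views: list[OmicsView]) -> list[OmicsView]:
    """Restrict all views, in identical order, to their common patients.

    The order of the first view's patients (restricted to the intersection)
    is used for every output view.
    """
    if not views:
        raise ValueError("need at least one view")
    common = set(views[0].patient_ids)
    for v in views[1:]:
        common &= set(v.patient_ids)
    if not common:
        raise ValueError("patient intersection across views is empty")
    ordered = [p for p in views[0].patient_ids if p in common]
    out = []
    for v in views:
        pos = {p: i for i, p in enumerate(v.patient_ids)}
        out.append(v.subset(patient_idx=[pos[p] for p in ordered]))
    return out


def preprocess_view(
    view: OmicsView,
    *,
    is_sequence: bool = False,
    n_top_variance: int | None = None,
    max_missing_fraction: float = 0.20,
    knn_k: int = 10,
    gini: bool = False,
    n_trees: int = 500,
    seed: int = 0,
) -> OmicsView:
    """Full preprocessing chain for one view.

    Order: missing-value filter -> KNN imputation -> log transform (sequence
    views only) -> top-variance selection -> z-normalisation -> optional
    Mean-Decrease-Gini cut-off.
    """
    v = filter_missing(view, max_missing_fraction)
    if v.missing_mask.any():
        v = knn_impute(v, k=min(knn_k, v.n_patients - 1))
    if is_sequence:
        v = log_transform(v)
    n_keep = n_top_variance if n_top_variance is not None else v.n_features
    v = select_top_variance(v, n_keep)
    v = zscore_normalize(v)
    if gini:
        v = gini_select(v, n_trees=n_trees, seed=seed)
    return v
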