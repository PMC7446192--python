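"""Cluster evaluation against survival and clinical annotations.

Three tests, each referred to a chi-squared distribution: the k-group
logrank test for differential survival across clusters, the Pearson
chi-squared test of independence for discrete clinical labels, and the
Kruskal-Wallis rank test for numeric labels.  ``enrichment_summary``
applies the appropriate test to every label and counts enrichments at an
uncorrected p <= 0.05, reporting -log10 of the logrank p alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .datatypes import ClinicalTable

__all__ = [
    "TestResult",
    "EnrichmentReport",
    "logrank_test",
    "chi2_enrichment",
    "kruskal_wallis",
    "enrichment_summary",
]


@dataclass
class TestResult:
    name: str
    test: str
    statistic: float
    df: int
    p: float


@dataclass
class EnrichmentReport:
    """Per-label test results plus summary counts."""

    results: list[TestResult]
    n_enriched: int
    logrank_minus_log10_p: float
    untestable: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.name,
                    "test": r.test,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p": r.p,
                }
                for r in self.results
            ]
        )


def _groups_from_labels(
    patient_ids: list[str], labels: dict[str, int]
) -> np.ndarray:
    try:
        return np.asarray([labels[p] for p in patient_ids])
    except KeyError as e:
        raise ValueError(f"partition misses patient {e.args[0]!r}") from None


def logrank_test(
    clinical: ClinicalTable, labels: dict[str, int]
) -> tuple[float, int, float]:
    """k-group logrank test of differential survival across clusters.

    At each distinct event time the observed events per group are compared
    with their expectation under the hypergeometric model (ties handled by
    the standard hypergeometric variance); the statistic is referred to a
    chi-squared distribution with k - 1 degrees of freedom.
    """
    groups = _groups_from_labels(clinical.patient_ids, labels)
    k = len(np.unique(groups))
    if k < 2:
        raise ValueError("logrank test needs at least 2 clusters")
    if clinical.event.sum() == 0:
        raise ValueError("logrank test needs at least one observed event")
    res = multivariate_logrank_test(
        clinical.survival_time, groups, clinical.event
    )
    return float(res.test_statistic), k - 1, float(res.p_value)


def chi2_enrichment(
    label: pd.Series, labels: dict[str, int]
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence between clusters and a discrete label.

    Missing label values are dropped; the contingency table must have at
    least two clusters and two categories.
    """
    groups = _groups_from_labels(list(label.index.astype(str)), labels)
    mask = label.notna().to_numpy()
    table = pd.crosstab(groups[mask], label[mask])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table of shape {table.shape}; "
            "need >= 2 clusters and >= 2 categories"
        )
    stat, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), int(df), float(p)


def kruskal_wallis(
    label: pd.Series, labels: dict[str, int]
) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test between clusters on a numeric label.

    Tie-corrected H statistic, referred to chi-squared with k - 1 degrees
    of freedom.  If every value is identical the statistic is 0 with p = 1
    (returned with a warning rather than an error).
    """
    groups = _groups_from_labels(list(label.index.astype(str)), labels)
    mask = label.notna().to_numpy()
    values = label[mask].to_numpy(dtype=float)
    groups = groups[mask]
    uniq = np.unique(groups)
    if len(uniq) < 2 or any((groups == g).sum() < 1 for g in uniq):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty clusters")
    samples = [values[groups == g] for g in uniq]
    if np.ptp(values) == 0:
        warnings.warn("all label values identical; H = 0", stacklevel=2)
        return 0.0, len(uniq) - 1, 1.0
    stat, p = stats.kruskal(*samples)
    return float(stat), len(uniq) - 1, float(p)


def enrichment_summary(
    clinical: ClinicalTable, labels: dict[str, int], alpha: float = 0.05
) -> EnrichmentReport:
    """Test every clinical label against the partition and count enrichments.

    Discrete labels get the chi-squared independence test, numeric labels
    the Kruskal-Wallis test, survival the logrank test.  ``n_enriched``
    counts clinical labels (survival excluded) with p <= alpha, with no
    multiple-testing correction.  Labels whose test cannot be run (e.g. a
    single observed category) are recorded as untestable and not counted.
    """
    results: list[TestResult] = []
    untestable: list[str] = []
    n_enriched = 0

    for col in clinical.discrete_labels.columns:
        try:
            stat, df, p = chi2_enrichment(clinical.discrete_labels[col], labels)
        except ValueError:
            untestable.append(col)
            continue
        results.append(TestResult(col, "chi2", stat, df, p))
        n_enriched += int(p <= alpha)
    for col in clinical.numeric_labels.columns:
        try:
            stat, df, p = kruskal_wallis(clinical.numeric_labels[col], labels)
        except ValueError:
            untestable.append(col)
            continue
        results.append(TestResult(col, "kruskal-wallis", stat, df, p))
        n_enriched += int(p <= alpha)

    stat, df, p = logrank_test(clinical, labels)
    results.append(TestResult("survival", "logrank", stat, df, p))
    minus_log10_p = float(-np.log10(max(p, np.finfo(float).tiny)))

    return EnrichmentReport(
        results=results,
        n_enriched=n_enriched,
        logrank_minus_log10_p=minus_log10_p,
        untestable=untestable,
    )
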