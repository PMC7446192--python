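"""Synthetic multi-omic cohorts with planted structure.

Every generator is a pure function of its parameters and a root seed; the
root seed is split into independent per-view streams so adding a view never
perturbs the others.  Three designs are provided:

* a dispersion design — two equal patient groups drawn from mean-zero
  normals with different variances (1 vs 0.5 by default), three views of
  10 patients x 100 features, where separation comes from spread rather
  than location;
* a mean-shift block design with configurable group sizes and separation,
  a strongly identified fixture for parameter-recovery tests;
* a hand-constructed triple of min-transitive 4-patient relations whose
  dendrograms disagree on one subtree, for consensus-combination tests.

A matching clinical-table generator plants group-linked exponential
survival and clinical labels with tunable association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, FuzzyRelation, OmicsView

__all__ = [
    "SyntheticCohort",
    "generate_fig5_cohort",
    "generate_dispersion_cohort",
    "generate_block_cohort",
    "generate_fig4_dendrograms",
    "generate_concordant_relation_triple",
    "generate_clinical",
]


@dataclass
class SyntheticCohort:
    """Views sharing a patient set, the planted partition, optional clinical data."""

    views: list[OmicsView]
    true_partition: dict[str, int]
    clinical: ClinicalTable | None
    seed: int

    @property
    def patient_ids(self) -> list[str]:
        return list(self.views[0].patient_ids)

    @property
    def true_labels(self) -> np.ndarray:
        return np.asarray([self.true_partition[p] for p in self.patient_ids])


def _view_rngs(seed: int, n_views: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_views)]


def generate_dispersion_cohort(
    n_views: int = 3,
    n_per_group: int = 5,
    n_features: int = 100,
    var_a: float = 1.0,
    var_b: float = 0.5,
    seed: int = 0,
) -> SyntheticCohort:
    """Two mean-zero groups that differ only in variance, in every view.

    The first group's rows are Normal(0, var_a) and the second group's rows
    Normal(0, var_b), independently across views and features, so group
    structure is carried by dispersion alone and the groups overlap.
    Defaults give 3 views of 10 patients x 100 features with variances
    1 and 0.5.
    """
    if n_views < 1 or n_per_group < 1 or n_features < 1:
        raise ValueError("sizes must be positive")
    if var_a <= 0 or var_b <= 0:
        raise ValueError("variances must be positive")
    n = 2 * n_per_group
    patients = [f"s{i + 1}" for i in range(n)]
    views = []
    for v, rng in enumerate(_view_rngs(seed, n_views)):
        x = np.empty((n, n_features))
        x[:n_per_group] = rng.normal(0.0, np.sqrt(var_a), (n_per_group, n_features))
        x[n_per_group:] = rng.normal(0.0, np.sqrt(var_b), (n_per_group, n_features))
        views.append(
            OmicsView(f"view{v + 1}", patients, [f"f{j + 1}" for j in range(n_features)], x)
        )
    partition = {p: int(i >= n_per_group) for i, p in enumerate(patients)}
    return SyntheticCohort(views, partition, None, seed)


#: alias used throughout the tests: the two-variance dispersion design
generate_fig5_cohort = generate_dispersion_cohort


def generate_block_cohort(
    n_views: int = 3,
    groups: tuple[int, ...] = (10, 10, 10),
    between_shift: float = 2.0,
    noise_sd: float = 1.0,
    n_features: int = 50,
    seed: int = 0,
) -> SyntheticCohort:
    """Mean-shifted groups: group g has mean ``g * between_shift`` on every feature.

    With ``between_shift = 0`` the cohort carries no structure (null);
    increasing the shift makes the planted partition progressively easier
    to recover, which supports monotonicity and k-recovery tests.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = sum(groups)
    patients = [f"s{i + 1}" for i in range(n)]
    membership = np.repeat(np.arange(len(groups)), groups)
    views = []
    for v, rng in enumerate(_view_rngs(seed, n_views)):
        x = rng.normal(0.0, noise_sd, (n, n_features))
        x += (membership * between_shift)[:, None]
        views.append(
            OmicsView(f"view{v + 1}", patients, [f"f{j + 1}" for j in range(n_features)], x)
        )
    partition = {p: int(g) for p, g in zip(patients, membership)}
    return SyntheticCohort(views, partition, None, seed)


def _ultrametric_relation(
    patients: list[str], levels: list[tuple[float, list[list[str]]]]
) -> FuzzyRelation:
    """Relation from nested partitions: pair similarity = level of first co-membership.

    ``levels`` lists (similarity, partition-as-blocks) from finest to
    coarsest; the coarsest must be the single all-patient block.  The
    result is min-transitive by construction (its alpha-cuts are nested
    equivalence relations).
    """
    idx = {p: i for i, p in enumerate(patients)}
    n = len(patients)
    values = np.eye(n)
    seen = np.eye(n, dtype=bool)
    for sim, blocks in levels:
        for block in blocks:
            for a in block:
                for b in block:
                    i, j = idx[a], idx[b]
                    if not seen[i, j]:
                        values[i, j] = sim
                        seen[i, j] = True
    if not seen.all():
        raise ValueError("levels do not cover all patient pairs")
    return FuzzyRelation(patients, values)


def generate_concordant_relation_triple() -> list[FuzzyRelation]:
    """Three closed 4-patient relations; (s1,s2,s3) is a subtree in two of three.

    The first two hierarchies nest (s1,s2,s3) below the full set at
    different levels; the third instead pairs (s3,s4) against (s1,s2).
    Combining the triple should retain the majority subtree (s1,s2,s3)
    nested inside (s1,s2,s3,s4).
    """
    p = ["s1", "s2", "s3", "s4"]
    r1 = _ultrametric_relation(
        p,
        [
            (0.9, [["s1", "s2"]]),
            (0.7, [["s1", "s2", "s3"]]),
            (0.4, [p]),
        ],
    )
    r2 = _ultrametric_relation(
        p,
        [
            (0.8, [["s2", "s3"]]),
            (0.6, [["s1", "s2", "s3"]]),
            (0.3, [p]),
        ],
    )
    r3 = _ultrametric_relation(
        p,
        [
            (0.85, [["s3", "s4"]]),
            (0.75, [["s1", "s2"]]),
            (0.5, [p]),
        ],
    )
    return [r1, r2, r3]


#: alias: the worked consensus-combination example over four patients
generate_fig4_dendrograms = generate_concordant_relation_triple


def generate_clinical(
    partition: dict[str, int],
    hazard_ratios: dict[int, float] | None = None,
    censor_rate: float = 0.2,
    label_assoc: float = 0.0,
    seed: int = 0,
    baseline_scale_days: float = 730.0,
) -> ClinicalTable:
    """Clinical table with group-linked exponential survival and labels.

    Survival in group g is exponential with rate ``hr_g / baseline_scale``;
    censoring times are independent exponentials with the rate chosen so
    the expected censoring fraction equals ``censor_rate`` exactly in every
    group.  One discrete label copies the group with probability
    ``label_assoc`` (otherwise uniform over categories) and one numeric
    label shifts its mean by ``label_assoc`` per group index.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    patients = list(partition)
    groups = np.asarray([partition[p] for p in patients])
    uniq = np.unique(groups)
    if hazard_ratios is None:
        hazard_ratios = {int(g): 1.0 for g in uniq}
    if any(hazard_ratios[int(g)] <= 0 for g in uniq):
        raise ValueError("hazard ratios must be positive")

    rng = np.random.default_rng(seed)
    rate = np.asarray([hazard_ratios[int(g)] for g in groups]) / baseline_scale_days
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        # for exponentials, P(C < T) = rc / (rc + rt)
        rate_c = rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / rate_c)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    categories = np.array([f"cat{g}" for g in uniq])
    copy_group = rng.random(len(patients)) < label_assoc
    random_cat = rng.choice(categories, size=len(patients))
    discrete = np.where(
        copy_group, np.array([f"cat{g}" for g in groups]), random_cat
    )
    numeric = label_assoc * groups + rng.normal(0.0, 1.0, len(patients))

    return ClinicalTable(
        patient_ids=patients,
        survival_time=time,
        event=event,
        discrete_labels=pd.DataFrame({"group_label": discrete}, index=patients),
        numeric_labels=pd.DataFrame({"group_score": numeric}, index=patients),
    )
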