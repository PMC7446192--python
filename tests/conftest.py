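"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use a different computational route than the
library: the transitive closure is iterated max-min matrix powers until a
fixed point, the ultrametric check is a direct triple loop, and the logrank
statistic is the textbook observed-minus-expected accumulation.
"""

import numpy as np
import pytest

from fhclust.datatypes import FuzzyRelation


def maxmin_power_closure(values: np.ndarray) -> np.ndarray:
    """Brute-force min-transitive closure: fixpoint of R <- max(R, R o R)."""
    r = values.copy()
    while True:
        comp = np.minimum(r[:, :, None], r[None, :, :]).max(axis=1)
        nxt = np.maximum(r, comp)
        if np.array_equal(nxt, r):
            return r
        r = nxt


def is_ultrametric_triple_loop(d: np.ndarray, tol: float = 1e-12) -> bool:
    """Direct all-triples check of D(x,z) <= max(D(x,y), D(y,z)) + tol."""
    n = d.shape[0]
    for x in range(n):
        for y in range(n):
            for z in range(n):
                if d[x, z] > max(d[x, y], d[y, z]) + tol:
                    return False
    return True


def random_relation(
    rng: np.random.Generator, n: int, levels: np.ndarray | None = None
) -> FuzzyRelation:
    """Random reflexive symmetric relation; entries from ``levels`` if given."""
    if levels is None:
        upper = rng.random(n * (n - 1) // 2)
    else:
        upper = rng.choice(levels, size=n * (n - 1) // 2)
    v = np.eye(n)
    iu = np.triu_indices(n, k=1)
    v[iu] = upper
    v = np.maximum(v, v.T)
    np.fill_diagonal(v, 1.0)
    return FuzzyRelation([f"p{i}" for i in range(n)], v)


def logrank_oracle(time, event, group):
    """Textbook k-group logrank: sum over event times of O - E with
    hypergeometric variance, statistic = (O-E)' V^-1 (O-E) on k-1 groups."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    groups = np.unique(group)
    k = len(groups)
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        n_g = np.array([(at_risk & (group == g)).sum() for g in groups])
        d_g = np.array([((time == t) & (event == 1) & (group == g)).sum() for g in groups])
        e_g = d_t * n_g / n_t
        o_minus_e += d_g - e_g
        if n_t > 1:
            for a in range(k):
                for b in range(k):
                    same = 1.0 if a == b else 0.0
                    var[a, b] += (
                        d_t * (n_t - d_t) / (n_t - 1)
                        * (n_g[a] / n_t) * (same - n_g[b] / n_t)
                    )
    u = o_minus_e[:-1]
    v = var[:-1, :-1]
    return float(u @ np.linalg.solve(v, u))


@pytest.fixture
def rng():
    return np.random.default_rng(20201)
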