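"""Min-transitive closure, ultrametric conversion, dendrogram correspondence."""

import numpy as np
import pytest

from fhclust import (
    FuzzyRelation,
    build_dendrogram,
    cut_dendrogram,
    is_min_transitive,
    maxmin_compose,
    min_transitive_closure,
    to_dissimilarity,
)
from fhclust.datatypes import UltrametricDissimilarity, _ultrametric_defect

from tests.conftest import (
    is_ultrametric_triple_loop,
    maxmin_power_closure,
    random_relation,
)

R3 = np.array([[1, 0.8, 0.4], [0.8, 1, 0.5], [0.4, 0.5, 1]])
R3_CLOSED = np.array([[1, 0.8, 0.5], [0.8, 1, 0.5], [0.5, 0.5, 1]])


def _rel(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"p{i}" for i in range(values.shape[0])]
    return FuzzyRelation(ids, values)


class TestMaxminCompose:
    def test_identity_relation_is_neutral_for_reflexive_input(self):
        r = _rel(R3)
        ident = _rel(np.eye(3))
        assert np.array_equal(maxmin_compose(r, ident).values, r.values)

    def test_all_ones_is_a_fixed_point(self):
        ones = _rel(np.ones((4, 4)))
        assert np.array_equal(maxmin_compose(ones, ones).values, np.ones((4, 4)))

    def test_worked_square(self):
        out = maxmin_compose(_rel(R3), _rel(R3))
        # (1,3): max(min(1,.4), min(.8,.5), min(.4,1)) = 0.5
        assert out.values[0, 2] == 0.5

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            maxmin_compose(_rel(R3), _rel(R3, ids=["x", "y", "z"]))


class TestClosure:
    def test_worked_example(self):
        closed = min_transitive_closure(_rel(R3))
        assert np.array_equal(closed.values, R3_CLOSED)

    def test_fixed_point_on_transitive_input(self):
        closed = _rel(R3_CLOSED)
        assert np.array_equal(min_transitive_closure(closed).values, R3_CLOSED)

    def test_crisp_equivalence_unchanged(self):
        block = np.kron(np.eye(2), np.ones((2, 2)))
        assert np.array_equal(min_transitive_closure(_rel(block)).values, block)

    def test_matches_power_oracle_on_random_relations(self, rng):
        """Closure equals the brute-force limit of max-min matrix powers."""
        levels = np.linspace(0, 1, 11)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            r = random_relation(rng, n, levels)
            assert np.array_equal(
                min_transitive_closure(r).values, maxmin_power_closure(r.values)
            )

    def test_idempotent_monotone_no_new_values(self, rng):
        levels = np.linspace(0, 1, 11)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            r = random_relation(rng, n, levels)
            c = min_transitive_closure(r)
            # idempotence
            assert np.array_equal(min_transitive_closure(c).values, c.values)
            # dominates the input, introduces no values absent from it
            assert np.all(c.values >= r.values)
            assert set(np.unique(c.values)) <= set(np.unique(r.values))
            # monotone: raising entries never lowers the closure
            bigger = np.minimum(r.values + rng.choice([0.0, 0.1], r.values.shape), 1.0)
            bigger = np.maximum(bigger, bigger.T)
            np.fill_diagonal(bigger, 1.0)
            c2 = min_transitive_closure(_rel(bigger))
            assert np.all(c2.values >= c.values - 1e-15)


class TestIsMinTransitive:
    def test_closure_output_is_transitive(self, rng):
        r = random_relation(rng, 7)
        assert is_min_transitive(min_transitive_closure(r))

    def test_worked_violation(self):
        assert not is_min_transitive(_rel(R3))

    def test_identity_is_transitive(self):
        assert is_min_transitive(_rel(np.eye(5)))


class TestLemmaCorrespondence:
    def test_dissimilarity_of_closed_relation(self):
        d = to_dissimilarity(_rel(R3_CLOSED))
        assert np.array_equal(d.values, 1.0 - R3_CLOSED + np.diag(np.zeros(3)))

    def test_similarity_one_maps_to_zero(self):
        d = to_dissimilarity(_rel(np.ones((3, 3))))
        assert np.all(d.values == 0)

    def test_non_transitive_input_rejected_with_triple(self):
        with pytest.raises(ValueError, match="not min-transitive"):
            to_dissimilarity(_rel(R3))

    def test_equivalence_both_directions(self, rng):
        """D = 1 - R is ultrametric exactly when R is min-transitive."""
        levels = np.linspace(0, 1, 11)
        n_perturbed_nontransitive = 0
        n_perturbed_failing_ultra = 0
        for _ in range(100):
            n = int(rng.integers(3, 9))
            r = min_transitive_closure(random_relation(rng, n, levels))
            d = 1.0 - r.values
            np.fill_diagonal(d, 0.0)
            assert is_ultrametric_triple_loop(d)
            # perturb one off-diagonal pair downward to (usually) break transitivity
            i, j = sorted(rng.choice(n, 2, replace=False))
            pert = r.values.copy()
            pert[i, j] = pert[j, i] = max(0.0, pert[i, j] - 0.35)
            pr = _rel(pert)
            dp = 1.0 - pert
            np.fill_diagonal(dp, 0.0)
            trans = is_min_transitive(pr)
            ultra = is_ultrametric_triple_loop(dp)
            assert trans == ultra
            if not trans:
                n_perturbed_nontransitive += 1
                n_perturbed_failing_ultra += int(not ultra)
        assert n_perturbed_nontransitive > 0
        assert n_perturbed_failing_ultra == n_perturbed_nontransitive


class TestDendrogram:
    def test_three_point_merge_structure(self):
        d = UltrametricDissimilarity(
            ["s1", "s2", "s3"],
            np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]),
        )
        dend = build_dendrogram(d)
        assert list(dend.heights) == [0.2, 0.5]
        assert frozenset({"s1", "s2"}) in dend.subtrees()

    def test_all_zero_dissimilarity_merges_at_zero(self):
        dend = build_dendrogram(UltrametricDissimilarity(list("abc"), np.zeros((3, 3))))
        assert np.all(dend.heights == 0)

    def test_crisp_two_blocks(self):
        d = 1.0 - np.kron(np.eye(2), np.ones((2, 2)))
        dend = build_dendrogram(UltrametricDissimilarity(list("abcd"), d))
        assert dend.heights[-1] == 1.0
        assert {frozenset("ab"), frozenset("cd")} <= dend.subtrees()

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            UltrametricDissimilarity(
                list("abc"), np.array([[0, 0.1, 0.9], [0.1, 0, 0.1], [0.9, 0.1, 0]])
            )

    def test_cophenetic_round_trip(self, rng):
        """Cophenetic distances of the dendrogram reproduce 1 - C exactly."""
        for _ in range(25):
            n = int(rng.integers(3, 31))
            c = min_transitive_closure(random_relation(rng, n))
            dend = build_dendrogram(to_dissimilarity(c))
            expect = 1.0 - c.values
            np.fill_diagonal(expect, 0.0)
            assert np.abs(dend.cophenetic_matrix() - expect).max() <= 1e-12


class TestCut:
    @pytest.fixture
    def dend(self):
        d = UltrametricDissimilarity(
            ["s1", "s2", "s3"],
            np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]),
        )
        return build_dendrogram(d)

    def test_k_equals_n_gives_singletons(self, dend):
        assert len(set(cut_dendrogram(dend, 3).values())) == 3

    def test_k_one_gives_single_cluster(self, dend):
        assert len(set(cut_dendrogram(dend, 1).values())) == 1

    def test_two_cluster_cut(self, dend):
        part = cut_dendrogram(dend, 2)
        assert part["s1"] == part["s2"] != part["s3"]

    def test_out_of_range_rejected(self, dend):
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 4)

    def test_tied_heights_warn_and_fall_back(self):
        dend = build_dendrogram(
            UltrametricDissimilarity(list("abc"), np.zeros((3, 3)))
        )
        with pytest.warns(UserWarning, match="tied"):
            part = dend.cut(2)
        assert len(set(part.values())) == 1


class TestExport:
    def test_newick_and_merge_table(self):
        d = UltrametricDissimilarity(
            ["s1", "s2", "s3"],
            np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]),
        )
        dend = build_dendrogram(d)
        nwk = dend.to_newick()
        assert nwk.endswith(";") and "s1:0.2" in nwk
        table = dend.merge_table()
        assert list(table.columns) == ["child_a", "child_b", "height", "size"]
        assert table["height"].tolist() == [0.2, 0.5]

    def test_relation_tsv_round_trip(self, rng, tmp_path):
        r = min_transitive_closure(random_relation(rng, 6))
        path = tmp_path / "rel.tsv"
        r.write_tsv(path)
        back = FuzzyRelation.read_tsv(path)
        assert back.patient_ids == r.patient_ids
        assert np.array_equal(back.values, r.values)


def test_ultrametric_defect_helper_agrees_with_loop(rng):
    for _ in range(20):
        n = int(rng.integers(3, 8))
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        assert (_ultrametric_defect(d) <= 1e-12) == is_ultrametric_triple_loop(d)
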