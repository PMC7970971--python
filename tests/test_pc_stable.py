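"""Conditional-independence testing and PC-stable structure learning."""

import math

import numpy as np
import pytest

from microcausal import (
    DataError,
    DataTable,
    cpdag_of_dag,
    dsep_oracle,
    gaussian_ci_test,
    learn_cpdag,
    learn_skeleton,
    orient_v_structures,
    partial_correlation,
    random_dag,
)
from conftest import make_chain_data, make_collider_data
from oracle_utils import all_dags


class TestDataTable:
    def test_rejects_missing_values(self):
        with pytest.raises(DataError, match="non-finite"):
            DataTable(np.array([[1.0, np.nan], [2.0, 3.0]]), ["a", "b"])

    def test_rejects_duplicate_names(self):
        with pytest.raises(DataError, match="duplicate"):
            DataTable(np.ones((3, 2)), ["a", "a"])

    def test_constant_column_flagged(self):
        t = DataTable(np.column_stack([np.arange(4.0), np.ones(4)]), ["a", "b"])
        assert t.constant_columns() == ["b"]


class TestPartialCorrelation:
    def test_empty_set_equals_pearson(self, rng):
        x = rng.standard_normal((500, 2))
        t = DataTable(x, ["a", "b"])
        expected = np.corrcoef(x, rowvar=False)[0, 1]
        assert partial_correlation(t, "a", "b") == pytest.approx(expected)

    def test_deterministic_copy_gives_one(self, rng):
        x = rng.standard_normal(300)
        t = DataTable(np.column_stack([x, x.copy()]), ["a", "b"])
        assert partial_correlation(t, "a", "b") == pytest.approx(1.0, abs=1e-9)

    def test_matches_first_order_recursion(self, rng):
        """|S| = 2 result equals recursive application of the first-order
        partial-correlation formula r_xy.z = (r_xy - r_xz r_yz)/sqrt(...)."""
        x = rng.standard_normal((400, 5))
        x[:, 1] += 0.5 * x[:, 0]
        x[:, 2] += 0.7 * x[:, 1]
        x[:, 3] += 0.4 * x[:, 0] - 0.3 * x[:, 2]
        names = list("abcde")
        t = DataTable(x, names)

        def rec(i, j, s):
            if not s:
                return np.corrcoef(x[:, names.index(i)], x[:, names.index(j)])[0, 1]
            k, rest = s[0], s[1:]
            rij = rec(i, j, rest)
            rik = rec(i, k, rest)
            rjk = rec(j, k, rest)
            return (rij - rik * rjk) / math.sqrt((1 - rik**2) * (1 - rjk**2))

        got = partial_correlation(t, "a", "c", {"b", "d"})
        assert got == pytest.approx(rec("a", "c", ("b", "d")), abs=1e-10)

    def test_zero_variance_variable_named(self):
        t = DataTable(np.column_stack([np.arange(5.0), np.ones(5)]), ["a", "flat"])
        with pytest.raises(DataError, match="flat"):
            partial_correlation(t, "a", "flat")


class TestGaussianCITest:
    def test_closed_form_fisher_z(self, rng):
        """r = 0.5 at n = 103, |S| = 0: z = 10 atanh(0.5) ~ 5.493."""
        # construct data with exact sample correlation 0.5 via two orthogonalized columns
        n = 103
        u = rng.standard_normal(n)
        v = rng.standard_normal(n)
        u = (u - u.mean()) / u.std()
        v = v - u * (u @ v) / (u @ u)
        v = (v - v.mean()) / v.std()
        b = 0.5 * u + math.sqrt(1 - 0.25) * v
        t = DataTable(np.column_stack([u, b]), ["x", "y"])
        res = gaussian_ci_test(t, "x", "y", alpha=0.05)
        assert res.statistic == pytest.approx(10 * math.atanh(0.5), abs=1e-6)
        assert res.p_value == pytest.approx(3.95e-8, rel=0.01)
        assert not res.independent

    def test_p_value_grows_as_n_shrinks(self, rng):
        x = rng.standard_normal((400, 2))
        x[:, 1] += 0.2 * x[:, 0]
        big = DataTable(x, ["a", "b"])
        small = DataTable(x[:100], ["a", "b"])
        r_big = partial_correlation(big, "a", "b")
        # same r, smaller n -> strictly larger p
        from microcausal.pc_stable import _fisher_z

        assert _fisher_z(r_big, 100, 0, 0.05).p_value > _fisher_z(r_big, 400, 0, 0.05).p_value

    def test_perfect_correlation_saturates(self, rng):
        x = rng.standard_normal(200)
        t = DataTable(np.column_stack([x, 2 * x]), ["a", "b"])
        res = gaussian_ci_test(t, "a", "b")
        assert res.p_value == pytest.approx(0.0, abs=1e-12)
        assert not res.independent


class TestLearnSkeleton:
    def test_rejects_bad_alpha(self, rng):
        t = DataTable(rng.standard_normal((50, 3)), list("abc"))
        with pytest.raises(DataError, match="alpha"):
            learn_skeleton(t, alpha=1.5)

    def test_independent_columns_disconnected(self, rng):
        t = DataTable(rng.standard_normal((2000, 2)), ["a", "b"])
        skel, seps = learn_skeleton(t, 0.05)
        assert skel.n_edges() == 0
        assert seps[frozenset(("a", "b"))] == frozenset()

    def test_chain_skeleton_and_sepset(self):
        t = make_chain_data()
        skel, seps = learn_skeleton(t, 0.05)
        assert set(skel.undirected_edges) == {
            frozenset(("X", "Y")),
            frozenset(("Y", "Z")),
        }
        assert seps[frozenset(("X", "Z"))] == {"Y"}

    def test_order_independence_under_column_permutation(self, rng):
        for _ in range(5):
            model = random_dag(7, 9, rng=rng)
            data = mc_sample(model, 400, rng)
            skel, seps = learn_skeleton(data, 0.05)
            perm = rng.permutation(data.n_variables)
            shuffled = DataTable(
                data.values[:, perm],
                [data.variable_names[k] for k in perm],
                data.sample_ids,
            )
            skel2, seps2 = learn_skeleton(shuffled, 0.05)
            assert set(skel.undirected_edges) == set(skel2.undirected_edges)
            assert seps == seps2


def mc_sample(model, m, rng):
    from microcausal import sample_from_dag

    return sample_from_dag(model, m, rng=rng)


class TestOrientVStructures:
    def test_collider_is_oriented(self):
        t = make_collider_data()
        skel, seps = learn_skeleton(t, 0.05)
        out = orient_v_structures(skel, seps)
        assert out.has_directed_edge("X", "Z")
        assert out.has_directed_edge("Y", "Z")

    def test_chain_triple_left_undirected(self):
        t = make_chain_data()
        skel, seps = learn_skeleton(t, 0.05)
        out = orient_v_structures(skel, seps)
        assert not out.directed_edges

    def test_triangle_has_no_unshielded_triples(self):
        from microcausal import PartiallyDirectedGraph

        tri = PartiallyDirectedGraph(
            list("abc"), [], [("a", "b"), ("b", "c"), ("a", "c")]
        )
        assert orient_v_structures(tri, {}) == tri

    def test_missing_sepset_is_an_error(self):
        from microcausal import PartiallyDirectedGraph

        path = PartiallyDirectedGraph(list("abc"), [], [("a", "b"), ("b", "c")])
        with pytest.raises(Exception, match="separating set"):
            orient_v_structures(path, {})


class TestLearnCpdag:
    def test_collider_with_positive_signs(self):
        t = make_collider_data()
        g = learn_cpdag(t, 0.05)
        assert g.directed_edges == frozenset({("X", "Z"), ("Y", "Z")})
        assert all(a.sign == 1 for a in g.annotations.values())

    def test_independent_columns_empty_graph(self, rng):
        t = DataTable(rng.standard_normal((2000, 4)), list("abcd"))
        g = learn_cpdag(t, 0.05)
        assert g.n_edges() == 0

    def test_constant_column_dropped(self, rng):
        vals = np.column_stack([rng.standard_normal(100), np.full(100, 3.0)])
        g = learn_cpdag(DataTable(vals, ["a", "flat"]), 0.05)
        assert g.nodes == ("a",)

    def test_oracle_soundness_all_dags_up_to_4_nodes(self):
        """With a d-separation oracle the learned graph equals the true
        CPDAG for every labeled DAG on <= 4 nodes."""
        for n in (2, 3, 4):
            for dag in all_dags(n):
                got = learn_cpdag(
                    None, ci_test=dsep_oracle(dag), nodes=dag.nodes, annotate=False
                )
                assert got == cpdag_of_dag(dag), f"failed on {sorted(dag.directed_edges)}"
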