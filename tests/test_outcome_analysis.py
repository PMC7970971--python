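"""Context embedding, effects on the outcome node, and Y-structures."""

import numpy as np
import pytest

from microcausal import (
    DataError,
    DataTable,
    PartiallyDirectedGraph,
    effect_pvalue_bootstrap,
    effects_on_outcome,
    embed_context,
    find_y_structures,
    learn_cpdag,
    random_dag,
    y_leg_edges,
)
from microcausal.outcome_analysis import ContextTable
from oracle_utils import brute_force_y_structures


def cohort(rng, n, shift=0.0, names=("t1", "t2", "t3"), prefix="s"):
    vals = rng.standard_normal((n, len(names))) + shift
    return DataTable(vals, list(names), [f"{prefix}{k}" for k in range(n)])


class TestEmbedContext:
    def test_row_counts_and_outcome_column(self, rng):
        uc = cohort(rng, 459, prefix="uc")
        healthy = cohort(rng, 429, prefix="h")
        ctx = embed_context([(uc, 1), (healthy, 0)])
        assert ctx.data.n_samples == 888
        assert ctx.outcome == "disease"
        assert ctx.data.column("disease").sum() == 459

    def test_single_cohort_constant_outcome_dropped_at_learning(self, rng):
        ctx = embed_context([(cohort(rng, 120), 0)])
        g = learn_cpdag(ctx.data, 0.05)
        assert "disease" not in g.nodes

    def test_ordinal_outcomes_accepted(self, rng):
        cohorts = [
            (cohort(rng, 30, prefix=p), v)
            for p, v in (("a", 0), ("b", 1), ("c", 2))
        ]
        ctx = embed_context(cohorts)
        assert set(np.unique(ctx.data.column("disease"))) == {0.0, 1.0, 2.0}

    def test_duplicate_sample_ids_rejected(self, rng):
        a = cohort(rng, 10, prefix="x")
        b = cohort(rng, 10, prefix="x")
        with pytest.raises(DataError, match="duplicated sample ids"):
            embed_context([(a, 1), (b, 0)])

    def test_empty_cohort_list_rejected(self):
        with pytest.raises(DataError, match="no cohorts"):
            embed_context([])

    def test_variable_intersection_taken(self, rng):
        a = cohort(rng, 20, names=("t1", "t2", "t3"), prefix="a")
        b = cohort(rng, 20, names=("t2", "t3", "t4"), prefix="b")
        ctx = embed_context([(a, 1), (b, 0)])
        assert ctx.taxa == ["t2", "t3"]

    def test_cohort_means_preserved(self, rng):
        a = cohort(rng, 50, shift=2.0, prefix="a")
        b = cohort(rng, 30, shift=-1.0, prefix="b")
        ctx = embed_context([(a, 1), (b, 0)])
        merged = ctx.data
        assert merged.values[:50, 0].mean() == pytest.approx(a.values[:, 0].mean())
        assert merged.values[50:, 1].mean() == pytest.approx(b.values[:, 1].mean())

    def test_binary_outcome_must_be_01(self, rng):
        t = cohort(rng, 20)
        vals = np.column_stack([t.values, np.repeat([1.0, 2.0], 10)])
        with pytest.raises(DataError, match="0, 1"):
            ContextTable(DataTable(vals, ["t1", "t2", "t3", "y"]), "y")


class TestEffectsOnOutcome:
    def test_planted_signal_ranks_first(self):
        """Two taxa feed the outcome (an identifiable collider); the
        stronger one tops the ranked table at its true coefficient."""
        rng = np.random.default_rng(5)
        n = 1500
        t1 = rng.standard_normal(n)
        t2 = rng.standard_normal(n)
        t3 = rng.standard_normal(n)
        outcome = 1.2 * t1 - 0.8 * t2 + rng.standard_normal(n)
        data = DataTable(
            np.column_stack([t1, t2, t3, outcome]), ["t1", "t2", "t3", "disease"]
        )
        ctx = ContextTable(data, "disease")
        g = learn_cpdag(data, 0.05)
        ranked = effects_on_outcome(g, ctx)
        assert ranked.iloc[0]["cause"] == "t1"
        assert ranked.iloc[0]["effect_on_outcome"] == pytest.approx(1.2, abs=0.1)
        assert ranked.iloc[1]["cause"] == "t2"
        assert ranked.iloc[1]["effect_on_outcome"] == pytest.approx(-0.8, abs=0.1)
        assert abs(ranked.iloc[2]["effect_on_outcome"]) < 0.1

    def test_isolated_outcome_all_zero(self, rng):
        data = cohort(rng, 300)
        ctx = embed_context([(data, 0), (cohort(rng, 300, prefix="b"), 1)])
        g = PartiallyDirectedGraph(ctx.data.variable_names)  # no edges at all
        ranked = effects_on_outcome(g, ctx)
        assert (ranked["effect_on_outcome"] == 0).all()

    def test_outcome_missing_from_graph_raises(self, rng):
        ctx = embed_context([(cohort(rng, 50), 0), (cohort(rng, 50, prefix="b"), 1)])
        g = PartiallyDirectedGraph(ctx.taxa)
        with pytest.raises(Exception, match="disease"):
            effects_on_outcome(g, ctx)


class TestEffectPvalueBootstrap:
    def test_planted_strong_effect_small_p(self):
        """Two independent causes make the collider at the outcome
        identifiable, so the planted effect keeps its sign across
        replicates and earns a small p."""
        rng = np.random.default_rng(9)
        n = 1000
        ts = rng.standard_normal((4, n))
        y = 1.5 * ts[0] - 1.0 * ts[1] + 1.2 * ts[2] + 0.9 * ts[3]
        y = y + rng.standard_normal(n)
        names = ["t1", "t2", "t3", "t4", "disease"]
        ctx = ContextTable(
            DataTable(np.column_stack([*ts, y]), names), "disease"
        )
        res = effect_pvalue_bootstrap(ctx, "t1", B=100, alpha=0.01, seed=3)
        assert res.p_value <= 0.05
        assert res.effects.shape == (100,)
        assert np.median(res.effects) == pytest.approx(1.5, abs=0.15)

    def test_independent_cause_large_p(self):
        rng = np.random.default_rng(10)
        n = 600
        ctx = ContextTable(
            DataTable(rng.standard_normal((n, 3)), ["t1", "t2", "disease"]),
            "disease",
        )
        res = effect_pvalue_bootstrap(ctx, "t1", B=40, seed=4)
        # with no causal path most replicates report effect exactly 0,
        # landing in both sign counts -> p clipped to 1
        assert res.p_value > 0.2

    def test_missing_cause_rejected(self, rng):
        ctx = ContextTable(
            DataTable(rng.standard_normal((50, 2)), ["t1", "disease"]), "disease"
        )
        with pytest.raises(DataError, match="ghost"):
            effect_pvalue_bootstrap(ctx, "ghost", B=5)


class TestYStructures:
    def fig_y_graph(self):
        """X -> Z <- Y with leg Z -> W, no other adjacencies."""
        return PartiallyDirectedGraph(
            ["X", "Y", "Z", "W"], [("X", "Z"), ("Y", "Z"), ("Z", "W")]
        )

    def test_canonical_y_structure_found(self):
        ys = find_y_structures(self.fig_y_graph())
        assert len(ys) == 1
        s = ys[0]
        assert s.parents == ("X", "Y") and s.center == "Z" and s.leg_target == "W"
        assert y_leg_edges(ys) == {("Z", "W")}

    def test_three_node_graphs_have_none(self, rng):
        for _ in range(5):
            g = random_dag(3, rng.integers(0, 4), rng=rng).graph
            assert find_y_structures(g) == []

    def test_shielded_variants_excluded(self):
        g = PartiallyDirectedGraph(
            ["X", "Y", "Z", "W"],
            [("X", "Z"), ("Y", "Z"), ("Z", "W"), ("X", "W")],
        )
        assert find_y_structures(g) == []

    def test_undirected_adjacency_blocks_leg(self):
        g = PartiallyDirectedGraph(
            ["X", "Y", "Z", "W"],
            [("X", "Z"), ("Y", "Z"), ("Z", "W")],
            [("Y", "W")],
        )
        assert find_y_structures(g) == []

    def test_matches_brute_force_on_random_dags(self, rng):
        for _ in range(50):
            g = random_dag(10, int(rng.integers(8, 20)), rng=rng).graph
            got = {(frozenset(s.parents), s.center, s.leg_target)
                   for s in find_y_structures(g)}
            expected = {
                (frozenset((x, y)), z, w)
                for x, y, z, w in brute_force_y_structures(g)
            }
            assert got == expected

    def test_invariant_under_relabeling(self, rng):
        g = random_dag(8, 12, rng=rng).graph
        mapping = {v: f"taxon_{k}" for k, v in enumerate(reversed(g.nodes))}
        relabeled = PartiallyDirectedGraph(
            [mapping[v] for v in g.nodes],
            [(mapping[a], mapping[b]) for a, b in g.directed_edges],
        )
        ys1 = {
            (frozenset(s.parents), s.center, s.leg_target)
            for s in find_y_structures(g)
        }
        ys2 = {
            (frozenset(s.parents), s.center, s.leg_target)
            for s in find_y_structures(relabeled)
        }
        mapped = {
            (frozenset(mapping[p] for p in ps), mapping[c], mapping[w])
            for ps, c, w in ys1
        }
        assert mapped == ys2
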