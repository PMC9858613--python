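import numpy as np
import pytest

from cimap.builder import (
    Skeleton,
    SkeletonEdge,
    build_cimap,
    components,
    learn_skeleton,
    orient_and_acyclify,
    orientation_score,
)
from cimap.cohort import Cohort, VariableDictionary, VariableSpec
from cimap.network import CPT, GroundTruthNetwork, simulate_cohort

from conftest import chain_network, make_binary_cohort
from oracles import tv_distance_oracle


def _independent_network(k=10, p=0.3):
    specs = [VariableSpec(f"v{i:02d}", "binary", ("0", "1")) for i in range(k)]
    cpts = {
        s.name: CPT(s.name, (), np.array([1 - p, p])) for s in specs
    }
    return GroundTruthNetwork(VariableDictionary(specs), cpts)


class TestSkeleton:
    def test_chain_recovered_exactly(self):
        """x->z->y: the skeleton is {x-z, z-y} with x-y pruned by conditioning.

        The true edges must survive in every seed; the spurious x-y edge
        is retained only when its conditional test falsely rejects, which
        happens with probability alpha, so exact recovery is checked
        against alpha plus 3 binomial sigma rather than a hard 95% floor.
        """
        net = chain_network(flip=0.1)
        exact = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort = simulate_cohort(net, 5_000, seed)
            sk = learn_skeleton(cohort, alpha=0.05, max_cond=1)
            got = set(sk.edges)
            assert {("x", "z"), ("y", "z")} <= got
            assert got <= {("x", "z"), ("y", "z"), ("x", "y")}
            if got == {("x", "z"), ("y", "z")}:
                exact += 1
        assert exact / n_seeds >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_null_skeleton_empty_with_bonferroni(self):
        net = _independent_network()
        empty = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort = simulate_cohort(net, 2_000, seed)
            sk = learn_skeleton(cohort, alpha=0.05, max_cond=2,
                                correction="bonferroni")
            if not sk.edges:
                empty += 1
        assert empty >= 0.95 * n_seeds

    def test_order_invariance(self, paper_net):
        cohort = simulate_cohort(paper_net, 2_000, 3)
        reversed_names = list(reversed(cohort.dictionary.names))
        shuffled = Cohort(
            cohort.data[reversed_names],
            cohort.dictionary.subset(reversed_names),
        )
        a = learn_skeleton(cohort, correction="bonferroni")
        b = learn_skeleton(shuffled, correction="bonferroni")
        assert set(a.edges) == set(b.edges)

    def test_max_cond_clamped_with_warning(self):
        cohort = make_binary_cohort({"a": [0, 1] * 20, "b": [0, 1] * 20})
        with pytest.warns(UserWarning, match="clamped"):
            learn_skeleton(cohort, max_cond=5)

    def test_retained_edges_have_higher_mi_than_pruned_at_equal_df(self, paper_net):
        """At the marginal screen, retention is monotone in MI for fixed df/N."""
        cohort = simulate_cohort(paper_net, 2_000, 5)
        binary = [n for n in cohort.dictionary.names
                  if cohort.dictionary[n].n_levels == 2]
        sub = Cohort(cohort.data[binary], cohort.dictionary.subset(binary))
        sk = learn_skeleton(sub, alpha=0.05, max_cond=0, correction="bonferroni")
        retained_mi = [rec.mi for rec in sk.edges.values()]
        from cimap.association import crosstab, mutual_information

        pruned = [
            mutual_information(crosstab(sub, *pair))
            for pair, s in sk.sepsets.items()
            if s == ()
        ]
        if retained_mi and pruned:
            assert min(retained_mi) > max(pruned)


class TestOrientation:
    def test_deterministic_copy_is_a_tie(self):
        rng = np.random.default_rng(0)
        x = (rng.random(5000) < 0.3).astype(int)
        cohort = make_binary_cohort({"x": x, "y": x})
        fwd, rev = orientation_score(cohort, "x", "y")
        assert fwd == pytest.approx(1.0, abs=1e-12)
        assert rev == pytest.approx(1.0, abs=1e-12)

    def test_strong_forward_mechanism_scores(self):
        """P(y=1|x) = 0.1/0.9 gives forward TV 0.8; reverse from Bayes."""
        rng = np.random.default_rng(1)
        n = 20_000
        px = 0.3
        x = (rng.random(n) < px).astype(int)
        y = (rng.random(n) < np.where(x == 1, 0.9, 0.1)).astype(int)
        cohort = make_binary_cohort({"x": x, "y": y})
        fwd, rev = orientation_score(cohort, "x", "y")
        assert fwd == pytest.approx(0.8, abs=0.02)
        # closed-form reversal of the same joint
        py1 = 0.1 * (1 - px) + 0.9 * px
        px1_y1 = 0.9 * px / py1
        px1_y0 = 0.1 * px / (1 - py1)
        expected_rev = tv_distance_oracle(
            [1 - px1_y1, px1_y1], [1 - px1_y0, px1_y0]
        )
        assert rev == pytest.approx(expected_rev, abs=0.02)
        assert fwd > rev

    def test_independent_variables_score_near_zero(self):
        rng = np.random.default_rng(2)
        cohort = make_binary_cohort(
            {"x": rng.integers(0, 2, 50_000), "y": rng.integers(0, 2, 50_000)}
        )
        fwd, rev = orientation_score(cohort, "x", "y")
        assert fwd < 0.05 and rev < 0.05


class TestOrientAndAcyclify:
    @staticmethod
    def _skeleton(edge_mis):
        variables = sorted({v for pair in edge_mis for v in pair})
        edges = {
            tuple(sorted(pair)): SkeletonEdge(mi=mi, p_marginal=1e-6, p_max=1e-6)
            for pair, mi in edge_mis.items()
        }
        return Skeleton(variables, edges, {}, 0.05, 0.05, 0)

    def test_single_edge(self):
        sk = self._skeleton({("a", "b"): 0.5})
        cm = orient_and_acyclify(sk, {("a", "b"): (0.9, 0.1)})
        assert len(cm.edges) == 1
        assert (cm.edges[0].source, cm.edges[0].target) == ("a", "b")
        assert cm.is_acyclic

    def test_three_cycle_reverses_weakest_edge(self):
        sk = self._skeleton({("a", "b"): 0.5, ("b", "c"): 0.3, ("a", "c"): 0.1})
        scores = {
            ("a", "b"): (0.9, 0.1),  # a -> b
            ("b", "c"): (0.9, 0.1),  # b -> c
            ("a", "c"): (0.1, 0.9),  # prefers c -> a, closing the cycle
        }
        cm = orient_and_acyclify(sk, scores)
        directed = {(e.source, e.target) for e in cm.edges}
        assert ("a", "b") in directed and ("b", "c") in directed
        assert ("a", "c") in directed  # weakest edge reversed
        assert cm.is_acyclic

    def test_tied_scores_use_lexicographic_source(self):
        sk = self._skeleton({("b", "a"): 0.4})
        cm = orient_and_acyclify(sk, {("a", "b"): (0.5, 0.5)})
        assert (cm.edges[0].source, cm.edges[0].target) == ("a", "b")


class TestBuildCIMap:
    def test_recovers_fixture_edges_and_mi(self, paper_net):
        cohort = simulate_cohort(paper_net, 10_000, 1)
        cm = build_cimap(cohort, alpha=0.05, max_cond=2, correction="bonferroni")
        assert cm.is_acyclic
        got = cm.edge_pairs()
        want = {tuple(sorted(e)) for e in paper_net.edges}
        assert got == want
        targets = {
            tuple(sorted((e["source"], e["target"]))): e["target_mi"]
            for e in paper_net.metadata["edges"]
        }
        for e in cm.edges:
            assert e.mi == pytest.approx(targets[e.pair], abs=0.03)
            assert e.orientation_score_forward is not None

    def test_single_variable_cohort_gives_empty_map(self):
        cohort = make_binary_cohort({"x": [0, 1, 0, 1]})
        cm = build_cimap(cohort)
        assert cm.edges == []

    def test_table1_fixture_smoke(self, table1):
        cm = build_cimap(table1, correction="bonferroni")
        assert cm.is_acyclic

    def test_acyclic_on_random_cohorts(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            cols = {}
            base = rng.integers(0, 2, n)
            for i in range(6):
                noise = rng.random(n) < rng.uniform(0.05, 0.5)
                cols[f"w{i}"] = np.where(noise, rng.integers(0, 2, n), base)
            cm = build_cimap(make_binary_cohort(cols), seed=seed)
            assert cm.is_acyclic

    def test_graphml_and_dot_export(self, paper_net, tmp_path):
        import networkx as nx

        cohort = simulate_cohort(paper_net, 2_000, 1)
        cm = build_cimap(cohort, correction="bonferroni")
        gpath = tmp_path / "map.graphml"
        cm.to_graphml(gpath)
        g = nx.read_graphml(gpath)
        assert g.number_of_edges() == len(cm.edges)
        dpath = tmp_path / "map.dot"
        cm.to_dot(dpath)
        assert "digraph" in dpath.read_text()


class TestComponents:
    def test_empty_map_gives_singletons(self):
        from cimap.builder import CIMap

        cm = CIMap(variables=["a", "b", "c"], edges=[], alpha=0.05)
        assert components(cm) == [["a"], ["b"], ["c"]]

    def test_fully_connected_toy_is_one_component(self):
        from cimap.builder import CIMap, Edge

        cm = CIMap(
            variables=["a", "b", "c"],
            edges=[Edge("a", "b", 0.5, 0.001), Edge("b", "c", 0.4, 0.001)],
            alpha=0.05,
        )
        assert components(cm) == [["a", "b", "c"]]

    def test_paper_clusters_separate(self, paper_net):
        cohort = simulate_cohort(paper_net, 10_000, 2)
        cm = build_cimap(cohort, correction="bonferroni")
        comps = components(cm)
        person = {"previous_attendance", "history_dsh", "known_camhs",
                  "low_mood", "anxiety", "asd_traits", "diagnosis_other"}
        household = {"neglect", "domestic_violence", "abuse", "social_worker",
                     "single_parent", "step_parent", "siblings",
                     "sep_loss_parent"}
        parental = {"parental_mental_health", "parent_drug_misuse",
                    "parental_crime"}
        sex_means = {"sex", "means", "risk"}
        as_sets = [set(c) for c in comps]
        for cluster in (person, household, parental, sex_means):
            assert cluster in as_sets
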