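import math

import numpy as np
import pandas as pd
import pytest

from bicnet import (
    Dataset,
    FamilyCandidates,
    Scorer,
    SearchConfig,
    SimulationConfig,
    VariableSpec,
    assemble_exact_dp,
    assemble_greedy,
    enumerate_families,
    hill_climb_baseline,
    learn,
    simulate,
)
from bicnet.exceptions import InvalidArgumentError
from bicnet.scoring import FamilyScore
from bicnet.search import FamilyIndex, _score_child_subsets

from _oracles import all_labeled_dags


def make_dataset(columns):
    frame = pd.DataFrame(columns)
    return Dataset(frame, tuple(VariableSpec(str(c)) for c in frame.columns))


def fs(child, parents, bic):
    return FamilyScore(child, frozenset(parents), bic, bic, 1, 10)


class TestEnumerateFamilies:
    def test_tiny_exhaustive_case(self, gaussian_pair):
        cand = enumerate_families(gaussian_pair, "B", SearchConfig(max_parents=1))
        families = {c.parents for c in cand.ranked}
        assert families == {frozenset(), frozenset({"A"})}

    def test_ranking_is_bic_descending(self, independent_continuous):
        cand = enumerate_families(independent_continuous, "X0", SearchConfig(max_parents=2))
        bics = [c.bic for c in cand.ranked]
        assert bics == sorted(bics, reverse=True)

    def test_chain_markov_separation(self):
        """For A -> B -> C, the top family of C is {B}, not {A}."""
        hits = reps = 0
        for s in range(100):
            rng = np.random.default_rng(5000 + s)
            a = rng.normal(size=1000)
            b = 2 * a + rng.normal(size=1000)
            c = -1.5 * b + rng.normal(size=1000)
            data = make_dataset({"A": a, "B": b, "C": c})
            cand = enumerate_families(data, "C", SearchConfig(max_parents=1))
            reps += 1
            hits += int(cand.ranked[0].parents == frozenset({"B"}))
        assert hits / reps >= 0.9

    def test_discrete_child_excludes_continuous_candidates(self):
        inst = simulate(SimulationConfig(network_kind="mixed", p=8, n=100, seed=3))
        child = inst.data.discrete_names[0]
        cand = enumerate_families(inst.data, child, SearchConfig(max_parents=2))
        continuous = set(inst.data.continuous_names)
        for fam in cand.ranked:
            assert not (fam.parents & continuous)

    def test_staged_enumeration_under_budget(self, rng):
        frame = {f"X{i:02d}": rng.normal(size=120) for i in range(12)}
        data = make_dataset(frame)
        config = SearchConfig(max_parents=4, enumeration_budget=100)
        cand = enumerate_families(data, "X00", config)
        assert any(not f.parents for f in cand.ranked)
        assert all(len(f.parents) <= 4 for f in cand.ranked)

    def test_empty_family_always_present(self, gaussian_pair):
        cand = enumerate_families(gaussian_pair, "B", SearchConfig(candidates_per_node=1))
        assert any(not f.parents for f in cand.ranked)


class TestAssembleGreedy:
    def test_acyclic_candidates_kept_verbatim(self):
        cand = {
            "A": FamilyCandidates("A", (fs("A", (), -5.0),)),
            "B": FamilyCandidates("B", (fs("B", ("A",), -3.0), fs("B", (), -4.0))),
        }
        res = assemble_greedy(cand)
        assert res.dag.edges == frozenset({("A", "B")})
        assert res.repairs == 0
        assert res.score == pytest.approx(-8.0)

    def test_two_node_cycle_keeps_costlier_direction(self):
        """A<->B: the family whose demotion loses more BIC survives."""
        cand = {
            "A": FamilyCandidates("A", (fs("A", ("B",), -10.0), fs("A", (), -12.0))),
            "B": FamilyCandidates("B", (fs("B", ("A",), -5.0), fs("B", (), -9.0))),
        }
        res = assemble_greedy(cand)
        # demoting A costs 2, demoting B costs 4 -> demote A, keep A->B
        assert res.dag.edges == frozenset({("A", "B")})
        assert res.repairs == 1
        assert res.score == pytest.approx(-17.0)

    def test_repair_never_beats_exact_dp(self):
        """Cycle repair is always bounded above by the DP optimum."""
        for s in range(30):
            inst = simulate(SimulationConfig(p=6, n=400, seed=700 + s))
            sc = Scorer(inst.data)
            config = SearchConfig(max_parents=3, candidates_per_node=40)
            cand = {
                c: enumerate_families(inst.data, c, config, sc)
                for c in sorted(inst.data.names)
            }
            greedy = assemble_greedy(cand, config)
            exact = assemble_exact_dp(cand)
            assert greedy.score <= exact.score + 1e-9

    def test_greedy_pipeline_usually_matches_exact_dp(self):
        """learn() with the greedy assembler (repair + order refinement)
        reaches the exact-DP optimum on most small instances."""
        matches = 0
        reps = 30
        for s in range(reps):
            inst = simulate(SimulationConfig(p=6, n=400, seed=700 + s))
            config = SearchConfig(max_parents=3, candidates_per_node=40)
            greedy = learn(inst.data, config)
            exact = learn(
                inst.data,
                SearchConfig(max_parents=3, candidates_per_node=40, assembler="exact_dp"),
            )
            assert greedy.score <= exact.score + 1e-6
            matches += int(abs(greedy.score - exact.score) < 1e-6)
        assert matches / reps >= 0.8


class TestAssembleExactDp:
    def test_single_node(self):
        cand = {"A": FamilyCandidates("A", (fs("A", (), -2.0),))}
        res = assemble_exact_dp(cand)
        assert res.dag.edges == frozenset()
        assert res.score == pytest.approx(-2.0)

    def test_matches_brute_force_over_all_dags(self):
        """p=4, all subsets as candidates: DP equals maximization over all
        543 labeled 4-node DAGs."""
        for s in range(5):
            inst = simulate(SimulationConfig(p=4, n=150, seed=50 + s))
            sc = Scorer(inst.data)
            names = sorted(inst.data.names)
            config = SearchConfig(max_parents=3, candidates_per_node=10_000)
            cand = {c: enumerate_families(inst.data, c, config, sc) for c in names}
            dp = assemble_exact_dp(cand)
            best = -math.inf
            dags = all_labeled_dags(names)
            assert len(dags) == 543
            for edges in dags:
                total = sum(
                    sc.family_score(v, frozenset(u for u, w in edges if w == v)).bic
                    for v in names
                )
                best = max(best, total)
            assert dp.score == pytest.approx(best, abs=1e-9)

    def test_size_limit(self):
        cand = {
            f"N{i:02d}": FamilyCandidates(f"N{i:02d}", (fs(f"N{i:02d}", (), -1.0),))
            for i in range(21)
        }
        with pytest.raises(InvalidArgumentError):
            assemble_exact_dp(cand)


class TestLearn:
    def test_two_node_edge_recovered(self):
        hits = reps = 0
        for s in range(100):
            rng = np.random.default_rng(8000 + s)
            a = rng.normal(size=1000)
            b = 2 * a + rng.normal(size=1000)
            data = make_dataset({"A": a, "B": b})
            res = learn(data, SearchConfig(max_parents=1))
            reps += 1
            adj = {frozenset(e) for e in res.dag.edges}
            hits += int(frozenset({"A", "B"}) in adj)
        assert hits / reps >= 0.95

    def test_independent_data_gives_empty_graph(self):
        hits = reps = 0
        for s in range(100):
            rng = np.random.default_rng(9000 + s)
            data = make_dataset({f"X{i}": rng.normal(size=1000) for i in range(4)})
            res = learn(data, SearchConfig(max_parents=2))
            reps += 1
            hits += int(len(res.dag.edges) == 0)
        assert hits / reps >= 0.9

    def test_column_order_invariance(self):
        """Shuffled and unshuffled columns yield the identical structure."""
        inst = simulate(SimulationConfig(p=10, n=200, seed=42))
        shuffled = learn(inst.data, SearchConfig())
        unshuffled = learn(inst.unshuffled(), SearchConfig())
        assert shuffled.dag.edges == unshuffled.dag.edges

    def test_deterministic_given_seed(self):
        inst = simulate(SimulationConfig(p=8, n=150, seed=77))
        a = learn(inst.data, SearchConfig(seed=5))
        b = learn(inst.data, SearchConfig(seed=5))
        assert a.dag == b.dag and a.score == b.score

    def test_weights_carry_fitted_coefficients(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=2000)
        b = 2.0 * a + rng.normal(size=2000)
        data = make_dataset({"A": a, "B": b})
        res = learn(data, SearchConfig(max_parents=1))
        (edge,) = list(res.dag.edges)
        # either direction of the (reversible) edge: weight = OLS slope
        u, v = edge
        expected = np.polyfit(data.column(u), data.column(v), 1)[0]
        assert res.weights[edge] == pytest.approx(expected, abs=1e-6)
        assert abs(expected) > 0.3  # genuinely informative dependence

    def test_learner_output_respects_mixed_constraint(self):
        inst = simulate(SimulationConfig(network_kind="mixed", p=8, n=200, seed=11))
        res = learn(inst.data, SearchConfig(max_parents=2))
        kind = {v.name: v.kind for v in res.dag.variables}
        for u, v in res.dag.edges:
            assert not (kind[v] == "discrete" and kind[u] == "continuous")
        from bicnet import topological_order

        topological_order(res.dag)


class TestHillClimb:
    def test_independent_data_empty_graph(self, rng):
        data = make_dataset({f"X{i}": rng.normal(size=1000) for i in range(4)})
        res = hill_climb_baseline(data, SearchConfig(max_parents=2))
        assert len(res.dag.edges) == 0

    def test_monotone_ascent_beats_empty_graph(self):
        inst = simulate(SimulationConfig(p=6, n=300, seed=21))
        sc = Scorer(inst.data)
        empty_score = sum(
            sc.family_score(v, frozenset()).bic for v in inst.data.names
        )
        res = hill_climb_baseline(inst.data, SearchConfig(max_parents=3))
        assert res.score >= empty_score - 1e-9

    def test_two_phase_matches_or_beats_hill_climb_usually(self):
        wins = reps = 0
        for s in range(30):
            inst = simulate(SimulationConfig(p=6, n=300, seed=600 + s))
            config = SearchConfig(max_parents=3)
            tp = learn(inst.data, config)
            hc = hill_climb_baseline(inst.data, config)
            reps += 1
            wins += int(tp.score >= hc.score - 1e-6)
        assert wins / reps >= 0.8


class TestFamilyIndex:
    def test_best_respects_allowed_mask(self):
        data_cols = {"A": np.arange(10.0), "B": np.arange(10.0)[::-1]}
        idx = FamilyIndex(["A", "B"])
        idx.add_child(
            "A",
            [(), ("B",)],
            np.array([-5.0, -1.0]),
            np.array([False, False]),
        )
        bic, parents = idx.best("A", idx.mask_of(["B"]))
        assert parents == ("B",)
        bic, parents = idx.best("A", np.uint64(0))
        assert parents == ()
        assert bic == pytest.approx(-5.0)

    def test_refinement_never_loses_score(self):
        from bicnet.search import _refine_order

        inst = simulate(SimulationConfig(p=8, n=300, seed=33))
        sc = Scorer(inst.data)
        config = SearchConfig(max_parents=3)
        names = sorted(inst.data.names)
        index = FamilyIndex(names)
        for c in names:
            index.add_child(c, *_score_child_subsets(inst.data, c, config, sc))
        start = list(names)
        pred = np.uint64(0)
        start_total = 0.0
        for nme in start:
            s, _ = index.best(nme, pred)
            start_total += s
            pred |= index.bit[nme]
        _, refined_total = _refine_order(index, start)
        assert refined_total >= start_total - 1e-9
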