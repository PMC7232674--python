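import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bicnet import (
    Dataset,
    Scorer,
    SimulationConfig,
    VariableSpec,
    generate_random_dag,
    global_bic,
    score_cgaussian_family,
    score_family,
    score_gaussian_family,
    score_multinomial_family,
    simulate,
)
from bicnet.exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    MixedConstraintError,
)

from _oracles import ols_gaussian_bic


def make_dataset(columns, kinds=None):
    frame = pd.DataFrame(columns)
    specs = []
    for name in frame.columns:
        kind = (kinds or {}).get(name, "continuous")
        if kind == "continuous":
            specs.append(VariableSpec(name))
        else:
            specs.append(VariableSpec(name, "discrete", kind))
    return Dataset(frame, tuple(specs))


class TestGaussianFamily:
    def test_matches_closed_form_oracle(self):
        """Fixed 5-row dataset against an independently coded OLS+BIC."""
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        y = [0.1, 2.1, 3.9, 6.2, 7.9]
        data = make_dataset({"x": x, "y": y})
        fs = score_gaussian_family(data, "y", ["x"])
        expected_bic, expected_ll, expected_k = ols_gaussian_bic([x], y)
        assert fs.bic == pytest.approx(expected_bic, rel=1e-12)
        assert fs.loglik == pytest.approx(expected_ll, rel=1e-12)
        assert fs.k == expected_k == 3
        assert fs.bic == pytest.approx(fs.loglik - 0.5 * fs.k * math.log(fs.n))

    def test_penalty_beats_chance_fit(self, rng):
        """An independent candidate parent loses to the empty family."""
        wins = 0
        reps = 200
        for _ in range(reps):
            data = make_dataset({
                "y": rng.normal(size=1000), "z": rng.normal(size=1000)
            })
            empty = score_gaussian_family(data, "y", [])
            with_parent = score_gaussian_family(data, "y", ["z"])
            wins += int(empty.bic > with_parent.bic)
        assert wins / reps >= 0.95

    def test_zero_residual_variance_flagged(self):
        x = np.linspace(0, 1, 50)
        data = make_dataset({"x": x, "y": 2 * x})
        fs = score_gaussian_family(data, "y", ["x"])
        assert fs.degenerate
        assert fs.bic == math.inf  # sentinel, excluded from search

    def test_insufficient_rows_rejected(self):
        data = make_dataset({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            score_gaussian_family(data, "y", ["x"])


class TestMultinomialFamily:
    def test_uniform_counts_closed_form(self):
        data = make_dataset({"b": [0] * 5 + [1] * 5}, kinds={"b": 2})
        fs = score_multinomial_family(data, "b", [], alpha=0.0)
        assert fs.loglik == pytest.approx(10 * math.log(0.5))
        assert fs.k == 1

    def test_deterministic_dependence_beats_empty(self, rng):
        a = rng.integers(0, 2, size=1000)
        data = make_dataset({"a": a, "b": a.copy()}, kinds={"a": 2, "b": 2})
        with_parent = score_multinomial_family(data, "b", ["a"])
        empty = score_multinomial_family(data, "b", [])
        assert with_parent.bic > empty.bic

    def test_continuous_parent_rejected(self):
        data = make_dataset({"a": [0.5, 1.5, 0.7], "b": [0, 1, 0]}, kinds={"b": 2})
        with pytest.raises(MixedConstraintError):
            score_multinomial_family(data, "b", ["a"])

    def test_unobserved_row_contributes_nothing(self):
        # parent level 2 never occurs; k still counts the full table
        data = make_dataset(
            {"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]}, kinds={"a": 3, "b": 2}
        )
        fs0 = score_multinomial_family(data, "b", ["a"], alpha=0.0)
        # with only the two observed rows the MLE loglik is 4*log(0.5)
        assert fs0.loglik == pytest.approx(4 * math.log(0.5))
        assert fs0.k == (2 - 1) * 3

    def test_alpha_zero_equals_mle(self, rng):
        a = rng.integers(0, 2, size=200)
        b = (a + rng.integers(0, 2, size=200)) % 2
        data = make_dataset({"a": a, "b": b}, kinds={"a": 2, "b": 2})
        fs = score_multinomial_family(data, "b", ["a"], alpha=0.0)
        # direct MLE cross-check
        ll = 0.0
        for av in (0, 1):
            sub = b[a == av]
            for bv in (0, 1):
                c = int((sub == bv).sum())
                if c:
                    ll += c * math.log(c / len(sub))
        assert fs.loglik == pytest.approx(ll)


class TestConditionalGaussianFamily:
    def test_reduces_to_gaussian_without_discrete_parents(self, gaussian_pair):
        a = score_cgaussian_family(gaussian_pair, "B", ["A"])
        b = score_gaussian_family(gaussian_pair, "B", ["A"])
        assert a.bic == pytest.approx(b.bic, abs=1e-9)

    def test_separated_means_beat_empty(self, rng):
        g = rng.integers(0, 2, size=1000)
        y = 4.0 * g + rng.normal(size=1000)
        data = make_dataset({"g": g, "y": y}, kinds={"g": 2})
        with_parent = score_cgaussian_family(data, "y", ["g"])
        empty = score_family(data, "y", [])
        assert with_parent.bic > empty.bic

    def test_single_configuration_matches_gaussian_k(self, rng):
        g = np.zeros(200, dtype=int)
        x = rng.normal(size=200)
        y = 2 * x + rng.normal(size=200)
        data = make_dataset({"g": g, "x": x, "y": y}, kinds={"g": 2})
        cg = score_cgaussian_family(data, "y", ["g", "x"])
        ga = score_gaussian_family(data, "y", ["x"])
        assert cg.bic == pytest.approx(ga.bic, abs=1e-9)

    def test_thin_configuration_pooled_and_flagged(self, rng):
        g = np.zeros(100, dtype=int)
        g[:1] = 1  # a single row in configuration 1 (< c+1 rows)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        data = make_dataset({"g": g, "x": x, "y": y}, kinds={"g": 2})
        fs = score_cgaussian_family(data, "y", ["g", "x"])
        assert "pooled_fallback" in fs.flags


class TestScorerFastPath:
    def test_gram_path_matches_direct_fit(self, rng):
        frame = {f"X{i}": rng.normal(size=300) for i in range(5)}
        frame["Y"] = frame["X0"] * 1.5 - frame["X3"] * 0.5 + rng.normal(size=300)
        data = make_dataset(frame)
        sc = Scorer(data)
        for parents in ([], ["X0"], ["X0", "X3"], ["X1", "X2", "X4"]):
            fast = sc.family_score("Y", parents)
            slow = score_gaussian_family(data, "Y", parents)
            assert fast.bic == pytest.approx(slow.bic, rel=1e-9)

    def test_bulk_path_matches_single_queries(self, rng):
        frame = {f"X{i}": rng.normal(size=200) for i in range(6)}
        data = make_dataset(frame)
        sc = Scorer(data)
        pool = [f"X{i}" for i in range(1, 6)]
        tuples, bics, degs = sc.score_all_continuous_subsets("X0", pool, 3)
        fresh = Scorer(data)
        for t, b, d in zip(tuples, bics, degs):
            if not d:
                assert b == pytest.approx(
                    fresh.family_score("X0", t).bic, rel=1e-9
                )

    def test_cache_returns_identical_object(self, gaussian_pair):
        sc = Scorer(gaussian_pair)
        assert sc.family_score("B", ["A"]) is sc.family_score("B", ["A"])

    def test_score_depends_only_on_family_columns(self, rng):
        """Permuting unrelated columns never changes a family score."""
        cols = {f"X{i}": rng.normal(size=150) for i in range(5)}
        data1 = make_dataset(cols)
        shuffled = {k: cols[k] for k in ["X3", "X0", "X4", "X1", "X2"]}
        data2 = make_dataset(shuffled)
        s1 = Scorer(data1).family_score("X0", ["X1", "X2"])
        s2 = Scorer(data2).family_score("X0", ["X1", "X2"])
        assert s1.bic == s2.bic  # exact: same arithmetic path


class TestGlobalBic:
    def test_decomposability_on_random_dags(self):
        """global_bic == sum of family scores, exactly, on 50 random pairs."""
        for s in range(50):
            inst = simulate(SimulationConfig(p=6, n=80, seed=200 + s))
            other = generate_random_dag(6, 1.0, seed=900 + s)
            # rename: generated dag uses the same X01.. names as the data
            sc = Scorer(inst.data)
            total = global_bic(other, inst.data, sc)
            expected = sum(
                sc.family_score(v, other.parents(v)).bic for v in other.names
            )
            assert total == pytest.approx(expected, abs=1e-9)

    def test_true_edge_improves_score(self):
        """Adding back a missing true edge raises the global BIC (n=1000)."""
        wins = reps = 0
        for s in range(40):
            inst = simulate(SimulationConfig(p=6, n=1000, seed=300 + s,
                                             shuffle_columns=False))
            dag = inst.truth.dag
            if not dag.edges:
                continue
            u, v = sorted(dag.edges)[0]
            reduced = type(dag)(dag.variables, dag.edges - {(u, v)})
            sc = Scorer(inst.data)
            reps += 1
            wins += int(
                global_bic(dag, inst.data, sc) > global_bic(reduced, inst.data, sc)
            )
        assert reps >= 30
        assert wins / reps >= 0.95

    def test_node_mismatch_rejected(self, gaussian_pair):
        dag = generate_random_dag(3, 0.5, seed=1)
        with pytest.raises(InvalidArgumentError):
            global_bic(dag, gaussian_pair)


@given(st.integers(min_value=0, max_value=10_000))
def test_bic_identity_holds(seed):
    rng = np.random.default_rng(seed)
    data = make_dataset({"a": rng.normal(size=50), "b": rng.normal(size=50)})
    fs = score_gaussian_family(data, "a", ["b"])
    assert fs.bic == pytest.approx(fs.loglik - 0.5 * fs.k * math.log(fs.n))
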