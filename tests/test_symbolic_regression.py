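"""The genetic-programming engine: evaluation, operators, evolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thioreact.exceptions import ValidationError
from thioreact.symbolic_regression import (
    ExpressionTree,
    GPConfig,
    RegressionDataset,
    evaluate_tree,
    evolve,
    fitness,
    random_tree,
    subtree_crossover,
    subtree_mutation,
)
from thioreact.synthetic_fixtures import FixtureSpec, generate_regression_dataset


def make_dataset(X: dict, y) -> RegressionDataset:
    return RegressionDataset(features=pd.DataFrame(X), response=np.asarray(y, float))


SMALL_CFG = GPConfig(seed=0, population_size=30, generations=5)


class TestEvaluate:
    def test_addition_tree(self):
        ds = make_dataset({"x0": [1.0, 3.0], "x1": [2.0, 4.0]}, [0.0, 1.0])
        out = evaluate_tree(("add", ("x", "x0"), ("x", "x1")), ds)
        np.testing.assert_array_equal(out, [3.0, 7.0])

    def test_protected_division_by_zero_returns_one(self):
        ds = make_dataset({"x0": [1.0, -2.0, 5.0]}, [0.0, 1.0, 2.0])
        out = evaluate_tree(("div", ("x", "x0"), ("c", 0.0)), ds)
        np.testing.assert_array_equal(out, [1.0, 1.0, 1.0])

    def test_affine_tree_matches_calibration_example(self):
        ds = make_dataset({"x0": [-3.39, 0.0, 1.0]}, [0.0, 1.0, 2.0])
        tree = ("add", ("mul", ("c", 0.525), ("x", "x0")), ("c", 8.646))
        out = evaluate_tree(tree, ds)
        assert out[0] == pytest.approx(6.866, abs=1e-3)
        assert out[1] == pytest.approx(8.646)

    def test_unknown_feature_name(self):
        ds = make_dataset({"x0": [1.0, 2.0]}, [0.0, 1.0])
        with pytest.raises(ValidationError, match="nope"):
            evaluate_tree(("x", "nope"), ds)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_protected_operators_are_total(self, seed):
        rng = np.random.default_rng(seed)
        ds = make_dataset(
            {"x0": rng.normal(size=10) * 10, "x1": rng.normal(size=10)},
            rng.normal(size=10),
        )
        cfg = GPConfig(seed=seed, population_size=2, generations=1, max_depth=6)
        tree = random_tree(rng, ["x0", "x1"], cfg)
        evaluate_tree(tree, ds)  # must not raise on finite inputs


class TestFitness:
    def test_perfect_tree_has_raw_one(self):
        ds = make_dataset({"x0": [1.0, 2.0, 3.0, 4.0]}, [2.0, 4.0, 6.0, 8.0])
        raw, _ = fitness(ExpressionTree(("x", "x0")), ds, SMALL_CFG)
        assert raw == pytest.approx(1.0, abs=1e-14)

    def test_parsimony_penalty_is_linear_in_length(self):
        ds = make_dataset({"x0": [1.0, 2.0, 3.0, 4.0]}, [2.0, 4.0, 6.0, 8.0])
        t1 = ExpressionTree(("x", "x0"))
        # same predictions, four extra nodes: x0 + 0*x0
        t2 = ExpressionTree(("add", ("x", "x0"), ("mul", ("c", 0.0), ("x", "x0"))))
        raw1, pen1 = fitness(t1, ds, SMALL_CFG)
        raw2, pen2 = fitness(t2, ds, SMALL_CFG)
        assert raw1 == raw2
        extra = t2.length - t1.length
        assert pen1 - pen2 == pytest.approx(
            SMALL_CFG.parsimony_coefficient * extra
        )

    def test_constant_prediction_scores_zero(self):
        ds = make_dataset({"x0": [1.0, 2.0, 3.0]}, [1.0, 5.0, 2.0])
        raw, _ = fitness(ExpressionTree(("c", 3.0)), ds, SMALL_CFG)
        assert raw == 0.0

    def test_random_tree_below_perfect_on_planted_data(self):
        ds = generate_regression_dataset(FixtureSpec(seed=9, n_species=50, planted="linear"))
        rng = np.random.default_rng(1)
        raw, _ = fitness(random_tree(rng, ds.feature_names, SMALL_CFG), ds, SMALL_CFG)
        assert raw < 1.0


class TestOperators:
    def test_crossover_of_identical_leaves_is_identity(self):
        rng = np.random.default_rng(0)
        a = ExpressionTree(("x", "x0"))
        child = subtree_crossover(a, a, rng, SMALL_CFG)
        assert child.root == a.root

    def test_crossover_respects_depth_cap(self):
        rng = np.random.default_rng(3)
        cfg = GPConfig(seed=3, population_size=2, generations=1, max_depth=5)
        for _ in range(500):
            a = random_tree(rng, ["x0", "x1"], cfg)
            b = random_tree(rng, ["x0", "x1"], cfg)
            child = subtree_crossover(a, b, rng, cfg)
            assert child.depth <= cfg.max_depth

    def test_mutation_respects_depth_cap(self):
        rng = np.random.default_rng(4)
        cfg = GPConfig(seed=4, population_size=2, generations=1, max_depth=5)
        for _ in range(500):
            a = random_tree(rng, ["x0", "x1"], cfg)
            child = subtree_mutation(a, rng, cfg, ["x0", "x1"])
            assert child.depth <= cfg.max_depth

    def test_operators_are_seed_deterministic(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            a = random_tree(rng, ["x0", "x1"], SMALL_CFG)
            b = random_tree(rng, ["x0", "x1"], SMALL_CFG)
            c = subtree_crossover(a, b, rng, SMALL_CFG)
            m = subtree_mutation(c, rng, SMALL_CFG, ["x0", "x1"])
            return m.root

        assert run(123) == run(123)
        assert run(123) != run(124)


class TestConfigAndDataset:
    def test_probability_mass_validated(self):
        with pytest.raises(ValidationError):
            GPConfig(seed=0, p_crossover=0.8, p_subtree_mutation=0.3)

    def test_population_and_samples_validated(self):
        with pytest.raises(ValidationError):
            GPConfig(seed=0, population_size=1)
        with pytest.raises(ValidationError):
            GPConfig(seed=0, max_samples=0.0)

    def test_constant_response_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            make_dataset({"x0": [1.0, 2.0, 3.0]}, [5.0, 5.0, 5.0])

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            make_dataset({"x0": [1.0, np.nan, 3.0]}, [1.0, 2.0, 3.0])

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_dataset({"x0": [1.0, 2.0, 3.0]}, [1.0, 2.0])


class TestEvolve:
    def test_history_is_monotone_and_deterministic(self):
        ds = generate_regression_dataset(
            FixtureSpec(seed=5, n_species=60, planted="linear")
        )
        cfg = GPConfig(seed=5, population_size=80, generations=12)
        res1 = evolve(ds, cfg)
        res2 = evolve(ds, cfg)
        assert res1.history == res2.history  # bit-identical
        assert res1.best.root == res2.best.root
        assert all(a <= b for a, b in zip(res1.history, res1.history[1:]))
        assert len(res1.history) == cfg.generations

    def test_finds_signal_on_planted_linear_data(self):
        ds = generate_regression_dataset(
            FixtureSpec(seed=5, n_species=60, planted="linear")
        )
        cfg = GPConfig(seed=5, population_size=100, generations=20)
        res = evolve(ds, cfg)
        assert res.best.fitness_raw > 0.9

    def test_zero_parsimony_makes_penalized_equal_raw(self):
        ds = generate_regression_dataset(
            FixtureSpec(seed=6, n_species=40, planted="linear")
        )
        cfg = GPConfig(
            seed=6, population_size=40, generations=3, parsimony_coefficient=0.0
        )
        tree = random_tree(np.random.default_rng(0), ds.feature_names, cfg)
        raw, pen = fitness(tree, ds, cfg)
        assert raw == pen

    def test_all_individuals_respect_depth_invariant(self):
        ds = generate_regression_dataset(
            FixtureSpec(seed=8, n_species=40, planted="linear")
        )
        cfg = GPConfig(seed=8, population_size=50, generations=8, max_depth=6)
        res = evolve(ds, cfg)
        assert res.best.depth <= cfg.max_depth
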