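"""Honey badger moves, rough-set dependency and wrapper feature selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from badgerseg.hboa import (
    BadgerPopulation,
    DecisionTable,
    FitnessConfig,
    binarize,
    density_factor,
    dependency_degree,
    digging_update,
    discretize,
    fitness,
    honey_update,
    init_population,
    optimize,
    pearson_screen,
    select_features,
)
from badgerseg.synthetic import make_feature_table


class ScriptedRNG:
    """Duck-typed generator returning a fixed sequence of draws."""

    def __init__(self, draws):
        self.draws = list(draws)

    def random(self, size=None):
        v = self.draws.pop(0)
        if size is None:
            return float(v)
        return np.full(size, float(v))


def make_pop(positions, best, lb=0.0, ub=1.0, iteration=0, max_iter=100, l=2.0, beta=1.0):
    positions = np.asarray(positions, dtype=float)
    d = positions.shape[1]
    return BadgerPopulation(
        positions=positions,
        lb=np.full(d, lb),
        ub=np.full(d, ub),
        best_position=np.asarray(best, dtype=float),
        best_fitness=0.0,
        fitnesses=np.zeros(positions.shape[0]),
        iteration=iteration,
        max_iter=max_iter,
        l=l,
        beta=beta,
    )


def gamma_oracle(attrs, dec, selected):
    """Brute-force positive-region count via per-group label sets."""
    groups = {}
    for row, label in zip(attrs[:, selected], dec):
        groups.setdefault(tuple(row), []).append(label)
    pos = sum(len(v) for v in groups.values() if len(set(v)) == 1)
    return pos / len(dec)


class TestInitPopulation:
    def test_bounds_and_shape(self, rng):
        pop = init_population(10, 4, -2.0, 3.0, seed=1)
        assert pop.positions.shape == (10, 4)
        assert pop.positions.min() >= -2.0 and pop.positions.max() <= 3.0
        assert pop.best_fitness == np.inf

    def test_deterministic(self):
        p1 = init_population(5, 3, 0.0, 1.0, seed=9)
        p2 = init_population(5, 3, 0.0, 1.0, seed=9)
        np.testing.assert_array_equal(p1.positions, p2.positions)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            init_population(1, 3, 0.0, 1.0)
        with pytest.raises(ValueError):
            init_population(5, 3, 1.0, 1.0)


class TestDensityFactor:
    def test_closed_forms(self):
        assert density_factor(0, 100, l=2.0) == pytest.approx(2.0)
        assert density_factor(100, 100, l=2.0) == pytest.approx(2.0 / math.e)
        assert density_factor(50, 100, l=2.0) == pytest.approx(2.0 * math.exp(-0.5))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            density_factor(-1, 100)
        with pytest.raises(ValueError):
            density_factor(0, 100, l=1.0)


class TestDiggingUpdate:
    def test_hand_evaluated_move(self):
        pop = make_pop([[0.2], [0.6]], best=[0.8])
        r2, r3, r4, r5, r6 = 0.5, 0.25, 0.1, 0.3, 0.4
        z = digging_update(pop, 0, ScriptedRNG([r2, r3, r4, r5, r6]))
        # independent arithmetic: alpha = 2*exp(0) = 2, q = +1 (r6 <= 0.5)
        di = 0.8 - 0.2
        g = (0.2 - 0.6) ** 2
        intensity = r2 * g / (4 * math.pi * di**2 + 1e-12)
        expected = 0.8 + intensity * 0.8 + 2.0 * di * r3 * abs(
            math.cos(2 * math.pi * r4) * (1 - math.cos(2 * math.pi * r5))
        )
        assert z[0] == pytest.approx(min(expected, 1.0), abs=1e-12)

    def test_q_sign_flip(self):
        pop = make_pop([[0.2], [0.6]], best=[0.5], lb=-10.0, ub=10.0)
        zp = digging_update(pop, 0, ScriptedRNG([0.5, 0.25, 0.1, 0.3, 0.4]))  # q = +1
        zm = digging_update(pop, 0, ScriptedRNG([0.5, 0.25, 0.1, 0.3, 0.7]))  # q = -1
        # both moves are best +/- the same displacement
        assert zp[0] + zm[0] == pytest.approx(2 * 0.5, abs=1e-12)
        assert zp[0] != zm[0]

    def test_fixed_point_at_incumbent(self):
        """Agent at the incumbent with an identical neighbour does not move."""
        pop = make_pop([[0.4], [0.4]], best=[0.4])
        z = digging_update(pop, 0, ScriptedRNG([0.5, 0.25, 0.1, 0.3, 0.4]))
        assert z[0] == pytest.approx(0.4)

    def test_clipped_to_bounds(self):
        pop = make_pop([[0.0], [1.0]], best=[1.0])
        z = digging_update(pop, 0, ScriptedRNG([1.0, 1.0, 0.5, 0.5, 0.0]))
        assert 0.0 <= z[0] <= 1.0


class TestHoneyUpdate:
    def test_hand_evaluated_move(self):
        pop = make_pop([[0.2], [0.6]], best=[0.8], iteration=50)
        r7, r6 = 0.3, 0.9  # q = -1
        z = honey_update(pop, 0, ScriptedRNG([r7, r6]))
        alpha = 2.0 * math.exp(-0.5)
        expected = 0.8 - r7 * alpha * (0.8 - 0.2)
        assert z[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_distance_fixed_point(self):
        pop = make_pop([[0.7], [0.1]], best=[0.7])
        z = honey_update(pop, 0, ScriptedRNG([0.9, 0.1]))
        assert z[0] == pytest.approx(0.7)


class TestOptimize:
    def test_sphere_minimum(self):
        for seed in range(3):
            best, val, trace = optimize(
                lambda z: float((z**2).sum()), d=2, lb=-5.0, ub=5.0, n_agents=20, seed=seed
            )
            assert val <= 1e-2
            assert np.all(np.abs(best) <= 5.0)
            assert np.all(np.diff(trace) <= 0.0)  # greedy: non-increasing

    def test_deterministic(self):
        obj = lambda z: float((z**2).sum())  # noqa: E731
        out1 = optimize(obj, d=3, lb=-1.0, ub=1.0, seed=4, max_iter=20)
        out2 = optimize(obj, d=3, lb=-1.0, ub=1.0, seed=4, max_iter=20)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_positions_stay_in_bounds(self):
        seen = []

        def obj(z):
            seen.append(z.copy())
            return float((z**2).sum())

        optimize(obj, d=2, lb=0.0, ub=1.0, n_agents=5, max_iter=20, seed=0)
        arr = np.array(seen)
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestDiscretize:
    def test_quantile_codes_oracle(self):
        df = pd.DataFrame({"a": np.arange(1.0, 11.0)})
        dt = discretize(df, np.zeros(10), n_bins=5)
        np.testing.assert_array_equal(dt.attributes[:, 0], [0, 0, 1, 1, 2, 2, 3, 3, 4, 4])

    def test_constant_column_coded_zero(self):
        df = pd.DataFrame({"a": np.ones(6), "b": np.arange(6.0)})
        dt = discretize(df, np.zeros(6), n_bins=3)
        assert np.all(dt.attributes[:, 0] == 0)

    def test_equal_frequency_counts(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=100)})
        dt = discretize(df, np.zeros(100), n_bins=5)
        counts = np.bincount(dt.attributes[:, 0], minlength=5)
        assert np.all(np.abs(counts - 20) <= 1)

    def test_decision_coding(self):
        df = pd.DataFrame({"a": np.arange(4.0)})
        dt = discretize(df, np.array(["x", "y", "x", "z"]), n_bins=2)
        assert np.unique(dt.decision).tolist() == [0, 1, 2]


class TestDependencyDegree:
    def test_label_copy_attribute_gives_one(self):
        dec = np.array([0, 1, 0, 1, 1, 0])
        dt = DecisionTable(attributes=dec[:, None].copy(), decision=dec, feature_names=("a",))
        assert dependency_degree(dt, np.array([True])) == pytest.approx(1.0)

    def test_constant_attribute_two_classes_gives_zero(self):
        dt = DecisionTable(
            attributes=np.zeros((6, 1), dtype=int),
            decision=np.array([0, 0, 0, 1, 1, 1]),
            feature_names=("a",),
        )
        assert dependency_degree(dt, np.array([True])) == pytest.approx(0.0)

    def test_partial_positive_region_toy(self):
        # group (0): labels {0,0} pure; group (1): labels {0,1} mixed -> gamma 2/4
        dt = DecisionTable(
            attributes=np.array([[0], [0], [1], [1]]),
            decision=np.array([0, 0, 0, 1]),
            feature_names=("a",),
        )
        assert dependency_degree(dt, np.array([True])) == pytest.approx(0.5)

    def test_empty_subset_rejected(self):
        dt = DecisionTable(
            attributes=np.zeros((3, 2), dtype=int),
            decision=np.zeros(3, dtype=int),
            feature_names=("a", "b"),
        )
        with pytest.raises(ValueError):
            dependency_degree(dt, np.array([False, False]))

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_oracle_and_monotone(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n, d = int(rng.integers(3, 9)), int(rng.integers(2, 5))
        attrs = rng.integers(0, 3, size=(n, d))
        dec = rng.integers(0, 3, size=n)
        dt = DecisionTable(attributes=attrs, decision=dec, feature_names=tuple("abcd"[:d]))
        gammas = {}
        for r in range(1, d + 1):
            for combo in itertools.combinations(range(d), r):
                sel = np.zeros(d, dtype=bool)
                sel[list(combo)] = True
                g = dependency_degree(dt, sel)
                assert g == pytest.approx(gamma_oracle(attrs, dec, sel), abs=1e-12)
                gammas[combo] = g
        # monotonicity: adding an attribute never decreases gamma
        for combo, g in gammas.items():
            for j in range(d):
                if j not in combo:
                    bigger = tuple(sorted(combo + (j,)))
                    assert gammas[bigger] >= g - 1e-12


class TestFitness:
    def test_full_subset_full_dependency(self):
        dec = np.array([0, 1, 0, 1])
        dt = DecisionTable(attributes=dec[:, None].copy(), decision=dec, feature_names=("a",))
        cfg = FitnessConfig()
        # gamma = 1, |Z|/d = 1 -> fit = eta
        assert fitness(np.array([True]), dt, cfg) == pytest.approx(0.01)

    def test_zero_dependency_half_subset(self):
        dt = DecisionTable(
            attributes=np.zeros((4, 2), dtype=int),
            decision=np.array([0, 0, 1, 1]),
            feature_names=("a", "b"),
        )
        cfg = FitnessConfig()
        # gamma = 0, |Z|/d = 1/2 -> 0.01 * 0.5 + 0.99
        assert fitness(np.array([True, False]), dt, cfg) == pytest.approx(0.995)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            FitnessConfig(eta=0.5, rho=0.6)
        with pytest.raises(ValueError):
            FitnessConfig(n_bins=1)


class TestBinarize:
    def test_threshold(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.2, 0.7, 0.5, 0.9])), [False, True, False, True]
        )

    def test_argmax_rescue_on_empty(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.1, 0.4, 0.3])), [False, True, False]
        )

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), threshold=1.0)


class TestSelectFeatures:
    def test_recovers_planted_informative_subset(self):
        features, labels, informative = make_feature_table(seed=0)
        res = select_features(features, labels, seed=0)
        picked = np.flatnonzero(res.mask)
        recall = len(set(informative) & set(picked)) / len(informative)
        assert recall >= 0.8
        assert res.gamma >= 0.95
        assert np.all(np.diff(res.trace) <= 0.0)

    def test_deterministic(self):
        features, labels, _ = make_feature_table(n=80, d=12, seed=3)
        r1 = select_features(features, labels, n_agents=10, max_iter=20, seed=5)
        r2 = select_features(features, labels, n_agents=10, max_iter=20, seed=5)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        assert r1.best_fitness == r2.best_fitness

    def test_input_validation(self):
        features, labels, _ = make_feature_table(n=40, d=8, seed=0)
        with pytest.raises(ValueError):
            select_features(features.iloc[:, :1], labels)
        with pytest.raises(ValueError):
            select_features(features, np.zeros(len(labels)))

    def test_selected_names_match_mask(self):
        features, labels, _ = make_feature_table(n=60, d=10, seed=1)
        res = select_features(features, labels, n_agents=8, max_iter=10, seed=2)
        assert res.selected_names == [
            n for n, m in zip(features.columns, res.mask) if m
        ]


class TestPearsonScreen:
    def test_matches_closed_form(self, rng):
        x = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        df = pd.DataFrame({"a": x})
        out = pearson_screen(df, y)
        xc = x - x.mean()
        yc = y - y.mean()
        r_expected = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert out.loc[0, "r"] == pytest.approx(r_expected, abs=1e-12)

    def test_label_copy_feature_r_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        out = pearson_screen(pd.DataFrame({"a": y.astype(float)}), y)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        out = pearson_screen(pd.DataFrame({"a": np.ones(6)}), np.array([0, 1] * 3))
        assert bool(out.loc[0, "zero_variance"])
        assert out.loc[0, "r"] == 0.0

    def test_mask_restricts_rows(self):
        df = pd.DataFrame({"a": np.arange(6.0), "b": np.arange(6.0)[::-1]})
        out = pearson_screen(df, np.array([0, 1] * 3), mask=np.array([True, False]))
        assert out["feature"].tolist() == ["a"]
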