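"""Fitness, relevance and the hierarchical composite: hand-enumerated
oracles, invariants, and closed-form parameter recovery."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from dsiscreen import (
    CohortTable,
    FeatureHierarchy,
    default_config,
    fit_dsi,
    fit_fitness,
    fitness_value,
    generate_cohort,
    score,
)
from dsiscreen.dsi import DSIModel, FitError, _max_youden, _weighted_mean


def make_table(columns: dict, labels, kinds=None):
    data = pd.DataFrame(columns, index=[f"S{i}" for i in range(len(labels))])
    kinds = kinds or {c: "continuous" for c in columns}
    return CohortTable(
        data=data, labels=pd.Series(labels, index=data.index), feature_kinds=kinds
    )


class TestFitness:
    def test_perfect_separation_hand_enumeration(self):
        # positives {2,3}, negatives {0,1}: f(2.5)=0.5/(0.5+0)=1, f(0.5)=0,
        # relevance 1 at the mid-gap threshold
        m = fit_fitness([0, 1], [2, 3])
        assert m.orientation == "higher_in_positive"
        assert fitness_value(m, 2.5) == 1.0
        assert fitness_value(m, 0.5) == 0.0
        assert m.relevance == 1.0
        assert m.chosen_threshold == pytest.approx(1.5)

    def test_apoe_carrier_counts_direct_evaluation(self):
        # carriers 10/19 in positives, 4/28 in negatives (one positive
        # ungenotyped): relevance = 10/19 + 24/28 - 1, f(1) = FN/(FN+FP)
        neg = [1.0] * 4 + [0.0] * 24
        pos = [1.0] * 10 + [0.0] * 9
        m = fit_fitness(neg, pos, kind="binary", feature="apoe_e4_carrier")
        assert m.relevance == pytest.approx(10 / 19 + 24 / 28 - 1)
        assert m.fitness(1.0) == pytest.approx((9 / 19) / ((9 / 19) + (4 / 28)))
        assert m.fitness(0.0) == 0.0

    def test_saturation_beyond_training_range(self):
        m = fit_fitness([0, 1], [2, 3])
        assert m.fitness(-100.0) == 0.0
        assert m.fitness(100.0) == 1.0

    def test_identical_constant_samples_are_neutral(self):
        m = fit_fitness([1.0, 1.0], [1.0, 1.0])
        assert m.relevance == 0.0
        assert m.degenerate
        assert m.fitness(0.0) == m.fitness(1.0) == m.fitness(5.0) == 0.5

    def test_lower_in_positive_orientation_learned(self):
        m = fit_fitness([5, 6, 7], [1, 2, 3], feature="volume")
        assert m.orientation == "lower_in_positive"
        assert m.relevance == 1.0
        assert m.fitness(0.0) == 1.0
        assert m.fitness(10.0) == 0.0

    def test_missing_values_dropped_before_fit(self):
        m = fit_fitness([0, 1, np.nan], [2, np.nan, 3])
        assert m.relevance == 1.0
        assert np.isnan(m.fitness(np.nan))

    def test_empty_class_raises_naming_feature(self):
        with pytest.raises(FitError, match="hippocampus"):
            fit_fitness([np.nan], [1.0, 2.0], feature="hippocampus")

    @given(
        neg=st.lists(st.floats(-50, 50), min_size=2, max_size=25),
        pos=st.lists(st.floats(-50, 50), min_size=2, max_size=25),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fitness_bounded_and_monotone_along_orientation(self, neg, pos):
        m = fit_fitness(neg, pos)
        grid = np.linspace(min(neg + pos) - 1, max(neg + pos) + 1, 101)
        vals = m.fitness(grid)
        assert ((vals >= 0) & (vals <= 1)).all()
        flip = m.orientation == "lower_in_positive"
        oriented = vals[::-1] if flip else vals
        assert (np.diff(oriented) >= -1e-12).all()
        # FN non-decreasing, FP non-increasing along the oriented axis
        fn = m.fn_curve(grid)[::-1] if flip else m.fn_curve(grid)
        fp = m.fp_curve(grid)[::-1] if flip else m.fp_curve(grid)
        assert (np.diff(fn) >= 0).all()
        assert (np.diff(fp) <= 0).all()

    @given(
        neg=st.lists(st.floats(-20, 20), min_size=2, max_size=15, unique=True),
        pos=st.lists(st.floats(-20, 20), min_size=2, max_size=15, unique=True),
        x=st.floats(-25, 25),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_class_swap_mirrors_fitness(self, neg, pos, x):
        # at evaluation points that are not training values and not inside a
        # separation gap, swapping the classes maps f to 1 - f
        if x in neg or x in pos:
            return
        m = fit_fitness(neg, pos)
        m_swapped = fit_fitness(pos, neg)
        if m.orientation == m_swapped.orientation:
            return  # direction tie: the swap did not mirror the orientation
        f = m.fitness(x)
        if f == 0.5:  # inside a perfect-separation gap: 0/0 region
            return
        assert m_swapped.fitness(x) == pytest.approx(1 - f, abs=1e-12)

    def test_relevance_never_negative_by_construction(self, rng):
        for _ in range(50):
            m = fit_fitness(rng.normal(size=8), rng.normal(size=8))
            assert 0.0 <= m.relevance <= 1.0

    def test_max_youden_tie_broken_toward_smaller_threshold(self):
        # {0,1} vs {2,3}: J=1 only at t=1.5; {0,2} vs {1,3}: several ties
        j, t = _max_youden(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert j == pytest.approx(0.5)
        assert t == pytest.approx(0.5)  # first (smallest) of the tied maxima


class TestHierarchicalModel:
    def test_single_leaf_root_equals_feature_fitness(self):
        table = make_table({"x": [0, 1, 2, 3]}, [0, 0, 1, 1])
        tree = FeatureHierarchy(name="root", features=["x"])
        model = fit_dsi(table, tree)
        result = score(model, table)
        leaf = model.leaf_models["x"]
        np.testing.assert_allclose(
            result.scores.to_numpy(), leaf.fitness(table.data["x"].to_numpy())
        )

    def test_group_weighted_average_hand_value(self):
        # fitness 0.8 (relevance 0.5) and 0.2 (relevance 0.25) -> 0.6
        v = _weighted_mean(np.array([[0.8, 0.2]]), np.array([0.5, 0.25]))
        assert v[0] == pytest.approx(0.6)

    def test_separable_training_scores_saturate(self):
        table = make_table(
            {"a": [0, 1, 2, 3], "b": [10, 11, 12, 13]}, [0, 0, 1, 1]
        )
        tree = FeatureHierarchy(name="root", features=["a", "b"])
        model = fit_dsi(table, tree)
        probe = make_table({"a": [-1, 5], "b": [9, 15]}, [0, 1])
        got = score(model, probe)
        np.testing.assert_allclose(got.scores.to_numpy(), [0.0, 1.0])

    def test_zero_relevance_leaf_is_inert(self):
        labels = [0, 0, 0, 1, 1, 1]
        cols = {"signal": [0, 1, 2, 10, 11, 12], "flat": [3.0] * 6}
        t1 = make_table({"signal": cols["signal"]}, labels)
        t2 = make_table(cols, labels)
        m1 = fit_dsi(t1, FeatureHierarchy(name="root", features=["signal"]))
        m2 = fit_dsi(t2, FeatureHierarchy(name="root", features=["signal", "flat"]))
        assert m2.leaf_models["flat"].relevance == 0.0
        np.testing.assert_allclose(
            score(m1, t1).scores.to_numpy(), score(m2, t2).scores.to_numpy()
        )

    def test_missing_value_renormalizes_onto_observed_leaf(self):
        # both leaves carry the same information -> equal relevance; a subject
        # missing one leaf must score exactly the observed leaf's fitness
        labels = [0, 0, 1, 1]
        table = make_table({"a": [0, 1, 10, 11], "b": [0, 1, 10, 11]}, labels)
        tree = FeatureHierarchy(name="root", features=["a", "b"])
        model = fit_dsi(table, tree)
        probe = make_table({"a": [0.5, np.nan], "b": [np.nan, 10.5]}, [0, 1])
        got = score(model, probe)
        a_only = model.leaf_models["a"].fitness(0.5)
        b_only = model.leaf_models["b"].fitness(10.5)
        assert got.scores.iloc[0] == pytest.approx(a_only)
        assert got.scores.iloc[1] == pytest.approx(b_only)
        assert got.n_observed_leaves.tolist() == [1, 1]

    def test_subject_with_no_observed_leaf_is_flagged(self):
        labels = [0, 0, 1, 1]
        table = make_table({"a": [0, 1, 10, 11]}, labels)
        tree = FeatureHierarchy(name="root", features=["a"])
        model = fit_dsi(table, tree)
        probe = make_table({"a": [np.nan, 5.0]}, [0, 1])
        got = score(model, probe)
        assert got.flagged.iloc[0]
        assert np.isnan(got.scores.iloc[0])
        assert not got.flagged.iloc[1]

    def test_all_children_zero_relevance_warns_and_is_neutral(self):
        labels = [0, 0, 1, 1]
        table = make_table({"flat": [2.0] * 4}, labels)
        tree = FeatureHierarchy(name="root", features=["flat"])
        with pytest.warns(UserWarning, match="zero relevance"):
            model = fit_dsi(table, tree)
        got = score(model, table)
        assert (got.scores == 0.5).all()

    def test_children_order_invariance(self, cohort, hierarchy):
        model = fit_dsi(cohort, hierarchy)
        flipped = FeatureHierarchy.from_dict(hierarchy.to_dict())
        flipped.children = flipped.children[::-1]
        model_f = fit_dsi(cohort, flipped)
        np.testing.assert_allclose(
            score(model, cohort).scores.to_numpy(),
            score(model_f, cohort).scores.to_numpy(),
        )

    def test_scores_in_unit_interval_on_synthetic_cohort(self, cohort, hierarchy):
        model = fit_dsi(cohort, hierarchy)
        result = score(model, cohort)
        vals = result.node_scores.to_numpy()
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()
        for fit in model.node_fits.values():
            assert fit.relevance >= 0.0

    def test_unknown_hierarchy_feature_raises(self, cohort):
        tree = FeatureHierarchy(name="root", features=["not_a_feature"])
        with pytest.raises(FitError, match="not_a_feature"):
            fit_dsi(cohort, tree)

    def test_json_round_trip_is_bit_exact(self, cohort, hierarchy, tmp_path):
        model = fit_dsi(cohort, hierarchy)
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = DSIModel.from_json(path)
        np.testing.assert_array_equal(
            score(model, cohort).scores.to_numpy(),
            score(clone, cohort).scores.to_numpy(),
        )
        for feat, m in model.leaf_models.items():
            np.testing.assert_array_equal(m.neg_oriented, clone.leaf_models[feat].neg_oriented)
            assert m.relevance == clone.leaf_models[feat].relevance


def population_youden_binormal(mu_n, sd_n, mu_p, sd_p):
    """J* = max_t |F_neg(t) - F_pos(t)|: the population Youden index for the
    better of the two threshold directions of a two-Gaussian feature."""
    res = minimize_scalar(
        lambda t: -abs(norm.cdf((t - mu_n) / sd_n) - norm.cdf((t - mu_p) / sd_p)),
        bounds=(min(mu_n, mu_p) - 5 * max(sd_n, sd_p), max(mu_n, mu_p) + 5 * max(sd_n, sd_p)),
        method="bounded",
    )
    return -res.fun


@pytest.fixture(scope="module")
def big_cohort():
    config = default_config(seed=29)
    config.n_negative = config.n_positive = 5000
    return config, generate_cohort(config)


class TestParameterRecovery:
    """At n = 5000/class, empirical leaf relevance approaches the population
    Youden index of the generating laws (closed form / numeric oracle)."""

    def test_continuous_leaf_relevance_matches_population_youden(self, big_cohort):
        config, table = big_cohort
        spec = config.feature("bmi")  # higher-in-negative, unequal SDs
        m = fit_fitness(
            table.class_values("bmi", 0), table.class_values("bmi", 1), feature="bmi"
        )
        expected = population_youden_binormal(
            spec.neg_params["mean"], spec.neg_params["sd"],
            spec.pos_params["mean"], spec.pos_params["sd"],
        )
        assert m.orientation == "lower_in_positive"
        assert m.relevance == pytest.approx(expected, abs=0.02)

    def test_bernoulli_leaf_relevance_matches_rate_difference(self, big_cohort):
        config, table = big_cohort
        spec = config.feature("apoe_e4_carrier")
        m = fit_fitness(
            table.class_values("apoe_e4_carrier", 0),
            table.class_values("apoe_e4_carrier", 1),
            kind="binary",
        )
        expected = spec.pos_params["p"] - spec.neg_params["p"]
        assert m.relevance == pytest.approx(expected, abs=0.02)
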