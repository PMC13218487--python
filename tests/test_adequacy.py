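"""Adequacy metrics, the mid-point p-value, and predictive simulation."""

import numpy as np
import pandas as pd
import pytest

import phylolex as px
from phylolex.adequacy import adequacy_report, compute_metrics, midpoint_p_value, simulate_predictive
from phylolex.cognates import CognateMatrix, read_matrix, table1_fixture_path
from phylolex.likelihood import LikelihoodConfig, ModelState, compress_matrix
from phylolex.mcmc import MCMCConfig, run_mcmc
from phylolex.simulate import PriorConfig, simulate_partition
from phylolex.trees import simulate_yule_tree
from tests.conftest import unit_clock


@pytest.fixture
def table1():
    return read_matrix(table1_fixture_path())


def test_worked_example_metrics(table1):
    """Hand counts on the printed five-language matrix: three columns are
    present in exactly one language (the belly cognates *terh-*, *gweh-*,
    *kwehl-*) and only the universal *two* column clears the 80% prevalence
    bar."""
    m = compute_metrics(table1)
    assert m.n_singletons == 3
    assert m.n_prevalent == 1
    # Slovene vs Polish differ in terh- and bhreus- out of 5 columns
    assert m.max_pairwise_distance <= 4 / 5
    assert m.min_pairwise_distance == pytest.approx(0.0)  # Polish == Czech
    assert m.mean_prop_present == pytest.approx(table1.values.mean())
    assert m.min_pairwise_distance <= m.mean_pairwise_distance <= m.max_pairwise_distance


def test_metrics_invariances(table1, rng):
    base = compute_metrics(table1)
    order = rng.permutation(len(table1.languages))
    shuffled = CognateMatrix(
        [table1.languages[i] for i in order],
        list(table1.columns),
        table1.values[order],
        dict(table1.partition_map),
    )
    for k, v in compute_metrics(shuffled).as_dict().items():
        assert v == pytest.approx(base.as_dict()[k], abs=1e-12)
    cols = rng.permutation(len(table1.columns))
    col_shuffled = CognateMatrix(
        list(table1.languages),
        [table1.columns[j] for j in cols],
        table1.values[:, cols],
        dict(table1.partition_map),
    )
    for k, v in compute_metrics(col_shuffled).as_dict().items():
        assert v == pytest.approx(base.as_dict()[k], abs=1e-12)


def test_identical_languages_distance_zero():
    vals = np.tile(np.array([[1, 0, 1]], dtype=np.int8), (3, 1))
    m = CognateMatrix(["a", "b", "c"], ["x0", "x1", "x2"], vals, {f"x{i}": "x" for i in range(3)})
    met = compute_metrics(m)
    assert met.max_pairwise_distance == 0.0


def test_metrics_reject_missing():
    m = CognateMatrix(["a", "b"], ["c"], np.array([[1], [-1]], dtype=np.int8), {"c": "x"})
    with pytest.raises(ValueError):
        compute_metrics(m)


def test_midpoint_p_value_discrete_toys():
    # P(T<2)=0.5, P(T=2)=0.25, P(T>2)=0.25 -> 2*min(0.625, 0.375) = 0.75
    assert midpoint_p_value(np.array([1, 1, 2, 3]), 2) == pytest.approx(0.75)
    # observed at the exact median of an odd sample with no ties -> 1
    assert midpoint_p_value(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), 3.0) == pytest.approx(1.0)
    # observed beyond every simulated value -> 0
    assert midpoint_p_value(np.arange(1000), 2000) == 0.0
    with pytest.raises(ValueError):
        midpoint_p_value(np.array([1.0]), 1.0)


def test_closed_loop_p_values_are_uniformish(rng):
    """When predictive simulations come from the true generating process, p_B
    is ~uniform over repeated experiments (mean ~ 0.5)."""
    tree = simulate_yule_tree(0.35, 5, rng)
    clock = unit_clock(tree, mu=0.08)
    params = px.CovarionParams(alpha=0.5, s=1.0, pi_obs=np.array([0.4, 0.6]))
    n_cols, n_sims, repeats = 60, 99, 200
    pvals = []
    for _ in range(repeats):
        obs = simulate_partition(tree, clock, params, 1.0, n_cols, rng)
        stat_obs = obs.mean()  # mean proportion present
        sims = np.array(
            [simulate_partition(tree, clock, params, 1.0, n_cols, rng).mean() for _ in range(n_sims)]
        )
        pvals.append(midpoint_p_value(sims, stat_obs))
    pvals = np.array(pvals)
    assert abs(pvals.mean() - 0.5) < 0.07
    assert (pvals < 0.05).mean() < 0.12


def _tiny_fixed_tree_trace(rng, tree, matrix, priors, chain=3000):
    pdata = compress_matrix(matrix, matrix.meanings)
    from phylolex.simulate import draw_from_priors

    truth = draw_from_priors(priors, tree.n_tips, np.ones(pdata.k), rng)
    init = ModelState(
        tree=tree.copy(),
        branch_rates=np.ones(tree.n_nodes),
        birth_rate=truth.birth_rate,
        alpha=truth.covarion.alpha,
        switch_rate=truth.covarion.s,
        pi_present=float(truth.covarion.pi_obs[1]),
        clock_sigma=max(truth.clock.sigma, 1e-6),
        m=np.ones(pdata.k),
    )
    cfg = MCMCConfig(chain_length=chain, sample_every=10, tree_mode="fixed", store_branch_rates=True)
    return run_mcmc(pdata, priors, LikelihoodConfig(weights=np.ones(pdata.k)), cfg, init, rng)


def test_simulate_predictive_shapes_and_reproducibility(rng):
    priors = PriorConfig()
    tree = simulate_yule_tree(0.35, 5, rng)
    clock = unit_clock(tree)
    params = px.CovarionParams(alpha=0.5, s=1.0, pi_obs=np.array([0.4, 0.6]))
    vals = simulate_partition(tree, clock, params, 1.0, 150, rng)
    keep = (vals == 1).any(axis=0)
    vals = vals[:, keep]
    cols = [f"p1_{i}" for i in range(vals.shape[1])]
    mat = CognateMatrix(list(tree.tip_labels), cols, vals, {c: "p1" for c in cols}, ascertained=True)
    trace = _tiny_fixed_tree_trace(rng, tree, mat, priors)
    counts = {"p1": vals.shape[1]}
    one = simulate_predictive(trace, tree, counts, 0.05, np.random.default_rng(5), n_reps=1)
    assert len(one) == 1
    a = simulate_predictive(trace, tree, counts, 0.05, np.random.default_rng(5), n_reps=4)
    b = simulate_predictive(trace, tree, counts, 0.05, np.random.default_rng(5), n_reps=4)
    pd.testing.assert_frame_equal(a, b)
    report = adequacy_report(a, compute_metrics(mat))
    assert set(report["metric"]) == set(px.adequacy.METRIC_NAMES)
    assert report["p_B"].between(0, 1).all()
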