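"""Pruning likelihood, ascertainment correction and the joint density."""

import itertools

import numpy as np
import pytest

import phylolex as px
from phylolex.cognates import CognateMatrix
from phylolex.likelihood import (
    LikelihoodConfig,
    ModelState,
    compress_matrix,
    corrected_partition_log_likelihood,
    data_log_likelihood,
    log_posterior,
    pattern_log_probability,
)
from phylolex.simulate import PriorConfig, draw_from_priors
from phylolex.trees import TimeTree, simulate_yule_tree
from tests.conftest import enumeration_log_probability, unit_clock


def _rand_params(rng):
    pi1 = rng.uniform(0.15, 0.85)
    return px.CovarionParams(
        alpha=rng.uniform(), s=rng.exponential(1) + 0.05, pi_obs=np.array([1 - pi1, pi1])
    )


def test_single_tip_is_root_marginal():
    tree = TimeTree(["only"], np.array([-1]), np.array([-1]), np.array([-1]), np.array([0.0]))
    clock = unit_clock(tree)
    params = px.CovarionParams(alpha=0.5, s=1.0, pi_obs=np.array([0.3, 0.7]))
    assert pattern_log_probability(np.array([1]), tree, clock, params) == pytest.approx(np.log(0.7))
    assert pattern_log_probability(np.array([0]), tree, clock, params) == pytest.approx(np.log(0.3))


def test_pruning_equals_enumeration(rng):
    for n in (3, 4):
        tree = simulate_yule_tree(0.4, n, rng)
        clock = px.ClockModel(mu=0.06, sigma=0.3, branch_rates=rng.lognormal(-0.045, 0.3, tree.n_nodes))
        params = _rand_params(rng)
        for pattern in itertools.product([0, 1], repeat=n):
            got = pattern_log_probability(np.array(pattern), tree, clock, params, m_partition=0.8)
            want = enumeration_log_probability(np.array(pattern), tree, clock, params, m=0.8)
            assert got == pytest.approx(want, abs=1e-10)


def test_patterns_normalize(rng):
    tree = simulate_yule_tree(0.4, 4, rng)
    clock = unit_clock(tree)
    params = _rand_params(rng)
    total = sum(
        np.exp(pattern_log_probability(np.array(p), tree, clock, params))
        for p in itertools.product([0, 1], repeat=4)
    )
    assert total == pytest.approx(1.0, abs=1e-10)


def test_corrected_probabilities_renormalize(rng):
    tree = simulate_yule_tree(0.4, 3, rng)
    clock = unit_clock(tree)
    params = _rand_params(rng)
    total = 0.0
    for p in itertools.product([0, 1], repeat=3):
        if sum(p) == 0:
            continue
        lp = corrected_partition_log_likelihood(
            np.array([p], dtype=np.int8), np.array([1.0]), tree, clock, params, 0.7
        )
        total += np.exp(lp)
    assert total == pytest.approx(1.0, abs=1e-10)


def test_correction_vanishes_when_absent_improbable(rng):
    """As the absent-state frequency goes to zero so does Pr(all-absent), and
    corrected equals uncorrected."""
    tree = simulate_yule_tree(0.4, 3, rng)
    clock = unit_clock(tree)
    params = px.CovarionParams(alpha=0.5, s=1.0, pi_obs=np.array([1e-8, 1 - 1e-8]))
    pat = np.array([[1, 1, 0]], dtype=np.int8)
    counts = np.array([1.0])
    a = corrected_partition_log_likelihood(pat, counts, tree, clock, params, 1.0, correction=True)
    b = corrected_partition_log_likelihood(pat, counts, tree, clock, params, 1.0, correction=False)
    assert a == pytest.approx(b, abs=1e-6)


def test_lower_rate_raises_corrected_probability(rng):
    """A smaller partition rate increases Pr(all-absent) and therefore raises
    every corrected pattern probability relative to the uncorrected one."""
    tree = simulate_yule_tree(0.4, 3, rng)
    clock = unit_clock(tree)
    params = px.CovarionParams(alpha=0.3, s=0.8, pi_obs=np.array([0.7, 0.3]))
    pat = np.array([[1, 0, 0]], dtype=np.int8)
    counts = np.array([1.0])

    def correction_gap(m):
        c = corrected_partition_log_likelihood(pat, counts, tree, clock, params, m, correction=True)
        u = corrected_partition_log_likelihood(pat, counts, tree, clock, params, m, correction=False)
        return c - u

    gaps = [correction_gap(m) for m in (1.0, 0.5, 0.2)]
    assert all(g > 0 for g in gaps)
    assert gaps[0] < gaps[1] < gaps[2]


def test_likelihood_factorizes_over_columns(rng):
    tree = simulate_yule_tree(0.4, 4, rng)
    clock = unit_clock(tree)
    params = _rand_params(rng)
    cols = ["c0", "c1"]
    vals = np.array([[1, 1], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
    m = CognateMatrix([f"L{i}" for i in range(4)], cols, vals, {c: "x" for c in cols})
    base = data_log_likelihood(compress_matrix(m, ["x"]), tree, clock, params, np.array([1.0]), correction=False)
    # duplicating a column adds exactly its own log probability
    cols3 = cols + ["c2"]
    vals3 = np.column_stack([vals, vals[:, 1]])
    m3 = CognateMatrix([f"L{i}" for i in range(4)], cols3, vals3, {c: "x" for c in cols3})
    with3 = data_log_likelihood(compress_matrix(m3, ["x"]), tree, clock, params, np.array([1.0]), correction=False)
    extra = pattern_log_probability(vals[:, 1], tree, clock, params)
    assert with3 == pytest.approx(base + extra, abs=1e-9)


def test_missing_data_rejected(rng):
    m = CognateMatrix(
        ["a", "b"], ["c0"], np.array([[1], [-1]], dtype=np.int8), {"c0": "x"}
    )
    with pytest.raises(ValueError, match="missing"):
        compress_matrix(m, ["x"])


def test_log_posterior_support_contract(rng):
    priors = PriorConfig()
    truth = draw_from_priors(priors, 5, np.ones(2), rng)
    state = ModelState(
        tree=truth.tree,
        branch_rates=truth.clock.branch_rates,
        birth_rate=truth.birth_rate,
        alpha=truth.covarion.alpha,
        switch_rate=truth.covarion.s,
        pi_present=float(truth.covarion.pi_obs[1]),
        clock_sigma=max(truth.clock.sigma, 1e-6),
        m=truth.rates.m,
    )
    cfg = LikelihoodConfig(weights=np.ones(2))
    lp, _ = log_posterior(state, None, priors, cfg)
    assert np.isfinite(lp)
    bad = state.copy()
    bad.alpha = 1.5
    assert log_posterior(bad, None, priors, cfg)[0] == -np.inf
    bad = state.copy()
    bad.switch_rate = -0.1
    assert log_posterior(bad, None, priors, cfg)[0] == -np.inf


def test_hyperprior_closed_forms_match_scipy():
    """The fast closed-form log densities equal the scipy frozen ones."""
    priors = PriorConfig()
    dists = priors.distributions()
    xs = {"birth_rate": 0.41, "alpha": 0.73, "switch_rate": 2.2, "pi_present": 0.31, "clock_sigma": 0.12}
    for name, x in xs.items():
        assert priors.log_hyperprior(name, x) == pytest.approx(
            float(dists[name].logpdf(x)), abs=1e-10
        )
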