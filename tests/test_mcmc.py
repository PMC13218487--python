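"""Sampler correctness: proposal invariants, prior recovery, and an analytic
posterior check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylolex as px
from phylolex.likelihood import LikelihoodConfig, ModelState, compress_matrix
from phylolex.mcmc import MCMCConfig, _TreeAgeScale, run_mcmc, weighted_delta_exchange
from phylolex.simulate import PriorConfig, draw_from_priors, sample_partition_rates
from phylolex.trees import simulate_yule_tree
from tests.conftest import unit_clock


def _init_from(truth):
    return ModelState(
        tree=truth.tree.copy(),
        branch_rates=truth.clock.branch_rates.copy(),
        birth_rate=truth.birth_rate,
        alpha=truth.covarion.alpha,
        switch_rate=truth.covarion.s,
        pi_present=float(truth.covarion.pi_obs[1]),
        clock_sigma=max(truth.clock.sigma, 1e-6),
        m=truth.rates.m.copy(),
    )


def test_delta_exchange_preserves_weighted_sum(rng):
    w = np.array([10.0, 1.0, 1.0])
    m = sample_partition_rates(1.0, w, rng).m
    for _ in range(200):
        res = weighted_delta_exchange(m, w, 0.3, rng)
        if res is None:
            continue
        m2, lhr = res
        assert lhr == 0.0
        assert np.sum(w * m2) == pytest.approx(np.sum(w * m), abs=1e-12)
        m = m2


def test_equal_weight_delta_exchange_is_plain(rng):
    m = np.array([1.0, 1.0])
    res = None
    while res is None:
        res = weighted_delta_exchange(m, np.ones(2), 0.2, rng)
    m2, _ = res
    assert m2.sum() == pytest.approx(2.0, abs=1e-12)
    assert abs(m2[0] - 1.0) == pytest.approx(abs(m2[1] - 1.0), abs=1e-12)


def test_delta_exchange_requires_two_partitions(rng):
    with pytest.raises(ValueError):
        weighted_delta_exchange(np.array([1.0]), np.array([1.0]), 0.1, rng)


def test_prior_only_mcmc_recovers_priors():
    """Sampling with the likelihood disabled reproduces every prior marginal
    (two-sample KS against the direct generator)."""
    rng = np.random.default_rng(42)
    priors = PriorConfig()
    w = np.ones(2)
    truth = draw_from_priors(priors, 6, w, rng)
    cfg = MCMCConfig(chain_length=80000, sample_every=20, tree_mode="sampled")
    trace = run_mcmc(None, priors, LikelihoodConfig(weights=w), cfg, _init_from(truth), rng)
    df = trace.burned()
    direct = pd.DataFrame(
        [draw_from_priors(priors, 6, w, rng).scalar_summary() for _ in range(3000)]
    )
    for p in ["birth_rate", "alpha", "switch_rate", "pi_present", "clock_sigma",
              "m_1", "tree_height", "tree_length", "mean_branch_rate"]:
        ks = stats.ks_2samp(df[p].to_numpy()[::8], direct[p].to_numpy())
        assert ks.pvalue > 0.005, f"{p}: prior not recovered (KS p={ks.pvalue:.2e})"


def test_weighted_prior_mcmc_matches_constructive_sampler():
    """Prior-only MCMC under delta-exchange weights (10,1,1) reproduces the
    weighted-Dirichlet construction's marginal moments."""
    rng = np.random.default_rng(7)
    priors = PriorConfig()
    w = np.array([10.0, 1.0, 1.0])
    truth = draw_from_priors(priors, 5, w, rng)
    cfg = MCMCConfig(chain_length=60000, sample_every=10, tree_mode="sampled")
    trace = run_mcmc(None, priors, LikelihoodConfig(weights=w), cfg, _init_from(truth), rng)
    df = trace.burned()
    direct = np.array([sample_partition_rates(1.0, w, rng).m for _ in range(8000)])
    for i in range(3):
        got = df[f"m_{i+1}"].to_numpy()
        assert got.mean() == pytest.approx(direct[:, i].mean(), abs=0.12 * max(1, direct[:, i].mean()))
        assert got.std() == pytest.approx(direct[:, i].std(), rel=0.25)


def test_two_tip_posterior_matches_grid():
    """Two tips, fixed substitution parameters: the MCMC posterior of the
    root age matches numerical integration on a fine grid."""
    rng = np.random.default_rng(3)
    lam = 0.4
    priors = PriorConfig(clock_rate=0.5)  # fast clock: short tree, informative data
    tree = simulate_yule_tree(lam, 2, rng)
    clock = unit_clock(tree, mu=priors.clock_rate)
    params = px.CovarionParams(alpha=1.0, s=1.0, pi_obs=np.array([0.5, 0.5]))
    n_cols = 400
    from phylolex.simulate import simulate_partition
    from phylolex.cognates import CognateMatrix

    vals = simulate_partition(tree, clock, params, 1.0, n_cols, rng)
    cols = [f"c{i}" for i in range(n_cols)]
    mat = CognateMatrix(list(tree.tip_labels), cols, vals, {c: "x" for c in cols})
    pdata = compress_matrix(mat, ["x"])

    # grid posterior over root age h: yule density * pattern likelihood
    from phylolex.likelihood import data_log_likelihood

    def loglik_at(h):
        t = tree.copy()
        t.ages[t.root] = h
        return data_log_likelihood(pdata, t, clock, params, np.array([1.0]), correction=False)

    grid = np.linspace(0.005, 2.5, 1000)
    logpost = np.array([-2 * lam * h + loglik_at(h) for h in grid])
    post = np.exp(logpost - logpost.max())
    post /= np.trapezoid(post, grid)
    cdf = np.concatenate([[0], np.cumsum((post[1:] + post[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]

    # MCMC with only the root-age move, everything else held fixed
    state = ModelState(
        tree=tree.copy(),
        branch_rates=np.ones(tree.n_nodes),
        birth_rate=lam,
        alpha=1.0,
        switch_rate=1.0,
        pi_present=0.5,
        clock_sigma=1e-6,
        m=np.array([1.0]),
    )
    # pin the hyperpriors by holding every parameter except the tree fixed
    cfg = MCMCConfig(chain_length=40000, sample_every=10, tree_mode="sampled")
    ops = [_TreeAgeScale(1.0, 0.3)]
    lik_cfg = LikelihoodConfig(ascertainment_correction=False, weights=np.ones(1))
    trace = run_mcmc(pdata, priors, lik_cfg, cfg, state, rng, operators=ops)
    heights = trace.burned()["tree_height"].to_numpy()

    # compare posterior quantiles with the grid CDF
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        h_q = np.quantile(heights, q)
        cdf_at = np.interp(h_q, grid, cdf)
        assert cdf_at == pytest.approx(q, abs=0.06)


def test_fixed_seed_reproducibility():
    rng_a = np.random.default_rng(11)
    rng_b = np.random.default_rng(11)
    priors = PriorConfig()
    w = np.ones(2)
    truth_a = draw_from_priors(priors, 5, w, rng_a)
    truth_b = draw_from_priors(priors, 5, w, rng_b)
    cfg = MCMCConfig(chain_length=2000, sample_every=10)
    ta = run_mcmc(None, priors, LikelihoodConfig(weights=w), cfg, _init_from(truth_a), rng_a)
    tb = run_mcmc(None, priors, LikelihoodConfig(weights=w), cfg, _init_from(truth_b), rng_b)
    pd.testing.assert_frame_equal(ta.samples, tb.samples)


def test_trace_tsv_round_trip(tmp_path, rng):
    priors = PriorConfig()
    w = np.ones(2)
    truth = draw_from_priors(priors, 5, w, rng)
    cfg = MCMCConfig(chain_length=1000, sample_every=10)
    trace = run_mcmc(None, priors, LikelihoodConfig(weights=w), cfg, _init_from(truth), rng)
    out = tmp_path / "trace.log"
    trace.write_tsv(out)
    back = pd.read_csv(out, sep="\t")
    assert "Sample" in back.columns
    assert len(back) == len(trace.samples)
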