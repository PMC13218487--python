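"""HPD, coverage, rank statistics, ESS and the reliability diagram."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylolex.diagnostics import (
    SBCReplicate,
    binned_cep,
    clade_reliability,
    coverage,
    ecdf_difference,
    ess,
    hpd_interval,
    pit_ranks,
    pool_clade_tables,
)


# -- HPD --------------------------------------------------------------------


def test_hpd_uniform_grid():
    lo, hi = hpd_interval(np.arange(1, 101), mass=0.95)
    assert hi - lo == 94  # 95 samples in the shortest window
    assert lo >= 1 and hi <= 100


def test_hpd_degenerate_and_normal(rng):
    assert hpd_interval(np.full(50, 3.2)) == (3.2, 3.2)
    x = rng.standard_normal(100000)
    lo, hi = hpd_interval(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)
    with pytest.raises(ValueError):
        hpd_interval(np.array([1.0]))


# -- coverage ---------------------------------------------------------------


def _toy_replicates(rng, n=200, calibrated=True):
    reps = []
    for _ in range(n):
        mu = rng.standard_normal()
        draws = mu + rng.standard_normal(400)
        truth = mu + (rng.standard_normal() if calibrated else 3.0)
        reps.append(
            SBCReplicate(true_values={"theta": truth}, draws=pd.DataFrame({"theta": draws}))
        )
    return reps


def test_coverage_calibrated(rng):
    frac, (lo, hi) = coverage(_toy_replicates(rng), "theta")
    assert lo <= 0.95 <= hi
    assert abs(frac - 0.95) < 0.05


def test_coverage_truth_at_median(rng):
    reps = []
    for _ in range(50):
        draws = rng.standard_normal(200)
        reps.append(
            SBCReplicate(true_values={"theta": float(np.median(draws))},
                         draws=pd.DataFrame({"theta": draws}))
        )
    frac, _ = coverage(reps, "theta", mass=0.5)
    assert frac == 1.0


def test_coverage_unknown_parameter(rng):
    with pytest.raises(KeyError):
        coverage(_toy_replicates(rng, n=3), "nope")


# -- PIT ranks --------------------------------------------------------------


def test_pit_extremes(rng):
    draws = pd.DataFrame({"x": np.linspace(1, 2, 200)})
    below = SBCReplicate(true_values={"x": 0.0}, draws=draws)
    above = SBCReplicate(true_values={"x": 5.0}, draws=draws)
    pit, ls = pit_ranks([below, above], "x", L=100, rng=rng)
    assert pit[0] == 0.0 and pit[1] == 1.0
    assert np.all(ls == 100)


def test_pit_self_consistency(rng):
    """Truth and draws from the same distribution give uniform ranks
    (chi-square over many replicates)."""
    reps = []
    for _ in range(4000):
        draws = rng.standard_normal(100)
        reps.append(
            SBCReplicate(true_values={"x": float(rng.standard_normal())},
                         draws=pd.DataFrame({"x": draws}))
        )
    pit, _ = pit_ranks(reps, "x", L=20, rng=rng)
    counts, _ = np.histogram(pit, bins=np.linspace(0, 1.0000001, 8))
    chi2 = ((counts - len(pit) / 7) ** 2 / (len(pit) / 7)).sum()
    assert stats.chi2(6).sf(chi2) > 0.01


def test_pit_invariant_under_monotone_transform(rng):
    reps_raw, reps_log = [], []
    for _ in range(50):
        draws = np.exp(rng.standard_normal(150))
        truth = float(np.exp(rng.standard_normal()))
        reps_raw.append(SBCReplicate(true_values={"x": truth}, draws=pd.DataFrame({"x": draws})))
        reps_log.append(SBCReplicate(true_values={"x": np.log(truth)}, draws=pd.DataFrame({"x": np.log(draws)})))
    a, _ = pit_ranks(reps_raw, "x", L=50, rng=np.random.default_rng(0))
    b, _ = pit_ranks(reps_log, "x", L=50, rng=np.random.default_rng(0))
    assert np.allclose(a, b)


# -- ECDF difference bands --------------------------------------------------


def test_ecdf_uniform_grid_passes(rng):
    ranks = (np.arange(50) + 0.5) / 50
    res = ecdf_difference(ranks, L=50, rng=rng)
    assert res.passed
    assert np.abs(res.diff).max() < 0.03


def test_ecdf_detects_systematic_bias(rng):
    ranks = rng.uniform(0, 0.45, size=60)  # truth always in the lower half
    res = ecdf_difference(ranks, L=100, rng=rng)
    assert not res.passed
    assert res.diff.max() > 0.3


def test_ecdf_band_calibration(rng):
    """Under uniformity ~5% of independent rank sets cross the 95% bands."""
    n, L = 40, 100
    ref = ecdf_difference(rng.integers(0, L + 1, n) / L, L=L, n_mc=4000, rng=rng)
    fails = 0
    trials = 800
    for _ in range(trials):
        ranks = rng.integers(0, L + 1, n) / L
        diff = (ranks[None, :] <= ref.grid[:, None]).mean(axis=1) - ref.grid
        fails += not np.all((diff >= ref.lower - 1e-12) & (diff <= ref.upper + 1e-12))
    rate = fails / trials
    assert 0.02 < rate < 0.09


# -- ESS --------------------------------------------------------------------


def test_ess_iid(rng):
    x = rng.standard_normal(30000)
    assert ess(x) == pytest.approx(30000, rel=0.10)


def test_ess_ar1(rng):
    rho = 0.9
    n = 40000
    x = np.empty(n)
    x[0] = 0
    noise = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + noise[i]
    expected = n * (1 - rho) / (1 + rho)
    assert ess(x) == pytest.approx(expected, rel=0.2)


def test_ess_duplicated_chain(rng):
    x = rng.standard_normal(2000)
    doubled = np.repeat(x, 2)
    assert ess(doubled) == pytest.approx(2000, rel=0.25)


def test_ess_constant_chain_warns():
    with pytest.warns(UserWarning, match="constant"):
        assert ess(np.full(100, 2.0)) == 100.0


def test_ess_agrees_with_arviz(rng):
    arviz = pytest.importorskip("arviz")
    rho = 0.8
    n = 20000
    x = np.empty(n)
    x[0] = 0
    noise = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + noise[i]
    ours = ess(x)
    theirs = float(arviz.ess(x))
    assert ours == pytest.approx(theirs, rel=0.3)


# -- reliability ------------------------------------------------------------


def test_pav_matches_hand_computation():
    """Six-point toy: isotonic regression means computed by hand with the
    pool-adjacent-violators algorithm."""
    support = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    y = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 1.0])
    # PAV by hand: blocks {0}, {1,2,3} -> 1/3, {4}, {5} => [0, 1/3, 1/3, 1/3, 1, 1]
    res = clade_reliability(support, y, n_boot=10, rng=np.random.default_rng(0))
    got = [res.cep_at(s) for s in support]
    assert np.allclose(got, [0, 1 / 3, 1 / 3, 1 / 3, 1, 1], atol=1e-9)


def test_reliability_diagonal_when_calibrated(rng):
    p = rng.uniform(0.05, 0.95, 6000)
    y = (rng.uniform(size=6000) < p).astype(float)
    res = clade_reliability(p, y, n_boot=50, rng=rng)
    assert res.cep_at(0.6) == pytest.approx(0.6, abs=0.07)
    assert res.cep_at(0.3) == pytest.approx(0.3, abs=0.07)
    cep, n = binned_cep(p, y, 0.6)
    assert n > 0 and cep == pytest.approx(0.6, abs=0.08)


def test_reliability_all_wrong(rng):
    p = rng.uniform(0, 1, 500)
    res = clade_reliability(p, np.zeros(500), n_boot=10, rng=rng)
    assert np.all(res.cep == 0)


def test_pool_clade_tables_requires_trees(rng):
    rep = SBCReplicate(true_values={}, draws=pd.DataFrame({"x": [1.0]}))
    with pytest.raises(ValueError, match="clade"):
        pool_clade_tables([rep])
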