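"""Calibration diagnostics for simulation-based calibration (SBC).

For each replicate the generating ('true') parameter values are compared with
the posterior sample inferred from the data they generated: a well-calibrated
analysis puts the truth inside the 95% HPD interval ~95% of the time
(coverage) and ranks it uniformly among near-independent posterior draws
(rank-uniformity / PIT, visualised as an ECDF difference curve with
Monte-Carlo-calibrated simultaneous bands).  Clade support is checked with a
reliability diagram: the conditional event probability (CEP) that a clade
with posterior support p is in the true tree should be ~p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression


@dataclass
class SBCReplicate:
    """One replicate's truth, posterior draws and clade table."""

    true_values: dict[str, float]
    draws: pd.DataFrame  # post-burn-in scalar draws
    ess: dict[str, float] = field(default_factory=dict)
    clade_posterior: dict[int, float] | None = None  # bitmask -> support
    true_clades: set[int] | None = None


# ---------------------------------------------------------------------------
# effective sample size


def ess(chain: np.ndarray) -> float:
    """Autocorrelation ESS: N / (1 + 2 sum rho_k), with Geyer's
    initial-positive-sequence truncation of the paired autocorrelations.

    A constant chain carries no information about mixing; it is reported as N
    with a warning.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    v = np.mean(x * x)
    if v == 0:
        warnings.warn("constant chain: ESS undefined, reporting N")
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    tau = 0.0
    for m in range(n // 2):
        g = rho[2 * m] + rho[2 * m + 1] if 2 * m + 1 < n else rho[2 * m]
        if g <= 0:
            break
        tau += g
    tau = max(2.0 * tau - 1.0, 1.0)
    return float(n / tau)


# ---------------------------------------------------------------------------
# HPD and coverage


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass*N) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least two samples for an HPD interval")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def coverage(
    replicates: list[SBCReplicate], parameter: str, mass: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of replicates whose HPD contains the truth, with the exact
    (Clopper-Pearson) binomial confidence interval."""
    hits = 0
    n = 0
    for rep in replicates:
        if parameter not in rep.draws.columns:
            raise KeyError(f"parameter {parameter!r} absent from trace")
        lo, hi = hpd_interval(rep.draws[parameter].to_numpy(), mass)
        t = rep.true_values[parameter]
        hits += int(lo <= t <= hi)
        n += 1
    if n == 0:
        raise ValueError("no replicates")
    ci = stats.binomtest(hits, n).proportion_ci(confidence_level=0.95, method="exact")
    return hits / n, (float(ci.low), float(ci.high))


# ---------------------------------------------------------------------------
# rank statistics


def _thin_indices(n: int, target: int, chain_ess: float) -> np.ndarray:
    """Indices of ~``target`` draws spaced at least n/ESS apart."""
    min_spacing = max(1, int(np.ceil(n / max(chain_ess, 1.0))))
    spacing = max(min_spacing, n // target)
    idx = np.arange(n - 1, -1, -spacing)[::-1]
    return idx[-target:] if len(idx) > target else idx


def pit_ranks(
    replicates: list[SBCReplicate],
    parameter: str,
    L: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised rank (rank / L) of the truth among L thinned posterior
    draws, per replicate; ties broken uniformly at random.

    Returns (pit values, per-replicate L actually used).  Draws are thinned to
    at most ``L`` values spaced ≥ trace_length/ESS apart so that ranks are
    computed over near-independent draws.
    """
    rng = rng or np.random.default_rng(0)
    if L < 10:
        warnings.warn("L < 10 gives very coarse ranks")
    pit = np.empty(len(replicates))
    l_used = np.empty(len(replicates), dtype=int)
    for r, rep in enumerate(replicates):
        x = rep.draws[parameter].to_numpy()
        e = rep.ess.get(parameter, float(len(x)))
        idx = _thin_indices(len(x), L, e)
        d = x[idx]
        t = rep.true_values[parameter]
        below = int(np.sum(d < t))
        ties = int(np.sum(d == t))
        rank = below + (rng.integers(0, ties + 1) if ties else 0)
        pit[r] = rank / len(d)
        l_used[r] = len(d)
    return pit, l_used


@dataclass
class ECDFResult:
    grid: np.ndarray
    diff: np.ndarray  # ECDF(z) - z
    lower: np.ndarray
    upper: np.ndarray
    passed: bool
    pointwise_level: float


def ecdf_difference(
    ranks: np.ndarray,
    L: int | np.ndarray = 100,
    level: float = 0.95,
    n_mc: int = 2000,
    rng: np.random.Generator | None = None,
) -> ECDFResult:
    """ECDF of the PIT values minus the uniform diagonal, with simultaneous
    confidence bands calibrated by Monte Carlo under rank uniformity.

    Bands are pointwise quantile envelopes whose pointwise level is tuned (by
    bisection over the Monte-Carlo sample of uniform-rank curves) so that the
    *simultaneous* non-crossing probability equals ``level``.  ``L`` may be a
    scalar or per-replicate vector of rank resolutions.
    """
    rng = rng or np.random.default_rng(0)
    ranks = np.asarray(ranks, dtype=float)
    n = len(ranks)
    ls = np.full(n, L) if np.isscalar(L) else np.asarray(L, dtype=int)
    grid = np.linspace(0.0, 1.0, 41)[1:-1]
    diff = (ranks[None, :] <= grid[:, None]).mean(axis=1) - grid

    # uniform-rank reference curves
    sims = np.empty((n_mc, len(grid)))
    u = rng.integers(0, ls[None, :] + 1, size=(n_mc, n)) / ls[None, :]
    sims = (u[:, None, :] <= grid[None, :, None]).mean(axis=2) - grid[None, :]

    def bands(gamma: float) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(sims, gamma / 2, axis=0)
        hi = np.quantile(sims, 1 - gamma / 2, axis=0)
        return lo, hi

    def simultaneous(gamma: float) -> float:
        lo, hi = bands(gamma)
        inside = np.all((sims >= lo - 1e-12) & (sims <= hi + 1e-12), axis=1)
        return inside.mean()

    g_lo, g_hi = 1e-4, 1.0 - level
    for _ in range(30):
        g_mid = 0.5 * (g_lo + g_hi)
        if simultaneous(g_mid) >= level:
            g_lo = g_mid
        else:
            g_hi = g_mid
    lower, upper = bands(g_lo)
    passed = bool(np.all((diff >= lower - 1e-12) & (diff <= upper + 1e-12)))
    return ECDFResult(grid, diff, lower, upper, passed, 1.0 - g_lo)


# ---------------------------------------------------------------------------
# clade reliability


@dataclass
class ReliabilityResult:
    support_grid: np.ndarray
    cep: np.ndarray  # isotonic (PAV) estimate of P(in true tree | support)
    lower: np.ndarray
    upper: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    _iso: IsotonicRegression | None = None

    def cep_at(self, support: float) -> float:
        return float(self._iso.predict([support])[0])


def pool_clade_tables(replicates: list[SBCReplicate]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (posterior support, in-true-tree flag) arrays over replicates."""
    p, y = [], []
    for rep in replicates:
        if rep.clade_posterior is None or rep.true_clades is None:
            raise ValueError("replicate carries no clade table (fixed-tree trace)")
        for clade, prob in rep.clade_posterior.items():
            p.append(prob)
            y.append(1.0 if clade in rep.true_clades else 0.0)
    return np.asarray(p), np.asarray(y)


def clade_reliability(
    support: np.ndarray,
    in_true: np.ndarray,
    n_bins: int = 10,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> ReliabilityResult:
    """CORP-style reliability diagram: isotonic (pool-adjacent-violators)
    regression of true-tree membership on posterior support, with bootstrap
    consistency bands and a binned histogram of support values."""
    rng = rng or np.random.default_rng(0)
    support = np.asarray(support, dtype=float)
    in_true = np.asarray(in_true, dtype=float)
    if len(support) == 0:
        raise ValueError("no clades to pool")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(support, in_true)
    grid = np.linspace(0.0, 1.0, 101)
    cep = iso.predict(grid)
    boot = np.empty((n_boot, len(grid)))
    n = len(support)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        ib = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        ib.fit(support[idx], in_true[idx])
        boot[b] = ib.predict(grid)
    lower = np.quantile(boot, 0.05, axis=0)
    upper = np.quantile(boot, 0.95, axis=0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(support, bins=edges)
    return ReliabilityResult(grid, cep, lower, upper, edges, counts, _iso=iso)


def binned_cep(
    support: np.ndarray, in_true: np.ndarray, center: float, half_width: float = 0.1
) -> tuple[float, int]:
    """Empirical CEP in the support bin ``center ± half_width``."""
    support = np.asarray(support, dtype=float)
    in_true = np.asarray(in_true, dtype=float)
    sel = (support >= center - half_width) & (support <= center + half_width)
    if not np.any(sel):
        return float("nan"), 0
    return float(in_true[sel].mean()), int(sel.sum())
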