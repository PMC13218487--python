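"""Ascertainment-corrected covarion likelihood.

Binary tip data are pruned over the four covarion states (observed 0 is
compatible with {absent-fast, absent-slow}, observed 1 with the present
states), marginalising the hidden rate class exactly.  Site patterns are
compressed per partition before pruning, and per-node rescaling keeps the
computation in a safe floating range at low rates.

Ascertainment bias: cognate sets absent in every language cannot be observed,
so each observed pattern probability is renormalised by
``1 - Pr(all-absent)``, with the all-absent probability computed under the
same tree, clock and substitution parameters (once per partition per
evaluation — it does not depend on the data columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cognates import CognateMatrix, MISSING
from .covarion import (
    CovarionParams,
    TIP_PARTIALS,
    TransitionKernel,
    build_q_matrix,
    root_frequencies,
)
from .simulate import (
    ClockModel,
    PriorConfig,
    effective_branch_lengths,
    log_branch_rates_prior,
    log_partition_rates_prior,
)
from .trees import TimeTree, log_yule_density


@dataclass
class LikelihoodConfig:
    ascertainment_correction: bool = True
    weights: np.ndarray | None = None  # partition weights (prior + operator)
    normalize_q: bool = True

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)


@dataclass
class PartitionedData:
    """Site-pattern-compressed data, one block per partition."""

    names: list[str]
    patterns: list[np.ndarray]  # (npat, ntips) int8 each
    counts: list[np.ndarray]
    n_columns: np.ndarray
    tip_labels: list[str]
    _padded: tuple | None = None

    @property
    def k(self) -> int:
        return len(self.names)

    def padded(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patterns padded to a common width for batched pruning.

        Returns (tip_partials (k, npat_max, ntips, 4), counts (k, npat_max),
        absent_idx (k,)).  Each partition's block ends with the all-absent
        pattern (index ``absent_idx``, needed for the ascertainment term);
        padding rows are all-absent with zero count.
        """
        if self._padded is None:
            k = self.k
            ntips = self.patterns[0].shape[1]
            npat_max = max(p.shape[0] for p in self.patterns) + 1
            tp = np.zeros((k, npat_max, ntips), dtype=np.int8)
            counts = np.zeros((k, npat_max))
            absent = np.empty(k, dtype=int)
            for i, (p, c) in enumerate(zip(self.patterns, self.counts)):
                tp[i, : p.shape[0]] = p
                counts[i, : p.shape[0]] = c
                absent[i] = p.shape[0]
            partials = TIP_PARTIALS[tp]  # (k, npat_max, ntips, 4)
            self._padded = (partials, counts, absent)
        return self._padded


def compress_matrix(
    m: CognateMatrix, partition_names: list[str] | None = None
) -> PartitionedData:
    """Collapse identical columns into unique patterns with counts."""
    if m.has_missing():
        raise ValueError("missing data is not supported by the likelihood")
    names = partition_names or m.meanings
    patterns, counts, ncols = [], [], []
    for nm in names:
        idx = m.column_indices(nm)
        if len(idx) == 0:
            raise ValueError(f"partition {nm!r} has no columns")
        cols = m.values[:, idx].T  # (ncols, ntips)
        uniq, cnt = np.unique(cols, axis=0, return_counts=True)
        patterns.append(uniq.astype(np.int8))
        counts.append(cnt.astype(float))
        ncols.append(len(idx))
    return PartitionedData(list(names), patterns, counts, np.array(ncols), list(m.languages))


def prune_log_pattern_probabilities(
    tree: TimeTree,
    p_mats: np.ndarray,
    tip_patterns: np.ndarray,
    root_p: np.ndarray,
) -> np.ndarray:
    """Felsenstein pruning: log probability of each pattern (rows of
    ``tip_patterns``, shape (npat, ntips)) given per-node transition matrices
    ``p_mats`` (n_nodes, 4, 4)."""
    npat = tip_patterns.shape[0]
    n_nodes = tree.n_nodes
    partial = np.empty((n_nodes, npat, 4))
    for t in range(tree.n_tips):
        partial[t] = TIP_PARTIALS[tip_patterns[:, t]]
    logscale = np.zeros(npat)
    for v in tree.postorder():
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        partial[v] = (partial[c1] @ p_mats[c1].T) * (partial[c2] @ p_mats[c2].T)
        # rescale only when values approach the underflow range
        if partial[v].max() < 1e-220:
            s = partial[v].max(axis=1)
            s[s == 0] = 1.0  # zero-probability pattern; log handled at root
            partial[v] /= s[:, None]
            logscale += np.log(s)
    pr = partial[tree.root] @ root_p
    with np.errstate(divide="ignore"):
        return np.log(pr) + logscale


def pattern_log_probability(
    pattern: np.ndarray,
    tree: TimeTree,
    clock: ClockModel,
    params: CovarionParams,
    m_partition: float = 1.0,
) -> float:
    """Log probability of one observed 0/1 pattern across the tips."""
    pattern = np.asarray(pattern)
    if np.any(pattern == MISSING):
        raise ValueError("missing data is not supported")
    kernel = TransitionKernel(build_q_matrix(params, normalize=True).q)
    p_mats = kernel(effective_branch_lengths(tree, clock, m_partition))
    logp = prune_log_pattern_probabilities(
        tree, p_mats, pattern[None, :], root_frequencies(params)
    )
    return float(logp[0])


def corrected_partition_log_likelihood(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: TimeTree,
    clock: ClockModel,
    params: CovarionParams,
    m_i: float,
    correction: bool = True,
    kernel: TransitionKernel | None = None,
    base_lengths: np.ndarray | None = None,
) -> float:
    """Sum over columns of log Pr(x) - log(1 - Pr(all-absent)) (the correction
    term applied once per column), or plain sum when ``correction=False``.

    ``base_lengths`` optionally supplies precomputed duration*mu*branch_rate
    products (shared across partitions)."""
    if kernel is None:
        kernel = TransitionKernel(build_q_matrix(params, normalize=True).q)
    root_p = root_frequencies(params)
    if base_lengths is None:
        p_mats = kernel(effective_branch_lengths(tree, clock, m_i))
    else:
        p_mats = kernel(base_lengths * m_i, check=False)
    if correction:
        aug = np.vstack([patterns, np.zeros((1, patterns.shape[1]), dtype=np.int8)])
        logp = prune_log_pattern_probabilities(tree, p_mats, aug, root_p)
        log_p_absent = logp[-1]
        if log_p_absent > -1e-10:
            raise FloatingPointError("Pr(all-absent) numerically at 1; degenerate model")
        denom = np.log1p(-np.exp(log_p_absent))
        return float(np.sum(counts * (logp[:-1] - denom)))
    logp = prune_log_pattern_probabilities(tree, p_mats, patterns, root_p)
    return float(np.sum(counts * logp))


def data_log_likelihood(
    data: PartitionedData,
    tree: TimeTree,
    clock: ClockModel,
    params: CovarionParams,
    m: np.ndarray,
    correction: bool = True,
) -> float:
    """Joint log likelihood over all partitions (shared substitution model,
    partition-specific branch-length multipliers).

    Partitions are pruned in one batched pass: transition matrices for every
    (partition, branch) pair come from a single spectral evaluation, and the
    postorder recursion runs over a partition axis.
    """
    kernel = TransitionKernel(build_q_matrix(params, normalize=True).q)
    base = tree.durations() * clock.mu * clock.branch_rates
    m = np.asarray(m, dtype=float)
    k = data.k
    n_nodes = tree.n_nodes
    ts = np.outer(m, base)  # (k, n_nodes)
    p_mats = kernel(ts.ravel(), check=False).reshape(k, n_nodes, 4, 4)
    tip_partials, counts, absent_idx = data.padded()
    npat = tip_partials.shape[1]
    partial = np.empty((n_nodes, k, npat, 4))
    for t in range(tree.n_tips):
        partial[t] = tip_partials[:, :, t]
    logscale = np.zeros((k, npat))
    for v in tree.postorder():
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        a = partial[c1] @ p_mats[:, c1].transpose(0, 2, 1)
        b = partial[c2] @ p_mats[:, c2].transpose(0, 2, 1)
        np.multiply(a, b, out=partial[v])
        if partial[v].max() < 1e-220:
            s = partial[v].max(axis=2)
            s[s == 0] = 1.0
            partial[v] /= s[:, :, None]
            logscale += np.log(s)
    root_p = root_frequencies(params)
    pr = partial[tree.root] @ root_p  # (k, npat)
    with np.errstate(divide="ignore"):
        logp = np.log(pr) + logscale
    rows = np.arange(k)
    log_absent = logp[rows, absent_idx]
    total = float(np.sum(counts * np.where(counts > 0, logp, 0.0)))
    if correction:
        if log_absent.max() > -1e-10:
            raise FloatingPointError("Pr(all-absent) numerically at 1; degenerate model")
        denom = np.log1p(-np.exp(log_absent))  # (k,)
        total -= float(np.sum(data.n_columns * denom))
    return total


# ---------------------------------------------------------------------------
# joint model state and posterior density


@dataclass
class ModelState:
    """A full MCMC state of the phylolinguistic model."""

    tree: TimeTree
    branch_rates: np.ndarray  # per node (root entry unused, kept at 1)
    birth_rate: float
    alpha: float
    switch_rate: float
    pi_present: float
    clock_sigma: float
    m: np.ndarray

    def covarion(self) -> CovarionParams:
        return CovarionParams.unchecked(self.alpha, self.switch_rate, self.pi_present)

    def clock(self, mu: float) -> ClockModel:
        return ClockModel(mu=mu, sigma=max(self.clock_sigma, 1e-12), branch_rates=self.branch_rates)

    def copy(self) -> "ModelState":
        return ModelState(
            tree=self.tree.copy(),
            branch_rates=self.branch_rates.copy(),
            birth_rate=self.birth_rate,
            alpha=self.alpha,
            switch_rate=self.switch_rate,
            pi_present=self.pi_present,
            clock_sigma=self.clock_sigma,
            m=self.m.copy(),
        )


def log_prior(state: ModelState, priors: PriorConfig, weights: np.ndarray) -> float:
    """Joint log prior: Yule tree (given birth rate) + hyperpriors +
    lognormal branch rates + weighted-Dirichlet partition rates."""
    if not (
        priors.alpha_lo <= state.alpha <= priors.alpha_hi
        and state.switch_rate > 0
        and 0 < state.pi_present < 1
        and state.clock_sigma > 0
        and state.birth_rate > 0
        and np.all(state.m > 0)
    ):
        return -np.inf
    lp = log_yule_density(state.tree, state.birth_rate)
    lp += priors.log_hyperprior("birth_rate", state.birth_rate)
    lp += priors.log_hyperprior("alpha", state.alpha)
    lp += priors.log_hyperprior("switch_rate", state.switch_rate)
    lp += priors.log_hyperprior("pi_present", state.pi_present)
    lp += priors.log_hyperprior("clock_sigma", state.clock_sigma)
    non_root = np.flatnonzero(state.tree.parent >= 0)
    lp += log_branch_rates_prior(state.branch_rates[non_root], state.clock_sigma)
    lp += log_partition_rates_prior(state.m, weights, priors.dirichlet_alpha)
    return lp


def log_posterior(
    state: ModelState,
    data: PartitionedData | None,
    priors: PriorConfig,
    cfg: LikelihoodConfig,
    power: float = 1.0,
) -> tuple[float, float]:
    """(log prior, log likelihood) of a state; ``data=None`` or ``power=0``
    skips the likelihood (prior-only sampling / path-sampling endpoint).
    Out-of-support states return ``-inf`` prior."""
    weights = cfg.weights if cfg.weights is not None else np.ones(len(state.m))
    lp = log_prior(state, priors, weights)
    if not np.isfinite(lp):
        return -np.inf, 0.0
    if data is None or power == 0.0:
        return lp, 0.0
    try:
        ll = data_log_likelihood(
            data,
            state.tree,
            state.clock(priors.clock_rate),
            state.covarion(),
            state.m,
            correction=cfg.ascertainment_correction,
        )
    except FloatingPointError:
        return -np.inf, 0.0
    return lp, ll
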